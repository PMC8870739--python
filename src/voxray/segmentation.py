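"""Four-class segmentation of pendant-breast CT intensity volumes.

Each coronal slice (constant z, perpendicular to the pendant axis) is
classified into air / skin / glandular / adipose tissue:

1. the breast mask is found by thresholding against the air background and
   filling holes;
2. skin is the boundary band selected by a local adaptive threshold (local
   window mean plus offset), limited to a maximum anatomical depth from the
   breast surface (a thin guaranteed rind at the surface is always skin);
3. glandular tissue is an intensity threshold inside the skin border,
   cleaned by binary erosion and hole filling;
4. the remaining interior voxels are adipose.

A final through-plane pass (erosion + hole filling along the pendant axis)
is applied to the 3D glandular mask so glandular structures are seamless
across coronal slices.

The numeric defaults below are this package's own; the procedure has the
above structure but published descriptions of it give no parameter values.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .materials import get_material
from .phantoms import (HUVolume, LabelVolume, LABEL_ADIPOSE, LABEL_AIR,
                       LABEL_GLANDULAR, LABEL_SKIN)


@dataclass
class SegmentationParams:
    """Tunable parameters of the breast-CT segmentation.

    All lengths in mm, intensities in the HU-like units of the input volume.
    """

    air_threshold: float = -500.0      # breast vs background
    skin_window_mm: float = 15.0       # adaptive-threshold window
    skin_offset: float = 60.0          # above local tissue mean -> skin
    max_skin_depth_mm: float = 3.0     # anatomical cap on skin depth
    min_skin_depth_mm: float = 2.0     # guaranteed surface rind
    gland_threshold: float = -45.0     # glandular vs adipose intensity
    erosion_iterations: int = 1
    through_plane_iterations: int = 1


def segment_breast_ct(volume: HUVolume,
                      params: SegmentationParams | None = None
                      ) -> LabelVolume:
    """Classify a pendant-breast HU volume into air/adipose/gland/skin."""
    p = params or SegmentationParams()
    vals = np.asarray(volume.values, dtype=float)
    nx, ny, nz = vals.shape
    dx = volume.voxel_size[0]
    labels = np.zeros(vals.shape, dtype=np.uint8)

    window_vox = max(3, int(round(p.skin_window_mm / dx)) | 1)
    breast3d = np.zeros(vals.shape, dtype=bool)
    for k in range(nz):
        breast3d[:, :, k] = ndimage.binary_fill_holes(
            vals[:, :, k] > p.air_threshold)
    # depth from the breast surface, in mm, measured in 3D so that the
    # dome cap (whose in-plane extent is large) is still a thin rind
    depth3d = ndimage.distance_transform_edt(
        breast3d, sampling=volume.voxel_size) if breast3d.any() else \
        np.zeros(vals.shape)
    for k in range(nz):  # coronal slices
        sl = vals[:, :, k]
        breast = breast3d[:, :, k]
        if not breast.any():
            continue
        depth = depth3d[:, :, k]
        # local mean over *tissue* only, so air outside the breast does not
        # drag the adaptive threshold down near the boundary
        w_sum = ndimage.uniform_filter(np.where(breast, sl, 0.0),
                                       size=window_vox)
        w_cnt = ndimage.uniform_filter(breast.astype(float),
                                       size=window_vox)
        local_mean = np.divide(w_sum, w_cnt, out=np.zeros_like(w_sum),
                               where=w_cnt > 0)
        skin = breast & (depth <= p.max_skin_depth_mm) \
            & ((sl > local_mean + p.skin_offset)
               | (depth <= p.min_skin_depth_mm))
        interior = breast & ~skin
        raw = interior & (sl > p.gland_threshold)
        gland = raw
        if p.erosion_iterations:
            # opening by reconstruction: erosion suppresses speckle, the
            # geodesic propagation restores the surviving structures
            eroded = ndimage.binary_erosion(
                raw, iterations=p.erosion_iterations, border_value=0)
            gland = ndimage.binary_propagation(eroded, mask=raw)
        gland = ndimage.binary_fill_holes(gland) & interior
        lab = labels[:, :, k]
        lab[skin] = LABEL_SKIN
        lab[interior] = LABEL_ADIPOSE
        lab[gland] = LABEL_GLANDULAR

    # through-plane pass: seamless glandular structure along the pendant axis
    gland3d = labels == LABEL_GLANDULAR
    interior3d = gland3d | (labels == LABEL_ADIPOSE)
    if p.through_plane_iterations and gland3d.any():
        line = np.zeros((1, 1, 3), dtype=bool)
        line[0, 0, :] = True
        eroded = ndimage.binary_erosion(
            gland3d, structure=line, iterations=p.through_plane_iterations,
            border_value=0)
        cleaned = ndimage.binary_propagation(eroded, mask=gland3d)
        cleaned = ndimage.binary_fill_holes(cleaned) & interior3d
        labels[gland3d & ~cleaned] = LABEL_ADIPOSE
        labels[cleaned] = LABEL_GLANDULAR

    material_map = {LABEL_AIR: get_material("air"),
                    LABEL_ADIPOSE: get_material("adipose"),
                    LABEL_GLANDULAR: get_material("glandular"),
                    LABEL_SKIN: get_material("skin")}
    return LabelVolume(volume.voxel_size, volume.origin, labels,
                       material_map)
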
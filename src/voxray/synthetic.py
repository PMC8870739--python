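"""Synthetic pendant-breast HU volumes with known ground truth.

Stand-in for clinical breast-CT scans: a half-ellipsoid pendant breast with
an elevated-intensity skin shell and an interior whose glandular structure is
carved from a correlated (Gaussian-filtered) random field, thresholded at
the quantile that realizes a requested glandular mass fraction.  The
generator returns both the HU volume and the ground-truth label volume, so
segmentation can be validated against a known answer.

This emulates the gross intensity structure of a breast CT scan (air
background, bright skin rind, blobby glandular texture); it does not attempt
realistic ligament/ductal anatomy.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage

from .materials import get_material
from .phantoms import (HUVolume, LabelVolume, LABEL_ADIPOSE, LABEL_AIR,
                       LABEL_GLANDULAR, LABEL_SKIN)

HU_AIR = -1000.0
HU_ADIPOSE = -120.0
HU_GLAND = 30.0
HU_SKIN = 60.0
HU_NOISE_SD = 12.0


def _gland_count_fraction(target_mass_fraction: float,
                          n_interior: int, n_skin: int) -> float:
    """Interior gland *count* fraction c such that the glandular mass share
    of the whole breast (skin included) equals the target."""
    rho_g = get_material("glandular").density
    rho_a = get_material("adipose").density
    rho_s = get_material("skin").density
    t = target_mass_fraction
    # solve c*Ni*rho_g = t * (c*Ni*rho_g + (1-c)*Ni*rho_a + Ns*rho_s)
    denom = n_interior * (rho_g * (1 - t) + t * rho_a)
    c = t * (n_interior * rho_a + n_skin * rho_s) / denom
    if not 0 <= c <= 1:
        raise ValueError("infeasible glandular fraction for this geometry")
    return c


def synth_breast_hu(height_mm: float = 60.0,
                    max_diameter_mm: float = 100.0,
                    skin_mm: float = 2.0,
                    target_gland_fraction: float = 0.17,
                    correlation_length_mm: float = 5.0,
                    seed: int = 0,
                    voxel_size_mm: float = 1.0,
                    ) -> tuple[HUVolume, LabelVolume]:
    """Generate a synthetic pendant-breast HU volume and its ground truth.

    The breast is a half ellipsoid with chest wall at z = 0 hanging to
    z = -height.  ``target_gland_fraction`` is the glandular mass fraction
    of the whole breast (skin included), realized exactly (up to one voxel)
    by quantile thresholding of the correlated interior field.
    """
    if not 0 <= target_gland_fraction < 1:
        raise ValueError("target gland fraction must be in [0, 1)")
    v = voxel_size_mm
    r = max_diameter_mm / 2.0
    if skin_mm >= r or height_mm <= skin_mm:
        raise ValueError("infeasible geometry")
    nx = ny = int(round(max_diameter_mm / v)) + 2
    nz = int(round(height_mm / v)) + 1
    x = (-(nx / 2) + np.arange(nx) + 0.5)[:, None, None] * v
    y = (-(ny / 2) + np.arange(ny) + 0.5)[None, :, None] * v
    z = (-(np.arange(nz)[::-1]) - 0.5)[None, None, :] * v  # z in (-h, 0)
    # ellipsoidal radius: 1 on the surface
    rho = np.sqrt((x / r) ** 2 + (y / r) ** 2 + (z / height_mm) ** 2)
    breast = rho <= 1.0
    # normalized depth from the surface, in mm (approximate: radial)
    depth = (1.0 - rho) * np.minimum(r, height_mm)
    skin = breast & (depth < skin_mm)
    interior = breast & ~skin

    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(
        rng.standard_normal((nx, ny, nz)), sigma=correlation_length_mm / v)
    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    labels[skin] = LABEL_SKIN
    labels[interior] = LABEL_ADIPOSE
    n_int, n_skin = int(interior.sum()), int(skin.sum())
    if target_gland_fraction > 0 and n_int > 0:
        c = _gland_count_fraction(target_gland_fraction, n_int, n_skin)
        thresh = np.quantile(field[interior], 1.0 - c)
        gland = interior & (field >= thresh)
        labels[gland] = LABEL_GLANDULAR

    hu = np.full((nx, ny, nz), HU_AIR)
    hu[labels == LABEL_ADIPOSE] = HU_ADIPOSE
    hu[labels == LABEL_GLANDULAR] = HU_GLAND
    hu[labels == LABEL_SKIN] = HU_SKIN
    hu += rng.normal(0.0, HU_NOISE_SD, size=hu.shape)

    origin = (-(nx / 2) * v, -(ny / 2) * v, -nz * v)
    material_map = {LABEL_AIR: get_material("air"),
                    LABEL_ADIPOSE: get_material("adipose"),
                    LABEL_GLANDULAR: get_material("glandular"),
                    LABEL_SKIN: get_material("skin")}
    return (HUVolume((v, v, v), origin, hu),
            LabelVolume((v, v, v), origin, labels, material_map))
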
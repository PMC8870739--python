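"""Voxelized phantoms: label volumes, geometric builders, volumetrics.

Coordinate convention: voxel indices are 0-based; the world position of the
centre of voxel (i, j, k) is ``origin + (index + 0.5) * voxel_size``; all
voxel extents are half-open.  Axis z is the pendant-breast / rotation axis in
CT geometry and the beam axis in planar geometry; *coronal* slices are planes
of constant z (perpendicular to the pendant axis).

Standard labels: 0 air, 1 adipose, 2 glandular, 3 skin; labels >= 4 are
homogeneous mixture materials (e.g. the 20/80 or 50/50 glandular/adipose
mixes, which are modelled as single materials, not voxel-level mixtures).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .materials import Material, get_material, mix_materials

LABEL_AIR = 0
LABEL_ADIPOSE = 1
LABEL_GLANDULAR = 2
LABEL_SKIN = 3
LABEL_MIXTURE = 4

_AIR_DENSITY_CEILING = 0.05  # g/cm^3; anything lighter counts as air


def _as_triple(v) -> tuple[float, float, float]:
    arr = np.broadcast_to(np.asarray(v, dtype=float), (3,))
    return float(arr[0]), float(arr[1]), float(arr[2])


@dataclass
class HUVolume:
    """Intensity (Hounsfield-unit-like) volume with geometry metadata."""

    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float]
    values: np.ndarray

    def __post_init__(self):
        self.voxel_size = _as_triple(self.voxel_size)
        self.origin = _as_triple(self.origin)
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("HU values must be finite")
        if min(self.voxel_size) <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class LabelVolume:
    """Voxelized label phantom plus label -> material map."""

    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float]
    labels: np.ndarray
    material_map: dict[int, Material] = field(default_factory=dict)

    def __post_init__(self):
        self.voxel_size = _as_triple(self.voxel_size)
        self.origin = _as_triple(self.origin)
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if min(self.voxel_size) <= 0 or min(self.labels.shape) <= 0:
            raise ValueError("dims and voxel size must be positive")
        self.material_map.setdefault(LABEL_AIR, get_material("air"))
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.material_map)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from "
                             "material_map")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def world_max(self) -> tuple[float, float, float]:
        return tuple(o + n * s for o, n, s in
                     zip(self.origin, self.dims, self.voxel_size))

    def centers(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one axis."""
        n = self.dims[axis]
        return (self.origin[axis]
                + (np.arange(n) + 0.5) * self.voxel_size[axis])

    def density_of_label(self) -> np.ndarray:
        """Lookup array label -> density [g/cm^3] (0 for unused labels)."""
        out = np.zeros(256)
        for lab, mat in self.material_map.items():
            out[lab] = mat.density
        return out

    def with_origin(self, origin) -> "LabelVolume":
        return LabelVolume(self.voxel_size, origin, self.labels,
                           dict(self.material_map))


def _center_grid(n, voxel, start):
    return start + (np.arange(n) + 0.5) * voxel


def build_compressed_breast(radius_mm: float = 100.0,
                            thickness_mm: float = 50.0,
                            skin_mm: float = 2.0,
                            interior_glandular_fraction: float = 0.20,
                            voxel_size_mm: float = 1.0) -> LabelVolume:
    """Semicircular-cross-section compressed-breast phantom.

    A half cylinder of the given radius (semicircle in the x-y plane, flat
    chest-wall side at y = 0) and thickness along the beam axis z.  The
    outermost ``skin_mm`` of the curved and entrance/exit surfaces (not the
    chest wall) are skin; the interior is a single homogeneous mixture of
    glandular and adipose tissue at the given glandular mass fraction, with
    mass-weighted density.
    """
    if radius_mm <= 0 or thickness_mm <= 0 or voxel_size_mm <= 0:
        raise ValueError("dimensions must be positive")
    if skin_mm >= radius_mm:
        raise ValueError("skin thicker than radius")
    v = voxel_size_mm
    nx = int(round(2 * radius_mm / v))
    ny = int(round(radius_mm / v))
    nz = int(round(thickness_mm / v))
    x = _center_grid(nx, v, -radius_mm)[:, None, None]
    y = _center_grid(ny, v, 0.0)[None, :, None]
    z = _center_grid(nz, v, 0.0)[None, None, :]
    r = np.sqrt(x ** 2 + y ** 2)
    inside = np.broadcast_to(r <= radius_mm, (nx, ny, nz)).copy()
    # distance to curved surface and to the entrance/exit faces
    depth = np.minimum(radius_mm - r,
                       np.minimum(z, thickness_mm - z))
    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    labels[inside] = LABEL_MIXTURE
    if skin_mm > 0:
        labels[inside & (depth < skin_mm)] = LABEL_SKIN
    interior = mix_materials(
        [(get_material("glandular"), interior_glandular_fraction),
         (get_material("adipose"), 1.0 - interior_glandular_fraction)],
        name=f"glandular_adipose_{interior_glandular_fraction:.0%}")
    material_map = {LABEL_AIR: get_material("air"),
                    LABEL_SKIN: get_material("skin"),
                    LABEL_MIXTURE: interior}
    return LabelVolume((v, v, v), (-radius_mm, 0.0, 0.0), labels,
                       material_map)


def build_uniform_cylinder(diameter_mm: float = 140.0,
                           height_mm: float = 150.0,
                           material: Material | None = None,
                           voxel_size_mm: float = 1.0) -> LabelVolume:
    """Homogeneous cylinder phantom centred on the rotation axis.

    Default material is the 50/50 glandular/adipose breast-CT mixture.  The
    cylinder top (chest-wall plane) is at z = 0 and the body extends to
    z = -height (pendant geometry).
    """
    if diameter_mm <= 0 or height_mm <= 0 or voxel_size_mm <= 0:
        raise ValueError("dimensions must be positive")
    material = material or get_material("glandular_adipose_50_50")
    v = voxel_size_mm
    r = diameter_mm / 2.0
    nx = ny = int(round(diameter_mm / v))
    nz = int(round(height_mm / v))
    x = _center_grid(nx, v, -r)[:, None]
    y = _center_grid(ny, v, -r)[None, :]
    inside = (x ** 2 + y ** 2 <= r ** 2)
    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    labels[inside, :] = LABEL_MIXTURE
    material_map = {LABEL_AIR: get_material("air"), LABEL_MIXTURE: material}
    return LabelVolume((v, v, v), (-r, -r, -height_mm), labels, material_map)


def phantom_volume(volume: LabelVolume, classes=None) -> float:
    """Volume [mm^3] of the voxels whose label is in ``classes``.

    ``classes=None`` counts every voxel of the grid (all classes).
    """
    if classes is None:
        count = volume.labels.size
    else:
        count = int(np.isin(volume.labels, list(classes)).sum())
    return count * volume.voxel_volume_mm3


def glandular_fraction_by_weight(volume: LabelVolume) -> float:
    """Glandular mass fraction of the phantom tissues (air excluded).

    Discrete glandular voxels count fully; homogeneous mixture materials
    contribute their glandular mass share.
    """
    gland_mass = 0.0
    tissue_mass = 0.0
    labels, counts = np.unique(volume.labels, return_counts=True)
    for lab, n in zip(labels, counts):
        mat = volume.material_map[int(lab)]
        if mat.density < _AIR_DENSITY_CEILING:
            continue
        mass = n * mat.density
        tissue_mass += mass
        gland_mass += mass * mat.glandular_share
    if tissue_mass == 0:
        raise ValueError("phantom contains no tissue voxels")
    return gland_mass / tissue_mass
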
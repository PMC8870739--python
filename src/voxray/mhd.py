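"""MetaImage (MHD header + RAW payload) I/O, via SimpleITK.

Arrays are indexed (x, y, z) in this package; MetaImage stores x-fastest,
which SimpleITK exposes as [z, y, x] numpy arrays, so axes are transposed on
the way in and out.  Round trips are bit-exact; label volumes carry a JSON
sidecar (``<stem>.materials.json``) with the label -> material map.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .materials import Material
from .phantoms import HUVolume, LabelVolume
from .transport import DoseGrid


class MHDFormatError(IOError):
    """Malformed MetaImage header or header/payload mismatch."""


def write_mhd(path, array: np.ndarray, voxel_size, origin) -> None:
    """Write a 2D/3D array as an uncompressed MHD + RAW pair."""
    arr = np.asarray(array)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.T))
    img.SetSpacing(tuple(np.broadcast_to(voxel_size, (3,)).astype(float)))
    img.SetOrigin(tuple(np.broadcast_to(origin, (3,)).astype(float)))
    sitk.WriteImage(img, str(path), useCompression=False)


def read_mhd(path):
    """Read an MHD volume -> (array (x,y,z), voxel_size, origin)."""
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise MHDFormatError(f"cannot read {path}: {exc}") from exc
    arr = sitk.GetArrayFromImage(img).T
    return arr, tuple(img.GetSpacing()), tuple(img.GetOrigin())


# -- typed helpers ---------------------------------------------------------------

def save_label_volume(path, volume: LabelVolume) -> None:
    """Labels as unsigned 8-bit MHD plus a material-map JSON sidecar."""
    path = Path(path)
    write_mhd(path, volume.labels.astype(np.uint8), volume.voxel_size,
              volume.origin)
    side = {
        str(lab): {
            "name": m.name,
            "density": m.density,
            "glandular_share": m.glandular_share,
            "mass_fractions": m.mass_fractions,
        }
        for lab, m in volume.material_map.items()
    }
    path.with_suffix(".materials.json").write_text(
        json.dumps(side, indent=1))


def load_label_volume(path) -> LabelVolume:
    path = Path(path)
    labels, spacing, origin = read_mhd(path)
    side = json.loads(path.with_suffix(".materials.json").read_text())
    material_map = {
        int(lab): Material(e["name"], e["mass_fractions"], e["density"],
                           glandular_share=e.get("glandular_share", 0.0))
        for lab, e in side.items()
    }
    return LabelVolume(spacing, origin, labels.astype(np.uint8),
                       material_map)


def save_hu_volume(path, volume: HUVolume) -> None:
    """HU volumes as 16-bit signed MHD."""
    write_mhd(path, np.round(volume.values).astype(np.int16),
              volume.voxel_size, volume.origin)


def load_hu_volume(path) -> HUVolume:
    values, spacing, origin = read_mhd(path)
    return HUVolume(spacing, origin, values.astype(np.int16))


def save_dose_grid(path, dose: DoseGrid, n_launched: int | None = None
                   ) -> None:
    """Dose grids as 32-bit float MHD (keV per voxel) + normalization sidecar."""
    path = Path(path)
    write_mhd(path, dose.energy_kev.astype(np.float32),
              dose.voxel_mm, dose.origin)
    side = {"units": "keV per voxel", "n_launched": n_launched,
            "out_of_grid_count": dose.out_of_grid_count}
    path.with_suffix(".norm.json").write_text(json.dumps(side, indent=1))


def load_dose_grid(path) -> tuple[DoseGrid, dict]:
    path = Path(path)
    energy, spacing, origin = read_mhd(path)
    side = json.loads(path.with_suffix(".norm.json").read_text())
    return DoseGrid(origin, spacing[0], energy.astype(np.float64)), side
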
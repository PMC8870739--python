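"""Dosimetric and imaging analysis: dose maps, MGD, gamma index, profiles.

Dose conversion turns deposited energy per voxel into absorbed dose (mGy)
using the voxel's material density, rescaled from the number of simulated
photons to a reference photon count.  The mean glandular dose (MGD) averages
over glandular-labelled voxels; on homogeneous-mixture phantoms (which have
no discrete glandular voxels) it averages over all mixture-tissue voxels --
the dose to a uniform mixture equals the dose to its glandular component, so
this is the natural convention there.

The 3D gamma index compares two dose maps voxel by voxel, combining a dose
difference criterion (percent of the global reference maximum) and a
distance-to-agreement (DTA) criterion; gamma <= 1 means the pair of criteria
is fulfilled at that voxel.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KEV_TO_JOULE
from .phantoms import LABEL_GLANDULAR, LabelVolume
from .transport import DoseGrid, RunResult

_AIR_DENSITY_CEILING = 0.05  # g/cm^3


# -- dose maps -------------------------------------------------------------------

@dataclass
class DoseMap:
    """Absorbed dose [mGy] on the dose grid, for ``n_reference`` photons."""

    origin: tuple[float, float, float]
    voxel_mm: float
    dose_mgy: np.ndarray
    tissue_mask: np.ndarray
    n_reference: float


def _voxel_mass_grams(dose_grid: DoseGrid, phantom: LabelVolume
                      ) -> np.ndarray:
    """Mass [g] of phantom material inside each dose voxel."""
    dims = dose_grid.energy_kev.shape
    density = phantom.density_of_label()[phantom.labels]
    pv_mm3 = phantom.voxel_volume_mm3
    # bin phantom voxel centres into dose voxels, accumulating their mass
    centers = np.meshgrid(*(phantom.centers(a) for a in range(3)),
                          indexing="ij")
    idx = [np.floor((c - o) / dose_grid.voxel_mm).astype(np.int64)
           for c, o in zip(centers, dose_grid.origin)]
    mass = np.zeros(dims)
    ok = np.ones(idx[0].shape, dtype=bool)
    for i, n in zip(idx, dims):
        ok &= (i >= 0) & (i < n)
    np.add.at(mass, (idx[0][ok], idx[1][ok], idx[2][ok]),
              density[ok] * pv_mm3 * 1e-3)  # g/cm^3 * mm^3 -> 1e-3 g
    return mass


def dose_grid_to_mGy(dose_grid: DoseGrid, phantom: LabelVolume,
                     n_launched: float, n_reference: float | None = None
                     ) -> DoseMap:
    """Convert deposited energy [keV] to absorbed dose [mGy].

    Dose = E * 1.602e-16 J/keV / voxel mass [kg], scaled by
    n_reference / n_launched.  Voxels containing only air report zero dose
    and are excluded from the tissue mask.
    """
    if n_launched <= 0:
        raise ValueError("n_launched must be positive")
    n_reference = n_launched if n_reference is None else n_reference
    mass_g = _voxel_mass_grams(dose_grid, phantom)
    air_mass = (dose_grid.voxel_mm ** 3) * _AIR_DENSITY_CEILING * 1e-3
    tissue = mass_g > air_mass
    dose = np.zeros_like(mass_g)
    dose[tissue] = (dose_grid.energy_kev[tissue] * KEV_TO_JOULE
                    / (mass_g[tissue] * 1e-3)) * 1e3 \
        * (n_reference / n_launched)
    return DoseMap(dose_grid.origin, dose_grid.voxel_mm, dose, tissue,
                   n_reference)


def _labels_on_dose_grid(dose_map: DoseMap, phantom: LabelVolume
                         ) -> np.ndarray:
    """Phantom label at each dose-voxel centre."""
    dims = dose_map.dose_mgy.shape
    centers = [dose_map.origin[a] + (np.arange(dims[a]) + 0.5)
               * dose_map.voxel_mm for a in range(3)]
    idx = [np.clip(np.floor((c - o) / s).astype(np.int64), 0, n - 1)
           for c, o, s, n in zip(centers, phantom.origin,
                                 phantom.voxel_size, phantom.dims)]
    ii, jj, kk = np.meshgrid(*idx, indexing="ij")
    return phantom.labels[ii, jj, kk]


def mgd(dose_map: DoseMap, phantom: LabelVolume) -> tuple[float, float]:
    """Mean glandular dose [mGy] and the distribution SD over its voxels.

    Averages over glandular-labelled voxels when the phantom has any;
    otherwise (homogeneous-mixture phantom) over all tissue voxels whose
    material carries a glandular mass share.
    """
    labels = _labels_on_dose_grid(dose_map, phantom)
    contributing = (labels == LABEL_GLANDULAR) & dose_map.tissue_mask
    if not contributing.any():
        share_labels = [lab for lab, mat in phantom.material_map.items()
                        if mat.glandular_share > 0]
        contributing = np.isin(labels, share_labels) & dose_map.tissue_mask
    if not contributing.any():
        raise ValueError("phantom has no glandular or mixture voxels")
    vals = dose_map.dose_mgy[contributing]
    return float(vals.mean()), float(vals.std())


# -- gamma index -----------------------------------------------------------------

@dataclass
class GammaResult:
    """Per-voxel gamma values and pass statistics of a dose-map comparison."""

    gamma: np.ndarray
    mask: np.ndarray
    pass_fraction: float
    dta_mm: float
    dd_percent: float
    normalization: str = "global (% of reference maximum)"


def gamma3d(reference: DoseMap, evaluated: DoseMap, dta_mm: float = 3.0,
            dd_percent: float = 3.0, mask: np.ndarray | None = None,
            search_radius_factor: float = 3.0) -> GammaResult:
    """3D gamma index of ``evaluated`` against ``reference``.

    gamma(r) = min over r' within the search radius of
    sqrt(|r - r'|^2 / dta^2 + (D_e(r') - D_r(r))^2 / dD^2), with dD given as
    a percentage of the *global maximum* of the reference map.  Evaluated at
    voxel centres without sub-voxel interpolation (the 1 mm grid is fine
    relative to the 3 mm DTA); the search is capped at
    ``search_radius_factor * dta_mm``.
    """
    ref = reference.dose_mgy
    ev = evaluated.dose_mgy
    if ref.shape != ev.shape or reference.voxel_mm != evaluated.voxel_mm:
        raise ValueError("dose maps are not on the same grid")
    if dta_mm <= 0 or dd_percent <= 0:
        raise ValueError("criteria must be positive")
    ref_max = float(ref.max())
    if ref_max <= 0:
        raise ValueError("reference map has zero maximum")
    dd = dd_percent / 100.0 * ref_max
    if mask is None:
        mask = reference.tissue_mask
    mask = np.asarray(mask, dtype=bool)

    v = reference.voxel_mm
    r_vox = int(np.floor(search_radius_factor * dta_mm / v))
    offs = []
    rng_off = range(-r_vox, r_vox + 1)
    for dx in rng_off:
        for dy in rng_off:
            for dz in rng_off:
                d2 = (dx * dx + dy * dy + dz * dz) * v * v
                if d2 <= (search_radius_factor * dta_mm) ** 2:
                    offs.append((d2, dx, dy, dz))
    offs.sort()

    gamma2 = np.full(ref.shape, np.inf)
    shape = ref.shape
    for d2, dx, dy, dz in offs:
        worst = gamma2[mask].max() if mask.any() else 0.0
        if d2 / dta_mm ** 2 >= worst:
            break
        src = tuple(slice(max(0, -o), min(n, n - o))
                    for o, n in zip((dx, dy, dz), shape))
        dst = tuple(slice(max(0, o), min(n, n + o))
                    for o, n in zip((dx, dy, dz), shape))
        cand = d2 / dta_mm ** 2 \
            + (ev[src] - ref[dst]) ** 2 / dd ** 2
        np.minimum(gamma2[dst], cand, out=gamma2[dst])

    gamma = np.sqrt(gamma2)
    passed = gamma[mask] <= 1.0
    return GammaResult(gamma, mask,
                       float(passed.mean()) if mask.any() else float("nan"),
                       dta_mm, dd_percent)


def central_slab_mask(dose_map: DoseMap, n_slices: int = 100,
                      axis: int = 2) -> np.ndarray:
    """Tissue mask restricted to the central ``n_slices`` along ``axis``."""
    mask = dose_map.tissue_mask.copy()
    n = mask.shape[axis]
    lo = max(0, (n - n_slices) // 2)
    hi = min(n, lo + n_slices)
    sel = [slice(None)] * 3
    sel[axis] = slice(lo, hi)
    keep = np.zeros_like(mask)
    keep[tuple(sel)] = True
    return mask & keep


# -- profiles --------------------------------------------------------------------

def line_profile(data: np.ndarray, axis: int = 0,
                 index: tuple | int | None = None) -> np.ndarray:
    """1D profile along ``axis`` at the given transverse index.

    ``index`` fixes the remaining axes (scalar for 2D images, pair for 3D
    volumes); ``None`` takes the central line.
    """
    data = np.asarray(data)
    other = [a for a in range(data.ndim) if a != axis]
    if index is None:
        index = tuple(data.shape[a] // 2 for a in other)
    elif np.isscalar(index):
        index = (int(index),)
    sel: list = [slice(None)] * data.ndim
    for a, i in zip(other, index):
        if not 0 <= i < data.shape[a]:
            raise IndexError("profile index out of range")
        sel[a] = i
    return data[tuple(sel)]


def percent_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise 100*(a-b)/b; NaN where b == 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles have different lengths")
    out = np.full(a.shape, np.nan)
    nz = b != 0
    out[nz] = 100.0 * (a[nz] - b[nz]) / b[nz]
    return out


# -- statistical uncertainty -----------------------------------------------------

def relative_uncertainty(result: RunResult,
                         mask: np.ndarray | None = None
                         ) -> tuple[np.ndarray, float]:
    """Per-pixel relative standard error of the batch-mean detector signal.

    Uses the batch method: k batch images give per-pixel SE of the mean;
    the summary statistic is the mean relative SE over in-beam pixels with
    nonzero signal.  Requires at least 5 batches.
    """
    k = result.n_batches
    if k < 5:
        raise ValueError("need at least 5 batches for uncertainty estimates")
    s = result.detector_image
    q = result.batch_sumsq
    mean = s / k
    var = np.maximum(q - s ** 2 / k, 0.0) / (k - 1)
    se = np.sqrt(var / k)
    rel = np.full(s.shape, np.nan)
    nz = mean > 0
    rel[nz] = se[nz] / mean[nz]
    if mask is not None:
        nz &= np.asarray(mask, dtype=bool)
    summary = float(np.nanmean(rel[nz])) if nz.any() else float("nan")
    return rel, summary


def relative_uncertainty_from_batches(batch_images: list[np.ndarray]
                                      ) -> tuple[np.ndarray, float]:
    """As :func:`relative_uncertainty`, from explicit per-batch images."""
    k = len(batch_images)
    if k < 5:
        raise ValueError("need at least 5 batches for uncertainty estimates")
    arr = np.stack(batch_images)
    mean = arr.mean(axis=0)
    se = arr.std(axis=0, ddof=1) / np.sqrt(k)
    rel = np.full(mean.shape, np.nan)
    nz = mean > 0
    rel[nz] = se[nz] / mean[nz]
    return rel, float(np.nanmean(rel[nz])) if nz.any() else float("nan")


def extrapolate_uncertainty(u: float, n_from: float, n_to: float) -> float:
    """Scale a relative uncertainty by the 1/sqrt(N) Monte Carlo law."""
    if n_from <= 0 or n_to <= 0:
        raise ValueError("photon counts must be positive")
    return u * np.sqrt(n_from / n_to)
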
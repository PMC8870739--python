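"""Analog Monte Carlo photon transport through voxel phantoms.

The engine launches unweighted photons from a collimated point source,
tracks them through the phantom's bounding box with Woodcock (delta)
tracking, samples photoelectric absorption, Compton (Klein-Nishina) and
Rayleigh (form-factor) interactions, deposits secondary-electron energy
locally at the interaction site (electrons are not tracked at these
energies), and scores the full photon energy of every photon crossing the
detector within bounds.  Outside the phantom grid the transport medium is
vacuum; air inside the grid participates as an (almost always virtual)
Woodcock material.

Woodcock tracking samples free paths from an energy-dependent *majorant*
attenuation coefficient (the maximum over the phantom's materials at the
photon energy); at each tentative site a real interaction occurs with
probability mu_local / mu_majorant, otherwise the flight continues.  This
avoids explicit voxel-boundary ray tracing entirely.

Energy bookkeeping is exact per batch: launched energy equals deposited +
detector-scored + escaped energy (detector-scored photons terminate at the
detector plane and are counted once, in the detector channel).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import ENERGY_CUTOFF_KEV, TABLE_EMAX_KEV, TABLE_EMIN_KEV
from .geometry import DetectorFrame, intersect_detector
from .materials import linear_attenuation
from .phantoms import LabelVolume
from .physics import RayleighSampler, rotate_directions, sample_compton
from .spectra import Spectrum
from .xsdata import CrossSectionSet, default_cross_sections

logger = logging.getLogger(__name__)

_EPS_MM = 1e-6


class MajorantViolationError(RuntimeError):
    """The local attenuation exceeded the Woodcock majorant (table bug)."""


@dataclass
class DoseGrid:
    """Deposited energy [keV] on a regular grid registered to world space."""

    origin: tuple[float, float, float]
    voxel_mm: float
    energy_kev: np.ndarray
    out_of_grid_kev: float = 0.0
    out_of_grid_count: int = 0

    @classmethod
    def for_phantom(cls, phantom: LabelVolume,
                    voxel_mm: float = 1.0) -> "DoseGrid":
        """Grid at ``voxel_mm`` resolution covering the phantom bounding box."""
        ext = [n * s for n, s in zip(phantom.dims, phantom.voxel_size)]
        dims = tuple(int(np.ceil(e / voxel_mm - 1e-9)) for e in ext)
        return cls(phantom.origin, voxel_mm, np.zeros(dims))

    def deposit(self, positions: np.ndarray, energies: np.ndarray) -> None:
        if positions.size == 0:
            return
        idx = np.floor((positions - np.asarray(self.origin))
                       / self.voxel_mm).astype(np.int64)
        dims = self.energy_kev.shape
        ok = np.all((idx >= 0) & (idx < np.array(dims)), axis=1)
        if not ok.all():
            lost = energies[~ok]
            self.out_of_grid_kev += float(lost.sum())
            self.out_of_grid_count += int(lost.size)
            logger.warning("dropped %d out-of-grid deposits", lost.size)
            idx, energies = idx[ok], energies[ok]
        np.add.at(self.energy_kev, (idx[:, 0], idx[:, 1], idx[:, 2]),
                  energies)

    def total_kev(self) -> float:
        return float(self.energy_kev.sum())


@dataclass
class RunResult:
    """Detector image + dose grid + provenance of one simulated exposure."""

    detector_image: np.ndarray        # cumulative impinging energy [keV]
    detector_primary: np.ndarray      # unscattered component of the above
    dose: DoseGrid
    n_launched: int
    seed: int
    n_batches: int
    batch_sumsq: np.ndarray           # per-pixel sum of squared batch images
    ledger: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


class TransportTables:
    """Precomputed per-label attenuation data on a uniform energy grid."""

    GRID_STEP_KEV = 0.25

    def __init__(self, phantom: LabelVolume,
                 xs: CrossSectionSet | None = None):
        xs = xs or default_cross_sections()
        self.grid = np.arange(TABLE_EMIN_KEV, TABLE_EMAX_KEV
                              + self.GRID_STEP_KEV / 2, self.GRID_STEP_KEV)
        labels = sorted(phantom.material_map)
        self.row_of_label = np.full(256, -1, dtype=np.int64)
        mats = []
        for row, lab in enumerate(labels):
            self.row_of_label[lab] = row
            mats.append(phantom.material_map[lab])
        n = len(mats)
        g = self.grid.size
        self.mu = np.zeros((n, g))            # total, 1/mm
        cum = np.zeros((n, 2, g))             # cumulative process fractions
        self.rayleigh = []
        for i, mat in enumerate(mats):
            pe = linear_attenuation(mat, self.grid, "photoelectric", xs)
            coh = linear_attenuation(mat, self.grid, "coherent", xs)
            inc = linear_attenuation(mat, self.grid, "incoherent", xs)
            tot = pe + coh + inc
            self.mu[i] = tot
            cum[i, 0] = pe / tot
            cum[i, 1] = (pe + coh) / tot
            self.rayleigh.append(RayleighSampler(mat, xs))
        self.cum = cum
        self.majorant = self.mu.max(axis=0) * (1.0 + 1e-12)

    def _index(self, e: np.ndarray):
        f = (e - self.grid[0]) / self.GRID_STEP_KEV
        i0 = np.clip(f.astype(np.int64), 0, self.grid.size - 2)
        return i0, f - i0

    def mu_majorant(self, e: np.ndarray) -> np.ndarray:
        i0, w = self._index(e)
        return self.majorant[i0] * (1 - w) + self.majorant[i0 + 1] * w

    def mu_local(self, rows: np.ndarray, e: np.ndarray) -> np.ndarray:
        i0, w = self._index(e)
        return self.mu[rows, i0] * (1 - w) + self.mu[rows, i0 + 1] * w

    def process_fractions(self, rows, e):
        i0, w = self._index(e)
        f_pe = self.cum[rows, 0, i0] * (1 - w) + self.cum[rows, 0, i0 + 1] * w
        f_pc = self.cum[rows, 1, i0] * (1 - w) + self.cum[rows, 1, i0 + 1] * w
        return f_pe, f_pc


def _ray_box(origins, dirs, bmin, bmax):
    """Slab-method ray / axis-aligned-box intersection -> (t_near, t_far)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / dirs
    t1 = (bmin - origins) * inv
    t2 = (bmax - origins) * inv
    tmin = np.nanmax(np.minimum(t1, t2), axis=1)
    tmax = np.nanmin(np.maximum(t1, t2), axis=1)
    hit = (tmax > np.maximum(tmin, 0.0))
    return np.where(hit, np.maximum(tmin, 0.0), np.inf), \
        np.where(hit, tmax, -np.inf)


class _Scoreboard:
    """Accumulates detector, dose and ledger quantities for one batch."""

    def __init__(self, frame: DetectorFrame, dose: DoseGrid):
        self.frame = frame
        self.dose = dose
        self.image = np.zeros((frame.nx, frame.ny))
        self.primary = np.zeros((frame.nx, frame.ny))
        self.detector_kev = 0.0
        self.escaped_kev = 0.0

    def score_exits(self, pos, dirs, energy, n_scatter):
        if energy.size == 0:
            return
        t, du, dv = intersect_detector(pos, dirs, self.frame)
        w2 = self.frame.width / 2.0
        px, py = self.frame.pitch
        hit = np.isfinite(t) & (du >= -w2) & (du < w2) \
            & (dv >= 0.0) & (dv < self.frame.height)
        i = np.floor((du[hit] + w2) / px).astype(np.int64)
        j = np.floor(dv[hit] / py).astype(np.int64)
        np.add.at(self.image, (i, j), energy[hit])
        self.detector_kev += float(energy[hit].sum())
        prim = hit & (n_scatter == 0)
        ip = np.floor((du[prim] + w2) / px).astype(np.int64)
        jp = np.floor(dv[prim] / py).astype(np.int64)
        np.add.at(self.primary, (ip, jp), energy[prim])
        self.escaped_kev += float(energy[~hit].sum())


def _transport_batch(source, frame, phantom, tables, spectrum, n, rng,
                     board: _Scoreboard):
    from .geometry import sample_collimated_directions

    energy = spectrum.sample_energies(n, rng)
    dirs = sample_collimated_directions(source, frame, n, rng)
    pos = np.broadcast_to(np.asarray(source, dtype=float), (n, 3)).copy()
    launched = float(energy.sum())
    n_scatter = np.zeros(n, dtype=np.int16)

    if phantom is None:
        board.score_exits(pos, dirs, energy, n_scatter)
        return launched, 0.0

    bmin = np.asarray(phantom.origin)
    bmax = np.asarray(phantom.world_max())
    vsize = np.asarray(phantom.voxel_size)
    labels = phantom.labels
    dims = np.array(labels.shape)

    t_in, _ = _ray_box(pos, dirs, bmin, bmax)
    miss = ~np.isfinite(t_in)
    board.score_exits(pos[miss], dirs[miss], energy[miss], n_scatter[miss])
    keep = ~miss
    pos = pos[keep] + dirs[keep] * (t_in[keep] + _EPS_MM)[:, None]
    dirs, energy, n_scatter = dirs[keep], energy[keep], n_scatter[keep]

    deposited = 0.0
    while energy.size:
        mu_maj = tables.mu_majorant(energy)
        step = -np.log(rng.random(energy.size)) / mu_maj
        prev = pos
        pos = pos + dirs * step[:, None]

        inside = np.all((pos >= bmin) & (pos < bmax), axis=1)
        if not inside.all():
            out = ~inside
            # score from the last in-box position: the straight flight from
            # there crosses the detector plane at the physical location
            board.score_exits(prev[out], dirs[out], energy[out],
                              n_scatter[out])
            pos, dirs, energy = pos[inside], dirs[inside], energy[inside]
            n_scatter, mu_maj = n_scatter[inside], mu_maj[inside]
            if energy.size == 0:
                break

        vox = np.floor((pos - bmin) / vsize).astype(np.int64)
        np.clip(vox, 0, dims - 1, out=vox)
        rows = tables.row_of_label[labels[vox[:, 0], vox[:, 1], vox[:, 2]]]
        mu_loc = tables.mu_local(rows, energy)
        if np.any(mu_loc > mu_maj * (1.0 + 1e-9)):
            raise MajorantViolationError(
                "local attenuation exceeds the Woodcock majorant")
        real = rng.random(energy.size) * mu_maj < mu_loc
        if not real.any():
            continue

        r_pos, r_dir = pos[real], dirs[real]
        r_e, r_rows = energy[real], rows[real]
        f_pe, f_pc = tables.process_fractions(r_rows, r_e)
        u = rng.random(r_e.size)
        is_pe = u < f_pe
        is_coh = (~is_pe) & (u < f_pc)
        is_inc = ~(is_pe | is_coh)

        # photoelectric: local absorption of the full photon energy
        board.dose.deposit(r_pos[is_pe], r_e[is_pe])
        deposited += float(r_e[is_pe].sum())

        # incoherent: Klein-Nishina energy/angle, local electron deposit
        new_e = r_e.copy()
        new_d = r_dir.copy()
        if is_inc.any():
            cos_t, e2 = sample_compton(r_e[is_inc], rng)
            board.dose.deposit(r_pos[is_inc], r_e[is_inc] - e2)
            deposited += float((r_e[is_inc] - e2).sum())
            new_e[is_inc] = e2
            new_d[is_inc] = rotate_directions(r_dir[is_inc], cos_t, rng)

        # coherent: form-factor modulated elastic redirection
        if is_coh.any():
            cos_all = np.empty(int(is_coh.sum()))
            coh_rows = r_rows[is_coh]
            for row in np.unique(coh_rows):
                sel = coh_rows == row
                cos_all[sel] = tables.rayleigh[row].sample_cos(
                    new_e[is_coh][sel], rng)
            new_d[is_coh] = rotate_directions(r_dir[is_coh], cos_all, rng)

        # photons falling below the cutoff terminate and deposit locally
        dead_soft = ~is_pe & (new_e < max(ENERGY_CUTOFF_KEV, TABLE_EMIN_KEV))
        if dead_soft.any():
            board.dose.deposit(r_pos[dead_soft], new_e[dead_soft])
            deposited += float(new_e[dead_soft].sum())

        survive = ~(is_pe | dead_soft)
        scat = np.zeros(r_e.size, dtype=np.int16)
        scat[is_inc | is_coh] = 1

        # merge survivors back into the in-flight set
        alive = ~real
        alive_idx = np.flatnonzero(real)[survive]
        keep_mask = alive.copy()
        keep_mask[alive_idx] = True
        energy_next = energy.copy()
        energy_next[real] = new_e
        dirs_next = dirs.copy()
        dirs_next[real] = new_d
        n_scatter_next = n_scatter.copy()
        n_scatter_next[real] += scat
        pos, dirs = pos[keep_mask], dirs_next[keep_mask]
        energy, n_scatter = energy_next[keep_mask], n_scatter_next[keep_mask]

    return launched, deposited


def run_projection(source, frame: DetectorFrame, phantom: LabelVolume | None,
                   spectrum: Spectrum, n_photons: int, seed,
                   n_batches: int = 1,
                   tables: TransportTables | None = None,
                   dose_grid: DoseGrid | None = None,
                   dose_voxel_mm: float = 1.0) -> RunResult:
    """Simulate one exposure: ``n_photons`` analog photons, batch-partitioned.

    Photons are launched from the collimated point source, transported until
    absorption, exit or cutoff, and every photon crossing the detector within
    bounds adds its current energy (primaries and scatter alike) to the
    struck pixel.  Deterministic for a fixed ``seed``; per-batch RNG
    substreams are derived from ``(seed, batch_index)``.
    """
    if n_photons <= 0:
        raise ValueError("n_photons must be positive")
    if phantom is not None and tables is None:
        tables = TransportTables(phantom)
    if dose_grid is None:
        dose_grid = (DoseGrid.for_phantom(phantom, dose_voxel_mm)
                     if phantom is not None
                     else DoseGrid((0, 0, 0), dose_voxel_mm, np.zeros((1, 1, 1))))
    board = _Scoreboard(frame, dose_grid)

    per_batch = np.full(n_batches, n_photons // n_batches, dtype=np.int64)
    per_batch[: n_photons % n_batches] += 1
    launched = deposited = 0.0
    image_total = np.zeros((frame.nx, frame.ny))
    primary_total = np.zeros((frame.nx, frame.ny))
    sumsq = np.zeros((frame.nx, frame.ny))
    for b, nb in enumerate(per_batch):
        if nb == 0:
            continue
        rng = np.random.default_rng([int(seed), b])
        board.image[:] = 0.0
        board.primary[:] = 0.0
        la, de = _transport_batch(source, frame, phantom, tables, spectrum,
                                  int(nb), rng, board)
        launched += la
        deposited += de
        image_total += board.image
        primary_total += board.primary
        sumsq += board.image ** 2
        logger.info("batch %d/%d: %d photons", b + 1, n_batches, nb)

    ledger = {
        "launched_kev": launched,
        "deposited_kev": deposited,
        "detector_kev": board.detector_kev,
        "escaped_kev": board.escaped_kev,
    }
    return RunResult(image_total, primary_total, dose_grid, n_photons,
                     int(seed), n_batches, sumsq, ledger,
                     meta={"dose_out_of_grid": dose_grid.out_of_grid_count})


def run_ct_scan(ct_setup, phantom: LabelVolume, spectrum: Spectrum,
                n_per_projection: int, seed, n_batches: int = 1,
                store_images: bool = True,
                dose_voxel_mm: float = 1.0):
    """Full rotational scan: per-view projections + accumulated dose grid.

    Per-view seeds are ``seed + view_index``; the dose grid accumulates over
    all views.  Returns ``(projection_stack, dose_grid, ledger)`` where the
    stack has shape (n_views, nx, ny) in float32 (or None if not stored).
    """
    tables = TransportTables(phantom)
    dose = DoseGrid.for_phantom(phantom, dose_voxel_mm)
    stack = None
    ledger = {"launched_kev": 0.0, "deposited_kev": 0.0,
              "detector_kev": 0.0, "escaped_kev": 0.0}
    for view in range(ct_setup.n_projections):
        source, frame = ct_setup.view(view)
        if stack is None and store_images:
            stack = np.zeros((ct_setup.n_projections, frame.nx, frame.ny),
                             dtype=np.float32)
        res = run_projection(source, frame, phantom, spectrum,
                             n_per_projection, seed + view,
                             n_batches=n_batches, tables=tables,
                             dose_grid=dose)
        for key in ledger:
            ledger[key] += res.ledger[key]
        if store_images:
            stack[view] = res.detector_image
        logger.info("view %d/%d done", view + 1, ct_setup.n_projections)
    return stack, dose, ledger
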
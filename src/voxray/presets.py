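"""Case-study presets and reproducible run configurations.

Four presets tie the modules into complete virtual experiments:

* ``flat_field``            -- planar half-field exposure, no object; the MC
  image is compared against the analytic solid-angle fluence map.
* ``breast_planar``         -- semicircular compressed-breast phantom,
  planar imaging + 3D dose + batch uncertainty.
* ``uniform_cylinder_ct``   -- rotational half-cone CT of the homogeneous
  50/50 cylinder; accumulated dose map + mean glandular dose.
* ``anthropomorphic``       -- synthetic pendant-breast HU volume, four-class
  segmentation, volumetrics (and optionally a scaled CT dose run).

The reference photon counts of the corresponding full-scale experiments are
1e11 (planar) and 1e9 per projection x 360 views (CT); presets run a scaled
photon count and report per-photon-normalized quantities, so results can be
rescaled to any exposure.  Every run writes a provenance manifest sufficient
to reproduce it bit-identically.
"""
from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .analysis import (central_slab_mask, dose_grid_to_mGy,
                       extrapolate_uncertainty, line_profile, mgd,
                       percent_difference, relative_uncertainty)
from .geometry import CTSetup, PlanarSetup, analytic_flat_field
from .mhd import save_dose_grid, save_label_volume, write_mhd
from .phantoms import (build_compressed_breast, build_uniform_cylinder,
                       glandular_fraction_by_weight, phantom_volume)
from .segmentation import SegmentationParams, segment_breast_ct
from .spectra import Spectrum, hvl_al
from .synthetic import synth_breast_hu
from .transport import run_ct_scan, run_projection

CASE_STUDIES = ("flat_field", "breast_planar", "uniform_cylinder_ct",
                "anthropomorphic")

#: full-scale photon counts of the reference experiments
PLANAR_REFERENCE_PHOTONS = 1e11
CT_REFERENCE_PHOTONS = 3.6e11


class CaseStudyError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Declarative description of one case-study run."""

    case: str
    seed: int
    n_photons: int = 1_000_000
    n_per_projection: int = 1_000_000
    n_views: int = 36
    n_batches: int = 10
    spectrum: str = ""          # fixture name or path; preset default if ""
    phantom_path: str = ""      # optional externally built phantom
    output_dir: str = "runs/out"
    voxel_size_mm: float = 1.0

    def __post_init__(self):
        if self.case not in CASE_STUDIES:
            raise ValueError(f"unknown case study {self.case!r}")
        if self.seed is None:
            raise ValueError("a seed is required (no silent nondeterminism)")
        if min(self.n_photons, self.n_per_projection, self.n_views) <= 0:
            raise ValueError("photon and view counts must be positive")


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig(**raw)


def _load_spectrum(cfg: RunConfig, default_fixture: str) -> Spectrum:
    name = cfg.spectrum or default_fixture
    if name in ("w28kv_al", "w80kv_cu"):
        return Spectrum.fixture(name)
    if not Path(name).exists():
        raise FileNotFoundError(f"spectrum file {name!r} not found")
    return Spectrum.from_file(name)


def _load_phantom(cfg: RunConfig, builder):
    if cfg.phantom_path:
        from .mhd import load_label_volume
        if not Path(cfg.phantom_path).exists():
            raise FileNotFoundError(
                f"phantom path {cfg.phantom_path!r} not found")
        return load_label_volume(cfg.phantom_path)
    return builder()


def _stage(name: str):
    """Context manager naming the pipeline stage in any raised error."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise CaseStudyError(f"stage {name!r} failed: {exc}") from exc
            return False
    return _Ctx()


def run_case_study(config: RunConfig) -> dict:
    """Execute a preset end to end and write its artifact bundle.

    Returns the report dictionary (also written as ``report.json``).
    Re-running with the same config reproduces identical numbers.
    """
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"case": config.case, "seed": config.seed}

    if config.case == "flat_field":
        setup = PlanarSetup()
        with _stage("spectrum"):
            spectrum = _load_spectrum(config, "w28kv_al")
        with _stage("simulate"):
            res = run_projection(setup.source, setup.detector, None,
                                 spectrum, config.n_photons, config.seed,
                                 n_batches=config.n_batches)
        with _stage("analyze"):
            analytic = analytic_flat_field(setup.source, setup.detector)
            img = res.detector_image
            norm = img / img.max()
            prof_mc = line_profile(norm, axis=1)
            prof_an = line_profile(analytic, axis=1)
            rel, usum = relative_uncertainty(res)
            report.update({
                "n_photons": config.n_photons,
                "mean_abs_percent_diff_vs_analytic": float(np.nanmean(
                    np.abs(percent_difference(prof_mc, prof_an)))),
                "mean_relative_se": usum,
            })
        with _stage("write"):
            write_mhd(out / "flat_field.mhd", img.astype(np.float32),
                      setup.detector.pitch[0], (0, 0, 0))

    elif config.case == "breast_planar":
        setup = PlanarSetup()
        with _stage("spectrum"):
            spectrum = _load_spectrum(config, "w28kv_al")
        with _stage("phantom"):
            phantom = _load_phantom(
                config, lambda: build_compressed_breast(
                    voxel_size_mm=config.voxel_size_mm))
            # position: entrance surface at SOD, exit at SDD - airgap
            phantom = phantom.with_origin(
                (phantom.origin[0], phantom.origin[1], setup.sod))
        with _stage("simulate"):
            res = run_projection(setup.source, setup.detector, phantom,
                                 spectrum, config.n_photons, config.seed,
                                 n_batches=config.n_batches)
        with _stage("analyze"):
            rel, usum = relative_uncertainty(res)
            dose_map = dose_grid_to_mGy(res.dose, phantom, config.n_photons)
            depth_profile = line_profile(dose_map.dose_mgy, axis=2)
            report.update({
                "n_photons": config.n_photons,
                "mean_relative_se": usum,
                "relative_se_at_1e11": extrapolate_uncertainty(
                    usum, config.n_photons, PLANAR_REFERENCE_PHOTONS),
                "dose_per_photon_entrance_mgy": float(depth_profile[0]
                                                      / config.n_photons),
            })
        with _stage("write"):
            write_mhd(out / "breast_image.mhd",
                      res.detector_image.astype(np.float32),
                      setup.detector.pitch[0], (0, 0, 0))
            save_dose_grid(out / "breast_dose.mhd", res.dose,
                           config.n_photons)
            np.savetxt(out / "depth_dose_profile.csv",
                       np.column_stack([np.arange(depth_profile.size) + 0.5,
                                        depth_profile]),
                       header="position_mm value_mGy", fmt="%.6e")

    elif config.case == "uniform_cylinder_ct":
        setup = CTSetup(n_projections=config.n_views)
        with _stage("spectrum"):
            spectrum = _load_spectrum(config, "w80kv_cu")
        with _stage("phantom"):
            phantom = _load_phantom(
                config, lambda: build_uniform_cylinder(
                    voxel_size_mm=config.voxel_size_mm))
        with _stage("simulate"):
            stack, dose, ledger = run_ct_scan(
                setup, phantom, spectrum, config.n_per_projection,
                config.seed, store_images=False)
        with _stage("analyze"):
            n_total = config.n_per_projection * config.n_views
            dose_map = dose_grid_to_mGy(dose, phantom, n_total)
            mean_gd, sd_gd = mgd(dose_map, phantom)
            report.update({
                "n_photons_total": n_total,
                "hvl_mm_al": hvl_al(spectrum),
                "mgd_mgy_per_photon": mean_gd / n_total,
                "mgd_mgy_at_3.6e11": mean_gd / n_total
                * CT_REFERENCE_PHOTONS,
                "mgd_sd_mgy": sd_gd,
                "central_mask_voxels": int(
                    central_slab_mask(dose_map, 100).sum()),
            })
        with _stage("write"):
            save_dose_grid(out / "cylinder_dose.mhd", dose, n_total)

    elif config.case == "anthropomorphic":
        with _stage("synthesize"):
            hu, truth = synth_breast_hu(seed=config.seed)
        with _stage("segment"):
            seg = segment_breast_ct(hu, SegmentationParams())
        with _stage("analyze"):
            report.update({
                "grid_volume_mm3": phantom_volume(seg),
                "tissue_volume_mm3": phantom_volume(seg, {1, 2, 3}),
                "gland_fraction_by_weight": glandular_fraction_by_weight(seg),
                "gland_fraction_truth": glandular_fraction_by_weight(truth),
            })
        with _stage("write"):
            save_label_volume(out / "segmented.mhd", seg)

    report["wall_time_s"] = time.time() - t0
    manifest = {"config": asdict(config), "voxray_version": __version__,
                "report": report}
    (out / "report.json").write_text(json.dumps(report, indent=1))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return report
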
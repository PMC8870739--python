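"""Monte Carlo transport engine: conservation, Woodcock tracking, scaling."""
import numpy as np
import pytest
from scipy import stats

from voxray import (CTSetup, Spectrum, analytic_flat_field, get_material,
                    linear_attenuation, percent_difference, run_ct_scan,
                    run_projection)
from voxray.phantoms import LABEL_MIXTURE, LabelVolume
from voxray.transport import TransportTables
from voxray.analysis import relative_uncertainty, line_profile

from conftest import absorber, water_slab


def _ledger_balance(ledger):
    return (ledger["launched_kev"] - ledger["deposited_kev"]
            - ledger["detector_kev"] - ledger["escaped_kev"])


class TestEnergyConservation:
    def test_exact_bookkeeping_planar_with_phantom(self, coarse_planar,
                                                   mono50):
        ph = water_slab()
        res = run_projection(coarse_planar.source, coarse_planar.detector,
                             ph, mono50, 100_000, seed=1)
        led = res.ledger
        assert abs(_ledger_balance(led)) < 1e-9 * led["launched_kev"]
        assert res.dose.total_kev() == pytest.approx(led["deposited_kev"])
        assert led["launched_kev"] == pytest.approx(100_000 * 50.0)

    def test_vacuum_phantom_everything_reaches_detector(self, coarse_planar,
                                                        mono50):
        labels = np.zeros((50, 50, 20), dtype=np.uint8)  # all air
        ph = LabelVolume((1, 1, 1), (-25, 0, 300), labels)
        res = run_projection(coarse_planar.source, coarse_planar.detector,
                             ph, mono50, 50_000, seed=2)
        led = res.ledger
        assert led["detector_kev"] / led["launched_kev"] > 0.999
        assert res.dose.total_kev() < 0.001 * led["launched_kev"]

    def test_opaque_phantom_absorbs_everything(self, coarse_planar, mono50,
                                               absorber_xs):
        labels = np.full((240, 160, 5), LABEL_MIXTURE, dtype=np.uint8)
        ph = LabelVolume((1.25, 1.25, 1.0), (-150, 0, 300), labels,
                         {0: get_material("air"),
                          LABEL_MIXTURE: absorber(5e3)})
        tables = TransportTables(ph, absorber_xs)
        res = run_projection(coarse_planar.source, coarse_planar.detector,
                             ph, mono50, 20_000, seed=3, tables=tables)
        assert res.detector_image.sum() == 0.0
        assert res.ledger["deposited_kev"] == pytest.approx(
            res.ledger["launched_kev"])


class TestWoodcockTracking:
    def test_layered_interaction_sites_match_analytic(self, narrow_frame,
                                                      absorber_xs):
        """Woodcock tracking through a 3-voxel heterogeneous stack
        reproduces the layered Beer-Lambert first-interaction probabilities
        (chi-square p > 0.001 at 1e6 photons)."""
        e0 = 20.0
        densities = (8.0, 16.0, 12.0)
        mats = {0: get_material("air")}
        labels = np.zeros((1, 1, 3), dtype=np.uint8)
        for i, rho in enumerate(densities):
            mats[4 + i] = absorber(rho, f"absorber{i}")
            labels[0, 0, i] = 4 + i
        ph = LabelVolume((1.0, 1.0, 1.0), (-0.5, 0.0, 300.0), labels, mats)
        tables = TransportTables(ph, absorber_xs)
        mu = [linear_attenuation(mats[4 + i], e0, xs=absorber_xs)
              for i in range(3)]
        n = 1_000_000
        spec = Spectrum(np.array([e0]), np.array([1.0]))
        res = run_projection(np.zeros(3), narrow_frame, ph, spec, n,
                             seed=4, tables=tables)
        counts = res.dose.energy_kev[0, 0, :] / e0
        # analytic layered attenuation (paths are axial to ~1e-4)
        att = np.exp(-np.cumsum([0.0] + mu))
        p = att[:-1] - att[1:]
        expected = np.append(n * p, n * att[-1])
        observed = np.append(counts, n - counts.sum())
        chi2 = stats.chisquare(observed, expected)
        assert chi2.pvalue > 0.001

    def test_absorber_has_no_scatter(self, narrow_frame, absorber_xs,
                                     mono50):
        """With coherent+incoherent zeroed, every interaction is
        photoelectric: no scattered photons reach the detector."""
        labels = np.full((1, 1, 3), LABEL_MIXTURE, dtype=np.uint8)
        ph = LabelVolume((1.0, 1.0, 1.0), (-0.5, 0.0, 300.0), labels,
                         {0: get_material("air"), LABEL_MIXTURE: absorber(4.0)})
        tables = TransportTables(ph, absorber_xs)
        res = run_projection(np.zeros(3), narrow_frame, ph, mono50,
                             100_000, seed=5, tables=tables)
        np.testing.assert_array_equal(res.detector_image,
                                      res.detector_primary)

    def test_slab_primary_transmission_beer_lambert(self, narrow_frame,
                                                    mono50):
        """Narrow-beam primary transmission through 20 mm of water equals
        exp(-mu t) within 4 sigma at 1e6 photons."""
        ph = water_slab(thickness_mm=20.0)
        n = 1_000_000
        res = run_projection(np.zeros(3), narrow_frame, ph, mono50, n,
                             seed=6)
        mu = linear_attenuation(get_material("water"), 50.0)
        p = np.exp(-mu * 20.0)
        transmitted = res.detector_primary.sum() / 50.0
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(transmitted - n * p) < 4 * sigma + 1

    def test_homogeneous_free_path_is_exponential(self, narrow_frame,
                                                  absorber_xs, mono50):
        """First-interaction depths in a homogeneous absorber: the mean
        matches 1/mu within 4 sigma."""
        rho = 2.0
        labels = np.full((1, 1, 40), LABEL_MIXTURE, dtype=np.uint8)
        ph = LabelVolume((1.0, 1.0, 1.0), (-0.5, 0.0, 300.0), labels,
                         {0: get_material("air"), LABEL_MIXTURE: absorber(rho)})
        tables = TransportTables(ph, absorber_xs)
        n = 300_000
        res = run_projection(np.zeros(3), narrow_frame, ph, mono50, n,
                             seed=7, tables=tables)
        mu = linear_attenuation(absorber(rho), 50.0, xs=absorber_xs)
        counts = res.dose.energy_kev[0, 0, :] / 50.0
        depths = np.arange(40) + 0.5
        n_int = counts.sum()
        # conditional mean depth of an exponential truncated at 40 mm
        t = 40.0
        expect = 1 / mu - t * np.exp(-mu * t) / (1 - np.exp(-mu * t))
        sample_mean = float((counts * depths).sum() / n_int)
        sd = np.sqrt(float((counts * depths ** 2).sum() / n_int)
                     - sample_mean ** 2)
        assert abs(sample_mean - expect) < 4 * sd / np.sqrt(n_int) + 0.5 / 12


class TestFlatField:
    def test_matches_analytic_solid_angle_map(self, coarse_planar):
        """MC flat field / analytic per-pixel solid angle is flat: profile
        differences bounded by 4x the per-pixel statistical error."""
        spec = Spectrum.fixture("w28kv_al")
        res = run_projection(coarse_planar.source, coarse_planar.detector,
                             None, spec, 400_000, seed=8, n_batches=10)
        analytic = analytic_flat_field(coarse_planar.source,
                                       coarse_planar.detector)
        img = res.detector_image / res.detector_image.sum()
        ana = analytic / analytic.sum()
        rel, _ = relative_uncertainty(res)
        pd = percent_difference(line_profile(img, axis=1),
                                line_profile(ana, axis=1))
        band = 100 * 4 * line_profile(rel, axis=1)
        assert np.all(np.abs(pd) <= band + 1e-9)

    def test_dose_grid_stays_zero_without_phantom(self, coarse_planar,
                                                  mono50):
        res = run_projection(coarse_planar.source, coarse_planar.detector,
                             None, mono50, 10_000, seed=9)
        assert res.dose.total_kev() == 0.0


class TestReproducibilityAndScaling:
    def test_identical_seed_bit_identical_results(self, coarse_planar,
                                                  mono50):
        ph = water_slab()
        r1 = run_projection(coarse_planar.source, coarse_planar.detector,
                            ph, mono50, 30_000, seed=10, n_batches=3)
        ph2 = water_slab()
        r2 = run_projection(coarse_planar.source, coarse_planar.detector,
                            ph2, mono50, 30_000, seed=10, n_batches=3)
        np.testing.assert_array_equal(r1.detector_image, r2.detector_image)
        np.testing.assert_array_equal(r1.dose.energy_kev, r2.dose.energy_kev)
        r3 = run_projection(coarse_planar.source, coarse_planar.detector,
                            water_slab(), mono50, 30_000, seed=11)
        assert np.any(r3.detector_image != r1.detector_image)

    def test_one_over_sqrt_n_error_scaling(self, coarse_planar):
        """Fitted log-log slope of the mean relative SE vs N is -0.5."""
        spec = Spectrum.fixture("w28kv_al")
        ns = [20_000, 200_000, 2_000_000]
        us = []
        for i, n in enumerate(ns):
            res = run_projection(coarse_planar.source,
                                 coarse_planar.detector, None, spec, n,
                                 seed=12 + i, n_batches=10)
            _, u = relative_uncertainty(res)
            us.append(u)
        slope = np.polyfit(np.log10(ns), np.log10(us), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.05)


@pytest.fixture(scope="module")
def small_ct():
    from voxray import build_uniform_cylinder
    setup = CTSetup(n_projections=8)
    ph = build_uniform_cylinder(diameter_mm=60, height_mm=60,
                                voxel_size_mm=2.0)
    spec = Spectrum.fixture("w80kv_cu")
    stack, dose, ledger = run_ct_scan(setup, ph, spec, 50_000, seed=21,
                                      store_images=True)
    return setup, ph, spec, stack, dose, ledger


class TestCTScan:
    def test_full_scan_dose_is_axially_symmetric(self, small_ct):
        """A full rotation deposits the same energy in the x- and y-aligned
        central slabs (within combined statistical error)."""
        _, ph, _, _, dose, _ = small_ct
        e = dose.energy_kev
        cy = e.shape[1] // 2
        x_slab = e[:, cy - 10:cy + 10, :].sum()
        y_slab = e[cy - 10:cy + 10, :, :].sum()
        assert x_slab / y_slab == pytest.approx(1.0, abs=0.1)

    def test_projection_stack_shape_and_ledger(self, small_ct):
        setup, _, _, stack, _, ledger = small_ct
        assert stack.shape[0] == setup.n_projections
        assert abs(_ledger_balance(ledger)) < 1e-9 * ledger["launched_kev"]

    def test_dose_per_photon_invariant_under_n(self, narrow_frame):
        ph = water_slab(thickness_mm=20.0)
        spec = Spectrum(np.array([40.0]), np.array([1.0]))
        doses = []
        for n in (50_000, 100_000):
            res = run_projection(np.zeros(3), narrow_frame, ph, spec, n,
                                 seed=22)
            doses.append(res.ledger["deposited_kev"] / n)
        assert doses[1] == pytest.approx(doses[0], rel=0.02)

    def test_single_view_depth_dose_decreases(self):
        """Entry-side dose exceeds the core dose in a single projection."""
        from voxray import build_uniform_cylinder
        setup = CTSetup(n_projections=8)
        ph = build_uniform_cylinder(diameter_mm=60, height_mm=60,
                                    voxel_size_mm=2.0)
        spec = Spectrum.fixture("w80kv_cu")
        source, frame = setup.view(0)
        res = run_projection(source, frame, ph, spec, 200_000, seed=23)
        e = res.dose.energy_kev
        # beam comes from +x; average over the central y/z block
        block = e[:, 20:40, 20:40].mean(axis=(1, 2))
        thirds = np.array_split(block, 3)
        # beam enters at +x (large index): entry > core > exit side
        assert thirds[2].mean() > thirds[1].mean() > thirds[0].mean()
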
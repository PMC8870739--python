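"""Dose conversion, MGD, gamma index (vs brute force), uncertainty."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from voxray import (DoseGrid, DoseMap, dose_grid_to_mGy,
                    extrapolate_uncertainty, gamma3d, get_material,
                    line_profile, mgd, percent_difference)
from voxray.analysis import (central_slab_mask,
                             relative_uncertainty_from_batches)
from voxray.phantoms import (LABEL_ADIPOSE, LABEL_GLANDULAR, LABEL_MIXTURE,
                             LabelVolume)

KEV_IN_1MM3_WATER_MGY = 1.602176634e-7  # 1 keV in 1 mm^3 at 1 g/cm^3


def _uniform_phantom(shape=(4, 4, 4), label=LABEL_GLANDULAR,
                     material=None):
    labels = np.full(shape, label, dtype=np.uint8)
    material = material or get_material("glandular")
    return LabelVolume((1, 1, 1), (0, 0, 0), labels, {label: material})


def _grid(energies, origin=(0, 0, 0)):
    return DoseGrid(origin, 1.0, np.asarray(energies, dtype=float))


class TestDoseConversion:
    def test_unit_arithmetic_1kev_1mm3(self):
        ph = _uniform_phantom(material=get_material("water"),
                              label=LABEL_MIXTURE)
        e = np.zeros((4, 4, 4))
        e[1, 1, 1] = 1.0
        dm = dose_grid_to_mGy(_grid(e), ph, n_launched=1)
        assert dm.dose_mgy[1, 1, 1] == pytest.approx(KEV_IN_1MM3_WATER_MGY,
                                                     rel=1e-9)

    def test_reference_scaling_is_linear(self):
        ph = _uniform_phantom()
        e = np.random.default_rng(0).random((4, 4, 4))
        d1 = dose_grid_to_mGy(_grid(e), ph, 100, 100)
        d2 = dose_grid_to_mGy(_grid(e), ph, 100, 200)
        np.testing.assert_allclose(d2.dose_mgy, 2 * d1.dose_mgy)

    def test_air_voxels_masked_and_zero(self):
        labels = np.zeros((3, 3, 3), dtype=np.uint8)
        labels[1, 1, 1] = LABEL_GLANDULAR
        ph = LabelVolume((1, 1, 1), (0, 0, 0), labels,
                         {LABEL_GLANDULAR: get_material("glandular")})
        e = np.ones((3, 3, 3))
        dm = dose_grid_to_mGy(_grid(e), ph, 1)
        assert dm.tissue_mask.sum() == 1
        assert dm.dose_mgy[0, 0, 0] == 0.0

    def test_nonpositive_photon_count_rejected(self):
        with pytest.raises(ValueError):
            dose_grid_to_mGy(_grid(np.zeros((2, 2, 2))),
                             _uniform_phantom((2, 2, 2)), 0)


class TestMGD:
    def test_uniform_gland_dose(self):
        ph = _uniform_phantom()
        e = np.full((4, 4, 4), 2.0)
        dm = dose_grid_to_mGy(_grid(e), ph, 1)
        mean, sd = mgd(dm, ph)
        assert mean == pytest.approx(2.0 * KEV_IN_1MM3_WATER_MGY / 1.04)
        assert sd == pytest.approx(0.0, abs=1e-18)

    def test_adipose_excluded_from_tally(self):
        labels = np.full((4, 4, 2), LABEL_ADIPOSE, dtype=np.uint8)
        labels[:, :, 0] = LABEL_GLANDULAR
        ph = LabelVolume((1, 1, 1), (0, 0, 0), labels,
                         {LABEL_ADIPOSE: get_material("adipose"),
                          LABEL_GLANDULAR: get_material("glandular")})
        dose = np.zeros((4, 4, 2))
        rho_g = get_material("glandular").density
        rho_a = get_material("adipose").density
        # deposit energies that realize 2 mGy in gland, 1 mGy in adipose
        dose[:, :, 0] = 2.0 / KEV_IN_1MM3_WATER_MGY * rho_g
        dose[:, :, 1] = 1.0 / KEV_IN_1MM3_WATER_MGY * rho_a
        dm = dose_grid_to_mGy(_grid(dose), ph, 1)
        mean, _ = mgd(dm, ph)
        assert mean == pytest.approx(2.0, rel=1e-9)

    def test_mixture_phantom_uses_all_mixture_voxels(self):
        ph = _uniform_phantom(label=LABEL_MIXTURE,
                              material=get_material(
                                  "glandular_adipose_50_50"))
        e = np.full((4, 4, 4), 3.0)
        dm = dose_grid_to_mGy(_grid(e), ph, 1)
        mean, sd = mgd(dm, ph)
        assert mean > 0 and sd == pytest.approx(0.0, abs=1e-18)

    def test_invariant_under_rescaling_chain(self):
        """MGD per reference photon is invariant under n_launched changes."""
        ph = _uniform_phantom()
        e = np.random.default_rng(1).random((4, 4, 4))
        m1 = mgd(dose_grid_to_mGy(_grid(e), ph, 10, 1000), ph)[0]
        m2 = mgd(dose_grid_to_mGy(_grid(10 * e), ph, 100, 1000), ph)[0]
        assert m1 == pytest.approx(m2, rel=1e-12)

    def test_no_contributing_voxels_rejected(self):
        ph = _uniform_phantom(label=LABEL_ADIPOSE,
                              material=get_material("adipose"))
        dm = dose_grid_to_mGy(_grid(np.ones((4, 4, 4))), ph, 1)
        with pytest.raises(ValueError):
            mgd(dm, ph)


def _dose_map(values, mask=None):
    values = np.asarray(values, dtype=float)
    mask = np.ones(values.shape, dtype=bool) if mask is None else mask
    return DoseMap((0, 0, 0), 1.0, values, mask, 1.0)


def _brute_force_gamma(ref, ev, dta, dd_frac, radius):
    """Exhaustive gamma over all voxel pairs within the search radius."""
    shape = ref.shape
    dd = dd_frac * ref.max()
    coords = np.argwhere(np.ones(shape, dtype=bool))
    gamma = np.full(shape, np.inf)
    for r in coords:
        d2 = ((coords - r) ** 2).sum(axis=1).astype(float)
        near = d2 <= radius ** 2
        diff = ev[tuple(coords[near].T)] - ref[tuple(r)]
        g2 = d2[near] / dta ** 2 + diff ** 2 / dd ** 2
        gamma[tuple(r)] = np.sqrt(g2.min())
    return gamma


class TestGamma3D:
    def test_identical_maps_gamma_zero_pass_one(self):
        m = _dose_map(np.random.default_rng(2).random((6, 6, 6)) + 0.5)
        res = gamma3d(m, m)
        assert np.all(res.gamma[res.mask] == 0.0)
        assert res.pass_fraction == 1.0

    def test_three_percent_spike_gives_gamma_one(self):
        """A reference voxel 3% (of the global max) above a flat evaluated
        map, with flat surroundings, sits exactly at gamma = 1 for 3%/3mm."""
        ref = np.ones((7, 7, 7))
        ref[0, 0, 0] = 2.0          # sets the global maximum
        ref[3, 3, 3] = 1.0 + 0.03 * 2.0
        ev = np.ones((7, 7, 7))
        ev[0, 0, 0] = 2.0
        res = gamma3d(_dose_map(ref), _dose_map(ev))
        assert res.gamma[3, 3, 3] == pytest.approx(1.0, rel=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_maps(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.random((8, 8, 8)) + 0.2
        ev = ref + rng.normal(0, 0.05, ref.shape)
        res = gamma3d(_dose_map(ref), _dose_map(ev), dta_mm=2.0,
                      dd_percent=3.0, search_radius_factor=3.0)
        brute = _brute_force_gamma(ref, ev, 2.0, 0.03, radius=6.0)
        np.testing.assert_allclose(res.gamma, brute, rtol=1e-9)

    def test_pass_fraction_monotone_in_criteria(self):
        rng = np.random.default_rng(3)
        ref = rng.random((8, 8, 8)) + 0.2
        ev = ref + rng.normal(0, 0.08, ref.shape)
        p = [gamma3d(_dose_map(ref), _dose_map(ev), dta_mm=dta,
                     dd_percent=dd).pass_fraction
             for dta, dd in [(1.0, 1.0), (2.0, 1.0), (2.0, 3.0),
                             (3.0, 3.0)]]
        assert p[0] <= p[1] <= p[2] <= p[3]

    def test_grid_mismatch_and_zero_reference_rejected(self):
        a = _dose_map(np.ones((4, 4, 4)))
        b = _dose_map(np.ones((5, 4, 4)))
        with pytest.raises(ValueError):
            gamma3d(a, b)
        with pytest.raises(ValueError):
            gamma3d(_dose_map(np.zeros((4, 4, 4))), a)

    def test_central_slab_mask_limits_extent(self):
        m = _dose_map(np.ones((6, 6, 30)))
        mask = central_slab_mask(m, n_slices=10)
        assert mask.sum() == 6 * 6 * 10
        assert not mask[:, :, 0].any()


class TestProfilesAndDifferences:
    def test_percent_difference_identity_and_scale(self):
        p = np.linspace(1, 5, 20)
        np.testing.assert_allclose(percent_difference(p, p), 0.0)
        np.testing.assert_allclose(percent_difference(1.01 * p, p), 1.0)

    def test_zero_denominator_masked(self):
        out = percent_difference(np.array([1.0, 2.0]), np.array([0.0, 2.0]))
        assert np.isnan(out[0]) and out[1] == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(np.zeros(3), np.zeros(4))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(b=hnp.arrays(np.float64, 12,
                        elements=st.floats(0.1, 1e3)),
           scale=st.floats(0.5, 2.0))
    def test_percent_difference_recovers_scale(self, b, scale):
        """percent_difference(scale*b, b) is 100*(scale-1) elementwise."""
        out = percent_difference(scale * b, b)
        np.testing.assert_allclose(out, 100 * (scale - 1), rtol=1e-9,
                                   atol=1e-9)

    def test_line_profile_extraction(self):
        img = np.arange(12).reshape(3, 4)
        np.testing.assert_array_equal(line_profile(img, axis=0, index=1),
                                      img[:, 1])
        vol = np.arange(27).reshape(3, 3, 3)
        np.testing.assert_array_equal(line_profile(vol, axis=2),
                                      vol[1, 1, :])
        with pytest.raises(IndexError):
            line_profile(img, axis=0, index=7)


class TestUncertainty:
    def test_identical_batches_give_zero(self):
        img = np.full((5, 5), 3.0)
        rel, summary = relative_uncertainty_from_batches([img] * 6)
        assert summary == pytest.approx(0.0, abs=1e-12)

    def test_poisson_batches_match_closed_form(self):
        """k batches of Poisson(m) counts: mean relative SE of the batch
        mean is ~1/sqrt(k m), within 20%."""
        rng = np.random.default_rng(4)
        k, m = 10, 100.0
        batches = [rng.poisson(m, size=(50, 50)).astype(float)
                   for _ in range(k)]
        _, summary = relative_uncertainty_from_batches(batches)
        assert summary == pytest.approx(1 / np.sqrt(k * m), rel=0.2)

    def test_extrapolation_identity_and_sqrt_law(self):
        assert extrapolate_uncertainty(0.3, 1e6, 1e6) == 0.3
        assert extrapolate_uncertainty(0.3, 1e6, 4e6) == pytest.approx(0.15)
        with pytest.raises(ValueError):
            extrapolate_uncertainty(0.3, 0, 1)

    def test_too_few_batches_rejected(self):
        with pytest.raises(ValueError):
            relative_uncertainty_from_batches([np.ones((2, 2))] * 3)
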
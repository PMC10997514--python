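"""Extrapolated structure factors and activation-level estimation."""

import numpy as np
import pytest

from flashmap.core import DifferenceSet, ReflectionSet
from flashmap.extrapolation import (
    NeScan,
    activation_from_ne,
    estimate_ne,
    extrapolated_coefficients,
    ne_from_activation,
    negative_density_curve,
    refinement_map_coefficients,
)
from flashmap.kinetics import real_space_cc
from flashmap.scaling import difference_coefficients
from flashmap.sf import compute_fc, default_grid, synthesize_map
from flashmap.synthetic import standard_scenario


def make_diff(refl, deltas):
    return DifferenceSet(
        cell=refl.cell, hkl=refl.hkl, delta=np.asarray(deltas, dtype=float),
        sigma=np.zeros(len(refl)), weight=np.ones(len(refl)), phase=refl.phase,
    )


class TestExtrapolatedCoefficients:
    def test_ne_zero_returns_fc(self, random_reflections):
        diff = make_diff(random_reflections, np.ones(len(random_reflections)))
        fe = extrapolated_coefficients(random_reflections, diff, 0.0)
        np.testing.assert_array_equal(fe.amplitude, random_reflections.amplitude)
        np.testing.assert_array_equal(fe.phase, random_reflections.phase)

    def test_zero_delta_returns_fc_for_any_ne(self, random_reflections):
        diff = make_diff(random_reflections, np.zeros(len(random_reflections)))
        fe = extrapolated_coefficients(random_reflections, diff, 17.5)
        np.testing.assert_array_equal(fe.amplitude, random_reflections.amplitude)

    def test_linearity_in_ne(self, random_reflections):
        rng = np.random.default_rng(1)
        diff = make_diff(random_reflections, rng.normal(0, 2, len(random_reflections)))
        fc = random_reflections.amplitude
        fe_a = extrapolated_coefficients(random_reflections, diff, 3.0).amplitude - fc
        fe_b = extrapolated_coefficients(random_reflections, diff, 5.0).amplitude - fc
        fe_ab = extrapolated_coefficients(random_reflections, diff, 8.0).amplitude - fc
        np.testing.assert_allclose(fe_ab, fe_a + fe_b, atol=1e-12)

    def test_negative_count_reported(self, random_reflections):
        diff = make_diff(random_reflections, -np.ones(len(random_reflections)))
        fe = extrapolated_coefficients(random_reflections, diff, 1e4)
        assert fe.n_negative == len(random_reflections)

    def test_fe_map_matches_light_model_at_ne_2_over_r(self):
        # modest displacement: the difference-Fourier approximation behind
        # the factor 2 is a small-perturbation result
        r = 0.2
        dark, light, site, fo_dark, fo_light = standard_scenario(
            seed=3, r=r, noise_frac=0.0, displacement=1.0, n_atoms=48
        )
        fc = compute_fc(dark, 1.9, 16.0)
        diff = difference_coefficients(fo_light, fo_dark, fc, weighting="none")
        fe = extrapolated_coefficients(fc, diff, 2.0 / r)
        grid = default_grid(dark.cell, 1.9)
        cc = real_space_cc(
            synthesize_map(fe, grid=grid),
            synthesize_map(compute_fc(light, 1.9, 16.0), grid=grid),
        )
        assert cc > 0.95


class TestNegativeDensityCurve:
    def test_ne_zero_matches_dark_model_map(self):
        dark, light, site, fo_dark, fo_light = standard_scenario(seed=5, noise_frac=0.0)
        fc = compute_fc(dark, 1.9, 16.0)
        diff = difference_coefficients(fo_light, fo_dark, fc, weighting="none")
        scan = negative_density_curve(fc, diff, [0.0, 1.0, 2.0], dark, mask_atoms=site)
        # a good dark model has essentially no deep negative density
        assert scan.neg_density[0] == pytest.approx(0.0, abs=1e-6)

    def test_flat_below_knee_grows_beyond(self):
        r = 0.2
        dark, light, site, fo_dark, fo_light = standard_scenario(seed=5, r=r, noise_frac=0.0)
        fc = compute_fc(dark, 1.9, 16.0)
        diff = difference_coefficients(fo_light, fo_dark, fc, weighting="none")
        ne = np.arange(1.0, 25.0, 1.0)
        scan = negative_density_curve(fc, diff, ne, dark, mask_atoms=site)
        knee = 2.0 / r
        # approximately flat baseline below the knee (series-termination
        # ripple leaves a small residue), strong growth beyond it
        baseline = scan.neg_density[ne < 0.8 * knee]
        assert np.all(baseline <= 0.05 * scan.neg_density.max())
        assert scan.neg_density[-1] > 0.0
        beyond = scan.neg_density[ne > 1.2 * knee]
        assert np.all(np.diff(beyond) >= -1e-9)

    def test_doubling_deltas_halves_knee(self):
        dark, light, site, fo_dark, fo_light = standard_scenario(seed=7, r=0.2, noise_frac=0.0)
        fc = compute_fc(dark, 1.9, 16.0)
        diff = difference_coefficients(fo_light, fo_dark, fc, weighting="none")
        doubled = DifferenceSet(
            cell=diff.cell, hkl=diff.hkl, delta=2.0 * diff.delta,
            sigma=diff.sigma, weight=diff.weight, phase=diff.phase,
        )
        ne = np.arange(1.0, 30.0, 0.5)
        knee_1 = estimate_ne(negative_density_curve(fc, diff, ne, dark, mask_atoms=site))
        knee_2 = estimate_ne(negative_density_curve(fc, doubled, ne, dark, mask_atoms=site))
        assert knee_2 == pytest.approx(knee_1 / 2.0, rel=0.2)

    def test_empty_mask_rejected(self, random_reflections, random_model):
        diff = make_diff(random_reflections, np.ones(len(random_reflections)))
        with pytest.raises(ValueError, match="empty mask"):
            negative_density_curve(
                random_reflections, diff, [1.0, 2.0, 3.0], random_model,
                mask_atoms=np.array([], dtype=int),
            )


class TestEstimateNe:
    def test_piecewise_linear_break_detected(self):
        ne = np.arange(2.0, 22.0, 2.0)
        y = np.maximum(0.0, ne - 10.0) * 1.0
        scan = NeScan(ne_values=ne, neg_density=y)
        assert estimate_ne(scan) == 10.0

    def test_strictly_linear_curve_is_an_error(self):
        ne = np.arange(2.0, 22.0, 2.0)
        scan = NeScan(ne_values=ne, neg_density=0.7 * ne)
        with pytest.raises(ValueError, match="no knee"):
            estimate_ne(scan)

    def test_too_few_points(self):
        scan = NeScan(ne_values=[1.0, 2.0, 3.0], neg_density=[0.0, 0.0, 1.0])
        with pytest.raises(ValueError, match="need >= 5"):
            estimate_ne(scan)

    def test_recovers_ne_14_at_one_seventh_activation(self):
        dark, light, site, fo_dark, fo_light = standard_scenario(seed=4, r=1.0 / 7.0)
        fc = compute_fc(dark, 1.9, 16.0)
        diff = difference_coefficients(fo_light, fo_dark, fc, weighting="none")
        scan = negative_density_curve(fc, diff, np.arange(2.0, 41.0, 2.0), dark, mask_atoms=site)
        assert estimate_ne(scan) == pytest.approx(14.0, rel=0.15)

    def test_parameter_recovery_across_activation_levels(self):
        # ground-truth sweep: estimates within 20% of 2/r in >= 90% of runs
        cases = {
            0.05: np.arange(10.0, 80.0, 2.0),
            0.1: np.arange(2.0, 61.0, 1.0),
            0.2: np.arange(2.0, 31.0, 1.0),
            0.5: np.arange(1.0, 12.5, 0.5),
        }
        results = []
        for r, ne_grid in cases.items():
            for seed in range(40, 45):
                dark, light, site, fo_dark, fo_light = standard_scenario(
                    seed=seed, r=r, noise_frac=0.02
                )
                fc = compute_fc(dark, 1.9, 16.0)
                diff = difference_coefficients(fo_light, fo_dark, fc, weighting="none")
                scan = negative_density_curve(fc, diff, ne_grid, dark, mask_atoms=site)
                try:
                    est = estimate_ne(scan)
                except ValueError:
                    results.append(False)
                    continue
                results.append(abs(est - 2.0 / r) <= 0.2 * (2.0 / r))
        assert np.mean(results) >= 0.9


class TestActivationConversion:
    def test_round_trip_and_printed_value(self):
        assert activation_from_ne(2.0) == 1.0
        assert activation_from_ne(14.0) == pytest.approx(1.0 / 7.0)
        for r in (0.05, 0.2, 1.0):
            assert activation_from_ne(ne_from_activation(r)) == pytest.approx(r)

    def test_overunity_activation_warns(self):
        with pytest.warns(UserWarning, match="> 1"):
            assert activation_from_ne(1.0) == 2.0


class TestRefinementCoefficients:
    def test_fe_equals_fc_returns_fc(self, random_reflections):
        out = refinement_map_coefficients(random_reflections, random_reflections)
        np.testing.assert_allclose(out.amplitude, random_reflections.amplitude)

    def test_hand_computed_three_reflections(self, cubic_cell):
        hkl = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
        fe = ReflectionSet(cell=cubic_cell, hkl=hkl, amplitude=[5.0, 2.0, 1.0],
                           sigma=[0.0] * 3, phase=[0.0, 90.0, 180.0])
        fc = ReflectionSet(cell=cubic_cell, hkl=hkl, amplitude=[4.0, 3.0, 1.0],
                           sigma=[0.0] * 3, phase=[0.0, 90.0, 180.0])
        out = refinement_map_coefficients(fe, fc)
        np.testing.assert_allclose(out.amplitude, [6.0, 1.0, 1.0])
        np.testing.assert_allclose(out.phase, [0.0, 90.0, 180.0])

    def test_index_mismatch_rejected(self, cubic_cell, random_reflections):
        other = ReflectionSet(cell=cubic_cell, hkl=[(9, 9, 9)], amplitude=[1.0],
                              sigma=[0.0], phase=[0.0])
        with pytest.raises(ValueError, match="do not match"):
            refinement_map_coefficients(random_reflections, other)
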
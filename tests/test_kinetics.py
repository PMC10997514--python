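"""Sigma-thresholded region integration, noise floors and map correlation."""

import numpy as np
import pytest
from scipy.stats import norm

from flashmap.core import RealSpaceMap
from flashmap.kinetics import (
    KineticsSeries,
    RegionSpec,
    feature_series,
    integrate_region,
    noise_floor,
    normalize_series,
    real_space_cc,
)
from flashmap.synthetic import make_toy_crystal

from conftest import build_model


@pytest.fixture
def toy_model():
    return make_toy_crystal(seed=21, n_atoms=96)


def make_map(model, values):
    return RealSpaceMap(cell=model.cell, values=values)


def region_for(model, resnums, **kw):
    return RegionSpec(name="r", residues=[("A", n) for n in resnums], **kw)


class TestIntegrateRegion:
    def test_zero_map_integrates_to_zero(self, toy_model):
        m = make_map(toy_model, np.zeros((24, 30, 32)))
        assert integrate_region(m, toy_model, region_for(toy_model, [1])) == 0.0

    def test_threshold_above_maximum_gives_zero(self, toy_model):
        rng = np.random.default_rng(0)
        m = make_map(toy_model, rng.normal(size=(24, 30, 32)))
        spec = region_for(toy_model, [1], sigma_threshold=50.0)
        assert integrate_region(m, toy_model, spec) == 0.0

    def test_blob_matches_voxel_loop_oracle(self, toy_model):
        shape = (24, 30, 32)
        grid = np.array(shape)
        cell = toy_model.cell
        atom_xyz = toy_model.coords()[toy_model.select_residue_atoms([("A", 1)])]
        # spherical blob centred on the first region atom
        fx, fy, fz = np.meshgrid(*[np.arange(n) / n for n in shape], indexing="ij")
        vox_frac = np.stack([fx, fy, fz], axis=-1)
        center_frac = cell.frac_matrix @ atom_xyz[0]
        d = vox_frac - center_frac
        d -= np.round(d)
        dist = np.linalg.norm(d.reshape(-1, 3) @ cell.orth_matrix.T, axis=1).reshape(shape)
        values = 5.0 * np.exp(-(dist**2) / 2.0)
        m = make_map(toy_model, values)
        spec = region_for(toy_model, [1], radius=2.0, sigma_threshold=3.0)
        result = integrate_region(m, toy_model, spec)
        # independent voxel loop
        sig = np.sqrt(np.mean((values - values.mean()) ** 2))
        vol = cell.volume / values.size
        total = 0.0
        for idx in np.ndindex(shape):
            frac = np.array(idx) / grid
            dmin = np.inf
            for xyz in atom_xyz:
                df = frac - cell.frac_matrix @ xyz
                df -= np.round(df)
                dmin = min(dmin, np.linalg.norm(cell.orth_matrix @ df))
            if dmin <= 2.0 and abs(values[idx]) > 3.0 * sig:
                total += abs(values[idx]) / sig * vol
        assert result == pytest.approx(total, rel=1e-10)

    def test_monotone_in_threshold(self, toy_model):
        rng = np.random.default_rng(3)
        m = make_map(toy_model, rng.normal(size=(24, 30, 32)))
        vals = [
            integrate_region(m, toy_model, region_for(toy_model, [1, 2], radius=3.0, sigma_threshold=t))
            for t in (3.0, 2.0, 1.0, 0.5)
        ]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_invariant_under_uniform_rescaling(self, toy_model):
        rng = np.random.default_rng(4)
        v = rng.normal(size=(24, 30, 32))
        spec = region_for(toy_model, [1, 2], radius=2.5, sigma_threshold=2.0)
        a = integrate_region(make_map(toy_model, v), toy_model, spec)
        b = integrate_region(make_map(toy_model, 37.5 * v), toy_model, spec)
        assert a == pytest.approx(b, rel=1e-12)

    def test_unresolvable_region(self, toy_model):
        with pytest.raises(ValueError, match="no atoms"):
            integrate_region(
                make_map(toy_model, np.zeros((24, 30, 32))),
                toy_model,
                RegionSpec(name="x", residues=[("B", 999)]),
            )


class TestNoiseFloor:
    def test_zero_map_gives_zero_floor(self, toy_model):
        m = make_map(toy_model, np.zeros((24, 30, 32)))
        spec = region_for(toy_model, [1])
        assert noise_floor(m, toy_model, spec, n=50, seed=1) == 0.0

    def test_deterministic_for_fixed_seed(self, toy_model):
        rng = np.random.default_rng(8)
        m = make_map(toy_model, rng.normal(size=(24, 30, 32)))
        spec = region_for(toy_model, [1], sigma_threshold=1.5)
        a = noise_floor(m, toy_model, spec, n=300, seed=42)
        b = noise_floor(m, toy_model, spec, n=300, seed=42)
        assert a == b
        assert a > 0

    def test_gaussian_field_matches_analytic_expectation(self, toy_model):
        # for an iid N(0,1) field, E[|rho| ; |rho| > k sigma] per voxel is
        # 2 phi(k); the floor should match the per-window expectation
        rng = np.random.default_rng(15)
        shape = (24, 30, 32)
        m = make_map(toy_model, rng.normal(size=shape))
        k = 2.0
        spec = region_for(toy_model, [1], radius=1.5, sigma_threshold=k)
        floor = noise_floor(m, toy_model, spec, n=400, region_size=6, seed=3)
        # independent window-mask voxel counter via brute-force distances
        residues = toy_model.residue_ids()
        cell = toy_model.cell
        fx, fy, fz = np.meshgrid(*[np.arange(n) / n for n in shape], indexing="ij")
        vox = np.stack([fx, fy, fz], axis=-1).reshape(-1, 3)
        counts = []
        for start in range(len(residues) - 5):
            window = residues[start : start + 6]
            xyz = toy_model.coords()[toy_model.select_residue_atoms(window)]
            near = np.zeros(len(vox), dtype=bool)
            for a in xyz:
                d = vox - cell.frac_matrix @ a
                d -= np.round(d)
                near |= np.linalg.norm(d @ cell.orth_matrix.T, axis=1) <= 1.5
            counts.append(near.sum())
        vol = cell.volume / m.n_voxels
        expected = np.mean(counts) * 2.0 * norm.pdf(k) * vol
        # MC spread: windows differ in size; allow 3 relative standard errors
        rel_se = np.std(counts) / np.mean(counts) / np.sqrt(400) + 0.05
        assert floor == pytest.approx(expected, rel=3 * rel_se + 0.1)

    def test_insufficient_residues(self, toy_model):
        m = make_map(toy_model, np.zeros((24, 30, 32)))
        spec = region_for(toy_model, [1])
        exclude = toy_model.residue_ids()[:-3]
        with pytest.raises(ValueError, match="usable residues"):
            noise_floor(m, toy_model, spec, n=10, exclude=exclude, seed=0)


class TestFeatureSeries:
    def test_all_zero_maps(self, toy_model):
        maps = [make_map(toy_model, np.zeros((24, 30, 32))) for _ in range(3)]
        fs = feature_series(maps, [0.4, 1.0, 2.0], toy_model.coords()[0])
        np.testing.assert_array_equal(fs.values, np.zeros(3))

    def test_negative_sign_on_positive_map_gives_zeros(self, toy_model):
        maps = [make_map(toy_model, np.abs(np.random.default_rng(1).normal(size=(24, 30, 32))))]
        fs = feature_series(maps, [1.0], toy_model.coords()[0], sign="negative")
        assert fs.values[0] == 0.0

    def test_series_scale_invariance(self, toy_model):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(24, 30, 32))
        center = toy_model.coords()[0]
        a = feature_series([make_map(toy_model, v)], [1.0], center)
        b = feature_series([make_map(toy_model, 100.0 * v)], [1.0], center)
        assert a.values[0] == pytest.approx(b.values[0], rel=1e-12)


class TestNormalizeSeries:
    def test_maximum_becomes_one_and_floor_ratio_preserved(self):
        s = KineticsSeries(
            name="s", delays=[1.0, 2.0, 3.0], values=[2.0, 8.0, 4.0],
            noise_floor=[0.5, 0.5, 0.5],
        )
        n = normalize_series(s)
        assert n.values.max() == 1.0
        np.testing.assert_allclose(n.noise_floor / n.values, s.noise_floor / s.values)
        assert n.normalized

    def test_all_equal_series(self):
        s = KineticsSeries(name="s", delays=[1.0, 2.0], values=[3.0, 3.0])
        np.testing.assert_array_equal(normalize_series(s).values, [1.0, 1.0])

    def test_all_zero_series_rejected(self):
        s = KineticsSeries(name="s", delays=[1.0, 2.0], values=[0.0, 0.0])
        with pytest.raises(ValueError, match="all-zero"):
            normalize_series(s)


class TestRealSpaceCC:
    def test_self_correlation_is_one(self, toy_model):
        rng = np.random.default_rng(5)
        m = make_map(toy_model, rng.normal(size=(16, 16, 16)))
        assert real_space_cc(m, m) == pytest.approx(1.0, abs=1e-12)

    def test_negation_gives_minus_one(self, toy_model):
        rng = np.random.default_rng(5)
        v = rng.normal(size=(16, 16, 16))
        cc = real_space_cc(make_map(toy_model, v), make_map(toy_model, -v))
        assert cc == pytest.approx(-1.0, abs=1e-12)

    def test_independent_noise_maps_decorrelated(self, toy_model):
        a = make_map(toy_model, np.random.default_rng(1).normal(size=(64, 64, 64)))
        b = make_map(toy_model, np.random.default_rng(2).normal(size=(64, 64, 64)))
        assert abs(real_space_cc(a, b)) < 0.01

    def test_zero_variance_rejected(self, toy_model):
        flat = make_map(toy_model, np.ones((8, 8, 8)))
        noisy = make_map(toy_model, np.random.default_rng(3).normal(size=(8, 8, 8)))
        with pytest.raises(ValueError, match="zero-variance"):
            real_space_cc(flat, noisy)

    def test_grid_mismatch_rejected(self, toy_model):
        a = make_map(toy_model, np.zeros((8, 8, 8)))
        b = make_map(toy_model, np.zeros((8, 8, 10)))
        with pytest.raises(ValueError, match="grid mismatch"):
            real_space_cc(a, b)
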
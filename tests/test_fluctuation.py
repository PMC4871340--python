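import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from _oracles import pcc_oracle, rmsf_oracle
from conftest import ensemble_from
from fluctnet.errors import ValidationError
from fluctnet.fluctuation import (
    MonitorConfig,
    RmsdMonitor,
    compute_pair_correlation,
    compute_rmsf,
    compute_state_metrics,
    mean_structure,
    superpose_ensemble,
)
from fluctnet.structure_io import AtomQuery

SQRT3 = np.sqrt(3.0)


def random_ensemble(rng, n_frames=50, n_atoms=8, scale=0.4):
    base = rng.uniform(0, 10, size=(n_atoms, 3))
    return ensemble_from(base[None] + rng.normal(scale=scale, size=(n_frames, n_atoms, 3)))


def sinusoid_ensemble(n_frames=240, n_atoms=3):
    """Atom deviation series built from mutually orthogonal full-period
    sinusoids, so the x/y/z series are exactly uncorrelated."""
    t = np.arange(n_frames)
    base = np.array([[2.0 * np.pi * k / n_frames] for k in (1, 2, 3)])  # (3, 1)
    dev = np.sin(base * t).T  # (F, 3): orthogonal columns, zero mean
    coords = np.zeros((n_frames, n_atoms, 3))
    coords[:, 0, :] = dev
    coords[:, 1, :] = dev  # atom 1 copies atom 0 exactly
    coords[:, 2, :] = 5.0 + np.cos(base * t).T
    return ensemble_from(coords)


class TestSuperpose:
    def test_rigid_motion_removed(self, rng):
        base = rng.uniform(0, 10, size=(6, 3))
        frames = []
        for _ in range(8):
            R = Rotation.random(random_state=rng).as_matrix()
            frames.append(base @ R.T + rng.uniform(-5, 5, size=3))
        ens = ensemble_from(np.array(frames))
        fitted = superpose_ensemble(ens, np.arange(6))
        mean = fitted.coordinates.mean(axis=0)
        assert np.abs(fitted.coordinates - mean).max() < 1e-9
        assert compute_rmsf(fitted, np.arange(6)).rmsf.max() < 1e-9

    def test_idempotent(self, rng):
        ens = random_ensemble(rng)
        once = superpose_ensemble(ens, np.arange(ens.n_atoms))
        twice = superpose_ensemble(once, np.arange(ens.n_atoms))
        assert np.abs(twice.coordinates - once.coordinates).max() < 1e-9

    def test_known_rotation_recovered(self, rng):
        base = rng.uniform(0, 10, size=(5, 3))
        R90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        ens = ensemble_from(np.array([base, base @ R90.T]))
        fitted = superpose_ensemble(ens, np.arange(5))
        assert np.abs(fitted.coordinates[1] - fitted.coordinates[0]).max() < 1e-9

    def test_internal_geometry_preserved(self, rng):
        ens = random_ensemble(rng, n_frames=6)
        fitted = superpose_ensemble(ens, np.arange(ens.n_atoms))
        for before, after in zip(ens.coordinates, fitted.coordinates):
            d0 = np.linalg.norm(before[:, None] - before[None], axis=-1)
            d1 = np.linalg.norm(after[:, None] - after[None], axis=-1)
            assert np.abs(d0 - d1).max() < 1e-9

    def test_collinear_selection_rejected(self):
        line = np.stack([np.linspace(0, 5, 4), np.zeros(4), np.zeros(4)], axis=1)
        coords = np.array([line, line + 0.1])
        with pytest.raises(ValidationError):
            superpose_ensemble(ensemble_from(coords), np.arange(4))

    def test_too_few_fit_atoms_rejected(self, rng):
        ens = random_ensemble(rng)
        with pytest.raises(ValidationError):
            superpose_ensemble(ens, [0, 1])


class TestMeanStructure:
    def test_two_frames(self):
        coords = np.zeros((2, 1, 3))
        coords[1, 0, 0] = 2.0
        np.testing.assert_allclose(
            mean_structure(ensemble_from(coords)), [[1.0, 0.0, 0.0]]
        )

    def test_constant_ensemble(self, rng):
        frame = rng.uniform(size=(4, 3))
        ens = ensemble_from(np.repeat(frame[None], 3, axis=0))
        np.testing.assert_allclose(mean_structure(ens), frame)

    def test_gaussian_center_recovered(self, rng):
        center = np.array([[1.0, -2.0, 3.0]])
        sigma = 0.5
        ens = ensemble_from(center[None] + rng.normal(scale=sigma, size=(200, 1, 3)))
        assert np.abs(mean_structure(ens) - center).max() < 4 * sigma / np.sqrt(200)


class TestRmsf:
    def test_constant_is_zero(self, rng):
        frame = rng.uniform(size=(5, 3))
        ens = ensemble_from(np.repeat(frame[None], 4, axis=0))
        np.testing.assert_allclose(compute_rmsf(ens, np.arange(5)).rmsf, 0.0)

    def test_two_frame_hand_value(self):
        coords = np.zeros((2, 1, 3))
        coords[1, 0, 0] = 2.0
        profile = compute_rmsf(ensemble_from(coords), [0])
        np.testing.assert_allclose(profile.rmsf, [1.0])  # <dx^2> = 1 with T denominator

    def test_isotropic_gaussian_closed_form(self, rng):
        sigma = 0.5
        ens = ensemble_from(rng.normal(scale=sigma, size=(20000, 2, 3)))
        rmsf = compute_rmsf(ens, [0, 1]).rmsf
        np.testing.assert_allclose(rmsf, SQRT3 * sigma, rtol=0.02)

    def test_empty_selection_rejected(self, rng):
        with pytest.raises(ValidationError):
            compute_rmsf(random_ensemble(rng), [])


class TestPairCorrelation:
    def test_self_pair_is_sqrt3(self):
        ens = sinusoid_ensemble()
        pmap = compute_pair_correlation(ens, [(0, 0)])
        np.testing.assert_allclose(np.diag(pmap.rho[0]), 1.0, atol=1e-12)
        np.testing.assert_allclose(pmap.rho[0] - np.diag(np.diag(pmap.rho[0])), 0.0, atol=1e-9)
        np.testing.assert_allclose(pmap.pcc[0], SQRT3, atol=1e-9)

    def test_copied_deviations_give_sqrt3(self):
        ens = sinusoid_ensemble()
        pmap = compute_pair_correlation(ens, [(0, 1)])
        np.testing.assert_allclose(pmap.pcc[0], SQRT3, atol=1e-9)
        assert not pmap.degenerate[0]

    def test_independent_atoms_near_zero(self, rng):
        ens = ensemble_from(rng.normal(size=(5000, 2, 3)))
        pmap = compute_pair_correlation(ens, [(0, 1)])
        assert pmap.pcc[0] < 0.2

    def test_symmetry_exact(self, rng):
        ens = random_ensemble(rng)
        forward = compute_pair_correlation(ens, [(2, 5)]).pcc[0]
        backward = compute_pair_correlation(ens, [(5, 2)]).pcc[0]
        assert forward == backward

    def test_bounds(self, rng):
        ens = random_ensemble(rng, n_frames=30, n_atoms=6)
        pairs = [(i, j) for i in range(6) for j in range(i, 6)]
        pmap = compute_pair_correlation(ens, pairs)
        assert np.all(np.abs(pmap.rho) <= 1 + 1e-12)
        assert np.all(pmap.pcc >= 0) and np.all(pmap.pcc <= 3 + 1e-12)
        self_pcc = pmap.pcc[[k for k, (i, j) in enumerate(pairs) if i == j]]
        assert np.all(self_pcc >= SQRT3 - 1e-9)

    def test_zero_variance_axis_flagged_not_nan(self, rng):
        coords = rng.normal(size=(50, 2, 3))
        coords[:, 1, 2] = 7.0  # z of atom 1 frozen
        pmap = compute_pair_correlation(ensemble_from(coords), [(0, 1), (0, 0)])
        assert pmap.degenerate[0]
        assert not pmap.degenerate[1]
        assert np.all(np.isfinite(pmap.rho))
        np.testing.assert_allclose(pmap.rho[0][:, 2], 0.0)

    def test_mean_normalization_is_sum_over_three(self, rng):
        ens = random_ensemble(rng)
        s = compute_pair_correlation(ens, [(0, 1)]).pcc[0]
        m = compute_pair_correlation(ens, [(0, 1)], normalization="mean").pcc[0]
        np.testing.assert_allclose(m, s / 3.0, rtol=1e-12)

    def test_pair_out_of_range_rejected(self, rng):
        with pytest.raises(ValidationError):
            compute_pair_correlation(random_ensemble(rng), [(0, 99)])

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValidationError):
            compute_pair_correlation(ensemble_from(np.zeros((2, 3, 3))), [(0, 1)])


class TestOracleEquivalence:
    def test_rmsf_and_pcc_match_literal_loops(self, rng):
        ens = random_ensemble(rng, n_frames=60, n_atoms=10)
        sel = np.arange(10)
        np.testing.assert_allclose(
            compute_rmsf(ens, sel).rmsf,
            rmsf_oracle(ens.coordinates.tolist()),
            atol=1e-10,
        )
        pairs = [(0, 3), (2, 7), (4, 4), (1, 9)]
        pmap = compute_pair_correlation(ens, pairs)
        for k, (i, j) in enumerate(pairs):
            assert abs(pmap.pcc[k] - pcc_oracle(ens.coordinates.tolist(), i, j)) < 1e-10


class TestRigidMotionInvariance:
    def test_rmsf_and_pcc_invariant(self, rng):
        ens = random_ensemble(rng, n_frames=40, n_atoms=7)
        R = Rotation.random(random_state=rng).as_matrix()
        shift = np.array([3.0, -1.0, 8.0])
        moved = ensemble_from(ens.coordinates @ R.T + shift)
        sel = np.arange(7)
        pairs = [(0, 1), (2, 6), (3, 3)]
        # anchoring to a common reference orientation makes the statistics
        # independent of how the input frames were globally placed
        a = superpose_ensemble(ens, sel, reference=ens.coordinates[0])
        b = superpose_ensemble(moved, sel, reference=ens.coordinates[0])
        np.testing.assert_allclose(
            compute_rmsf(a, sel).rmsf, compute_rmsf(b, sel).rmsf, atol=1e-8
        )
        np.testing.assert_allclose(
            compute_pair_correlation(a, pairs).pcc,
            compute_pair_correlation(b, pairs).pcc,
            atol=1e-8,
        )


class TestStateMetrics:
    def test_distance_345(self, toy_receptor):
        top, ref = toy_receptor
        coords = np.repeat(ref[None], 3, axis=0)
        ca1, ca2 = top.calpha_index(1), top.calpha_index(2)
        coords[:, ca1] = [0.0, 0.0, 0.0]
        coords[:, ca2] = [3.0, 4.0, 0.0]
        metrics = compute_state_metrics(
            ensemble_from(coords), ref, top, MonitorConfig(distance_pair=(1, 2))
        )
        np.testing.assert_allclose(metrics.distances, 5.0)

    def test_rmsd_zero_for_reference_ensemble(self, toy_receptor):
        top, ref = toy_receptor
        coords = np.repeat(ref[None], 4, axis=0)
        config = MonitorConfig(
            rmsd_monitors=(RmsdMonitor("backbone", AtomQuery(heavy=True)),)
        )
        metrics = compute_state_metrics(ensemble_from(coords), ref, top, config)
        np.testing.assert_allclose(metrics.rmsd["backbone"], 0.0, atol=1e-9)

    def test_distance_translation_invariant(self, toy_receptor):
        top, ref = toy_receptor
        coords = np.repeat(ref[None], 3, axis=0)
        config = MonitorConfig(distance_pair=(3, 17))
        d0 = compute_state_metrics(ensemble_from(coords), ref, top, config).distances
        d1 = compute_state_metrics(
            ensemble_from(coords + np.array([1.0, 0.0, 0.0])), ref, top, config
        ).distances
        np.testing.assert_allclose(d0, d1, atol=1e-12)

    def test_missing_calpha_rejected(self, toy_receptor):
        top, ref = toy_receptor
        coords = np.repeat(ref[None], 3, axis=0)
        with pytest.raises(ValidationError):
            compute_state_metrics(
                ensemble_from(coords), ref, top, MonitorConfig(distance_pair=(1, 999))
            )
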
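"""Mixing-matrix construction and the two-stage deconvolution inverse problem."""

import numpy as np
import pytest

from fluxcycle.deconvolution import (
    abundance_mixing_matrix,
    aggregate_bins_to_phases,
    aggregate_pool_measurements,
    build_mixing_matrix,
    deconvolve_mids,
    deconvolve_pools,
    select_lambda_lcurve,
)
from fluxcycle.population import PhaseDefinition, PopulationParams


class TestMixingMatrix:
    def test_rows_are_stochastic(self):
        p = PopulationParams(T=20.0, theta0=0.0, s0=0.05, D=0.001)
        W = build_mixing_matrix(p, np.arange(8) * 2.5, 6)
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(W >= 0)

    def test_sharp_population_gives_permutation_rows(self):
        p = PopulationParams(T=20.0, theta0=0.0, s0=0.0, D=0.0)
        W = build_mixing_matrix(p, np.array([2.5, 7.5, 12.5]), 4)
        np.testing.assert_allclose(W, np.eye(4)[[0, 1, 2]], atol=1e-12)

    def test_single_release_single_bin(self):
        p = PopulationParams(T=20.0, theta0=0.0, s0=0.1, D=0.01)
        W = build_mixing_matrix(p, np.array([3.0]), 1)
        np.testing.assert_allclose(W, [[1.0]])


class TestPoolDeconvolution:
    def test_identity_mixing_returns_measurements(self):
        P = deconvolve_pools(np.array([2.0, 4.0]), np.array([1.0, 1.0]), np.eye(2), lam=0.0)
        np.testing.assert_allclose(P, [2.0, 4.0], atol=1e-10)

    def test_exact_two_by_two_solve(self):
        W = np.array([[0.5, 0.5], [0.25, 0.75]])
        P = deconvolve_pools(np.array([3.0, 3.5]), np.array([0.1, 0.1]), W, lam=0.0)
        np.testing.assert_allclose(P, [2.0, 4.0], atol=1e-8)

    def test_constant_measurements_fit_with_zero_residual(self):
        rng = np.random.default_rng(3)
        W = rng.dirichlet(np.ones(4), size=6)
        meas = np.full(6, 2.5)
        P = deconvolve_pools(meas, np.full(6, 0.1), W, lam=0.0)
        np.testing.assert_allclose(W @ P, meas, atol=1e-8)

    def test_dead_bin_without_smoothing_is_an_error(self):
        W = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="unidentifiable"):
            deconvolve_pools(np.array([1.0, 1.0]), np.array([0.1, 0.1]), W, lam=0.0)

    def test_replicate_aggregation_shrinks_uncertainty(self):
        vals = np.full((4, 6), 2.0)
        sds = np.full((4, 6), 0.2)
        mean, sd = aggregate_pool_measurements([(vals, sds), (vals, sds)])
        np.testing.assert_allclose(mean, 2.0)
        np.testing.assert_allclose(sd, 0.2 / np.sqrt(12))


class TestMidDeconvolution:
    def test_single_bin_passthrough(self):
        meas = np.array([[[0.3, 0.7], [0.1, 0.9]]])  # (R=1, T=2, K=2)
        out, flagged = deconvolve_mids(meas, np.array([[1.0]]), np.array([2.0]), lam=0.0)
        np.testing.assert_allclose(out[0], meas[0], atol=1e-9)
        assert flagged == []

    def test_identical_bins_reproduce_shared_mid(self):
        rng = np.random.default_rng(1)
        W = rng.dirichlet(np.ones(3), size=5)
        mid = np.array([0.2, 0.5, 0.3])
        meas = np.tile(mid, (5, 2, 1))
        out, _ = deconvolve_mids(meas, W, np.array([1.0, 2.0, 0.5]), lam=0.5)
        for b in range(3):
            np.testing.assert_allclose(out[b], np.tile(mid, (2, 1)), atol=1e-6)

    def test_well_conditioned_recovery_is_exact(self):
        rng = np.random.default_rng(2)
        B = 3
        W = np.eye(B) + 0.05
        W /= W.sum(axis=1, keepdims=True)
        pools = np.array([1.0, 2.0, 3.0])
        truth = rng.dirichlet(np.ones(4), size=(B, 2))  # (B, T, K)
        A = abundance_mixing_matrix(W, pools)
        meas = np.einsum("rb,btk->rtk", A, truth)
        out, _ = deconvolve_mids(meas, W, pools, lam=0.0)
        np.testing.assert_allclose(out, truth, atol=1e-6)

    def test_outputs_live_on_the_simplex(self, osc_bundle):
        m = osc_bundle.measurements["glc"]
        met = "Cit"
        out, _ = deconvolve_mids(
            m.mids[met], osc_bundle.truth.mixing, osc_bundle.truth.bin_pools[met],
            lam=0.1, sd=m.mid_sds[met]
        )
        assert np.all(out >= 0)
        np.testing.assert_allclose(out.sum(axis=2), 1.0, atol=1e-9)

    def test_infinite_smoothing_collapses_bins_to_common_signal(self):
        rng = np.random.default_rng(4)
        W = rng.dirichlet(np.ones(4), size=6)
        pools = np.array([1.0, 1.5, 0.5, 2.0])
        truth = rng.dirichlet(np.ones(3), size=(4, 1))
        meas = np.einsum("rb,btk->rtk", abundance_mixing_matrix(W, pools), truth)
        out, _ = deconvolve_mids(meas, W, pools, lam=1e8)
        spread = out.max(axis=0) - out.min(axis=0)
        assert spread.max() < 1e-3


class TestLambdaSelection:
    def test_lcurve_picks_an_interior_corner(self):
        rng = np.random.default_rng(5)
        W = rng.dirichlet(np.ones(6), size=8)
        truth = 2.0 + np.cos(2 * np.pi * (np.arange(6) + 0.5) / 6)
        meas = W @ truth + rng.normal(0, 0.05, 8)
        sd = np.full(8, 0.05)
        lams = np.logspace(-4, 2, 13)

        def solve(lam):
            P = deconvolve_pools(meas, sd, W, lam=lam)
            return P, float(np.linalg.norm((W @ P - meas) / sd))

        lam = select_lambda_lcurve(solve, lams)
        assert lams[0] < lam < lams[-1]


class TestPhaseAggregation:
    def test_uniform_bins_average_exactly(self):
        phases = PhaseDefinition(("G1", "S"), (0.0, 0.5, 1.0))
        pools = np.array([1.0, 3.0, 2.0, 4.0])
        mids = np.tile(np.array([0.25, 0.75]), (4, 1, 1))  # (B, T=1, K=2)
        ppools, pmids = aggregate_bins_to_phases(pools, mids, phases)
        assert ppools["G1"] == pytest.approx(2.0)
        assert ppools["S"] == pytest.approx(3.0)
        np.testing.assert_allclose(pmids["G1"], [[0.25, 0.75]])

    def test_aggregated_mids_are_abundance_weighted(self):
        phases = PhaseDefinition(("G1", "S"), (0.0, 0.5, 1.0))
        pools = np.array([3.0, 1.0, 1.0, 1.0])
        mids = np.zeros((4, 1, 2))
        mids[0] = [1.0, 0.0]
        mids[1] = [0.0, 1.0]
        mids[2:] = [0.5, 0.5]
        _, pmids = aggregate_bins_to_phases(pools, mids, phases)
        np.testing.assert_allclose(pmids["G1"], [[0.75, 0.25]])
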
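"""Labeling kinetics: EMU simulation, oracle equivalence, steady states,
natural-abundance correction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fluxcycle import (
    FluxMap,
    parse_network,
    simulate_labeling,
    simulate_labeling_bruteforce,
    steady_state_mids,
    correct_natural_abundance,
)
from fluxcycle.labeling import (
    TracerSpec,
    enrichment,
    fully_labeled_mid,
    marginal_mid,
    natural_abundance_matrix,
    unlabeled_mid,
)
from conftest import random_toy_network

SINGLE_POOL = """
[metabolites]
S, 2, 1.0, source, 0.0
B, 2, {pool}, balanced, {dil}
Snk, 2, 1.0, sink, 0.0
[reactions]
vin: S (ab) -> B (ab)
vout: B (ab) -> Snk (ab)
"""


def single_pool(pool=1.0, dil=0.0):
    return parse_network(SINGLE_POOL.format(pool=pool, dil=dil))


class TestClosedForm:
    @pytest.mark.parametrize("pool,tau", [(1.0, 1.0), (2.0, 2.0)])
    def test_exponential_turnover(self, pool, tau):
        """Unlabeled fraction of a single balanced pool is exp(-(v/C) tau)."""
        net = single_pool(pool)
        fm = FluxMap(net={"vin": 1.0, "vout": 1.0})
        tr = TracerSpec("t", {"S": fully_labeled_mid(2)})
        res = simulate_labeling(net, fm, tr, [tau])
        expected = np.exp(-tau / pool)
        assert res["B"].mids[0] == pytest.approx([expected, 0.0, 1.0 - expected], abs=1e-8)

    def test_time_zero_is_unlabeled(self, tca_network, tca_fluxmap, glc_tracer):
        res = simulate_labeling(tca_network, tca_fluxmap, glc_tracer, [0.0])
        for met, tc in res.items():
            if not tca_network.metabolites[met].is_source:
                assert tc.mids[0] == pytest.approx(unlabeled_mid(tc.n_carbons), abs=1e-12)

    def test_flux_pool_joint_scaling_invariance(self, toy_chain, glc_tracer):
        """Scaling all fluxes and pools by c leaves trajectories unchanged;
        scaling only fluxes by c compresses time by c."""
        tr = TracerSpec("t", {"S": fully_labeled_mid(2)})
        fm = FluxMap(net={r: 0.7 for r in toy_chain.reactions})
        times = np.array([0.5, 1.0, 2.0])
        base = simulate_labeling(toy_chain, fm, tr, times)
        c = 3.0
        from fluxcycle.fluxfit import network_with_pools

        pools = {m.name: m.pool_size * c for m in toy_chain.metabolites.values() if m.is_balanced}
        both = simulate_labeling(network_with_pools(toy_chain, pools), fm.scaled(c), tr, times)
        fast = simulate_labeling(toy_chain, fm.scaled(c), tr, times / c)
        for met in ("A", "B", "C"):
            np.testing.assert_allclose(both[met].mids, base[met].mids, atol=1e-7)
            np.testing.assert_allclose(fast[met].mids, base[met].mids, atol=1e-7)

    def test_monotone_enrichment_on_linear_chain(self, toy_chain):
        tr = TracerSpec("t", {"S": fully_labeled_mid(2)})
        fm = FluxMap(net={r: 1.0 for r in toy_chain.reactions})
        times = np.linspace(0.0, 6.0, 25)
        res = simulate_labeling(toy_chain, fm, tr, times)
        for met in ("A", "B", "C"):
            e = [enrichment(m) for m in res[met].mids]
            assert np.all(np.diff(e) >= -1e-9)

    def test_mids_stay_normalized(self, tca_network, tca_fluxmap, gln_tracer):
        res = simulate_labeling(
            tca_network, tca_fluxmap, gln_tracer, [0.0, 0.5, 1.0, 4.0]
        )
        for tc in res.values():
            np.testing.assert_allclose(tc.mids.sum(axis=1), 1.0, atol=1e-6)


class TestOracleEquivalence:
    def test_single_pool_identical(self):
        net = single_pool()
        fm = FluxMap(net={"vin": 1.0, "vout": 1.0})
        tr = TracerSpec("t", {"S": fully_labeled_mid(2)})
        times = [0.0, 0.5, 1.0, 2.0]
        emu = simulate_labeling(net, fm, tr, times, rtol=1e-11, atol=1e-13)
        bf = simulate_labeling_bruteforce(net, fm, tr, times)
        np.testing.assert_allclose(emu["B"].mids, bf["B"].mids, atol=1e-9)

    def test_symmetric_metabolite_scrambles_positions(self):
        """A positionally one-sided condensation into a symmetric pool yields
        equal labeling of both downstream carbon positions (hand enumeration:
        each position carries half the label)."""
        net = parse_network(
            """
[metabolites]
X, 1, 1.0, source, 0.0
Y, 1, 1.0, source, 0.0
F, 2, 1.0, balanced, 0.0, symmetric
P, 2, 1.0, balanced, 0.0
Snk, 2, 1.0, sink, 0.0
[reactions]
vf: X (a) + Y (b) -> F (ab)
vp: F (ab) -> P (ab)
vout: P (ab) -> Snk (ab)
"""
        )
        fm = FluxMap(net={r: 1.0 for r in net.reactions})
        tr = TracerSpec("t", {"X": np.array([0.0, 1.0]), "Y": np.array([1.0, 0.0])})
        res = simulate_labeling(
            net, fm, tr, [50.0], targets=[("P", (1,)), ("P", (2,))], rtol=1e-10, atol=1e-12
        )
        # F itself is fed only labeled-at-position-1, but consumption scrambles
        assert res["P"].mids[0] == pytest.approx([0.5, 0.5], abs=1e-6)

    def test_random_networks_match_bruteforce(self):
        rng = np.random.default_rng(2024)
        for _ in range(3):
            net, fm = random_toy_network(rng)
            tr = TracerSpec("t", {"S": fully_labeled_mid(2)})
            times = [0.0, 0.3, 1.0, 3.0]
            emu = simulate_labeling(net, fm, tr, times, rtol=1e-11, atol=1e-13)
            bf = simulate_labeling_bruteforce(net, fm, tr, times)
            for met in emu:
                np.testing.assert_allclose(
                    emu[met].mids, bf[met].mids, atol=1e-8, err_msg=met
                )


class TestSteadyState:
    def test_fully_labeled_sources_saturate_chain(self, toy_chain):
        fm = FluxMap(net={r: 1.0 for r in toy_chain.reactions})
        tr = TracerSpec("t", {"S": fully_labeled_mid(2)})
        ss = steady_state_mids(toy_chain, fm, tr)
        for met in ("A", "B", "C"):
            assert ss[met][-1] == pytest.approx(1.0, abs=1e-12)

    def test_dilution_gives_binary_mixture(self):
        net = single_pool(dil=0.5)
        fm = FluxMap(net={"vin": 1.0, "vout": 1.0})
        tr = TracerSpec("t", {"S": fully_labeled_mid(2)})
        ss = steady_state_mids(net, fm, tr)
        assert ss["B"] == pytest.approx([0.5, 0.0, 0.5], abs=1e-12)

    def test_matches_long_integration_on_default_network(
        self, tca_network, tca_fluxmap, glc_tracer
    ):
        ss = steady_state_mids(tca_network, tca_fluxmap, glc_tracer)
        long = simulate_labeling(
            tca_network, tca_fluxmap, glc_tracer, [0.0, 200.0], rtol=1e-10, atol=1e-12
        )
        for met, mid in ss.items():
            np.testing.assert_allclose(long[met].mids[-1], mid, atol=1e-6, err_msg=met)

    def test_zero_turnover_pool_raises(self):
        net = single_pool()
        fm = FluxMap(net={"vin": 0.0, "vout": 0.0})
        tr = TracerSpec("t", {"S": fully_labeled_mid(2)})
        with pytest.raises(Exception, match="B"):
            steady_state_mids(net, fm, tr)


class TestNaturalAbundance:
    def test_pure_unlabeled_one_carbon(self):
        out = correct_natural_abundance(np.array([0.9893, 0.0107]), 1, 0.0107)
        assert out == pytest.approx([1.0, 0.0], abs=1e-12)

    def test_pure_unlabeled_two_carbons(self):
        raw = np.array([0.97871, 0.02117, 0.00011])
        out = correct_natural_abundance(raw, 2, 0.0107)
        assert out == pytest.approx([1.0, 0.0, 0.0], abs=1e-4)

    def test_zero_abundance_is_identity(self):
        raw = np.array([0.2, 0.5, 0.3])
        np.testing.assert_allclose(correct_natural_abundance(raw, 2, 0.0), raw)

    @given(
        st.integers(min_value=1, max_value=6),
        st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=7, max_size=7),
    )
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_roundtrip_inverts_forward_convolution(self, n, weights):
        mid = np.array(weights[: n + 1])
        mid /= mid.sum()
        raw = natural_abundance_matrix(n, 0.0107) @ mid
        np.testing.assert_allclose(
            correct_natural_abundance(raw, n, 0.0107), mid, atol=1e-10
        )

    def test_rejects_unphysical_abundance(self):
        with pytest.raises(ValueError):
            correct_natural_abundance(np.array([1.0, 0.0]), 1, 0.2)


class TestMarginalMid:
    def test_fully_labeled_marginal_is_fully_labeled(self):
        np.testing.assert_allclose(marginal_mid(fully_labeled_mid(4), 2), [0, 0, 1])

    def test_hypergeometric_mixture(self):
        # one of three carbons labeled: a 2-carbon subset carries it w.p. 2/3
        mid = np.array([0.0, 1.0, 0.0, 0.0])
        np.testing.assert_allclose(marginal_mid(mid, 2), [1 / 3, 2 / 3, 0.0])
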
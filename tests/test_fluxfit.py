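"""Flux fitting, profile-likelihood intervals, redox accounting, oscillations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fluxcycle import FluxMap, parse_network, simulate_labeling, validate_steady_state
from fluxcycle.fluxfit import (
    FitConfig,
    FreeFluxBasis,
    compute_redox_oxphos,
    fit_fluxes,
    oscillation_summary,
    profile_likelihood_ci,
)
from fluxcycle.labeling import LabelingTimeCourse, TracerSpec, fully_labeled_mid


def make_obs(network, fluxmap, tracer, times, mets, sd=0.01):
    sim = simulate_labeling(network, fluxmap, tracer, times)
    return {
        m: LabelingTimeCourse(m, times, sim[m].mids, sd=np.full_like(sim[m].mids, sd))
        for m in mets
    }


class TestParameterization:
    def test_every_candidate_satisfies_steady_state(self, toy_branch, tca_network):
        rng = np.random.default_rng(0)
        for net in (toy_branch, tca_network):
            basis = FreeFluxBasis(net)
            for _ in range(5):
                q = rng.uniform(0.1, 2.0, basis.k)
                v = basis.net_fluxes(q)
                fm = FluxMap(net=dict(zip(basis.reaction_ids, v)))
                assert validate_steady_state(fm, net) == []

    def test_pivot_fluxes_are_reproduced_identically(self, tca_network):
        basis = FreeFluxBasis(tca_network)
        q = np.linspace(0.5, 1.5, basis.k)
        fm = basis.to_fluxmap(q)
        np.testing.assert_allclose([fm.net[r] for r in basis.free_ids], q, atol=1e-12)


class TestFitFluxes:
    def test_single_pool_closed_form_rate(self):
        """Exponential labeling at rate v/C = 0.5 with C = 2 implies v = 1."""
        net = parse_network(
            """
[metabolites]
S, 2, 1.0, source, 0.0
B, 2, 2.0, balanced, 0.0
Snk, 2, 1.0, sink, 0.0
[reactions]
vin: S (ab) -> B (ab)
vout: B (ab) -> Snk (ab)
"""
        )
        tr = TracerSpec("t", {"S": fully_labeled_mid(2)})
        times = np.array([0.5, 1.0, 2.0, 4.0])
        u = np.exp(-0.5 * times)
        mids = np.stack([u, np.zeros_like(u), 1 - u], axis=1)
        obs = {"B": LabelingTimeCourse("B", times, mids, sd=np.full_like(mids, 0.01))}
        fit = fit_fluxes(net, [(tr, obs)], FitConfig(n_starts=4, seed=0, flux_upper=5.0))
        assert fit.fluxmap.net["vin"] == pytest.approx(1.0, rel=1e-4)
        assert fit.ssr < 1e-10

    def test_refit_recovers_truth_on_branch(self, toy_branch, toy_branch_fluxmap):
        tr = TracerSpec("t", {"S": fully_labeled_mid(2)})
        times = np.array([0.25, 0.5, 1.0, 2.0, 4.0])
        obs = make_obs(toy_branch, toy_branch_fluxmap, tr, times, ["A", "B"])
        fit = fit_fluxes(toy_branch, [(tr, obs)], FitConfig(n_starts=4, seed=2, flux_upper=5.0))
        for rid, v in toy_branch_fluxmap.net.items():
            assert fit.fluxmap.net[rid] == pytest.approx(v, rel=1e-3)
        assert fit.ssr < 1e-8

    def test_doubled_sigma_on_duplicates_halves_ssr(self, toy_branch, toy_branch_fluxmap):
        tr = TracerSpec("t", {"S": fully_labeled_mid(2)})
        times = np.array([0.5, 1.0, 2.0])
        sim = simulate_labeling(toy_branch, toy_branch_fluxmap, tr, times)
        # evaluate at a non-optimal point so SSR is nonzero
        off = FluxMap(net={k: v * 1.2 for k, v in toy_branch_fluxmap.net.items()})
        from fluxcycle.fluxfit import _FitProblem

        def ssr_for(obs):
            prob = _FitProblem(toy_branch, [(tr, obs)], FitConfig())
            x = prob.basis.from_fluxmap(off)
            return float(np.sum(prob.residuals(x) ** 2))

        obs1 = {
            m: LabelingTimeCourse(m, times, sim[m].mids, sd=np.full_like(sim[m].mids, 0.01))
            for m in ("A", "B")
        }
        # duplicated observations with doubled sigma: same minimizer, half SSR
        times2 = np.repeat(times, 2) + np.tile([0.0, 1e-6], 3)
        obs2 = {
            m: LabelingTimeCourse(
                m,
                times2,
                np.repeat(sim[m].mids, 2, axis=0),
                sd=np.full((6, 3), 0.02),
            )
            for m in ("A", "B")
        }
        assert ssr_for(obs2) == pytest.approx(0.5 * ssr_for(obs1), rel=1e-3)

    def test_unmodeled_metabolite_rejected(self, toy_branch):
        tr = TracerSpec("t", {"S": fully_labeled_mid(2)})
        mids = np.array([[1.0, 0.0, 0.0]])
        obs = {"Ghost": LabelingTimeCourse("Ghost", [1.0], mids)}
        with pytest.raises(KeyError, match="Ghost"):
            fit_fluxes(toy_branch, [(tr, obs)], FitConfig(n_starts=1))


class TestProfileLikelihood:
    @pytest.fixture(scope="class")
    @staticmethod
    def branch_fit(toy_branch, toy_branch_fluxmap):
        tr = TracerSpec("t", {"S": fully_labeled_mid(2)})
        times = np.array([0.25, 0.5, 1.0, 2.0, 4.0])
        obs = make_obs(toy_branch, toy_branch_fluxmap, tr, times, ["A", "B"])
        return fit_fluxes(
            toy_branch, [(tr, obs)], FitConfig(n_starts=3, seed=3, flux_upper=5.0)
        )

    def test_noise_free_interval_contains_truth(self, branch_fit, toy_branch_fluxmap):
        ci = profile_likelihood_ci(branch_fit, "vb")
        assert ci.lo <= toy_branch_fluxmap.net["vb"] <= ci.hi
        assert ci.reliable

    def test_higher_level_never_shrinks_interval(self, branch_fit):
        ci95 = profile_likelihood_ci(branch_fit, "v2", level=0.95)
        ci99 = profile_likelihood_ci(branch_fit, "v2", level=0.99)
        assert ci99.lo <= ci95.lo + 1e-9
        assert ci99.hi >= ci95.hi - 1e-9

    def test_unobservable_flux_reports_open_interval(self):
        net = parse_network(
            """
[metabolites]
S, 2, 1.0, source, 0.0
A, 2, 1.5, balanced, 0.0
S2, 2, 1.0, source, 0.0
C, 2, 1.0, balanced, 0.0
Snk, 2, 1.0, sink, 0.0
[reactions]
vin: S (ab) -> A (ab)
va: A (ab) -> Snk (ab)
vc_in: S2 (ab) -> C (ab)
vc_out: C (ab) -> Snk (ab)
"""
        )
        truth = FluxMap(net={"vin": 1.0, "va": 1.0, "vc_in": 0.5, "vc_out": 0.5})
        tr = TracerSpec("t", {"S": fully_labeled_mid(2)})
        times = np.array([0.5, 1.0, 2.0])
        obs = make_obs(net, truth, tr, times, ["A"])  # C never observed
        fit = fit_fluxes(net, [(tr, obs)], FitConfig(n_starts=3, seed=4, flux_upper=5.0))
        ci = profile_likelihood_ci(fit, "vc_out")
        assert ci.open_hi


class TestRedox:
    ACCT = {
        "nadh": {"pdh": 1.0, "akgdh": 1.0, "mdh": 1.0},
        "nadph": {"idh_ox": 1.0},
        "fadh2": {"sdh": 1.0},
    }

    def test_textbook_tally(self):
        fm = FluxMap(net={"pdh": 1.0, "akgdh": 1.0, "mdh": 1.0, "idh_ox": 1.0, "sdh": 1.0})
        r = compute_redox_oxphos(fm, self.ACCT)
        assert (r.nadh, r.fadh2, r.o2_equivalent) == (4.0, 1.0, 2.5)

    def test_all_zero_fluxes_give_zero_rates(self):
        fm = FluxMap(net={k: 0.0 for t in self.ACCT.values() for k in t})
        r = compute_redox_oxphos(fm, self.ACCT)
        assert r.nadh == r.fadh2 == r.o2_equivalent == 0.0

    def test_exact_linearity(self):
        rng = np.random.default_rng(6)
        keys = [k for t in self.ACCT.values() for k in t]
        v1 = FluxMap(net={k: float(rng.uniform(0, 2)) for k in keys})
        v2 = FluxMap(net={k: float(rng.uniform(0, 2)) for k in keys})
        vsum = FluxMap(net={k: v1.net[k] + v2.net[k] for k in keys})
        r1, r2, rs = (compute_redox_oxphos(v, self.ACCT) for v in (v1, v2, vsum))
        assert rs.nadh == pytest.approx(r1.nadh + r2.nadh)
        assert rs.fadh2 == pytest.approx(r1.fadh2 + r2.fadh2)

    def test_nadph_excluded_on_request(self):
        fm = FluxMap(net={"pdh": 1.0, "akgdh": 0.0, "mdh": 0.0, "idh_ox": 1.0, "sdh": 0.0})
        assert compute_redox_oxphos(fm, self.ACCT).nadh == 2.0
        assert compute_redox_oxphos(fm, self.ACCT, include_nadph=False).nadh == 1.0

    def test_missing_flux_for_accounting_entry_raises(self):
        with pytest.raises(KeyError):
            compute_redox_oxphos(FluxMap(net={"pdh": 1.0}), self.ACCT)

    def test_interval_propagation_matches_ci_halfwidth(
        self, toy_branch, toy_branch_fluxmap
    ):
        """A rate equal to one free flux inherits exactly that flux's CI."""
        from fluxcycle.fluxfit import redox_intervals_from_cis

        tr = TracerSpec("t", {"S": fully_labeled_mid(2)})
        times = np.array([0.25, 0.5, 1.0, 2.0, 4.0])
        obs = make_obs(toy_branch, toy_branch_fluxmap, tr, times, ["A", "B"])
        fit = fit_fluxes(
            toy_branch, [(tr, obs)], FitConfig(n_starts=3, seed=8, flux_upper=5.0)
        )
        fit.ci["vb"] = profile_likelihood_ci(fit, "vb")
        acct = {"nadh": {"vb": 1.0}, "fadh2": {}}
        summary = redox_intervals_from_cis(fit, acct)
        lo, hi = summary.nadh_interval
        ci = fit.ci["vb"]
        assert hi - lo == pytest.approx(ci.hi - ci.lo, rel=1e-9)
        assert lo <= summary.nadh <= hi


class TestOscillationSummary:
    def test_flat_profile_peaks_at_first_phase_by_tie_rule(self):
        s = oscillation_summary({"G1": 1.0, "S": 1.0, "G2M": 1.0}, ("G1", "S", "G2M"))
        assert s.relative_amplitude == 0.0
        assert s.peak_phase == "G1"

    def test_two_phase_arithmetic(self):
        s = oscillation_summary({"G1": 2.0, "S": 4.0}, ("G1", "S"))
        assert s.relative_amplitude == pytest.approx(2.0 / 3.0)
        assert s.peak_phase == "S"

    @given(st.permutations(["G1", "S", "G2M"]))
    @settings(deadline=None, derandomize=True)
    def test_amplitude_invariant_under_relabeling(self, order):
        values = {"G1": 1.0, "S": 3.0, "G2M": 2.0}
        s = oscillation_summary(values, tuple(order))
        assert s.relative_amplitude == pytest.approx(1.0)
        assert s.peak_phase == "S"

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            oscillation_summary({"G1": 0.0, "S": 0.0}, ("G1", "S"))
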
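"""Scenario construction, experiment generation, determinism, recovery scoring."""

import filecmp
from pathlib import Path

import numpy as np
import pytest

from fluxcycle import default_redox_accounting, validate_steady_state
from fluxcycle.deconvolution import (
    abundance_mixing_matrix,
    aggregate_pool_measurements,
    build_mixing_matrix,
    deconvolve_pools,
)
from fluxcycle.fluxfit import compute_redox_oxphos
from fluxcycle.synthetic import evaluate_recovery, generate_experiment, make_scenario


class TestMakeScenario:
    def test_constant_scenario_has_identical_bins(self):
        cfg = make_scenario("constant")
        bins = cfg.bin_fluxmaps()
        for fm in bins[1:]:
            for rid, v in bins[0].net.items():
                assert fm.net[rid] == pytest.approx(v, abs=1e-14)

    def test_oscillating_glucose_peak_lies_in_g1(self):
        cfg = make_scenario("oscillating")
        centers = cfg.bin_centers()
        pdh = np.array([fm.net["pdh"] for fm in cfg.bin_fluxmaps()])
        a, b = cfg.phases.interval("G1")
        assert a <= centers[np.argmax(pdh)] < b
        for rid in ("gls", "idh_red"):
            vals = np.array([fm.net[rid] for fm in cfg.bin_fluxmaps()])
            sa, sb = cfg.phases.interval("S")
            assert sa <= centers[np.argmax(vals)] < sb

    def test_oscillating_nadh_production_constant_across_bins(self):
        cfg = make_scenario("oscillating")
        acct = default_redox_accounting()
        rates = [compute_redox_oxphos(fm, acct).nadh for fm in cfg.bin_fluxmaps()]
        assert max(rates) - min(rates) < 1e-9

    def test_every_bin_fluxmap_is_balanced(self):
        for name in ("constant", "oscillating", "glucose_dominant"):
            cfg = make_scenario(name)
            for fm in cfg.bin_fluxmaps():
                assert validate_steady_state(fm, cfg.network) == []

    def test_unknown_scenario_lists_options(self):
        with pytest.raises(ValueError, match="constant"):
            make_scenario("nope")


class TestGenerateExperiment:
    def test_single_bin_noise_free_passthrough(self, tca_network):
        cfg = make_scenario("constant", seed=1)
        cfg.n_bins = 1
        cfg.mid_noise_sd = 0.0
        cfg.pool_rel_sd = 0.0
        cfg.phase_frac_sd = 0.0
        bundle = generate_experiment(cfg)
        for tr in ("glc", "gln"):
            m = bundle.measurements[tr]
            for met in cfg.observed_metabolites:
                truth = bundle.truth.bin_mids[tr][met][0]
                for r in range(len(cfg.release_times)):
                    np.testing.assert_allclose(m.mids[met][r], truth, atol=1e-12)

    def test_constant_scenario_measurements_release_invariant(self):
        cfg = make_scenario("constant", seed=1)
        cfg.mid_noise_sd = 0.0
        cfg.pool_rel_sd = 0.0
        bundle = generate_experiment(cfg)
        m = bundle.measurements["glc"]
        for met in ("Cit", "Mal"):
            arr = m.mids[met]
            for r in range(1, arr.shape[0]):
                np.testing.assert_allclose(arr[r], arr[0], atol=1e-10)

    def test_noise_free_measurements_lie_in_mixing_row_space(self):
        cfg = make_scenario("oscillating", seed=2)
        cfg.mid_noise_sd = 0.0
        cfg.pool_rel_sd = 0.0
        bundle = generate_experiment(cfg)
        W = bundle.truth.mixing
        for met in ("Cit", "AKG"):
            A = abundance_mixing_matrix(W, bundle.truth.bin_pools[met])
            pred = np.einsum("rb,btk->rtk", A, bundle.truth.bin_mids["glc"][met])
            np.testing.assert_allclose(
                pred, bundle.measurements["glc"].mids[met], atol=1e-10
            )
            np.testing.assert_allclose(
                W @ bundle.truth.bin_pools[met],
                bundle.measurements["glc"].pools[met][:, 0],
                atol=1e-10,
            )

    def test_fixed_seed_gives_byte_identical_files(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_experiment(make_scenario("oscillating", seed=11), d1)
        generate_experiment(make_scenario("oscillating", seed=11), d2)
        files = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        assert files
        for f in files:
            assert filecmp.cmp(d1 / f, d2 / f, shallow=False), f

    def test_noise_never_helps_pool_recovery(self):
        """Mean pool-deconvolution RMSE is monotone in the noise level."""
        levels = [0.0, 0.1, 0.3]
        mean_err = []
        for sd in levels:
            errs = []
            for seed in range(10):
                cfg = make_scenario("oscillating", seed=100 + seed)
                cfg.mid_noise_sd = 0.0
                cfg.pool_rel_sd = sd
                cfg.phase_frac_sd = 0.0
                cfg.observed_metabolites = ["Cit", "Mal"]
                bundle = generate_experiment(cfg)
                W = bundle.truth.mixing
                for met in cfg.observed_metabolites:
                    m = bundle.measurements["glc"]
                    pm, psd = aggregate_pool_measurements([(m.pools[met], m.pool_sds[met])])
                    P = deconvolve_pools(pm, psd, W, lam=0.1)
                    T = bundle.truth.bin_pools[met]
                    errs.append(np.sqrt(np.mean(((P - T) / T) ** 2)))
            mean_err.append(np.mean(errs))
        assert mean_err[0] <= mean_err[1] <= mean_err[2]


class TestEvaluateRecovery:
    def test_perfect_outputs_score_zero(self):
        cfg = make_scenario("oscillating", seed=3)
        cfg.observed_metabolites = ["Cit"]
        bundle = generate_experiment(cfg)
        t = bundle.truth
        rep = evaluate_recovery(t, t.bin_pools, t.bin_mids)
        assert rep.overall_pool_rel_rmse == 0.0
        assert rep.overall_mid_rmse == 0.0

    def test_constant_offset_reports_that_offset(self):
        cfg = make_scenario("oscillating", seed=3)
        cfg.observed_metabolites = ["Cit"]
        bundle = generate_experiment(cfg)
        t = bundle.truth
        shifted = {tr: {m: arr + 0.05 for m, arr in per.items()} for tr, per in t.bin_mids.items()}
        rep = evaluate_recovery(t, t.bin_pools, shifted)
        assert rep.overall_mid_rmse == pytest.approx(0.05, rel=1e-6)

    def test_peak_agreement_detects_shuffled_phases(self):
        cfg = make_scenario("oscillating", seed=3)
        cfg.observed_metabolites = ["Cit"]
        bundle = generate_experiment(cfg)
        t = bundle.truth
        rep = evaluate_recovery(
            t, t.bin_pools, t.bin_mids, est_peaks={"pdh": "G1", "gls": "G2M"}
        )
        assert rep.peak_agreement == {"pdh": True, "gls": False}

    def test_shape_mismatch_is_an_error(self):
        cfg = make_scenario("oscillating", seed=3)
        cfg.observed_metabolites = ["Cit"]
        bundle = generate_experiment(cfg)
        t = bundle.truth
        bad = {m: np.ones(3) for m in t.bin_pools}
        with pytest.raises(ValueError, match="mismatch"):
            evaluate_recovery(t, bad, t.bin_mids)

    def test_ci_coverage_fraction(self):
        cfg = make_scenario("oscillating", seed=3)
        cfg.observed_metabolites = ["Cit"]
        bundle = generate_experiment(cfg)
        t = bundle.truth
        v = t.phase_fluxes("pdh")["G1"]
        cis = {"G1": {"pdh": (v - 0.1, v + 0.1)}, "S": {"pdh": (0.0, 1e-6)}}
        rep = evaluate_recovery(t, t.bin_pools, t.bin_mids, est_cis=cis)
        assert rep.ci_coverage == pytest.approx(0.5)
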
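"""End-to-end orchestration: simulate, analyze, report.

``run_analyze`` chains the stages on a dataset directory:
population fit -> mixing matrix -> pool deconvolution -> MID deconvolution
-> per-phase flux fit -> profile-likelihood CIs -> redox/OxPhos rates ->
oscillation summaries. Every stage's settings and the input file hashes are
logged in the results manifest, which (with the seed) reproduces a run
byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import default_redox_accounting, load_default_network
from .deconvolution import (
    aggregate_bins_to_phases,
    aggregate_pool_measurements,
    build_mixing_matrix,
    deconvolve_mids,
    deconvolve_pools,
    label_bins,
)
from .fluxfit import (
    FitConfig,
    FluxFitResult,
    compute_redox_oxphos,
    fit_fluxes,
    oscillation_summary,
    profile_likelihood_ci,
    redox_intervals_from_cis,
)
from .io import fmt, read_measurements, read_phase_fractions, write_json
from .labeling import LabelingTimeCourse, TracerSpec, fully_labeled_mid
from .network import parse_network
from .population import PhaseDefinition, fit_population_params
from .synthetic import generate_experiment, make_scenario

logger = logging.getLogger("fluxcycle")

SCHEMA_VERSION = 1


@dataclass
class AnalysisSettings:
    """Knobs of the analysis stages; one seed drives all randomness."""

    n_bins: int = 6
    lam_pools: float = 0.1
    lam_mids: float = 0.1
    seed: int = 0
    popfit_starts: int = 8
    fit_starts: int = 4
    fit_rtol: float = 1e-7
    fit_atol: float = 1e-9
    flux_upper: float = 10.0
    profile_fluxes: tuple[str, ...] = ("pdh",)
    summary_fluxes: dict = field(
        default_factory=lambda: {
            "glucose_oxidation": "pdh",
            "glutamine_oxidative": "gls",
            "reductive_carboxylation": "idh_red",
        }
    )
    include_nadph: bool = True
    T_fixed: float | None = None


def _hash_file(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _hash_config(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def run_simulate(
    scenario: str,
    outdir: Path,
    *,
    seed: int = 0,
    n_bins: int = 6,
) -> Path:
    """Generate a synthetic dataset directory with a reproducibility manifest."""
    outdir = Path(outdir)
    cfg = make_scenario(scenario, seed=seed)
    cfg.n_bins = n_bins
    logger.info("simulate: scenario=%s seed=%d bins=%d -> %s", scenario, seed, n_bins, outdir)
    generate_experiment(cfg, outdir)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "stage": "simulate",
        "scenario": scenario,
        "seed": seed,
        "n_bins": n_bins,
        "files": {p.name: _hash_file(p) for p in sorted(outdir.glob("*.csv"))},
        "config_hash": _hash_config({"scenario": scenario, "seed": seed, "n_bins": n_bins}),
    }
    write_json(outdir / "manifest.json", manifest)
    return outdir


def validate_dataset(datadir: Path) -> list[str]:
    """Schema check only; returns a list of problems (empty = valid)."""
    datadir = Path(datadir)
    problems: list[str] = []
    if not (datadir / "network.network").exists():
        problems.append("missing network.network")
    else:
        try:
            parse_network((datadir / "network.network").read_text())
        except Exception as exc:
            problems.append(f"network.network: {exc}")
    meas_files = sorted(datadir.glob("measurements_*.csv"))
    if not meas_files:
        problems.append("no measurements_*.csv files")
    for f in meas_files:
        try:
            m = read_measurements(f)
            for met, arr in m.mids.items():
                sums = arr.sum(axis=2)
                if np.any(np.abs(sums - 1.0) > 1e-3):
                    problems.append(f"{f.name}: {met} MID rows do not sum to 1")
        except Exception as exc:
            problems.append(f"{f.name}: {exc}")
    pf = datadir / "phase_fractions.csv"
    if not pf.exists():
        problems.append("missing phase_fractions.csv")
    else:
        try:
            _, fractions, _ = read_phase_fractions(pf)
            if np.any(np.abs(fractions.sum(axis=1) - 1.0) > 1e-3):
                problems.append("phase_fractions.csv: rows do not sum to 1")
        except Exception as exc:
            problems.append(f"phase_fractions.csv: {exc}")
    return problems


def _tracer_from_name(name: str) -> TracerSpec:
    # tracer naming convention of the shipped scenarios
    if name == "glc":
        return TracerSpec("glc", {"GlcPyr": fully_labeled_mid(3)})
    if name == "gln":
        return TracerSpec("gln", {"GlnSrc": fully_labeled_mid(5)})
    raise ValueError(f"unknown tracer {name!r}; expected 'glc' or 'gln'")


def run_analyze(
    datadir: Path,
    outdir: Path,
    settings: AnalysisSettings | None = None,
) -> dict:
    """Run the full analysis chain on a dataset directory.

    Returns the results dictionary (also serialized into ``outdir``).
    """
    settings = settings or AnalysisSettings()
    datadir, outdir = Path(datadir), Path(outdir)
    problems = validate_dataset(datadir)
    if problems:
        raise ValueError(f"dataset {datadir} failed validation: {problems}")
    outdir.mkdir(parents=True, exist_ok=True)

    network = parse_network((datadir / "network.network").read_text())
    meas_files = sorted(datadir.glob("measurements_*.csv"))
    measurements = {
        f.stem.split("_", 1)[1]: read_measurements(f, tracer=f.stem.split("_", 1)[1])
        for f in meas_files
    }
    phase_times, phase_fracs, names = read_phase_fractions(datadir / "phase_fractions.csv")
    phases = PhaseDefinition(names=names)

    logger.info("analyze: population fit on %d time points", len(phase_times))
    popfit = fit_population_params(
        phase_times,
        phase_fracs,
        phases,
        T_fixed=settings.T_fixed,
        n_starts=settings.popfit_starts,
        seed=settings.seed + 1,
    )
    first = next(iter(measurements.values()))
    release_times, chase_times = first.release_times, first.chase_times
    for m in measurements.values():
        if not np.array_equal(m.chase_times, chase_times):
            raise ValueError("chase grids differ between tracer files")
    W = build_mixing_matrix(popfit.params, release_times, settings.n_bins)

    logger.info("analyze: deconvolution (B=%d, lam_pools=%g, lam_mids=%g)",
                settings.n_bins, settings.lam_pools, settings.lam_mids)
    mets = first.metabolites
    bin_pools: dict[str, np.ndarray] = {}
    bin_mids: dict[str, dict[str, np.ndarray]] = {t: {} for t in measurements}
    flagged: dict[str, list[int]] = {}
    for met in mets:
        reps = [(m.pools[met], m.pool_sds[met]) for m in measurements.values()]
        pool_meas, pool_sd = aggregate_pool_measurements(reps)
        bin_pools[met] = deconvolve_pools(pool_meas, pool_sd, W, lam=settings.lam_pools)
        for tname, m in measurements.items():
            bin_mids[tname][met], fl = deconvolve_mids(
                m.mids[met], W, bin_pools[met], lam=settings.lam_mids, sd=m.mid_sds[met]
            )
            if fl:
                flagged[f"{tname}:{met}"] = fl

    _write_deconvolution_csv(outdir, bin_pools, bin_mids, chase_times, phases)

    # bin -> phase aggregation (abundance-weighted)
    phase_pools: dict[str, dict[str, float]] = {}
    phase_mids: dict[str, dict[str, dict[str, np.ndarray]]] = {t: {} for t in measurements}
    for met in mets:
        pp, _ = aggregate_bins_to_phases(bin_pools[met], bin_mids[next(iter(measurements))][met], phases)
        phase_pools[met] = pp
        for tname in measurements:
            _, pm = aggregate_bins_to_phases(bin_pools[met], bin_mids[tname][met], phases)
            phase_mids[tname][met] = pm

    mid_sd_level = float(np.mean([m.mid_sds[met].mean() for m in measurements.values() for met in mets]))
    fits: dict[str, FluxFitResult] = {}
    for pi, phase in enumerate(phases.names):
        obs = []
        for tname in measurements:
            tracer = _tracer_from_name(tname)
            series = {}
            for met in mets:
                mids = phase_mids[tname][met][phase]
                series[met] = LabelingTimeCourse(
                    met, chase_times, mids, sd=np.full_like(mids, mid_sd_level)
                )
            obs.append((tracer, series))
        pools = {met: phase_pools[met][phase] for met in mets}
        cfg = FitConfig(
            n_starts=settings.fit_starts,
            seed=settings.seed + 100 + pi,
            rtol=settings.fit_rtol,
            atol=settings.fit_atol,
            flux_upper=settings.flux_upper,
        )
        logger.info("analyze: fitting fluxes for phase %s (%d starts)", phase, cfg.n_starts)
        fit = fit_fluxes(network, obs, cfg, pools=pools, phase=phase)
        for rid in settings.profile_fluxes:
            logger.info("analyze: profile CI for %s in phase %s", rid, phase)
            fit.ci[rid] = profile_likelihood_ci(fit, rid)
        fits[phase] = fit

    accounting = default_redox_accounting()
    redox = {}
    for phase, fit in fits.items():
        if fit.ci:
            redox[phase] = redox_intervals_from_cis(
                fit, accounting, include_nadph=settings.include_nadph
            )
        else:
            redox[phase] = compute_redox_oxphos(
                fit.fluxmap, accounting, include_nadph=settings.include_nadph
            )
    summaries = {}
    for label, rid in settings.summary_fluxes.items():
        per_phase = {phase: fits[phase].fluxmap.net[rid] for phase in phases.names}
        s = oscillation_summary(per_phase, phases.names)
        summaries[label] = {
            "reaction": rid,
            "per_phase": per_phase,
            "relative_amplitude": s.relative_amplitude,
            "peak_phase": s.peak_phase,
        }
    nadh_per_phase = {phase: redox[phase].nadh for phase in phases.names}
    s = oscillation_summary(nadh_per_phase, phases.names)
    summaries["nadh_production"] = {
        "reaction": None,
        "per_phase": nadh_per_phase,
        "relative_amplitude": s.relative_amplitude,
        "peak_phase": s.peak_phase,
    }

    results = {
        "schema_version": SCHEMA_VERSION,
        "population_fit": {
            "T": popfit.params.T,
            "theta0": popfit.params.theta0,
            "s0": popfit.params.s0,
            "D": popfit.params.D,
            "ssr": popfit.ssr,
        },
        "flagged_bins": flagged,
        "phase_pools": phase_pools,
        "flux_fits": {
            phase: {
                "fluxes": fit.fluxmap.net,
                "free_parameters": dict(zip(fit.param_names, fit.x.tolist())),
                "ssr": fit.ssr,
                "n_starts_converged": fit.n_starts_converged,
                "ci95": {
                    rid: {
                        "lo": ci.lo,
                        "hi": ci.hi,
                        "open_lo": ci.open_lo,
                        "open_hi": ci.open_hi,
                        "reliable": ci.reliable,
                    }
                    for rid, ci in fit.ci.items()
                },
            }
            for phase, fit in fits.items()
        },
        "redox": {
            phase: {
                "nadh": r.nadh,
                "fadh2": r.fadh2,
                "o2_equivalent": r.o2_equivalent,
                "nadh_interval": list(r.nadh_interval) if r.nadh_interval else None,
                "fadh2_interval": list(r.fadh2_interval) if r.fadh2_interval else None,
                "o2_interval": list(r.o2_interval) if r.o2_interval else None,
            }
            for phase, r in redox.items()
        },
        "oscillations": summaries,
        "settings": {**asdict(settings), "profile_fluxes": list(settings.profile_fluxes)},
        "input_hashes": {p.name: _hash_file(p) for p in sorted(datadir.glob("*.csv"))},
    }
    write_json(outdir / "results.json", results)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "stage": "analyze",
        "settings": results["settings"],
        "input_hashes": results["input_hashes"],
        "config_hash": _hash_config(results["settings"]),
    }
    write_json(outdir / "manifest.json", manifest)
    return results


def _write_deconvolution_csv(outdir, bin_pools, bin_mids, chase_times, phases):
    B = len(next(iter(bin_pools.values())))
    bin_phase = label_bins(B, phases)
    lines = ["bin,phase,metabolite,pool_size"]
    for met in bin_pools:
        for b in range(B):
            lines.append(f"{b},{bin_phase[b]},{met},{fmt(bin_pools[met][b])}")
    (Path(outdir) / "deconvolved_pools.csv").write_text("\n".join(lines) + "\n")
    for tname, per_met in bin_mids.items():
        rows = ["bin,phase,metabolite,tau_h," + ",".join(f"M{i}" for i in range(7))]
        for met in per_met:
            arr = per_met[met]
            for b in range(arr.shape[0]):
                for ti, tau in enumerate(chase_times):
                    vals = [fmt(v) for v in arr[b, ti]] + [""] * (7 - arr.shape[2])
                    rows.append(f"{b},{bin_phase[b]},{met},{fmt(tau)}," + ",".join(vals))
        (Path(outdir) / f"deconvolved_mids_{tname}.csv").write_text("\n".join(rows) + "\n")


def run_report(results_dir: Path) -> str:
    """Render a deterministic markdown report from a results directory."""
    results_dir = Path(results_dir)
    rpath = results_dir / "results.json"
    if not rpath.exists():
        raise FileNotFoundError(f"incomplete results: missing {rpath}")
    results = json.loads(rpath.read_text())
    lines = ["# fluxcycle analysis report", ""]
    pf = results["population_fit"]
    lines += [
        "## Population fit",
        "",
        f"Cycle length T = {pf['T']:.4g} h, theta0 = {pf['theta0']:.4g}, "
        f"s0 = {pf['s0']:.4g}, D = {pf['D']:.4g} (SSR {pf['ssr']:.3g})",
        "",
        "## Per-phase fluxes",
        "",
    ]
    for phase, fit in results["flux_fits"].items():
        lines += [f"### {phase} (SSR {fit['ssr']:.4g})", "", "| reaction | net flux | 95% CI |", "|---|---|---|"]
        for rid in sorted(fit["fluxes"]):
            ci = fit["ci95"].get(rid)
            if ci:
                lo = "open" if ci["open_lo"] else f"{ci['lo']:.4g}"
                hi = "open" if ci["open_hi"] else f"{ci['hi']:.4g}"
                note = "" if ci["reliable"] else " (unreliable)"
                ci_txt = f"[{lo}, {hi}]{note}"
            else:
                ci_txt = "-"
            lines.append(f"| {rid} | {fit['fluxes'][rid]:.4g} | {ci_txt} |")
        lines.append("")
    lines += ["## Redox / OxPhos", "", "| phase | NADH | FADH2 | O2-equivalent |", "|---|---|---|---|"]
    for phase, r in results["redox"].items():
        lines.append(f"| {phase} | {r['nadh']:.4g} | {r['fadh2']:.4g} | {r['o2_equivalent']:.4g} |")
    lines += ["", "## Oscillations", "", "| quantity | relative amplitude | peak phase |", "|---|---|---|"]
    for label, s in results["oscillations"].items():
        lines.append(f"| {label} | {s['relative_amplitude']:.4g} | {s['peak_phase']} |")
    text = "\n".join(lines) + "\n"
    (results_dir / "report.md").write_text(text)
    return text
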
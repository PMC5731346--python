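"""Synthetic pulse-chase temporal-fluxomics experiments with known truth.

Emulates the full study design: a synchronized population is released, its
position distribution advects and broadens; at each release time a tracer
switch starts a chase, during which each position bin's metabolism (its flux
map and pools, frozen over the short chase) imprints bin-specific labeling
kinetics; the instrument sees the abundance-weighted population average plus
noise. Everything the pipeline later estimates is serialized as ground truth.

Scenarios
---------
``constant``
    identical fluxes in every bin — the null case.
``oscillating``
    glucose oxidation (PDH) peaks in G1, glutamine-derived oxidative flux and
    reductive carboxylation peak in S, and the per-bin flux maps are solved so
    that total NADH production is identical in every bin: complementary
    oscillations with phase-constant reducing-equivalent output.
``glucose_dominant``
    phase-constant fluxes with glucose oxidation dominating glutamine entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .deconvolution import build_mixing_matrix
from .fluxfit import compute_redox_oxphos, oscillation_summary
from .io import TracerMeasurements, write_json, write_measurements, write_phase_fractions, fmt
from .labeling import TracerSpec, fully_labeled_mid, simulate_labeling
from .network import FluxMap, Network, serialize_network, validate_steady_state
from .population import PhaseDefinition, PopulationParams, evolve_density, phase_fractions

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "ExperimentBundle",
    "make_scenario",
    "generate_experiment",
    "evaluate_recovery",
    "RecoveryReport",
]

SCENARIOS = ("constant", "oscillating", "glucose_dominant")

# Oscillation geometry: anchor flux maps sit at the phase centers.
_ANCHOR_POSITIONS = {"G1": 0.2, "S": 0.575, "G2M": 0.875}
_NADH_TARGET = 4.6  # per-bin NADH production enforced across every anchor

# (pdh, gls, idh_red) at each anchor; pc and acl are phase-constant.
_SCENARIO_ANCHORS = {
    "oscillating": {
        "G1": (1.4, 0.6, 0.15),
        "S": (1.0, 0.9, 0.30),
        "G2M": (1.0, 0.6, 0.15),
    },
    "constant": {
        "G1": (1.0, 0.6, 0.15),
        "S": (1.0, 0.6, 0.15),
        "G2M": (1.0, 0.6, 0.15),
    },
    "glucose_dominant": {
        "G1": (1.6, 0.3, 0.05),
        "S": (1.6, 0.3, 0.05),
        "G2M": (1.6, 0.3, 0.05),
    },
}
_PC, _ACL = 0.3, 0.2


def _anchor_fluxmap(pdh: float, gls: float, idh_red: float) -> FluxMap:
    """Solve the remaining TCA fluxes from the balances plus NADH constancy.

    With yields NADH(P): pdh, idh_ox, akgdh, mdh = +1, idh_red = -1, the total
    reducing-equivalent production is 4*pdh + 2*gls - 3*acc_out, independent
    of idh_red; acc_out is chosen to pin it at the scenario target.
    """
    acc_out = (4.0 * pdh + 2.0 * gls - _NADH_TARGET) / 3.0
    cs = pdh + _ACL - acc_out
    idh_ox = pdh - acc_out + idh_red
    tca_flux = pdh - acc_out + gls  # akgdh = sdh = fh = mdh
    net = dict(
        pyr_in=pdh + _PC,
        pdh=pdh,
        pc=_PC,
        cs=cs,
        idh_ox=idh_ox,
        idh_red=idh_red,
        akgdh=tca_flux,
        sdh=tca_flux,
        fh=tca_flux,
        mdh=tca_flux,
        gls=gls,
        gdh=gls,
        acl=_ACL,
        acc_out=acc_out,
        oaa_out=_PC + gls,
    )
    if any(v < 0 for v in net.values()):
        raise ValueError(f"anchor fluxes infeasible: {net}")
    return FluxMap(net=net)


@dataclass
class ScenarioConfig:
    """Fully specified synthetic experiment."""

    name: str
    network: Network
    anchor_fluxmaps: dict[str, FluxMap]
    anchor_positions: dict[str, float]
    pop_params: PopulationParams
    phases: PhaseDefinition
    release_times: np.ndarray
    chase_times: np.ndarray
    tracers: list[TracerSpec]
    observed_metabolites: list[str]
    n_bins: int = 6
    mid_noise_sd: float = 0.01
    pool_rel_sd: float = 0.10
    phase_frac_sd: float = 0.01
    pool_oscillation_amp: float = 0.2
    seed: int = 0

    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) / self.n_bins

    def bin_fluxmaps(self) -> list[FluxMap]:
        """Circular linear interpolation of the anchor flux maps at bin centers.

        Interpolation is linear in flux space, so steady state and the NADH
        constancy constraint (both linear) are inherited by every bin.
        """
        names = list(self.anchor_positions)
        pos = np.array([self.anchor_positions[n] for n in names])
        order = np.argsort(pos)
        pos, names = pos[order], [names[i] for i in order]
        out = []
        for theta in self.bin_centers():
            j = np.searchsorted(pos, theta)
            lo, hi = (j - 1) % len(pos), j % len(pos)
            span = (pos[hi] - pos[lo]) % 1.0 or 1.0
            w = ((theta - pos[lo]) % 1.0) / span
            f_lo, f_hi = self.anchor_fluxmaps[names[lo]], self.anchor_fluxmaps[names[hi]]
            net = {
                rid: (1 - w) * f_lo.net[rid] + w * f_hi.net[rid] for rid in f_lo.net
            }
            out.append(FluxMap(net=net))
        return out

    def bin_pools(self) -> dict[str, np.ndarray]:
        """Per-bin pool sizes: smooth cosine modulation of the network pools."""
        amp = 0.0 if self.name == "constant" else self.pool_oscillation_amp
        theta = self.bin_centers()
        mod = 1.0 + amp * np.cos(2 * np.pi * (theta - 0.3))
        return {
            m.name: m.pool_size * mod
            for m in self.network.metabolites.values()
            if m.is_balanced
        }

    def designed_amplitudes(self) -> dict[str, float]:
        """Relative oscillation amplitude of the designed fluxes over bins."""
        bins = self.bin_fluxmaps()
        out = {}
        for rid in ("pdh", "gls", "idh_red"):
            vals = np.array([fm.net[rid] for fm in bins])
            out[rid] = float((vals.max() - vals.min()) / vals.mean())
        return out


def make_scenario(name: str, seed: int = 0, network: Network | None = None) -> ScenarioConfig:
    """Build one of the shipped study designs.

    Eight release times over one 20-h cycle, six chase times to 4 h, six
    position bins, MID noise sd 0.01 and 10% lognormal pool noise — the
    smallest design for which the mixing matrix stays well conditioned.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; options: {SCENARIOS}")
    if network is None:
        from . import load_default_network

        network = load_default_network()
    anchors = {
        ph: _anchor_fluxmap(*vals) for ph, vals in _SCENARIO_ANCHORS[name].items()
    }
    for ph, fm in anchors.items():
        bad = validate_steady_state(fm, network)
        if bad:
            raise ValueError(f"anchor {ph} violates steady state: {bad}")
    tracers = [
        TracerSpec("glc", {"GlcPyr": fully_labeled_mid(3)}),
        TracerSpec("gln", {"GlnSrc": fully_labeled_mid(5)}),
    ]
    observed = ["Pyr", "AcCoA", "Cit", "AKG", "Suc", "Fum", "Mal", "OAA", "Glu"]
    T_cycle = 20.0
    return ScenarioConfig(
        name=name,
        network=network,
        anchor_fluxmaps=anchors,
        anchor_positions=dict(_ANCHOR_POSITIONS),
        pop_params=PopulationParams(T=T_cycle, theta0=0.0, s0=0.05, D=0.0005),
        phases=PhaseDefinition(),
        release_times=np.arange(8) * (T_cycle / 8.0),
        chase_times=np.array([0.0, 0.25, 0.5, 1.0, 2.0, 4.0]),
        tracers=tracers,
        observed_metabolites=observed,
        seed=seed,
    )


@dataclass
class GroundTruth:
    scenario: str
    bin_fluxmaps: list[FluxMap]
    bin_pools: dict[str, np.ndarray]
    bin_mids: dict[str, dict[str, np.ndarray]]  # tracer -> met -> (B, T, K)
    mixing: np.ndarray  # (R, B), division-weighted
    pop_params: PopulationParams
    phases: PhaseDefinition
    designed_amplitudes: dict[str, float]

    def phase_fluxes(self, rid: str) -> dict[str, float]:
        """Bin-overlap-weighted mean of one flux per phase."""
        B = len(self.bin_fluxmaps)
        edges = np.linspace(0.0, 1.0, B + 1)
        vals = np.array([fm.net[rid] for fm in self.bin_fluxmaps])
        out = {}
        for name in self.phases.names:
            a, b = self.phases.interval(name)
            ov = np.clip(np.minimum(edges[1:], b) - np.maximum(edges[:-1], a), 0.0, None)
            out[name] = float(np.sum(ov * vals) / ov.sum())
        return out


@dataclass
class ExperimentBundle:
    config: ScenarioConfig
    measurements: dict[str, TracerMeasurements]
    phase_times: np.ndarray
    phase_fracs: np.ndarray
    truth: GroundTruth


def generate_experiment(
    config: ScenarioConfig,
    outdir: Path | None = None,
    *,
    rtol: float = 1e-9,
    atol: float = 1e-11,
) -> ExperimentBundle:
    """Simulate the experiment and (optionally) write all schema files.

    For each release time the frozen population density mixes the per-bin
    labeling trajectories (simulated once per bin and tracer); Gaussian noise
    (sd ``mid_noise_sd``) is added to MID channels which are then clipped and
    renormalized, and multiplicative lognormal noise to pools. Identical
    config and seed give byte-identical files.
    """
    net = config.network
    for b, fm in enumerate(config.bin_fluxmaps()):
        bad = validate_steady_state(fm, net)
        if bad:
            raise ValueError(f"bin {b} flux map violates steady state: {bad}")
    rng = np.random.default_rng(config.seed)
    bins = config.bin_fluxmaps()
    pools = config.bin_pools()
    B = config.n_bins
    R = len(config.release_times)
    taus = config.chase_times
    sim_times = taus if taus[0] > 0 else taus  # grid includes tau=0 naturally
    targets = [
        (m, tuple(range(1, net.metabolites[m].n_carbons + 1)))
        for m in config.observed_metabolites
    ]

    from .fluxfit import network_with_pools

    bin_mids: dict[str, dict[str, np.ndarray]] = {tr.name: {} for tr in config.tracers}
    for b in range(B):
        net_b = network_with_pools(net, {m: pools[m][b] for m in pools})
        for tr in config.tracers:
            sim = simulate_labeling(
                net_b, bins[b], tr, sim_times, targets=targets, rtol=rtol, atol=atol
            )
            for met in config.observed_metabolites:
                store = bin_mids[tr.name].setdefault(
                    met, np.zeros((B, len(taus), net.metabolites[met].n_carbons + 1))
                )
                store[b] = sim[met].mids

    W = build_mixing_matrix(config.pop_params, config.release_times, B)

    measurements: dict[str, TracerMeasurements] = {}
    for tr in config.tracers:
        pools_meas: dict[str, np.ndarray] = {}
        pool_sds: dict[str, np.ndarray] = {}
        mids_meas: dict[str, np.ndarray] = {}
        mid_sds: dict[str, np.ndarray] = {}
        for met in config.observed_metabolites:
            P = pools[met]
            pop_pool = W @ P  # (R,)
            A = W * P[None, :]
            A = A / A.sum(axis=1, keepdims=True)
            clean = np.einsum("rb,btk->rtk", A, bin_mids[tr.name][met])
            noisy = clean + rng.normal(0.0, config.mid_noise_sd, clean.shape) if config.mid_noise_sd > 0 else clean.copy()
            noisy = np.clip(noisy, 0.0, None)
            noisy /= noisy.sum(axis=2, keepdims=True)
            # every chase sample re-quantifies the pool (constant over the
            # chase at metabolic steady state -> technical replicates)
            pool_noisy = pop_pool[:, None] * (
                np.exp(rng.normal(0.0, config.pool_rel_sd, (R, len(taus))))
                if config.pool_rel_sd > 0
                else np.ones((R, len(taus)))
            )
            K = clean.shape[2]
            mids_meas[met] = noisy
            mid_sds[met] = np.full((R, len(taus), K), max(config.mid_noise_sd, 1e-4))
            pools_meas[met] = pool_noisy
            pool_sds[met] = np.maximum(config.pool_rel_sd, 1e-4) * pop_pool[:, None] * np.ones(
                (R, len(taus))
            )
        measurements[tr.name] = TracerMeasurements(
            tracer=tr.name,
            release_times=config.release_times,
            chase_times=taus,
            pools=pools_meas,
            pool_sds=pool_sds,
            mids=mids_meas,
            mid_sds=mid_sds,
        )

    fracs = np.array(
        [
            phase_fractions(
                evolve_density(config.pop_params, t, 400), config.phases
            )
            for t in config.release_times
        ]
    )
    if config.phase_frac_sd > 0:
        fracs = fracs + rng.normal(0.0, config.phase_frac_sd, fracs.shape)
        fracs = np.clip(fracs, 1e-9, None)
        fracs /= fracs.sum(axis=1, keepdims=True)

    truth = GroundTruth(
        scenario=config.name,
        bin_fluxmaps=bins,
        bin_pools=pools,
        bin_mids=bin_mids,
        mixing=W,
        pop_params=config.pop_params,
        phases=config.phases,
        designed_amplitudes=config.designed_amplitudes(),
    )
    bundle = ExperimentBundle(
        config=config,
        measurements=measurements,
        phase_times=config.release_times,
        phase_fracs=fracs,
        truth=truth,
    )
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _write_bundle(bundle: ExperimentBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config
    (outdir / "network.network").write_text(serialize_network(cfg.network))
    for name, meas in bundle.measurements.items():
        write_measurements(outdir / f"measurements_{name}.csv", meas)
    write_phase_fractions(
        outdir / "phase_fractions.csv", bundle.phase_times, bundle.phase_fracs, cfg.phases.names
    )
    tdir = outdir / "truth"
    tdir.mkdir(exist_ok=True)
    lines = ["bin,reaction,net_flux"]
    for b, fm in enumerate(bundle.truth.bin_fluxmaps):
        for rid in sorted(fm.net):
            lines.append(f"{b},{rid},{fmt(fm.net[rid])}")
    (tdir / "bin_fluxes.csv").write_text("\n".join(lines) + "\n")
    lines = ["bin,metabolite,pool_size"]
    for met in sorted(bundle.truth.bin_pools):
        for b, v in enumerate(bundle.truth.bin_pools[met]):
            lines.append(f"{b},{met},{fmt(v)}")
    (tdir / "bin_pools.csv").write_text("\n".join(lines) + "\n")
    for tr_name, per_met in bundle.truth.bin_mids.items():
        rows = ["bin,metabolite,tau_h," + ",".join(f"M{i}" for i in range(7))]
        for met in sorted(per_met):
            arr = per_met[met]
            for b in range(arr.shape[0]):
                for ti, tau in enumerate(cfg.chase_times):
                    vals = [fmt(v) for v in arr[b, ti]] + [""] * (7 - arr.shape[2])
                    rows.append(f"{b},{met},{fmt(tau)}," + ",".join(vals))
        (tdir / f"bin_mids_{tr_name}.csv").write_text("\n".join(rows) + "\n")
    lines = ["t_release_h," + ",".join(f"bin{b}" for b in range(cfg.n_bins))]
    for t, row in zip(cfg.release_times, bundle.truth.mixing):
        lines.append(",".join([fmt(t)] + [fmt(v) for v in row]))
    (tdir / "mixing.csv").write_text("\n".join(lines) + "\n")
    write_json(
        tdir / "params.json",
        {
            "scenario": cfg.name,
            "pop_params": {
                "T": cfg.pop_params.T,
                "theta0": cfg.pop_params.theta0,
                "s0": cfg.pop_params.s0,
                "D": cfg.pop_params.D,
            },
            "designed_amplitudes": bundle.truth.designed_amplitudes,
            "seed": cfg.seed,
            "n_bins": cfg.n_bins,
        },
    )


# -- recovery scoring --------------------------------------------------------


@dataclass
class RecoveryReport:
    pool_rel_rmse: dict[str, float]
    mid_rmse: dict[str, float]
    overall_pool_rel_rmse: float
    overall_mid_rmse: float
    ci_coverage: float | None = None
    peak_agreement: dict[str, bool] = field(default_factory=dict)


def evaluate_recovery(
    truth: GroundTruth,
    est_pools: dict[str, np.ndarray],
    est_mids: dict[str, dict[str, np.ndarray]],
    *,
    est_peaks: dict[str, str] | None = None,
    est_cis: dict[str, dict[str, tuple[float, float]]] | None = None,
) -> RecoveryReport:
    """Score pipeline outputs against the generator's ground truth.

    ``est_mids`` mirrors ``truth.bin_mids`` (tracer -> metabolite -> B,T,K);
    ``est_cis`` maps phase -> reaction -> interval, scored against the
    bin-overlap-weighted true phase fluxes.
    """
    pool_rel: dict[str, float] = {}
    for met, P in truth.bin_pools.items():
        if met not in est_pools:
            continue
        est = np.asarray(est_pools[met], dtype=float)
        if est.shape != P.shape:
            raise ValueError(f"{met}: pool shape mismatch {est.shape} vs {P.shape}")
        pool_rel[met] = float(np.sqrt(np.mean(((est - P) / P) ** 2)))
    mid_rmse: dict[str, float] = {}
    for tr_name, per_met in truth.bin_mids.items():
        if tr_name not in est_mids:
            continue
        for met, M in per_met.items():
            if met not in est_mids[tr_name]:
                continue
            est = np.asarray(est_mids[tr_name][met], dtype=float)
            if est.shape != M.shape:
                raise ValueError(f"{tr_name}/{met}: MID shape mismatch")
            mid_rmse[f"{tr_name}:{met}"] = float(np.sqrt(np.mean((est - M) ** 2)))
    coverage = None
    if est_cis:
        hits = total = 0
        for phase, per_rid in est_cis.items():
            for rid, (lo, hi) in per_rid.items():
                v = truth.phase_fluxes(rid)[phase]
                hits += int(lo <= v <= hi)
                total += 1
        coverage = hits / total if total else None
    peaks: dict[str, bool] = {}
    if est_peaks:
        for rid, phase in est_peaks.items():
            true_peak = max(truth.phase_fluxes(rid).items(), key=lambda kv: kv[1])[0]
            peaks[rid] = phase == true_peak
    return RecoveryReport(
        pool_rel_rmse=pool_rel,
        mid_rmse=mid_rmse,
        overall_pool_rel_rmse=float(np.sqrt(np.mean([v**2 for v in pool_rel.values()]))) if pool_rel else float("nan"),
        overall_mid_rmse=float(np.sqrt(np.mean([v**2 for v in mid_rmse.values()]))) if mid_rmse else float("nan"),
        ci_coverage=coverage,
        peak_agreement=peaks,
    )
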
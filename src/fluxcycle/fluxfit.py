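"""Isotopically non-stationary metabolic flux analysis.

Phase-specific fluxes are fitted to (deconvolved) MID time courses by bounded
multistart least squares. Candidate flux maps are parameterized on the null
space of the balanced stoichiometric matrix, so every candidate satisfies
metabolic steady state structurally; the free parameters are the net fluxes
of a pivot reaction subset plus log-scaled exchange fluxes of reversible
reactions. Confidence intervals come from the profile likelihood: the named
flux is walked away from its optimum while all other parameters re-optimize,
until the weighted SSR crosses SSR_min + chi^2(1 df, level).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg
from scipy.optimize import least_squares
from scipy.stats import chi2

from .labeling import LabelingTimeCourse, TracerSpec, simulate_labeling
from .network import FluxMap, Metabolite, Network

__all__ = [
    "FreeFluxBasis",
    "FitConfig",
    "FluxFitResult",
    "ProfileCI",
    "RedoxSummary",
    "OscillationSummary",
    "fit_fluxes",
    "profile_likelihood_ci",
    "compute_redox_oxphos",
    "oscillation_summary",
    "network_with_pools",
]

CHI2_1DF_95 = 3.841458820694124


# -- parameterization --------------------------------------------------------


class FreeFluxBasis:
    """Null-space parameterization of steady-state net fluxes.

    v = basis @ q where q are the net fluxes of the pivot reactions (chosen by
    QR with column pivoting for a well-conditioned basis). Any q yields a
    balanced v; non-negativity of the dependent fluxes is enforced by penalty
    during fitting.
    """

    def __init__(self, network: Network):
        S, mets, rxns = network.stoichiometric_matrix()
        self.reaction_ids = rxns
        N = linalg.null_space(S) if S.size else np.eye(len(rxns))
        if N.shape[1] == 0:
            raise ValueError("stoichiometric matrix has trivial null space; no free fluxes")
        _, _, piv = linalg.qr(N.T, pivoting=True)
        self.pivots = sorted(piv[: N.shape[1]].tolist())
        M = N[self.pivots, :]
        self.basis = N @ np.linalg.inv(M)  # (n_rxn, k); basis[pivots] == I
        self.free_ids = [rxns[i] for i in self.pivots]
        self.k = len(self.pivots)
        self.reversible_ids = [rid for rid in rxns if network.reactions[rid].reversible]

    def net_fluxes(self, q: np.ndarray) -> np.ndarray:
        return self.basis @ np.asarray(q, dtype=float)

    def to_fluxmap(self, x: np.ndarray) -> FluxMap:
        """x = [q (k net free fluxes), log10 exchange fluxes (per reversible)]."""
        q = x[: self.k]
        v = self.net_fluxes(q)
        net = {rid: float(v[i]) for i, rid in enumerate(self.reaction_ids)}
        exch = {
            rid: float(10.0 ** x[self.k + j]) for j, rid in enumerate(self.reversible_ids)
        }
        return FluxMap(net=net, exchange=exch)

    def from_fluxmap(self, fluxmap: FluxMap) -> np.ndarray:
        q = [fluxmap.net.get(rid, 0.0) for rid in self.free_ids]
        ex = [
            np.log10(max(fluxmap.exchange.get(rid, 1e-6), 1e-12))
            for rid in self.reversible_ids
        ]
        return np.array(q + ex, dtype=float)

    @property
    def n_params(self) -> int:
        return self.k + len(self.reversible_ids)

    @property
    def param_names(self) -> list[str]:
        return list(self.free_ids) + [f"exch:{rid}" for rid in self.reversible_ids]


def network_with_pools(network: Network, pools: Mapping[str, float]) -> Network:
    """Copy of the network with pool sizes replaced (e.g. deconvolved values)."""
    mets = []
    for m in network.metabolites.values():
        if m.name in pools:
            mets.append(
                Metabolite(
                    name=m.name,
                    n_carbons=m.n_carbons,
                    pool_size=float(pools[m.name]),
                    role=m.role,
                    dilution_fraction=m.dilution_fraction,
                    symmetric=m.symmetric,
                )
            )
        else:
            mets.append(m)
    return Network(mets, network.reactions.values())


# -- fitting ----------------------------------------------------------------


@dataclass
class FitConfig:
    """Optimizer settings; all randomness flows from ``seed``."""

    n_starts: int = 20
    seed: int = 0
    flux_upper: float = 10.0
    exch_upper: float | None = None  # default: 100 x flux_upper
    rtol: float = 1e-8
    atol: float = 1e-10
    penalty_weight: float = 1e4
    xtol: float = 1e-12
    ftol: float = 1e-12
    max_nfev: int | None = None


@dataclass
class ProfileCI:
    lo: float
    hi: float
    open_lo: bool = False
    open_hi: bool = False
    reliable: bool = True
    level: float = 0.95


@dataclass
class FluxFitResult:
    """Best-fit fluxes for one cell-cycle phase with fit diagnostics."""

    fluxmap: FluxMap
    x: np.ndarray
    param_names: list[str]
    ssr: float
    n_starts_converged: int
    start_ssrs: list[float]
    phase: str | None = None
    ci: dict[str, ProfileCI] = field(default_factory=dict)
    problem: "_FitProblem | None" = None


class _FitProblem:
    """Residual evaluator shared by the fit and its profile-likelihood CIs."""

    def __init__(
        self,
        network: Network,
        observations: Sequence[tuple[TracerSpec, Mapping[str, LabelingTimeCourse]]],
        config: FitConfig,
    ):
        self.network = network
        self.config = config
        self.basis = FreeFluxBasis(network)
        self.obs: list[tuple[TracerSpec, list[tuple[str, np.ndarray, np.ndarray, np.ndarray]], np.ndarray]] = []
        for tracer, series in observations:
            all_times = sorted({float(t) for tc in series.values() for t in tc.times})
            grid = np.array(all_times)
            entries = []
            for met, tc in series.items():
                if met not in network.metabolites:
                    raise KeyError(f"observation of unmodeled metabolite {met}")
                idx = np.searchsorted(grid, tc.times)
                sd = tc.sd if tc.sd is not None else np.full_like(tc.mids, 0.01)
                entries.append((met, idx, tc.mids, np.asarray(sd, dtype=float)))
            self.obs.append((tracer, entries, grid))

    def residuals(self, x: np.ndarray, pin: tuple[int, float] | None = None) -> np.ndarray:
        fluxmap = self.basis.to_fluxmap(x)
        v = np.array([fluxmap.net[rid] for rid in self.basis.reaction_ids])
        parts = [self.config.penalty_weight * np.minimum(v, 0.0)]
        if pin is not None:
            ridx, target = pin
            parts.append(np.array([self.config.penalty_weight * (v[ridx] - target)]))
        sim_ok = True
        for tracer, entries, grid in self.obs:
            targets = [
                (met, tuple(range(1, self.network.metabolites[met].n_carbons + 1)))
                for met, _, _, _ in entries
            ]
            try:
                sim = simulate_labeling(
                    self.network,
                    fluxmap,
                    tracer,
                    grid,
                    targets=targets,
                    rtol=self.config.rtol,
                    atol=self.config.atol,
                    check_steady_state=False,
                )
            except Exception:
                sim_ok = False
                break
            for met, idx, mids, sd in entries:
                resid = (sim[met].mids[idx] - mids) / sd
                parts.append(resid.ravel())
        if not sim_ok:
            n = sum(m.size for _, _, m, _ in self.obs[0][1])
            parts = [np.full(max(n, 1), 1e6)]
        return np.concatenate(parts)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        cfg = self.config
        exch_hi = cfg.exch_upper if cfg.exch_upper is not None else 100.0 * cfg.flux_upper
        lo = np.concatenate(
            [np.zeros(self.basis.k), np.full(len(self.basis.reversible_ids), -6.0)]
        )
        hi = np.concatenate(
            [
                np.full(self.basis.k, cfg.flux_upper),
                np.full(len(self.basis.reversible_ids), np.log10(exch_hi)),
            ]
        )
        return lo, hi

    def optimize(
        self, x0: np.ndarray, pin: tuple[int, float] | None = None
    ) -> tuple[np.ndarray, float, bool]:
        lo, hi = self.bounds()
        x0 = np.clip(x0, lo, hi)
        sol = least_squares(
            lambda x: self.residuals(x, pin),
            x0,
            bounds=(lo, hi),
            xtol=self.config.xtol,
            ftol=self.config.ftol,
            gtol=1e-12,
            max_nfev=self.config.max_nfev,
        )
        ssr = float(np.sum(self.residuals(sol.x, None) ** 2)) if pin is not None else float(
            np.sum(sol.fun**2)
        )
        return sol.x, ssr, bool(sol.success)


def fit_fluxes(
    network: Network,
    observations: Sequence[tuple[TracerSpec, Mapping[str, LabelingTimeCourse]]],
    config: FitConfig | None = None,
    *,
    pools: Mapping[str, float] | None = None,
    phase: str | None = None,
    x0_extra: Sequence[np.ndarray] = (),
) -> FluxFitResult:
    """Fit free net (and exchange) fluxes to labeling time courses.

    ``observations`` pairs each tracer with the MID time courses measured
    under it; multiple tracers are fitted simultaneously. Pool sizes may be
    overridden by ``pools`` (deconvolved values). Multistart bounded least
    squares; all starts are drawn from one seeded generator. ``x0_extra``
    supplies additional deterministic starting points.
    """
    config = config or FitConfig()
    if pools:
        network = network_with_pools(network, pools)
    problem = _FitProblem(network, observations, config)
    lo, hi = problem.bounds()
    rng = np.random.default_rng(config.seed)
    starts = [np.asarray(x, dtype=float) for x in x0_extra]
    while len(starts) < config.n_starts:
        starts.append(rng.uniform(lo, hi))
    best = None
    start_ssrs: list[float] = []
    n_ok = 0
    for x0 in starts:
        try:
            x, ssr, ok = problem.optimize(x0)
        except Exception:
            start_ssrs.append(np.inf)
            continue
        start_ssrs.append(ssr)
        if ok:
            n_ok += 1
        if ok and (best is None or ssr < best[1]):
            best = (x, ssr)
    if best is None:
        raise RuntimeError(
            f"flux fit failed to converge in any of {len(starts)} starts; "
            f"per-start SSRs: {start_ssrs}"
        )
    x, ssr = best
    return FluxFitResult(
        fluxmap=problem.basis.to_fluxmap(x),
        x=x,
        param_names=problem.basis.param_names,
        ssr=ssr,
        n_starts_converged=n_ok,
        start_ssrs=start_ssrs,
        phase=phase,
        problem=problem,
    )


def profile_likelihood_ci(
    fit: FluxFitResult,
    flux_id: str,
    level: float = 0.95,
    *,
    max_doublings: int = 30,
    rel_tol: float = 1e-3,
) -> ProfileCI:
    """Profile-likelihood confidence interval for one net flux.

    Walks the flux away from its optimum (re-optimizing all other parameters)
    until SSR crosses SSR_min + chi^2(1, level), then bisects the crossing.
    A profile still below the threshold at the walk limit is reported open;
    a failed re-optimization marks the interval unreliable rather than
    silently widening it.
    """
    if fit.problem is None:
        raise ValueError("fit carries no problem context; rerun fit_fluxes")
    problem = fit.problem
    basis = problem.basis
    if flux_id not in basis.reaction_ids:
        raise KeyError(f"unknown reaction {flux_id}")
    ridx = basis.reaction_ids.index(flux_id)
    v_hat = fit.fluxmap.net[flux_id]
    threshold = fit.ssr + chi2.ppf(level, 1)
    scale = max(abs(v_hat), 1e-3)
    walk_limit = max(10.0 * problem.config.flux_upper, 10.0 * scale)
    reliable = True

    def profile_ssr(c: float, x_warm: np.ndarray) -> tuple[float, np.ndarray]:
        nonlocal reliable
        x, ssr, ok = problem.optimize(x_warm, pin=(ridx, c))
        if not ok:
            reliable = False
        return ssr, x

    def walk(direction: int) -> tuple[float, bool]:
        step = 0.05 * scale
        c_in, x_warm = v_hat, fit.x.copy()
        for _ in range(max_doublings):
            c = c_in + direction * step
            if direction < 0 and c < 0.0:
                c = 0.0
            ssr, x = profile_ssr(c, x_warm)
            if ssr > threshold:
                # bisect between c_in (inside) and c (outside)
                a, b = c_in, c
                while abs(b - a) > rel_tol * scale:
                    m = 0.5 * (a + b)
                    ssr_m, x = profile_ssr(m, x)
                    if ssr_m > threshold:
                        b = m
                    else:
                        a = m
                return 0.5 * (a + b), False
            c_in, x_warm = c, x
            if direction < 0 and c == 0.0:
                return 0.0, False
            if direction > 0 and c >= walk_limit:
                return c, True
            step *= 2.0
        return c_in, True

    lo, open_lo = walk(-1)
    hi, open_hi = walk(+1)
    lo = min(lo, v_hat)
    hi = max(hi, v_hat)
    return ProfileCI(lo=lo, hi=hi, open_lo=open_lo, open_hi=open_hi, reliable=reliable, level=level)


# -- derived rates and oscillation summaries ---------------------------------


@dataclass
class RedoxSummary:
    """Reducing-equivalent production and oxygen-equivalent OxPhos rate."""

    nadh: float
    fadh2: float
    o2_equivalent: float
    nadh_interval: tuple[float, float] | None = None
    fadh2_interval: tuple[float, float] | None = None
    o2_interval: tuple[float, float] | None = None


def compute_redox_oxphos(
    fluxmap: FluxMap,
    accounting: Mapping[str, Mapping[str, float]],
    *,
    include_nadph: bool = True,
) -> RedoxSummary:
    """Linear cofactor bookkeeping over net fluxes.

    NADH = sum_i yield_i v_i (optionally folding the NADPH table in),
    FADH2 likewise; the oxygen-equivalent OxPhos rate is (NADH + FADH2) / 2
    (each O atom accepts the electrons of one reducing equivalent). Negative
    totals indicate an inconsistent accounting/flux pair and raise.
    """
    for table in accounting.values():
        for rid in table:
            if rid not in fluxmap.net:
                raise KeyError(f"accounting references reaction {rid} with no flux")

    def tally(table: Mapping[str, float]) -> float:
        return float(sum(y * fluxmap.net[rid] for rid, y in table.items()))

    nadh = tally(accounting.get("nadh", {}))
    if include_nadph:
        nadh += tally(accounting.get("nadph", {}))
    fadh2 = tally(accounting.get("fadh2", {}))
    if nadh < 0 or fadh2 < 0:
        raise ValueError(
            f"negative reducing-equivalent rate (NADH {nadh:g}, FADH2 {fadh2:g})"
        )
    return RedoxSummary(nadh=nadh, fadh2=fadh2, o2_equivalent=0.5 * (nadh + fadh2))


def redox_intervals_from_cis(
    fit: FluxFitResult,
    accounting: Mapping[str, Mapping[str, float]],
    *,
    include_nadph: bool = True,
) -> RedoxSummary:
    """Redox summary with intervals propagated from profile-likelihood CIs.

    Each rate is linear in the free fluxes, rate = g . q with g = B^T y (B the
    null-space basis, y the per-reaction yields); the interval half-width is
    the conservative sum of |g_j| times each free flux's CI half-width. Only
    free fluxes with a computed CI contribute; if none of the fluxes a rate
    depends on has one, that interval is left None.
    """
    if fit.problem is None:
        raise ValueError("fit carries no problem context; rerun fit_fluxes")
    basis = fit.problem.basis
    summary = compute_redox_oxphos(fit.fluxmap, accounting, include_nadph=include_nadph)

    def yields_vector(tables: list[Mapping[str, float]]) -> np.ndarray:
        y = np.zeros(len(basis.reaction_ids))
        for table in tables:
            for rid, yy in table.items():
                y[basis.reaction_ids.index(rid)] += yy
        return y

    def interval(tables: list[Mapping[str, float]], center: float):
        g = basis.basis.T @ yields_vector(tables)
        hw = 0.0
        any_ci = False
        for j, rid in enumerate(basis.free_ids):
            ci = fit.ci.get(rid)
            if ci is None or not ci.reliable or ci.open_lo or ci.open_hi:
                continue
            any_ci = True
            hw += abs(g[j]) * 0.5 * (ci.hi - ci.lo)
        return (center - hw, center + hw) if any_ci else None

    nadh_tables = [accounting.get("nadh", {})]
    if include_nadph:
        nadh_tables.append(accounting.get("nadph", {}))
    fadh_tables = [accounting.get("fadh2", {})]
    summary.nadh_interval = interval(nadh_tables, summary.nadh)
    summary.fadh2_interval = interval(fadh_tables, summary.fadh2)
    # O2-equivalent = (NADH + FADH2)/2, so halve the combined yield tables
    half_tables = [
        {rid: 0.5 * y for rid, y in table.items()}
        for table in nadh_tables + fadh_tables
    ]
    summary.o2_interval = interval(half_tables, summary.o2_equivalent)
    return summary


@dataclass
class OscillationSummary:
    relative_amplitude: float
    peak_phase: str


def oscillation_summary(
    per_phase: Mapping[str, float], order: Sequence[str] | None = None
) -> OscillationSummary:
    """Relative amplitude (max - min)/mean and peak phase (ties -> earliest)."""
    order = list(order) if order is not None else list(per_phase)
    values = np.array([per_phase[p] for p in order], dtype=float)
    if len(values) < 2 or not np.all(np.isfinite(values)):
        raise ValueError("need >= 2 phases with finite values")
    mean = values.mean()
    if mean <= 0:
        raise ValueError("mean of per-phase values must be > 0")
    amp = float((values.max() - values.min()) / mean)
    peak = order[int(np.argmax(values))]
    return OscillationSummary(relative_amplitude=amp, peak_phase=peak)
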
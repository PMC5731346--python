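"""Isotopically non-stationary labeling simulation on the EMU system.

After a tracer switch at chase time tau = 0, each EMU's mass-isotopomer
distribution X obeys

    C * dX/dt = sum_in v_in * X_in  -  (sum_out v_out) * X,

where C is the metabolite pool size, influx terms are the (convolution of)
precursor EMU MIDs, and a ``dilution_fraction`` d of every influx carries
unlabeled material. Fluxes and pools are constant during a chase (metabolic
steady state within a cell-cycle phase window); only the isotopic state moves.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce
from math import comb
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .emu import EmuNode, EmuSystem, emu_decompose
from .network import FluxMap, Network, validate_steady_state

__all__ = [
    "SimulationError",
    "TracerSpec",
    "LabelingTimeCourse",
    "unlabeled_mid",
    "fully_labeled_mid",
    "enrichment",
    "marginal_mid",
    "simulate_labeling",
    "steady_state_mids",
    "correct_natural_abundance",
]


class SimulationError(RuntimeError):
    """Labeling integration or steady-state solve failed."""


def unlabeled_mid(n_carbons: int) -> np.ndarray:
    mid = np.zeros(n_carbons + 1)
    mid[0] = 1.0
    return mid


def fully_labeled_mid(n_carbons: int) -> np.ndarray:
    mid = np.zeros(n_carbons + 1)
    mid[-1] = 1.0
    return mid


def is_valid_mid(mid: np.ndarray, tol: float = 1e-6) -> bool:
    mid = np.asarray(mid, dtype=float)
    return bool(np.all(mid >= -1e-12) and abs(mid.sum() - 1.0) <= tol)


def enrichment(mid: np.ndarray) -> float:
    """Average fraction of labeled carbons, sum_k k*mid[k] / n."""
    mid = np.asarray(mid, dtype=float)
    n = len(mid) - 1
    return float(np.dot(np.arange(n + 1), mid) / n) if n else 0.0


def marginal_mid(mid: np.ndarray, subset_size: int) -> np.ndarray:
    """MID of a random carbon subset under positional exchangeability.

    Given a metabolite-level MID over n carbons, the mass distribution of a
    size-s subset is the hypergeometric mixture
    P(m) = sum_k mid[k] * C(k, m) C(n-k, s-m) / C(n, s). Exact for fully
    labeled or unlabeled species, which is all the tracers used here supply.
    """
    mid = np.asarray(mid, dtype=float)
    n = len(mid) - 1
    s = subset_size
    if s > n:
        raise ValueError("subset larger than the molecule")
    out = np.zeros(s + 1)
    for m in range(s + 1):
        acc = 0.0
        for k in range(n + 1):
            if m <= k and s - m <= n - k:
                acc += mid[k] * comb(k, m) * comb(n - k, s - m) / comb(n, s)
        out[m] = acc
    return out


@dataclass(frozen=True)
class TracerSpec:
    """Fixed labeling of source metabolites after the media swap at tau = 0.

    ``source_mids`` maps source metabolite names to their MIDs; any source not
    listed is unlabeled. The swap is instantaneous by convention.
    """

    name: str
    source_mids: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        for met, mid in self.source_mids.items():
            if not is_valid_mid(np.asarray(mid)):
                raise ValueError(f"tracer {self.name}: invalid MID for {met}")

    def emu_mid(self, network: Network, node: EmuNode) -> np.ndarray:
        met = network.metabolites[node.metabolite]
        if node.metabolite in self.source_mids:
            return marginal_mid(np.asarray(self.source_mids[node.metabolite], float), node.size)
        return unlabeled_mid(node.size)


@dataclass
class LabelingTimeCourse:
    """MID time course of one metabolite over chase times tau (hours)."""

    metabolite: str
    times: np.ndarray
    mids: np.ndarray  # shape (n_times, n_carbons + 1)
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mids = np.asarray(self.mids, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"{self.metabolite}: times must be strictly ascending")
        if self.mids.shape[0] != len(self.times):
            raise ValueError(f"{self.metabolite}: one MID row per time required")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)

    @property
    def n_carbons(self) -> int:
        return self.mids.shape[1] - 1


# -- EMU forward simulation --------------------------------------------------


class _CompiledSystem:
    """Index structure for fast evaluation of the EMU ODE right-hand side."""

    def __init__(
        self,
        network: Network,
        system: EmuSystem,
        fluxmap: FluxMap,
        tracer: TracerSpec,
    ):
        self.network = network
        self.system = system
        solved = system.solved_nodes()
        self.solved = solved
        self.offsets: dict[EmuNode, int] = {}
        off = 0
        for node in solved:
            self.offsets[node] = off
            off += node.size + 1
        self.n_state = off

        cons = network.consumption_flux(fluxmap)
        self.decay = np.zeros(self.n_state)
        for node in solved:
            met = network.metabolites[node.metabolite]
            sl = slice(self.offsets[node], self.offsets[node] + node.size + 1)
            self.decay[sl] = cons[node.metabolite] / met.pool_size

        # Constant forcing (edges fed only by tracer sources, plus dilution)
        # and dynamic edges (at least one integrated source).
        self.forcing = np.zeros(self.n_state)
        self.dynamic: list[tuple[int, int, float, list[object]]] = []
        for node in solved:
            met = network.metabolites[node.metabolite]
            d = met.dilution_fraction
            o = self.offsets[node]
            e0 = unlabeled_mid(node.size)
            for edge in system.edges_by_target[node]:
                r = network.reactions[edge.reaction_id]
                fwd, bwd = fluxmap.forward_backward(r)
                v = edge.weight * (fwd if edge.direction == 1 else bwd)
                if v == 0.0:
                    continue
                coeff = v / met.pool_size
                self.forcing[o : o + node.size + 1] += coeff * d * e0
                srcs: list[object] = []
                any_dynamic = False
                for src in edge.sources:
                    if network.metabolites[src.metabolite].is_source:
                        srcs.append(tracer.emu_mid(network, src))
                    else:
                        srcs.append((self.offsets[src], src.size + 1))
                        any_dynamic = True
                if any_dynamic:
                    self.dynamic.append((o, node.size + 1, coeff * (1.0 - d), srcs))
                else:
                    const = reduce(np.convolve, [np.asarray(s) for s in srcs])
                    self.forcing[o : o + node.size + 1] += coeff * (1.0 - d) * const

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        dy = self.forcing - self.decay * y
        for o, ln, coeff, srcs in self.dynamic:
            vecs = [s if isinstance(s, np.ndarray) else y[s[0] : s[0] + s[1]] for s in srcs]
            dy[o : o + ln] += coeff * reduce(np.convolve, vecs)
        return dy

    def jac_sparsity(self) -> np.ndarray:
        J = np.zeros((self.n_state, self.n_state), dtype=bool)
        np.fill_diagonal(J, True)
        for o, ln, _, srcs in self.dynamic:
            for s in srcs:
                if not isinstance(s, np.ndarray):
                    J[o : o + ln, s[0] : s[0] + s[1]] = True
        return J

    def initial_state(self, overrides: Mapping[str, np.ndarray] | None) -> np.ndarray:
        y0 = np.zeros(self.n_state)
        for node in self.solved:
            o = self.offsets[node]
            if overrides and node.metabolite in overrides:
                y0[o : o + node.size + 1] = marginal_mid(
                    np.asarray(overrides[node.metabolite], float), node.size
                )
            else:
                y0[o] = 1.0
        return y0


def _default_targets(network: Network) -> list[tuple[str, tuple[int, ...]]]:
    return [
        (m.name, tuple(range(1, m.n_carbons + 1)))
        for m in network.metabolites.values()
        if m.is_balanced
    ]


def _extract(
    network: Network,
    comp: _CompiledSystem,
    tracer: TracerSpec,
    targets: list[tuple[str, tuple[int, ...]]],
    times: np.ndarray,
    Y: np.ndarray,
) -> dict[str, LabelingTimeCourse]:
    out: dict[str, LabelingTimeCourse] = {}
    for name, carbons in targets:
        node = EmuNode(name, tuple(sorted(carbons)))
        if network.metabolites[name].is_source:
            mid = tracer.emu_mid(network, node)
            mids = np.tile(mid, (len(times), 1))
        else:
            o = comp.offsets[node]
            mids = Y[:, o : o + node.size + 1]
        mids = np.clip(mids, 0.0, None)
        out[name] = LabelingTimeCourse(name, times, mids)
    return out


def simulate_labeling(
    network: Network,
    fluxmap: FluxMap,
    tracer: TracerSpec,
    times: Sequence[float],
    targets: list[tuple[str, tuple[int, ...]]] | None = None,
    *,
    initial_mids: Mapping[str, np.ndarray] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    check_steady_state: bool = True,
) -> dict[str, LabelingTimeCourse]:
    """Simulate MID time courses for the target metabolites.

    ``times`` are chase times in hours (ascending, >= 0). Targets default to
    the full-carbon MIDs of every balanced metabolite. The initial condition
    is fully unlabeled unless ``initial_mids`` overrides it per metabolite.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0 or np.any(times < 0) or np.any(np.diff(times) <= 0):
        raise ValueError("times must be ascending and non-negative")
    if check_steady_state:
        violations = validate_steady_state(fluxmap, network, tol_factor=1e-6)
        if violations:
            raise ValueError(f"flux map violates steady state: {violations}")
    if targets is None:
        targets = _default_targets(network)
    system = emu_decompose(network, targets)
    comp = _CompiledSystem(network, system, fluxmap, tracer)
    y0 = comp.initial_state(initial_mids)
    if comp.n_state == 0 or times[-1] == 0.0:
        Y = np.tile(y0, (len(times), 1))
        return _extract(network, comp, tracer, targets, times, Y)
    kwargs = {"jac_sparsity": comp.jac_sparsity()} if method == "BDF" else {}
    sol = solve_ivp(
        comp.rhs,
        (0.0, float(times[-1])),
        y0,
        method=method,
        t_eval=times,
        rtol=rtol,
        atol=atol,
        **kwargs,
    )
    if not sol.success:
        reached = sol.t[-1] if len(sol.t) else 0.0
        raise SimulationError(
            f"stiff integration failed at t={reached:g} h "
            f"(state dim {comp.n_state}): {sol.message}"
        )
    return _extract(network, comp, tracer, targets, times, sol.y.T)


def steady_state_mids(
    network: Network,
    fluxmap: FluxMap,
    tracer: TracerSpec,
    targets: list[tuple[str, tuple[int, ...]]] | None = None,
) -> dict[str, np.ndarray]:
    """Algebraic fixed point of the labeling system (tau -> infinity limit).

    Solved per EMU size class in ascending order; within a class the balance
    is linear in the unknown MIDs because convolution edges only reference
    strictly smaller EMUs.
    """
    if targets is None:
        targets = _default_targets(network)
    system = emu_decompose(network, targets)
    cons = network.consumption_flux(fluxmap)
    solution: dict[EmuNode, np.ndarray] = {}
    for node in system.source_nodes():
        solution[node] = tracer.emu_mid(network, node)
    for size in system.sizes:
        cls = [
            n
            for n in system.size_classes[size]
            if not network.metabolites[n.metabolite].is_source
        ]
        if not cls:
            continue
        index = {n: i for i, n in enumerate(cls)}
        A = np.zeros((len(cls), len(cls)))
        B = np.zeros((len(cls), size + 1))
        for n in cls:
            i = index[n]
            met = network.metabolites[n.metabolite]
            v_out = cons[n.metabolite]
            if v_out <= 0:
                raise SimulationError(f"zero-turnover pool: {n.metabolite}")
            A[i, i] = v_out
            d = met.dilution_fraction
            e0 = unlabeled_mid(size)
            for edge in system.edges_by_target[n]:
                r = network.reactions[edge.reaction_id]
                fwd, bwd = fluxmap.forward_backward(r)
                v = edge.weight * (fwd if edge.direction == 1 else bwd)
                if v == 0.0:
                    continue
                B[i] += v * d * e0
                if len(edge.sources) == 1 and edge.sources[0] in index:
                    A[i, index[edge.sources[0]]] -= v * (1.0 - d)
                else:
                    conv = reduce(np.convolve, [solution[s] for s in edge.sources])
                    B[i] += v * (1.0 - d) * conv
        try:
            X = np.linalg.solve(A, B)
        except np.linalg.LinAlgError as exc:
            raise SimulationError(f"singular labeling balance in size class {size}") from exc
        for n in cls:
            solution[n] = np.clip(X[index[n]], 0.0, None)
    out: dict[str, np.ndarray] = {}
    for name, carbons in targets:
        out[name] = solution[EmuNode(name, tuple(sorted(carbons)))]
    return out


# -- natural-abundance correction -------------------------------------------


def natural_abundance_matrix(n_carbons: int, p13: float) -> np.ndarray:
    """Forward convolution: observed = M @ true, from binomial 13C incorporation.

    A molecule with true tracer shift j has its remaining n-j carbons 13C with
    probability p13 each, so M[i, j] = C(n-j, i-j) p^(i-j) (1-p)^(n-i).
    """
    n = n_carbons
    M = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        for i in range(j, n + 1):
            M[i, j] = comb(n - j, i - j) * p13 ** (i - j) * (1 - p13) ** (n - i)
    return M


def correct_natural_abundance(
    raw: np.ndarray, n_carbons: int, p13: float = 0.0107
) -> np.ndarray:
    """Remove natural 13C abundance from a measured MID.

    Inverts the binomial convolution matrix, clips small negatives and
    renormalizes. ``p13`` must be a physically sensible abundance (<= 5%).
    """
    if not 0.0 <= p13 <= 0.05:
        raise ValueError("p13 outside [0, 0.05]")
    if n_carbons > 20:
        raise ValueError("natural-abundance inversion unstable beyond 20 carbons")
    raw = np.asarray(raw, dtype=float)
    if len(raw) != n_carbons + 1:
        raise ValueError("MID length must be n_carbons + 1")
    corrected = np.linalg.solve(natural_abundance_matrix(n_carbons, p13), raw)
    corrected = np.clip(corrected, 0.0, None)
    s = corrected.sum()
    if s <= 0:
        raise ValueError("corrected MID sums to zero")
    return corrected / s
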
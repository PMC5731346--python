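"""Brute-force positional-isotopomer simulator (validation oracle).

Integrates the full 2^n isotopomer distribution of every balanced metabolite
directly from the atom maps, with no EMU reduction. Condensation terms draw
substrate molecules independently from their pools, so the production rate of
a product isotopomer is the flux times the product of substrate isotopomer
fractions. Much larger than the EMU system, but conceptually independent of
it — the two paths share only the network definition.
"""

from __future__ import annotations

import itertools
from functools import reduce
from math import comb
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .labeling import LabelingTimeCourse, SimulationError, TracerSpec
from .network import FluxMap, Network

__all__ = ["simulate_labeling_bruteforce"]

STATE_CAP = 100_000


def _pattern_distribution(mid: np.ndarray, n: int) -> np.ndarray:
    """Exchangeable positional distribution consistent with a MID."""
    x = np.zeros(2**n)
    for idx in range(2**n):
        k = bin(idx).count("1")
        x[idx] = mid[k] / comb(n, k)
    return x


def _marginal_mid(x: np.ndarray, n: int) -> np.ndarray:
    mid = np.zeros(n + 1)
    for idx, v in enumerate(x):
        mid[bin(idx).count("1")] += v
    return mid


def simulate_labeling_bruteforce(
    network: Network,
    fluxmap: FluxMap,
    tracer: TracerSpec,
    times: Sequence[float],
    targets: Sequence[str] | None = None,
    *,
    initial_mids: Mapping[str, np.ndarray] | None = None,
    rtol: float = 1e-11,
    atol: float = 1e-13,
) -> dict[str, LabelingTimeCourse]:
    """Full positional-isotopomer integration; returns marginal MIDs.

    Raises if the total isotopomer state count exceeds ``STATE_CAP``.
    """
    times = np.asarray(times, dtype=float)
    balanced = [m for m in network.metabolites.values() if m.is_balanced]
    n_state = sum(2**m.n_carbons for m in balanced)
    if n_state > STATE_CAP:
        raise ValueError(f"isotopomer state count {n_state} exceeds cap {STATE_CAP}")

    offsets: dict[str, int] = {}
    off = 0
    for m in balanced:
        offsets[m.name] = off
        off += 2**m.n_carbons

    source_dist: dict[str, np.ndarray] = {}
    for m in network.metabolites.values():
        if m.is_source:
            mid = np.asarray(
                tracer.source_mids.get(m.name, np.eye(m.n_carbons + 1)[0]), dtype=float
            )
            source_dist[m.name] = _pattern_distribution(mid, m.n_carbons)

    # Per (variant, balanced product instance): transfer matrix T mapping the
    # joint substrate pattern distribution to the product pattern distribution.
    terms: list[tuple[int, int, float, np.ndarray, list[object], float]] = []
    for var in network.variants():
        r = network.reactions[var.reaction_id]
        fwd, bwd = fluxmap.forward_backward(r)
        v = var.weight * (fwd if var.direction == 1 else bwd)
        if v == 0.0:
            continue
        for pname, pmap in var.products:
            pmet = network.metabolites[pname]
            if not pmet.is_balanced:
                continue
            np_c = pmet.n_carbons
            # which substrate instance and carbon supplies each product carbon
            supply: list[tuple[int, int]] = []
            involved: list[int] = []
            for letter in pmap:
                for si, (_, smap) in enumerate(var.substrates):
                    pos = smap.find(letter)
                    if pos >= 0:
                        if si not in involved:
                            involved.append(si)
                        supply.append((si, pos))
                        break
            dims = [2 ** len(var.substrates[si][1]) for si in involved]
            T = np.zeros((2**np_c, int(np.prod(dims))))
            for combo in itertools.product(*(range(d) for d in dims)):
                pidx = 0
                for c, (si, pos) in enumerate(supply):
                    bit = (combo[involved.index(si)] >> pos) & 1
                    pidx |= bit << c
                col = int(np.ravel_multi_index(combo, dims)) if len(dims) > 1 else combo[0]
                T[pidx, col] = 1.0
            srcs: list[object] = []
            for si in involved:
                sname = var.substrates[si][0]
                if network.metabolites[sname].is_balanced:
                    srcs.append((offsets[sname], 2 ** network.metabolites[sname].n_carbons))
                else:
                    srcs.append(source_dist[sname])
            terms.append((offsets[pname], 2**np_c, v, T, srcs, pmet.dilution_fraction))

    cons = network.consumption_flux(fluxmap)
    decay = np.zeros(n_state)
    inv_pool = np.zeros(n_state)
    for m in balanced:
        sl = slice(offsets[m.name], offsets[m.name] + 2**m.n_carbons)
        decay[sl] = cons[m.name] / m.pool_size
        inv_pool[sl] = 1.0 / m.pool_size

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = -decay * y
        for o, ln, v, T, srcs, d in terms:
            vecs = [s if isinstance(s, np.ndarray) else y[s[0] : s[0] + s[1]] for s in srcs]
            joint = reduce(np.kron, vecs)
            prod = T @ joint
            dy[o : o + ln] += v * (1.0 - d) * prod * inv_pool[o]
            dy[o] += v * d * inv_pool[o]
        return dy

    sparsity = np.zeros((n_state, n_state), dtype=bool)
    np.fill_diagonal(sparsity, True)
    for o, ln, _, _, srcs, _ in terms:
        for s in srcs:
            if not isinstance(s, np.ndarray):
                sparsity[o : o + ln, s[0] : s[0] + s[1]] = True

    y0 = np.zeros(n_state)
    for m in balanced:
        o = offsets[m.name]
        if initial_mids and m.name in initial_mids:
            y0[o : o + 2**m.n_carbons] = _pattern_distribution(
                np.asarray(initial_mids[m.name], float), m.n_carbons
            )
        else:
            y0[o] = 1.0

    if times[-1] == 0.0:
        Y = np.tile(y0, (len(times), 1))
    else:
        sol = solve_ivp(
            rhs,
            (0.0, float(times[-1])),
            y0,
            method="BDF",
            t_eval=times,
            rtol=rtol,
            atol=atol,
            jac_sparsity=sparsity,
        )
        if not sol.success:
            raise SimulationError(f"brute-force integration failed: {sol.message}")
        Y = sol.y.T

    if targets is None:
        targets = [m.name for m in balanced]
    out: dict[str, LabelingTimeCourse] = {}
    for name in targets:
        met = network.metabolites[name]
        if met.is_balanced:
            o = offsets[name]
            mids = np.array(
                [_marginal_mid(row[o : o + 2**met.n_carbons], met.n_carbons) for row in Y]
            )
        else:
            mid = np.asarray(
                tracer.source_mids.get(name, np.eye(met.n_carbons + 1)[0]), dtype=float
            )
            mids = np.tile(mid, (len(times), 1))
        out[name] = LabelingTimeCourse(name, times, np.clip(mids, 0.0, None))
    return out
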
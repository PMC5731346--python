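"""Recover cell-cycle-position-bin-specific signals from population averages.

A synchronized culture sampled at release time t_r is a mixture of cells at
different cycle positions; the mixing weights w_rb (division-weighted mass of
position bin b at time t_r) come from the population model. Pool sizes mix
linearly,

    meas_r = sum_b w_rb P_b,

while MIDs mix weighted by abundance,

    meas_r(tau) = sum_b w_rb P_b M_b(tau) / sum_b w_rb P_b.

Both stages are solved as non-negative least squares with circular Tikhonov
smoothing across neighboring bins (adjacent cycle positions have similar
metabolic states); MIDs are renormalized to the simplex per bin and time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .population import PopulationDensity, PopulationParams, PhaseDefinition, evolve_density

__all__ = [
    "build_mixing_matrix",
    "deconvolve_pools",
    "deconvolve_mids",
    "select_lambda_lcurve",
    "DeconvolutionResult",
    "aggregate_bins_to_phases",
]


def build_mixing_matrix(
    params: PopulationParams,
    release_times: np.ndarray,
    n_bins: int,
    *,
    division_weighting: bool = True,
) -> np.ndarray:
    """Row-stochastic matrix: row r = bin masses at release time t_r."""
    release_times = np.asarray(release_times, dtype=float)
    if np.any(release_times < 0):
        raise ValueError("release times must be >= 0")
    return np.array(
        [
            evolve_density(params, t, n_bins, division_weighting=division_weighting).masses
            for t in release_times
        ]
    )


def circular_difference_matrix(n_bins: int) -> np.ndarray:
    """Rows P_{b+1} - P_b with circular wrap; zero matrix for a single bin."""
    if n_bins == 1:
        return np.zeros((1, 1))
    L = -np.eye(n_bins)
    for b in range(n_bins):
        L[b, (b + 1) % n_bins] += 1.0
    return L


def _smoothed_nnls(A: np.ndarray, b: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    n = A.shape[1]
    A_aug, b_aug = A, b
    if lam > 0:
        L = circular_difference_matrix(n)
        A_aug = np.vstack([A, np.sqrt(lam) * L])
        b_aug = np.concatenate([b, np.zeros(n)])
    x, _ = nnls(A_aug, b_aug)
    resid = float(np.linalg.norm(A @ x - b))
    return x, resid


def deconvolve_pools(
    meas: np.ndarray,
    sd: np.ndarray,
    W: np.ndarray,
    lam: float = 0.0,
) -> np.ndarray:
    """Per-bin pool sizes from population-averaged pools at each release time.

    Minimizes sum_r ((meas_r - sum_b w_rb P_b) / sd_r)^2
    + lam * sum_b (P_{b+1} - P_b)^2 (circular) subject to P_b >= 0.

    The smoothing term is made dimensionless: the circular differences are
    taken on pools relative to the mean measured level and weighted like an
    average data row, so one ``lam`` works across metabolites whose pools
    differ by orders of magnitude.
    """
    meas = np.asarray(meas, dtype=float)
    sd = np.asarray(sd, dtype=float)
    W = np.asarray(W, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("measurement sd must be > 0")
    if lam == 0.0 and np.any(W.sum(axis=0) == 0.0):
        dead = np.nonzero(W.sum(axis=0) == 0.0)[0]
        raise ValueError(f"unidentifiable bins {dead.tolist()} (zero mixing mass, lam=0)")
    A = W / sd[:, None]
    b = meas / sd
    scale = np.mean(1.0 / sd) / max(np.mean(meas), 1e-300)
    P, _ = _smoothed_nnls(A, b, lam * scale**2)
    return P


def aggregate_pool_measurements(
    replicates: "list[tuple[np.ndarray, np.ndarray]]",
) -> tuple[np.ndarray, np.ndarray]:
    """Combine per-sample pool replicates into one value + sd per release time.

    Each element is (values, sds) of shape (n_release, n_chase) from one
    tracer experiment; pools are constant over a chase (metabolic steady
    state), so all chase samples are technical replicates. Returns the mean
    and its standard error per release time.
    """
    vals = np.concatenate([v for v, _ in replicates], axis=1)
    sds = np.concatenate([s for _, s in replicates], axis=1)
    n = vals.shape[1]
    mean = vals.mean(axis=1)
    sd_mean = np.sqrt((sds**2).mean(axis=1) / n)
    return mean, sd_mean


def abundance_mixing_matrix(W: np.ndarray, pools: np.ndarray) -> np.ndarray:
    """Row-stochastic abundance-weighted mixing: a_rb = w_rb P_b / sum_b w_rb P_b."""
    A = W * np.asarray(pools, dtype=float)[None, :]
    denom = A.sum(axis=1, keepdims=True)
    if np.any(denom <= 0):
        raise ValueError("a release time has zero total abundance")
    return A / denom


def deconvolve_mids(
    meas_mids: np.ndarray,
    W: np.ndarray,
    pools: np.ndarray,
    lam: float = 0.0,
    sd: np.ndarray | None = None,
    *,
    simplex_weight: float = 1e4,
) -> tuple[np.ndarray, list[int]]:
    """Per-bin MID time courses from population-averaged MIDs.

    ``meas_mids`` has shape (n_release, n_times, n_channels); all release
    times must share one chase grid (enforced upstream). For each chase time
    all mass channels are solved jointly as one non-negative least-squares
    problem carrying the data rows, circular smoothing rows per channel, and
    heavily weighted sum-to-one rows per bin (the simplex constraint); the
    result is projected exactly onto the simplex afterwards.

    Returns (bin MIDs of shape (n_bins, n_times, n_channels), list of bins
    whose total mixing mass is so small they are effectively determined by
    the smoothing prior rather than data).
    """
    meas = np.asarray(meas_mids, dtype=float)
    if meas.ndim != 3:
        raise ValueError("meas_mids must be (n_release, n_times, n_channels)")
    R, T, K = meas.shape
    B = W.shape[1]
    if W.shape[0] != R:
        raise ValueError("mixing matrix rows must match release times")
    A = abundance_mixing_matrix(W, pools)
    if sd is None:
        sd = np.ones_like(meas)
    sd = np.asarray(sd, dtype=float)
    if sd.shape != meas.shape:
        raise ValueError("sd shape must match meas_mids")
    if np.any(sd <= 0):
        raise ValueError("MID sd must be > 0")
    col_mass = A.sum(axis=0)
    flagged = np.nonzero(col_mass < 1e-6 * col_mass.max())[0].tolist()
    if flagged and lam == 0.0:
        raise ValueError(f"unidentifiable bins {flagged} (zero mixing mass, lam=0)")

    data_block = np.kron(A, np.eye(K))  # rows (r, k), cols (b, k)
    sum_block = simplex_weight * np.kron(np.eye(B), np.ones((1, K)))
    blocks = [sum_block]
    rhs_extra = [simplex_weight * np.ones(B)]
    if lam > 0:
        # dimensionless lam: smoothing rows weighted like an average data row
        wbar = float(np.mean(1.0 / sd))
        L = circular_difference_matrix(B)
        blocks.append(np.sqrt(lam) * wbar * np.kron(L, np.eye(K)))
        rhs_extra.append(np.zeros(B * K))
    out = np.zeros((B, T, K))
    for t in range(T):
        w = (1.0 / sd[:, t, :]).ravel()
        Aw = data_block * w[:, None]
        bw = meas[:, t, :].ravel() * w
        A_aug = np.vstack([Aw] + blocks)
        b_aug = np.concatenate([bw] + rhs_extra)
        x, _ = nnls(A_aug, b_aug)
        out[:, t, :] = x.reshape(B, K)
    sums = out.sum(axis=2)
    if np.any(sums <= 0):
        raise ValueError("deconvolved MID collapsed to zero; constraints infeasible")
    out = out / sums[:, :, None]
    return out, flagged


def select_lambda_lcurve(
    solve: "callable",
    lams: np.ndarray,
) -> float:
    """L-curve corner selection: maximize curvature of (log residual, log seminorm).

    ``solve(lam)`` must return (solution vector/array, residual norm);
    the roughness seminorm is computed here from the circular differences.
    """
    lams = np.asarray(lams, dtype=float)
    if len(lams) < 3:
        raise ValueError("need at least 3 candidate lambdas")
    rho, eta = [], []
    for lam in lams:
        x, resid = solve(lam)
        x = np.asarray(x, dtype=float)
        flat = x.reshape(x.shape[0], -1)
        L = circular_difference_matrix(flat.shape[0])
        rho.append(max(resid, 1e-14))
        eta.append(max(float(np.linalg.norm(L @ flat)), 1e-14))
    lr, le = np.log(rho), np.log(eta)
    # discrete curvature of the parameterized curve (lr(lam), le(lam))
    best_i, best_c = 1, -np.inf
    for i in range(1, len(lams) - 1):
        a = np.array([lr[i] - lr[i - 1], le[i] - le[i - 1]])
        b = np.array([lr[i + 1] - lr[i], le[i + 1] - le[i]])
        cross = a[0] * b[1] - a[1] * b[0]
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        c = cross / denom if denom > 0 else -np.inf
        if c > best_c:
            best_c, best_i = c, i
    return float(lams[best_i])


@dataclass
class DeconvolutionResult:
    """Bin-resolved pools and MIDs, with provenance of the inverse problem."""

    pools: dict[str, np.ndarray]  # metabolite -> (B,)
    mids: dict[str, np.ndarray]  # metabolite -> (B, T, K)
    chase_times: np.ndarray
    lam_pools: float
    lam_mids: float
    residual_norm: float
    bin_phases: list[str] = field(default_factory=list)
    flagged_bins: list[int] = field(default_factory=list)


def label_bins(n_bins: int, phases: PhaseDefinition) -> list[str]:
    centers = (np.arange(n_bins) + 0.5) / n_bins
    return [phases.phase_of(c) for c in centers]


def aggregate_bins_to_phases(
    pools: np.ndarray,
    mids: np.ndarray,
    phases: PhaseDefinition,
) -> tuple[dict[str, float], dict[str, np.ndarray]]:
    """Abundance-weighted per-phase means of bin pools and MIDs.

    Bins are attributed to phases by interval overlap of the bin with the
    phase; MID means are renormalized to the simplex.
    """
    B = len(pools)
    edges = np.linspace(0.0, 1.0, B + 1)
    width = 1.0 / B
    phase_pools: dict[str, float] = {}
    phase_mids: dict[str, np.ndarray] = {}
    for name in phases.names:
        a, b = phases.interval(name)
        overlap = np.clip(np.minimum(edges[1:], b) - np.maximum(edges[:-1], a), 0.0, None)
        frac = overlap / width
        wsum = frac.sum()
        phase_pools[name] = float(np.sum(frac * pools) / wsum)
        weights = frac * pools
        if weights.sum() <= 0:
            weights = frac
        m = np.tensordot(weights, mids, axes=(0, 0)) / weights.sum()
        sums = m.sum(axis=-1, keepdims=True)
        phase_mids[name] = m / np.where(sums > 0, sums, 1.0)
    return phase_pools, phase_mids
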
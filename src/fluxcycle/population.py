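"""Cell-cycle position distribution of a synchronizing-then-desynchronizing
population.

Cell-cycle position theta lives on the unit circle [0, 1). After release from
synchronization a cohort advects at rate 1/T (T = cycle length, hours) and
broadens; the density at clock time t is a wrapped Gaussian with mean
theta0 + t/T and variance s0^2 + 2 D t (advection-diffusion on the circle).
With division weighting on, lineage mass doubles at every wrap of theta past
1, reflecting that a divided lineage contributes two cells to population-
averaged signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import norm

__all__ = [
    "PhaseDefinition",
    "PopulationParams",
    "PopulationDensity",
    "evolve_density",
    "phase_fractions",
    "fit_population_params",
]


@dataclass(frozen=True)
class PhaseDefinition:
    """Ordered half-open position intervals partitioning [0, 1)."""

    names: tuple[str, ...] = ("G1", "S", "G2M")
    boundaries: tuple[float, ...] = (0.0, 0.4, 0.75, 1.0)

    def __post_init__(self) -> None:
        b = self.boundaries
        if len(b) != len(self.names) + 1 or b[0] != 0.0 or b[-1] != 1.0:
            raise ValueError("boundaries must run from 0.0 to 1.0, one interval per phase")
        if any(b[i + 1] <= b[i] for i in range(len(b) - 1)):
            raise ValueError("phase boundaries must be strictly increasing")

    def interval(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        return self.boundaries[i], self.boundaries[i + 1]

    def phase_of(self, theta: float) -> str:
        theta = theta % 1.0
        for i, name in enumerate(self.names):
            if self.boundaries[i] <= theta < self.boundaries[i + 1]:
                return name
        return self.names[-1]  # pragma: no cover


@dataclass(frozen=True)
class PopulationParams:
    """Desynchronization model parameters.

    T: cycle length (h); theta0: mean position at release; s0: initial spread
    (position units); D: dispersion rate (position^2 / h).
    """

    T: float
    theta0: float = 0.0
    s0: float = 0.02
    D: float = 0.002

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("cycle length T must be > 0")
        if self.s0 < 0 or self.D < 0:
            raise ValueError("s0 and D must be >= 0")
        if not 0.0 <= self.theta0 < 1.0:
            raise ValueError("theta0 must lie in [0, 1)")


@dataclass
class PopulationDensity:
    """Bin-integrated mass over B uniform position bins at one clock time."""

    masses: np.ndarray
    division_weighted: bool = True

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        if np.any(self.masses < -1e-12):
            raise ValueError("bin masses must be non-negative")
        if abs(self.masses.sum() - 1.0) > 1e-9:
            raise ValueError("bin masses must sum to 1")

    @property
    def n_bins(self) -> int:
        return len(self.masses)

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_bins + 1)

    @property
    def bin_centers(self) -> np.ndarray:
        e = self.bin_edges
        return 0.5 * (e[:-1] + e[1:])

    def mean_position(self) -> float:
        """Circular mean of the binned density."""
        ang = 2 * np.pi * self.bin_centers
        z = np.sum(self.masses * np.exp(1j * ang))
        return float((np.angle(z) / (2 * np.pi)) % 1.0)


def evolve_density(
    params: PopulationParams,
    t: float,
    n_bins: int = 10,
    *,
    division_weighting: bool = True,
) -> PopulationDensity:
    """Density over position bins at clock time t after release.

    The unwrapped cohort position x ~ Normal(theta0 + t/T, s0^2 + 2 D t);
    mass on the wrap interval [k, k+1) carries weight 2^k when division
    weighting is on (k completed divisions since release; k < 0, reachable
    only through the Gaussian tail, carries weight 2^k < 1).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if n_bins < 1:
        raise ValueError("need at least one bin")
    mu = params.theta0 + t / params.T
    var = params.s0**2 + 2.0 * params.D * t
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    masses = np.zeros(n_bins)
    if var == 0.0:
        k = int(np.floor(mu))
        b = min(int((mu - k) * n_bins), n_bins - 1)
        masses[b] = 1.0
        return PopulationDensity(masses, division_weighted=division_weighting)
    sigma = np.sqrt(var)
    k_lo = int(np.floor(mu - 8.5 * sigma)) - 1
    k_hi = int(np.ceil(mu + 8.5 * sigma)) + 1
    for k in range(k_lo, k_hi + 1):
        w = 2.0**k if division_weighting else 1.0
        cdf = norm.cdf((k + edges - mu) / sigma)
        masses += w * np.diff(cdf)
    total = masses.sum()
    if total <= 0:  # pragma: no cover - unreachable for finite params
        raise ValueError("degenerate density")
    return PopulationDensity(masses / total, division_weighted=division_weighting)


def phase_fractions(density: PopulationDensity, phases: PhaseDefinition) -> np.ndarray:
    """Mass per phase, distributing each bin by its overlap with the phase.

    Exact when the density is constant within each bin; fractions sum to 1.
    """
    edges = density.bin_edges
    widths = np.diff(edges)
    out = np.zeros(len(phases.names))
    for p, name in enumerate(phases.names):
        a, b = phases.interval(name)
        overlap = np.clip(np.minimum(edges[1:], b) - np.maximum(edges[:-1], a), 0.0, None)
        out[p] = np.sum(density.masses * overlap / widths)
    return out


@dataclass
class PopulationFit:
    params: PopulationParams
    ssr: float
    n_starts_converged: int


def fit_population_params(
    times: np.ndarray,
    observed_fractions: np.ndarray,
    phases: PhaseDefinition | None = None,
    *,
    T_fixed: float | None = None,
    n_bins: int = 200,
    n_starts: int = 12,
    seed: int = 0,
    division_weighting: bool = True,
    T_bounds: tuple[float, float] = (8.0, 48.0),
) -> PopulationFit:
    """Fit (theta0, s0, D[, T]) to observed phase fractions over release times.

    Bounded multistart least squares; requires >= 4 observation times. The
    model fractions come from :func:`evolve_density` on a fine internal grid.
    """
    phases = phases or PhaseDefinition()
    times = np.asarray(times, dtype=float)
    observed = np.asarray(observed_fractions, dtype=float)
    if len(times) < 4:
        raise ValueError("need at least 4 observation times")
    if observed.shape != (len(times), len(phases.names)):
        raise ValueError("observed_fractions shape must be (n_times, n_phases)")
    if np.any(np.abs(observed.sum(axis=1) - 1.0) > 1e-3):
        raise ValueError("each observed fraction row must sum to 1 within 1e-3")

    fit_T = T_fixed is None

    def unpack(x: np.ndarray) -> PopulationParams:
        theta0, s0, D = x[0] % 1.0, x[1], x[2]
        T = x[3] if fit_T else T_fixed
        return PopulationParams(T=T, theta0=theta0, s0=s0, D=max(D, 0.0))

    def residuals(x: np.ndarray) -> np.ndarray:
        p = unpack(x)
        model = np.array(
            [
                phase_fractions(
                    evolve_density(p, t, n_bins, division_weighting=division_weighting),
                    phases,
                )
                for t in times
            ]
        )
        return (model - observed).ravel()

    lo = [0.0, 0.0, 0.0] + ([T_bounds[0]] if fit_T else [])
    hi = [1.0, 0.4, 0.05] + ([T_bounds[1]] if fit_T else [])
    rng = np.random.default_rng(seed)
    best = None
    n_ok = 0
    diagnostics = []
    for i in range(n_starts):
        x0 = rng.uniform(lo, hi)
        x0[0] = min(x0[0], 1.0 - 1e-9)
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
        except Exception as exc:  # pragma: no cover - optimizer pathologies
            diagnostics.append(str(exc))
            continue
        if not sol.success:
            diagnostics.append(sol.message)
            continue
        n_ok += 1
        ssr = float(np.sum(sol.fun**2))
        if best is None or ssr < best[0]:
            best = (ssr, sol.x)
    if best is None:
        raise RuntimeError(f"population fit failed in all starts: {diagnostics}")
    return PopulationFit(params=unpack(best[1]), ssr=best[0], n_starts_converged=n_ok)
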
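"""CSV/JSON schemas for measurements, phase fractions and ground truth.

All floats are serialized with 12 significant digits so that a fixed seed
yields byte-identical files across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

FLOAT_FMT = "%.12g"


def fmt(x: float) -> str:
    return FLOAT_FMT % x


@dataclass
class TracerMeasurements:
    """Population-averaged measurements from one tracer experiment.

    Every chase sample quantifies both the pool and the MID, so
    ``pools[met]`` has shape (n_release, n_chase) — replicates of a quantity
    constant over the chase — and ``mids[met]`` has shape
    (n_release, n_chase, n_carbons + 1).
    """

    tracer: str
    release_times: np.ndarray
    chase_times: np.ndarray
    pools: dict[str, np.ndarray]
    pool_sds: dict[str, np.ndarray]
    mids: dict[str, np.ndarray]
    mid_sds: dict[str, np.ndarray]

    @property
    def metabolites(self) -> list[str]:
        return list(self.mids)


def write_measurements(path: Path, meas: TracerMeasurements) -> None:
    """Schema: t_release_h, tau_h, metabolite, pool_size, pool_sd, M0.., sd0.."""
    max_k = max(arr.shape[2] for arr in meas.mids.values())
    cols = (
        ["t_release_h", "tau_h", "metabolite", "pool_size", "pool_sd"]
        + [f"M{i}" for i in range(max_k)]
        + [f"sd{i}" for i in range(max_k)]
    )
    lines = [",".join(cols)]
    for met in meas.metabolites:
        arr, sds = meas.mids[met], meas.mid_sds[met]
        K = arr.shape[2]
        for r, t_rel in enumerate(meas.release_times):
            for ti, tau in enumerate(meas.chase_times):
                row = [fmt(t_rel), fmt(tau), met, fmt(meas.pools[met][r, ti]), fmt(meas.pool_sds[met][r, ti])]
                row += [fmt(v) for v in arr[r, ti]] + [""] * (max_k - K)
                row += [fmt(v) for v in sds[r, ti]] + [""] * (max_k - K)
                lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_measurements(path: Path, tracer: str = "") -> TracerMeasurements:
    df = pd.read_csv(path)
    release_times = np.array(sorted(df["t_release_h"].unique()))
    chase_times = np.array(sorted(df["tau_h"].unique()))
    m_cols = sorted((c for c in df.columns if c.startswith("M") and c[1:].isdigit()),
                    key=lambda c: int(c[1:]))
    pools: dict[str, np.ndarray] = {}
    pool_sds: dict[str, np.ndarray] = {}
    mids: dict[str, np.ndarray] = {}
    mid_sds: dict[str, np.ndarray] = {}
    for met, g in df.groupby("metabolite", sort=False):
        sub = g.sort_values(["t_release_h", "tau_h"])
        vals = sub[m_cols].to_numpy(dtype=float)
        K = int(np.sum(~np.isnan(vals[0])))
        R, T = len(release_times), len(chase_times)
        if len(sub) != R * T:
            raise ValueError(f"{path}: metabolite {met} missing rows (chase grids inconsistent)")
        mids[met] = vals[:, :K].reshape(R, T, K)
        sd_cols = [f"sd{i}" for i in range(K)]
        mid_sds[met] = sub[sd_cols].to_numpy(dtype=float).reshape(R, T, K)
        pools[met] = sub["pool_size"].to_numpy(dtype=float).reshape(R, T)
        pool_sds[met] = sub["pool_sd"].to_numpy(dtype=float).reshape(R, T)
    return TracerMeasurements(
        tracer=tracer,
        release_times=release_times,
        chase_times=chase_times,
        pools=pools,
        pool_sds=pool_sds,
        mids=mids,
        mid_sds=mid_sds,
    )


def write_phase_fractions(path: Path, times: np.ndarray, fractions: np.ndarray,
                          names: tuple[str, ...]) -> None:
    header = "t_release_h," + ",".join(f"frac_{n}" for n in names)
    lines = [header]
    for t, row in zip(times, fractions):
        lines.append(",".join([fmt(t)] + [fmt(v) for v in row]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_phase_fractions(path: Path) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path)
    names = tuple(c[5:] for c in df.columns if c.startswith("frac_"))
    times = df["t_release_h"].to_numpy(dtype=float)
    fractions = df[[f"frac_{n}" for n in names]].to_numpy(dtype=float)
    return times, fractions, names


def write_json(path: Path, obj) -> None:
    """Deterministic JSON with 12-significant-digit floats."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not serializable: {type(o)}")

    text = json.dumps(_round_floats(obj), indent=1, sort_keys=True, default=default)
    Path(path).write_text(text + "\n")


def _round_floats(obj):
    if isinstance(obj, float):
        return float(fmt(obj))
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist())
    if isinstance(obj, (np.floating,)):
        return float(fmt(float(obj)))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj
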
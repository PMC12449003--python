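"""Hemodynamic descriptors and spatial (transport/perfusion) analyses.

From last-cycle waveforms this module computes, per vessel: systolic,
diastolic and period-mean pressure and flow; pulse pressure
``PP = P_s - P_d``; flow pulsatility index ``PI = (Q_s - Q_d)/Q_m``; and the
damping factors ``DF_Y = max(Y) / Y`` (Y in {PI, PP}), where the reference
maximum is taken over the whole network, so the maximizing vessel has
``DF = 1`` and damping grows toward the periphery.

The spatial analyses follow root-to-terminal paths: the *transport* level
aggregates per-distance-bin maxima of PI and mean pressure along sampled
paths; the *perfusion* level looks at the terminal vessels only, against
their distance to the root and their diameter.  Trends are summarized by
ordinary-least-squares slopes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import units
from .ccogen import VascularTree
from .flow1d import SimulationResult

__all__ = [
    "Waveform",
    "temporal_stats",
    "pulsatility_and_pulse",
    "compute_indices",
    "damping_factors",
    "PathSample",
    "sample_paths",
    "TrendFit",
    "transport_perfusion_analysis",
    "summarize_median_iqr",
]


@dataclass
class Waveform:
    """Uniformly sampled periodic signal over one period (no duplicate endpoint)."""

    t: np.ndarray
    values: np.ndarray
    period: float

    def __post_init__(self):
        if len(self.t) < 32:
            raise ValueError("at least 32 samples per period are required")


def temporal_stats(w: Waveform) -> tuple[float, float, float]:
    """(systolic, diastolic, mean): max, min and period-mean of the signal.

    The mean is the trapezoidal period average; for uniform sampling of a
    periodic signal this is the plain sample mean.
    """
    v = np.asarray(w.values, dtype=float)
    if v.size == 0:
        raise ValueError("empty waveform")
    return float(v.max()), float(v.min()), float(v.mean())


def pulsatility_and_pulse(q_wave: Waveform, p_wave: Waveform) -> tuple[float, float]:
    """(PI, PP): flow pulsatility index and pulse pressure."""
    qs, qd, qm = temporal_stats(q_wave)
    ps, pd_, _ = temporal_stats(p_wave)
    if qm == 0:
        raise ZeroDivisionError("PI undefined: mean flow is zero")
    return (qs - qd) / qm, ps - pd_


def compute_indices(result: SimulationResult) -> pd.DataFrame:
    """Per-vessel index table from the last simulated cycle.

    Pressures in mmHg, flows in ml/s.  Index sampling location is the distal
    end of each vessel.
    """
    t, p, q = result.last_cycle()
    ps, pd_, pm = p.max(0), p.min(0), p.mean(0)
    qs, qd, qm = q.max(0), q.min(0), q.mean(0)
    if np.any(qm == 0):
        raise ZeroDivisionError("PI undefined: zero mean flow at a vessel")
    df = pd.DataFrame({
        "vessel": np.arange(p.shape[1]),
        "P_s": units.cgs_to_mmhg(ps),
        "P_d": units.cgs_to_mmhg(pd_),
        "P_m": units.cgs_to_mmhg(pm),
        "Q_s": qs,
        "Q_d": qd,
        "Q_m": qm,
    })
    df["PP"] = df["P_s"] - df["P_d"]
    df["PI"] = (df["Q_s"] - df["Q_d"]) / df["Q_m"]
    return damping_factors(df)


def damping_factors(indices: pd.DataFrame) -> pd.DataFrame:
    """Add ``DF_PI`` and ``DF_PP`` columns: network maximum over local value.

    A vessel with a zero index receives ``inf`` (flagged, not an error).
    """
    out = indices.copy()
    for y in ("PI", "PP"):
        ref = out[y].max()
        with np.errstate(divide="ignore"):
            out[f"DF_{y}"] = ref / out[y].to_numpy()
    return out


@dataclass
class PathSample:
    """One root-to-terminal path with cumulative arc-length coordinates."""

    segments: np.ndarray  # ordered ids, root first
    arc_length: np.ndarray  # cumulative length at each segment's distal end, cm

    def __post_init__(self):
        if np.any(np.diff(self.arc_length) <= 0):
            raise ValueError("cumulative path length must be strictly increasing")


def sample_paths(tree: VascularTree, n_paths: int, seed: int) -> list[PathSample]:
    """Uniformly sample ``n_paths`` terminals (without replacement) and trace
    each back to the root."""
    terms = tree.terminal_ids()
    if n_paths > len(terms):
        raise ValueError(
            f"n_paths={n_paths} exceeds the terminal count {len(terms)}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(terms, size=n_paths, replace=False)
    lengths = tree.lengths
    paths = []
    for tid in chosen:
        ids = tree.path_to_root(int(tid))[::-1]  # root first
        arc = np.cumsum(lengths[ids])
        paths.append(PathSample(segments=np.asarray(ids), arc_length=arc))
    return paths


@dataclass
class TrendFit:
    slope: float
    intercept: float
    units: str


def _ols(x, y):
    if len(x) < 2:
        return float("nan"), float("nan")
    coef = np.polyfit(np.asarray(x, float), np.asarray(y, float), 1)
    return float(coef[0]), float(coef[1])


def transport_perfusion_analysis(paths: list[PathSample],
                                 indices: pd.DataFrame,
                                 tree: VascularTree,
                                 bin_width: float = 1.0) -> dict:
    """Transport-level curves and perfusion-level scatter with trend slopes.

    Transport level: per-distance-bin maxima of PI and mean pressure over
    all sampled path points; slopes fitted to the bin maxima.  Perfusion
    level: indices at the terminal vessels against distance to root and
    diameter; slopes fitted to the raw terminal points.  Empty bins are
    skipped.
    """
    if not paths:
        raise ValueError("no paths given")
    by_vessel = indices.set_index("vessel")
    seg_ids = np.concatenate([p.segments for p in paths])
    arcs = np.concatenate([p.arc_length for p in paths])
    uniq, first = np.unique(seg_ids, return_index=True)
    pi = by_vessel.loc[uniq, "PI"].to_numpy()
    pm = by_vessel.loc[uniq, "P_m"].to_numpy()
    arc_u = arcs[first]

    bins = np.arange(0.0, arc_u.max() + bin_width, bin_width)
    which = np.digitize(arc_u, bins) - 1
    rows = []
    for b in range(len(bins) - 1):
        m = which == b
        if not m.any():
            continue
        rows.append({
            "L": 0.5 * (bins[b] + bins[b + 1]),
            "PI_t": float(pi[m].max()),
            "P_m_t": float(pm[m].max()),
            "n": int(m.sum()),
        })
    transport = pd.DataFrame(rows)
    s_pi, i_pi = _ols(transport["L"], transport["PI_t"])
    s_pm, i_pm = _ols(transport["L"], transport["P_m_t"])

    term_ids = np.array([p.segments[-1] for p in paths])
    term_arc = np.array([p.arc_length[-1] for p in paths])
    perf = pd.DataFrame({
        "vessel": term_ids,
        "L": term_arc,
        "D_um": units.cm_to_um(2.0 * tree.radius[term_ids]),
        "PI_p": by_vessel.loc[term_ids, "PI"].to_numpy(),
        "P_m_p": by_vessel.loc[term_ids, "P_m"].to_numpy(),
    })
    sp_pi, ip_pi = _ols(perf["L"], perf["PI_p"])
    sp_pm, ip_pm = _ols(perf["L"], perf["P_m_p"])
    return {
        "transport": transport,
        "perfusion": perf,
        "transport_PI_trend": TrendFit(s_pi, i_pi, "1/cm"),
        "transport_Pm_trend": TrendFit(s_pm, i_pm, "mmHg/cm"),
        "perfusion_PI_trend": TrendFit(sp_pi, ip_pi, "1/cm"),
        "perfusion_Pm_trend": TrendFit(sp_pm, ip_pm, "mmHg/cm"),
    }


def summarize_median_iqr(indices: pd.DataFrame,
                         columns=("P_m", "PP", "PI", "DF_PP", "DF_PI")) -> dict:
    """Median [Q1, Q3] summary in the conventional reporting format."""
    out = {}
    for c in columns:
        if c not in indices:
            continue
        v = indices[c].replace([np.inf, -np.inf], np.nan).dropna()
        q1, med, q3 = v.quantile([0.25, 0.5, 0.75])
        out[c] = {"median": float(med), "q1": float(q1), "q3": float(q3),
                  "text": f"{med:.3g} [{q1:.3g}, {q3:.3g}]"}
    return out
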
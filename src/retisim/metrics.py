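"""Scalar response metrics and cohort statistics.

From each trace the analysis extracts the rising time constant of the
axon-terminal membrane potential (τ_V-Term) and of the calcium current
(τ_I-Term) — the time after stimulus onset at which the deflection from
baseline first reaches 1 − 1/e ≈ 63.2 % of its peak — the peak inward
calcium current I_peak and its time, the post-pulse tail current, and a
single-exponential decay constant τ_Decay fitted to the post-peak segment.
Healthy and degenerate cohorts are compared metric-by-metric with Welch's
two-sample t-test (cohort sizes and variances differ).

Currents are analysed as absolute inward current, |i_Ca| with inward
negative; metrics whose defining feature is absent (flat trace,
non-decaying segment) are reported as NaN rather than zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .membrane import TraceSet

__all__ = [
    "ResponseMetrics",
    "CohortComparison",
    "rise_time_constant",
    "peak_and_tail",
    "decay_time_constant",
    "cohort_compare",
    "trace_metrics",
    "metrics_table",
    "significance_stars",
]

RISE_FRACTION = 1.0 - 1.0 / np.e


@dataclass(frozen=True)
class ResponseMetrics:
    """Scalar response metrics of one cell at one pulse duration.

    Times in ms, currents in pA, potentials in mV; NaN marks an undefined
    metric.
    """

    tau_v_term: float
    tau_i_term: float
    i_peak: float
    t_peak: float
    i_tail: float
    tau_decay: float
    v_end_soma: float
    v_end_dendrite: float
    v_end_axon: float
    v_end_axon_terminal: float


@dataclass(frozen=True)
class CohortComparison:
    """Welch comparison of one metric between two cohorts."""

    metric: str
    mean_a: float
    se_a: float
    n_a: int
    mean_b: float
    se_b: float
    n_b: int
    t_stat: float
    p_value: float
    stars: str


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def _interp_crossing(t: np.ndarray, y: np.ndarray, level: float) -> float:
    """First time y reaches level, linearly interpolated between samples."""
    above = y >= level
    if not above.any():
        return np.nan
    k = int(np.argmax(above))
    if k == 0:
        return float(t[0])
    t0, t1 = t[k - 1], t[k]
    y0, y1 = y[k - 1], y[k]
    if y1 == y0:
        return float(t1)
    return float(t0 + (level - y0) / (y1 - y0) * (t1 - t0))


def rise_time_constant(t: np.ndarray, y: np.ndarray, onset: float) -> float:
    """Time after ``onset`` to reach 63.2 % of the peak deflection from the
    pre-onset baseline, in ms; NaN for a flat trace."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    pre = t <= onset
    baseline = y[pre][-1] if pre.any() else y[0]
    post = t >= onset
    dev = np.abs(y[post] - baseline)
    peak = dev.max()
    if peak <= 0 or not np.isfinite(peak):
        return np.nan
    tc = _interp_crossing(t[post], dev, RISE_FRACTION * peak)
    return float(tc - onset)


def peak_and_tail(t: np.ndarray, i_ca: np.ndarray, onset: float,
                  offset: float) -> tuple[float, float, float]:
    """(I_peak, t_peak, I_tail): the largest |inward current| during the
    pulse, its first time, and the largest |inward current| after offset.

    Currents are returned as magnitudes in the units of ``i_ca`` (inward
    currents are negative in the traces).  Ties report the earlier time.
    """
    t = np.asarray(t, float)
    i_ca = np.asarray(i_ca, float)
    if offset <= onset:
        raise ValueError("offset must come after onset")
    stim = (t >= onset) & (t <= offset)
    post = t > offset
    if not stim.any():
        raise ValueError("no samples inside the stimulus window")
    mag = np.abs(np.minimum(i_ca, 0.0))  # inward only
    m_stim = mag[stim]
    i_peak = float(m_stim.max())
    t_peak = float(t[stim][int(np.argmax(m_stim))])
    i_tail = float(mag[post].max()) if post.any() else 0.0
    return i_peak, t_peak, i_tail


def decay_time_constant(t: np.ndarray, i_ca: np.ndarray, t_peak: float,
                        floor_fraction: float = 0.1) -> float:
    """Exponential decay constant (ms) of |i_Ca| after its peak.

    Least-squares fit of log|i| on the segment from the peak down to
    ``floor_fraction`` of the peak magnitude (default 10 %); NaN if the
    segment does not decay.
    """
    t = np.asarray(t, float)
    mag = np.abs(np.asarray(i_ca, float))
    k0 = int(np.searchsorted(t, t_peak))
    k0 = min(k0, len(t) - 1)
    peak = mag[k0]
    if peak <= 0:
        return np.nan
    seg = mag[k0:]
    ts = t[k0:]
    below = seg <= floor_fraction * peak
    k1 = int(np.argmax(below)) if below.any() else len(seg)
    seg, ts = seg[:max(k1, 3)], ts[:max(k1, 3)]
    good = seg > 0
    if good.sum() < 3 or seg[good][-1] >= seg[good][0]:
        return np.nan
    slope, _ = np.polyfit(ts[good], np.log(seg[good]), 1)
    if slope >= 0:
        return np.nan
    return float(-1.0 / slope)


def cohort_compare(values_a, values_b, metric: str = "") -> CohortComparison:
    """Welch two-sample comparison: means ± SE, t, two-sided p, stars."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each cohort needs at least two finite values")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            t_stat, p = 0.0, 1.0
        else:
            warnings.warn("degenerate variance in both cohorts", stacklevel=2)
            t_stat, p = np.nan, np.nan
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t_stat, p = stats.ttest_ind(a, b, equal_var=False)
    return CohortComparison(
        metric=metric,
        mean_a=float(a.mean()), se_a=float(a.std(ddof=1) / np.sqrt(len(a))), n_a=len(a),
        mean_b=float(b.mean()), se_b=float(b.std(ddof=1) / np.sqrt(len(b))), n_b=len(b),
        t_stat=float(t_stat), p_value=float(p), stars=significance_stars(float(p)),
    )


def trace_metrics(tr: TraceSet, current_metric: str = "per_terminal") -> ResponseMetrics:
    """All scalar metrics of one simulated trace.

    ``current_metric`` selects the reported calcium-current quantity:
    ``per_terminal`` (default) divides the summed terminal current by the
    number of terminal compartments — the average current through one
    synaptic terminal — while ``total`` reports the whole-cell sum.
    Requires ``tr.meta`` to carry ``onset`` and ``duration`` (set by
    :func:`retisim.protocol.run_sweep`).
    """
    if current_metric == "per_terminal":
        i_trace = tr.i_ca_total / max(int(tr.meta.get("n_terminals", 1)), 1)
    elif current_metric == "total":
        i_trace = tr.i_ca_total
    else:
        raise ValueError(f"unknown current_metric {current_metric!r}")
    onset = float(tr.meta["onset"])
    offset = onset + float(tr.meta["duration"])
    tau_v = rise_time_constant(tr.t, tr.v_terminal_mean, onset)
    tau_i = rise_time_constant(tr.t, np.abs(i_trace), onset)
    i_peak, t_peak, i_tail = peak_and_tail(tr.t, i_trace, onset, offset)
    tau_d = decay_time_constant(tr.t, i_trace, t_peak)
    k_end = int(np.searchsorted(tr.t, offset, side="right")) - 1
    return ResponseMetrics(
        tau_v_term=tau_v, tau_i_term=tau_i, i_peak=i_peak,
        t_peak=t_peak - onset, i_tail=i_tail, tau_decay=tau_d,
        v_end_soma=float(tr.v_sections["soma"][k_end]),
        v_end_dendrite=float(tr.v_sections["dendrite"][k_end]),
        v_end_axon=float(tr.v_sections["axon"][k_end]),
        v_end_axon_terminal=float(tr.v_sections["axon_terminal"][k_end]),
    )


def metrics_table(traces: dict[tuple[str, float], TraceSet],
                  cell_info: dict[str, dict] | None = None,
                  current_metric: str = "per_terminal") -> pd.DataFrame:
    """Tidy table: one row per (cell, duration) with all scalar metrics."""
    rows = []
    for (cell_id, dur), tr in sorted(traces.items()):
        m = trace_metrics(tr, current_metric)
        row = {"cell_id": cell_id, "duration": dur}
        if cell_info and cell_id in cell_info:
            row.update(cell_info[cell_id])
        row.update(vars(m) if not hasattr(m, "__dataclass_fields__") else
                   {k: getattr(m, k) for k in m.__dataclass_fields__})
        rows.append(row)
    return pd.DataFrame(rows)
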
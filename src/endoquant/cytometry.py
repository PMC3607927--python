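"""Flow-cytometry event analysis: gating, quadrants, geometric means, markers.

Event tables carry two intensity channels per event: the receptor fusion
protein (``syfp``, marking transfected cells) and the quantum-dot ligand
(``qd``).  The analysis is threshold-based throughout: a SYFP-positive gate
derived from the autofluorescence of non-transfected control cells,
quadrant counts in the (syfp, qd) plane, per-histogram geometric means
normalized to time zero, and an M1 marker placed so that ~4% of gated
events exceed it at time zero, whose normalized exceedance fraction
("Marker / 0 min") tracks internalized label over time.

All quantiles use linear interpolation between order statistics
(numpy's default), so every threshold is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GateSpec",
    "MarkerStat",
    "gate_positive",
    "quadrant_statistics",
    "geometric_mean",
    "place_marker",
    "marker_series",
    "fold_vs_control",
]


@dataclass
class GateSpec:
    """Channel thresholds with their provenance (control sample + quantile)."""

    syfp_threshold: float
    qd_threshold: float
    provenance: dict = field(default_factory=dict)


@dataclass
class MarkerStat:
    """M1 marker threshold and its per-time exceedance series."""

    m1_threshold: float
    fractions: dict  # time_min -> fraction of gated events above threshold
    normalized: dict  # time_min -> fraction(t) / fraction(0)
    reference_label: str = ""


def _channel(table: pd.DataFrame, channel: str) -> np.ndarray:
    if channel not in table.columns:
        raise ValueError(f"missing channel column: {channel!r}")
    x = table[channel].to_numpy(dtype=float)
    if len(x) == 0:
        raise ValueError("empty event table")
    return x


def gate_positive(
    sample: pd.DataFrame,
    control: pd.DataFrame,
    channel: str = "syfp",
    quantile: float = 0.995,
):
    """Gate events above a control-derived autofluorescence threshold.

    The threshold is the given quantile of the control (non-transfected)
    channel distribution; events of ``sample`` strictly above it are
    retained.  Returns ``(GateSpec, gated subset)``.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    ctrl = _channel(control, channel)
    if len(ctrl) < 100:
        import warnings

        warnings.warn(f"control has only {len(ctrl)} events; gate may be unstable")
    thr = float(np.quantile(ctrl, quantile))
    gate = GateSpec(
        syfp_threshold=thr if channel == "syfp" else math.nan,
        qd_threshold=thr if channel == "qd" else math.nan,
        provenance={"channel": channel, "quantile": quantile, "n_control": len(ctrl)},
    )
    gated = sample.loc[sample[channel].to_numpy(dtype=float) > thr].copy()
    return gate, gated


def quadrant_statistics(events: pd.DataFrame, gate: GateSpec) -> dict:
    """Counts in the four (syfp, qd) quadrants plus the labeled fraction.

    Quadrant convention: I = qd-high / syfp-low; II = both high;
    III = both low; IV = syfp-high / qd-low.  The labeled fraction is
    II / (II + IV): among transfected (syfp-high) events, the share also
    carrying high QD signal.  Undefined (None) when no event is syfp-high.
    """
    syfp = _channel(events, "syfp")
    qd = _channel(events, "qd")
    hi_s = syfp > gate.syfp_threshold
    hi_q = qd > gate.qd_threshold
    counts = {
        "I": int((~hi_s & hi_q).sum()),
        "II": int((hi_s & hi_q).sum()),
        "III": int((~hi_s & ~hi_q).sum()),
        "IV": int((hi_s & ~hi_q).sum()),
    }
    denom = counts["II"] + counts["IV"]
    counts["labeled_fraction"] = counts["II"] / denom if denom > 0 else None
    return counts


def geometric_mean(values, zero_policy: str = "exclude", floor: float = 1e-6) -> float:
    """exp(mean(ln x)) with an explicit policy for non-positive values.

    ``exclude`` drops them; ``floor`` clips them up to ``floor``.  At least
    one positive value must survive the policy.
    """
    x = np.asarray(values, dtype=float)
    if zero_policy == "exclude":
        x = x[x > 0]
    elif zero_policy == "floor":
        x = np.maximum(x, floor)
    else:
        raise ValueError(f"unknown zero_policy: {zero_policy!r}")
    if len(x) == 0:
        raise ValueError("no positive values after zero policy")
    return float(np.exp(np.mean(np.log(x))))


def geometric_mean_series(tables_by_time: dict, channel: str = "qd", **kw) -> pd.DataFrame:
    """Per-time geometric means of a channel, normalized to time zero."""
    if 0 not in tables_by_time and 0.0 not in tables_by_time:
        raise ValueError("time-zero table required for normalization")
    rows = []
    for t in sorted(tables_by_time):
        gm = geometric_mean(_channel(tables_by_time[t], channel), **kw)
        rows.append({"time_min": float(t), "geometric_mean": gm})
    df = pd.DataFrame(rows)
    gm0 = float(df.loc[df["time_min"] == 0.0, "geometric_mean"].iloc[0])
    df["normalized"] = df["geometric_mean"] / gm0
    return df


def place_marker(reference: pd.DataFrame, tail_fraction: float = 0.04, channel: str = "qd") -> float:
    """Threshold leaving ~``tail_fraction`` of the reference events above it.

    The reference is the gated time-zero sample; the threshold is its
    (1 - tail_fraction) channel quantile (linear interpolation).  With
    heavy ties the realized tail can deviate; callers can report the
    realized fraction via :func:`marker_series`.
    """
    if not 0 < tail_fraction < 0.5:
        raise ValueError("tail_fraction must be in (0, 0.5)")
    x = _channel(reference, channel)
    if len(x) < 50:
        import warnings

        warnings.warn(f"marker reference has only {len(x)} events")
    return float(np.quantile(x, 1.0 - tail_fraction))


def marker_series(tables_by_time: dict, m1_threshold: float, channel: str = "qd") -> MarkerStat:
    """Fraction of gated events above the M1 marker per time, normalized to t=0.

    The normalized series starts at exactly 1 by construction; a zero
    exceedance fraction at time zero makes the normalization undefined.
    """
    if 0 not in tables_by_time and 0.0 not in tables_by_time:
        raise ValueError("time-zero table required for Marker/0min normalization")
    fractions = {}
    for t, tab in tables_by_time.items():
        x = _channel(tab, channel)
        fractions[float(t)] = float((x > m1_threshold).mean())
    f0 = fractions[0.0]
    if f0 == 0:
        raise ValueError("no events above the marker at t=0: normalization undefined")
    normalized = {t: f / f0 for t, f in fractions.items()}
    return MarkerStat(m1_threshold=m1_threshold, fractions=fractions, normalized=normalized)


def fold_vs_control(sample_fraction: float, control_fraction: float) -> float:
    """Specific-binding fold: sample fraction over the ligand-free control."""
    if control_fraction <= 0:
        raise ValueError("control fraction must be positive")
    return sample_fraction / control_fraction
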
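"""Cohort-level lead-sensitivity statistics.

For each of the 12 leads the per-record statistic is the maximum absolute QRS
amplitude (irrespective of polarity).  Cohort location is summarised with a
95% truncated mean (the lowest and highest 2.5% of values are dropped before
averaging), and the sensitivity of lead i to LVH is the relative difference

    D_i = (maxLead_i_LVH - maxLead_i_ctrl) / maxLead_i_ctrl

between the LVH and control cohort means.  D is dimensionless and invariant
to any common rescaling of all records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ecg_forward import LEAD_NAMES

__all__ = [
    "CohortAmplitudes",
    "truncated_mean",
    "per_record_max_amplitudes",
    "cohort_lead_means",
    "lead_amplitude_difference",
    "rank_leads",
    "plot_lead_sensitivity",
]


@dataclass
class CohortAmplitudes:
    """Truncated-mean max |QRS| per lead and cohort, plus D_i."""

    ctrl: pd.Series           # mV, index = leads
    lvh: pd.Series            # mV
    d: pd.Series              # dimensionless
    n_ctrl: int
    n_lvh: int


def truncated_mean(values, trim_fraction: float = 0.025) -> float:
    """Mean after dropping floor(n * trim_fraction) values from each tail."""
    v = np.sort(np.asarray(values, float))
    n = len(v)
    k = math.floor(n * trim_fraction)
    if n - 2 * k <= 0:
        raise ValueError("no values remain after trimming")
    return float(v[k:n - k].mean())


def per_record_max_amplitudes(ecgs: dict, apply_filter: bool = True,
                              mode: str = "clinical") -> tuple[pd.DataFrame, list]:
    """Per-record max |QRS| per lead (mV) through the feature pipeline.

    ``ecgs`` maps record id -> ECG12.  Records are filtered, beats detected,
    and the per-record statistic is the median across beats of the per-beat
    max |amplitude|; records without a detectable QRS are dropped and their
    ids returned separately.
    """
    from .ecg_features import detect_beats, filter_ecg, wave_amplitudes
    from .ecg_forward import ECG12

    rows, dropped = {}, []
    for rid, ecg in ecgs.items():
        if apply_filter:
            filt = filter_ecg(ecg.stack(), ecg.fs)
            ecg = ECG12(leads=dict(zip(LEAD_NAMES, filt)), fs=ecg.fs)
        if mode == "clinical":
            beats = detect_beats(ecg.stack(), ecg.fs)
            if len(beats) == 0:
                dropped.append(rid)
                continue
            n_ms = len(ecg.time_ms) * 1000.0 / ecg.fs
            per_beat = []
            for b in beats:
                t = b * 1000.0 / ecg.fs
                w = (max(t - 60.0, 0.0), min(t + 60.0, n_ms - 1000.0 / ecg.fs))
                per_beat.append(wave_amplitudes(ecg, w))
            rows[rid] = {k: float(np.median([f.max_abs(k) for f in per_beat]))
                         for k in LEAD_NAMES}
        else:
            from .ecg_features import extract_features
            feats = extract_features(ecg, "simulated")
            rows[rid] = {k: feats.max_abs(k) for k in LEAD_NAMES}
    return pd.DataFrame.from_dict(rows, orient="index"), dropped


def cohort_lead_means(per_record_max: pd.DataFrame, labels: pd.Series,
                      trim_fraction: float = 0.025) -> CohortAmplitudes:
    """Truncated-mean per-lead amplitudes for control and LVH cohorts.

    ``per_record_max`` has one row per record and one column per lead (max
    |QRS| in mV, e.g. the median across beats for multi-beat records);
    ``labels`` holds 'ctrl' / 'lvh' per record.
    """
    missing = [k for k in LEAD_NAMES if k not in per_record_max.columns]
    if missing:
        raise ValueError(f"missing leads: {missing}")
    labels = labels.reindex(per_record_max.index)
    groups = {}
    for name in ("ctrl", "lvh"):
        sub = per_record_max.loc[labels == name, list(LEAD_NAMES)]
        if len(sub) == 0:
            raise ValueError(f"cohort {name!r} is empty")
        groups[name] = sub.apply(lambda col: truncated_mean(col, trim_fraction))
    d = lead_amplitude_difference(groups["ctrl"], groups["lvh"])
    return CohortAmplitudes(ctrl=groups["ctrl"], lvh=groups["lvh"], d=d,
                            n_ctrl=int((labels == "ctrl").sum()),
                            n_lvh=int((labels == "lvh").sum()))


def lead_amplitude_difference(ctrl_means: pd.Series, lvh_means: pd.Series) -> pd.Series:
    """Relative difference D_i per lead; control means must be positive."""
    ctrl = ctrl_means.astype(float)
    if (ctrl <= 0).any():
        raise ValueError("control means must be positive")
    return (lvh_means.astype(float) - ctrl) / ctrl


def rank_leads(d: pd.Series) -> list[str]:
    """Leads in descending order of D, ties broken by canonical lead order."""
    missing = [k for k in LEAD_NAMES if k not in d.index]
    if missing:
        raise ValueError(f"missing leads in D: {missing}")
    order = {k: i for i, k in enumerate(LEAD_NAMES)}
    return sorted(LEAD_NAMES, key=lambda k: (-float(d[k]), order[k]))


def plot_lead_sensitivity(d: pd.Series, path: str | None = None):
    """Shaded 12-lead map of D_i (darker = more sensitive to LVH)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 2.2))
    vals = np.array([float(d[k]) for k in LEAD_NAMES])
    lo, hi = vals.min(), vals.max()
    shade = (vals - lo) / (hi - lo) if hi > lo else np.ones_like(vals)
    ax.bar(range(12), vals, color=[(1 - s, 1 - s, 1 - s) for s in shade],
           edgecolor="black")
    ax.set_xticks(range(12), LEAD_NAMES)
    ax.set_ylabel("relative amplitude difference D")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
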
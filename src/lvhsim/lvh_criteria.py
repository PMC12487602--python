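"""Voltage-based ECG criteria for LVH and their cohort metrics.

Three established criteria are implemented on QRS R/S amplitudes:

* Sokolow-Lyon: S(V1) + max(R(V5), R(V6)) >= 3.5 mV (sex-independent);
* Cornell: R(aVL) + S(V3) >= 2.8 mV (men) / 2.0 mV (women, configurable);
* Peguero-Lo Presti: deepest precordial S + S(V4) >= 2.8 mV (men) / 2.3 mV
  (women, configurable).

Threshold comparisons are inclusive (value equal to the cutoff counts as a
positive call).  Classification metrics against an image-based truth
(mass-index flag) use the standard definitions; precision and F-score are
undefined (None) when no positives are predicted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ecg_features import QRSFeatures

__all__ = [
    "CriteriaThresholds",
    "CohortMetrics",
    "sokolow_lyon",
    "cornell",
    "peguero",
    "evaluate_cohort",
    "criteria_table",
]

PRECORDIAL = ("V1", "V2", "V3", "V4", "V5", "V6")


@dataclass(frozen=True)
class CriteriaThresholds:
    sokolow: float = 3.5
    cornell_male: float = 2.8
    cornell_female: float = 2.0
    peguero_male: float = 2.8
    peguero_female: float = 2.3


def sokolow_lyon(features: QRSFeatures,
                 thresholds: CriteriaThresholds = CriteriaThresholds()
                 ) -> tuple[float, bool]:
    value = features.s["V1"] + max(features.r["V5"], features.r["V6"])
    return value, value >= thresholds.sokolow


def cornell(features: QRSFeatures, sex: str = "male",
            thresholds: CriteriaThresholds = CriteriaThresholds()
            ) -> tuple[float, bool]:
    value = features.r["aVL"] + features.s["V3"]
    thr = thresholds.cornell_male if sex == "male" else thresholds.cornell_female
    return value, value >= thr


def peguero(features: QRSFeatures, sex: str = "male",
            thresholds: CriteriaThresholds = CriteriaThresholds(),
            all_leads: bool = False) -> tuple[float, bool]:
    """Deepest S + S(V4).

    The deepest-S search is restricted to the precordial leads by default
    (set ``all_leads`` for the original all-lead variant).
    """
    pool = list(features.s) if all_leads else list(PRECORDIAL)
    value = max(features.s[k] for k in pool) + features.s["V4"]
    thr = thresholds.peguero_male if sex == "male" else thresholds.peguero_female
    return value, value >= thr


@dataclass
class CohortMetrics:
    sensitivity: float
    specificity: float
    precision: float | None
    f_score: float | None


def evaluate_cohort(values: np.ndarray, truth: np.ndarray,
                    threshold: float) -> CohortMetrics:
    """Classification metrics of criterion values against truth flags.

    Decisions are inclusive (value >= threshold).  Precision and F are None
    when no positives are predicted.
    """
    values = np.asarray(values, float)
    truth = np.asarray(truth, bool)
    if values.shape != truth.shape:
        raise ValueError("values and truth must have the same length")
    pred = values >= threshold
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    prec = tp / (tp + fp) if tp + fp else None
    f = (2 * prec * sens / (prec + sens)
         if prec is not None and prec + sens > 0 else None)
    return CohortMetrics(sensitivity=sens, specificity=spec, precision=prec, f_score=f)


def criteria_table(features_by_model: dict[str, QRSFeatures],
                   truth_by_model: dict[str, bool],
                   sex: str = "male",
                   thresholds: CriteriaThresholds = CriteriaThresholds()
                   ) -> pd.DataFrame:
    """Per-model criterion values/decisions plus a metrics footer.

    Returns a tidy DataFrame with one row per model (columns: model, truth,
    sokolow, cornell, peguero and the *_pos decision flags); cohort metrics
    are attached in ``df.attrs['metrics']``.
    """
    rows = []
    for name, feats in features_by_model.items():
        sv, sp = sokolow_lyon(feats, thresholds)
        cv, cp = cornell(feats, sex, thresholds)
        pv, pp = peguero(feats, sex, thresholds)
        rows.append({"model": name, "truth": bool(truth_by_model[name]),
                     "sokolow": sv, "sokolow_pos": sp,
                     "cornell": cv, "cornell_pos": cp,
                     "peguero": pv, "peguero_pos": pp})
    df = pd.DataFrame(rows)
    thr = {"sokolow": thresholds.sokolow,
           "cornell": thresholds.cornell_male if sex == "male" else thresholds.cornell_female,
           "peguero": thresholds.peguero_male if sex == "male" else thresholds.peguero_female}
    df.attrs["metrics"] = {
        crit: evaluate_cohort(df[crit].to_numpy(), df["truth"].to_numpy(), t)
        for crit, t in thr.items()}
    return df
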
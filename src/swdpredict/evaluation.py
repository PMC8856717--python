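"""Performance metrics for SWD prediction and TP/FP classification.

Two layers of evaluation are used.  Prediction metrics score the precursor
detector itself: sensitivity = predicted SWDs / all SWDs x 100%, plus the
false-alarm rate in events per hour of analyzed recording.  Classification
metrics score the downstream random forest that sorts detections into true
and false positives: sensitivity, specificity, precision, balanced
accuracy = (sensitivity + specificity) / 2, and
F1 = 2 x precision x sensitivity / (precision + sensitivity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PredictionMetrics", "ConfusionMatrix", "ClassificationMetrics",
    "prediction_metrics", "classification_metrics", "group_combinations",
    "sens_fp_correlation", "tp_fp_energy_summary",
]


@dataclass(frozen=True)
class PredictionMetrics:
    sensitivity_pct: float
    fp_per_h: float

    @property
    def sensitivity_rounded(self) -> int:
        """Sensitivity to the nearest integer percent, as printed in
        summaries; full precision is kept in ``sensitivity_pct``."""
        return int(round(self.sensitivity_pct))


def prediction_metrics(n_predicted_swds: int, n_unpredicted_swds: int,
                       n_fp: int, hours: float) -> PredictionMetrics:
    """Sensitivity (%) of SWD prediction and false alarms per hour."""
    if min(n_predicted_swds, n_unpredicted_swds, n_fp) < 0:
        raise ValueError("counts must be non-negative")
    if hours <= 0:
        raise ValueError("recording duration must be positive")
    total = n_predicted_swds + n_unpredicted_swds
    if total == 0:
        raise ValueError("sensitivity undefined with zero SWDs")
    return PredictionMetrics(
        sensitivity_pct=100.0 * n_predicted_swds / total,
        fp_per_h=n_fp / hours,
    )


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of detection events by true class x predicted class."""

    fp_as_fp: float
    fp_as_tp: float
    tp_as_fp: float
    tp_as_tp: float

    def __post_init__(self) -> None:
        if min(self.fp_as_fp, self.fp_as_tp, self.tp_as_fp, self.tp_as_tp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_tp_class(self) -> float:
        return self.tp_as_tp + self.tp_as_fp

    @property
    def n_fp_class(self) -> float:
        return self.fp_as_fp + self.fp_as_tp


@dataclass(frozen=True)
class ClassificationMetrics:
    balanced_accuracy_pct: float
    f1_pct: float
    sensitivity_pct: float
    specificity_pct: float
    precision_pct: float


def classification_metrics(cm: ConfusionMatrix) -> ClassificationMetrics:
    """Balanced accuracy, F1, sensitivity, specificity and precision (%)."""
    if cm.n_tp_class == 0 or cm.n_fp_class == 0:
        raise ValueError("both classes must be represented")
    sens = 100.0 * cm.tp_as_tp / cm.n_tp_class
    spec = 100.0 * cm.fp_as_fp / cm.n_fp_class
    n_pred_tp = cm.tp_as_tp + cm.fp_as_tp
    prec = 100.0 * cm.tp_as_tp / n_pred_tp if n_pred_tp > 0 else 0.0
    f1 = (2 * prec * sens / (prec + sens)) if (prec + sens) > 0 else 0.0
    return ClassificationMetrics(
        balanced_accuracy_pct=(sens + spec) / 2,
        f1_pct=f1,
        sensitivity_pct=sens,
        specificity_pct=spec,
        precision_pct=prec,
    )


KNOWN_GROUPS = ("CC", "CT", "TT", "CCC", "CCT", "CTT", "TTT", "MCCC")


def group_combinations(sweep: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SEM of sensitivity and false-alarm rate per site group.

    ``sweep`` is the tidy table from threshold sweeps (one row per
    combination x threshold); empty groups are simply absent.
    """
    if sweep.empty:
        raise ValueError("empty sweep table")
    unknown = set(sweep["group"]) - set(KNOWN_GROUPS)
    if unknown:
        raise ValueError(f"unknown group tags: {sorted(unknown)}")
    g = sweep.groupby("group")
    out = pd.DataFrame({
        "mean_sensitivity_pct": g["sensitivity_pct"].mean(),
        "sem_sensitivity_pct": g["sensitivity_pct"].sem(ddof=1),
        "mean_fp_per_h": g["fp_per_h"].mean(),
        "sem_fp_per_h": g["fp_per_h"].sem(ddof=1),
        "n_rows": g.size(),
    })
    order = [x for x in KNOWN_GROUPS if x in out.index]
    return out.loc[order]


def sens_fp_correlation(sweep: pd.DataFrame) -> tuple[float, float]:
    """Pearson r (and two-sided p) between per-combination mean
    sensitivity and mean false-alarm rate."""
    per_combo = sweep.groupby("combination")[
        ["sensitivity_pct", "fp_per_h"]].mean()
    if len(per_combo) < 3:
        raise ValueError("correlation requires at least 3 combinations")
    x = per_combo["sensitivity_pct"].to_numpy()
    y = per_combo["fp_per_h"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in sweep results")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def tp_fp_energy_summary(events, n_fp_sample: int = 50,
                         rng_seed: int = 0) -> pd.DataFrame:
    """Per-band mean +/- SEM of per-channel W for TPs vs sampled FPs.

    Uses every TP detection and ``n_fp_sample`` false positives drawn
    without replacement (seeded); if fewer FPs exist, all are used with a
    warning.  Rows are (class, band); per-channel energies within a band
    are pooled.
    """
    tps = [e for e in events if e.label == "TP"]
    fps = [e for e in events if e.label == "FP"]
    if not tps:
        raise ValueError("no true-positive events to summarize")
    if not fps:
        raise ValueError("no false-positive events to summarize")
    rng = np.random.default_rng(rng_seed)
    if len(fps) < n_fp_sample:
        warnings.warn(f"only {len(fps)} false positives available; using all")
        fp_sel = fps
    else:
        fp_sel = [fps[i] for i in
                  rng.choice(len(fps), size=n_fp_sample, replace=False)]

    band_names = tps[0].band_names
    n_bands = len(band_names)
    rows = []
    for cls, evs in (("TP", tps), ("FP", fp_sel)):
        feats = np.stack([e.features for e in evs])  # (n_ev, bands*channels)
        per_band = feats.reshape(len(evs), n_bands, -1)
        for bi, bname in enumerate(band_names):
            vals = per_band[:, bi, :].reshape(-1)
            rows.append({
                "class": cls,
                "band": bname,
                "mean_W": float(vals.mean()),
                "sem_W": float(vals.std(ddof=1) / np.sqrt(vals.size))
                if vals.size > 1 else np.nan,
                "n_events": len(evs),
            })
    return pd.DataFrame(rows)
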
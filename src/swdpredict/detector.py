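"""Precursor detection, recording-site combinations, and threshold sweeps.

A time point is flagged as carrying an SWD precursor when three criteria
hold simultaneously on the cross-channel band-energy products:

1. the 5-10 Hz (precursor) product exceeds a detection threshold;
2. the precursor product exceeds the 3-5 Hz (slow-wave-sleep) product;
3. the precursor product exceeds the 7-20 Hz (spindle) product.

Alarms fire at the first time point satisfying all three criteria and the
detector then holds off for a refractory interval (dead time) before it
can fire again, as an online alarm system would; each detection event
carries the per-channel, per-band energies at its time as its feature
vector.  This extraction rule makes the number of alarms provably
non-increasing in the detection threshold.

Site combinations follow the standard grouping: all pairs and triples of
the eight S1/thalamic sites plus the M2 triple (85 combinations in all),
tagged CC/CT/TT/CCC/CCT/CTT/TTT/MCCC by cortical-vs-thalamic membership.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations as _combinations
from typing import Sequence

import numpy as np
import pandas as pd

from . import labeling as _labeling
from .evaluation import prediction_metrics
from .signal_io import (M2_SITES, S1_SITES, THALAMIC_SITES, SeizureAnnotation,
                        SignalRecord, site_class)
from .spectral import (DEFAULT_BANDS, BandDef, BandEnergySeries,
                       ProductSeries, band_energy_series, channel_product)

__all__ = [
    "DetectorConfig", "DetectionEvent", "SiteCombination",
    "detect_events", "enumerate_site_combinations", "sweep_thresholds",
    "calibrate_threshold", "default_threshold_grid", "CalibrationResult",
]

#: Default threshold grids: 14 values for three-site products, 16 for
#: two-site products.  Ranges are expressed in this package's normalized
#: product units and chosen so that the outer levels correspond to
#: saturated sensitivity / false-alarm regimes (the standard convention
#: for setting sweep endpoints); absolute threshold values do not
#: transfer between normalizations, only the grid sizes do.
GRID_3SITE = (0.1, 0.75, 14)
GRID_2SITE = (0.2, 2.4, 16)


def default_threshold_grid(n_sites: int) -> np.ndarray:
    """Linearly spaced default threshold grid for 2- or 3-site products."""
    if n_sites == 3:
        lo, hi, n = GRID_3SITE
    elif n_sites == 2:
        lo, hi, n = GRID_2SITE
    else:
        raise ValueError("grids are defined for 2 or 3 recording sites")
    return np.linspace(lo, hi, n)


@dataclass(frozen=True)
class DetectorConfig:
    """Detection threshold and alarm dead-time (refractory) interval."""

    threshold: float
    refractory_s: float = 1.0
    bands: tuple[BandDef, ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.refractory_s < 0:
            raise ValueError("refractory interval must be non-negative")


@dataclass
class DetectionEvent:
    """One merged precursor detection.

    ``features`` holds the per-channel W values at the event time, band-
    major (all channels of band 0, then band 1, ...): length 3 x n_channels
    for the three standard bands.  ``products`` holds the per-band product
    values at the event time.
    """

    t: float
    features: np.ndarray
    products: np.ndarray
    channels: tuple[str, ...]
    band_names: tuple[str, ...]
    label: str = _labeling.UNLABELED


@dataclass(frozen=True)
class SiteCombination:
    """A 2- or 3-site subset with its cortical/thalamic group tag."""

    sites: tuple[str, ...]
    group: str

    def __str__(self) -> str:
        return "+".join(self.sites)


_GROUP_BY_PROFILE = {
    ("C", "C"): "CC", ("C", "T"): "CT", ("T", "T"): "TT",
    ("C", "C", "C"): "CCC", ("C", "C", "T"): "CCT",
    ("C", "T", "T"): "CTT", ("T", "T", "T"): "TTT",
    ("M", "M", "M"): "MCCC",
}


def combination_group(sites: Sequence[str]) -> str:
    """Group tag (CC ... MCCC) from cortical/thalamic membership."""
    profile = tuple(sorted(site_class(s) for s in sites))
    try:
        return _GROUP_BY_PROFILE[profile]
    except KeyError:
        raise ValueError(f"no group defined for site set {tuple(sites)}")


def make_combination(sites: Sequence[str]) -> SiteCombination:
    return SiteCombination(sites=tuple(sites), group=combination_group(sites))


def enumerate_site_combinations(available_sites: Sequence[str],
                                ) -> list[SiteCombination]:
    """All analyzed site combinations among the available sites.

    S1 and thalamic sites combine freely in pairs and triples; M2 sites
    form only their own triple.  With the full montage (8 S1/thalamic
    sites + 3 M2 sites) this yields 56 + 1 = 57 triples and 28 pairs,
    85 combinations in total.
    """
    sites = list(available_sites)
    if len(set(sites)) != len(sites):
        raise ValueError("duplicate recording sites")
    standard = [s for s in sites if s in S1_SITES + THALAMIC_SITES]
    combos: list[SiteCombination] = []
    for triple in _combinations(standard, 3):
        combos.append(make_combination(triple))
    if all(m in sites for m in M2_SITES):
        combos.append(make_combination(M2_SITES))
    for pair in _combinations(standard, 2):
        combos.append(make_combination(pair))
    return combos


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _alarm_indices(mask: np.ndarray, times: np.ndarray,
                   refractory_s: float) -> list[int]:
    """Greedy dead-time alarm extraction: an alarm fires at the first
    super-threshold sample, then the detector re-arms only after
    ``refractory_s`` has elapsed.

    This is the maximum packing of the super-threshold time-set with
    minimum separation ``refractory_s``; because any packing of a subset
    is also a packing of the superset, the alarm count is guaranteed
    non-increasing as the threshold rises.
    """
    on = np.flatnonzero(mask)
    if on.size == 0:
        return []
    t_on = times[on]
    out = [int(on[0])]
    j = 0
    while True:
        nxt = int(np.searchsorted(t_on, t_on[j] + refractory_s, side="left"))
        j = max(nxt, j + 1)  # refractory 0 degenerates to every sample
        if j >= on.size:
            return out
        out.append(int(on[j]))


def detect_events(products: ProductSeries, energies: BandEnergySeries,
                  config: DetectorConfig) -> list[DetectionEvent]:
    """Apply the three precursor criteria and extract alarms.

    An alarm is raised at the first time point satisfying all three
    criteria; the detector then stays silent for ``refractory_s`` before
    it can fire again (dead-time semantics, see :func:`_alarm_indices`).
    ``energies`` supplies the feature vectors; it must share timestamps
    with ``products`` and contain the product's channels.
    """
    if products.times.shape != energies.times.shape or not np.allclose(
            products.times, energies.times):
        raise ValueError("product and energy series timestamps differ")
    p_prec = products.band("precursor")
    p_sws = products.band("sws")
    p_spin = products.band("spindle")
    mask = (p_prec > config.threshold) & (p_prec > p_sws) & (p_prec > p_spin)

    ch_idx = [energies.channel_index(c) for c in products.channels]
    band_names = tuple(b.name for b in energies.bands)
    events = []
    for i in _alarm_indices(mask, products.times, config.refractory_s):
        feats = energies.values[:, ch_idx, i].reshape(-1)  # band-major
        events.append(DetectionEvent(
            t=float(products.times[i]),
            features=feats,
            products=products.values[:, i].copy(),
            channels=products.channels,
            band_names=band_names,
        ))
    return events


# ---------------------------------------------------------------------------
# Sweeps and calibration
# ---------------------------------------------------------------------------

def _detect_and_score(energies: BandEnergySeries, prod: ProductSeries,
                      annotation: SeizureAnnotation, threshold: float,
                      hours: float, refractory_s: float,
                      labeling_config: _labeling.LabelingConfig):
    cfg = DetectorConfig(threshold=threshold, refractory_s=refractory_s)
    events = detect_events(prod, energies, cfg)
    events, counts = _labeling.label_detections(events, annotation,
                                                labeling_config)
    metrics = prediction_metrics(counts.n_tp_swd, counts.n_missed,
                                 counts.n_fp, hours)
    return events, counts, metrics


def sweep_thresholds(record: SignalRecord, annotation: SeizureAnnotation,
                     combination: SiteCombination,
                     grid: Sequence[float] | None = None,
                     energies: BandEnergySeries | None = None,
                     refractory_s: float = 1.0,
                     labeling_config: _labeling.LabelingConfig | None = None,
                     **energy_kwargs) -> pd.DataFrame:
    """Detection performance of one site combination across a threshold grid.

    Returns a tidy DataFrame with one row per threshold: combination,
    group, threshold, sensitivity_pct, fp_per_h, n_tp, n_fp, n_swd.
    ``energies`` may be precomputed (e.g. shared across combinations);
    otherwise it is derived from the record.
    """
    grid = np.asarray(default_threshold_grid(len(combination.sites))
                      if grid is None else list(grid), dtype=float)
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("threshold grid must be non-empty and positive")
    if energies is None:
        energies = band_energy_series(record, **energy_kwargs)
    labeling_config = labeling_config or _labeling.LabelingConfig()
    prod = channel_product(energies, combination.sites)
    hours = record.duration_s / 3600.0

    rows = []
    for thr in grid:
        _, counts, metrics = _detect_and_score(
            energies, prod, annotation, thr, hours, refractory_s,
            labeling_config)
        rows.append({
            "combination": str(combination),
            "group": combination.group,
            "threshold": thr,
            "sensitivity_pct": metrics.sensitivity_pct,
            "fp_per_h": metrics.fp_per_h,
            "n_tp": counts.n_tp_swd,
            "n_fp": counts.n_fp,
            "n_swd": counts.n_swd,
        })
    return pd.DataFrame(rows)


@dataclass
class CalibrationResult:
    threshold: float
    sensitivity_pct: float
    reached: bool


def calibrate_threshold(record: SignalRecord, annotation: SeizureAnnotation,
                        combination: SiteCombination,
                        target_sensitivity_pct: float = 60.0,
                        energies: BandEnergySeries | None = None,
                        refractory_s: float = 1.0,
                        labeling_config: _labeling.LabelingConfig | None = None,
                        max_iter: int = 60,
                        **energy_kwargs) -> CalibrationResult:
    """Find the largest threshold still reaching the target sensitivity.

    Sensitivity is a non-increasing step function of the threshold;
    bisection (on a log scale) converges to the boundary, returning the
    threshold whose achieved sensitivity is the smallest value >= target
    (ties resolve to the larger threshold).  If even the smallest probed
    threshold misses the target, that threshold is returned with
    ``reached=False`` and a warning.
    """
    if not (0 < target_sensitivity_pct <= 100):
        raise ValueError("target sensitivity must lie in (0, 100]")
    if len(annotation) < 5:
        raise ValueError("calibration requires at least 5 annotated SWDs")
    if energies is None:
        energies = band_energy_series(record, **energy_kwargs)
    labeling_config = labeling_config or _labeling.LabelingConfig()
    prod = channel_product(energies, combination.sites)
    hours = record.duration_s / 3600.0

    def sens(thr: float) -> float:
        _, _, m = _detect_and_score(energies, prod, annotation, thr, hours,
                                    refractory_s, labeling_config)
        return m.sensitivity_pct

    # Sensitivity is monotone non-increasing in the threshold only on the
    # upper branch: at thresholds far below the baseline product the mask
    # saturates and run merging collapses distinct detections.  Probe a
    # descending log grid from the maximum product, take the largest
    # threshold reaching the target, then sharpen by bisection within the
    # bracketing interval.
    p = prod.band("precursor")
    pos = p[p > 0]
    lo = float(pos.min()) / 2 if pos.size else 1e-12
    hi = float(p.max()) * 1.01 + 1e-12
    probes = np.exp(np.linspace(np.log(hi), np.log(max(lo, 1e-12)), 33))
    sens_probes = np.array([sens(t) for t in probes])

    if sens_probes[0] >= target_sensitivity_pct:
        return CalibrationResult(float(probes[0]), float(sens_probes[0]),
                                 reached=True)
    hits = np.flatnonzero(sens_probes >= target_sensitivity_pct)
    if hits.size == 0:
        best = int(np.argmax(sens_probes))
        warnings.warn(
            f"target sensitivity {target_sensitivity_pct}% unreachable; "
            f"best achievable is {sens_probes[best]:.1f}% at threshold "
            f"{probes[best]:.4g}")
        return CalibrationResult(float(probes[best]),
                                 float(sens_probes[best]), reached=False)
    k = int(hits[0])  # largest probe threshold reaching the target
    llo, lhi = np.log(probes[k]), np.log(probes[k - 1])
    for _ in range(max_iter):
        lmid = 0.5 * (llo + lhi)
        if sens(float(np.exp(lmid))) >= target_sensitivity_pct:
            llo = lmid
        else:
            lhi = lmid
        if lhi - llo < 1e-6:
            break
    thr = float(np.exp(llo))
    return CalibrationResult(thr, sens(thr), reached=True)
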
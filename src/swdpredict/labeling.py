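"""SWD onset marking and true/false-positive labeling of detections.

Onsets are marked by the amplitude rule used in visual SWD scoring: the
peak of the first spike reaching twice the amplitude of the background
EEG; across channels the earliest qualifying spike wins.  Detections are
labeled relative to a 1-s preictal window before each marked onset:
inside the window they are true positives, during the discharge itself
they are discarded (neither true nor false), anywhere else — interictal —
they are false positives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .signal_io import SeizureAnnotation, SignalRecord

__all__ = ["LabelingConfig", "LabelCounts", "mark_swd_onsets",
           "label_detections"]

TP = "TP"
FP = "FP"
ICTAL_DISCARD = "ICTAL_DISCARD"
UNLABELED = "UNLABELED"


@dataclass(frozen=True)
class LabelingConfig:
    """Conventions for onset marking and TP/FP assignment.

    preictal_window_s : detections within [onset - w, onset] are TPs
        (closed at the onset: zero-latency predictions count).
    background_window_s : artifact-free stretch before each coarse event
        over which background amplitude is estimated.
    background_stat : how background amplitude is summarized; only
        "p99_abs" (99th percentile of |signal|) is implemented.
    onset_multiplier : spike threshold as a multiple of background.
    postictal_discard_s : detections within this interval after the SWD
        offset are also discarded: the causal 0.5-s analysis window and
        the wavelet tails still see ictal signal there, so such alarms
        reflect the discharge itself, not interictal activity.
    """

    preictal_window_s: float = 1.0
    background_window_s: float = 10.0
    background_stat: str = "p99_abs"
    onset_multiplier: float = 2.0
    postictal_discard_s: float = 1.0

    def __post_init__(self) -> None:
        if self.preictal_window_s <= 0:
            raise ValueError("preictal window must be positive")
        if self.onset_multiplier <= 1:
            raise ValueError("onset multiplier must exceed 1")
        if self.background_stat != "p99_abs":
            raise ValueError(f"unknown background stat {self.background_stat!r}")


@dataclass
class LabelCounts:
    """Event-level outcome counts from :func:`label_detections`."""

    n_swd: int
    n_tp_swd: int        # SWDs with >= 1 detection in their preictal window
    n_missed: int
    n_fp: int
    n_tp_events: int     # detections labeled TP (may exceed n_tp_swd)
    n_discarded: int

    @property
    def n_events(self) -> int:
        return self.n_tp_events + self.n_fp + self.n_discarded


def mark_swd_onsets(record: SignalRecord,
                    coarse_events: list[tuple[float, float]],
                    config: LabelingConfig = LabelingConfig(),
                    ) -> SeizureAnnotation:
    """Refine coarse SWD intervals to precise onsets by the 2x-background
    first-spike rule.

    For each coarse event and channel, background amplitude is the 99th
    percentile of |signal| over ``background_window_s`` seconds preceding
    the event (shrunk, with a warning, if a previous event intrudes;
    an error below 1 s).  The onset candidate is the first local extremum
    inside the event whose absolute amplitude reaches
    ``onset_multiplier`` x background; the earliest candidate across
    channels becomes the onset.  Events with no qualifying spike are
    dropped with a warning.
    """
    fs = record.fs
    refined: list[tuple[float, float]] = []
    prev_off = -np.inf
    for start_s, end_s in sorted(coarse_events):
        if start_s < 0 or end_s > record.duration_s or start_s >= end_s:
            raise ValueError(f"coarse event ({start_s}, {end_s}) outside record")
        bg_start = start_s - config.background_window_s
        if bg_start < max(prev_off, 0.0):
            bg_start = max(prev_off, 0.0)
            if start_s - bg_start >= 1.0:
                warnings.warn("background window shrunk to avoid previous event")
        if start_s - bg_start < 1.0:
            raise ValueError("less than 1 s of background before event")
        b0, b1 = record.time_to_sample(bg_start), record.time_to_sample(start_s)
        e0, e1 = b1, record.time_to_sample(end_s)

        best: float | None = None
        for c in range(record.n_channels):
            bg = np.percentile(np.abs(record.data[c, b0:b1]), 99)
            seg = np.abs(record.data[c, e0:e1])
            peaks, _ = find_peaks(seg, height=config.onset_multiplier * bg)
            if peaks.size:
                t = (e0 + peaks[0]) / fs
                best = t if best is None else min(best, t)
        if best is None:
            warnings.warn(f"event at {start_s:.1f}s has no qualifying spike; dropped")
            continue
        refined.append((best, end_s))
        prev_off = end_s
    return SeizureAnnotation(events=refined)


def label_detections(events, annotation: SeizureAnnotation,
                     config: LabelingConfig = LabelingConfig(),
                     ):
    """Assign TP / FP / ICTAL_DISCARD labels to detection events in place.

    A detection at time t is a TP if t lies in [onset - w, onset] of any
    SWD, discarded if it falls inside the discharge or its immediate
    aftermath (onset, offset + postictal_discard_s], and a false positive
    otherwise (interictal).  An SWD counts as predicted if at least one
    TP falls in its preictal window.

    Returns ``(events, LabelCounts)``.
    """
    onsets = annotation.onsets()
    offsets = np.array([e[1] for e in annotation.events], dtype=float)
    w = config.preictal_window_s

    predicted = np.zeros(len(onsets), dtype=bool)
    n_fp = n_tp = n_disc = 0
    for ev in events:
        t = ev.t
        # candidate SWD: first with onset >= t could own the preictal window
        i = int(np.searchsorted(onsets, t))
        if i < len(onsets) and onsets[i] - w <= t <= onsets[i]:
            ev.label = TP
            predicted[i] = True
            n_tp += 1
        elif i > 0 and onsets[i - 1] < t <= offsets[i - 1] + config.postictal_discard_s:
            ev.label = ICTAL_DISCARD
            n_disc += 1
        else:
            ev.label = FP
            n_fp += 1

    counts = LabelCounts(
        n_swd=len(onsets),
        n_tp_swd=int(predicted.sum()),
        n_missed=int((~predicted).sum()),
        n_fp=n_fp,
        n_tp_events=n_tp,
        n_discarded=n_disc,
    )
    return events, counts
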
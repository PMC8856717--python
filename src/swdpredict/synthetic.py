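"""Synthetic multichannel LFP recordings with annotated spike-and-wave
discharges (SWDs).

The generator emulates the statistical structure of chronic recordings in
genetic absence-epilepsy rat strains:

* GAERS-like records: ~17 SWDs/h of 10-30 s at 5-7 Hz, with a 24-h
  sinusoidal (diurnal) rate modulation peaking at dark-phase onset.
* WAG/Rij-like records: ~10 SWDs/h of ~7 s at 8-10 Hz.
* 1/f^alpha Gaussian background per channel.
* Each SWD is a harmonic-rich spike-wave train (narrow Gaussian spike plus
  opposing half-sine wave per cycle).  The spike peak is scaled to twice
  the 99th percentile of the channel's absolute background amplitude, so
  the onset-marking rule ("first spike at twice background") is exactly
  satisfiable.  Thalamus-like channels get smaller, broader spikes with
  reversed polarity.
* A 5-10 Hz precursor burst starts 0.3-0.9 s before every SWD onset,
  scaled per channel role: channels near the cortical initiation site
  ("precursor_strong") carry it at full amplitude, thalamic channels
  ("precursor_weak") attenuated, and "precursor_none" channels not at all.
* Confounders are injected outside seizures: arousal-theta bursts
  (5-9 Hz, the dominant source of precursor-like false alarms), sleep
  spindles (8-16 Hz bursts) and slow-wave-sleep epochs (3-5 Hz
  oscillation).

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .signal_io import SeizureAnnotation, SignalRecord

__all__ = [
    "ChannelSpec", "SyntheticSpec", "sample_seizure_times",
    "generate_recording", "gaers_spec", "wagrij_spec", "benchmark_spec",
]

#: Reference cortical spike amplitude (uV); per-channel spike amplitudes
#: scale relative to this so that cortex ~700 uV implies thalamus ~500 uV.
CORTICAL_SPIKE_UV = 700.0

ROLES = ("precursor_strong", "precursor_weak", "precursor_none")

#: Precursor burst amplitude per role, in units of the background SD.
ROLE_PRECURSOR_AMP = {
    "precursor_strong": 1.0,
    "precursor_weak": 0.3,
    "precursor_none": 0.0,
}


@dataclass(frozen=True)
class ChannelSpec:
    """One synthetic channel: recording site, precursor role, SWD shape."""

    site: str
    role: str = "precursor_strong"
    polarity: int = 1                    # -1 for reversed (thalamic) spikes
    spike_amp_uv: float = CORTICAL_SPIKE_UV
    spike_width_s: float = 0.010         # Gaussian sigma; broader in thalamus
    confounder_gain: float = 1.0         # spindles/theta/SWS expression;
                                         # thalamic sites express sleep
                                         # oscillations more strongly

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown channel role {self.role!r}")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")


def _cortical(site: str) -> ChannelSpec:
    return ChannelSpec(site=site)


def _thalamic(site: str, role: str = "precursor_weak") -> ChannelSpec:
    return ChannelSpec(site=site, role=role, polarity=-1,
                       spike_amp_uv=500.0, spike_width_s=0.020,
                       confounder_gain=1.5)


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic recording.

    Defaults describe a GAERS-like animal recorded in the three deep S1
    layers.  Rates are per hour; amplitudes in uV unless stated.
    """

    fs: float = 500.0
    duration_s: float = 3600.0
    channels: tuple[ChannelSpec, ...] = (
        _cortical("S1_L4"), _cortical("S1_L5"), _cortical("S1_L6"),
    )
    base_swd_rate_per_h: float = 17.0
    diurnal_mod_amplitude: float = 0.5   # relative, in [0, 1)
    diurnal_phase_h: float = 12.0        # hour of peak rate (dark onset)
    swd_freq_hz: tuple[float, float] = (5.0, 7.0)
    swd_duration_s: tuple[float, float] = (10.0, 30.0)
    background_sigma_uv: float = 150.0
    one_over_f_exponent: float = 1.0
    precursor_lead_s: tuple[float, float] = (0.3, 0.9)
    precursor_freq_hz: tuple[float, float] = (5.0, 10.0)
    theta_rate_per_h: float = 480.0
    theta_freq_hz: tuple[float, float] = (5.0, 9.0)
    theta_duration_s: tuple[float, float] = (0.3, 1.5)
    theta_amp_sd: tuple[float, float] = (0.4, 1.0)
    spindle_rate_per_h: float = 60.0
    spindle_freq_hz: tuple[float, float] = (8.0, 16.0)
    spindle_duration_s: tuple[float, float] = (0.5, 1.5)
    spindle_amp_sd: float = 1.0          # x background SD
    sws_epoch_rate_per_h: float = 10.0
    sws_epoch_duration_s: tuple[float, float] = (30.0, 120.0)
    sws_freq_hz: tuple[float, float] = (3.0, 5.0)
    sws_amp_sd: float = 0.8              # x background SD
    onset_multiplier: float = 2.0        # spike peak vs p99 |background|
    min_gap_s: float = 5.0               # between consecutive SWDs
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("fs and duration_s must be positive")
        for r in (self.base_swd_rate_per_h, self.spindle_rate_per_h,
                  self.sws_epoch_rate_per_h):
            if r < 0:
                raise ValueError("rates must be non-negative")
        if not (0 <= self.diurnal_mod_amplitude < 1):
            raise ValueError("diurnal modulation amplitude must be in [0, 1)")
        lo, hi = self.precursor_lead_s
        if not (0 < lo <= hi <= 5.0):
            raise ValueError("precursor lead range must lie within (0, 5] s")

    @property
    def sites(self) -> list[str]:
        return [c.site for c in self.channels]


def gaers_spec(duration_s: float = 3600.0, fs: float = 500.0,
               **overrides) -> SyntheticSpec:
    """GAERS-like spec: deep-S1 triple, 17 SWD/h, 5-7 Hz, 10-30 s."""
    return SyntheticSpec(fs=fs, duration_s=duration_s, **overrides)


def wagrij_spec(duration_s: float = 3600.0, fs: float = 500.0,
                **overrides) -> SyntheticSpec:
    """WAG/Rij-like spec: ~10 SWD/h, ~7 s events at 8-10 Hz, no diurnal
    modulation (short dark-phase recordings)."""
    defaults = dict(
        base_swd_rate_per_h=10.0, swd_freq_hz=(8.0, 10.0),
        swd_duration_s=(5.0, 9.0), diurnal_mod_amplitude=0.0,
    )
    defaults.update(overrides)
    return SyntheticSpec(fs=fs, duration_s=duration_s, **defaults)


def benchmark_spec(duration_s: float = 7200.0, fs: float = 500.0,
                   include_m2: bool = False, **overrides) -> SyntheticSpec:
    """Eight-site cortico-thalamic spec for site-combination sweeps.

    S1 layers carry the precursor at full strength, thalamic nuclei at
    reduced strength with reversed, broader spikes; optional M2 channels
    carry no precursor.
    """
    channels = [
        _cortical("S1_L4"), _cortical("S1_L5"), _cortical("S1_L6"),
        _thalamic("VPM"), _thalamic("Po"), _thalamic("ATN"),
        _thalamic("rRTN"), _thalamic("cRTN"),
    ]
    if include_m2:
        channels += [ChannelSpec(site=s, role="precursor_none")
                     for s in ("M2_5a", "M2_5b", "M2_6")]
    return SyntheticSpec(fs=fs, duration_s=duration_s,
                         channels=tuple(channels), **overrides)


# ---------------------------------------------------------------------------
# Seizure timing
# ---------------------------------------------------------------------------

def _rate_per_s(spec: SyntheticSpec, t: np.ndarray) -> np.ndarray:
    """Inhomogeneous Poisson rate lambda(t) in events/s."""
    base = spec.base_swd_rate_per_h / 3600.0
    m = spec.diurnal_mod_amplitude
    phase = spec.diurnal_phase_h * 3600.0
    return base * (1.0 + m * np.cos(2 * np.pi * (t - phase) / 86400.0))


def sample_seizure_times(spec: SyntheticSpec,
                         rng_seed: int | np.random.Generator,
                         ) -> list[tuple[float, float]]:
    """Draw non-overlapping SWD (onset_s, offset_s) intervals.

    Counts follow an inhomogeneous Poisson process with a 24-h cosine rate
    modulation; durations are uniform over ``swd_duration_s``.  Each event
    is placed by rejection against already-placed events (minimum
    ``min_gap_s`` separation); after 1000 failed placements the remaining
    events are dropped.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    base = spec.base_swd_rate_per_h / 3600.0
    if base == 0:
        return []
    lam_max = base * (1.0 + spec.diurnal_mod_amplitude)
    # expected total count from the integrated rate (cosine integrates out
    # only over full days; integrate numerically for arbitrary durations)
    tgrid = np.linspace(0, spec.duration_s, 4097)
    n_target = rng.poisson(np.trapezoid(_rate_per_s(spec, tgrid), tgrid))

    placed: list[tuple[float, float]] = []
    rejections = 0
    for _ in range(n_target):
        while True:
            t = rng.uniform(0, spec.duration_s)
            # thinning for the diurnal profile
            if rng.uniform(0, lam_max) > _rate_per_s(spec, np.array([t]))[0]:
                continue
            dur = rng.uniform(*spec.swd_duration_s)
            if t + dur > spec.duration_s:
                rejections += 1
            elif any(t < off + spec.min_gap_s and on - spec.min_gap_s < t + dur
                     for on, off in placed):
                rejections += 1
            else:
                placed.append((t, t + dur))
                break
            if rejections >= 1000:
                warnings.warn("seizure placement saturated; truncating list")
                placed.sort()
                return placed
    placed.sort()
    return placed


# ---------------------------------------------------------------------------
# Waveform synthesis
# ---------------------------------------------------------------------------

def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float,
                      sigma: float, alpha: float) -> np.ndarray:
    """Gaussian noise with a 1/f^alpha amplitude spectrum, unit-free SD
    ``sigma``; spectrum flattened below 0.5 Hz to bound slow drift."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.maximum(f, 0.5) ** (-alpha / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n)
    sd = x.std()
    return x * (sigma / sd) if sd > 0 else x


def _spike_wave_train(t_rel: np.ndarray, freq: float, amp: float,
                      spike_sigma: float) -> np.ndarray:
    """Spike-wave cycle train on relative time >= 0: a narrow Gaussian
    spike at every 1/freq, an opposing half-sine wave between spikes.
    Spike peaks sit exactly at t_rel = k / freq."""
    phase = t_rel * freq
    p = phase - np.round(phase)             # in [-0.5, 0.5), 0 at spike peak
    d = p / freq                            # seconds from nearest spike
    spike = np.exp(-0.5 * (d / spike_sigma) ** 2)
    frac = phase - np.floor(phase)          # position within the cycle
    wave = -0.4 * np.sin(np.pi * frac) ** 2
    return amp * (spike + wave)


def _burst_envelope(n: int) -> np.ndarray:
    """Tapered burst envelope: flat at full amplitude with 12.5% cosine
    ramps at each end (Tukey), so the stated burst amplitude is actually
    sustained rather than reached only momentarily."""
    from scipy.signal.windows import tukey
    return tukey(max(n, 3), alpha=0.25)[:n]


def _place_outside(rng: np.random.Generator, duration: float, length: float,
                   blocked: list[tuple[float, float]], margin: float = 2.0,
                   tries: int = 100) -> float | None:
    """Uniform start time for a burst of `length` avoiding blocked
    intervals (with margin); None if no placement found."""
    for _ in range(tries):
        t = rng.uniform(0, max(duration - length, 1e-9))
        if all(t + length < on - margin or t > off + margin
               for on, off in blocked):
            return t
    return None


def generate_recording(spec: SyntheticSpec,
                       rng_seed: int) -> tuple[SignalRecord, SeizureAnnotation]:
    """Synthesize an annotated multichannel recording.

    Returns a :class:`SignalRecord` plus a :class:`SeizureAnnotation`
    whose onsets mark the exact sample of the first spike peak of each
    injected SWD.  Bit-reproducible for a given (spec, rng_seed).
    """
    rng = np.random.default_rng(rng_seed)
    fs = spec.fs
    n = int(round(spec.duration_s * fs))
    nch = len(spec.channels)

    data = np.empty((nch, n))
    p99 = np.empty(nch)
    for c in range(nch):
        data[c] = _one_over_f_noise(rng, n, fs, spec.background_sigma_uv,
                                    spec.one_over_f_exponent)
        p99[c] = np.percentile(np.abs(data[c]), 99)

    seizures = sample_seizure_times(spec, rng)
    tgrid = np.arange(n) / fs
    sigma = spec.background_sigma_uv

    events: list[tuple[float, float]] = []
    for on, off in seizures:
        i0 = int(np.floor(on * fs + 0.5))
        on_snap = i0 / fs                       # first spike peak on-grid
        freq = rng.uniform(*spec.swd_freq_hz)
        i1 = min(int(np.floor(off * fs + 0.5)), n)
        seg = np.arange(i0, i1)
        t_rel = seg / fs - on_snap
        for c, ch in enumerate(spec.channels):
            amp = (spec.onset_multiplier * p99[c]
                   * ch.spike_amp_uv / CORTICAL_SPIKE_UV)
            data[c, seg] += ch.polarity * _spike_wave_train(
                t_rel, freq, amp, ch.spike_width_s)

        lead = rng.uniform(*spec.precursor_lead_s)
        pf = rng.uniform(*spec.precursor_freq_hz)
        j0 = max(int(np.floor((on_snap - lead) * fs + 0.5)), 0)
        pseg = np.arange(j0, i0)
        if pseg.size:
            burst = np.sin(2 * np.pi * pf * (pseg / fs)) * _burst_envelope(pseg.size)
            for c, ch in enumerate(spec.channels):
                a = ROLE_PRECURSOR_AMP[ch.role] * sigma
                data[c, pseg] += ch.polarity * a * burst
        events.append((on_snap, i1 / fs))

    cgain = np.array([ch.confounder_gain for ch in spec.channels])

    # arousal-theta confounders: brief 5-9 Hz bursts during active
    # wakefulness, the main source of precursor-like false alarms.
    # Rodent theta is sawtooth-like, so a strong second harmonic
    # (10-18 Hz, i.e. inside the spindle band) is included — this is what
    # spectrally distinguishes these false alarms from the near-sinusoidal
    # preictal precursor.  Global across channels, placed clear of
    # seizures and preictal windows.
    n_theta = rng.poisson(spec.theta_rate_per_h * spec.duration_s / 3600.0)
    for _ in range(n_theta):
        dur = rng.uniform(*spec.theta_duration_s)
        t0 = _place_outside(rng, spec.duration_s, dur, events)
        f0 = rng.uniform(*spec.theta_freq_hz)
        amp = rng.uniform(*spec.theta_amp_sd) * sigma
        if t0 is None:
            continue
        k0 = int(round(t0 * fs))
        k1 = min(k0 + int(round(dur * fs)), n)
        seg = np.arange(k0, k1)
        ph = 2 * np.pi * f0 * (seg / fs)
        burst = amp * (np.sin(ph) + 1.0 * np.sin(2 * ph)) * _burst_envelope(seg.size)
        # volume-conducted theta reaches the electrodes unevenly, unlike
        # the locally generated S1 precursor
        gains = cgain * rng.uniform(0.6, 1.0, size=nch)
        data[:, seg] += gains[:, None] * burst[None, :]

    # spindle confounders, global across channels, outside seizures
    n_spindles = rng.poisson(spec.spindle_rate_per_h * spec.duration_s / 3600.0)
    for _ in range(n_spindles):
        dur = rng.uniform(*spec.spindle_duration_s)
        t0 = _place_outside(rng, spec.duration_s, dur, events)
        f0 = rng.uniform(*spec.spindle_freq_hz)
        if t0 is None:
            continue
        k0 = int(round(t0 * fs))
        k1 = min(k0 + int(round(dur * fs)), n)
        seg = np.arange(k0, k1)
        burst = (spec.spindle_amp_sd * sigma
                 * np.sin(2 * np.pi * f0 * (seg / fs)) * _burst_envelope(seg.size))
        data[:, seg] += cgain[:, None] * burst[None, :]

    # slow-wave-sleep epochs with a 3-5 Hz oscillation, outside seizures
    n_sws = rng.poisson(spec.sws_epoch_rate_per_h * spec.duration_s / 3600.0)
    for _ in range(n_sws):
        dur = rng.uniform(*spec.sws_epoch_duration_s)
        t0 = _place_outside(rng, spec.duration_s, dur, events)
        f0 = rng.uniform(*spec.sws_freq_hz)
        if t0 is None:
            continue
        k0 = int(round(t0 * fs))
        k1 = min(k0 + int(round(dur * fs)), n)
        seg = np.arange(k0, k1)
        osc = (spec.sws_amp_sd * sigma
               * np.sin(2 * np.pi * f0 * (seg / fs)) * _burst_envelope(seg.size))
        data[:, seg] += cgain[:, None] * osc[None, :]

    record = SignalRecord(data=data, fs=fs, channel_sites=spec.sites,
                          strain_tag="SYNTHETIC")
    annotation = SeizureAnnotation(events=events)
    return record, annotation
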
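"""Sliding-window wavelet band energies and their cross-channel products.

The precursor detector works on three band energies per channel — 5-10 Hz
(SWD precursor), 3-5 Hz (light slow-wave sleep) and 7-20 Hz (sleep
spindles) — each the mean magnitude-squared of a complex-Morlet continuous
wavelet transform over a 500-ms causal window sliding along the trace.
Cross-channel synchrony is summarized by the per-band product of these
energies over two or three recording sites.

The CWT is evaluated in the Fourier domain: one FFT per channel, then one
inverse FFT per analysis frequency against an analytic Gaussian kernel.
This keeps memory flat in the number of frequencies and makes 24-h records
tractable on a single core.  ``pywt``'s cmor wavelet is used as an
independent cross-check in the test suite, not as the computation path.

Band energies are normalized per channel and band by the whole-recording
median, then multiplied by ``norm_scale``.  The median division makes the
series dimensionless and transferable across recording amplitudes; the
scale (default 0.25) places baseline two- and three-channel products below
the standard detection-threshold grids so that the threshold criterion is
operative (see docs/methods.md for the calibration rationale).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import fft as sfft

from .signal_io import SignalRecord

__all__ = [
    "BandDef", "DEFAULT_BANDS", "BandEnergySeries", "ProductSeries",
    "wavelet_spectrum", "band_energy_series", "channel_product",
    "DEFAULT_MORLET_OMEGA0", "DEFAULT_NORM_SCALE",
]

#: Morlet dimensionless center frequency (time-bandwidth parameter).
DEFAULT_MORLET_OMEGA0 = 2.0 * np.pi

#: Scale applied after median normalization (see module docstring).
DEFAULT_NORM_SCALE = 0.25

#: Spacing of the within-band frequency grid (Hz).
DEFAULT_FREQ_STEP = 0.5

#: Reflection padding applied before the CWT to soften edge effects (s).
EDGE_PAD_S = 2.0


@dataclass(frozen=True)
class BandDef:
    """A named frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(f"need 0 < f_lo < f_hi, got {self}")

    def freqs(self, step: float = DEFAULT_FREQ_STEP) -> np.ndarray:
        return np.arange(self.f_lo, self.f_hi + step / 2, step)


DEFAULT_BANDS: tuple[BandDef, ...] = (
    BandDef("precursor", 5.0, 10.0),
    BandDef("sws", 3.0, 5.0),
    BandDef("spindle", 7.0, 20.0),
)


@dataclass
class BandEnergySeries:
    """Normalized sliding-window wavelet band energies W[band, channel, t].

    ``times`` are the right edges (in seconds) of causal windows
    [t - window_s, t]; the first time is at least ``window_s``.
    """

    times: np.ndarray
    values: np.ndarray  # (n_bands, n_channels, n_times), >= 0
    bands: tuple[BandDef, ...]
    channel_sites: list[str]
    window_s: float
    stride_s: float
    normalization: str = "per-channel median"
    norm_scale: float = DEFAULT_NORM_SCALE

    def band_index(self, name: str) -> int:
        for i, b in enumerate(self.bands):
            if b.name == name:
                return i
        raise KeyError(f"no band named {name!r}")

    def channel_index(self, site_or_index) -> int:
        if isinstance(site_or_index, (int, np.integer)):
            return int(site_or_index)
        return self.channel_sites.index(site_or_index)

    def to_frame(self) -> pd.DataFrame:
        """Long-form (time, band, channel, value) table."""
        nb, nc, nt = self.values.shape
        rows = {
            "time_s": np.tile(self.times, nb * nc),
            "band": np.repeat([b.name for b in self.bands], nc * nt),
            "channel": np.tile(np.repeat(self.channel_sites, nt), nb),
            "value": self.values.reshape(-1),
        }
        return pd.DataFrame(rows)

    def save_npz(self, path) -> None:
        np.savez(
            path, times=self.times, values=self.values,
            band_names=np.array([b.name for b in self.bands]),
            band_lo=np.array([b.f_lo for b in self.bands]),
            band_hi=np.array([b.f_hi for b in self.bands]),
            channel_sites=np.array(self.channel_sites),
            window_s=self.window_s, stride_s=self.stride_s,
            norm_scale=self.norm_scale,
        )


@dataclass
class ProductSeries:
    """Per-band product of band energies over a 2- or 3-channel subset."""

    times: np.ndarray
    values: np.ndarray  # (n_bands, n_times)
    bands: tuple[BandDef, ...]
    channels: tuple[str, ...]

    def band(self, name: str) -> np.ndarray:
        for i, b in enumerate(self.bands):
            if b.name == name:
                return self.values[i]
        raise KeyError(f"no band named {name!r}")


# ---------------------------------------------------------------------------
# Morlet CWT (Fourier-domain)
# ---------------------------------------------------------------------------

def _morlet_kernel(freq_axis: np.ndarray, f0: float, omega0: float) -> np.ndarray:
    """Frequency response of an analytic Morlet atom centered at f0.

    Gaussian with sigma_f = f0 / omega0, unit peak gain, zero on the
    negative-frequency half — so a unit cosine at f0 yields |coef| = 1/2
    independent of frequency (linear in amplitude, |coef|^2 linear in
    power).
    """
    sigma_f = f0 / omega0
    h = np.exp(-0.5 * ((freq_axis - f0) / sigma_f) ** 2)
    h[freq_axis <= 0] = 0.0
    return h


def _padded_fft(x: np.ndarray, fs: float):
    """Reflection-pad by EDGE_PAD_S and return (X, freq_axis, pad, nfft)."""
    n = x.size
    pad = min(int(round(EDGE_PAD_S * fs)), n - 1)
    xp = np.concatenate([x[pad:0:-1], x, x[-2:-pad - 2:-1]]) if pad else x
    nfft = sfft.next_fast_len(xp.size)
    X = sfft.fft(xp, n=nfft)
    freq_axis = sfft.fftfreq(nfft, d=1.0 / fs)
    return X, freq_axis, pad, nfft


def wavelet_spectrum(record: SignalRecord, channel: int,
                     freqs: Sequence[float],
                     morlet_omega0: float = DEFAULT_MORLET_OMEGA0) -> np.ndarray:
    """Magnitude-squared Morlet CWT of one channel.

    Returns an (n_freqs, n_samples) array of |CWT|^2.  Scaling the input
    by a scales the output by a^2.
    """
    freqs = np.asarray(list(freqs), dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency list")
    nyq = record.fs / 2
    if np.any(freqs <= 0) or np.any(freqs >= nyq):
        raise ValueError(f"frequencies must lie in (0, {nyq}) Hz")
    x = record.data[channel]
    X, fax, pad, _ = _padded_fft(x, record.fs)
    out = np.empty((freqs.size, x.size))
    for i, f0 in enumerate(freqs):
        coef = sfft.ifft(X * _morlet_kernel(fax, f0, morlet_omega0))
        out[i] = np.abs(coef[pad:pad + x.size]) ** 2
    return out


def _causal_window_mean(e: np.ndarray, win: int) -> np.ndarray:
    """Mean over the causal window [i - win + 1, i] for i >= win - 1."""
    cs = np.concatenate([[0.0], np.cumsum(e)])
    return (cs[win:] - cs[:-win]) / win


def band_energy_series(record: SignalRecord,
                       bands: Sequence[BandDef] = DEFAULT_BANDS,
                       window_s: float = 0.5,
                       stride_s: float | None = None,
                       morlet_omega0: float = DEFAULT_MORLET_OMEGA0,
                       freq_step: float = DEFAULT_FREQ_STEP,
                       norm_scale: float = DEFAULT_NORM_SCALE) -> BandEnergySeries:
    """Compute W[band, channel, t]: windowed, median-normalized CWT energy.

    For each channel and band, |CWT|^2 is averaged over the band's
    frequency grid and over a causal ``window_s`` window ending at t, then
    divided by the whole-recording median of that windowed series (computed
    at full sample resolution, so values at shared timestamps are invariant
    to ``stride_s``) and multiplied by ``norm_scale``.

    ``stride_s`` defaults to one sample.
    """
    fs = record.fs
    win = int(round(window_s * fs))
    if win < 2:
        raise ValueError("window must span at least 2 samples")
    if record.n_samples < win:
        raise ValueError("recording shorter than the analysis window")
    stride_s = stride_s if stride_s is not None else 1.0 / fs
    stride_n = max(1, int(round(stride_s * fs)))

    bands = tuple(bands)
    for b in bands:
        if b.f_hi >= fs / 2:
            raise ValueError(f"band {b.name} exceeds Nyquist ({fs / 2} Hz)")

    n = record.n_samples
    # index i holds the window [i - win + 1, i]; keep times >= window_s
    idx = np.arange(win, n, stride_n)
    times = (idx + 1) / fs  # right edge of the causal window, in seconds
    values = np.empty((len(bands), record.n_channels, idx.size))

    for c in range(record.n_channels):
        X, fax, pad, _ = _padded_fft(record.data[c], fs)
        for bi, band in enumerate(bands):
            acc = np.zeros(n)
            fgrid = band.freqs(freq_step)
            for f0 in fgrid:
                coef = sfft.ifft(X * _morlet_kernel(fax, f0, morlet_omega0))
                acc += np.abs(coef[pad:pad + n]) ** 2
            acc /= fgrid.size
            wm = _causal_window_mean(acc, win)  # length n - win + 1
            med = float(np.median(wm))
            if med <= 0:
                raise ValueError(
                    f"degenerate signal: zero median band energy in channel "
                    f"{record.channel_sites[c]}, band {band.name}"
                )
            values[bi, c] = norm_scale * wm[idx - (win - 1)] / med

    return BandEnergySeries(
        times=times, values=values, bands=bands,
        channel_sites=list(record.channel_sites),
        window_s=window_s, stride_s=stride_n / fs,
        normalization="per-channel median x norm_scale",
        norm_scale=norm_scale,
    )


def channel_product(series: BandEnergySeries,
                    channels: Sequence) -> ProductSeries:
    """Per-band elementwise product of W over a 2- or 3-channel subset.

    ``channels`` may be site labels or integer indices.
    """
    if len(channels) not in (2, 3):
        raise ValueError("product is defined over 2 or 3 channels")
    idx = [series.channel_index(c) for c in channels]
    sites = tuple(series.channel_sites[i] for i in idx)
    values = np.prod(series.values[:, idx, :], axis=1)
    return ProductSeries(times=series.times, values=values,
                         bands=series.bands, channels=sites)
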
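"""Reading, writing and preprocessing of multichannel LFP recordings.

Recordings are held in :class:`SignalRecord`: a channels-by-samples array of
amplitudes in microvolts, a sampling rate, and one recording-site label per
channel drawn from the cortico-thalamic vocabulary used throughout the
package (deep S1 layers, thalamic nuclei, M2 layers).  Three on-disk formats
are supported: plain EDF (16-bit), CSV with site labels as header, and NPZ.
Seizure annotations travel in a sidecar CSV with one (onset_s, offset_s) row
per spike-and-wave discharge.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

#: Recording-site vocabulary.  S1 layers are cortical ("C"), the five
#: thalamic nuclei are "T", M2 layers are "M"; anything else is OTHER.
S1_SITES = ("S1_L4", "S1_L5", "S1_L6")
THALAMIC_SITES = ("VPM", "Po", "ATN", "rRTN", "cRTN")
M2_SITES = ("M2_5a", "M2_5b", "M2_6")
SITE_VOCABULARY = S1_SITES + THALAMIC_SITES + M2_SITES + ("OTHER",)

#: Default mapping from common EDF channel-label fragments to site labels.
DEFAULT_EDF_SITE_MAP = {
    "ctx4": "S1_L4", "ctx5": "S1_L5", "ctx6": "S1_L6",
    "s1_l4": "S1_L4", "s1_l5": "S1_L5", "s1_l6": "S1_L6",
    "vpm": "VPM", "po": "Po", "atn": "ATN",
    "rrtn": "rRTN", "crtn": "cRTN",
    "m2_5a": "M2_5a", "m2_5b": "M2_5b", "m2_6": "M2_6",
    "mctx5a": "M2_5a", "mctx5b": "M2_5b", "mctx6": "M2_6",
}


def site_class(site: str) -> str:
    """Return 'C' for S1, 'T' for thalamus, 'M' for M2, 'O' otherwise."""
    if site in S1_SITES:
        return "C"
    if site in THALAMIC_SITES:
        return "T"
    if site in M2_SITES:
        return "M"
    return "O"


@dataclass
class SignalRecord:
    """A multichannel LFP recording in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Amplitudes in uV.
    fs : float
        Sampling rate in Hz.
    channel_sites : list of str
        One site label per channel; labels outside the vocabulary raise.
    start_time : float
        Offset of the first sample in seconds (default 0).
    strain_tag : str
        One of {"GAERS", "WAGRij", "SYNTHETIC"}.
    """

    data: np.ndarray
    fs: float
    channel_sites: list[str]
    start_time: float = 0.0
    strain_tag: str = "SYNTHETIC"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_sites) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_sites)} site labels for "
                f"{self.data.shape[0]} channels"
            )
        for s in self.channel_sites:
            if s not in SITE_VOCABULARY:
                raise ValueError(f"unknown recording site {s!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("signal contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, site: str) -> int:
        """Index of the first channel recorded at `site`."""
        return self.channel_sites.index(site)

    def time_to_sample(self, t: float) -> int:
        """Convert seconds (from record start) to the nearest sample index,
        rounding half away from zero."""
        return int(np.floor((t - self.start_time) * self.fs + 0.5))


@dataclass
class SeizureAnnotation:
    """Sorted, non-overlapping (onset_s, offset_s) SWD intervals.

    Onsets follow the convention of marking the peak of the first spike
    whose amplitude reaches twice the background EEG amplitude.
    """

    events: list[tuple[float, float]] = field(default_factory=list)
    onset_convention: str = "first_spike_peak_2x_background"

    def __post_init__(self) -> None:
        self.events = [(float(a), float(b)) for a, b in self.events]
        prev_off = -np.inf
        for on, off in self.events:
            if on >= off:
                raise ValueError(f"onset {on} not before offset {off}")
            if on < prev_off:
                raise ValueError("annotation events overlap or are unsorted")
            prev_off = off

    def __len__(self) -> int:
        return len(self.events)

    def onsets(self) -> np.ndarray:
        return np.array([e[0] for e in self.events], dtype=float)


# ---------------------------------------------------------------------------
# Annotation sidecar CSV
# ---------------------------------------------------------------------------

def write_annotation(annotation: SeizureAnnotation, path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["onset_s", "offset_s"])
        for on, off in annotation.events:
            w.writerow([f"{on:.6f}", f"{off:.6f}"])
    return path


def read_annotation(path) -> SeizureAnnotation:
    events = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            events.append((float(row["onset_s"]), float(row["offset_s"])))
    return SeizureAnnotation(events=events)


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------

#: EDF physical range used when writing (uV); defines the 16-bit
#: quantization step (2 * EDF_PHYS_RANGE_UV / 65535).
EDF_PHYS_RANGE_UV = 5000.0


def write_recording(record: SignalRecord, path, format: str | None = None) -> Path:
    """Write a recording as EDF, CSV or NPZ.

    The format is inferred from the file suffix when not given.  EDF files
    are plain EDF (not EDF+) with physical dimension uV and a symmetric
    physical range of +/-5000 uV; amplitudes are clipped to that range and
    quantized to 16 bits.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        header = ",".join(record.channel_sites)
        np.savetxt(path, record.data.T, delimiter=",", header=header, comments="")
    elif fmt == "npz":
        np.savez(
            path,
            data=record.data,
            fs=record.fs,
            channel_sites=np.array(record.channel_sites),
            start_time=record.start_time,
            strain_tag=record.strain_tag,
        )
    elif fmt == "edf":
        _write_edf(record, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_recording(path, format: str | None = None,
                   site_map: dict | None = None,
                   fs: float | None = None,
                   strain_tag: str = "SYNTHETIC") -> SignalRecord:
    """Read an EDF, CSV or NPZ recording into a :class:`SignalRecord`.

    EDF channel labels are mapped to the site vocabulary through `site_map`
    (default :data:`DEFAULT_EDF_SITE_MAP`, matched case-insensitively);
    unmapped channels are tagged OTHER.  CSV files carry the site labels in
    their header and need `fs` supplied.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        if fs is None:
            raise ValueError("reading CSV requires the sampling rate `fs`")
        with open(path) as fh:
            header = fh.readline().strip()
        sites = [s.strip() for s in header.split(",")]
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return SignalRecord(data=data.T, fs=fs, channel_sites=sites,
                            strain_tag=strain_tag)
    if fmt == "npz":
        with np.load(path, allow_pickle=False) as z:
            return SignalRecord(
                data=z["data"],
                fs=float(z["fs"]),
                channel_sites=[str(s) for s in z["channel_sites"]],
                start_time=float(z["start_time"]),
                strain_tag=str(z["strain_tag"]),
            )
    if fmt == "edf":
        return _read_edf(path, site_map=site_map, strain_tag=strain_tag)
    raise ValueError(f"unknown format {fmt!r}")


def _map_label(label: str, site_map: dict) -> str:
    key = label.strip().lower().replace(" ", "").replace("-", "_")
    if label in SITE_VOCABULARY:
        return label
    for frag, site in site_map.items():
        if key == frag.lower():
            return site
    return "OTHER"


def _read_edf(path: Path, site_map: dict | None, strain_tag: str) -> SignalRecord:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_v = raw.get_data()  # mne returns volts for eeg-typed channels
    site_map = site_map if site_map is not None else DEFAULT_EDF_SITE_MAP
    sites = [_map_label(ch, site_map) for ch in raw.ch_names]
    return SignalRecord(data=data_v * 1e6, fs=float(raw.info["sfreq"]),
                        channel_sites=sites, strain_tag=strain_tag)


def _write_edf(record: SignalRecord, path: Path) -> None:
    """Minimal plain-EDF writer: one data record per second, int16 samples,
    physical dimension uV over +/-EDF_PHYS_RANGE_UV."""
    fs = record.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writing requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s data record
    n_records = record.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    nch = record.n_channels
    pmin, pmax = -EDF_PHYS_RANGE_UV, EDF_PHYS_RANGE_UV
    dmin, dmax = -32768, 32767

    def pad(text: str, n: int) -> bytes:
        b = text.encode("ascii")[:n]
        return b + b" " * (n - len(b))

    header = b"".join([
        pad("0", 8),                       # version
        pad("X X X X", 80),                # patient id (anonymous)
        pad("Startdate X X X X", 80),      # recording id
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (nch + 1)), 8),      # header bytes
        pad("", 44),                       # reserved ("" => plain EDF)
        pad(str(n_records), 8),
        pad("1", 8),                       # record duration (s)
        pad(str(nch), 4),
    ])
    labels = b"".join(pad(s, 16) for s in record.channel_sites)
    transducer = b"".join(pad("", 80) for _ in range(nch))
    phys_dim = b"".join(pad("uV", 8) for _ in range(nch))
    phys_min = b"".join(pad(f"{pmin:g}", 8) for _ in range(nch))
    phys_max = b"".join(pad(f"{pmax:g}", 8) for _ in range(nch))
    dig_min = b"".join(pad(str(dmin), 8) for _ in range(nch))
    dig_max = b"".join(pad(str(dmax), 8) for _ in range(nch))
    prefilter = b"".join(pad("", 80) for _ in range(nch))
    n_samp = b"".join(pad(str(spr), 8) for _ in range(nch))
    reserved = b"".join(pad("", 32) for _ in range(nch))

    gain = (dmax - dmin) / (pmax - pmin)
    clipped = np.clip(record.data[:, : n_records * spr], pmin, pmax)
    digital = np.round((clipped - pmin) * gain + dmin).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header + labels + transducer + phys_dim + phys_min +
                 phys_max + dig_min + dig_max + prefilter + n_samp + reserved)
        for r in range(n_records):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())


def edf_quantization_step_uv() -> float:
    """Amplitude resolution of the written EDF files in uV."""
    return 2 * EDF_PHYS_RANGE_UV / 65535.0


# ---------------------------------------------------------------------------
# Acquisition-style filtering
# ---------------------------------------------------------------------------

def preprocess_filter(record: SignalRecord, hp_hz: float = 1.0,
                      lp_hz: float = 100.0, notch_hz: float | None = 50.0,
                      notch_q: float = 30.0) -> SignalRecord:
    """Band-pass (1-100 Hz) plus 50-Hz notch, as applied at acquisition.

    Filters are applied forward-backward (zero phase) so event times are
    not shifted — a deliberate divergence from the causal acquisition
    hardware, chosen to keep onset labeling unbiased.
    """
    nyq = record.fs / 2
    if not (0 < hp_hz < lp_hz):
        raise ValueError("need 0 < hp_hz < lp_hz")
    if lp_hz >= nyq:
        raise ValueError(f"low-pass {lp_hz} Hz at or above Nyquist {nyq} Hz")
    sos = sps.butter(4, [hp_hz, lp_hz], btype="bandpass", fs=record.fs,
                     output="sos")
    out = sps.sosfiltfilt(sos, record.data, axis=1)
    if notch_hz is not None and notch_hz < nyq:
        b, a = sps.iirnotch(notch_hz, notch_q, fs=record.fs)
        out = sps.filtfilt(b, a, out, axis=1)
    return replace(record, data=out)
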
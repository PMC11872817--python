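"""Reading, referencing, filtering and artifact screening of multichannel EEG.

The preprocessing chain mirrors a conventional clinical resting-state
workflow: channels are re-referenced to the common average, high-pass
filtered at 0.1 Hz to remove drift, notch filtered at 50 Hz to remove line
interference, and screened for high-amplitude artifacts with a simple
threshold rule.  All filtering is zero-phase (forward-backward) because
instantaneous-phase estimates are computed downstream.

Conventions: signals are in microvolts, sample indices are 0-based and
retained intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "EEGRecording",
    "RegionSet",
    "RegionSignal",
    "DEFAULT_MONTAGE",
    "DEFAULT_REGIONS",
    "read_recording",
    "apply_average_reference",
    "apply_filters",
    "select_artifact_free",
    "region_signal",
]

#: 21-channel 10/20 montage (19 standard scalp positions plus Fpz and Oz).
DEFAULT_MONTAGE: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2", "Fpz", "Oz",
)

# Modern (10/10-style) aliases mapped onto the classic 10/20 labels.
_LABEL_SYNONYMS = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}

_CANONICAL_BY_LOWER = {name.lower(): name for name in DEFAULT_MONTAGE}
_CANONICAL_BY_LOWER.update({k.lower(): v for k, v in _LABEL_SYNONYMS.items()})


def normalize_label(label: str) -> str:
    """Map an electrode label to its canonical 10/20 spelling.

    Case-insensitive; strips a leading ``EEG `` prefix and trailing
    reference suffixes such as ``-REF``; applies the T3/T7-style synonym
    table.  Unknown labels are returned stripped but otherwise unchanged.
    """
    name = label.strip()
    if name.upper().startswith("EEG "):
        name = name[4:].strip()
    for suffix in ("-REF", "-LE", "-AVG"):
        if name.upper().endswith(suffix):
            name = name[: -len(suffix)]
    return _CANONICAL_BY_LOWER.get(name.lower(), name)


@dataclass
class EEGRecording:
    """One subject/condition multichannel EEG time series.

    Attributes
    ----------
    subject_id : str
    condition : str
        ``"pre"`` or ``"post"``.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Ordered, unique 10/20 electrode names.
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    segments : list of (int, int), optional
        Retained artifact-free intervals, half-open sample ranges.  ``None``
        means the whole recording is retained.
    """

    subject_id: str
    condition: str
    fs: float
    channel_labels: list[str]
    data: np.ndarray
    segments: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.condition not in ("pre", "post"):
            raise ValueError(f"condition must be 'pre' or 'post', got {self.condition!r}")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per data row required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("duplicate channel labels")
        if self.segments is not None:
            self.segments = [(int(a), int(b)) for a, b in self.segments]
            prev_end = 0
            for a, b in self.segments:
                if not (0 <= a < b <= self.n_samples):
                    raise ValueError(f"segment ({a}, {b}) outside [0, {self.n_samples})")
                if a < prev_end:
                    raise ValueError("segments must be ascending and non-overlapping")
                prev_end = b

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def retained_segments(self) -> list[tuple[int, int]]:
        """Retained intervals; the full recording when none were marked."""
        if self.segments is None:
            return [(0, self.n_samples)]
        return list(self.segments)

    def replace(self, **kwargs) -> "EEGRecording":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class RegionSet:
    """Named groups of 10/20 channels over which signals/features average."""

    regions: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "regions",
            {name: tuple(chs) for name, chs in self.regions.items()},
        )
        for name, chs in self.regions.items():
            if not chs:
                raise ValueError(f"region {name!r} has no channels")

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.regions[name]

    def names(self) -> list[str]:
        return list(self.regions)

    def validate_montage(self, channel_labels: list[str]) -> None:
        present = set(channel_labels)
        for name, chs in self.regions.items():
            missing = [c for c in chs if c not in present]
            if len(missing) == len(chs):
                raise ValueError(
                    f"region {name!r}: none of its channels {missing} present"
                )


#: Scalp regions of interest used throughout the analysis.
DEFAULT_REGIONS = RegionSet(
    {
        "occipital": ("O1", "O2"),
        "frontal-complete": ("Fp1", "Fp2", "F4", "F3", "F8", "F7", "Fz"),
        "fronto-polar": ("Fp1", "Fp2"),
        "temporal": ("T3", "T4"),
        "parietal": ("P3", "P4", "Pz"),
    }
)


@dataclass
class RegionSignal:
    """Region-average signal restricted to retained samples.

    ``samples`` is the concatenation of the per-segment region means;
    ``segment_bounds`` marks each source segment inside the concatenated
    array so spectral/coupling stages can window segments independently.
    """

    region: str
    fs: float
    samples: np.ndarray
    segment_bounds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.segment_bounds:
            self.segment_bounds = [(0, len(self.samples))]

    def segment_arrays(self) -> list[np.ndarray]:
        return [self.samples[a:b] for a, b in self.segment_bounds]


# ---------------------------------------------------------------------------
# Reading


def read_recording(
    path: str | os.PathLike,
    format: str = "auto",
    *,
    fs: float | None = None,
    subject_id: str = "",
    condition: str = "pre",
) -> EEGRecording:
    """Read an EEG recording from EDF or delimited text.

    Parameters
    ----------
    path
        File to read.
    format
        ``"edf"``, ``"delimited"`` or ``"auto"`` (by extension).
    fs
        Sampling rate in Hz; required for delimited input (EDF carries it).
    subject_id, condition
        Metadata attached to the returned recording.

    Delimited files have one column per channel with a header row of
    electrode labels (CSV or TSV), values in microvolts.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "auto":
        format = "edf" if path.lower().endswith(".edf") else "delimited"

    if format == "edf":
        import mne

        try:
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        except Exception as exc:  # pragma: no cover - backend-specific message
            raise ValueError(f"unparseable EDF file {path!r}: {exc}") from exc
        labels = [normalize_label(ch) for ch in raw.ch_names]
        data = raw.get_data() * 1e6  # MNE uses volts internally
        fs_read = float(raw.info["sfreq"])
    elif format == "delimited":
        if fs is None:
            raise ValueError("fs is required for delimited input")
        try:
            frame = pd.read_csv(path, sep=None, engine="python")
        except Exception as exc:
            raise ValueError(f"unparseable delimited file {path!r}: {exc}") from exc
        labels = [normalize_label(str(c)) for c in frame.columns]
        data = frame.to_numpy(dtype=float).T
        fs_read = float(fs)
    else:
        raise ValueError(f"unknown format {format!r}")

    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate channel labels after normalization: {dupes}")
    return EEGRecording(
        subject_id=subject_id,
        condition=condition,
        fs=fs_read,
        channel_labels=labels,
        data=data,
    )


# ---------------------------------------------------------------------------
# Referencing and filtering


def apply_average_reference(rec: EEGRecording) -> EEGRecording:
    """Re-reference to the common average.

    Subtracts the instantaneous mean across channels from every channel, so
    the column sums of the result are zero.  Requires at least two channels.
    """
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.replace(data=data)


@lru_cache(maxsize=64)
def _filter_sos(fs: float, highpass_hz: float, notch_hz: float) -> np.ndarray:
    sos_hp = sps.butter(4, highpass_hz, btype="highpass", fs=fs, output="sos")
    b, a = sps.iirnotch(notch_hz, Q=30.0, fs=fs)
    sos_notch = sps.tf2sos(b, a)
    return np.vstack([sos_hp, sos_notch])


def apply_filters(
    rec: EEGRecording, highpass_hz: float = 0.1, notch_hz: float = 50.0
) -> EEGRecording:
    """Zero-phase 0.1 Hz high-pass and 50 Hz notch filtering.

    4th-order Butterworth high-pass and a Q=30 IIR notch, each applied
    forward-backward (``sosfiltfilt``) so downstream phase estimates are not
    biased.  Each retained segment is filtered independently to avoid
    smearing across rejection gaps.  Edge handling uses even-reflection
    padding over up to three corner periods of the high-pass: the default
    odd extension excites very large low-frequency transients at a 0.1 Hz
    corner.
    """
    if not (0 < highpass_hz < notch_hz):
        raise ValueError("require 0 < highpass_hz < notch_hz")
    if notch_hz >= rec.fs / 2:
        raise ValueError(f"notch frequency {notch_hz} Hz at or above Nyquist")
    sos = _filter_sos(rec.fs, highpass_hz, notch_hz)
    data = rec.data.copy()
    for a, b in rec.retained_segments():
        padlen = min(b - a - 1, int(3 * rec.fs / highpass_hz))
        data[:, a:b] = sps.sosfiltfilt(
            sos, rec.data[:, a:b], axis=1, padtype="even", padlen=padlen
        )
    return rec.replace(data=data)


# ---------------------------------------------------------------------------
# Artifact screening


def select_artifact_free(
    rec: EEGRecording, amplitude_uV: float = 150.0, pad_s: float = 0.5
) -> EEGRecording:
    """Mark maximal intervals where all channels stay within ±threshold.

    An automated stand-in for manual artifact rejection: any sample where
    any channel exceeds ``amplitude_uV`` (in absolute value) is discarded
    together with ``pad_s`` seconds on either side; the remaining maximal
    runs become the retained segments.
    """
    if amplitude_uV <= 0:
        raise ValueError("amplitude threshold must be positive")
    if pad_s < 0:
        raise ValueError("pad_s must be non-negative")
    bad = np.any(np.abs(rec.data) > amplitude_uV, axis=0)
    pad = int(round(pad_s * rec.fs))
    if pad and bad.any():
        idx = np.flatnonzero(bad)
        mask = np.zeros_like(bad)
        for i in idx:
            mask[max(0, i - pad) : i + pad + 1] = True
        bad = mask
    good = ~bad
    if not good.any():
        raise ValueError("empty recording: no samples below the artifact threshold")
    edges = np.flatnonzero(np.diff(good.astype(int)))
    starts = [0] if good[0] else []
    starts += [int(e) + 1 for e in edges if good[e + 1]]
    ends = [int(e) + 1 for e in edges if good[e]]
    if good[-1]:
        ends.append(rec.n_samples)
    segments = list(zip(starts, ends))
    return rec.replace(segments=segments)


# ---------------------------------------------------------------------------
# Region averaging


def region_signal(rec: EEGRecording, regions: RegionSet, name: str) -> RegionSignal:
    """Sample-wise mean of a region's available channels over retained samples."""
    if name not in regions.regions:
        raise KeyError(f"unknown region {name!r}")
    wanted = regions[name]
    rows = [rec.channel_labels.index(c) for c in wanted if c in rec.channel_labels]
    if not rows:
        missing = [c for c in wanted if c not in rec.channel_labels]
        raise ValueError(f"region {name!r}: channels {missing} absent from montage")
    mean = rec.data[rows].mean(axis=0)
    pieces, bounds, pos = [], [], 0
    for a, b in rec.retained_segments():
        pieces.append(mean[a:b])
        bounds.append((pos, pos + (b - a)))
        pos += b - a
    return RegionSignal(
        region=name,
        fs=rec.fs,
        samples=np.concatenate(pieces) if pieces else np.empty(0),
        segment_bounds=bounds,
    )


def channel_signal(rec: EEGRecording, label: str) -> RegionSignal:
    """Single-channel signal over retained samples (as a RegionSignal)."""
    if label not in rec.channel_labels:
        raise ValueError(f"channel {label!r} absent from montage")
    return region_signal(rec, RegionSet({label: (label,)}), label)


def segment_table(recs: list[EEGRecording]) -> pd.DataFrame:
    """Retained-segment bookkeeping as a table (subject, condition, start_s, end_s)."""
    rows = []
    for rec in recs:
        for a, b in rec.retained_segments():
            rows.append(
                {
                    "subject": rec.subject_id,
                    "condition": rec.condition,
                    "start_s": a / rec.fs,
                    "end_s": b / rec.fs,
                }
            )
    return pd.DataFrame(rows, columns=["subject", "condition", "start_s", "end_s"])
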
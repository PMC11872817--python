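"""Power spectra, region band power, and region-pair coherence.

Spectra are Welch averages of Hanning-windowed periodograms (window 512
samples, 50% overlap) giving a 200/512 = 0.390625 Hz grid at the 200 Hz
sampling rate used throughout.  Coherence is magnitude-squared coherence of
region-average signals,

    Coh_XY(f) = |S_XY(f)|^2 / (S_XX(f) S_YY(f)),

with cross- and auto-spectra averaged over the same windows.  Retained
segments are windowed independently and pooled with window-count weights;
segments shorter than one window are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io_preprocess import RegionSet, RegionSignal

__all__ = [
    "BandSet",
    "PowerSpectrum",
    "CoherencePair",
    "DEFAULT_BANDS",
    "power_spectrum",
    "band_power",
    "coherence",
    "band_coherence",
]


@dataclass(frozen=True)
class BandSet:
    """Named frequency intervals, half-open ``[low, high)`` in Hz.

    Half-open edges keep adjacent bands (4, 14, 31 Hz ...) from being
    counted twice.
    """

    bands: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "bands", {k: (float(lo), float(hi)) for k, (lo, hi) in self.bands.items()}
        )
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"band {name!r}: require low < high, got ({lo}, {hi})")

    def __iter__(self):
        return iter(self.bands)

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.bands[name]

    def names(self) -> list[str]:
        return list(self.bands)


#: Clinical band decomposition, including the composite bands used in the
#: pre/post comparison.
DEFAULT_BANDS = BandSet(
    {
        "delta": (1, 4),
        "theta": (4, 8),
        "alpha": (8, 14),
        "beta": (14, 31),
        "gamma": (31, 80),
        "theta-alpha": (4, 14),
        "alpha-beta-gamma": (8, 80),
        "beta-gamma": (14, 80),
    }
)


@dataclass
class PowerSpectrum:
    """One-sided Welch power spectral density (µV²/Hz)."""

    frequencies: np.ndarray
    power: np.ndarray
    n_segments: int  # number of averaged windows

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)


@dataclass
class CoherencePair:
    """Magnitude-squared coherence between two region signals."""

    region_x: str
    region_y: str
    frequencies: np.ndarray
    coherence: np.ndarray
    n_segments: int


def _as_segments(x, fs: float | None) -> tuple[list[np.ndarray], float]:
    if isinstance(x, RegionSignal):
        return x.segment_arrays(), x.fs
    if fs is None:
        raise ValueError("fs is required for plain-array input")
    return [np.asarray(x, dtype=float)], float(fs)


def _welch_segments(
    segs: list[np.ndarray],
    fs: float,
    window_len: int,
    overlap: float,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Window-count-weighted Welch average across retained segments."""
    step = window_len - int(window_len * overlap)
    acc, freqs, total = None, None, 0
    for seg in segs:
        if len(seg) < window_len:
            continue
        k = 1 + (len(seg) - window_len) // step
        f, p = sps.welch(
            seg,
            fs=fs,
            window="hann",
            nperseg=window_len,
            noverlap=int(window_len * overlap),
            detrend="constant",
            scaling="density",
        )
        acc = k * p if acc is None else acc + k * p
        freqs = f
        total += k
    if total == 0:
        raise ValueError(
            f"no retained segment reaches the window length ({window_len} samples)"
        )
    return freqs, acc / total, total


def power_spectrum(
    x: RegionSignal | np.ndarray,
    fs: float | None = None,
    window_len: int = 512,
    overlap: float = 0.5,
) -> PowerSpectrum:
    """Welch power spectral density of a (region) signal.

    Frequency spacing is ``fs / window_len`` (0.390625 Hz at 200 Hz / 512).
    The density normalization satisfies Parseval: ``sum(power) * df`` equals
    the (window-corrected) signal variance.
    """
    segs, fs = _as_segments(x, fs)
    freqs, power, total = _welch_segments(segs, fs, window_len, overlap)
    return PowerSpectrum(frequencies=freqs, power=power, n_segments=total)


def band_power(
    spectra: dict[str, PowerSpectrum],
    regions: RegionSet,
    region: str,
    band: str | tuple[float, float],
    bands: BandSet = DEFAULT_BANDS,
    exclude: tuple[float, float] | None = None,
) -> float:
    """Region band power: channel mean of per-channel mean band PSD.

    ``spectra`` maps channel label to its PowerSpectrum; the region value is
    the mean over the region's available channels of the mean power across
    frequency bins with ``low <= f < high``.  ``exclude`` optionally drops a
    sub-interval (e.g. 48-52 Hz around the notch trough) from the mean.
    """
    lo, hi = bands[band] if isinstance(band, str) else band
    chans = [c for c in regions[region] if c in spectra]
    if not chans:
        raise ValueError(f"no spectra available for region {region!r}")
    vals = []
    for c in chans:
        spec = spectra[c]
        sel = _band_mask(spec.frequencies, lo, hi, exclude)
        vals.append(float(spec.power[sel].mean()))
    return float(np.mean(vals))


def _band_mask(freqs: np.ndarray, lo: float, hi: float, exclude) -> np.ndarray:
    sel = (freqs >= lo) & (freqs < hi)
    if exclude is not None:
        sel &= ~((freqs >= exclude[0]) & (freqs < exclude[1]))
    if not sel.any():
        raise ValueError(f"band ({lo}, {hi}) Hz covers no frequency bins")
    return sel


def coherence(
    x: RegionSignal | np.ndarray,
    y: RegionSignal | np.ndarray,
    fs: float | None = None,
    window_len: int = 512,
    overlap: float = 0.5,
) -> CoherencePair:
    """Magnitude-squared coherence between two aligned signals.

    Cross- and auto-spectra are averaged over the same Hanning windows
    before forming the ratio; at least two windows are required (the
    single-window estimator is identically 1).
    """
    xsegs, fsx = _as_segments(x, fs)
    ysegs, fsy = _as_segments(y, fs)
    if fsx != fsy:
        raise ValueError(f"sampling rates differ: {fsx} vs {fsy}")
    if [len(s) for s in xsegs] != [len(s) for s in ysegs]:
        raise ValueError("signals must share aligned retained segments")
    step = window_len - int(window_len * overlap)
    noverlap = int(window_len * overlap)
    kw = dict(
        fs=fsx,
        window="hann",
        nperseg=window_len,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
    )
    pxx = pyy = pxy = None
    freqs, total = None, 0
    for sx, sy in zip(xsegs, ysegs):
        if len(sx) < window_len:
            continue
        k = 1 + (len(sx) - window_len) // step
        f, px = sps.welch(sx, **kw)
        _, py = sps.welch(sy, **kw)
        _, pz = sps.csd(sx, sy, **kw)
        if pxx is None:
            pxx, pyy, pxy = k * px, k * py, k * pz
        else:
            pxx, pyy, pxy = pxx + k * px, pyy + k * py, pxy + k * pz
        freqs = f
        total += k
    if total < 2:
        raise ValueError(
            f"coherence needs at least 2 windows, got {total} "
            "(a single-window estimate is identically 1)"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(pxy) ** 2 / (pxx * pyy)
    coh = np.nan_to_num(coh, nan=0.0)
    name_x = x.region if isinstance(x, RegionSignal) else "x"
    name_y = y.region if isinstance(y, RegionSignal) else "y"
    return CoherencePair(
        region_x=name_x,
        region_y=name_y,
        frequencies=freqs,
        coherence=coh,
        n_segments=total,
    )


def band_coherence(
    pair: CoherencePair,
    band: str | tuple[float, float],
    bands: BandSet = DEFAULT_BANDS,
    exclude: tuple[float, float] | None = None,
) -> float:
    """Mean coherence over the band's frequency bins (``low <= f < high``)."""
    lo, hi = bands[band] if isinstance(band, str) else band
    sel = _band_mask(pair.frequencies, lo, hi, exclude)
    return float(pair.coherence[sel].mean())


def spectra_frame(spectra: dict[str, PowerSpectrum], subject: str, condition: str) -> pd.DataFrame:
    """Long-format export of per-channel spectra."""
    rows = []
    for chan, spec in spectra.items():
        rows.append(
            pd.DataFrame(
                {
                    "subject": subject,
                    "condition": condition,
                    "channel": chan,
                    "frequency": spec.frequencies,
                    "power": spec.power,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
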
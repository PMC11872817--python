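"""Phase-amplitude cross-frequency coupling via the Canolty modulation index.

For a modulating band f2 and a modulated band f1 the composite signal
``w[n] = A_f1[n] * exp(i * phi_f2[n])`` combines the analytic-signal
envelope at the fast band with the analytic-signal phase at the slow band;
the modulation index is

    MI = | (1/N) * sum_n w[n] |.

If the fast envelope is independent of the slow phase the phasors cancel
and MI is near 0; systematic envelope peaks at a preferred phase leave a
non-zero resultant.  Comodulograms evaluate MI on a grid of modulating
centers 1..10 Hz (1 Hz steps, ±1 Hz bands, clipped below at 0.5 Hz) by
modulated centers 20..85 Hz (5 Hz steps, ±5 Hz bands).  Raw MI is reported;
an optional circular time-shift surrogate z-score is available but off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .io_preprocess import RegionSignal

__all__ = [
    "CfcGrid",
    "analytic_phase",
    "analytic_amplitude",
    "mi_from_phase_amplitude",
    "modulation_index",
    "cfc_grid",
    "DEFAULT_MODULATING_CENTERS",
    "DEFAULT_MODULATED_CENTERS",
]

DEFAULT_MODULATING_CENTERS: tuple[float, ...] = tuple(float(f) for f in range(1, 11))
DEFAULT_MODULATED_CENTERS: tuple[float, ...] = tuple(float(f) for f in range(20, 86, 5))

#: half-widths of the bands around each center, Hz
MODULATING_HALF_BW = 1.0
MODULATED_HALF_BW = 5.0
#: lowest permissible band edge, Hz (keeps the 1 Hz center's band causal)
MIN_BAND_EDGE = 0.5


@dataclass
class CfcGrid:
    """Comodulogram: modulation index over modulating x modulated centers."""

    phase_source: str
    amp_source: str
    modulating_centers: np.ndarray
    modulated_centers: np.ndarray
    mi: np.ndarray  # (n_modulating, n_modulated)

    def __post_init__(self) -> None:
        self.modulating_centers = np.asarray(self.modulating_centers, dtype=float)
        self.modulated_centers = np.asarray(self.modulated_centers, dtype=float)
        self.mi = np.asarray(self.mi, dtype=float)

    def argmax_cell(self) -> tuple[float, float]:
        """(modulating, modulated) centers of the grid maximum."""
        i, j = np.unravel_index(int(np.argmax(self.mi)), self.mi.shape)
        return float(self.modulating_centers[i]), float(self.modulated_centers[j])


@lru_cache(maxsize=512)
def _bandpass_sos(fs: float, low: float, high: float) -> np.ndarray:
    if not (0 < low < high < fs / 2):
        raise ValueError(f"band ({low}, {high}) Hz not inside (0, {fs / 2}) Hz")
    return sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")


def _segments(x, fs: float | None) -> tuple[list[np.ndarray], float]:
    if isinstance(x, RegionSignal):
        return x.segment_arrays(), x.fs
    if fs is None:
        raise ValueError("fs is required for plain-array input")
    return [np.asarray(x, dtype=float)], float(fs)


def _analytic(x, fs, band, part: str, trim_cycles: float = 1.0) -> np.ndarray:
    low, high = band
    segs, fs = _segments(x, fs)
    sos = _bandpass_sos(fs, low, high)
    trim = int(round(trim_cycles * fs / low))
    out = []
    for seg in segs:
        if len(seg) <= 2 * trim + 8:
            continue  # too short for stable edges
        analytic = sps.hilbert(sps.sosfiltfilt(sos, seg))
        core = analytic[trim : len(seg) - trim] if trim else analytic
        out.append(np.angle(core) if part == "phase" else np.abs(core))
    if not out:
        raise ValueError("no retained segment long enough for this band")
    return np.concatenate(out)


def analytic_phase(x, band: tuple[float, float], fs: float | None = None) -> np.ndarray:
    """Instantaneous phase (radians) of the band-passed analytic signal.

    Zero-phase Butterworth band-pass followed by the Hilbert transform; one
    cycle of the band's low edge is trimmed from each segment end to avoid
    analytic-signal edge artifacts.
    """
    return _analytic(x, fs, band, "phase")


def analytic_amplitude(x, band: tuple[float, float], fs: float | None = None) -> np.ndarray:
    """Instantaneous envelope (same band extraction as `analytic_phase`)."""
    return _analytic(x, fs, band, "amplitude")


def mi_from_phase_amplitude(phase: np.ndarray, amplitude: np.ndarray) -> float:
    """Canolty modulation index from precomputed phase/envelope series."""
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude series must have equal length")
    if phase.size == 0:
        raise ValueError("empty series")
    return float(np.abs(np.mean(amplitude * np.exp(1j * phase))))


def modulation_index(
    phase_sig,
    amp_sig,
    f_mod: tuple[float, float],
    f_car: tuple[float, float],
    fs: float | None = None,
) -> float:
    """MI between one signal's slow phase and another's fast envelope.

    Both series are trimmed by one cycle of the *modulating* band's low
    edge (the larger of the two trims) so they stay aligned.
    """
    phase = _analytic(phase_sig, fs, f_mod, "phase")
    # envelope trimmed by the modulating band's (longer) edge so lengths match
    segs, fs_a = _segments(amp_sig, fs)
    sos = _bandpass_sos(fs_a, *f_car)
    trim = int(round(fs_a / f_mod[0]))
    amps = []
    for seg in segs:
        if len(seg) <= 2 * trim + 8:
            continue
        analytic = sps.hilbert(sps.sosfiltfilt(sos, seg))
        amps.append(np.abs(analytic[trim : len(seg) - trim]))
    if not amps:
        raise ValueError("no retained segment long enough for this band pair")
    amp = np.concatenate(amps)
    return mi_from_phase_amplitude(phase, amp)


def cfc_grid(
    phase_region: RegionSignal,
    amp_region: RegionSignal,
    modulating: tuple[float, ...] = DEFAULT_MODULATING_CENTERS,
    modulated: tuple[float, ...] = DEFAULT_MODULATED_CENTERS,
    min_cycles: float = 3.0,
) -> CfcGrid:
    """Comodulogram between a phase-providing and an amplitude-providing signal.

    Within-region coupling passes the same signal twice.  Each cell uses a
    modulating band of ``center +/- 1`` Hz (clipped below at 0.5 Hz) and a
    modulated band of ``center +/- (5 + f_modulating)`` Hz, wide enough to
    hold the coupling sidebands; one cycle of the modulating band's low
    edge is trimmed from every segment end.  Segments shorter than
    ``min_cycles`` cycles of the lowest modulating band edge are skipped.
    """
    fs = phase_region.fs
    if fs != amp_region.fs:
        raise ValueError("phase and amplitude signals must share the sampling rate")
    psegs = phase_region.segment_arrays()
    asegs = amp_region.segment_arrays()
    if [len(s) for s in psegs] != [len(s) for s in asegs]:
        raise ValueError("signals must share aligned retained segments")

    lowest_edge = max(MIN_BAND_EDGE, min(modulating) - MODULATING_HALF_BW)
    min_len = int(round(min_cycles * fs / lowest_edge))
    keep = [i for i, s in enumerate(psegs) if len(s) >= min_len]
    if not keep:
        raise ValueError("no retained segment long enough for coupling analysis")
    psegs = [psegs[i] for i in keep]
    asegs = [asegs[i] for i in keep]

    # Phase series are shared across the modulated axis; envelopes use a
    # modulated bandwidth of +/- (MODULATED_HALF_BW + f_phase) so that the
    # amplitude-modulation sidebands at fa +/- fp fall inside the band —
    # with a bandwidth narrower than the modulating frequency the coupled
    # cell itself would carry a flat envelope and the comodulogram maximum
    # would land on a neighbouring cell.
    mi = np.zeros((len(modulating), len(modulated)))
    for i, fp in enumerate(modulating):
        low = max(MIN_BAND_EDGE, fp - MODULATING_HALF_BW)
        high = fp + MODULATING_HALF_BW
        sos = _bandpass_sos(fs, low, high)
        phases = [np.angle(sps.hilbert(sps.sosfiltfilt(sos, s))) for s in psegs]
        trim = int(round(fs / low))
        half = MODULATED_HALF_BW + fp
        for j, fa in enumerate(modulated):
            lo2 = fa - half
            hi2 = min(fa + half, 0.995 * fs / 2)
            sos2 = _bandpass_sos(fs, lo2, hi2)
            num = 0.0 + 0.0j
            count = 0
            for ph, aseg in zip(phases, asegs):
                n = len(ph)
                if n <= 2 * trim + 8:
                    continue
                am = np.abs(sps.hilbert(sps.sosfiltfilt(sos2, aseg)))
                sl = slice(trim, n - trim)
                num += np.sum(am[sl] * np.exp(1j * ph[sl]))
                count += n - 2 * trim
            mi[i, j] = np.abs(num) / count if count else 0.0
    return CfcGrid(
        phase_source=phase_region.region,
        amp_source=amp_region.region,
        modulating_centers=np.asarray(modulating),
        modulated_centers=np.asarray(modulated),
        mi=mi,
    )


def surrogate_zscore(
    phase: np.ndarray,
    amplitude: np.ndarray,
    n_surrogates: int = 200,
    seed: int = 0,
) -> float:
    """Optional circular time-shift surrogate z-score for one MI value.

    The envelope is circularly shifted by ``n_surrogates`` random offsets;
    the observed MI is standardized against the surrogate distribution.
    """
    rng = np.random.default_rng(seed)
    observed = mi_from_phase_amplitude(phase, amplitude)
    n = len(phase)
    shifts = rng.integers(1, n - 1, size=n_surrogates)
    null = np.array(
        [mi_from_phase_amplitude(phase, np.roll(amplitude, int(s))) for s in shifts]
    )
    sd = null.std()
    if sd == 0:
        raise ValueError("degenerate surrogate distribution")
    return float((observed - null.mean()) / sd)
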
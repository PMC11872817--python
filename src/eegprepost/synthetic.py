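"""Seeded synthetic resting-state EEG cohorts for end-to-end verification.

Each subject/condition recording is assembled from

* 1/f^beta background noise per channel (independent across channels),
* band-limited oscillations per scalp region, mixed from a shared
  region-level source plus an independent per-channel source so that
  member channels are coherent in the oscillation band,
* optional phase-amplitude-coupled components (a slow rhythm whose phase
  modulates a fast rhythm's envelope), and
* configurable pre-to-post effects on band power, region coherence,
  signal structure (entropy) and coupling depth.

Subject-level amplitude variation is drawn once per subject and shared
between the two conditions, so the cohort has the paired structure the
group statistics assume; condition-level noise realizations are
independent.  Everything is deterministic under the master seed, with
per-subject/per-condition streams derived by stable sub-seeding.

The generator emulates the statistical structure the analysis pipeline
measures; it makes no attempt at biophysical realism (no volume
conduction, head geometry, or physiological artifact waveforms).
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io_preprocess import DEFAULT_MONTAGE, DEFAULT_REGIONS, EEGRecording, RegionSet
from .spectral import DEFAULT_BANDS, BandSet

__all__ = [
    "Oscillation",
    "PacSpec",
    "PlantedEffect",
    "SyntheticCohortConfig",
    "pink_noise",
    "pac_component",
    "simulate_subject",
    "simulate_cohort",
    "write_cohort",
    "write_edf",
]


@dataclass(frozen=True)
class Oscillation:
    """Band-limited rhythm added to one region's channels.

    ``shared_fraction`` is the fraction of oscillation power coming from
    the region-shared source; it controls within-region band coherence.
    """

    region: str
    center_hz: float
    bandwidth_hz: float
    rms_uV: float
    shared_fraction: float = 0.7


@dataclass(frozen=True)
class PacSpec:
    """Phase-amplitude coupling between two regions (or within one)."""

    phase_region: str
    amp_region: str
    f_phase: float
    f_amp: float
    depth: float
    rms_uV: float = 4.0


@dataclass(frozen=True)
class PlantedEffect:
    """A pre-to-post change applied to the post recording.

    kind:
      ``power``     multiply band power of the target region by `multiplier`
      ``coherence`` multiply the shared-source power fraction of the target
                    region's oscillations in `band` by `multiplier`
      ``entropy``   multiply the slow structured drift of the target region
                    by `multiplier` (a base drift is added in both
                    conditions whenever an entropy effect targets a region)
      ``cfc``       add `depth_delta` to the matching PacSpec's depth
    """

    kind: str
    target: str
    band: str | None = None
    multiplier: float = 1.0
    depth_delta: float = 0.0


def _default_oscillations() -> tuple[Oscillation, ...]:
    # Eyes-closed resting profile: posterior alpha, frontal theta, mild
    # temporal beta.
    return (
        Oscillation("occipital", 10.0, 2.0, 8.0),
        Oscillation("parietal", 10.0, 2.0, 6.0),
        Oscillation("frontal-complete", 6.0, 2.0, 4.0),
        Oscillation("temporal", 20.0, 6.0, 3.0),
    )


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study-shaped cohort: 10 subjects x {pre, post}, 21 channels, 200 Hz.

    The default duration (120 s) keeps simulation-heavy test suites fast;
    ``clinical_scale()`` returns the 757 s (12.62 min) variant matching the
    mean artifact-free length of the emulated recordings.
    """

    n_subjects: int = 10
    fs: float = 200.0
    duration_s: float = 120.0
    montage: tuple[str, ...] = DEFAULT_MONTAGE
    regions: RegionSet = field(default_factory=lambda: DEFAULT_REGIONS)
    background_beta: float = 1.0
    background_rms: float = 15.0
    oscillations: tuple[Oscillation, ...] = field(default_factory=_default_oscillations)
    pac: tuple[PacSpec, ...] = ()
    effects: tuple[PlantedEffect, ...] = ()
    subject_sd: float = 0.15  # lognormal sigma of per-subject amplitude scaling
    n_spikes: int = 0  # optional high-amplitude test artifacts per recording
    spike_uV: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.duration_s * self.fs < 500:
            raise ValueError("recording must be at least 500 samples for entropy")
        for p in self.pac:
            if not (0 <= p.depth <= 1):
                raise ValueError("coupling depth must be in [0, 1]")
        for e in self.effects:
            if e.kind not in ("power", "coherence", "entropy", "cfc"):
                raise ValueError(f"unknown effect kind {e.kind!r}")
            if e.multiplier <= 0:
                raise ValueError("effect multipliers must be positive")

    def clinical_scale(self) -> "SyntheticCohortConfig":
        return replace(self, duration_s=757.0)


# ---------------------------------------------------------------------------
# Signal primitives


def _rng(seed_parts) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(seed_parts)))


def pink_noise(
    n: int, beta: float, rms: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f^beta."""
    if n <= 1:
        raise ValueError("need more than one sample")
    if not 0 <= beta <= 2:
        raise ValueError("spectral exponent beta must be in [0, 2]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n)
    x -= x.mean()
    sd = x.std()
    return x / sd * rms if sd > 0 else x


def _pink_noise_matrix(
    rows: int, n: int, beta: float, rms: float, rng: np.random.Generator
) -> np.ndarray:
    """Independent 1/f^beta rows, generated in one spectral pass."""
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    spec = amp * (
        rng.standard_normal((rows, len(freqs)))
        + 1j * rng.standard_normal((rows, len(freqs)))
    )
    x = np.fft.irfft(spec, n=n, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    x /= x.std(axis=-1, keepdims=True)
    return x * rms


@lru_cache(maxsize=256)
def _bandpass_sos_cached(fs: float, low: float, high: float) -> np.ndarray:
    return sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")


def _narrowband(
    n: int,
    fs: float,
    center: float,
    bandwidth: float,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise around `center`.

    With ``size`` given, returns ``size`` independent rows filtered in one
    pass.
    """
    low = max(0.05, center - bandwidth / 2)
    high = min(fs / 2 - 1e-6, center + bandwidth / 2)
    sos = _bandpass_sos_cached(float(fs), low, high)
    white = rng.standard_normal((size or 1, n))
    x = sps.sosfiltfilt(sos, white, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    x /= x.std(axis=-1, keepdims=True)
    return x if size else x[0]


def pac_component(
    n: int,
    fs: float,
    f_phase: float,
    f_amp: float,
    depth: float,
    rms: float = 1.0,
    seed: int | np.random.Generator = 0,
    jitter_sd: float = 0.1,
) -> np.ndarray:
    """Slow rhythm plus a fast rhythm whose envelope follows the slow phase.

        s(t) = sin(phi(t)) + (1 + depth * sin(phi(t))) * sin(2 pi f_amp t + eta)

    with phi(t) = 2 pi f_phase t (+ random start phase) and small carrier
    phase jitter eta (SD ``jitter_sd`` radians).  depth = 0 gives two
    uncoupled rhythms.
    """
    if not f_phase < f_amp < fs / 2:
        raise ValueError("require f_phase < f_amp < fs/2")
    if not 0 <= depth <= 1:
        raise ValueError("depth must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(n) / fs
    phi = 2 * np.pi * f_phase * t + rng.uniform(0, 2 * np.pi)
    jitter = rng.normal(0.0, jitter_sd, n) if jitter_sd > 0 else 0.0
    carrier = np.sin(2 * np.pi * f_amp * t + rng.uniform(0, 2 * np.pi) + jitter)
    s = np.sin(phi) + (1 + depth * np.sin(phi)) * carrier
    s -= s.mean()
    return s / s.std() * rms


def _pac_pair(
    n: int,
    fs: float,
    spec: PacSpec,
    depth: float,
    rng: np.random.Generator,
    jitter_sd: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """(slow, fast) components sharing one modulating phase."""
    t = np.arange(n) / fs
    phi = 2 * np.pi * spec.f_phase * t + rng.uniform(0, 2 * np.pi)
    jitter = rng.normal(0.0, jitter_sd, n) if jitter_sd > 0 else 0.0
    carrier = np.sin(2 * np.pi * spec.f_amp * t + rng.uniform(0, 2 * np.pi) + jitter)
    slow = np.sin(phi)
    fast = (1 + depth * np.sin(phi)) * carrier
    scale = spec.rms_uV
    return slow / slow.std() * scale, fast / fast.std() * scale


# ---------------------------------------------------------------------------
# Subject simulation


def _scale_band_power(
    x: np.ndarray, fs: float, band: tuple[float, float], multiplier: float
) -> np.ndarray:
    """Multiply the signal's power inside [low, high) Hz by `multiplier`."""
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), 1 / fs)
    sel = (freqs >= band[0]) & (freqs < band[1])
    spec[sel] *= np.sqrt(multiplier)
    return np.fft.irfft(spec, n=len(x))


def simulate_subject(
    config: SyntheticCohortConfig,
    subject_index: int,
    condition: str,
    bands: BandSet = DEFAULT_BANDS,
) -> EEGRecording:
    """Simulate one recording; ``condition='post'`` applies planted effects."""
    if condition not in ("pre", "post"):
        raise ValueError("condition must be 'pre' or 'post'")
    n = int(round(config.duration_s * config.fs))
    fs = config.fs
    montage = list(config.montage)
    idx_of = {c: i for i, c in enumerate(montage)}
    is_post = condition == "post"

    param_rng = _rng([config.seed, subject_index, 7])
    cond_rng = _rng([config.seed, subject_index, 1 if condition == "pre" else 2])

    # Subject-level amplitude variation, shared across conditions.
    bg_scale = float(np.exp(param_rng.normal(0.0, config.subject_sd)))
    osc_scales = np.exp(param_rng.normal(0.0, config.subject_sd, len(config.oscillations)))

    data = _pink_noise_matrix(
        len(montage), n, config.background_beta,
        config.background_rms * bg_scale, cond_rng,
    )

    # Region oscillations: shared source + independent per-channel source.
    for osc, osc_scale in zip(config.oscillations, osc_scales):
        shared_frac = osc.shared_fraction
        if is_post:
            for eff in config.effects:
                if (
                    eff.kind == "coherence"
                    and eff.target == osc.region
                    and (eff.band is None or _band_contains(bands, eff.band, osc.center_hz))
                ):
                    shared_frac = float(np.clip(shared_frac * eff.multiplier, 0.0, 0.99))
        w_shared = np.sqrt(shared_frac)
        w_indep = np.sqrt(1.0 - shared_frac)
        shared = _narrowband(n, fs, osc.center_hz, osc.bandwidth_hz, cond_rng)
        rms = osc.rms_uV * float(osc_scale)
        members = [c for c in config.regions[osc.region] if c in idx_of]
        indep = _narrowband(
            n, fs, osc.center_hz, osc.bandwidth_hz, cond_rng, size=len(members)
        )
        for row, ch_label in enumerate(members):
            data[idx_of[ch_label]] += rms * (w_shared * shared + w_indep * indep[row])

    # Slow structured drift for regions carrying an entropy effect.
    for eff in config.effects:
        if eff.kind != "entropy":
            continue
        amp = 0.5 * config.background_rms * bg_scale
        if is_post:
            amp *= eff.multiplier
        drift = _narrowband(n, fs, 0.35, 0.5, cond_rng) * amp
        for ch_label in config.regions[eff.target]:
            if ch_label in idx_of:
                data[idx_of[ch_label]] += drift

    # Phase-amplitude coupling.
    for pac in config.pac:
        depth = pac.depth
        if is_post:
            for eff in config.effects:
                if eff.kind == "cfc" and eff.target in (
                    pac.phase_region,
                    f"{pac.phase_region}->{pac.amp_region}",
                ):
                    depth = float(np.clip(depth + eff.depth_delta, 0.0, 1.0))
        slow, fast = _pac_pair(n, fs, pac, depth, cond_rng)
        for ch_label in config.regions[pac.phase_region]:
            if ch_label in idx_of:
                data[idx_of[ch_label]] += slow
        for ch_label in config.regions[pac.amp_region]:
            if ch_label in idx_of:
                data[idx_of[ch_label]] += fast

    # Planted band-power changes, exact in expectation by spectral scaling.
    if is_post:
        for eff in config.effects:
            if eff.kind != "power":
                continue
            band = bands[eff.band] if isinstance(eff.band, str) else eff.band
            for ch_label in config.regions[eff.target]:
                if ch_label in idx_of:
                    ch = idx_of[ch_label]
                    data[ch] = _scale_band_power(data[ch], fs, band, eff.multiplier)

    # Optional high-amplitude spikes (for artifact-screening tests).
    for _ in range(config.n_spikes):
        pos = int(cond_rng.integers(0, n))
        ch = int(cond_rng.integers(0, len(montage)))
        data[ch, pos] += config.spike_uV * (1 if cond_rng.random() < 0.5 else -1)

    return EEGRecording(
        subject_id=f"S{subject_index + 1:02d}",
        condition=condition,
        fs=fs,
        channel_labels=montage,
        data=data,
    )


def _band_contains(bands: BandSet, band: str | tuple[float, float], f: float) -> bool:
    lo, hi = bands[band] if isinstance(band, str) else band
    return lo <= f < hi


def simulate_cohort(config: SyntheticCohortConfig) -> list[EEGRecording]:
    """All pre and post recordings of the cohort, subject-major order."""
    out = []
    for i in range(config.n_subjects):
        out.append(simulate_subject(config, i, "pre"))
        out.append(simulate_subject(config, i, "post"))
    return out


# ---------------------------------------------------------------------------
# Writing (EDF / delimited) and manifests


def _fmt_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        if isinstance(value, float):
            for prec in range(6, 0, -1):
                s = f"{value:.{prec}g}"
                if len(s) <= width:
                    break
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: EEGRecording, path: str | os.PathLike) -> None:
    """Write a plain (continuous) 16-bit EDF file.

    One-second data records; a trailing partial second is truncated.
    Physical ranges are symmetric per channel, so round-trip error is
    bounded by the 16-bit quantization step.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per record (1 s records)
    n_records = rec.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record")
    ns = rec.n_channels

    phys_max = np.maximum(np.abs(rec.data).max(axis=1), 1.0) * 1.0001
    dig_max, dig_min = 32767, -32768

    header = b""
    header += _fmt_field("0", 8)
    header += _fmt_field(f"{rec.subject_id} {rec.condition}", 80)
    header += _fmt_field("synthetic EEG", 80)
    header += _fmt_field("01.01.20", 8)
    header += _fmt_field("00.00.00", 8)
    header += _fmt_field(256 * (ns + 1), 8)
    header += _fmt_field("", 44)
    header += _fmt_field(n_records, 8)
    header += _fmt_field(1, 8)
    header += _fmt_field(ns, 4)
    for lab in rec.channel_labels:
        header += _fmt_field(lab, 16)
    header += b"".join(_fmt_field("", 80) for _ in range(ns))
    header += b"".join(_fmt_field("uV", 8) for _ in range(ns))
    header += b"".join(_fmt_field(float(-p), 8) for p in phys_max)
    header += b"".join(_fmt_field(float(p), 8) for p in phys_max)
    header += b"".join(_fmt_field(dig_min, 8) for _ in range(ns))
    header += b"".join(_fmt_field(dig_max, 8) for _ in range(ns))
    header += b"".join(_fmt_field("", 80) for _ in range(ns))
    header += b"".join(_fmt_field(spr, 8) for _ in range(ns))
    header += b"".join(_fmt_field("", 32) for _ in range(ns))
    assert len(header) == 256 * (ns + 1)

    scale = phys_max / dig_max  # symmetric range: digital = physical / scale
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            sl = slice(r * spr, (r + 1) * spr)
            for ch in range(ns):
                digital = np.clip(
                    np.round(rec.data[ch, sl] / scale[ch]), dig_min, dig_max
                ).astype("<i2")
                fh.write(struct.pack(f"<{spr}h", *digital))


def write_delimited(rec: EEGRecording, path: str | os.PathLike) -> None:
    """Write a CSV with one column per channel, header row of labels."""
    pd.DataFrame(rec.data.T, columns=rec.channel_labels).to_csv(
        path, index=False, float_format="%.4f"
    )


def write_cohort(
    recordings: list[EEGRecording],
    directory: str | os.PathLike,
    format: str = "edf",
) -> str:
    """Write one file per recording plus a TSV manifest; returns its path."""
    directory = os.fspath(directory)
    if not os.path.isdir(directory):
        raise IOError(f"not a directory: {directory!r}")
    if format not in ("edf", "csv"):
        raise ValueError(f"unknown format {format!r}")
    rows = []
    for rec in recordings:
        fname = f"{rec.subject_id}_{rec.condition}.{format}"
        fpath = os.path.join(directory, fname)
        if format == "edf":
            write_edf(rec, fpath)
        else:
            write_delimited(rec, fpath)
        rows.append(
            {
                "subject": rec.subject_id,
                "condition": rec.condition,
                "path": fname,
                "fs": rec.fs,
            }
        )
    manifest = os.path.join(directory, "manifest.tsv")
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest
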
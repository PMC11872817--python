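"""End-to-end pre/post analysis: manifest -> features -> paired statistics.

The processing order is fixed: read, average reference, zero-phase
filtering (0.1 Hz high-pass, 50 Hz notch), amplitude-based artifact
screening, then feature extraction (region band power, region-pair band
coherence, Tsallis entropy, comodulograms) and paired Wilcoxon comparison.

Feature naming conventions in tables and results:

* power/entropy targets are region names (entropy adds ``"all"``);
* cross-region coherence pairs are ``"X:Y"``; a bare region name denotes
  within-region coherence, computed as the mean magnitude-squared
  coherence over the region's distinct channel pairs;
* cfc targets are ``"X->Y"`` (phase from X, amplitude from Y; both
  directions are computed for cross-region pairs) or a bare region name
  for within-region coupling; each grid cell is one feature with band
  label ``"<modulating>-<modulated>"`` in Hz.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import crossfreq, entropy, group_stats, spectral
from .io_preprocess import (
    DEFAULT_REGIONS,
    EEGRecording,
    RegionSet,
    apply_average_reference,
    apply_filters,
    read_recording,
    region_signal,
    segment_table,
    select_artifact_free,
)
from .spectral import DEFAULT_BANDS, BandSet

logger = logging.getLogger("eegprepost")

__all__ = ["AnalysisConfig", "preprocess", "extract_features", "analyze_cohort",
           "run_analysis", "run_simulate"]

#: Region-pair list for coherence (a single name = within-region).
DEFAULT_COHERENCE_PAIRS: tuple[tuple[str, str], ...] = (
    ("occipital", "occipital"),
    ("temporal", "temporal"),
    ("parietal", "frontal-complete"),
    ("frontal-complete", "frontal-complete"),
    ("parietal", "parietal"),
    ("parietal", "fronto-polar"),
    ("fronto-polar", "fronto-polar"),
    ("parietal", "temporal"),
    ("frontal-complete", "temporal"),
)

#: Region pairs for phase-amplitude coupling.
DEFAULT_CFC_PAIRS: tuple[tuple[str, str], ...] = (
    ("parietal", "fronto-polar"),
    ("temporal", "temporal"),
    ("fronto-polar", "fronto-polar"),
    ("frontal-complete", "temporal"),
    ("parietal", "temporal"),
)


@dataclass
class AnalysisConfig:
    """All tunable parameters of the analysis in one auditable place."""

    regions: RegionSet = field(default_factory=lambda: DEFAULT_REGIONS)
    bands: BandSet = field(default_factory=lambda: DEFAULT_BANDS)
    window_len: int = 512
    overlap: float = 0.5
    highpass_hz: float = 0.1
    notch_hz: float = 50.0
    amplitude_uV: float = 150.0
    pad_s: float = 0.5
    entropy_lengths: np.ndarray | None = None  # default: 100 lengths in [1, 500]
    min_entropy_segment: int = 500
    coherence_pairs: tuple[tuple[str, str], ...] = DEFAULT_COHERENCE_PAIRS
    cfc_pairs: tuple[tuple[str, str], ...] = DEFAULT_CFC_PAIRS
    include_cfc: bool = True
    modulating_centers: tuple[float, ...] = crossfreq.DEFAULT_MODULATING_CENTERS
    modulated_centers: tuple[float, ...] = crossfreq.DEFAULT_MODULATED_CENTERS
    alpha: float = 0.05
    trend_bound: float = 0.10
    fdr: bool = False
    exclude_notch_band: bool = False  # drop 48-52 Hz bins from band means
    save_curves: bool = True  # write spectra / coherence curve TSVs

    def __post_init__(self) -> None:
        if not self.alpha < self.trend_bound:
            raise ValueError("alpha must be below the trend bound")

    @property
    def band_exclude(self) -> tuple[float, float] | None:
        return (48.0, 52.0) if self.exclude_notch_band else None

    def describe(self) -> dict:
        return {
            "regions": {k: list(v) for k, v in self.regions.regions.items()},
            "bands": {k: list(v) for k, v in self.bands.bands.items()},
            "window_len": self.window_len,
            "overlap": self.overlap,
            "highpass_hz": self.highpass_hz,
            "notch_hz": self.notch_hz,
            "amplitude_uV": self.amplitude_uV,
            "coherence_pairs": [list(p) for p in self.coherence_pairs],
            "cfc_pairs": [list(p) for p in self.cfc_pairs],
            "include_cfc": self.include_cfc,
            "modulating_centers": list(self.modulating_centers),
            "modulated_centers": list(self.modulated_centers),
            "alpha": self.alpha,
            "trend_bound": self.trend_bound,
            "fdr": self.fdr,
            "exclude_notch_band": self.exclude_notch_band,
        }


def preprocess(rec: EEGRecording, cfg: AnalysisConfig | None = None) -> EEGRecording:
    """Average reference, zero-phase filters, artifact screening (in order)."""
    cfg = cfg or AnalysisConfig()
    rec = apply_average_reference(rec)
    rec = apply_filters(rec, cfg.highpass_hz, cfg.notch_hz)
    rec = select_artifact_free(rec, cfg.amplitude_uV, cfg.pad_s)
    return rec


# ---------------------------------------------------------------------------
# Vectorized spectral helpers (one Welch/CSD call per segment for all
# signals/pairs; numerically identical to the per-signal public API).


def _segment_slices(rec: EEGRecording) -> list[tuple[int, int]]:
    return rec.retained_segments()


def _welch_stack(segments: list[np.ndarray], fs, window_len, overlap):
    """Weighted Welch average for a stack of aligned signals.

    ``segments``: list of (n_signals, seg_len) arrays.  Returns
    (freqs, psd (n_signals, n_freqs), total windows).
    """
    step = window_len - int(window_len * overlap)
    kw = dict(fs=fs, window="hann", nperseg=window_len,
              noverlap=int(window_len * overlap), detrend="constant",
              scaling="density", axis=-1)
    acc, freqs, total = None, None, 0
    for seg in segments:
        if seg.shape[-1] < window_len:
            continue
        k = 1 + (seg.shape[-1] - window_len) // step
        f, p = sps.welch(seg, **kw)
        acc = k * p if acc is None else acc + k * p
        freqs, total = f, total + k
    if total == 0:
        raise ValueError("no retained segment reaches the window length")
    return freqs, acc / total, total


def _csd_stack(segments_x, segments_y, fs, window_len, overlap):
    step = window_len - int(window_len * overlap)
    kw = dict(fs=fs, window="hann", nperseg=window_len,
              noverlap=int(window_len * overlap), detrend="constant",
              scaling="density", axis=-1)
    acc, total = None, 0
    for sx, sy in zip(segments_x, segments_y):
        if sx.shape[-1] < window_len:
            continue
        k = 1 + (sx.shape[-1] - window_len) // step
        _, p = sps.csd(sx, sy, **kw)
        acc = k * p if acc is None else acc + k * p
        total += k
    return acc / total, total


def extract_features(rec: EEGRecording, cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Long-format feature table for one preprocessed recording."""
    cfg = cfg or AnalysisConfig()
    cfg.regions.validate_montage(rec.channel_labels)
    fs = rec.fs
    slices = _segment_slices(rec)
    rows: list[dict] = []

    # --- band power (per-channel spectra, region means) ---
    segs = [rec.data[:, a:b] for a, b in slices]
    freqs, psd, _ = _welch_stack(segs, fs, cfg.window_len, cfg.overlap)
    spectra = {
        ch: spectral.PowerSpectrum(freqs, psd[i], 1)
        for i, ch in enumerate(rec.channel_labels)
    }
    for region in cfg.regions.names():
        for band in cfg.bands.names():
            rows.append(
                {
                    "feature_kind": "power",
                    "region_or_pair": region,
                    "band": band,
                    "value": spectral.band_power(
                        spectra, cfg.regions, region, band, cfg.bands,
                        exclude=cfg.band_exclude,
                    ),
                }
            )

    # --- coherence (region-average signals; channel pairs within region) ---
    region_sigs = {
        name: region_signal(rec, cfg.regions, name) for name in cfg.regions.names()
    }
    idx_of = {c: i for i, c in enumerate(rec.channel_labels)}
    pair_rows_x, pair_rows_y, pair_meta = [], [], []
    for x, y in cfg.coherence_pairs:
        if x == y:
            chans = [c for c in cfg.regions[x] if c in idx_of]
            for a, b in itertools.combinations(chans, 2):
                pair_rows_x.append(("chan", idx_of[a]))
                pair_rows_y.append(("chan", idx_of[b]))
                pair_meta.append(x)
        else:
            pair_rows_x.append(("region", x))
            pair_rows_y.append(("region", y))
            pair_meta.append(f"{x}:{y}")

    def _stack_for(rowspec):
        out = []
        for si, (a, b) in enumerate(slices):
            mat = np.empty((len(rowspec), b - a))
            for r, (kind, key) in enumerate(rowspec):
                if kind == "chan":
                    mat[r] = rec.data[key, a:b]
                else:
                    bounds = region_sigs[key].segment_bounds[si]
                    mat[r] = region_sigs[key].samples[bounds[0]: bounds[1]]
            out.append(mat)
        return out

    if pair_meta:
        sx, sy = _stack_for(pair_rows_x), _stack_for(pair_rows_y)
        _, pxx, _ = _welch_stack(sx, fs, cfg.window_len, cfg.overlap)
        _, pyy, _ = _welch_stack(sy, fs, cfg.window_len, cfg.overlap)
        pxy, total = _csd_stack(sx, sy, fs, cfg.window_len, cfg.overlap)
        if total < 2:
            raise ValueError("coherence needs at least 2 windows")
        msc = np.abs(pxy) ** 2 / (pxx * pyy)
        # average curves over within-region channel pairs
        curves: dict[str, list[np.ndarray]] = {}
        for name, row in zip(pair_meta, msc):
            curves.setdefault(name, []).append(row)
        for name, rows_ in curves.items():
            curve = np.mean(rows_, axis=0)
            pair = spectral.CoherencePair("", "", freqs, curve, total)
            for band in cfg.bands.names():
                rows.append(
                    {
                        "feature_kind": "coherence",
                        "region_or_pair": name,
                        "band": band,
                        "value": spectral.band_coherence(
                            pair, band, cfg.bands, exclude=cfg.band_exclude
                        ),
                    }
                )

    # --- Tsallis entropy (regions + all channels) ---
    ent = entropy.entropy_table(
        rec, cfg.regions, cfg.entropy_lengths, cfg.min_entropy_segment
    )
    region_scopes = set(cfg.regions.names()) | {"all"}
    for res in ent:
        if res.scope in region_scopes:
            rows.append(
                {
                    "feature_kind": "entropy",
                    "region_or_pair": res.scope,
                    "band": "broadband",
                    "value": res.value,
                }
            )

    # --- phase-amplitude coupling comodulograms ---
    if cfg.include_cfc:
        for x, y in cfg.cfc_pairs:
            directions = [(x, y)] if x == y else [(x, y), (y, x)]
            for px, py in directions:
                grid = crossfreq.cfc_grid(
                    region_sigs[px],
                    region_sigs[py],
                    cfg.modulating_centers,
                    cfg.modulated_centers,
                )
                name = px if px == py else f"{px}->{py}"
                for i, fp in enumerate(grid.modulating_centers):
                    for j, fa in enumerate(grid.modulated_centers):
                        rows.append(
                            {
                                "feature_kind": "cfc",
                                "region_or_pair": name,
                                "band": f"{fp:g}-{fa:g}",
                                "value": grid.mi[i, j],
                            }
                        )

    frame = pd.DataFrame(rows)
    frame.insert(0, "subject_id", rec.subject_id)
    frame.insert(1, "condition", rec.condition)
    return frame


def curve_tables(
    rec: EEGRecording, cfg: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format per-channel spectra and per-pair coherence curves.

    Returns ``(spectra, coherence)`` frames with columns
    (subject, condition, channel|pair, frequency, value) for export
    alongside the scalar feature table.
    """
    cfg = cfg or AnalysisConfig()
    fs = rec.fs
    slices = _segment_slices(rec)
    segs = [rec.data[:, a:b] for a, b in slices]
    freqs, psd, _ = _welch_stack(segs, fs, cfg.window_len, cfg.overlap)
    spectra = pd.concat(
        [
            pd.DataFrame(
                {
                    "subject": rec.subject_id,
                    "condition": rec.condition,
                    "channel": ch,
                    "frequency": freqs,
                    "value": psd[i],
                }
            )
            for i, ch in enumerate(rec.channel_labels)
        ],
        ignore_index=True,
    )

    region_sigs = {
        name: region_signal(rec, cfg.regions, name) for name in cfg.regions.names()
    }
    idx_of = {c: i for i, c in enumerate(rec.channel_labels)}
    frames = []
    for x, y in cfg.coherence_pairs:
        if x == y:
            chans = [c for c in cfg.regions[x] if c in idx_of]
            curves = []
            for a, b in itertools.combinations(chans, 2):
                pair = spectral.coherence(
                    _chan_region_signal(rec, a),
                    _chan_region_signal(rec, b),
                    window_len=cfg.window_len,
                    overlap=cfg.overlap,
                )
                curves.append(pair.coherence)
            curve, name = np.mean(curves, axis=0), x
            f = pair.frequencies
        else:
            pair = spectral.coherence(
                region_sigs[x], region_sigs[y],
                window_len=cfg.window_len, overlap=cfg.overlap,
            )
            curve, name, f = pair.coherence, f"{x}:{y}", pair.frequencies
        frames.append(
            pd.DataFrame(
                {
                    "subject": rec.subject_id,
                    "condition": rec.condition,
                    "pair": name,
                    "frequency": f,
                    "value": curve,
                }
            )
        )
    return spectra, pd.concat(frames, ignore_index=True)


def _chan_region_signal(rec: EEGRecording, label: str):
    from .io_preprocess import channel_signal

    return channel_signal(rec, label)


def analyze_cohort(
    recordings: list[EEGRecording],
    cfg: AnalysisConfig | None = None,
    do_preprocess: bool = True,
) -> tuple[pd.DataFrame, list[group_stats.PairedTestResult]]:
    """Features plus paired statistics for an in-memory cohort."""
    cfg = cfg or AnalysisConfig()
    tables = []
    for rec in recordings:
        proc = preprocess(rec, cfg) if do_preprocess else rec
        tables.append(extract_features(proc, cfg))
    features = pd.concat(tables, ignore_index=True)
    results = group_stats.compare_all(
        features[features["condition"] == "pre"],
        features[features["condition"] == "post"],
        alpha=cfg.alpha,
        trend_bound=cfg.trend_bound,
        fdr=cfg.fdr,
    )
    return features, results


# ---------------------------------------------------------------------------
# Manifest-driven run


def _load_manifest(manifest_path: str) -> pd.DataFrame:
    mf = pd.read_csv(manifest_path, sep="\t")
    required = {"subject", "condition", "path"}
    if not required.issubset(mf.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    counts = mf.groupby(["subject", "condition"]).size()
    if (counts != 1).any():
        raise ValueError("manifest must list each subject/condition exactly once")
    by_subject = mf.groupby("subject")["condition"].agg(set)
    bad = [s for s, conds in by_subject.items() if conds != {"pre", "post"}]
    if bad:
        raise ValueError(f"subjects without a complete pre/post pair: {bad}")
    base = os.path.dirname(os.path.abspath(manifest_path))
    for p in mf["path"]:
        full = p if os.path.isabs(p) else os.path.join(base, p)
        if not os.path.exists(full):
            row = mf[mf["path"] == p].iloc[0]
            raise FileNotFoundError(
                f"missing recording for subject {row['subject']} ({row['condition']}): {full}"
            )
    return mf


def run_analysis(
    manifest_path: str,
    cfg: AnalysisConfig | None = None,
    out_dir: str = "results",
    seed: int | None = None,
) -> dict:
    """Run the full pipeline from a manifest; write tables under `out_dir`.

    Failing subjects are collected and reported; the run continues as long
    as at least two complete pairs survive.  Outputs: ``features.tsv``,
    ``results.tsv``/``results.json``, ``segments.tsv``, per-pair cfc masks,
    and ``run_log.json`` recording every parameter actually used.
    """
    cfg = cfg or AnalysisConfig()
    mf = _load_manifest(manifest_path)
    base = os.path.dirname(os.path.abspath(manifest_path))
    os.makedirs(out_dir, exist_ok=True)

    processed: list[EEGRecording] = []
    failures: dict[str, str] = {}
    for subject, group in mf.groupby("subject", sort=True):
        try:
            pair = []
            for _, row in group.iterrows():
                p = row["path"]
                full = p if os.path.isabs(p) else os.path.join(base, p)
                rec = read_recording(
                    full,
                    fs=row.get("fs"),
                    subject_id=str(subject),
                    condition=str(row["condition"]),
                )
                pair.append(preprocess(rec, cfg))
            processed.extend(pair)
        except Exception as exc:
            failures[str(subject)] = str(exc)
            logger.warning("subject %s failed: %s", subject, exc)
    n_pairs = len(processed) // 2
    if n_pairs < 2:
        raise RuntimeError(
            f"fewer than 2 complete subject pairs survived preprocessing; "
            f"failures: {failures}"
        )

    features, results = analyze_cohort(processed, cfg, do_preprocess=False)
    res_frame = group_stats.results_frame(results)

    if cfg.save_curves:
        spectra_frames, coh_frames = [], []
        for rec in processed:
            sf, cf = curve_tables(rec, cfg)
            spectra_frames.append(sf)
            coh_frames.append(cf)
        pd.concat(spectra_frames, ignore_index=True).to_csv(
            os.path.join(out_dir, "spectra.tsv"), sep="\t", index=False
        )
        pd.concat(coh_frames, ignore_index=True).to_csv(
            os.path.join(out_dir, "coherence_curves.tsv"), sep="\t", index=False
        )

    features.to_csv(os.path.join(out_dir, "features.tsv"), sep="\t", index=False)
    res_frame.to_csv(os.path.join(out_dir, "results.tsv"), sep="\t", index=False)
    res_frame.to_json(
        os.path.join(out_dir, "results.json"), orient="records", indent=2
    )
    segment_table(processed).to_csv(
        os.path.join(out_dir, "segments.tsv"), sep="\t", index=False
    )
    if cfg.include_cfc:
        for name in sorted(
            res_frame.loc[res_frame["feature_kind"] == "cfc", "region_or_pair"].unique()
        ):
            mask = group_stats.cfc_significance_mask(results, name)
            safe = name.replace("->", "_to_").replace(":", "_")
            mask.to_csv(os.path.join(out_dir, f"cfc_mask_{safe}.tsv"), sep="\t")

    log = {
        "config": cfg.describe(),
        "config_hash": hashlib.sha256(
            json.dumps(cfg.describe(), sort_keys=True).encode()
        ).hexdigest()[:16],
        "seed": seed,
        "n_subjects": n_pairs,
        "failures": failures,
        "n_features": int(len(res_frame)),
        "n_significant": int(res_frame["significant"].sum()),
    }
    with open(os.path.join(out_dir, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=2)
    logger.info(
        "analysis complete: %d subjects, %d features, %d significant",
        n_pairs, log["n_features"], log["n_significant"],
    )
    return log


def run_simulate(config, out_dir: str, format: str = "edf") -> str:
    """Simulate a cohort and write it with a manifest; returns manifest path."""
    from .synthetic import simulate_cohort, write_cohort

    os.makedirs(out_dir, exist_ok=True)
    cohort = simulate_cohort(config)
    return write_cohort(cohort, out_dir, format=format)
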
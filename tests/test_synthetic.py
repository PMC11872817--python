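import os

import numpy as np
import pandas as pd
import pytest

from eegprepost import (
    AnalysisConfig,
    SyntheticCohortConfig,
    extract_features,
    pac_component,
    pink_noise,
    preprocess,
    read_recording,
    simulate_cohort,
    simulate_subject,
    write_cohort,
)
from eegprepost.crossfreq import cfc_grid
from eegprepost.io_preprocess import RegionSignal
from eegprepost.synthetic import PacSpec, PlantedEffect


def spectral_slope(x, fs=200.0, fmin=1.0, fmax=80.0):
    """Log-log periodogram regression slope: the 1/f exponent oracle."""
    from scipy import signal as sps

    f, p = sps.welch(x, fs=fs, nperseg=1024)
    sel = (f >= fmin) & (f <= fmax)
    return np.polyfit(np.log10(f[sel]), np.log10(p[sel]), 1)[0]


class TestPinkNoise:
    def test_white_spectrum_flat(self):
        x = pink_noise(200_000, 0.0, 1.0, seed=0)
        assert abs(spectral_slope(x)) < 0.15

    def test_one_over_f_slope(self):
        x = pink_noise(200_000, 1.0, 1.0, seed=0)
        assert spectral_slope(x) == pytest.approx(-1.0, abs=0.15)

    def test_requested_rms(self):
        x = pink_noise(50_000, 1.0, 12.5, seed=1)
        assert x.std() == pytest.approx(12.5, rel=1e-9)

    def test_deterministic_under_seed(self):
        np.testing.assert_array_equal(
            pink_noise(1000, 1.0, 1.0, seed=5), pink_noise(1000, 1.0, 1.0, seed=5)
        )

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            pink_noise(1000, 3.0, 1.0)


class TestPacComponent:
    def test_frequency_order_enforced(self):
        with pytest.raises(ValueError):
            pac_component(1000, 200.0, 60.0, 6.0, 0.5)

    def test_depth_zero_no_coupling(self):
        rng = np.random.default_rng(2)
        x = pac_component(24_000, 200.0, 6.0, 60.0, 0.0, rms=8.0, seed=rng)
        x = x + pink_noise(24_000, 1.0, 4.0, rng)
        from eegprepost.crossfreq import analytic_amplitude, analytic_phase, surrogate_zscore

        ph = analytic_phase(x, (5.0, 7.0), fs=200.0)
        am = analytic_amplitude(x, (49.0, 71.0), fs=200.0)
        am = am[(len(am) - len(ph)) // 2 :][: len(ph)]
        assert abs(surrogate_zscore(ph, am, n_surrogates=200, seed=0)) < 4

    def test_depth_one_localizes(self):
        rng = np.random.default_rng(3)
        x = pac_component(12_000, 200.0, 6.0, 60.0, 1.0, rms=8.0, seed=rng)
        x = x + pink_noise(12_000, 1.0, 8.0, rng)
        sig = RegionSignal("x", 200.0, x)
        assert cfc_grid(sig, sig).argmax_cell() == (6.0, 60.0)

    def test_mi_monotone_in_depth(self):
        from eegprepost.crossfreq import modulation_index

        mis = []
        for depth in (0.2, 0.8):
            x = pac_component(24_000, 200.0, 6.0, 60.0, depth, rms=8.0, seed=17)
            mis.append(modulation_index(x, x, (5.0, 7.0), (49.0, 71.0), fs=200.0))
        assert mis[1] > mis[0]


class TestSimulateSubject:
    def test_default_cohort_shape(self):
        cfg = SyntheticCohortConfig(duration_s=10)
        rec = simulate_subject(cfg, 0, "pre")
        assert rec.data.shape == (21, 2000)
        assert rec.fs == 200.0
        cohort = simulate_cohort(cfg)
        assert len(cohort) == 20
        assert {r.condition for r in cohort} == {"pre", "post"}

    def test_deterministic_under_seed(self):
        cfg = SyntheticCohortConfig(duration_s=5, seed=11)
        a = simulate_subject(cfg, 3, "post")
        b = simulate_subject(cfg, 3, "post")
        np.testing.assert_array_equal(a.data, b.data)

    def test_subjects_and_conditions_differ(self):
        cfg = SyntheticCohortConfig(duration_s=5, seed=11)
        a = simulate_subject(cfg, 0, "pre")
        b = simulate_subject(cfg, 1, "pre")
        c = simulate_subject(cfg, 0, "post")
        assert not np.allclose(a.data, b.data)
        assert not np.allclose(a.data, c.data)

    def test_null_config_pre_post_same_distribution(self):
        # without effects, post differs in realization but not in scale
        cfg = SyntheticCohortConfig(duration_s=10, seed=4)
        pre = simulate_subject(cfg, 0, "pre")
        post = simulate_subject(cfg, 0, "post")
        assert post.data.std() == pytest.approx(pre.data.std(), rel=0.1)

    def test_power_effect_realized_ratio(self):
        # x1.3 planted on occipital beta-gamma: realized post/pre band-power
        # ratio averaged over 10 subjects stays near the multiplier
        eff = (PlantedEffect("power", "occipital", band="beta-gamma", multiplier=1.3),)
        cfg = SyntheticCohortConfig(duration_s=10, seed=42, effects=eff)
        acfg = AnalysisConfig(include_cfc=False)
        ratios = []
        for i in range(10):
            vals = {}
            for cond in ("pre", "post"):
                feats = extract_features(preprocess(simulate_subject(cfg, i, cond)), acfg)
                sel = (
                    (feats.feature_kind == "power")
                    & (feats.region_or_pair == "occipital")
                    & (feats.band == "beta-gamma")
                )
                vals[cond] = feats.loc[sel, "value"].iloc[0]
            ratios.append(vals["post"] / vals["pre"])
        assert 1.15 < np.mean(ratios) < 1.45

    def test_coherence_effect_shifts_band_coherence(self):
        eff = (PlantedEffect("coherence", "occipital", band="alpha", multiplier=0.3),)
        cfg = SyntheticCohortConfig(duration_s=20, seed=8, effects=eff)
        acfg = AnalysisConfig(include_cfc=False)
        diffs = []
        for i in range(5):
            vals = {}
            for cond in ("pre", "post"):
                feats = extract_features(preprocess(simulate_subject(cfg, i, cond)), acfg)
                sel = (
                    (feats.feature_kind == "coherence")
                    & (feats.region_or_pair == "occipital")
                    & (feats.band == "alpha")
                )
                vals[cond] = feats.loc[sel, "value"].iloc[0]
            diffs.append(vals["post"] - vals["pre"])
        assert np.mean(diffs) < -0.05  # weakened shared source lowers coherence

    def test_entropy_effect_raises_te(self):
        eff = (PlantedEffect("entropy", "temporal", multiplier=3.0),)
        cfg = SyntheticCohortConfig(duration_s=10, seed=9, effects=eff)
        acfg = AnalysisConfig(include_cfc=False)
        diffs = []
        for i in range(5):
            vals = {}
            for cond in ("pre", "post"):
                feats = extract_features(preprocess(simulate_subject(cfg, i, cond)), acfg)
                sel = (feats.feature_kind == "entropy") & (feats.region_or_pair == "temporal")
                vals[cond] = feats.loc[sel, "value"].iloc[0]
            diffs.append(vals["post"] - vals["pre"])
        assert np.mean(diffs) > 0.01

    def test_cfc_effect_raises_mi(self):
        pac = (PacSpec("temporal", "temporal", 6.0, 60.0, 0.1, rms_uV=8.0),)
        eff = (PlantedEffect("cfc", "temporal", depth_delta=0.9),)
        cfg = SyntheticCohortConfig(duration_s=30, seed=10, pac=pac, effects=eff)
        from eegprepost.io_preprocess import DEFAULT_REGIONS, region_signal

        mis = {}
        for cond in ("pre", "post"):
            rec = preprocess(simulate_subject(cfg, 0, cond))
            sig = region_signal(rec, DEFAULT_REGIONS, "temporal")
            grid = cfc_grid(sig, sig)
            i = list(grid.modulating_centers).index(6.0)
            j = list(grid.modulated_centers).index(60.0)
            mis[cond] = grid.mi[i, j]
        assert mis["post"] > 2 * mis["pre"]

    def test_spikes_injected_for_artifact_tests(self):
        cfg = SyntheticCohortConfig(duration_s=10, seed=2, n_spikes=3, spike_uV=600)
        rec = simulate_subject(cfg, 0, "pre")
        assert np.abs(rec.data).max() > 300


class TestWriteCohort:
    def test_edf_roundtrip_within_quantization(self, tmp_path):
        cfg = SyntheticCohortConfig(duration_s=5, n_subjects=1, seed=3)
        rec = simulate_subject(cfg, 0, "pre")
        manifest = write_cohort([rec], tmp_path, format="edf")
        mf = pd.read_csv(manifest, sep="\t")
        back = read_recording(
            os.path.join(tmp_path, mf.loc[0, "path"]),
            subject_id="S01", condition="pre",
        )
        assert back.channel_labels == rec.channel_labels
        assert back.fs == rec.fs
        qstep = (np.abs(rec.data).max(axis=1) * 1.0001 / 32767).max()
        assert np.abs(back.data - rec.data).max() <= 2 * qstep

    def test_csv_roundtrip(self, tmp_path):
        cfg = SyntheticCohortConfig(duration_s=5, n_subjects=1, seed=3)
        rec = simulate_subject(cfg, 0, "post")
        write_cohort([rec], tmp_path, format="csv")
        back = read_recording(tmp_path / "S01_post.csv", fs=200.0)
        np.testing.assert_allclose(back.data, rec.data, atol=1e-3)

    def test_manifest_row_count(self, tmp_path):
        cfg = SyntheticCohortConfig(duration_s=5, n_subjects=3, seed=0)
        manifest = write_cohort(simulate_cohort(cfg), tmp_path, format="csv")
        mf = pd.read_csv(manifest, sep="\t")
        assert len(mf) == 6

    def test_missing_directory_rejected(self, tmp_path):
        cfg = SyntheticCohortConfig(duration_s=5, n_subjects=1, seed=0)
        with pytest.raises(IOError):
            write_cohort(simulate_cohort(cfg), tmp_path / "nope", format="csv")
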
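import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eegprepost import (
    compare_all,
    effect_size_r,
    normality_screen,
    results_frame,
    wilcoxon_signed_rank,
)
from eegprepost.group_stats import cfc_significance_mask


def dataset_with_negative_ranksum_3(n=10):
    """Tie-free paired data whose single negative difference has rank 3."""
    pre = np.arange(1.0, n + 1)
    diffs = np.array([1, 2, -2.5, 4, 5, 6, 7, 8, 9, 10], dtype=float)
    return pre, pre + diffs


class TestWilcoxon:
    def test_single_negative_difference_rank_three(self):
        pre, post = dataset_with_negative_ranksum_3()
        W, Z, p = wilcoxon_signed_rank(pre, post)
        assert W == 3
        assert abs(Z) == pytest.approx(2.4973, abs=1e-4)
        assert p == pytest.approx(0.0125, abs=1e-3)  # printed as 0.013

    def test_uniform_shift_tie_corrected(self):
        # all |differences| tied: variance 96.25 - 20.625 = 75.625
        pre = np.arange(1.0, 11.0)
        W, Z, p = wilcoxon_signed_rank(pre, pre + 1)
        assert W == 0
        assert abs(Z) == pytest.approx(27.5 / np.sqrt(75.625), abs=1e-4)
        ref = stats.wilcoxon(pre + 1, pre, correction=False, method="approx")
        assert Z == pytest.approx(ref.zstatistic, abs=1e-10)

    def test_matches_scipy_on_random_data(self, rng):
        for _ in range(10):
            pre = rng.standard_normal(15)
            post = pre + rng.standard_normal(15) * 0.5 + 0.2
            W, Z, p = wilcoxon_signed_rank(pre, post)
            ref = stats.wilcoxon(post, pre, correction=False, method="approx")
            # scipy's two-sided zstatistic is the always-negative min-rank-sum
            # convention; ours is signed by direction of change
            assert abs(Z) == pytest.approx(abs(ref.zstatistic), abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_antisymmetry(self, rng):
        pre = rng.standard_normal(12)
        post = pre + rng.standard_normal(12)
        W1, Z1, p1 = wilcoxon_signed_rank(pre, post)
        W2, Z2, p2 = wilcoxon_signed_rank(post, pre)
        assert Z1 == pytest.approx(-Z2)
        assert W1 == W2
        assert p1 == pytest.approx(p2)

    def test_exhaustive_sign_enumeration_n8(self):
        # tie-free n=8: ranks are 1..8, so the null distribution of the
        # smaller rank sum is fully enumerable over all 2^8 sign patterns.
        # The uncorrected normal approximation estimates the mid-p exact
        # probability (half weight on the observed value).
        ranks = np.arange(1, 9)
        w_null = []
        for signs in itertools.product([1, -1], repeat=8):
            s = np.array(signs)
            w_null.append(
                min(ranks[s > 0].sum(initial=0), ranks[s < 0].sum(initial=0))
            )
        w_null = np.array(w_null)
        worst = 0.0
        for signs in itertools.product([1, -1], repeat=8):
            s = np.array(signs)
            diffs = s * ranks.astype(float)
            _, _, p_approx = wilcoxon_signed_rank(np.zeros(8), diffs)
            w_obs = min(ranks[s > 0].sum(initial=0), ranks[s < 0].sum(initial=0))
            p_exact = float((w_null < w_obs).mean() + 0.5 * (w_null == w_obs).mean())
            worst = max(worst, abs(p_approx - p_exact))
        assert worst <= 0.03

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0], [2.0])
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0, 3.0])


class TestEffectSize:
    @pytest.mark.parametrize(
        "z,expected",
        [(-2.4973, 0.7897), (-2.5992, 0.8219), (2.2934, 0.7252),
         (1.9876, 0.6285), (2.0896, 0.6608), (-1.8869, 0.5967)],
    )
    def test_reported_effect_sizes_n10(self, z, expected):
        assert abs(effect_size_r(z, 10)) == pytest.approx(expected, abs=5e-5)

    def test_zero_statistic(self):
        assert effect_size_r(0.0, 7) == 0.0

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            effect_size_r(1.0, 0)


class TestNormalityScreen:
    def test_normal_sample_passes(self):
        x = np.random.default_rng(1).standard_normal(1000)
        _, p = normality_screen(x)
        assert p > 0.05

    def test_skewed_sample_fails(self):
        x = np.random.default_rng(2).exponential(1.0, 1000)
        _, p = normality_screen(x)
        assert p < 0.001

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            normality_screen(np.full(10, 2.0))


def _feature_table(values: dict, condition: str) -> pd.DataFrame:
    rows = []
    for (kind, target, band), subj_vals in values.items():
        for i, v in enumerate(subj_vals):
            rows.append(
                {
                    "subject_id": f"S{i:02d}",
                    "condition": condition,
                    "feature_kind": kind,
                    "region_or_pair": target,
                    "band": band,
                    "value": v,
                }
            )
    return pd.DataFrame(rows)


class TestCompareAll:
    def test_identical_tables_non_testable(self, rng):
        vals = {("power", "occipital", "alpha"): rng.random(10)}
        pre = _feature_table(vals, "pre")
        post = _feature_table(vals, "post")
        results = compare_all(pre, post)
        assert len(results) == 1
        assert not results[0].testable
        assert not results[0].significant

    def test_planted_shift_detected_and_r_identity(self, rng):
        base = rng.random(10)
        pre = _feature_table({("power", "occipital", "beta"): base,
                              ("power", "parietal", "beta"): rng.random(10)}, "pre")
        post_vals = {("power", "occipital", "beta"): base + 1.0,
                     ("power", "parietal", "beta"): pre[pre.region_or_pair == "parietal"]["value"].to_numpy() + rng.normal(0, 0.2, 10)}
        post = _feature_table(post_vals, "post")
        results = compare_all(pre, post)
        by_key = {(r.region_or_pair): r for r in results}
        assert by_key["occipital"].significant
        for r in results:
            if r.testable:
                assert abs(r.r) == pytest.approx(abs(r.Z) / np.sqrt(10), abs=1e-12)

    def test_subject_mismatch_rejected(self, rng):
        pre = _feature_table({("power", "occipital", "alpha"): rng.random(10)}, "pre")
        post = _feature_table({("power", "occipital", "alpha"): rng.random(9)}, "post")
        with pytest.raises(ValueError, match="subject sets"):
            compare_all(pre, post)

    def test_fdr_flag_adjusts(self, rng):
        vals = {("power", f"r{i}", "alpha"): rng.random(10) for i in range(20)}
        pre = _feature_table(vals, "pre")
        post_vals = {k: v + rng.normal(0, 0.3, 10) for k, v in vals.items()}
        post = _feature_table(post_vals, "post")
        results = compare_all(pre, post, fdr=True)
        assert all(r.p_adjusted is not None for r in results if r.testable)
        assert all(r.p_adjusted >= r.p - 1e-12 for r in results if r.testable)

    def test_results_frame_rounds_r(self, rng):
        base = rng.random(10)
        pre = _feature_table({("entropy", "all", "broadband"): base}, "pre")
        post = _feature_table({("entropy", "all", "broadband"): base + 0.1}, "post")
        frame = results_frame(compare_all(pre, post))
        assert frame.loc[0, "r"] == round(frame.loc[0, "r"], 4)

    def test_cfc_mask_shape_and_values(self, rng):
        cells = {("cfc", "temporal", f"{fp}-{fa}"): rng.random(10)
                 for fp in (1, 2) for fa in (20, 25)}
        pre = _feature_table(cells, "pre")
        post = _feature_table({k: v + 0.5 for k, v in cells.items()}, "post")
        results = compare_all(pre, post)
        mask = cfc_significance_mask(results, "temporal")
        assert mask.shape == (2, 2)
        assert set(np.unique(mask.values)) <= {0, 1}
        assert mask.values.sum() == 4  # +0.5 shift on every cell is significant
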
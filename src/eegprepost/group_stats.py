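"""Paired pre/post comparison: Wilcoxon signed-rank, Z, p, and r = Z/sqrt(n).

Every scalar feature (region band power, band coherence, Tsallis entropy,
comodulogram cell) is compared across conditions with the Wilcoxon
signed-rank test for paired samples.  Zero differences are dropped, ties in
|difference| receive midranks, W is the smaller of the two rank sums, and
the normal approximation

    Z = (W - m(m+1)/4) / sqrt(m(m+1)(2m+1)/24 - sum(t^3 - t)/48)

is used without continuity correction (m = number of non-zero pairs; t the
tie-group sizes).  Z is signed: negative when the post values dominate
(sum of negative-difference ranks is the smaller), positive otherwise.  The
effect size is r = Z / sqrt(n) with n the number of pairs.  A one-sample
Kolmogorov-Smirnov screen on the standardized differences is reported
alongside but never gates the nonparametric test.  No multiple-comparison
correction is applied by default; Benjamini-Hochberg is available as a
flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedTestResult",
    "wilcoxon_signed_rank",
    "effect_size_r",
    "normality_screen",
    "compare_all",
    "results_frame",
    "cfc_significance_mask",
]

ALPHA_DEFAULT = 0.05
TREND_DEFAULT = 0.10


@dataclass
class PairedTestResult:
    """Wilcoxon outcome for one feature.

    ``W`` is the smaller signed-rank sum; ``Z`` the approximate statistic
    (signed by direction of change); ``r = Z / sqrt(n)``.  ``testable`` is
    False when every difference was zero.
    """

    feature_kind: str
    region_or_pair: str
    band: str
    n: int
    W: float
    Z: float
    p: float
    r: float
    significant: bool
    trend: bool
    testable: bool = True
    p_adjusted: float | None = None


def wilcoxon_signed_rank(pre, post) -> tuple[float, float, float]:
    """Paired Wilcoxon signed-rank test with normal approximation.

    Returns ``(W, Z, p)``: the smaller rank sum, the signed tie-corrected
    Z without continuity correction, and the two-sided normal-tail p.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    if len(pre) < 2:
        raise ValueError("need at least 2 pairs")
    d = post - pre
    d = d[d != 0]
    m = len(d)
    if m == 0:
        raise ValueError("degenerate data: all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    W = min(w_plus, w_minus)
    mean = m * (m + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / 48.0
    var = m * (m + 1) * (2 * m + 1) / 24.0 - tie_term
    if var <= 0:
        raise ValueError("degenerate data: zero variance of the rank statistic")
    zmag = (mean - W) / math.sqrt(var)
    # Negative Z when the increase direction dominates (negative ranks are
    # the smaller sum), positive when the decrease direction dominates.
    if w_minus < w_plus:
        Z = -zmag
    elif w_plus < w_minus:
        Z = zmag
    else:
        Z = 0.0
    p = min(1.0, 2.0 * stats.norm.sf(zmag))
    return W, Z, p


def effect_size_r(Z: float, n: int) -> float:
    """Effect size r = Z / sqrt(n) for a rank test with n pairs."""
    if n < 1:
        raise ValueError("n must be at least 1")
    return float(Z) / math.sqrt(n)


def normality_screen(diffs) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test of standardized differences.

    Standardizes the paired differences and compares them with the
    standard normal.  Reported alongside the Wilcoxon result; a rejection
    motivates the nonparametric test but does not alter it.
    """
    d = np.asarray(diffs, dtype=float)
    if len(d) < 3:
        raise ValueError("need at least 3 differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate data: constant differences")
    z = (d - d.mean()) / sd
    res = stats.kstest(z, "norm")
    return float(res.statistic), float(res.pvalue)


_KEY = ["feature_kind", "region_or_pair", "band"]


def compare_all(
    features_pre: pd.DataFrame,
    features_post: pd.DataFrame,
    alpha: float = ALPHA_DEFAULT,
    trend_bound: float = TREND_DEFAULT,
    fdr: bool = False,
) -> list[PairedTestResult]:
    """One paired Wilcoxon test per feature of a long-format feature table.

    Both tables need columns ``subject_id, feature_kind, region_or_pair,
    band, value`` and matching subject sets.  Features whose differences
    are all zero are returned as non-testable rather than raising.  With
    ``fdr=True``, Benjamini-Hochberg adjusted p-values drive the
    significance flags.
    """
    pre_subj = set(features_pre["subject_id"])
    post_subj = set(features_post["subject_id"])
    if pre_subj != post_subj:
        missing = sorted(pre_subj.symmetric_difference(post_subj))
        raise ValueError(f"subject sets differ between conditions: {missing}")

    pre_piv = features_pre.pivot_table(
        index=_KEY, columns="subject_id", values="value", sort=False
    )
    post_piv = features_post.pivot_table(
        index=_KEY, columns="subject_id", values="value", sort=False
    )
    post_piv = post_piv.reindex(index=pre_piv.index, columns=pre_piv.columns)
    if post_piv.isna().any().any() or pre_piv.isna().any().any():
        raise ValueError("feature tables are not aligned (missing feature rows)")

    results: list[PairedTestResult] = []
    for key, pre_row in pre_piv.iterrows():
        kind, target, band = key
        pre_v = pre_row.to_numpy()
        post_v = post_piv.loc[key].to_numpy()
        n = len(pre_v)
        if np.all(post_v == pre_v):
            results.append(
                PairedTestResult(
                    kind, target, band, n, math.nan, math.nan, math.nan,
                    math.nan, False, False, testable=False,
                )
            )
            continue
        W, Z, p = wilcoxon_signed_rank(pre_v, post_v)
        r = effect_size_r(Z, n)
        results.append(
            PairedTestResult(
                kind, target, band, n, W, Z, p, r,
                significant=p < alpha,
                trend=alpha <= p < trend_bound,
            )
        )

    if fdr:
        from statsmodels.stats.multitest import multipletests

        testable = [res for res in results if res.testable]
        if testable:
            reject, p_adj, _, _ = multipletests(
                [res.p for res in testable], alpha=alpha, method="fdr_bh"
            )
            for res, rej, pa in zip(testable, reject, p_adj):
                res.p_adjusted = float(pa)
                res.significant = bool(rej)
                res.trend = (not rej) and pa < trend_bound
    return results


def results_frame(results: list[PairedTestResult]) -> pd.DataFrame:
    """Result list as a table, r reported to 4 decimals."""
    frame = pd.DataFrame([vars(r) for r in results])
    frame["r"] = frame["r"].round(4)
    return frame


def cfc_significance_mask(
    results: list[PairedTestResult], pair: str
) -> pd.DataFrame:
    """0/1 comodulogram significance mask for one region pair.

    Rows are modulating centers, columns modulated centers; cfc feature
    bands are encoded ``"<modulating>-<modulated>"`` in Hz.
    """
    cells = {}
    for res in results:
        if res.feature_kind != "cfc" or res.region_or_pair != pair:
            continue
        fp, fa = (float(v) for v in res.band.split("-"))
        cells[(fp, fa)] = int(bool(res.significant))
    if not cells:
        raise ValueError(f"no cfc results for pair {pair!r}")
    fps = sorted({k[0] for k in cells})
    fas = sorted({k[1] for k in cells})
    mat = pd.DataFrame(0, index=fps, columns=fas)
    for (fp, fa), v in cells.items():
        mat.loc[fp, fa] = v
    mat.index.name = "modulating_hz"
    mat.columns.name = "modulated_hz"
    return mat
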
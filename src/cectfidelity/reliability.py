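"""Statistical tests and rater-reliability computations.

Wraps the standard tests the evaluation uses (exact binomial,
two-proportion z, Wilcoxon rank-sum, Benjamini-Hochberg) and provides
chance-corrected agreement statistics for ordinal rater scores:
weighted Cohen's kappa (linear or quadratic disagreement weights) and
the Prevalence- and Bias-Adjusted Kappa, PABAK = (k*Po - 1)/(k - 1)
for k categories with observed agreement Po.  Confidence intervals are
seeded nonparametric bootstrap percentile intervals over images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "KappaResult",
    "ReliabilityResult",
    "exact_binomial",
    "two_proportion_z",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "weighted_kappa",
    "pabak",
    "rater_pair_reliability",
    "rater_summary",
    "sd_vs_agreement",
]


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    n: tuple = ()
    adjusted_p: float | None = None
    note: str = ""


@dataclass
class KappaResult:
    value: float
    ci_low: float
    ci_high: float
    n: int
    method: str


@dataclass
class ReliabilityResult:
    """Reliability of one rater pair."""

    rater_a: str
    rater_b: str
    n: int
    percent_agreement: dict = field(default_factory=dict)  # per category + "total"
    weighted_kappa: KappaResult | None = None
    pabak: KappaResult | None = None


def exact_binomial(k: int, n: int, p0: float = 0.5, sided: str = "two") -> TestResult:
    """Exact binomial test; two-sided by the minimum-likelihood method."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError("need 0 <= k <= n, n >= 1")
    if not (0 < p0 < 1):
        raise ValueError("p0 must be in (0, 1)")
    alternative = {"two": "two-sided", "greater": "greater"}[sided]
    res = sps.binomtest(k, n, p0, alternative=alternative)
    return TestResult("binomial", float(k / n), float(res.pvalue), n=(n,))


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """Pooled-variance two-proportion z-test, two-sided normal p.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled
    proportion.  A degenerate pooled proportion (0 or 1) leaves the
    statistic undefined (NaN, flagged in ``note``).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1 or not (0 <= k <= n):
            raise ValueError("need 0 <= k <= n, n >= 1 in both groups")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return TestResult("two_proportion_z", float("nan"), float("nan"),
                          n=(n1, n2), note="degenerate pooled proportion")
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (k1 / n1 - k2 / n2) / se
    p = 2 * sps.norm.sf(abs(z))
    return TestResult("two_proportion_z", float(z), float(p), n=(n1, n2))


def wilcoxon_rank_sum(x, y, exact_max_n: int = 20) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with midrank ties.

    Exact null distribution when there are no ties and the combined
    sample size is at most ``exact_max_n``; tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (no_ties and pooled.size <= exact_max_n) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult("wilcoxon_rank_sum", float(res.statistic),
                      float(min(res.pvalue, 1.0)), n=(x.size, y.size), note=method)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _kappa_from_pairs(a: np.ndarray, b: np.ndarray, cats: np.ndarray, w: np.ndarray) -> float:
    k = len(cats)
    idx = {c: i for i, c in enumerate(cats)}
    obs = np.zeros((k, k))
    for x, y in zip(a, b):
        obs[idx[x], idx[y]] += 1
    obs /= obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0))
    num = (w * obs).sum()
    den = (w * exp).sum()
    if num == 0:
        return 1.0
    if den == 0:
        return float("nan")
    return float(1.0 - num / den)


def weighted_kappa(
    r1,
    r2,
    weights: str = "linear",
    categories=None,
    n_boot: int = 2000,
    seed: int = 0,
) -> KappaResult:
    """Weighted Cohen's kappa with bootstrap percentile CI.

    Disagreement weights are |i - j|/(k - 1) (linear, default) or its
    square (quadratic) over the ordered category set.  The 95% CI is a
    seeded nonparametric bootstrap over paired observations; pass
    ``n_boot=0`` to skip it.
    """
    a = np.asarray(r1)
    b = np.asarray(r2)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("r1 and r2 must be paired 1-D score vectors")
    if len(np.unique(list(zip(a, b)), axis=0)) < 2:
        raise ValueError("need at least 2 distinct paired observations")
    cats = np.asarray(sorted(set(a) | set(b)) if categories is None else list(categories))
    k = len(cats)
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    w = np.abs(i - j) / max(k - 1, 1)
    if weights == "quadratic":
        w = w**2
    elif weights != "linear":
        raise ValueError("weights must be 'linear' or 'quadratic'")
    value = _kappa_from_pairs(a, b, cats, w)
    lo = hi = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(a)
        boots = np.empty(n_boot)
        for t in range(n_boot):
            sel = rng.integers(0, n, n)
            boots[t] = _kappa_from_pairs(a[sel], b[sel], cats, w)
        lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return KappaResult(value, float(lo), float(hi), len(a), f"weighted_kappa[{weights}]")


def pabak(r1, r2, k_categories: int | None = None, n_boot: int = 2000, seed: int = 0) -> KappaResult:
    """Prevalence- and bias-adjusted kappa, (k*Po - 1)/(k - 1)."""
    a = np.asarray(r1)
    b = np.asarray(r2)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("r1 and r2 must be non-empty paired vectors")
    k = k_categories or len(set(a) | set(b))
    if k < 2:
        raise ValueError("need at least 2 categories")

    def stat(x, y):
        po = float(np.mean(x == y))
        return (k * po - 1.0) / (k - 1.0)

    value = stat(a, b)
    lo = hi = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = a.size
        boots = np.empty(n_boot)
        for t in range(n_boot):
            sel = rng.integers(0, n, n)
            boots[t] = stat(a[sel], b[sel])
        lo, hi = np.percentile(boots, [2.5, 97.5])
    return KappaResult(float(value), float(lo), float(hi), a.size, f"pabak[k={k}]")


def rater_pair_reliability(
    scores_a,
    scores_b,
    rater_a: str = "R1",
    rater_b: str = "R2",
    dichotomize_at: int = 2,
    weights: str = "linear",
    n_boot: int = 2000,
    seed: int = 0,
) -> ReliabilityResult:
    """Full reliability summary for one rater pair.

    Weighted kappa is computed on the raw 1-5 scores; PABAK and the
    per-category percent agreements on the dichotomized scores
    (score < ``dichotomize_at`` -> category 0, "dissimilar").
    """
    a = np.asarray(scores_a, dtype=int)
    b = np.asarray(scores_b, dtype=int)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("paired non-empty score vectors required")
    da = (a >= dichotomize_at).astype(int)
    db = (b >= dichotomize_at).astype(int)
    pct = {
        "0": float(np.mean((da == 0) & (db == 0))) * 100,
        "1": float(np.mean((da == 1) & (db == 1))) * 100,
    }
    pct["total"] = pct["0"] + pct["1"]
    return ReliabilityResult(
        rater_a=rater_a,
        rater_b=rater_b,
        n=a.size,
        percent_agreement=pct,
        weighted_kappa=weighted_kappa(a, b, weights=weights,
                                      categories=[1, 2, 3, 4, 5],
                                      n_boot=n_boot, seed=seed),
        pabak=pabak(da, db, k_categories=2, n_boot=n_boot, seed=seed + 1),
    )


def rater_summary(table: pd.DataFrame, threshold: float = 2.0) -> dict:
    """Mean score and fraction of images scoring below the threshold.

    ``table`` is tidy (image_id, phase, rater, score).  The mean pools
    all (image, rater) scores; the below-threshold fraction uses each
    image's mean score across raters.  Per-phase strata included.
    """
    if table.empty:
        raise ValueError("no scores")
    per_image = table.groupby("image_id")["score"].mean()
    out = {
        "mean_score": float(table["score"].mean()),
        "fraction_below_threshold": float((per_image < threshold).mean()),
        "n_images": int(per_image.size),
        "n_scores": int(len(table)),
        "per_phase_mean": table.groupby("phase")["score"].mean().to_dict(),
    }
    return out


def sd_vs_agreement(
    sd_table: pd.DataFrame,
    heatmap: pd.DataFrame,
    features: list[str] | None = None,
    n_bins: int = 13,
) -> dict:
    """Does imputed-image SD predict feature agreement with GT?

    ``sd_table`` has one row per imputed image (study_id, phase, sd);
    ``heatmap`` is the per-(image, feature) agreement matrix from
    :func:`cectfidelity.concord.agreement_heatmap_data`.  Per feature,
    the SDs of agreeing vs disagreeing images are compared by Wilcoxon
    rank-sum with BH adjustment across testable features (features
    with an empty group are skipped and recorded).  Per image, images
    are binned by agreeing-feature fraction (bins of width 1/n_bins)
    and the mean SD per bin is rank-correlated with the bin level.
    """
    if features is None:
        features = [c for c in heatmap.columns if c != "fraction_agree"]
    sd = sd_table.set_index(["study_id", "phase"])["sd"]
    hm = heatmap.reindex(sd.index)
    rows, pvals, tested = [], [], []
    for feat in features:
        col = hm[feat]
        agree_sd = sd[col == 1.0].to_numpy()
        disagree_sd = sd[col == 0.0].to_numpy()
        if agree_sd.size == 0 or disagree_sd.size == 0:
            rows.append({"feature": feat, "n_agree": agree_sd.size,
                         "n_disagree": disagree_sd.size, "statistic": np.nan,
                         "p_value": np.nan, "adjusted_p": np.nan, "skipped": True})
            continue
        res = wilcoxon_rank_sum(agree_sd, disagree_sd)
        rows.append({"feature": feat, "n_agree": agree_sd.size,
                     "n_disagree": disagree_sd.size, "statistic": res.statistic,
                     "p_value": res.p_value, "adjusted_p": np.nan, "skipped": False})
        pvals.append(res.p_value)
        tested.append(len(rows) - 1)
    if pvals:
        adj = bh_adjust(pvals)
        for i, q in zip(tested, adj):
            rows[i]["adjusted_p"] = float(q)
    per_feature = pd.DataFrame(rows)

    frac = hm["fraction_agree"]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bins = np.clip(np.digitize(frac, edges[1:-1], right=True), 0, n_bins - 1)
    per_image = pd.DataFrame({"fraction_agree": frac.to_numpy(), "sd": sd.to_numpy(), "bin": bins})
    binned = per_image.groupby("bin").agg(mean_sd=("sd", "mean"), n=("sd", "size")).reset_index()
    if len(binned) >= 3:
        rho, p = sps.spearmanr(binned["bin"], binned["mean_sd"])
        trend = TestResult("spearman_bins", float(rho), float(p), n=(len(binned),))
    else:
        trend = TestResult("spearman_bins", float("nan"), float("nan"),
                           n=(len(binned),), note="too few occupied bins")
    return {"per_feature": per_feature, "binned": binned, "trend": trend}
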
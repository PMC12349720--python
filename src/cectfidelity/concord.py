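"""GT-vs-imputed feature concordance: agreement, correlation, profiles.

Operates on tidy per-image feature tables (one row per study x phase x
provenance) as produced by :mod:`cectfidelity.characterize` or read
from an annotation spreadsheet.  Pairs are matched on (study, phase);
a pair with a missing value in either member is excluded from that
feature's statistic (pairwise deletion) with exclusion counts logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .characterize import CATEGORICAL_FEATURES, QUANTITATIVE_FEATURES
from .core import PHASES, Phase

logger = logging.getLogger(__name__)

__all__ = [
    "pair_tables",
    "categorical_agreement",
    "quantitative_correlation",
    "correlation_table",
    "intensity_profiles",
    "profile_diff_summary",
    "agreement_heatmap_data",
]

_STRATA = ["all"] + [p.value for p in PHASES]


def pair_tables(gt: pd.DataFrame, imp: pd.DataFrame) -> pd.DataFrame:
    """Inner-join GT and imputed tables on (study_id, phase).

    Returns one row per pair with ``_gt`` / ``_imp`` suffixed columns.
    """
    key = ["study_id", "phase"]
    for df, name in ((gt, "gt"), (imp, "imp")):
        if df.duplicated(key).any():
            raise ValueError(f"{name} table has duplicate (study_id, phase) rows")
    merged = gt.merge(imp, on=key, suffixes=("_gt", "_imp"), how="inner")
    dropped = len(gt) + len(imp) - 2 * len(merged)
    if dropped:
        logger.info("pairing dropped %d unmatched rows", dropped)
    return merged


def categorical_agreement(
    gt: pd.DataFrame, imp: pd.DataFrame, null_p: float = 0.5
) -> pd.DataFrame:
    """Per-feature agreement fractions, pooled and per phase.

    Returns a tidy table with columns feature, stratum, n_pairs,
    n_agree, agreement_fraction, p_value (exact binomial against
    ``null_p``, two-sided).  Features with zero non-missing pairs in a
    stratum are reported with NaN fraction.
    """
    pairs = pair_tables(gt, imp)
    rows = []
    for feature in CATEGORICAL_FEATURES:
        a, b = pairs[f"{feature}_gt"], pairs[f"{feature}_imp"]
        ok = a.notna() & b.notna()
        agree = ok & (a == b)
        for stratum in _STRATA:
            sel = ok if stratum == "all" else ok & (pairs["phase"] == stratum)
            n = int(sel.sum())
            k = int((agree & sel).sum()) if n else 0
            if n:
                frac = k / n
                p = float(sps.binomtest(k, n, null_p).pvalue)
            else:
                frac, p = np.nan, np.nan
            rows.append(
                {
                    "feature": feature,
                    "stratum": stratum,
                    "n_pairs": n,
                    "n_agree": k,
                    "agreement_fraction": frac,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


def quantitative_correlation(gt_values, imp_values) -> dict:
    """Least-squares fit of imputed on GT values plus R^2.

    R^2 is the squared Pearson correlation of the paired values.  A
    constant vector (or n < 3) yields an undefined, flagged result.
    """
    x = np.asarray(gt_values, dtype=float)
    y = np.asarray(imp_values, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"slope": np.nan, "intercept": np.nan, "r_squared": np.nan,
                "n": n, "defined": False}
    fit = sps.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
        "n": n,
        "defined": True,
    }


def correlation_table(gt: pd.DataFrame, imp: pd.DataFrame) -> pd.DataFrame:
    """Quantitative GT-vs-imputed correlation for all 8 features."""
    pairs = pair_tables(gt, imp)
    rows = []
    for feature in QUANTITATIVE_FEATURES:
        x = pd.to_numeric(pairs[f"{feature}_gt"], errors="coerce")
        y = pd.to_numeric(pairs[f"{feature}_imp"], errors="coerce")
        ok = x.notna() & y.notna()
        if ok.sum() < 3:
            rows.append({"feature": feature, "slope": np.nan, "intercept": np.nan,
                         "r_squared": np.nan, "n": int(ok.sum()), "defined": False})
            continue
        res = quantitative_correlation(x[ok], y[ok])
        rows.append({"feature": feature, **res})
    return pd.DataFrame(rows)


def intensity_profiles(gt: pd.DataFrame, imp: pd.DataFrame) -> pd.DataFrame:
    """Per-study four-phase mean-ROI-intensity profiles, GT and imputed.

    Studies missing any phase in either provenance are excluded (and
    logged).  Returns a tidy frame (study_id, phase, mean_hu_gt,
    mean_hu_imp) with phases in acquisition order.
    """
    pairs = pair_tables(gt, imp)[["study_id", "phase", "mean_hu_gt", "mean_hu_imp"]]
    counts = pairs.groupby("study_id")["phase"].nunique()
    complete = counts[counts == len(PHASES)].index
    excluded = sorted(set(pairs["study_id"]) - set(complete))
    if excluded:
        logger.info("excluding studies with missing phases: %s", excluded)
    out = pairs[pairs["study_id"].isin(complete)].copy()
    out["phase"] = pd.Categorical(out["phase"], [p.value for p in PHASES], ordered=True)
    return out.sort_values(["study_id", "phase"]).reset_index(drop=True)


def profile_diff_summary(profiles: pd.DataFrame) -> pd.DataFrame:
    """Signed and magnitude mean-ROI-intensity differences, per phase and pooled.

    The signed difference is imputed minus GT, so a negative pooled
    mean indicates imputed images slightly darker on average.
    """
    if profiles.empty:
        raise ValueError("no paired profiles")
    diff = profiles["mean_hu_imp"].to_numpy(float) - profiles["mean_hu_gt"].to_numpy(float)
    rows = []
    for stratum in _STRATA:
        sel = np.ones(len(diff), bool) if stratum == "all" else (
            profiles["phase"].astype(str) == stratum
        ).to_numpy()
        d = diff[sel]
        rows.append(
            {
                "stratum": stratum,
                "mean_signed_diff": float(d.mean()) if d.size else np.nan,
                "mean_magnitude_diff": float(np.abs(d).mean()) if d.size else np.nan,
                "n": int(d.size),
            }
        )
    return pd.DataFrame(rows)


def agreement_heatmap_data(gt: pd.DataFrame, imp: pd.DataFrame) -> pd.DataFrame:
    """Per-(image, feature) boolean agreement matrix.

    Index is (study_id, phase); columns are the 13 categorical
    features; missing-in-either cells are NaN.  A final
    ``fraction_agree`` column holds each image's agreeing-feature
    fraction over its non-missing features.
    """
    pairs = pair_tables(gt, imp)
    out = pd.DataFrame(index=pd.MultiIndex.from_frame(pairs[["study_id", "phase"]]))
    for feature in CATEGORICAL_FEATURES:
        a, b = pairs[f"{feature}_gt"], pairs[f"{feature}_imp"]
        ok = (a.notna() & b.notna()).to_numpy()
        agree = np.where(ok, (a == b).to_numpy(), np.nan)
        out[feature] = agree
    out["fraction_agree"] = out[CATEGORICAL_FEATURES].mean(axis=1, skipna=True)
    return out
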
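"""Benign/malignant diagnostic-feature mapping and GT-vs-imputed scoring.

Six feature values are typical of benign renal masses and eight of
malignant ones.  For each mapped (feature, value) pair the module
scores the fraction of images of the corresponding diagnosis that
present the concordant value, separately for ground-truth and imputed
images, and compares the two proportions with a pooled two-proportion
z-test.  The map is fixed; custom maps may be passed explicitly but
the canonical one cannot be mutated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PHASES
from .reliability import two_proportion_z

__all__ = [
    "DxTriple",
    "build_diagnosis_map",
    "diagnostic_feature_fraction",
    "compare_gt_imputed_dx",
]


@dataclass(frozen=True)
class DxTriple:
    feature: str
    value: object
    implied_diagnosis: str  # {"benign", "malignant"}


_BENIGN = (
    ("enhancement_pattern", "homogeneous"),
    ("margin_shape", "smooth"),
    ("margin_aggressiveness", "well_marginated"),
    ("composition", "cystic"),
    ("thresholded_size", False),  # small size < 10 mm
    ("thresholded_mean_enhancement", False),  # mean enhancement < 10 HU
)

_MALIGNANT = (
    ("enhancement_pattern", "heterogeneous"),
    ("necrosis", "present"),
    ("margin_shape", "lobulated"),
    ("margin_aggressiveness", "infiltrative"),
    ("composition", "solid"),
    ("pelvis_invasion", "yes"),
    ("thresholded_size", True),  # large size > 10 mm
    ("thresholded_mean_enhancement", True),  # mean enhancement > 10 HU
)


def build_diagnosis_map() -> tuple[DxTriple, ...]:
    """The fixed 6 benign + 8 malignant (feature, value, diagnosis) triples."""
    return tuple(
        [DxTriple(f, v, "benign") for f, v in _BENIGN]
        + [DxTriple(f, v, "malignant") for f, v in _MALIGNANT]
    )


def _label(t: DxTriple) -> str:
    return f"{t.implied_diagnosis}:{t.feature}={t.value}"


def diagnostic_feature_fraction(
    features: pd.DataFrame,
    diagnoses: pd.Series | dict,
    dx_map: tuple[DxTriple, ...] | None = None,
) -> pd.DataFrame:
    """Fraction of images presenting the value typical of their diagnosis.

    ``features`` is a per-image table of one provenance; ``diagnoses``
    maps study_id -> {"benign", "malignant"}.  For each mapped triple,
    fraction = (#images of that diagnosis with feature == value) /
    (#images of that diagnosis with the feature non-missing), pooled
    and per phase.  Diagnosis classes with no images are flagged NaN.
    """
    dx_map = dx_map or build_diagnosis_map()
    if isinstance(diagnoses, dict):
        diagnoses = pd.Series(diagnoses)
    dx = features["study_id"].map(diagnoses)
    if dx.isna().any():
        missing = sorted(features.loc[dx.isna(), "study_id"].unique())
        raise ValueError(f"missing diagnosis label for studies: {missing}")
    rows = []
    for t in dx_map:
        vals = features[t.feature]
        in_class = (dx == t.implied_diagnosis).to_numpy()
        ok = vals.notna().to_numpy() & in_class
        hit = ok & (vals == t.value).to_numpy()
        for stratum in ["all"] + [p.value for p in PHASES]:
            sel = np.ones(len(features), bool) if stratum == "all" else (
                features["phase"] == stratum
            ).to_numpy()
            n = int((ok & sel).sum())
            k = int((hit & sel).sum())
            rows.append(
                {
                    "mapped": _label(t),
                    "feature": t.feature,
                    "value": t.value,
                    "implied_diagnosis": t.implied_diagnosis,
                    "stratum": stratum,
                    "n": n,
                    "k": k,
                    "fraction": k / n if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


def compare_gt_imputed_dx(gt_half: pd.DataFrame, imp_half: pd.DataFrame) -> pd.DataFrame:
    """Two-proportion z-test per mapped feature (pooled stratum).

    Both halves must come from :func:`diagnostic_feature_fraction` on
    the same image set and map.  Swapping the halves negates every z.
    """
    g = gt_half[gt_half["stratum"] == "all"].set_index("mapped")
    i = imp_half[imp_half["stratum"] == "all"].set_index("mapped")
    if not g.index.equals(i.index):
        raise ValueError("GT and imputed halves use different maps")
    rows = []
    for mapped in g.index:
        k1, n1 = int(g.loc[mapped, "k"]), int(g.loc[mapped, "n"])
        k2, n2 = int(i.loc[mapped, "k"]), int(i.loc[mapped, "n"])
        if n1 == 0 or n2 == 0:
            z, p, defined = np.nan, np.nan, False
        else:
            res = two_proportion_z(k1, n1, k2, n2)
            z, p, defined = res.statistic, res.p_value, np.isfinite(res.statistic)
        rows.append(
            {
                "mapped": mapped,
                "fraction_gt": g.loc[mapped, "fraction"],
                "fraction_imp": i.loc[mapped, "fraction"],
                "z": z,
                "p_value": p,
                "defined": defined,
            }
        )
    return pd.DataFrame(rows)
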
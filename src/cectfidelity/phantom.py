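"""Synthetic four-phase renal CT phantoms and surrogate "imputed" images.

The phantom is a 2-D single-slice tumor crop (default 128x128 px at
1 mm/px) containing a parametric kidney (cortex / medulla / sinus /
pelvis compartments on a fat background) and a parametric tumor with
controllable margin shape and definition, heterogeneity, necrosis,
macroscopic fat, cystic composition, exophytic fraction, side, depth
and size.  Every categorical imaging feature of interest is therefore
known by construction, which makes the downstream feature-extraction
and concordance pipeline testable end to end without patient data.

Surrogate "imputed" images are produced by a parameterized degradation
of the ground-truth image (blur, intensity bias, heterogeneity damping,
residual noise).  The degradation family is an explicit stand-in for
the error structure of a generative imputation model; it makes no claim
about any particular model's residuals.

Phase physiology encoded in the default compartment curves: the cortex
is brightest in the corticomedullary phase (peak cortical contrast),
cortex and medulla are both bright in the nephrographic phase, and the
collecting system (pelvis) is brightest in the excretory phase; all
soft tissue sits near muscle attenuation before contrast.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import PHASES, POST_CONTRAST_PHASES, Phase, PhaseImage, Provenance, StudySet

__all__ = [
    "PhantomSpec",
    "DegradationSpec",
    "CohortConfig",
    "render_phantom",
    "compartment_masks",
    "tumor_mask",
    "apply_degradation",
    "degrade_study",
    "simulate_cohort",
    "simulate_rater_scores",
    "solve_exophytic_center",
    "truth_from_spec",
    "exophytic_category",
    "recovery_grid",
    "TRUTH_FEATURES",
]

# Kidney geometry as fractions of image size (semi-axes / offsets).
_KIDNEY_SEMI = (0.36, 0.235)
_MEDULLA_SEMI = (0.28, 0.18)
_SINUS_SEMI = (0.10, 0.0625)
_SINUS_MEDIAL_OFFSET = 0.0625
_PELVIS_RADIUS = 0.031
_PELVIS_MEDIAL_OFFSET = 0.031

#: default mean HU of each kidney compartment per phase
#: (precontrast, corticomedullary, nephrographic, excretory)
DEFAULT_COMPARTMENT_CURVES: dict[str, tuple[float, float, float, float]] = {
    "cortex": (35.0, 180.0, 140.0, 100.0),
    "medulla": (35.0, 60.0, 130.0, 100.0),
    "sinus": (-80.0, -80.0, -80.0, -80.0),
    "pelvis": (10.0, 15.0, 30.0, 250.0),
    "background": (-90.0, -90.0, -90.0, -90.0),
}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic four-phase renal tumor crop.

    ``tumor_semi_axes_mm`` are the tumor ellipse semi-axes (row axis,
    column axis) in mm; the longest lesion dimension implied is twice
    the larger semi-axis.  ``heterogeneity`` is the texture amplitude in
    HU, realized as a smooth zero-mean random field with standard
    deviation ``heterogeneity / 2`` added to enhancing tumor tissue in
    the post-contrast phases.  ``phase_curve`` is the mean HU of solid
    tumor tissue per phase in acquisition order.
    """

    image_size: int = 128
    pixel_spacing: float = 1.0
    kidney_side: str = "left"  # {"left", "right"}
    tumor_center: tuple[float, float] = (64.0, 75.0)  # (row, col) px
    tumor_semi_axes_mm: tuple[float, float] = (10.0, 8.0)
    margin_shape: str = "smooth"  # {"smooth", "lobulated"}
    lobulation_amplitude: float = 0.0  # relative radial perturbation
    n_lobes: int = 7
    margin_definition: str = "well_marginated"  # {"well_marginated", "infiltrative"}
    edge_blur_px: float = 0.0
    heterogeneity: float = 0.0  # HU texture amplitude
    necrosis_fraction: float = 0.0
    has_fat: bool = False
    fat_hu: float = -40.0
    fat_fraction: float = 0.05
    composition: str = "solid"  # {"solid", "cystic"}
    exophytic_fraction: float = 0.0  # target fraction of tumor outside kidney
    invades_pelvis: bool = False
    phase_curve: tuple[float, float, float, float] = (30.0, 80.0, 110.0, 90.0)
    compartment_curves: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COMPARTMENT_CURVES)
    )
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")
        if len(self.phase_curve) != 4:
            raise ValueError("phase_curve must have exactly 4 entries")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (0 <= self.necrosis_fraction < 1):
            raise ValueError("necrosis_fraction must be in [0, 1)")
        if self.necrosis_fraction + (self.fat_fraction if self.has_fat else 0.0) >= 1:
            raise ValueError("necrosis + fat regions exceed the tumor area")
        if self.kidney_side not in ("left", "right"):
            raise ValueError("kidney_side must be 'left' or 'right'")
        if not (0 <= self.exophytic_fraction <= 1):
            raise ValueError("exophytic_fraction must be in [0, 1]")

    @property
    def hilum_sign(self) -> int:
        """Column direction of the medial (hilum) side: -1 left, +1 right."""
        return -1 if self.kidney_side == "left" else +1

    @property
    def kidney_center(self) -> tuple[float, float]:
        return (self.image_size / 2.0, self.image_size / 2.0)

    def replace(self, **kw) -> "PhantomSpec":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class DegradationSpec:
    """Surrogate-imputation degradation: an all-zero spec is the identity."""

    blur_sigma: float = 0.0  # px
    intensity_bias: float = 0.0  # HU
    heterogeneity_damping: float = 0.0  # in [0, 1]; 0 = none
    residual_noise_sigma: float = 0.0  # HU
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blur_sigma < 0 or self.residual_noise_sigma < 0:
            raise ValueError("blur and noise sigmas must be >= 0")
        if not (0 <= self.heterogeneity_damping <= 1):
            raise ValueError("heterogeneity_damping must be in [0, 1]")

    @property
    def is_identity(self) -> bool:
        return (
            self.blur_sigma == 0
            and self.intensity_bias == 0
            and self.heterogeneity_damping == 0
            and self.residual_noise_sigma == 0
        )


def _ellipse_mask(shape, center, semi_axes, lobulation=0.0, n_lobes=7):
    """Boolean ellipse, optionally with a sinusoidal radial perturbation."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    u = (rr - center[0]) / semi_axes[0]
    v = (cc - center[1]) / semi_axes[1]
    r = np.hypot(u, v)
    if lobulation:
        theta = np.arctan2(v, u)
        return r <= 1.0 + lobulation * np.sin(n_lobes * theta)
    return r <= 1.0


def compartment_masks(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Kidney / cortex / medulla / sinus / pelvis masks for a spec's geometry."""
    n = spec.image_size
    shape = (n, n)
    kc = spec.kidney_center
    kidney = _ellipse_mask(shape, kc, (n * _KIDNEY_SEMI[0], n * _KIDNEY_SEMI[1]))
    inner = _ellipse_mask(shape, kc, (n * _MEDULLA_SEMI[0], n * _MEDULLA_SEMI[1]))
    sinus_center = (kc[0], kc[1] + spec.hilum_sign * n * _SINUS_MEDIAL_OFFSET)
    sinus = _ellipse_mask(shape, sinus_center, (n * _SINUS_SEMI[0], n * _SINUS_SEMI[1]))
    pelvis_center = (
        sinus_center[0],
        sinus_center[1] + spec.hilum_sign * n * _PELVIS_MEDIAL_OFFSET,
    )
    r = n * _PELVIS_RADIUS
    pelvis = _ellipse_mask(shape, pelvis_center, (r, r))
    sinus &= kidney
    pelvis &= kidney
    medulla = inner & kidney & ~sinus & ~pelvis
    cortex = kidney & ~inner
    return {
        "kidney": kidney,
        "cortex": cortex,
        "medulla": medulla,
        "sinus": sinus & ~pelvis,
        "pelvis": pelvis,
    }


def tumor_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean tumor support mask (before any margin fade)."""
    n = spec.image_size
    semi = (
        spec.tumor_semi_axes_mm[0] / spec.pixel_spacing,
        spec.tumor_semi_axes_mm[1] / spec.pixel_spacing,
    )
    amp = spec.lobulation_amplitude if spec.margin_shape == "lobulated" else 0.0
    return _ellipse_mask((n, n), spec.tumor_center, semi, amp, spec.n_lobes)


def _subregion_disk(tumor: np.ndarray, spec: PhantomSpec, fraction: float, row_sign: int):
    """Disk covering ~``fraction`` of the tumor, offset along the row axis."""
    area = tumor.sum()
    radius = np.sqrt(fraction * area / np.pi)
    a_row = spec.tumor_semi_axes_mm[0] / spec.pixel_spacing
    center = (spec.tumor_center[0] + row_sign * a_row / 2.5, spec.tumor_center[1])
    disk = _ellipse_mask(tumor.shape, center, (radius, radius))
    return disk & tumor


def render_phantom(spec: PhantomSpec, seed: int = 0) -> StudySet:
    """Render a deterministic four-phase study from a phantom spec.

    With ``noise_sigma = 0`` and ``heterogeneity = 0`` the tumor region
    is piecewise constant per phase and its ROI mean equals the spec's
    ``phase_curve`` entry for that phase.
    """
    n = spec.image_size
    comps = compartment_masks(spec)
    tumor = tumor_mask(spec)
    if not tumor.any():
        raise ValueError("tumor mask is empty")
    edge = np.zeros_like(tumor)
    edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
    if (tumor & edge).any():
        raise ValueError("tumor extends outside the image crop")

    necrosis = (
        _subregion_disk(tumor, spec, spec.necrosis_fraction, -1)
        if spec.necrosis_fraction > 0
        else np.zeros_like(tumor)
    )
    fat = (
        _subregion_disk(tumor, spec, spec.fat_fraction, +1)
        if spec.has_fat
        else np.zeros_like(tumor)
    )
    fat &= ~necrosis
    enhancing = tumor & ~necrosis & ~fat

    rng = np.random.default_rng(seed)
    texture = np.zeros((n, n))
    if spec.heterogeneity > 0:
        f = gaussian_filter(rng.standard_normal((n, n)), 2.0)
        sel = f[enhancing]
        # exact zero mean / target SD over the enhancing tissue
        f = (f - sel.mean()) / sel.std() * (spec.heterogeneity / 2.0)
        texture = f

    fade = None
    if spec.margin_definition == "infiltrative" and spec.edge_blur_px > 0:
        # renormalized so the fade is ~1 at the mask boundary and decays
        # outward: the interior is untouched and the ramp is continuous
        soft = gaussian_filter(tumor.astype(float), spec.edge_blur_px)
        fade = np.clip(2.0 * soft, 0.0, 1.0)

    images: dict[Phase, PhaseImage] = {}
    for phase in PHASES:
        i = phase.index
        img = np.full((n, n), spec.compartment_curves["background"][i], dtype=float)
        for name in ("cortex", "medulla", "sinus", "pelvis"):
            img[comps[name]] = spec.compartment_curves[name][i]
        tumor_hu = spec.phase_curve[i]
        if fade is not None:
            # outward fade: interior keeps the exact tumor value, the
            # surround blends toward it over ~edge_blur_px
            img = img * (1.0 - fade) + tumor_hu * fade
        img[tumor] = tumor_hu
        if phase in POST_CONTRAST_PHASES:
            img[enhancing] += texture[enhancing]
        # necrotic tissue does not enhance: precontrast attenuation in
        # every phase; macroscopic fat keeps its fat attenuation
        img[necrosis] = spec.phase_curve[0]
        img[fat] = spec.fat_hu
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, (n, n))
        images[phase] = PhaseImage(
            pixels=img,
            phase=phase,
            pixel_spacing=spec.pixel_spacing,
            provenance=Provenance.GROUND_TRUTH,
        )

    comps = dict(comps)
    comps["necrosis"] = necrosis
    comps["fat"] = fat
    return StudySet(
        images=images,
        tumor_roi=tumor,
        compartments=comps,
        meta={
            "kidney_side": spec.kidney_side,
            "hilum_sign": spec.hilum_sign,
            "kidney_center": spec.kidney_center,
            "seed": seed,
        },
    )


def apply_degradation(study: StudySet, phase: Phase | str, deg: DegradationSpec) -> PhaseImage:
    """Produce a surrogate "imputed" image for one phase of a study.

    The pipeline is blur -> heterogeneity damping (toward the tumor-ROI
    mean, inside the ROI) -> additive intensity bias -> residual noise.
    An all-zero spec returns a pixel-identical copy.
    """
    phase = Phase(phase)
    if phase not in study.images:
        raise KeyError(f"unknown phase {phase!r}")
    src = study[phase]
    x = src.pixels.copy()
    rng = np.random.default_rng(deg.seed)
    if deg.blur_sigma > 0:
        x = gaussian_filter(x, deg.blur_sigma)
    if deg.heterogeneity_damping > 0:
        roi = study.tumor_roi
        m = x[roi].mean()
        x[roi] = m + (1.0 - deg.heterogeneity_damping) * (x[roi] - m)
    x = x + deg.intensity_bias
    if deg.residual_noise_sigma > 0:
        x = x + rng.normal(0.0, deg.residual_noise_sigma, x.shape)
    return PhaseImage(
        pixels=x,
        phase=phase,
        pixel_spacing=src.pixel_spacing,
        study_id=src.study_id,
        provenance=Provenance.SURROGATE,
    )


def degrade_study(study: StudySet, degs: dict[Phase, DegradationSpec]) -> dict[Phase, PhaseImage]:
    """Apply a per-phase degradation to every phase independently."""
    return {Phase(p): apply_degradation(study, p, d) for p, d in degs.items()}


# ---------------------------------------------------------------------------
# placement helpers and ground-truth feature derivation
# ---------------------------------------------------------------------------


def solve_exophytic_center(
    spec: PhantomSpec,
    target: float,
    direction: tuple[float, float] | None = None,
    tol: float = 0.005,
    max_iter: int = 50,
) -> tuple[float, float]:
    """Find a tumor center whose mask places ``target`` of its area
    outside the kidney, by bisection along an outward ray from the
    kidney center (default: the lateral direction)."""
    if not (0 <= target < 1):
        raise ValueError("target exophytic fraction must be in [0, 1)")
    kidney = compartment_masks(spec)["kidney"]
    if direction is None:
        direction = (0.0, -spec.hilum_sign)  # lateral
    d = np.asarray(direction, dtype=float)
    d /= np.hypot(*d)
    kc = np.asarray(spec.kidney_center)

    def frac_outside(t: float) -> float:
        m = tumor_mask(spec.replace(tumor_center=tuple(kc + t * d)))
        if not m.any():
            return 1.0
        return 1.0 - (m & kidney).sum() / m.sum()

    if target == 0:
        return tuple(kc + 0.0 * d)
    lo, hi = 0.0, spec.image_size * 0.48
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = frac_outside(mid)
        if abs(f - target) <= tol:
            break
        if f < target:
            lo = mid
        else:
            hi = mid
    return tuple(kc + mid * d)


def exophytic_category(f: float, half_tol: float = 0.05, endo_tol: float = 0.005) -> str:
    """Bucket an exophytic fraction into the four clinical categories."""
    if abs(f - 0.5) <= half_tol:
        return "half_half"
    if f <= endo_tol:
        return "endophytic"
    return "lt50_exophytic" if f < 0.5 else "gt50_exophytic"


TRUTH_FEATURES = [
    "enhancement_pattern",
    "margin_shape",
    "margin_aggressiveness",
    "exophytic_category",
    "composition",
    "necrosis",
    "macroscopic_fat",
    "kidney_side",
    "medial_lateral",
    "depth_location",
    "pelvis_invasion",
]


def truth_from_spec(spec: PhantomSpec, depth_location: str) -> dict[str, object]:
    """Categorical feature values implied by a phantom spec.

    ``depth_location`` is the placement intent (cortical /
    corticomedullary / sinus) chosen when the tumor center was set; the
    remaining features derive analytically from the spec.  Valid for
    well-separated parameter settings (the generator's regime), not for
    arbitrary boundary cases.
    """
    heterogeneous = spec.composition == "solid" and (
        spec.heterogeneity >= 20.0 or spec.necrosis_fraction >= 0.05
    )
    medial = (spec.tumor_center[1] - spec.kidney_center[1]) * spec.hilum_sign > 0
    mean_enh = [spec.phase_curve[i] - spec.phase_curve[0] for i in range(1, 4)]
    return {
        "enhancement_pattern": "heterogeneous" if heterogeneous else "homogeneous",
        "margin_shape": spec.margin_shape,
        "margin_aggressiveness": spec.margin_definition,
        "exophytic_category": exophytic_category(spec.exophytic_fraction),
        "composition": spec.composition,
        "necrosis": "present" if spec.necrosis_fraction >= 0.05 else "absent",
        "macroscopic_fat": "present" if spec.has_fat else "absent",
        "kidney_side": spec.kidney_side,
        "medial_lateral": "medial" if medial else "lateral",
        "depth_location": depth_location,
        "pelvis_invasion": "yes" if spec.invades_pelvis else "no",
        "thresholded_size": bool(2.0 * max(spec.tumor_semi_axes_mm) > 10.0),
        "thr_enh_corticomedullary": bool(mean_enh[0] > 10.0),
        "thr_enh_nephrographic": bool(mean_enh[1] > 10.0),
        "thr_enh_excretory": bool(mean_enh[2] > 10.0),
    }


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Study conditions for a simulated paired GT/surrogate cohort.

    Defaults mirror the evaluated design: four 128x128 phases per study
    with realistic CT noise, a mostly-malignant case mix, and a
    moderate degradation standing in for imputation error.
    """

    p_malignant: float = 0.89
    noise_sigma: float = 7.0
    blur_range: tuple[float, float] = (0.5, 1.5)
    bias_sd: float = 15.0
    damping_range: tuple[float, float] = (0.0, 0.3)
    residual_noise_range: tuple[float, float] = (2.0, 8.0)

    @classmethod
    def zero_degradation(cls, noise_sigma: float = 7.0) -> "CohortConfig":
        """GT/surrogate pairs that are pixel-identical (identity chain)."""
        return cls(
            noise_sigma=noise_sigma,
            blur_range=(0.0, 0.0),
            bias_sd=0.0,
            damping_range=(0.0, 0.0),
            residual_noise_range=(0.0, 0.0),
        )

    def validate(self) -> None:
        if not (0 <= self.p_malignant <= 1):
            raise ValueError("p_malignant must be in [0, 1]")
        for lo, hi in (self.blur_range, self.damping_range, self.residual_noise_range):
            if lo > hi or lo < 0:
                raise ValueError("parameter ranges must satisfy 0 <= lo <= hi")


def _sample_spec(rng: np.random.Generator, malignant: bool, config: CohortConfig):
    """Draw one phantom spec from the benign or malignant archetype."""
    side = rng.choice(["left", "right"])
    spec = PhantomSpec(kidney_side=side, noise_sigma=config.noise_sigma)

    if malignant:
        semi_long = rng.uniform(8.0, 16.0)
        axes = (semi_long, semi_long * rng.uniform(0.6, 0.9))
        lobulated = rng.random() < 0.6
        infiltrative = rng.random() < 0.4
        necrosis = rng.uniform(0.1, 0.3) if rng.random() < 0.5 else 0.0
        het = rng.uniform(30.0, 50.0)
        pre = rng.uniform(25.0, 40.0)
        curve = (
            pre,
            pre + rng.uniform(40.0, 90.0),
            pre + rng.uniform(60.0, 110.0),
            pre + rng.uniform(40.0, 80.0),
        )
        spec = spec.replace(
            tumor_semi_axes_mm=axes,
            margin_shape="lobulated" if lobulated else "smooth",
            lobulation_amplitude=rng.uniform(0.2, 0.35) if lobulated else 0.0,
            margin_definition="infiltrative" if infiltrative else "well_marginated",
            edge_blur_px=rng.uniform(3.0, 5.0) if infiltrative else 0.0,
            heterogeneity=het,
            necrosis_fraction=necrosis,
            has_fat=False,
            composition="solid",
            phase_curve=curve,
        )
        invade = rng.random() < 0.15
    else:
        cystic = rng.random() < 0.5
        semi_long = rng.uniform(3.5, 9.0)
        axes = (semi_long, semi_long * rng.uniform(0.7, 0.95))
        if cystic:
            base = rng.uniform(5.0, 15.0)
            curve = (base, base + 2.0, base + 3.0, base + 2.0)
        else:
            pre = rng.uniform(25.0, 40.0)
            curve = (pre, pre + 6.0, pre + 8.0, pre + 5.0)
        spec = spec.replace(
            tumor_semi_axes_mm=axes,
            composition="cystic" if cystic else "solid",
            has_fat=(not cystic) and rng.random() < 0.4,
            phase_curve=curve,
        )
        invade = False

    # placement: pelvis-invading tumors sit at the collecting system;
    # otherwise draw a depth, with exophytic growth only for cortical
    n = spec.image_size
    kc = spec.kidney_center
    h = spec.hilum_sign
    if invade:
        depth = "sinus"
        center = (kc[0], kc[1] + h * n * (_SINUS_MEDIAL_OFFSET + _PELVIS_MEDIAL_OFFSET) - h * 2.0)
        spec = spec.replace(
            invades_pelvis=True,
            tumor_center=center,
            tumor_semi_axes_mm=(max(axes[0], 6.0), max(axes[1], 5.0)),
        )
    else:
        depth = rng.choice(["cortical", "corticomedullary", "sinus"], p=[0.55, 0.35, 0.10])
        if depth == "sinus":
            # lateral part of the sinus, clear of the pelvis disk
            center = (kc[0] + rng.uniform(-3, 3), kc[1] + h * 4.0 / 128 * n)
            spec = spec.replace(
                tumor_center=center,
                tumor_semi_axes_mm=(min(axes[0], 5.0), min(axes[1], 3.0)),
            )
        elif depth == "corticomedullary":
            lateral = rng.random() < 0.7
            sign = -h if lateral else h
            if lateral:
                center = (kc[0] + rng.uniform(-6, 6), kc[1] + sign * 11.0 / 128 * n)
            else:
                center = (kc[0] + rng.uniform(18, 22) * rng.choice([-1, 1]), kc[1] + sign * 6.0 / 128 * n)
            spec = spec.replace(
                tumor_center=center,
                tumor_semi_axes_mm=(min(axes[0], 9.0), min(axes[1], 7.0)),
            )
        else:  # cortical: small endophytic or exophytic
            f = float(rng.choice([0.0, 0.25, 0.5, 0.75], p=[0.25, 0.35, 0.15, 0.25]))
            if f == 0.0:
                center = (
                    kc[0] + rng.uniform(-4, 4),
                    kc[1] - h * rng.uniform(25.0, 26.5) / 128 * n,
                )
                spec = spec.replace(
                    tumor_center=center,
                    tumor_semi_axes_mm=(min(axes[0], 4.0), min(axes[1], 3.0)),
                )
            else:
                angle = rng.uniform(-0.4, 0.4)
                direction = (np.sin(angle), -h * np.cos(angle))
                spec = spec.replace(exophytic_fraction=f)
                center = solve_exophytic_center(spec, f, direction)
                spec = spec.replace(tumor_center=center)
    return spec, depth


def simulate_cohort(
    n_studies: int,
    config: CohortConfig | None = None,
    seed: int = 0,
) -> tuple[list[dict], pd.DataFrame]:
    """Simulate paired ground-truth / surrogate four-phase studies.

    Returns ``(pairs, truth)`` where each pair dict holds ``study_id``,
    the GT ``StudySet``, and the per-phase surrogate images
    (``surrogates``: phase -> PhaseImage); ``truth`` is the cohort
    truth table (one row per study: spec parameters, implied categorical
    features, diagnosis, seeds).  Each phase is degraded independently.
    """
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    config = config or CohortConfig()
    config.validate()
    root = np.random.default_rng(seed)
    pairs: list[dict] = []
    rows: list[dict] = []
    for i in range(n_studies):
        study_seed = int(root.integers(0, 2**31 - 1))
        rng = np.random.default_rng(study_seed)
        malignant = bool(rng.random() < config.p_malignant)
        spec, depth = _sample_spec(rng, malignant, config)
        study_id = f"S{i + 1:03d}"
        study = render_phantom(spec, seed=int(rng.integers(0, 2**31 - 1)))
        study.study_id = study_id
        for im in study.images.values():
            im.study_id = study_id

        degs = {}
        for phase in PHASES:
            degs[phase] = DegradationSpec(
                blur_sigma=float(rng.uniform(*config.blur_range)),
                intensity_bias=float(rng.normal(0.0, config.bias_sd)) if config.bias_sd > 0 else 0.0,
                heterogeneity_damping=float(rng.uniform(*config.damping_range)),
                residual_noise_sigma=float(rng.uniform(*config.residual_noise_range)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        surrogates = degrade_study(study, degs)
        pairs.append({"study_id": study_id, "gt": study, "surrogates": surrogates})

        row = {"study_id": study_id, "diagnosis": "malignant" if malignant else "benign",
               "study_seed": study_seed}
        row.update(truth_from_spec(spec, depth))
        for f, v in dataclasses.asdict(spec).items():
            if f != "compartment_curves":
                row[f"spec_{f}"] = v if not isinstance(v, tuple) else str(v)
        rows.append(row)
    return pairs, pd.DataFrame(rows)


def simulate_rater_scores(
    image_ids: list[tuple[str, str]],
    hallucination: np.ndarray,
    n_raters: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate 1-5 similarity scores from ``n_raters`` readers.

    Each image's latent quality decreases with its hallucination index;
    raters add an individual bias and independent noise before rounding
    to the 1-5 scale.  Returns a tidy table (image_id, phase, rater,
    score).
    """
    rng = np.random.default_rng(seed)
    hallucination = np.asarray(hallucination, dtype=float)
    biases = np.linspace(-0.5, 0.5, n_raters)
    rows = []
    for (study_id, phase), h in zip(image_ids, hallucination):
        latent = 5.0 - 7.0 * h
        for r in range(n_raters):
            s = latent + biases[r] + rng.normal(0.0, 0.8)
            rows.append(
                {
                    "image_id": f"{study_id}:{phase}",
                    "study_id": study_id,
                    "phase": str(phase),
                    "rater": f"R{r + 1}",
                    "score": int(np.clip(round(s), 1, 5)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# recovery grid: well-separated phantoms with known categorical truth
# ---------------------------------------------------------------------------


def recovery_grid() -> list[tuple[PhantomSpec, dict]]:
    """A grid of >= 32 noiseless phantoms with well-separated parameters
    and their implied categorical feature truth.

    The first 16 entries are the full factorial of margin shape x margin
    definition x heterogeneity x necrosis at a fixed corticomedullary
    placement; the remainder vary composition, fat, exophytic fraction,
    side, medial/lateral position, depth, pelvis invasion and size.
    """
    out: list[tuple[PhantomSpec, dict]] = []
    base = PhantomSpec(
        kidney_side="left",
        tumor_center=(64.0, 75.0),
        tumor_semi_axes_mm=(10.0, 8.0),
        phase_curve=(30.0, 80.0, 110.0, 90.0),
        noise_sigma=0.0,
    )

    def add(spec: PhantomSpec, depth: str) -> None:
        out.append((spec, truth_from_spec(spec, depth)))

    for shape in ("smooth", "lobulated"):
        for definition in ("well_marginated", "infiltrative"):
            for het in (0.0, 40.0):
                for nec in (0.0, 0.2):
                    add(
                        base.replace(
                            margin_shape=shape,
                            lobulation_amplitude=0.3 if shape == "lobulated" else 0.0,
                            margin_definition=definition,
                            edge_blur_px=4.0 if definition == "infiltrative" else 0.0,
                            heterogeneity=het,
                            necrosis_fraction=nec,
                        ),
                        "corticomedullary",
                    )

    # cystic benign lesion
    add(base.replace(composition="cystic", phase_curve=(10.0, 12.0, 13.0, 12.0)),
        "corticomedullary")
    # fat-containing lesion (angiomyolipoma-like)
    add(base.replace(has_fat=True), "corticomedullary")
    # small low-enhancement benign cortical lesion
    small = base.replace(
        tumor_center=(64.0, 64.0 - (-1) * 25.5),  # lateral cortex, left kidney
        tumor_semi_axes_mm=(4.0, 3.0),
        phase_curve=(30.0, 36.0, 38.0, 34.0),
    )
    add(small, "cortical")
    # exophytic ladder on lateral cortical tumors
    for f in (0.25, 0.5, 0.75):
        spec = base.replace(exophytic_fraction=f, tumor_semi_axes_mm=(9.0, 7.0))
        spec = spec.replace(tumor_center=solve_exophytic_center(spec, f))
        add(spec, "cortical")
    # right-sided mirror of the base and of an exophytic tumor
    right = base.replace(kidney_side="right", tumor_center=(64.0, 53.0))
    add(right, "corticomedullary")
    spec = base.replace(kidney_side="right", exophytic_fraction=0.7,
                        tumor_semi_axes_mm=(9.0, 7.0))
    spec = spec.replace(tumor_center=solve_exophytic_center(spec, 0.7))
    add(spec, "cortical")
    # medial endophytic corticomedullary tumor (left: medial is -col)
    add(base.replace(tumor_center=(44.0, 58.0), tumor_semi_axes_mm=(6.0, 5.0)),
        "corticomedullary")
    # sinus tumor (lateral part of the sinus, clear of the pelvis)
    add(base.replace(tumor_center=(64.0, 60.0), tumor_semi_axes_mm=(5.0, 3.0)),
        "sinus")
    # pelvis-invading sinus tumor
    add(
        base.replace(
            tumor_center=(64.0, 54.0),
            tumor_semi_axes_mm=(6.0, 5.0),
            invades_pelvis=True,
        ),
        "sinus",
    )
    # aggressive composite malignant phenotype, right side
    add(
        PhantomSpec(
            kidney_side="right",
            tumor_center=(64.0, 53.0),
            tumor_semi_axes_mm=(12.0, 9.0),
            margin_shape="lobulated",
            lobulation_amplitude=0.3,
            margin_definition="infiltrative",
            edge_blur_px=4.0,
            heterogeneity=40.0,
            necrosis_fraction=0.25,
            has_fat=False,
            phase_curve=(35.0, 100.0, 130.0, 105.0),
        ),
        "corticomedullary",
    )
    # cystic exophytic lesion
    spec = base.replace(
        composition="cystic",
        phase_curve=(8.0, 10.0, 11.0, 10.0),
        exophytic_fraction=0.25,
        tumor_semi_axes_mm=(8.0, 6.5),
    )
    spec = spec.replace(tumor_center=solve_exophytic_center(spec, 0.25))
    add(spec, "cortical")
    # excretory-dominant enhancement curve
    add(base.replace(phase_curve=(30.0, 60.0, 90.0, 120.0)), "corticomedullary")
    # right kidney, medial endophytic corticomedullary tumor
    add(
        base.replace(kidney_side="right", tumor_center=(44.0, 70.0),
                     tumor_semi_axes_mm=(6.0, 5.0)),
        "corticomedullary",
    )
    # strongly exophytic lobulated tumor
    spec = base.replace(
        margin_shape="lobulated",
        lobulation_amplitude=0.3,
        exophytic_fraction=0.75,
        tumor_semi_axes_mm=(9.0, 7.0),
    )
    spec = spec.replace(tumor_center=solve_exophytic_center(spec, 0.75))
    add(spec, "cortical")
    # fat and necrosis together
    add(base.replace(has_fat=True, necrosis_fraction=0.2), "corticomedullary")
    return out
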
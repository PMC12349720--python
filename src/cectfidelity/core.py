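"""Core containers for four-phase renal CECT crops.

A *study* is one four-phase contrast-enhanced CT acquisition of a renal
mass, cropped to a small (by default 128x128) window around the tumor.
Pixel values are Hounsfield Units (HU).  The four phases are ordered by
acquisition time: precontrast, corticomedullary (arterial),
nephrographic (venous) and excretory.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "Phase",
    "PHASES",
    "POST_CONTRAST_PHASES",
    "Provenance",
    "PhaseImage",
    "StudySet",
    "HU_CLIP_RANGE",
]

#: HU window applied before any intensity statistic.
HU_CLIP_RANGE = (-150.0, 1000.0)


class Phase(str, enum.Enum):
    """Acquisition phase of a four-phase renal CECT protocol, in order."""

    PRECONTRAST = "precontrast"
    CORTICOMEDULLARY = "corticomedullary"
    NEPHROGRAPHIC = "nephrographic"
    EXCRETORY = "excretory"

    @property
    def index(self) -> int:
        return PHASES.index(self)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


PHASES: tuple[Phase, ...] = (
    Phase.PRECONTRAST,
    Phase.CORTICOMEDULLARY,
    Phase.NEPHROGRAPHIC,
    Phase.EXCRETORY,
)

POST_CONTRAST_PHASES: tuple[Phase, ...] = PHASES[1:]


class Provenance(str, enum.Enum):
    GROUND_TRUTH = "ground_truth"
    IMPUTED = "imputed"
    SURROGATE = "surrogate"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class PhaseImage:
    """One HU-valued 2-D tumor crop.

    Parameters
    ----------
    pixels
        2-D float array of HU values (unclipped; clipping is an explicit
        downstream operation).
    phase
        Acquisition phase label.
    pixel_spacing
        Isotropic in-plane spacing in mm per pixel (> 0).
    study_id
        Identifier of the parent study.
    provenance
        ``ground_truth`` for acquired images, ``imputed`` for generative
        model output, ``surrogate`` for the degradation simulator.
    """

    pixels: np.ndarray
    phase: Phase
    pixel_spacing: float = 1.0
    study_id: str = ""
    provenance: Provenance = Provenance.GROUND_TRUTH

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("PhaseImage pixels must be a 2-D grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("PhaseImage pixels must be finite")
        if not self.pixel_spacing > 0:
            raise ValueError("pixel_spacing must be > 0")
        self.phase = Phase(self.phase)
        self.provenance = Provenance(self.provenance)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def copy_with(self, **kw) -> "PhaseImage":
        data = dict(
            pixels=self.pixels.copy(),
            phase=self.phase,
            pixel_spacing=self.pixel_spacing,
            study_id=self.study_id,
            provenance=self.provenance,
        )
        data.update(kw)
        return PhaseImage(**data)


@dataclass
class StudySet:
    """The four phase images of one study sharing a pixel grid.

    ``tumor_roi`` is the tumor region-of-interest mask (boolean, same
    grid).  ``compartments`` optionally carries kidney-compartment masks
    (``kidney``, ``cortex``, ``medulla``, ``sinus``, ``pelvis``) for
    synthetic studies where anatomy is known.  ``meta`` carries
    free-form study metadata (e.g. ``kidney_side``).
    """

    images: Mapping[Phase, PhaseImage]
    tumor_roi: np.ndarray
    compartments: dict[str, np.ndarray] = field(default_factory=dict)
    study_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.images = {Phase(p): im for p, im in self.images.items()}
        if set(self.images) != set(PHASES):
            missing = [p.value for p in PHASES if p not in self.images]
            raise ValueError(f"study must contain all four phases; missing: {missing}")
        shapes = {im.shape for im in self.images.values()}
        if len(shapes) != 1:
            raise ValueError("phase images must share one geometry")
        self.tumor_roi = np.asarray(self.tumor_roi, dtype=bool)
        (shape,) = shapes
        if self.tumor_roi.shape != shape:
            raise ValueError("tumor ROI must share the image grid")
        if not self.tumor_roi.any():
            raise ValueError("tumor ROI is empty")
        for name, mask in self.compartments.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != shape:
                raise ValueError(f"compartment mask {name!r} must share the image grid")
            self.compartments[name] = mask
        for im in self.images.values():
            if not im.study_id:
                im.study_id = self.study_id

    def __getitem__(self, phase: Phase | str) -> PhaseImage:
        return self.images[Phase(phase)]

    @property
    def pixel_spacing(self) -> float:
        return next(iter(self.images.values())).pixel_spacing

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.images.values())).shape

    def with_image(self, image: PhaseImage) -> "StudySet":
        """Return a new study with one phase replaced (e.g. by a surrogate)."""
        images = {p: im for p, im in self.images.items()}
        images[image.phase] = image
        return StudySet(
            images=images,
            tumor_roi=self.tumor_roi.copy(),
            compartments={k: v.copy() for k, v in self.compartments.items()},
            study_id=self.study_id,
            meta=dict(self.meta),
        )
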
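"""Readers and writers for the formats the pipeline touches.

Image studies travel as NIfTI (one file per phase), DICOM series, or a
portable NumPy archive (``.npz``) used for fixtures and intermediate
results.  Feature tables are CSV/XLSX with a user-editable schema map
translating spreadsheet headers onto the canonical feature names.
Phase identity and HU rescaling are never guessed: phase labels come
from the caller/config, and DICOM files must declare a rescale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom

from .characterize import CATEGORICAL_FEATURES, QUANTITATIVE_FEATURES
from .core import PHASES, Phase, PhaseImage, Provenance, StudySet

__all__ = [
    "write_study_npz",
    "read_study_npz",
    "write_study_nifti",
    "read_study",
    "read_dicom_image",
    "FeatureTable",
    "read_feature_table",
    "write_feature_table",
]

_MASK_PREFIX = "mask_"


def write_study_npz(study: StudySet, path) -> Path:
    """Write a study (4 phases + ROI + compartment masks) to one archive."""
    path = Path(path)
    arrays = {f"phase_{p.value}": study[p].pixels for p in PHASES}
    arrays["tumor_roi"] = study.tumor_roi
    for name, mask in study.compartments.items():
        arrays[f"{_MASK_PREFIX}{name}"] = mask
    meta = {
        "study_id": study.study_id,
        "pixel_spacing": study.pixel_spacing,
        "provenance": {p.value: study[p].provenance.value for p in PHASES},
        "meta": {k: v for k, v in study.meta.items() if isinstance(v, (str, int, float, list, tuple))},
    }
    arrays["meta_json"] = np.array(json.dumps(meta))
    np.savez_compressed(path, **arrays)
    return path


def read_study_npz(path) -> StudySet:
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(str(z["meta_json"]))
        images = {}
        for p in PHASES:
            key = f"phase_{p.value}"
            if key not in z:
                raise ValueError(f"archive is missing phase {p.value!r}")
            images[p] = PhaseImage(
                pixels=z[key],
                phase=p,
                pixel_spacing=float(meta["pixel_spacing"]),
                study_id=meta["study_id"],
                provenance=Provenance(meta["provenance"][p.value]),
            )
        compartments = {
            k[len(_MASK_PREFIX):]: z[k].astype(bool)
            for k in z.files
            if k.startswith(_MASK_PREFIX)
        }
        return StudySet(
            images=images,
            tumor_roi=z["tumor_roi"].astype(bool),
            compartments=compartments,
            study_id=meta["study_id"],
            meta=meta.get("meta", {}),
        )


def write_study_nifti(study: StudySet, directory) -> dict[str, Path]:
    """Write one NIfTI per phase plus the ROI mask; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    s = study.pixel_spacing
    affine = np.diag([s, s, 1.0, 1.0])
    paths: dict[str, Path] = {}
    for p in PHASES:
        path = directory / f"{study.study_id or 'study'}_{p.value}.nii"
        nib.save(nib.Nifti1Image(study[p].pixels[..., None].astype(np.float32), affine), path)
        paths[p.value] = path
    roi_path = directory / f"{study.study_id or 'study'}_roi.nii"
    nib.save(nib.Nifti1Image(study.tumor_roi[..., None].astype(np.uint8), affine), roi_path)
    paths["tumor_roi"] = roi_path
    return paths


def read_dicom_image(path, phase: Phase | str, study_id: str = "",
                     provenance: str = "ground_truth") -> PhaseImage:
    """Read one DICOM slice as HU, applying the declared rescale.

    Raises if the file declares no RescaleSlope/RescaleIntercept: raw
    stored values are not assumed to be HU.
    """
    ds = pydicom.dcmread(str(path))
    if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
        raise ValueError(f"{path}: no rescale declared; cannot interpret stored values as HU")
    hu = ds.pixel_array.astype(float) * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
    spacing = float(ds.PixelSpacing[0]) if "PixelSpacing" in ds else 1.0
    return PhaseImage(pixels=hu, phase=Phase(phase), pixel_spacing=spacing,
                      study_id=study_id, provenance=Provenance(provenance))


def read_study(
    paths: dict[str, str | Path],
    layout: str = "nifti_per_phase",
    roi_path=None,
    pixel_spacing: float | None = None,
    study_id: str = "",
) -> StudySet:
    """Assemble a StudySet from per-phase files.

    ``paths`` maps phase label -> file; phase labels are taken from the
    mapping, never guessed from file names.  Layouts: ``nifti_per_phase``,
    ``dicom_series``, ``array_archive`` (a single npz; ``paths`` ignored
    except for the ``archive`` key).
    """
    if layout == "array_archive":
        return read_study_npz(paths["archive"])
    missing = [p.value for p in PHASES if p.value not in paths]
    if missing:
        raise ValueError(f"missing phase file(s): {missing}")
    images = {}
    for p in PHASES:
        f = Path(paths[p.value])
        if layout == "nifti_per_phase":
            img = nib.load(str(f))
            data = np.asarray(img.dataobj, dtype=float)
            data = data[..., 0] if data.ndim == 3 else data
            spacing = pixel_spacing or float(img.header.get_zooms()[0])
            images[p] = PhaseImage(pixels=data, phase=p, pixel_spacing=spacing,
                                   study_id=study_id)
        elif layout == "dicom_series":
            images[p] = read_dicom_image(f, p, study_id=study_id)
        else:
            raise ValueError(f"unknown layout {layout!r}")
    shapes = {im.shape for im in images.values()}
    if len(shapes) != 1:
        raise ValueError("phase geometries differ")
    if roi_path is None:
        raise ValueError("a tumor ROI mask is required")
    roi = np.asarray(nib.load(str(roi_path)).dataobj)
    roi = roi[..., 0] if roi.ndim == 3 else roi
    return StudySet(images=images, tumor_roi=roi.astype(bool), study_id=study_id)


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

_KEY_COLUMNS = ["study_id", "phase", "provenance"]
CANONICAL_COLUMNS = _KEY_COLUMNS + CATEGORICAL_FEATURES + QUANTITATIVE_FEATURES


@dataclass
class FeatureTable:
    """Aligned GT/imputed per-image feature rows."""

    gt: pd.DataFrame
    imputed: pd.DataFrame
    passthrough: list[str]

    @property
    def n_pairs(self) -> int:
        key = ["study_id", "phase"]
        return len(self.gt.merge(self.imputed, on=key)[key])


def read_feature_table(path, schema_map: dict[str, str] | None = None,
                       strict: bool = True) -> FeatureTable:
    """Read a per-image feature spreadsheet (CSV or XLSX).

    ``schema_map`` maps canonical column names onto the file's headers
    for any header that differs.  All 21 canonical features plus the
    key columns must be resolvable; unmapped extra columns are kept as
    passthrough.  With ``strict``, rows without a GT/imputed partner
    raise; otherwise they are dropped.
    """
    path = Path(path)
    df = pd.read_excel(path) if path.suffix.lower() in (".xlsx", ".xls") else pd.read_csv(path)
    schema_map = schema_map or {}
    rename = {v: k for k, v in schema_map.items()}
    df = df.rename(columns=rename)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table is missing canonical columns: {missing}")
    passthrough = [c for c in df.columns if c not in CANONICAL_COLUMNS]

    prov = df["provenance"].astype(str)
    gt = df[prov == "ground_truth"].copy()
    imp = df[prov != "ground_truth"].copy()
    key = ["study_id", "phase"]
    paired = gt.merge(imp[key], on=key)[key]
    unpaired = (len(gt) - len(paired)) + (len(imp) - len(paired))
    if unpaired and strict:
        raise ValueError(f"{unpaired} rows have no GT/imputed partner")
    if unpaired:
        gt = gt.merge(paired, on=key)
        imp = imp.merge(paired, on=key)
    return FeatureTable(gt=gt.reset_index(drop=True), imputed=imp.reset_index(drop=True),
                        passthrough=passthrough)


def write_feature_table(gt: pd.DataFrame, imputed: pd.DataFrame, path) -> Path:
    """Write aligned GT/imputed rows to one tidy CSV."""
    path = Path(path)
    out = pd.concat([gt, imputed], ignore_index=True)
    cols = [c for c in CANONICAL_COLUMNS if c in out.columns]
    cols += [c for c in out.columns if c not in cols]
    out[cols].to_csv(path, index=False)
    return path
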
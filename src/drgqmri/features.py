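"""DRG imaging features from quantitative maps and ROI label masks.

Three features per dorsal root ganglion (DRG): volume (voxel count times
voxel volume, mm^3), mean T2 (ms) and proton density (PD, a.u.) — the ROI
mean of the fitted M0 map normalised to a cerebrospinal-fluid (CSF) reference
restricted to the same axial slices, which approximates "same distance from
the receiving coil" matching and cancels the unknown global signal scale.

Aggregation follows the reading-session design: each rater segments every
DRG; per-DRG records are kept in a long table, then per subject the two sides
are averaged within level, the two levels (L5, S1) averaged into a
"mean of L5 and S1", and finally rater values averaged — producing one
analysis value per subject and feature.

Volume is computed from the raw mask voxel count (geometry feature); T2 and
PD means use only QC-clean voxels (intensity features need trustworthy fits).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .relaxometry import QuantMaps

__all__ = [
    "LabelInfo",
    "RoiMask",
    "DrgFeatureRecord",
    "compute_volume",
    "extract_roi_mean",
    "normalize_pd",
    "build_feature_table",
    "LEVELS",
    "SIDES",
]

LEVELS = ("L5", "S1")
SIDES = ("L", "R")


@dataclass(frozen=True)
class LabelInfo:
    """Identity of one labelled structure: DRG at a level/side, or CSF."""

    structure: str  # "DRG", "CSF" or "tissue"
    level: str = "NA"  # "L5", "S1" or "NA"
    side: str = "NA"  # "L", "R" or "NA"
    rater_id: str = "truth"


@dataclass
class RoiMask:
    """Labelled 3D integer mask with per-label identity and voxel spacing."""

    labels: np.ndarray
    spacing: Tuple[float, float, float]
    label_table: Dict[int, LabelInfo]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if np.any(self.labels < 0):
            raise ValueError("labels must be non-negative")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from label_table")

    @property
    def voxel_volume(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def drg_labels(self) -> List[int]:
        return [lab for lab, info in self.label_table.items()
                if info.structure == "DRG"]

    def csf_label(self) -> int:
        for lab, info in self.label_table.items():
            if info.structure == "CSF":
                return lab
        raise KeyError("mask has no CSF label")

    def label_for(self, level: str, side: str) -> int:
        for lab, info in self.label_table.items():
            if info.structure == "DRG" and info.level == level and info.side == side:
                return lab
        raise KeyError(f"no DRG label for level={level}, side={side}")


@dataclass(frozen=True)
class DrgFeatureRecord:
    """Per-DRG feature record for one rater."""

    subject_id: str
    level: str
    side: str
    rater_id: str
    volume: float  # mm^3, raw voxel count x voxel volume
    t2_mean: float  # ms, QC-filtered ROI mean
    pd: float  # a.u., CSF-normalised
    n_voxels: int
    qc_excluded_fraction: float


def compute_volume(mask: RoiMask, label: int) -> float:
    """ROI volume in mm^3: voxel count times voxel volume, spacing taken from
    the mask geometry (not any protocol constant)."""
    n = int(np.sum(mask.labels == label))
    if n == 0:
        raise ValueError(f"label {label} is empty in this mask")
    return n * mask.voxel_volume


def extract_roi_mean(map_volume: np.ndarray, mask: RoiMask, label: int,
                     qc_flags: Optional[np.ndarray] = None):
    """Arithmetic mean of a map over unflagged in-ROI voxels.

    Returns ``(mean, excluded_fraction)``.  Raises if every ROI voxel is
    QC-flagged, carrying the counts in the message.
    """
    sel = mask.labels == label
    n_total = int(sel.sum())
    if n_total == 0:
        raise ValueError(f"label {label} is empty in this mask")
    if qc_flags is not None:
        good = sel & (qc_flags == 0)
    else:
        good = sel
    n_good = int(good.sum())
    if n_good == 0:
        raise RuntimeError(
            f"all {n_total} voxels of label {label} are QC-flagged; "
            "inspect the fit-quality report before extracting features")
    return float(np.mean(map_volume[good])), 1.0 - n_good / n_total


def normalize_pd(m0_map: np.ndarray, mask: RoiMask, drg_label: int,
                 csf_label: int, qc_flags: Optional[np.ndarray] = None) -> float:
    """CSF-normalised proton density of one DRG.

    ``pd = mean(M0 | DRG) / mean(M0 | CSF on the DRG's axial slices)``.  The
    slice restriction keeps the reference at the same coil distance as the
    ganglion.  Scale-invariant: multiplying the whole M0 map by c > 0 leaves
    pd unchanged.
    """
    drg_sel = mask.labels == drg_label
    if not drg_sel.any():
        raise ValueError(f"DRG label {drg_label} is empty")
    z_slices = np.unique(np.nonzero(drg_sel)[2])
    csf_sel = np.zeros_like(drg_sel)
    csf_sel[:, :, z_slices] = mask.labels[:, :, z_slices] == csf_label
    if qc_flags is not None:
        drg_sel = drg_sel & (qc_flags == 0)
        csf_sel = csf_sel & (qc_flags == 0)
        if not drg_sel.any():
            raise RuntimeError(f"all voxels of DRG label {drg_label} are QC-flagged")
    if not csf_sel.any():
        raise ValueError(
            f"no usable CSF reference voxels on the axial slices of DRG label "
            f"{drg_label}; segment the CSF reference over a wider slice range")
    return float(np.mean(m0_map[drg_sel]) / np.mean(m0_map[csf_sel]))


def _records_for_subject(subject_id: str, maps: QuantMaps,
                         masks_by_rater: Mapping[str, RoiMask]) -> List[DrgFeatureRecord]:
    records = []
    for rater_id, mask in masks_by_rater.items():
        csf = mask.csf_label()
        for level in LEVELS:
            for side in SIDES:
                lab = mask.label_for(level, side)
                vol = compute_volume(mask, lab)
                t2_mean, excl = extract_roi_mean(maps.t2, mask, lab, maps.qc_flags)
                pd_val = normalize_pd(maps.m0, mask, lab, csf, maps.qc_flags)
                records.append(DrgFeatureRecord(
                    subject_id=subject_id, level=level, side=side,
                    rater_id=str(rater_id), volume=vol, t2_mean=t2_mean,
                    pd=pd_val, n_voxels=int(np.sum(mask.labels == lab)),
                    qc_excluded_fraction=excl))
    return records


FEATURES = ("volume", "t2", "pd")
_LONG_COLS = {"volume": "volume", "t2": "t2_mean", "pd": "pd"}


def build_feature_table(
    subjects: Iterable[Tuple[str, QuantMaps, Mapping[str, RoiMask]]],
    demographics: Optional[pd.DataFrame] = None,
):
    """Assemble the long per-DRG table and the per-subject analysis table.

    Parameters
    ----------
    subjects : iterable of (subject_id, QuantMaps, {rater_id: RoiMask})
    demographics : DataFrame indexed by ``subject_id`` with at least a
        ``group`` column; ``height`` (cm) and ``weight`` (kg) yield BMI.

    Returns
    -------
    long_df : DataFrame
        One row per (subject, level, side, rater) with volume/t2_mean/pd.
    cohort_df : DataFrame
        One row per subject: demographics plus, for each feature, values at
        L5, S1 and the mean of the two levels, sides and raters averaged
        arithmetically (sides within level, then levels, then raters).
    completeness : dict
        Subjects dropped from the aggregated table and why.
    """
    all_records: List[DrgFeatureRecord] = []
    completeness: Dict[str, str] = {}
    subject_ids: List[str] = []
    for subject_id, maps, masks_by_rater in subjects:
        subject_ids.append(subject_id)
        try:
            all_records.extend(_records_for_subject(subject_id, maps, masks_by_rater))
        except (KeyError, ValueError, RuntimeError) as exc:
            completeness[subject_id] = str(exc)
            warnings.warn(
                f"subject {subject_id} dropped from aggregated table: {exc}")

    long_df = pd.DataFrame([r.__dict__ for r in all_records])

    rows = []
    for subject_id in subject_ids:
        if subject_id in completeness:
            continue
        sub = long_df[long_df.subject_id == subject_id]
        row: Dict[str, object] = {"subject_id": subject_id}
        for feat in FEATURES:
            col = _LONG_COLS[feat]
            # sides -> level value, per rater; then mean of levels; then raters
            per_rater_level = sub.groupby(["rater_id", "level"])[col].mean()
            per_rater_mean = per_rater_level.groupby("rater_id").mean()
            for level in LEVELS:
                row[f"{feat}_{level}"] = float(
                    per_rater_level.xs(level, level="level").mean())
            row[f"{feat}_mean"] = float(per_rater_mean.mean())
        rows.append(row)
    cohort_df = pd.DataFrame(rows).set_index("subject_id") if rows else pd.DataFrame()

    if demographics is not None and not cohort_df.empty:
        demo = demographics.copy()
        if "subject_id" in demo.columns:
            demo = demo.set_index("subject_id")
        cohort_df = demo.join(cohort_df, how="inner")
        if {"height", "weight"}.issubset(cohort_df.columns) and "bmi" not in cohort_df:
            cohort_df["bmi"] = cohort_df["weight"] / (cohort_df["height"] / 100.0) ** 2
    return long_df, cohort_df, completeness
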
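"""Per-subject features and cohort statistics.

Each subject contributes three region-mean curvatures (m⁻¹): the
mid-forehead strip (``h_mid``) and the left/right supraorbital strips,
pooled per subject into ``h_orb = (left + right) / 2`` to match the single
clinically reported "right/left lateral orbital areas" value.

Group comparison uses Welch's unequal-variance two-sample t-test by
default (the groups differ in size and spread); Student's pooled-variance
test is available. Summary SDs use the n−1 sample denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .curvature import CurvatureField, mean_curvature, smooth_field
from .errors import CranioCurveError, InputError, SegmentationError, StatisticsError
from .mesh_io import LandmarkSet
from .regions import (
    RegionMask,
    region_mean_curvature,
    segment_midforehead,
    segment_supraorbital,
)

log = logging.getLogger(__name__)

FEATURE_COLUMNS = ["subject_id", "source", "h_mid", "h_orb_left", "h_orb_right", "h_orb"]


@dataclass
class GroupSummary:
    """Mean ± SD of both features for one labelled group."""

    group_name: str
    n: int
    h_mid_mean: float
    h_mid_sd: float
    h_orb_mean: float
    h_orb_sd: float


def subject_features(
    subject_id: str,
    field: CurvatureField,
    masks: dict[str, RegionMask],
    source: str = "synthetic",
) -> dict:
    """One feature row from a curvature field and its three region masks."""
    h_mid = region_mean_curvature(field, masks["midforehead"])
    h_l = region_mean_curvature(field, masks["supraorbital_left"])
    h_r = region_mean_curvature(field, masks["supraorbital_right"])
    return {
        "subject_id": subject_id,
        "source": source,
        "h_mid": h_mid,
        "h_orb_left": h_l,
        "h_orb_right": h_r,
        "h_orb": (h_l + h_r) / 2.0,
    }


def features_from_mesh(
    subject_id: str,
    mesh,
    landmarks: LandmarkSet,
    midforehead_width_mm: float = 10.0,
    supraorbital_width_mm: float = 10.0,
    smoothing_iterations: int = 0,
    up_hint=None,
    source: str = "synthetic",
) -> dict:
    """Full single-subject pipeline: curvature → segmentation → features.

    ``up_hint`` ("above the rim" direction) defaults to the direction from
    the rim centroid toward the anterior fontanelle, which is frame-free.
    """
    field = mean_curvature(mesh)
    if smoothing_iterations:
        field = smooth_field(field, mesh, smoothing_iterations)
    masks = {}
    masks["midforehead"] = segment_midforehead(
        mesh, landmarks, midforehead_width_mm, vertex_areas=field.vertex_area
    )
    for side in ("left", "right"):
        rim = getattr(landmarks, f"rim_{side}")
        hint = up_hint
        if hint is None:
            hint = landmarks.anterior_fontanelle - rim.mean(axis=0)
        masks[f"supraorbital_{side}"] = segment_supraorbital(
            mesh,
            rim,
            supraorbital_width_mm,
            up_hint=hint,
            region_name=f"supraorbital_{side}",
            vertex_areas=field.vertex_area,
        )
    return subject_features(subject_id, field, masks, source=source)


def build_features(subjects: dict) -> tuple[pd.DataFrame, list[str]]:
    """Assemble a feature table from per-subject (field, masks) pairs.

    ``subjects`` maps subject_id → dict with keys ``field``, ``masks`` and
    optionally ``source``. Per-subject failures are recorded and skipped,
    never fatal to the batch. Returns (table, failed subject ids).
    """
    ids = list(subjects)
    if len(set(ids)) != len(ids):
        raise InputError("duplicate subject ids in feature batch")
    rows, failed = [], []
    for sid, payload in subjects.items():
        try:
            rows.append(
                subject_features(
                    sid,
                    payload["field"],
                    payload["masks"],
                    source=payload.get("source", "synthetic"),
                )
            )
        except (SegmentationError, CranioCurveError) as exc:
            log.warning("subject %s failed: %s", sid, exc)
            failed.append(sid)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS), failed


def _merge_labels(features: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    missing = set(features["subject_id"]) - set(labels["subject_id"])
    if missing:
        raise InputError(f"subjects without labels: {sorted(missing)}")
    return features.merge(labels, on="subject_id", how="inner")


def group_summary(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    group_column: str = "clinician_label",
    surgical_value: str = "operative",
) -> tuple[GroupSummary, GroupSummary, dict]:
    """Per-group mean/SD of both features plus surgical − non-surgical differences.

    Returns (surgical summary, non-surgical summary, differences dict with
    keys ``h_mid`` and ``h_orb``).
    """
    df = _merge_labels(features, labels)
    summaries = {}
    for name, sub in df.groupby(group_column):
        if len(sub) < 2:
            raise StatisticsError(f"group {name!r} has n={len(sub)} < 2")
        summaries[name] = GroupSummary(
            group_name=str(name),
            n=len(sub),
            h_mid_mean=float(sub["h_mid"].mean()),
            h_mid_sd=float(sub["h_mid"].std(ddof=1)),
            h_orb_mean=float(sub["h_orb"].mean()),
            h_orb_sd=float(sub["h_orb"].std(ddof=1)),
        )
    if len(summaries) != 2:
        raise StatisticsError(f"expected 2 groups, found {sorted(summaries)}")
    surgical = summaries.pop(surgical_value, None)
    if surgical is None:
        raise StatisticsError(f"no group labelled {surgical_value!r}")
    (other,) = summaries.values()
    diffs = summary_differences(surgical, other)
    return surgical, other, diffs


def summary_differences(surgical: GroupSummary, conservative: GroupSummary) -> dict:
    """Surgical − non-surgical differences of the group mean curvatures (m⁻¹)."""
    return {
        "h_mid": surgical.h_mid_mean - conservative.h_mid_mean,
        "h_orb": surgical.h_orb_mean - conservative.h_orb_mean,
    }


def load_reference_summary() -> pd.DataFrame:
    """Published group-level curvature statistics (means ± SD, m⁻¹).

    Columns: group, n, h_mid_mean, h_mid_sd, h_orb_mean, h_orb_sd, for the
    surgical/non-surgical treatment groups and the severe/mild clusters.
    """
    with resources.files("craniocurve.data").joinpath("reference_groups.csv").open() as fh:
        return pd.read_csv(fh)


def reference_group_summary(group: str) -> GroupSummary:
    """One row of the published reference table as a GroupSummary."""
    df = load_reference_summary()
    row = df.loc[df["group"] == group]
    if row.empty:
        raise InputError(f"unknown reference group {group!r}; have {df['group'].tolist()}")
    r = row.iloc[0]
    return GroupSummary(
        group_name=group,
        n=int(r["n"]),
        h_mid_mean=float(r["h_mid_mean"]),
        h_mid_sd=float(r["h_mid_sd"]),
        h_orb_mean=float(r["h_orb_mean"]),
        h_orb_sd=float(r["h_orb_sd"]),
    )


def welch_test(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    feature_name: str,
    group_column: str = "clinician_label",
    equal_var: bool = False,
) -> tuple[float, float, float]:
    """Two-sample t-test on one feature. Returns (t, df, two-sided p).

    Welch's unequal-variance form by default; set ``equal_var=True`` for
    the pooled Student test. Two identical degenerate groups return
    (0, df, 1) with a warning rather than NaN.
    """
    df = _merge_labels(features, labels)
    grouped = {name: sub[feature_name].to_numpy() for name, sub in df.groupby(group_column)}
    if len(grouped) != 2:
        raise StatisticsError("welch_test needs exactly 2 groups")
    # reverse-lexicographic order puts the affected group first for the
    # conventional label pairs (operative/conservative, surgical/nonsurgical,
    # severe/mild), so t > 0 when that group has the larger mean
    a, b = (grouped[k] for k in sorted(grouped, reverse=True))
    if len(a) < 2 or len(b) < 2:
        raise StatisticsError("both groups need n >= 2")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        log.warning("zero variance in both groups with equal means; p = 1")
        return 0.0, float(len(a) + len(b) - 2), 1.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)
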
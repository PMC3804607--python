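"""Crypt morphometry, budding staging and population statistics.

Isolated colonic crypts are test-tube shaped epithelial invaginations.  Their
production of daughter crypts proceeds through four stages: a quiescent crypt
(stage 0), the appearance of a small bud near the base (stage 1), mid-budding
with the developing front ascending the parent axis (stage 2), and a nearly
mature daughter still attached while the front sits in the top half of the
parent (stage 3).  This module measures crypt geometry from polyline
annotations, assigns budding stages from the height of the developing front,
quantifies budding asymmetry, tabulates stage frequencies per age and colon
region, and runs the one-way ANOVA group comparisons used throughout the
analysis.

Conventions
-----------
* All coordinates and lengths are in micrometres; polylines are ``(n, 3)``
  arrays ordered base -> top (axis order ``(z, y, x)``).
* Budding crypts are described by the two branch lengths below the division
  point: the parent-side branch (division point down to the parent base) and
  the daughter branch (division point down to the daughter base).
* The developing-front height ``h`` is measured from the parent base along the
  parent axis; the stage is a function of ``f = h / L``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

#: Default height (as a fraction of crypt length above the base) at which the
#: basal width is measured — "about 20% of the crypt length from the crypt
#: base".
BASAL_WIDTH_FRACTION = 0.20

#: Stage boundaries on the normalized developing-front height f = h / L.
#: f < STAGE1_BOUNDARY   -> stage 1 (small bud near the bottom)
#: f < STAGE3_BOUNDARY   -> stage 2 (mid-budding)
#: f >= STAGE3_BOUNDARY  -> stage 3 (front has reached the top half)
STAGE1_BOUNDARY = 0.25
STAGE3_BOUNDARY = 0.50

#: AI cutoff (percent) below which a budding event is scored symmetric.
AI_SYMMETRY_CUTOFF = 1.0

REGION_CODES = {"distal": "D", "middle": "M", "proximal": "P", "total": "T"}


class AnnotationError(ValueError):
    """Raised for malformed or insufficient crypt annotations."""


class StageClassificationError(ValueError):
    """Raised when a bud is present but its front height is unknown."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CryptAnnotation:
    """Manual annotation of a single crypt in micrometre coordinates.

    ``axis`` runs base -> top.  For budding crypts, ``branches`` holds the two
    polylines below the division point (parent-continuation and daughter),
    both starting at the shared division point, which must lie on the axis.
    """

    axis: np.ndarray
    branches: Optional[tuple[np.ndarray, np.ndarray]] = None
    basal_width_segment: Optional[np.ndarray] = None
    crypt_id: str = ""
    region: str = ""
    age: Optional[float] = None

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        if self.axis.ndim != 2 or self.axis.shape[1] != 3 or len(self.axis) < 2:
            raise AnnotationError(
                "axis must be an (n>=2, 3) polyline of micrometre points"
            )
        if self.branches is not None:
            b0 = np.asarray(self.branches[0], dtype=float)
            b1 = np.asarray(self.branches[1], dtype=float)
            if not np.allclose(b0[0], b1[0]):
                raise AnnotationError(
                    "both branches must start at the same division point"
                )
            d = _point_to_polyline_distance(b0[0], self.axis)
            if d > 1.0:  # one micrometre slack for hand annotation
                raise AnnotationError(
                    f"division point {b0[0]} lies {d:.2f} um off the axis"
                )
            self.branches = (b0, b1)
        if self.basal_width_segment is not None:
            seg = np.asarray(self.basal_width_segment, dtype=float)
            if seg.shape != (2, 3):
                raise AnnotationError("basal_width_segment must be two 3D points")
            self.basal_width_segment = seg


@dataclass
class CryptMorphology:
    """Measured morphology of one crypt."""

    crypt_id: str
    length: float
    basal_width: Optional[float] = None
    area: Optional[float] = None
    stage: int = 0
    asymmetry_index: Optional[float] = None
    is_daughter: bool = False
    region: str = ""
    age: Optional[float] = None


def _point_to_polyline_distance(point: np.ndarray, polyline: np.ndarray) -> float:
    p = np.asarray(point, float)
    a, b = polyline[:-1], polyline[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.min(np.linalg.norm(proj - p, axis=1)))


# ---------------------------------------------------------------------------
# Elementary measurements
# ---------------------------------------------------------------------------

def measure_length(axis: np.ndarray) -> float:
    """Total 3D polyline length in micrometres.

    The crypt length is the sum of the Euclidean lengths of the segments of
    the annotation polyline drawn along the crypt's luminal axis.
    """
    pts = np.asarray(axis, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise AnnotationError("length measurement needs >= 2 points in 3D")
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def measure_basal_width(
    annotation: Optional[CryptAnnotation] = None,
    *,
    crypt_mask: Optional[np.ndarray] = None,
    axis: Optional[np.ndarray] = None,
    voxel_size: float = 1.0,
    height_fraction: float = BASAL_WIDTH_FRACTION,
) -> float:
    """Basal width of a crypt in micrometres.

    With an annotated width segment the measurement is simply its Euclidean
    length.  In automatic mode (``crypt_mask`` given) the width is the maximal
    chord of the crypt cross-section in a one-voxel slab at
    ``height_fraction * length`` above the base, measured perpendicular to the
    crypt axis.  The default 20% height matches the convention of drawing the
    basal-width line at about one fifth of the crypt length from the base.
    """
    if not (0.0 < height_fraction < 1.0):
        raise ValueError(f"height_fraction must lie in (0, 1), got {height_fraction}")
    if annotation is not None and annotation.basal_width_segment is not None:
        seg = annotation.basal_width_segment
        return float(np.linalg.norm(seg[1] - seg[0]))
    if crypt_mask is None:
        raise AnnotationError(
            "basal width needs either an annotated width segment or a crypt mask"
        )
    if axis is None and annotation is not None:
        axis = annotation.axis
    from .compartmental import axial_coordinates  # local import, no cycle

    arc, total = axial_coordinates(crypt_mask, axis=axis, voxel_size=voxel_size)
    target = height_fraction * total
    in_slab = crypt_mask & (np.abs(arc - target) <= voxel_size / 2.0)
    coords = np.argwhere(in_slab).astype(float) * voxel_size
    if len(coords) < 2:
        raise AnnotationError("no crypt voxels found at the basal-width height")
    return float(np.max(pdist(coords)))


def rect_area(length: float, width: float) -> float:
    """Estimated rectangular area (length x width) as a crypt-size proxy."""
    if length <= 0 or width <= 0:
        raise ValueError(f"length and width must be positive, got ({length}, {width})")
    return float(length) * float(width)


def asymmetry_index(branch_lengths: Sequence[float]) -> float:
    """Asymmetry index (AI): mean percentage deviation of branch lengths.

    ``AI = 100 * mean(|L_i - Lbar|) / Lbar`` over the branches of a budding
    crypt.  For the usual two-branch case this reduces to
    ``100 * |L1 - L2| / (L1 + L2)``.  Budding events with AI above the 1%
    cutoff are scored asymmetric.
    """
    lengths = np.asarray(branch_lengths, dtype=float)
    if lengths.ndim != 1 or len(lengths) < 2:
        raise ValueError("asymmetry index needs at least two branch lengths")
    if np.any(lengths <= 0):
        raise ValueError(f"branch lengths must be positive, got {lengths}")
    mean = lengths.mean()
    return float(100.0 * np.mean(np.abs(lengths - mean)) / mean)


def is_asymmetric(ai: float, cutoff: float = AI_SYMMETRY_CUTOFF) -> bool:
    """Score a budding event asymmetric when its AI exceeds the cutoff (1%)."""
    return ai > cutoff


def classify_stage(
    length: float,
    front_height: Optional[float] = None,
    *,
    has_bud: Optional[bool] = None,
    stage1_boundary: float = STAGE1_BOUNDARY,
    stage3_boundary: float = STAGE3_BOUNDARY,
) -> int:
    """Assign the budding stage from parent length and developing-front height.

    With no bud the crypt is stage 0.  Otherwise, with ``f = front_height /
    length``: stage 1 while the front is near the bottom (``f <
    stage1_boundary``), stage 2 while ascending (``f < stage3_boundary``), and
    stage 3 once the front has reached the top half (``f >= stage3_boundary``).
    The stage-3 boundary at one half is fixed by the staging definition; the
    stage-1/2 boundary at one quarter is an operational choice and is
    configurable.
    """
    if length <= 0:
        raise ValueError(f"parent length must be positive, got {length}")
    if has_bud is None:
        has_bud = front_height is not None
    if not has_bud:
        return 0
    if front_height is None:
        raise StageClassificationError(
            "bud present but the developing-front height is unavailable"
        )
    f = front_height / length
    if f < stage1_boundary:
        return 1
    if f < stage3_boundary:
        return 2
    return 3


# ---------------------------------------------------------------------------
# Population tabulation
# ---------------------------------------------------------------------------

STAGE_COLUMNS = ["pct_stage1", "pct_stage2", "pct_stage3", "pct_stage0"]


def tabulate_budding(records: pd.DataFrame | Iterable[tuple]) -> pd.DataFrame:
    """Tabulate stage frequencies and budding percentages per (age, region).

    ``records`` holds one row per scored crypt with columns ``age``,
    ``region`` and ``stage`` (region names or single-letter codes D/M/P).
    Returns one row per (age, region) plus a total row (region ``T``) per age,
    with per-stage percentages, ``budding_pct`` (stages 1+2) and
    ``nonbudding_pct`` (stages 0+3).  Percentages are computed from raw counts
    and rounded to one decimal only on output, so budding percentages stay
    internally consistent with the stage counts rather than with the rounded
    per-stage percentages.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(records, columns=["age", "region", "stage"])
    records = records.copy()
    if records.empty:
        warnings.warn("no crypt records to tabulate; returning empty table")
        return pd.DataFrame(
            columns=["age_weeks", "region", "total_counted", *STAGE_COLUMNS,
                     "budding_pct", "nonbudding_pct"]
        )
    bad = set(records["stage"]) - {0, 1, 2, 3}
    if bad:
        raise ValueError(f"stage labels must be in 0..3, got {sorted(bad)}")
    records["region"] = [
        REGION_CODES.get(str(r).lower(), str(r).upper()) for r in records["region"]
    ]

    rows = []
    for age in sorted(records["age"].unique()):
        sub = records[records["age"] == age]
        groups = [(code, sub[sub["region"] == code])
                  for code in ["D", "M", "P"] if (sub["region"] == code).any()]
        groups.append(("T", sub))
        for code, grp in groups:
            if grp.empty:
                warnings.warn(f"empty group (age={age}, region={code}); row omitted")
                continue
            counts = grp["stage"].value_counts().reindex([0, 1, 2, 3], fill_value=0)
            n = int(counts.sum())
            pct = 100.0 * counts / n
            budding = 100.0 * (counts[1] + counts[2]) / n
            rows.append(
                {
                    "age_weeks": age,
                    "region": code,
                    "total_counted": n,
                    "pct_stage1": round(pct[1], 1),
                    "pct_stage2": round(pct[2], 1),
                    "pct_stage3": round(pct[3], 1),
                    "pct_stage0": round(pct[0], 1),
                    "budding_pct": round(budding, 1),
                    "nonbudding_pct": round(100.0 - budding, 1),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    F: float
    p: float


def anova_one_way(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical single-factor ANOVA over two or more groups of measurements.

    Returns the F statistic and its p-value from the F distribution.  This is
    the test used for regional length/width comparisons and for per-region
    staining-intensity comparisons.
    """
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs at least two groups")
    arrays = []
    for i, g in enumerate(groups):
        a = np.asarray(g, dtype=float)
        if a.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values ({a.size})")
        arrays.append(a)
    f, p = stats.f_oneway(*arrays)
    return AnovaResult(F=float(f), p=float(p))


@dataclass
class MatureDaughterSummary:
    mature_mean: float
    daughter_mean: float
    n_pairs: int
    anova: Optional[AnovaResult]
    mature_lengths: list = field(default_factory=list)
    daughter_lengths: list = field(default_factory=list)
    note: str = ""


def compare_mature_daughter(
    stage3_pairs: Sequence[tuple],
) -> MatureDaughterSummary:
    """Compare mature vs daughter members of stage-3 crypt pairs.

    Each pair holds the two attached crypts of a stage-3 event, as
    ``(length, )`` or ``(length, basal_width)`` tuples per member.  The
    daughter is the member with the smaller basal width when widths are
    available (daughters are typically smaller in basal width), else the
    shorter member.  Ties leave both members labelled mature, with a warning.
    Group means are returned with a one-way ANOVA on the two length groups
    (skipped, with a notice, when either group has fewer than two values).
    """
    mature, daughter = [], []
    notes = []
    for pair in stage3_pairs:
        (m0, m1) = pair
        l0, w0 = (m0 if len(m0) == 2 else (m0[0], None)) if isinstance(m0, (tuple, list)) else (m0, None)
        l1, w1 = (m1 if len(m1) == 2 else (m1[0], None)) if isinstance(m1, (tuple, list)) else (m1, None)
        key0, key1 = (w0, w1) if (w0 is not None and w1 is not None) else (l0, l1)
        if key0 == key1:
            warnings.warn("stage-3 pair with equal members; both labelled mature")
            mature.extend([l0, l1])
            continue
        if key0 < key1:
            daughter.append(l0)
            mature.append(l1)
        else:
            daughter.append(l1)
            mature.append(l0)
    if not mature and not daughter:
        raise ValueError("no stage-3 pairs supplied")
    anova = None
    if len(mature) >= 2 and len(daughter) >= 2:
        anova = anova_one_way([mature, daughter])
    else:
        notes.append("too few pairs for a group comparison; test skipped")
    return MatureDaughterSummary(
        mature_mean=float(np.mean(mature)) if mature else float("nan"),
        daughter_mean=float(np.mean(daughter)) if daughter else float("nan"),
        n_pairs=len(stage3_pairs),
        anova=anova,
        mature_lengths=list(mature),
        daughter_lengths=list(daughter),
        note="; ".join(notes),
    )


def morphology_from_annotation(annotation: CryptAnnotation) -> CryptMorphology:
    """Measure one annotated crypt: length, width, area, stage and AI."""
    length = measure_length(annotation.axis)
    width = None
    if annotation.basal_width_segment is not None:
        width = measure_basal_width(annotation)
    area = rect_area(length, width) if width else None
    stage = 0
    ai = None
    if annotation.branches is not None:
        b_parent, b_daughter = annotation.branches
        h = measure_length(b_parent)
        stage = classify_stage(length, front_height=h)
        if stage in (1, 2):
            ai = asymmetry_index([h, measure_length(b_daughter)])
    return CryptMorphology(
        crypt_id=annotation.crypt_id,
        length=length,
        basal_width=width,
        area=area,
        stage=stage,
        asymmetry_index=ai,
        region=annotation.region,
        age=annotation.age,
    )
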
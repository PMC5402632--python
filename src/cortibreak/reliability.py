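"""Agreement between two sets of detected interruptions.

Two label maps (two operators of the semi-automated procedure, the fully-
vs semi-automated run, or algorithm vs visual scoring) are compared by
voxel overlap: a pair of interruptions counts as matching when it shares
at least 20 voxels (0.011 mm^3 at the 82 µm voxel — the smallest volume
the detector can return).  From the matched counts follow

    proportion of matching interruptions
        = n_match / (n_a + n_b - n_match) * 100     (a Jaccard on counts)
    PPV         = n_match / n_algorithm * 100
    sensitivity = n_match / n_visual   * 100

and joint-level reliability is the single-measures intraclass correlation
from a two-way random-effects model with absolute agreement, ICC(2,1),
with its standard F-based 95% confidence interval.

Multi-overlap resolution is not standardized anywhere; this module assigns
pairs one-to-one, greedily by descending overlap (ties broken by the
smaller label pair), which the test suite bounds against an exhaustive
assignment oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .volume_io import LabelMap, ValidationError

__all__ = [
    "MatchResult",
    "RatingsTable",
    "AgreementStats",
    "match_interruptions",
    "proportion_matching",
    "positive_predictive_value",
    "sensitivity",
    "agreement_stats",
    "icc_two_way_random_absolute",
]


@dataclass
class MatchResult:
    n_a: int
    n_b: int
    n_match: int
    pairs: list[tuple[int, int, int]]  # (label_a, label_b, overlap_voxels)


@dataclass
class RatingsTable:
    """Joints x raters matrix of per-joint ratings (counts or surfaces)."""

    values: np.ndarray
    joint_ids: list | None = None
    rater_ids: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("ratings must be a 2D joints x raters matrix")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValidationError("need at least 2 joints and 2 raters")
        if not np.isfinite(self.values).all():
            raise ValidationError("ratings table has missing/non-finite cells")
        if self.joint_ids is None:
            self.joint_ids = list(range(n))
        if self.rater_ids is None:
            self.rater_ids = list(range(k))


@dataclass
class AgreementStats:
    proportion_matching_pct: float
    ppv_pct: float
    sensitivity_pct: float


def match_interruptions(
    a: LabelMap, b: LabelMap, min_overlap_voxels: int = 20
) -> MatchResult:
    """One-to-one pairing of interruptions by voxel overlap.

    Candidate pairs overlap by at least ``min_overlap_voxels``; assignment
    is greedy by descending overlap, ties to the smaller (label_a,
    label_b) pair.
    """
    if a.shape != b.shape:
        raise ValidationError("label maps are on different lattices")
    n_a, n_b = a.n_labels, b.n_labels
    both = (a.data > 0) & (b.data > 0)
    pairs: list[tuple[int, int, int]] = []
    if both.any():
        la, lb = a.data[both].ravel(), b.data[both].ravel()
        pair_codes, counts = np.unique(
            la.astype(np.int64) * (n_b + 1) + lb, return_counts=True
        )
        candidates = [
            (int(c), int(code // (n_b + 1)), int(code % (n_b + 1)))
            for code, c in zip(pair_codes, counts)
            if c >= min_overlap_voxels
        ]
        candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
        used_a: set[int] = set()
        used_b: set[int] = set()
        for overlap, label_a, label_b in candidates:
            if label_a in used_a or label_b in used_b:
                continue
            used_a.add(label_a)
            used_b.add(label_b)
            pairs.append((label_a, label_b, overlap))
    return MatchResult(n_a=n_a, n_b=n_b, n_match=len(pairs), pairs=pairs)


def proportion_matching(n_a: int, n_b: int, n_match: int) -> float:
    """Percent of interruptions found at the same location by both raters."""
    if n_match > min(n_a, n_b):
        raise ValidationError("n_match cannot exceed min(n_a, n_b)")
    denom = n_a + n_b - n_match
    if denom == 0:
        raise ValidationError("proportion of matching interruptions undefined "
                              "when both sets are empty")
    return n_match / denom * 100.0


def positive_predictive_value(n_match: int, n_algorithm: int) -> float:
    """Percent of algorithm detections confirmed by the gold standard."""
    if n_algorithm <= 0:
        raise ValidationError("PPV undefined without algorithm detections")
    return n_match / n_algorithm * 100.0


def sensitivity(n_match: int, n_visual: int) -> float:
    """Percent of gold-standard interruptions found by the algorithm."""
    if n_visual <= 0:
        raise ValidationError("sensitivity undefined without visual detections")
    return n_match / n_visual * 100.0


def agreement_stats(match: MatchResult) -> AgreementStats:
    """All three agreement measures, treating set A as the algorithm and
    set B as the gold standard."""
    return AgreementStats(
        proportion_matching_pct=proportion_matching(match.n_a, match.n_b, match.n_match),
        ppv_pct=positive_predictive_value(match.n_match, match.n_a),
        sensitivity_pct=sensitivity(match.n_match, match.n_b),
    )


def icc_two_way_random_absolute(
    ratings: RatingsTable, alpha: float = 0.05
) -> dict:
    """Single-measures ICC(2,1): two-way random effects, absolute agreement.

    Mean squares come from the two-way ANOVA decomposition (rows =
    joints/subjects, columns = raters); the confidence interval is the
    standard F-distribution construction with Satterthwaite degrees of
    freedom.  Returns ``{"icc": float, "ci95": (lo, hi)}``.
    """
    x = ratings.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or ss_total == 0:
        raise ValidationError("ICC undefined: no variance in the ratings")
    icc = (msr - mse) / denom

    if mse > 0:
        fj = msc / mse
        vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
        vd = (n - 1) * (k * icc * fj) ** 2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
        v = vn / vd
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f1 * mse) / (
            f1 * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f2 * msr
        )
    else:  # perfect agreement: degenerate interval
        lower = upper = icc
    return {"icc": float(icc), "ci95": (float(lower), float(upper))}
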
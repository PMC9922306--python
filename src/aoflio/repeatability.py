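"""Cross-exposure comparison: repeatability and damage prediction.

Two co-registered exposures of the same retinal patch share ROI labels after
identical cropping, so ROI matching is identity on shared labels.  Two
confusion schemes are supported:

* repeatability — putative-S call on day 1 ("ground truth") vs day 2;
  sensitivity = n11/(n11+n12), specificity = n22/(n22+n21);
* damage prediction — initial-exposure Cluster 1 membership vs post-damage
  hypofluorescence.  The sensitivity here conditions on the baseline call
  (Cluster-1 cones that did / did not darken), i.e. it is a positive-
  predictive-style figure, matching how the original study reports it.

Hypofluorescent ("dark") cones are detected automatically: a cone is dark
when its summed intensity falls below ``threshold_ratio`` times the median
intensity of its nearest cone neighbors.  The default ratio 0.5 sits between
the ~2.6-fold brightness drop of damaged cones (0.385x) and ordinary
cell-to-cell brightness variability.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .flim_io import RoiMask

__all__ = [
    "ConfusionCounts",
    "DarkCallParams",
    "RoiMatch",
    "match_rois",
    "detect_dark_cones",
    "confusion_metrics",
    "dark_fraction_by_cluster",
    "confusion_from_calls",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts; n11 = condition-positive and test-positive."""

    n11: int
    n12: int
    n21: int
    n22: int
    scheme: str = "repeatability"

    def __post_init__(self) -> None:
        if min(self.n11, self.n12, self.n21, self.n22) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22


@dataclass(frozen=True)
class DarkCallParams:
    """Parameters of the automated hypofluorescent-cone rule."""

    neighbor_count: int = 6
    threshold_ratio: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_ratio < 1.0:
            raise ValueError("threshold_ratio must be in (0, 1)")
        if self.neighbor_count < 3:
            raise ValueError("neighbor_count must be >= 3")


@dataclass
class RoiMatch:
    """Label correspondence between two co-registered masks."""

    matched: dict[int, int]
    unmatched_a: list[int]
    unmatched_b: list[int]


def match_rois(mask_a: RoiMask, mask_b: RoiMask, crop=None) -> RoiMatch:
    """Identity mapping on labels shared by two co-registered masks.

    ``crop`` (a :class:`~aoflio.flim_io.CropRect`) is applied to both masks
    first when given.  Labels present in only one mask are reported unmatched.
    """
    if crop is not None:
        mask_a = crop.apply_mask(mask_a)
        mask_b = crop.apply_mask(mask_b)
    if mask_a.labels.shape != mask_b.labels.shape:
        raise ValueError("masks must have the same (cropped) shape")
    labels_a = set(mask_a.kind_by_label)
    labels_b = set(mask_b.kind_by_label)
    shared = sorted(labels_a & labels_b)
    return RoiMatch(
        matched={l: l for l in shared},
        unmatched_a=sorted(labels_a - labels_b),
        unmatched_b=sorted(labels_b - labels_a),
    )


def detect_dark_cones(
    intensity: np.ndarray,
    mask: RoiMask,
    params: DarkCallParams = DarkCallParams(),
) -> dict[int, bool]:
    """Flag cones dimmer than ``threshold_ratio`` x their neighbors' median.

    Cone intensity is the summed image intensity over the cone's pixels;
    neighbors are the ``neighbor_count`` nearest other cones by centroid
    distance.  Returns {cone label: is_dark}.
    """
    cone_labels = mask.labels_of_kind("cone")
    if len(cone_labels) < params.neighbor_count + 1:
        raise ValueError(
            f"need more than {params.neighbor_count} cones, "
            f"got {len(cone_labels)}"
        )
    sums = ndimage.sum_labels(intensity, labels=mask.labels, index=cone_labels)
    centroids = np.array(
        ndimage.center_of_mass(np.ones_like(mask.labels), labels=mask.labels,
                               index=cone_labels)
    )
    tree = cKDTree(centroids)
    # k+1 because the nearest hit is the cone itself
    _, idx = tree.query(centroids, k=params.neighbor_count + 1)
    out: dict[int, bool] = {}
    for i, label in enumerate(cone_labels):
        neighbors = [j for j in idx[i] if j != i][: params.neighbor_count]
        ref = float(np.median(sums[neighbors]))
        out[label] = bool(sums[i] < params.threshold_ratio * ref)
    return out


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity and positive fraction from confusion counts.

    Values are exact rational arithmetic converted to float, in percent;
    ``*_display`` entries are rounded half-even to one decimal, matching the
    usual reporting convention.  Zero-denominator metrics are NaN.
    """

    def pct(num: int, den: int) -> float:
        return float(100 * Fraction(num, den)) if den > 0 else np.nan

    sens = pct(counts.n11, counts.n11 + counts.n12)
    spec = pct(counts.n22, counts.n22 + counts.n21)
    pos = pct(counts.n11 + counts.n12, counts.total) if counts.total else np.nan
    out = {
        "sensitivity_pct": sens,
        "specificity_pct": spec,
        "positive_fraction_pct": pos,
    }
    for key in list(out):
        v = out[key]
        out[key.replace("_pct", "_display")] = (
            float(np.round(v, 1)) if np.isfinite(v) else np.nan
        )
    return out


def confusion_from_calls(
    truth: np.ndarray, test: np.ndarray, scheme: str = "repeatability"
) -> ConfusionCounts:
    """Tabulate confusion counts from boolean condition/test vectors."""
    truth = np.asarray(truth, dtype=bool)
    test = np.asarray(test, dtype=bool)
    if truth.shape != test.shape:
        raise ValueError("condition and test vectors must align")
    return ConfusionCounts(
        n11=int(np.sum(truth & test)),
        n12=int(np.sum(truth & ~test)),
        n21=int(np.sum(~truth & test)),
        n22=int(np.sum(~truth & ~test)),
        scheme=scheme,
    )


def dark_fraction_by_cluster(
    initial_assignments: np.ndarray, dark_flags: np.ndarray
) -> dict[int, float]:
    """Percent of matched cones flagged dark within each initial cluster."""
    assignments = np.asarray(initial_assignments)
    dark = np.asarray(dark_flags, dtype=bool)
    if assignments.shape != dark.shape:
        raise ValueError("assignments and flags must align")
    out: dict[int, float] = {}
    for cid in np.unique(assignments):
        sel = assignments == cid
        n = int(sel.sum())
        out[int(cid)] = (
            float(100 * Fraction(int(dark[sel].sum()), n)) if n else np.nan
        )
    return out
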
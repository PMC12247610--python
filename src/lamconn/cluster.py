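"""Laminar connectivity typing and reliability.

Vertex-wise laminar FCS profiles are clustered with k-means under a
correlation distance (1 - Pearson r between depth profiles), k = 2.  Cluster
indices are anchored to a physiological meaning: the cluster whose mean
profile peaks in the middle third of the cortical ribbon is labelled 1
(feedforward-type, granular input), the other 2 (feedback-type,
superficial termination).  Reliability of the resulting parcellations is
quantified by the mean two-label Dice coefficient between split-half
repetitions, compared against pairs of fair random labelings (expected Dice
0.5) with a two-sample t-test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "Parcellation",
    "ReliabilityResult",
    "kmeans_profiles",
    "dice_parcellation",
    "dice_binary",
    "select_network_component",
    "group_network_mask",
    "split_half_reliability",
    "random_pattern_null",
    "compare_dice",
]

LABEL_MIDDLE = 1  # feedforward-type: FCS peaks at middle depths
LABEL_SUPERFICIAL = 2  # feedback-type: FCS peaks at superficial depths
LABEL_UNCLASSIFIED = 0


@dataclass
class Parcellation:
    """Per-vertex laminar-type labels within a region mask.

    Labels: 1 = middle-peak (feedforward-type), 2 = superficial-peak
    (feedback-type), 0 = unclassified (zero-variance profile or outside the
    region).
    """

    labels: np.ndarray  # (V,) int in {0, 1, 2}
    region: np.ndarray  # (V,) bool
    cluster_profiles: dict = field(default_factory=dict)  # label -> (D,) mean profile

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.region = np.asarray(self.region, dtype=bool)
        if len(self.labels) != len(self.region):
            raise ValueError("labels/region length mismatch")
        if np.any(self.labels[~self.region] != 0):
            raise ValueError("labels must be zero outside the region mask")


@dataclass
class ReliabilityResult:
    """Split-half Dice values, their random-pattern null, and the t-test."""

    dice_values: np.ndarray
    null_dice: np.ndarray
    t_stat: float
    p_value: float

    @property
    def n_pairs(self) -> int:
        return len(self.dice_values)


def _middle_band(n_depths: int) -> tuple[int, int]:
    """0-based inclusive index range of the middle third of the ribbon.

    For 18 depths this is depths 7-12 in 1-based counting.
    """
    lo = n_depths // 3
    hi = int(np.ceil(2 * n_depths / 3)) - 1
    return lo, hi


def _anchor_labels(mean_profiles: list[np.ndarray]) -> dict[int, int]:
    """Map internal cluster indices {0, 1} to anchored labels {1, 2}."""
    peaks = [int(np.nanargmax(p)) for p in mean_profiles]
    n_depths = len(mean_profiles[0])
    lo, hi = _middle_band(n_depths)
    in_band = [lo <= pk <= hi for pk in peaks]
    if in_band[0] != in_band[1]:
        middle_cluster = 0 if in_band[0] else 1
    elif peaks[0] != peaks[1]:
        if in_band[0]:  # both in the middle band: smaller peak index wins
            middle_cluster = int(np.argmin(peaks))
        else:  # neither in band: closer to the ribbon middle wins
            mid = (n_depths - 1) / 2
            d0, d1 = abs(peaks[0] - mid), abs(peaks[1] - mid)
            middle_cluster = 0 if (d0 < d1 or (d0 == d1 and peaks[0] < peaks[1])) else 1
    else:
        middle_cluster = 0
    return {middle_cluster: LABEL_MIDDLE, 1 - middle_cluster: LABEL_SUPERFICIAL}


def _corr_kmeans_once(Z: np.ndarray, k: int, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """One Lloyd run on row-standardized profiles Z (unit-norm rows).

    Correlation distance 1 - r is half the squared Euclidean distance between
    standardized profiles, so Lloyd updates with re-standardized centroids
    minimize the within-cluster correlation-distance sum.
    """
    n = len(Z)
    # greedy farthest-profile seeding from a random start
    centers = [int(rng.integers(n))]
    sim = Z @ Z[centers[0]]
    for _ in range(1, k):
        centers.append(int(np.argmin(sim)))
        sim = np.maximum(sim, Z @ Z[centers[-1]])
    C = Z[centers].copy()
    assign = np.zeros(n, dtype=int)
    for it in range(100):
        sims = Z @ C.T  # (n, k)
        new_assign = np.argmax(sims, axis=1)
        for j in range(k):  # re-seed empty clusters with the worst-fit profile
            if not np.any(new_assign == j):
                worst = int(np.argmin(np.max(sims, axis=1)))
                new_assign[worst] = j
        if it > 0 and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            m = Z[assign == j].mean(axis=0)
            norm = np.linalg.norm(m)
            if norm > 1e-12:
                C[j] = m / norm
    inertia = float(np.sum(1.0 - np.einsum("ij,ij->i", Z, C[assign])))
    return assign, inertia


def kmeans_profiles(
    fcs_map,
    region: np.ndarray,
    k: int = 2,
    n_restarts: int = 10,
    seed: int = 0,
) -> Parcellation:
    """Cluster laminar FCS profiles with correlation-distance k-means.

    Profiles with zero variance (or missing values) are labelled 0 and
    excluded from the fit.  For k = 2 the cluster indices are anchored by
    the peak depth of the cluster mean profiles (middle band -> label 1).
    """
    values = fcs_map.values if hasattr(fcs_map, "values") else np.asarray(fcs_map, float)
    region = np.asarray(region, dtype=bool)
    P = values[region]  # (n, D)
    n = len(P)
    if n < k:
        raise ValueError("region must contain at least k vertices")
    finite = np.all(np.isfinite(P), axis=1)
    std = P.std(axis=1)
    usable = finite & (std > 1e-12)
    if usable.sum() < k:
        raise ValueError("fewer than k non-constant profiles in the region")
    Z = P[usable] - P[usable].mean(axis=1, keepdims=True)
    Z /= np.linalg.norm(Z, axis=1, keepdims=True)
    # degenerate: all profiles identical up to positive scaling
    g = Z @ Z[0]
    if np.all(g > 1.0 - 1e-10):
        raise ValueError("degenerate input: all profiles are positively proportional")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, float] | None = None
    for _ in range(n_restarts):
        assign, inertia = _corr_kmeans_once(Z, k, rng)
        if best is None or inertia < best[1]:
            best = (assign, inertia)
    assign = best[0]
    mean_profiles = [P[usable][assign == j].mean(axis=0) for j in range(k)]
    if k == 2:
        mapping = _anchor_labels(mean_profiles)
    else:
        mapping = {j: j + 1 for j in range(k)}
    region_labels = np.zeros(n, dtype=int)
    region_labels[usable] = [mapping[a] for a in assign]
    labels = np.zeros(len(region), dtype=int)
    labels[region] = region_labels
    profiles = {mapping[j]: mean_profiles[j] for j in range(k)}
    return Parcellation(labels=labels, region=region, cluster_profiles=profiles)


def dice_binary(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|) of two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a vertex space")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("both masks are empty")
    return 2.0 * int((a & b).sum()) / (na + nb)


def dice_parcellation(a: Parcellation, b: Parcellation) -> float:
    """Anchored-label mean Dice between two-cluster parcellations.

    Computed over vertices classified in both maps; per anchored label the
    binary Dice is formed, a label empty in both maps is skipped, and the
    unweighted mean over available labels is returned.  No permutation
    matching: label semantics are fixed by the anchoring.
    """
    if not np.array_equal(a.region, b.region):
        raise ValueError("parcellations must share the same region mask")
    both = (a.labels > 0) & (b.labels > 0)
    la, lb = a.labels[both], b.labels[both]
    dscs = []
    for lab in (LABEL_MIDDLE, LABEL_SUPERFICIAL):
        na, nb = int(np.sum(la == lab)), int(np.sum(lb == lab))
        if na + nb == 0:
            continue
        inter = int(np.sum((la == lab) & (lb == lab)))
        dscs.append(2.0 * inter / (na + nb))
    if not dscs:
        raise ValueError("both labels empty in both parcellations")
    return float(np.mean(dscs))


def select_network_component(
    candidates: list[np.ndarray],
    atlas_mask: np.ndarray,
    z_thresh: float = 2.0,
) -> tuple[np.ndarray, int, float]:
    """Pick the candidate z-map best matching an atlas network mask.

    Each candidate is thresholded at z > ``z_thresh``; the candidate with the
    highest binary Dice against the atlas mask wins (ties and the all-zero
    case go to the lowest index).  Returns (mask, index, dice).
    """
    if not candidates:
        raise ValueError("no candidate components")
    atlas_mask = np.asarray(atlas_mask, dtype=bool)
    best_idx, best_dice, best_mask = -1, -1.0, None
    any_nonempty = False
    for i, zmap in enumerate(candidates):
        m = np.asarray(zmap, dtype=float) > z_thresh
        if not m.any():
            continue
        any_nonempty = True
        d = dice_binary(m, atlas_mask) if atlas_mask.any() else 0.0
        if d > best_dice:
            best_idx, best_dice, best_mask = i, d, m
    if not any_nonempty:
        raise ValueError("all thresholded candidate maps are empty")
    if best_dice == 0.0:
        warnings.warn("no candidate overlaps the atlas mask; returning the first nonempty one")
    return best_mask, best_idx, best_dice


def group_network_mask(individual_masks: list[np.ndarray], threshold: float = 0.5) -> np.ndarray:
    """Average binary masks on the template and binarize at >= threshold."""
    stack = np.array([np.asarray(m, dtype=float) for m in individual_masks])
    return stack.mean(axis=0) >= threshold


def split_half_reliability(
    session_maps: list,
    region: np.ndarray,
    n_rep: int = 50,
    seed: int = 0,
    k: int = 2,
    n_restarts: int = 10,
) -> np.ndarray:
    """Split-half reliability of the laminar-type parcellation.

    Sessions are randomly divided into two equal halves ``n_rep`` times
    (odd counts differ by one); each half's maps are averaged, clustered
    with :func:`kmeans_profiles`, and compared with the anchored-label Dice.
    """
    if len(session_maps) < 4:
        raise ValueError("need at least 4 sessions for split-half analysis")
    vals = [m.values if hasattr(m, "values") else np.asarray(m, float) for m in session_maps]
    rng = np.random.default_rng(seed)
    n = len(vals)
    out = np.empty(n_rep)
    for r in range(n_rep):
        perm = rng.permutation(n)
        half = n // 2
        m1 = np.mean([vals[i] for i in perm[:half]], axis=0)
        m2 = np.mean([vals[i] for i in perm[half:]], axis=0)
        p1 = kmeans_profiles(m1, region, k=k, n_restarts=n_restarts, seed=int(rng.integers(2**31)))
        p2 = kmeans_profiles(m2, region, k=k, n_restarts=n_restarts, seed=int(rng.integers(2**31)))
        out[r] = dice_parcellation(p1, p2)
    return out


def random_pattern_null(
    region: np.ndarray | int,
    n_pairs: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Dice null: pairs of parcellations with fair independent random labels.

    Every region vertex is assigned label 1 or 2 with probability one half,
    independently; each pair's anchored-label mean Dice is returned.  Under
    this model the expected Dice is exactly 0.5.
    """
    if isinstance(region, (int, np.integer)):
        region_mask = np.ones(int(region), dtype=bool)
    else:
        region_mask = np.asarray(region, dtype=bool)
    n = int(region_mask.sum())
    if n == 0:
        raise ValueError("region is empty")
    rng = np.random.default_rng(seed)
    out = np.empty(n_pairs)
    for i in range(n_pairs):
        la = np.zeros(len(region_mask), dtype=int)
        lb = np.zeros(len(region_mask), dtype=int)
        la[region_mask] = rng.integers(1, 3, size=n)
        lb[region_mask] = rng.integers(1, 3, size=n)
        pa = Parcellation(labels=la, region=region_mask)
        pb = Parcellation(labels=lb, region=region_mask)
        out[i] = dice_parcellation(pa, pb)
    return out


def compare_dice(
    observed: np.ndarray,
    null: np.ndarray,
    welch: bool = False,
) -> tuple[float, float]:
    """Two-sample t-test of observed Dice values against the random null.

    Pooled-variance by default, Welch optional; two-sided p.  When both
    samples have zero variance and equal means, returns (0, 1).
    """
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    if len(observed) < 2 or len(null) < 2:
        raise ValueError("need at least 2 values per sample")
    if observed.std() == 0 and null.std() == 0:
        if observed.mean() == null.mean():
            return 0.0, 1.0
    t, p = stats.ttest_ind(observed, null, equal_var=not welch)
    return float(t), float(p)
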
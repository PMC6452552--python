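"""Candidate segmentations from the two-level forest stack.

The full-view forest classifies every pixel directly (candidate R1).  The
zoom-view bank produces N coarse masks CR_1..CR_N which are fused: a
probability map p(i,j) = n(i,j)/N counts how many coarse results mark each
pixel, a 2-cluster fuzzy C-means bipartitions the map into membrane vs
background, a morphological cleanup removes speckle false positives, and an
iterative refinement loop discards coarse results whose Jaccard similarity to
the current consensus falls below a cutoff w2, rebuilding the consensus until
the retained set is stable (candidate R2).  The final choice between R1 and
R2 is left to the user by default; an automatic highest-Jaccard selector can
be enabled when a gold mask is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from skimage.morphology import disk, opening, remove_small_objects

from .features import FeatureConfig, FeatureStack, compute_feature_stack
from .training import ForestModel, FullViewModel, ZoomViewModel


@dataclass(frozen=True)
class FcmConfig:
    """2-cluster fuzzy C-means on the scalar probability values."""

    n_clusters: int = 2
    fuzzifier: float = 2.0
    tol: float = 1e-5
    max_iters: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters != 2:
            raise ValueError("bipartition requires exactly 2 clusters")
        if self.fuzzifier <= 1:
            raise ValueError("fuzzifier must be > 1")


@dataclass(frozen=True)
class CleanupConfig:
    min_component_area: int = 50
    opening_radius: int = 1


@dataclass(frozen=True)
class RefinementConfig:
    w1: float = 1.0
    w2: float = 0.3
    max_iters: int = 10
    fcm: FcmConfig = field(default_factory=FcmConfig)
    cleanup: CleanupConfig = field(default_factory=CleanupConfig)
    cleanup_r1: bool = True  # apply the same cleanup to the full-view candidate

    def __post_init__(self) -> None:
        if not 0 < self.w1 <= 1:
            raise ValueError("w1 must be in (0, 1]")
        if not 0 <= self.w2 < 1:
            raise ValueError("w2 must be in [0, 1)")


@dataclass
class ProbabilityMap:
    """Per-pixel fraction of coarse results labelling the pixel as membrane."""

    p: np.ndarray  # float64 in [0, 1]
    n_sources: int


class Candidate(Enum):
    UNSET = "unset"
    R1 = "R1"
    R2 = "R2"


@dataclass
class SegmentationResult:
    R1: np.ndarray
    R2: np.ndarray
    coarse_results: list[np.ndarray]
    probability_map: ProbabilityMap
    retained_indices: list[int]
    jaccard_R1: float | None = None
    jaccard_R2: float | None = None
    selected: Candidate = Candidate.UNSET


# ---------------------------------------------------------------------------
# Pixel classification (level-1 voting)
# ---------------------------------------------------------------------------

def vote_fraction(trees: Sequence, X: np.ndarray, gbm_label: int = 1) -> np.ndarray:
    """Fraction of trees whose hard prediction equals the membrane label."""
    votes = np.zeros(X.shape[0], dtype=np.int64)
    for tree in trees:
        votes += np.asarray(tree.predict(X)) == gbm_label
    return votes / len(trees)


def classify_image(
    model: ForestModel,
    image: np.ndarray,
    cfg: FeatureConfig,
    stack: FeatureStack | None = None,
) -> np.ndarray:
    """Per-pixel majority vote over the forest's trees.

    A pixel is membrane iff strictly more than half the trees vote membrane;
    an exact tie counts as background.
    """
    if stack is None:
        stack = compute_feature_stack(image, cfg)
    if stack.channel_names != model.channel_names:
        raise ValueError(
            "feature channels do not match the model's training channels: "
            f"{stack.channel_names[:3]}... vs {model.channel_names[:3]}..."
        )
    frac = vote_fraction(model.forest.estimators_, stack.as_matrix())
    return (frac > 0.5).reshape(image.shape)


def coarse_results(
    zoom: ZoomViewModel,
    image: np.ndarray,
    cfg: FeatureConfig,
    stack: FeatureStack | None = None,
) -> list[np.ndarray]:
    """Classify the image with every zoom-view forest (CR_1..CR_N, in order)."""
    if stack is None:
        stack = compute_feature_stack(image, cfg)
    return [classify_image(f, image, cfg, stack=stack) for f in zoom.forests]


# ---------------------------------------------------------------------------
# Probability map
# ---------------------------------------------------------------------------

def probability_map(crs: Sequence[np.ndarray]) -> ProbabilityMap:
    """p(i,j) = n(i,j)/N, the exact per-pixel fraction of coarse results
    marking the pixel as membrane; equivalently the mean of indicator masks."""
    if len(crs) == 0:
        raise ValueError("empty coarse-result list")
    shape = crs[0].shape
    if any(cr.shape != shape for cr in crs):
        raise ValueError("coarse results have mismatched shapes")
    counts = np.zeros(shape, dtype=np.int64)
    for cr in crs:
        counts += cr.astype(np.int64)
    return ProbabilityMap(p=counts / len(crs), n_sources=len(crs))


# ---------------------------------------------------------------------------
# Fuzzy C-means bipartition
# ---------------------------------------------------------------------------

def _fcm_scalar(values: np.ndarray, weights: np.ndarray, cfg: FcmConfig) -> tuple[float, float]:
    """2-cluster FCM on weighted scalar data; returns sorted centroids.

    Iterates the standard membership/centroid fixed point with fuzzifier m,
    initialized deterministically from the extreme observed values, stopping
    when the maximum membership change drops below tol.
    """
    m = cfg.fuzzifier
    expo = 2.0 / (m - 1.0)
    c = np.array([values.min(), values.max()], dtype=np.float64)
    u = None
    for _ in range(cfg.max_iters):
        d = np.abs(values[:, None] - c[None, :])  # (n, 2)
        zero = d < 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = (d[:, :, None] / d[:, None, :]) ** expo
            new_u = 1.0 / ratio.sum(axis=2)
        # values coinciding with a centroid get crisp membership
        any_zero = zero.any(axis=1)
        if any_zero.any():
            new_u[any_zero] = zero[any_zero].astype(np.float64)
            new_u[any_zero] /= new_u[any_zero].sum(axis=1, keepdims=True)
        um = (new_u ** m) * weights[:, None]
        c = (um * values[:, None]).sum(axis=0) / um.sum(axis=0)
        if u is not None and np.abs(new_u - u).max() < cfg.tol:
            u = new_u
            break
        u = new_u
    return (float(c.min()), float(c.max()))


def fcm_bipartition(pm: ProbabilityMap, cfg: FcmConfig | None = None) -> np.ndarray:
    """Split the probability map into membrane (high cluster) vs background.

    A constant map is degenerate: it returns an empty mask with a warning.
    """
    cfg = cfg or FcmConfig()
    values, counts = np.unique(pm.p, return_counts=True)
    if len(values) < 2:
        warnings.warn("probability map is constant; returning empty mask", stacklevel=2)
        return np.zeros(pm.p.shape, dtype=bool)
    lo_c, hi_c = _fcm_scalar(values.astype(np.float64), counts.astype(np.float64), cfg)
    # membrane = higher membership in the larger-centroid cluster, i.e. closer to it
    return np.abs(pm.p - hi_c) < np.abs(pm.p - lo_c)


# ---------------------------------------------------------------------------
# Morphological cleanup
# ---------------------------------------------------------------------------

def morphological_cleanup(mask: np.ndarray, cfg: CleanupConfig | None = None) -> np.ndarray:
    """Binary opening with a disc, then drop small 8-connected components."""
    cfg = cfg or CleanupConfig()
    out = mask.astype(bool)
    if cfg.opening_radius > 0:
        out = opening(out, disk(cfg.opening_radius))
    if cfg.min_component_area > 1:
        # drop components with area < min_component_area (max_size is inclusive)
        out = remove_small_objects(out, max_size=cfg.min_component_area - 1, connectivity=2)
    return out


# ---------------------------------------------------------------------------
# Iterative refinement
# ---------------------------------------------------------------------------

def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(inter / union)


def _consensus(
    crs: Sequence[np.ndarray], retained: Sequence[int], cfg: RefinementConfig, use_fcm: bool
) -> np.ndarray:
    pm = probability_map([crs[i] for i in retained])
    if use_fcm:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant-map degeneracy inside the loop
            core = fcm_bipartition(pm, cfg.fcm)
        if not core.any() and (pm.p > 0).any():
            # constant non-zero map (e.g. a single retained CR): threshold instead
            core = pm.p >= 0.5
    else:
        core = pm.p >= 0.5
    return morphological_cleanup(core, cfg.cleanup)


def _initial_retained(crs: Sequence[np.ndarray], w1: float) -> list[int]:
    n = len(crs)
    if w1 >= 1.0 or n == 1:
        return list(range(n))
    k = max(1, int(np.ceil(w1 * n)))
    # rank by mean pairwise Jaccard to the other coarse results
    scores = []
    for i in range(n):
        js = [_jaccard(crs[i], crs[j]) for j in range(n) if j != i]
        scores.append(np.mean(js))
    order = np.argsort(-np.asarray(scores), kind="stable")
    return sorted(int(i) for i in order[:k])


def iterative_refinement(
    crs: Sequence[np.ndarray],
    cfg: RefinementConfig | None = None,
    use_fcm: bool = True,
) -> tuple[np.ndarray, list[int]]:
    """Consensus-building loop over the coarse results.

    Starting from the w1 fraction of coarse results most similar to the rest
    (all of them when w1 = 1), the loop alternates: build the probability map
    of the retained set, bipartition it (FCM by default, plain 0.5 threshold
    when ``use_fcm`` is false), clean it up morphologically, then re-admit
    every coarse result whose Jaccard to this consensus is >= w2.  Stops when
    the retained set is stable, would become empty (the previous set is kept),
    or after ``max_iters`` passes.  Returns the final consensus mask and the
    retained indices (0-based).
    """
    cfg = cfg or RefinementConfig()
    if len(crs) == 0:
        raise ValueError("empty coarse-result list")
    retained = _initial_retained(crs, cfg.w1)
    consensus = _consensus(crs, retained, cfg, use_fcm)
    for _ in range(cfg.max_iters):
        j = [_jaccard(cr, consensus) for cr in crs]
        new_retained = [i for i, ji in enumerate(j) if ji >= cfg.w2]
        if not new_retained or new_retained == retained:
            break
        retained = new_retained
        consensus = _consensus(crs, retained, cfg, use_fcm)
    return consensus, retained


# ---------------------------------------------------------------------------
# End-to-end segmentation of one image
# ---------------------------------------------------------------------------

def segment(
    image: np.ndarray,
    full: FullViewModel,
    zoom: ZoomViewModel,
    cfg: RefinementConfig | None = None,
    feature_cfg: FeatureConfig | None = None,
    gold: np.ndarray | None = None,
    auto_select: bool = False,
) -> SegmentationResult:
    """Produce both candidate segmentations for a test image.

    R1 is the full-view forest's vote mask (cleaned up unless ``cleanup_r1``
    is off); R2 is the refined zoom-view consensus.  With a gold mask both
    candidates are scored by Jaccard; the final choice is left unset unless
    ``auto_select`` is on (then the higher-scoring candidate is marked).
    """
    cfg = cfg or RefinementConfig()
    feature_cfg = feature_cfg or FeatureConfig()
    if full.forest.channel_names != zoom.forests[0].channel_names:
        raise ValueError("full-view and zoom-view models disagree on features")
    stack = compute_feature_stack(image, feature_cfg)
    r1 = classify_image(full.forest, image, feature_cfg, stack=stack)
    if cfg.cleanup_r1:
        r1 = morphological_cleanup(r1, cfg.cleanup)
    crs = coarse_results(zoom, image, feature_cfg, stack=stack)
    pm = probability_map(crs)
    r2, retained = iterative_refinement(crs, cfg)
    result = SegmentationResult(
        R1=r1, R2=r2, coarse_results=crs, probability_map=pm,
        retained_indices=retained,
    )
    if gold is not None:
        result.jaccard_R1 = _jaccard(r1, gold)
        result.jaccard_R2 = _jaccard(r2, gold)
        if auto_select:
            result.selected = (
                Candidate.R1 if result.jaccard_R1 >= result.jaccard_R2 else Candidate.R2
            )
    return result
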
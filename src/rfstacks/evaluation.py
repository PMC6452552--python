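"""Jaccard scoring, the cross-grayscale heat map, and the ablation suite.

The heat map scores every test image against every zoom-view forest to show
that a forest trained on one grayscale group is only sensitive to test images
of a nearby group, while the stacked models generalize.  The ablation suite
compares plain majority voting (V), FCM postprocessing (V+F), iterative
refinement on the voting path (V+I), and the full pipeline (V+F+I == R2)
against the full-view candidate (R1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureConfig
from .segmentation import (
    RefinementConfig,
    classify_image,
    coarse_results,
    fcm_bipartition,
    iterative_refinement,
    morphological_cleanup,
    probability_map,
)
from .synthetic import (
    LabeledImage,
    SyntheticSpec,
    generate_grouped_dataset,
    generate_membrane,
)
from .training import FullViewModel, TrainingConfig, ZoomViewModel, derive_seed, train_full_view, train_zoom_view

ABLATION_VARIANTS = ("V", "V+F", "V+I", "V+F+I", "RFS1", "final")


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """|A n B| / |A u B|; two empty masks score 1.0, exactly one empty 0.0."""
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    a = a.astype(bool)
    b = b.astype(bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


@dataclass
class HeatmapGrid:
    scores: np.ndarray  # (n_test_images, N)
    row_means: np.ndarray  # GBM mean gray per test image, sorted ascending
    col_intervals: list[tuple[float, float]]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"[{lo:g},{hi:g})" for lo, hi in self.col_intervals]
        df = pd.DataFrame(self.scores, columns=cols)
        df.insert(0, "gbm_mean", self.row_means)
        return df


def heatmap_grid(
    zoom: ZoomViewModel,
    tests: list[LabeledImage],
    feature_cfg: FeatureConfig,
    refinement_cfg: RefinementConfig | None = None,
    crs_per_test: list[list[np.ndarray]] | None = None,
) -> HeatmapGrid:
    """Jaccard of every (test image, zoom forest) pair after cleanup.

    Rows are sorted by the test image's mean GBM gray so the diagonal band of
    grayscale sensitivity is visible.  Precomputed coarse results (aligned
    with ``tests``) may be passed to avoid reclassification.
    """
    cfg = refinement_cfg or RefinementConfig()
    means = np.array([t.mask_mean for t in tests])
    order = np.argsort(means, kind="stable")
    rows = []
    for ti in order:
        t = tests[ti]
        if crs_per_test is not None:
            masks = crs_per_test[ti]
        else:
            masks = coarse_results(zoom, t.image, feature_cfg)
        rows.append([jaccard(t.mask, morphological_cleanup(m, cfg.cleanup)) for m in masks])
    return HeatmapGrid(
        scores=np.asarray(rows, dtype=np.float64),
        row_means=means[order],
        col_intervals=[(g.lo, g.hi) for g in zoom.groups],
    )


# ---------------------------------------------------------------------------
# Ablation suite
# ---------------------------------------------------------------------------

def ablation(
    image: LabeledImage,
    zoom: ZoomViewModel,
    full: FullViewModel,
    cfg: RefinementConfig,
    feature_cfg: FeatureConfig,
    crs: list[np.ndarray] | None = None,
    r1: np.ndarray | None = None,
) -> dict[str, float]:
    """Score the pipeline variants on one gold-labelled image.

    V: plain majority of the coarse results (p >= 0.5, no cleanup);
    V+F: FCM bipartition of the probability map plus cleanup;
    V+I: the refinement loop with 0.5-thresholding in place of FCM;
    V+F+I: the full refinement (candidate R2); RFS1: candidate R1;
    final: the better of R1 and R2 (the expert would pick it given the gold).
    """
    gold = image.mask
    if crs is None:
        crs = coarse_results(zoom, image.image, feature_cfg)
    pm = probability_map(crs)
    v_mask = pm.p >= 0.5
    vf_mask = morphological_cleanup(fcm_bipartition(pm, cfg.fcm), cfg.cleanup)
    vi_mask, _ = iterative_refinement(crs, cfg, use_fcm=False)
    vfi_mask, _ = iterative_refinement(crs, cfg, use_fcm=True)
    if r1 is None:
        r1 = classify_image(full.forest, image.image, feature_cfg)
        if cfg.cleanup_r1:
            r1 = morphological_cleanup(r1, cfg.cleanup)
    scores = {
        "V": jaccard(gold, v_mask),
        "V+F": jaccard(gold, vf_mask),
        "V+I": jaccard(gold, vi_mask),
        "V+F+I": jaccard(gold, vfi_mask),
        "RFS1": jaccard(gold, r1),
    }
    scores["final"] = max(scores["RFS1"], scores["V+F+I"])
    return scores


def summarize(reports: list[dict[str, float]]) -> pd.DataFrame:
    """Mean and sample variance per variant; a single report has variance 0."""
    if not reports:
        raise ValueError("no reports")
    df = pd.DataFrame(reports)
    out = pd.DataFrame({"mean": df.mean(), "variance": df.var(ddof=1).fillna(0.0)})
    out.index.name = "variant"
    return out


# ---------------------------------------------------------------------------
# Seeded synthetic benchmark
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkResult:
    heatmap: HeatmapGrid
    own_group_hit_rate: float  # fraction of rows whose max is in own group +-1
    forest_mean_jaccard: np.ndarray  # mean Jaccard of each zoom forest over all tests
    rfs1_mean_jaccard: float
    ablation_reports: list[dict[str, float]]
    ablation_summary: pd.DataFrame
    test_groups: list[int] = field(default_factory=list)


def _own_group_hit_rate(grid: HeatmapGrid, test_groups_sorted: list[int]) -> float:
    hits = 0
    for row, g in zip(grid.scores, test_groups_sorted):
        best = int(np.argmax(row)) + 1  # 1-based group of the row maximum
        if abs(best - g) <= 1:
            hits += 1
    return hits / len(test_groups_sorted)


def run_benchmark(
    seed: int,
    n_groups: int = 5,
    train_per_group: int = 3,
    samples_per_image: int = 500,
    n_trees: int = 25,
    max_depth: int = 9,
    n_test: int = 10,
    mean_start: float = 75.0,
    bin_width: float = 14.0,
    frame: tuple[int, int] = (100, 140),
    scales: tuple[float, ...] = (1.0, 2.0, 4.0),
) -> BenchmarkResult:
    """Train the stack on a grouped synthetic dataset and evaluate it.

    The defaults span membrane means 75-145 across 5 bins with 3 training
    images per bin, a scaled-down stand-in for the wide clinical grayscale
    spread; test images are drawn 2 per bin with fresh seeds.
    """
    feature_cfg = FeatureConfig(scales=scales)
    base = SyntheticSpec(height=frame[0], width=frame[1], ribbon_width_range=(3.0, 7.0))
    train_cfg = TrainingConfig(
        n_groups=n_groups,
        samples_per_image=samples_per_image,
        n_trees=n_trees,
        max_depth=max_depth,
        feature_config=feature_cfg,
        mean_start=mean_start,
        bin_width=bin_width,
        seed=derive_seed(seed, 10),
    )
    dataset = generate_grouped_dataset(
        n_groups, train_per_group, mean_start, bin_width,
        base_spec=base, seed=derive_seed(seed, 11),
    )
    full = train_full_view(dataset, train_cfg)
    zoom = train_zoom_view(dataset, train_cfg)

    # test images: cycle through the groups, fresh seeds, means at bin interior
    rng = np.random.default_rng(derive_seed(seed, 12))
    tests: list[LabeledImage] = []
    test_groups: list[int] = []
    morphs = ("strip", "closed", "compound")
    for k in range(n_test):
        g = (k % n_groups) + 1
        lo = mean_start + (g - 1) * bin_width
        target = rng.uniform(lo + 0.1 * bin_width, lo + 0.9 * bin_width)
        spec = base.replace(
            morphology=morphs[k % 3], gbm_mean=float(target),
            seed=derive_seed(seed, 13, k),
        )
        tests.append(generate_membrane(spec))
        test_groups.append(g)

    ref_cfg = RefinementConfig()
    # classify each test once per forest; reuse everywhere
    crs_per_test = [coarse_results(zoom, t.image, feature_cfg) for t in tests]
    r1_masks = []
    for t in tests:
        r1 = classify_image(full.forest, t.image, feature_cfg)
        if ref_cfg.cleanup_r1:
            r1 = morphological_cleanup(r1, ref_cfg.cleanup)
        r1_masks.append(r1)

    grid = heatmap_grid(zoom, tests, feature_cfg, ref_cfg, crs_per_test=crs_per_test)
    means = np.array([t.mask_mean for t in tests])
    order = np.argsort(means, kind="stable")
    groups_sorted = [test_groups[i] for i in order]
    hit_rate = _own_group_hit_rate(grid, groups_sorted)

    forest_means = grid.scores.mean(axis=0)
    rfs1_mean = float(np.mean([jaccard(t.mask, r1) for t, r1 in zip(tests, r1_masks)]))

    reports = [
        ablation(t, zoom, full, ref_cfg, feature_cfg, crs=crs_per_test[i], r1=r1_masks[i])
        for i, t in enumerate(tests)
    ]
    return BenchmarkResult(
        heatmap=grid,
        own_group_hit_rate=hit_rate,
        forest_mean_jaccard=forest_means,
        rfs1_mean_jaccard=rfs1_mean,
        ablation_reports=reports,
        ablation_summary=summarize(reports),
        test_groups=groups_sorted,
    )
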
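"""Grayscale grouping, pixel sampling, and the two-level forest stack.

Level 1 is an ordinary bagged random forest (T bootstrap trees of depth <= D,
sqrt-of-F random feature subsets at splits).  Level 2 stacks forests across
grayscale groups in two ways: the *full-view* model pools M samples from one
image of every group into a single forest (training integration), while the
*zoom-view* model trains one forest per group (testing integration — their
outputs are fused later at segmentation time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureConfig, FeatureStack, compute_feature_stack
from .synthetic import GrayscaleGroup, GroupedTrainingSet, LabeledImage, make_groups

LABEL_GBM = 1
LABEL_BACKGROUND = 0

# defaults of the published pipeline
DEFAULT_N_GROUPS = 37
DEFAULT_SAMPLES_PER_IMAGE = 2000
DEFAULT_N_TREES = 100
DEFAULT_MAX_DEPTH = 9
DEFAULT_MEAN_START = 73.5
DEFAULT_BIN_WIDTH = 2.0


@dataclass(frozen=True)
class TrainingConfig:
    n_groups: int = DEFAULT_N_GROUPS
    samples_per_image: int = DEFAULT_SAMPLES_PER_IMAGE
    n_trees: int = DEFAULT_N_TREES
    max_depth: int = DEFAULT_MAX_DEPTH
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    balance_classes: bool = True
    pool_group_images: bool = False  # extension: use all images of a group
    mean_start: float = DEFAULT_MEAN_START
    bin_width: float = DEFAULT_BIN_WIDTH
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_groups", "samples_per_image", "n_trees", "max_depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def groups(self) -> list[GrayscaleGroup]:
        return make_groups(self.n_groups, self.mean_start, self.bin_width)


@dataclass
class PixelSample:
    feature_vector: np.ndarray
    label: int  # LABEL_GBM or LABEL_BACKGROUND
    origin: tuple[str, int, int]  # (image id, row, col)


@dataclass
class ForestModel:
    """A trained bagged forest plus the metadata needed to reuse it safely."""

    forest: RandomForestClassifier
    channel_names: list[str]
    training_meta: dict

    @property
    def n_trees(self) -> int:
        return len(self.forest.estimators_)

    def tree_votes(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting GBM for each row of X (hard votes)."""
        votes = np.zeros(X.shape[0], dtype=np.int64)
        for est in self.forest.estimators_:
            votes += est.predict(X).astype(np.int64) == LABEL_GBM
        return votes / self.n_trees


@dataclass
class FullViewModel:
    forest: ForestModel


@dataclass
class ZoomViewModel:
    forests: list[ForestModel]  # index-aligned with groups (forests[g-1])
    groups: list[GrayscaleGroup]

    @property
    def n_groups(self) -> int:
        return len(self.forests)


def derive_seed(master: int, *keys: int) -> int:
    """Deterministic child seed (< 2**31) from a master seed and indices."""
    return int(np.random.SeedSequence([master, *keys]).generate_state(1)[0] % (2**31 - 1))


# ---------------------------------------------------------------------------
# Group assignment
# ---------------------------------------------------------------------------

def assign_group(image: LabeledImage, groups: Sequence[GrayscaleGroup]) -> int:
    """Return the 1-based group whose bin contains the image's mean GBM gray.

    Means below the first bin clamp to group 1, above the last to group N,
    each with a warning.  An empty mask has no mean and raises.
    """
    mean = image.mask_mean  # raises on empty mask
    for grp in groups:
        if grp.contains(mean):
            return grp.index
    if mean < groups[0].lo:
        warnings.warn(
            f"GBM mean {mean:.2f} below first bin [{groups[0].lo}, {groups[0].hi}); "
            "clamping to group 1", stacklevel=2,
        )
        return groups[0].index
    warnings.warn(
        f"GBM mean {mean:.2f} above last bin [{groups[-1].lo}, {groups[-1].hi}); "
        f"clamping to group {groups[-1].index}", stacklevel=2,
    )
    return groups[-1].index


# ---------------------------------------------------------------------------
# Pixel sampling
# ---------------------------------------------------------------------------

def sample_pixels(
    image: LabeledImage,
    m: int,
    balance: bool,
    seed: int,
    cfg: FeatureConfig,
    stack: FeatureStack | None = None,
    image_id: str = "",
) -> list[PixelSample]:
    """Draw exactly ``m`` labelled pixels from an image, without replacement.

    Balanced mode draws ceil(m/2) GBM and floor(m/2) background pixels; if a
    class is too small it falls back to proportional sampling with a warning.
    """
    h, w = image.image.shape
    if m > h * w:
        raise ValueError(f"cannot draw {m} samples from a {h}x{w} image")
    if stack is None:
        stack = compute_feature_stack(image.image, cfg)
    rng = np.random.default_rng(seed)
    flat_mask = image.mask.ravel()
    fg = np.flatnonzero(flat_mask)
    bg = np.flatnonzero(~flat_mask)
    n_fg_want = (m + 1) // 2
    n_bg_want = m // 2
    if balance and (len(fg) < n_fg_want or len(bg) < n_bg_want):
        warnings.warn(
            f"class too small for balanced sampling ({len(fg)} GBM / {len(bg)} "
            "background pixels); falling back to proportional sampling",
            stacklevel=2,
        )
        balance = False
    if balance:
        idx = np.concatenate([
            rng.choice(fg, size=n_fg_want, replace=False),
            rng.choice(bg, size=n_bg_want, replace=False),
        ])
    else:
        idx = rng.choice(h * w, size=m, replace=False)
    X = stack.as_matrix()[idx]
    labels = np.where(flat_mask[idx], LABEL_GBM, LABEL_BACKGROUND)
    rows, cols = np.divmod(idx, w)
    return [
        PixelSample(feature_vector=X[i], label=int(labels[i]),
                    origin=(image_id, int(rows[i]), int(cols[i])))
        for i in range(m)
    ]


def _samples_to_arrays(samples: Sequence[PixelSample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([s.feature_vector for s in samples])
    y = np.array([s.label for s in samples], dtype=np.int64)
    return X, y


# ---------------------------------------------------------------------------
# Forest training
# ---------------------------------------------------------------------------

def train_forest(
    samples: Sequence[PixelSample],
    t: int,
    d: int,
    seed: int,
    channel_names: Sequence[str],
    meta: dict | None = None,
) -> ForestModel:
    """Train a bagged ensemble of ``t`` trees of depth <= ``d``.

    Bootstrap resampling per tree and sqrt-of-F random feature subsets at
    splits follow the usual random-forest construction.
    """
    if not samples:
        raise ValueError("no samples")
    X, y = _samples_to_arrays(samples)
    if len(np.unique(y)) < 2:
        raise ValueError("training samples contain a single class")
    forest = RandomForestClassifier(
        n_estimators=t,
        max_depth=d,
        max_features="sqrt",
        bootstrap=True,
        criterion="gini",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    training_meta = {"t": t, "d": d, "seed": seed, "n_samples": len(samples),
                     "criterion": "gini", **(meta or {})}
    return ForestModel(forest=forest, channel_names=list(channel_names),
                       training_meta=training_meta)


def _select_session_images(
    dataset: GroupedTrainingSet, cfg: TrainingConfig, rng: np.random.Generator
) -> dict[int, list[LabeledImage]]:
    """One random image per group (or all of them when pooling is on)."""
    selected: dict[int, list[LabeledImage]] = {}
    for grp in dataset.groups:
        imgs = dataset.images.get(grp.index, [])
        if not imgs:
            raise ValueError(f"group {grp.index} has no training images")
        if cfg.pool_group_images:
            selected[grp.index] = list(imgs)
        else:
            selected[grp.index] = [imgs[rng.integers(len(imgs))]]
    return selected


def _group_samples(
    images: Sequence[LabeledImage], grp_index: int, cfg: TrainingConfig
) -> list[PixelSample]:
    samples: list[PixelSample] = []
    for k, img in enumerate(images):
        samples.extend(sample_pixels(
            img, cfg.samples_per_image, cfg.balance_classes,
            seed=derive_seed(cfg.seed, grp_index, k),
            cfg=cfg.feature_config,
            image_id=f"group{grp_index}_img{k}",
        ))
    return samples


def train_full_view(dataset: GroupedTrainingSet, cfg: TrainingConfig) -> FullViewModel:
    """Train the full-view forest on M x N pixels pooled across all groups."""
    rng = np.random.default_rng(derive_seed(cfg.seed, 0))
    selected = _select_session_images(dataset, cfg, rng)
    pooled: list[PixelSample] = []
    provenance: dict[int, list[str]] = {}
    for grp in dataset.groups:
        group_samples = _group_samples(selected[grp.index], grp.index, cfg)
        pooled.extend(group_samples)
        provenance[grp.index] = [s.origin[0] for s in group_samples[:1]]
    model = train_forest(
        pooled, cfg.n_trees, cfg.max_depth, derive_seed(cfg.seed, 1),
        channel_names=cfg.feature_config.channel_names(),
        meta={"view": "full", "pooled_samples": len(pooled),
              "selected_images": provenance},
    )
    return FullViewModel(forest=model)


def train_zoom_view(dataset: GroupedTrainingSet, cfg: TrainingConfig) -> ZoomViewModel:
    """Train one forest per grayscale group (the zoom-view bank RF_1..RF_N)."""
    rng = np.random.default_rng(derive_seed(cfg.seed, 0))
    selected = _select_session_images(dataset, cfg, rng)
    forests: list[ForestModel] = []
    for grp in dataset.groups:
        group_samples = _group_samples(selected[grp.index], grp.index, cfg)
        forests.append(train_forest(
            group_samples, cfg.n_trees, cfg.max_depth,
            derive_seed(cfg.seed, 2, grp.index),
            channel_names=cfg.feature_config.channel_names(),
            meta={"view": "zoom", "group": grp.index,
                  "interval": (grp.lo, grp.hi)},
        ))
    return ZoomViewModel(forests=forests, groups=list(dataset.groups))
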
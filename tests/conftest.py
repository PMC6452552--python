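import numpy as np
import pytest

from rfstacks import (
    FeatureConfig,
    GroupedTrainingSet,
    LabeledImage,
    SyntheticSpec,
    TrainingConfig,
    generate_grouped_dataset,
    generate_membrane,
    run_benchmark,
    train_full_view,
    train_zoom_view,
)


@pytest.fixture(scope="session")
def tiny_feature_cfg() -> FeatureConfig:
    """Cheap feature stack for unit tests (4 families, 2 scales)."""
    return FeatureConfig(
        enabled_families=("mean", "sobel", "gaussian_blur", "neighbors"),
        scales=(1.0, 2.0),
    )


@pytest.fixture(scope="session")
def small_labeled() -> LabeledImage:
    return generate_membrane(
        SyntheticSpec(morphology="strip", height=60, width=80,
                      ribbon_width_range=(3.0, 6.0), seed=7)
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_feature_cfg) -> GroupedTrainingSet:
    base = SyntheticSpec(height=60, width=80, ribbon_width_range=(3.0, 6.0))
    return generate_grouped_dataset(
        n_groups=2, images_per_group=1, mean_start=90.0, bin_width=25.0,
        base_spec=base, seed=42,
    )


@pytest.fixture(scope="session")
def tiny_training_cfg(tiny_feature_cfg) -> TrainingConfig:
    return TrainingConfig(
        n_groups=2, samples_per_image=200, n_trees=5, max_depth=5,
        feature_config=tiny_feature_cfg, mean_start=90.0, bin_width=25.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_models(tiny_dataset, tiny_training_cfg):
    full = train_full_view(tiny_dataset, tiny_training_cfg)
    zoom = train_zoom_view(tiny_dataset, tiny_training_cfg)
    return full, zoom


@pytest.fixture(scope="session")
def benchmark_result():
    """The canonical seeded generalization benchmark (shared across tests)."""
    return run_benchmark(seed=0)


def random_mask(rng: np.random.Generator, shape=(8, 8), p=0.4) -> np.ndarray:
    return rng.random(shape) < p
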
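import numpy as np
import pytest

from eegselect import FeatureTable, ObjectiveConfig, PlantSpec, generate_feature_table


def make_planted_table(
    d: int,
    informative: tuple[int, ...],
    effect_size: float = 3.0,
    seed: int = 0,
    n_subjects: int = 10,
    n_recordings: int = 12,
    coeffs_per_channel: int = 5,
    noise_sd: float = 1.0,
) -> tuple[PlantSpec, FeatureTable]:
    spec = PlantSpec(
        n_subjects=n_subjects,
        n_recordings=n_recordings,
        n_channels=d,
        informative_channels=informative,
        effect_size=effect_size,
        noise_sd=noise_sd,
        seed=seed,
    )
    return spec, generate_feature_table(spec, coeffs_per_channel)


@pytest.fixture(scope="session")
def obj_config() -> ObjectiveConfig:
    return ObjectiveConfig()


@pytest.fixture(scope="session")
def small_planted():
    """d=6 planted table with strongly separable channels {0, 3}."""
    return make_planted_table(6, (0, 3), effect_size=5.0, seed=7, coeffs_per_channel=3)


@pytest.fixture(autouse=True)
def _silence_degenerate_metric_warnings():
    """Per-class zero-denominator warnings are expected on hard tables."""
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="zero denominator")
        yield
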
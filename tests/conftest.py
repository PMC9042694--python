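from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from cytomil.mil import MILConfig
from cytomil.synthetic import SynthConfig, generate_dataset

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

REPO_ROOT = Path(__file__).resolve().parents[1]


@pytest.fixture(scope="session")
def tiny_cfg() -> SynthConfig:
    """3 malignant + 3 benign slides on a 4x4 grid of 32 px patches."""
    return SynthConfig(
        n_slides_malignant=3,
        n_slides_benign=3,
        grid_rows=4,
        grid_cols=4,
        patch_px=32,
        pos_patch_fraction=0.25,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_slides(tiny_cfg):
    return generate_dataset(tiny_cfg)


@pytest.fixture()
def fast_mil_cfg() -> MILConfig:
    """Short training schedule for unit tests."""
    return MILConfig(
        k_top=4,
        n_neg_random=4,
        epochs_stage1=1,
        epochs_stage2=3,
        learning_rate=0.02,
        batch_size=16,
        seed=5,
        input_px=32,
    )


@pytest.fixture(scope="session")
def demo_config_path() -> Path:
    return REPO_ROOT / "configs" / "demo.yaml"
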
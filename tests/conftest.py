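import warnings

import numpy as np
import pytest

from radcrt.pipeline import PipelineConfig, run_all
from radcrt.preprocess import CTVolume, VOIMask
from radcrt.synthetic import CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_bundle():
    """The default study-design cohort (27 + 17 cases, 6 + 6 responders)."""
    return generate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def strong_run():
    """One full pipeline run on the default strong-effect cohort."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_all(PipelineConfig.with_seed(7))


@pytest.fixture
def ball_mask():
    """Digitized ball of radius 10 voxels at 1 mm isotropic spacing."""
    n = 25
    c = (n - 1) / 2
    zz, yy, xx = np.meshgrid(*([np.arange(n)] * 3), indexing="ij")
    flags = (((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= 10 ** 2)
    return VOIMask(flags.astype(np.uint8), (1.0, 1.0, 1.0))


def make_volume(values, spacing=(1.0, 1.0, 1.0)):
    return CTVolume(np.asarray(values, dtype=float), spacing)


def make_mask(flags, spacing=(1.0, 1.0, 1.0)):
    return VOIMask(np.asarray(flags, dtype=np.uint8), spacing)
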
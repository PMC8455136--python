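import numpy as np
import pytest

from hybmap import ChromosomeSpec, PipelineConfig
from hybmap.pipeline import run_pipeline


@pytest.fixture(scope="session")
def study_run():
    """One full-scale pipeline run under the study conditions: 93 F2,
    obligate single crossover per chromosome per meiosis, 5x coverage,
    sequencing error 0.005, default six-chromosome karyotype."""
    return run_pipeline(PipelineConfig(seed=0))


@pytest.fixture()
def small_chroms():
    """A light two-autosome + X karyotype for unit tests."""
    return [
        ChromosomeSpec("c1", 4_000_000),
        ChromosomeSpec("c2", 3_000_000),
        ChromosomeSpec("cX", 2_000_000, is_x=True),
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
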
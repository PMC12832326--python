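import numpy as np
import pytest

from phalanx.config import GeneratorConfig
from phalanx.measurement import compute_ratios
from phalanx.pipeline import build_default_reference, calibrated_ts_config
from phalanx.synthetic import generate_reference_cohort, generate_ts_cohort


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def ref_cohort(default_config):
    """Default-calibration reference cohort at the study sample size."""
    return generate_reference_cohort(default_config)


@pytest.fixture(scope="session")
def ref_ratios(ref_cohort):
    _, lengths = ref_cohort
    ratios, rejects = compute_ratios(lengths)
    assert len(rejects) == 0
    return ratios


@pytest.fixture(scope="session")
def reference_build(default_config):
    """(table, trim_report, retained_ratios, metadata) for the default cohort."""
    return build_default_reference(default_config)


@pytest.fixture(scope="session")
def reference_table(reference_build):
    return reference_build[0]


@pytest.fixture(scope="session")
def ts_calibrated_config(default_config, reference_table):
    return calibrated_ts_config(default_config, reference_table)


@pytest.fixture(scope="session")
def ts_large(ts_calibrated_config):
    """10,000-subject TS cohort from the mixture-calibrated ratio backend."""
    cfg = ts_calibrated_config.model_copy(update={"ts_n": 10_000})
    return generate_ts_cohort(cfg, backend="ratio_level")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
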
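import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from metexpand.annotate import AnnotationConfig
from metexpand.simulate import StudyConfig, generate_study
from metexpand.suspects import record_from_smiles


@pytest.fixture(scope="session")
def zero_noise_study():
    """30-compound two-mode study with no noise: ground truth is exact."""
    cfg = StudyConfig(
        n_compounds=30,
        frac_in_spectral_library=0.5,
        frac_in_suspect_list=0.6,
        n_formula_only=2,
        n_decoy_features=3,
        mz_jitter_ppm=0.0,
        spurious_peak_rate=0.0,
        peak_dropout_rate=0.0,
        seed=11,
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def noisy_study():
    """200-feature study at the generator's default noise levels."""
    cfg = StudyConfig(
        n_compounds=195,
        frac_in_spectral_library=1.0,
        frac_in_suspect_list=0.6,
        n_formula_only=0,
        n_decoy_features=5,
        strict_ground_truth=False,
        seed=42,
    )
    return generate_study(cfg)


@pytest.fixture
def ethanol():
    return record_from_smiles("C1", "ethanol", "CCO")


@pytest.fixture
def hexadecanamide():
    return record_from_smiles("C2", "hexadecanamide", "CCCCCCCCCCCCCCCC(N)=O")


@pytest.fixture
def rng():
    return np.random.default_rng(7)
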
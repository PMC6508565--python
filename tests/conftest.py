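import warnings

import numpy as np
import pytest

from phenogxe import synthetic as syn

# mixed-model fits routinely emit convergence chatter on boundary cases;
# keep test output readable
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_config():
    return syn.ExperimentConfig(
        n_genotypes=4, reps_per_treatment=(4, 4, 3),
        day_start=8, day_end=16,
        early_onset_range=(9, 10), late_onset_range=(14, 15),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return syn.generate_experiment(small_config)


@pytest.fixture(scope="session")
def rendered_plant():
    return syn.render_plant_image(5000, 0.3, canvas_size=(128, 128), seed=5)
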
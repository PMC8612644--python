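import numpy as np
import pytest

from facemvpa.core import default_affine
from facemvpa.synth import (
    ExperimentDesign,
    Region,
    SignalSpec,
    generate_design,
    generate_patterns,
)


@pytest.fixture(scope="session")
def design16() -> ExperimentDesign:
    """Shared 16-run event-related design."""
    return generate_design(16, seed=101)


@pytest.fixture(scope="session")
def design4() -> ExperimentDesign:
    return generate_design(4, seed=102)


@pytest.fixture(scope="session")
def small_spec() -> SignalSpec:
    """10^3 grid with a single subcategory region at the center."""
    return SignalSpec(
        grid_shape=(10, 10, 10),
        affine=default_affine(3.5),
        regions=[Region((17.5, 17.5, 17.5), 10.5, "subcategory", 1.0)],
    )


@pytest.fixture(scope="session")
def noisy_patterns(design16, small_spec):
    return generate_patterns(design16, small_spec, noise_sd=1.0, seed=7)


def make_noise_patterns(n_runs, n_conditions, n_voxels, seed, labels=None):
    """Pure-noise BetaPatternSet on a flat grid (helper for null tests)."""
    from facemvpa.core import BetaPatternSet

    rng = np.random.default_rng(seed)
    if labels is None:
        labels = tuple(f"c{i}" for i in range(n_conditions))
    return BetaPatternSet(
        betas=rng.standard_normal((n_runs, n_conditions, n_voxels)),
        condition_labels=labels,
        grid_shape=(n_voxels, 1, 1),
        affine=default_affine(1.0),
    )
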
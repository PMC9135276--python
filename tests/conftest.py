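import warnings

import numpy as np
import pytest

from spheroquant import synthetic as syn


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Pipeline stages warn about excluded wells/cells; tests assert on
    results, not on log noise, unless they opt in with pytest.warns."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def sorted_spheroid():
    """One shell-sorted spheroid image (true edge/center ratio 3) + truth."""
    spec = syn.SyntheticSpheroidSpec(sorting_strength=np.log(3.0), seed=11)
    return syn.gen_spheroid_image(spec)


@pytest.fixture(scope="session")
def mixed_spheroid():
    """One well-mixed spheroid image + truth."""
    spec = syn.SyntheticSpheroidSpec(sorting_strength=0.0, seed=11)
    return syn.gen_spheroid_image(spec)


@pytest.fixture(scope="session")
def monolayer_uniform():
    return syn.gen_monolayer_image(n_cells=120, enrichment=0.0, seed=3)


@pytest.fixture(scope="session")
def monolayer_enriched():
    return syn.gen_monolayer_image(n_cells=120, enrichment=5.0, seed=3)
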
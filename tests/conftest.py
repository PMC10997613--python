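import warnings

import numpy as np
import pytest

from mitescan.synthetic import RenderSettings, default_plant_spec, generate_plant

# scikit-image 0.26 renames some morphology helpers; the pinned calls work
# on the installed version and the warnings only add noise to test output
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def default_plant():
    """One rendered plant with the default symptom load, shared read-only."""
    spec = default_plant_spec(n_leaves=8, seed=42)
    scan_ab, scan_ad, truth = generate_plant(spec)
    return {"spec": spec, "ab": scan_ab, "ad": scan_ad, "truth": truth}


@pytest.fixture(scope="session")
def clean_plant():
    """A plant with no eggs, no feces, no damage (blank biology)."""
    n = 5
    spec = default_plant_spec(n_leaves=n, seed=7, mean_eggs=0, mean_feces=0,
                              mean_damage_fraction=0)
    spec = type(spec)(
        n_leaves=n, leaf_lengths_mm=spec.leaf_lengths_mm,
        eggs_per_leaf=[0] * n, feces_per_leaf=[0] * n,
        damage_fraction_per_leaf=[0.0] * n, bubble_density=0.0, seed=7,
    )
    scan_ab, scan_ad, truth = generate_plant(spec)
    return {"spec": spec, "ab": scan_ab, "ad": scan_ad, "truth": truth}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
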
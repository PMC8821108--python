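import numpy as np
import pandas as pd
import pytest

import hapattern as hp


@pytest.fixture(scope="session")
def ref_cohort():
    """Reference synthetic cohort: 30/30/60 samples, shift 2.5, hazard 0.7."""
    cfg = hp.reference_config(seed=0)
    expr, clinical, truth = hp.simulate_cohort(cfg)
    return expr, clinical, truth


@pytest.fixture(scope="session")
def big_cohort():
    """Larger cohort (75/75/150) for power-hungry checks."""
    cfg = hp.CohortConfig(n_per_pattern=(75, 75, 150), seed=3)
    expr, clinical, truth = hp.simulate_cohort(cfg)
    return expr, clinical, truth


@pytest.fixture()
def toy_expr():
    rng = np.random.default_rng(42)
    genes = [f"G{i}" for i in range(10)]
    samples = [f"S{j}" for j in range(6)]
    return pd.DataFrame(rng.normal(size=(10, 6)), index=genes, columns=samples)
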
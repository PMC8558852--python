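import numpy as np
import pandas as pd
import pytest

from coexdiff import synthetic


@pytest.fixture(scope="session")
def small_annotation() -> pd.DataFrame:
    return synthetic.generate_annotation(30, 12, 4, seed=11)


@pytest.fixture(scope="session")
def module_dataset():
    """Counts with one tumorA-only 8-gene module and planted DE genes."""
    ann = synthetic.generate_annotation(60, 20, 5, seed=7)
    params = synthetic.GeneratorParams(
        de_fraction=0.3,
        modules=(synthetic.ModuleSpec(8, 0.9, ("tumorA",)),),
        hazard_log2hr=1.0,
    )
    design = synthetic.CohortDesign(30, 30, 24, {6: 10, 7: 14, 8: 6})
    data, truth = synthetic.generate_counts(design, ann, params, seed=7)
    return ann, data, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
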
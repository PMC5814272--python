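import warnings

import numpy as np
import pandas as pd
import pytest

from immunoscope.io_formats import ExpressionMatrix
from immunoscope.synthetic import CohortConfig, generate_cohort, synthetic_panel


@pytest.fixture(scope="session")
def demo_cohort():
    """A small seeded cohort shared by read-only tests."""
    cfg = CohortConfig(n_samples=40, seed=123)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(cfg)


@pytest.fixture(scope="session")
def demo_panel():
    return synthetic_panel(n_cell_types=6, genes_per_set=12, n_tcell=2)


@pytest.fixture()
def noise_expression():
    """I.i.d. lognormal expression: 120 genes x 20 samples, no structure."""
    rng = np.random.default_rng(2024)
    genes = [f"G{i:03d}" for i in range(120)]
    samples = [f"S{i:02d}" for i in range(20)]
    df = pd.DataFrame(np.exp(rng.normal(2.0, 1.0, size=(120, 20))),
                      index=genes, columns=samples)
    return ExpressionMatrix(df)
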
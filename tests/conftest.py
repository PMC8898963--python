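import numpy as np
import pandas as pd
import pytest

import regscore as rs


@pytest.fixture(scope="session")
def small_cohort():
    """Well-separated synthetic cohort with survival signal (shared, read-only)."""
    expr, truth = rs.generate_cohort(
        n_samples=200, n_genes=300, n_regulators=12, delta=3.0,
        program_size=25, overlap_frac=0.1, noise_sd=1.0, seed=11,
        beta_surv=0.7)
    surv = rs.generate_survival(truth, baseline_hazard=0.01, censor_rate=0.3,
                                seed=12)
    return expr, truth, surv


@pytest.fixture()
def tiny_expr():
    data = pd.DataFrame(
        [[5.0, 1.0, 2.0, 4.0],
         [4.0, 2.0, 1.0, 5.0],
         [3.0, 3.0, 4.0, 1.0],
         [2.0, 4.0, 5.0, 2.0],
         [1.0, 5.0, 3.0, 3.0]],
        index=[f"g{i+1}" for i in range(5)],
        columns=[f"s{i+1}" for i in range(4)])
    return rs.ExpressionMatrix(data)
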
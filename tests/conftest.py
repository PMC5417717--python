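import numpy as np
import pandas as pd
import pytest

from vulntrend.synthetic import (FluxSimSpec, TrendingSimSpec,
                                 simulate_expression, simulate_flux)
from vulntrend.trending import ExpressionStudy


@pytest.fixture
def planted_spec() -> TrendingSimSpec:
    """Moderate planted study matching the design this pipeline models."""
    return TrendingSimSpec(n_transcripts=300, n_per_group=3,
                           n_planted_protective=20, n_planted_harmful=20,
                           effect_log2fc=2.0, noise_sd=0.25, seed=11)


@pytest.fixture
def noise_free_study():
    spec = TrendingSimSpec(n_transcripts=120, n_per_group=3,
                           n_planted_protective=15, n_planted_harmful=10,
                           effect_log2fc=2.0, noise_sd=0.0, seed=5)
    return simulate_expression(spec)


@pytest.fixture
def noisy_plate():
    return simulate_flux(FluxSimSpec(n_wells_per_group=8, noise_sd=2.0,
                                     seed=3))


def make_study(matrix: np.ndarray, seed_names: bool = True) -> ExpressionStudy:
    """Wrap a raw (transcripts x 9) array as a 3x3 EDL/GS/TA study."""
    n = matrix.shape[0]
    samples = [f"{g}_{i}" for g in ("EDL", "GS", "TA") for i in (1, 2, 3)]
    groups = pd.Series([s.split("_")[0] for s in samples], index=samples)
    df = pd.DataFrame(matrix, index=[f"T{i:04d}" for i in range(n)],
                      columns=samples)
    return ExpressionStudy(matrix=df, groups=groups,
                           group_order=("EDL", "GS", "TA"))
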
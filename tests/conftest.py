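import warnings

import numpy as np
import pandas as pd
import pytest

from admixfine.containers import DosageMatrix
from admixfine.synthetic import (
    CausalVariant,
    SimulationConfig,
    simulate_case_control,
)

warnings.filterwarnings("ignore", message="only .* overlapping variants")
warnings.filterwarnings("ignore", message="study .* dropped")


@pytest.fixture(scope="session")
def causal_dataset():
    """Mid-size admixed case-control cohort with one planted causal variant."""
    cfg = SimulationConfig(
        n_cases=400,
        n_controls=400,
        n_variants=80,
        causal=[CausalVariant("var00020", float(np.log(1.6)))],
        seed=101,
    )
    return simulate_case_control(cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """Small cohort with no genetic effects (independent variants)."""
    cfg = SimulationConfig(
        n_cases=250, n_controls=250, n_variants=60, block_len_range=(1, 1), seed=202
    )
    return simulate_case_control(cfg)


def make_matrix(dosages: np.ndarray, typed: bool = True, pos0: int = 1000, step: int = 100):
    """Wrap a raw samples x variants array in a DosageMatrix."""
    dosages = np.asarray(dosages, dtype=float)
    n, v = dosages.shape
    meta = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(v)],
            "chrom": "1",
            "pos": pos0 + step * np.arange(v),
            "risk_allele": "A",
            "other_allele": "G",
            "typed": typed,
            "rsq": 1.0,
        }
    )
    return DosageMatrix(dosages, [f"s{i}" for i in range(n)], meta)
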
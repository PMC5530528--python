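import numpy as np
import pandas as pd
import pytest

from clonebreak import FitConfig, Scenario, run_comparison


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_scenario(**kwargs) -> Scenario:
    """A desk-sized genome (60 x 500 kb segments over 3 chromosomes) for
    fast end-to-end fits."""
    defaults = dict(
        n_chromosomes=3,
        chromosome_length=10_000_000,
        n_events=6,
        n_resample=20,
        seed=0,
    )
    defaults.update(kwargs)
    return Scenario(**defaults)


def tiny_segments(n: int, chrom: str = "1", length: int = 500_000,
                  readcount: int = 0) -> pd.DataFrame:
    """A bare segment table of n equal bins on one chromosome."""
    starts = np.arange(n) * length
    return pd.DataFrame({
        "chromosome": chrom,
        "start": starts,
        "end": starts + length,
        "length": length,
        "effective_length": float(length),
        "readcount": readcount,
        "allele_a_readcount": 0,
        "allele_b_readcount": 0,
    })


@pytest.fixture(scope="session")
def recovery_experiments():
    """Replicated segment-count simulation experiments shared by the
    parameter-recovery and model-comparison acceptance tests.

    Descendant fraction 0.2: both the breakpoint model and the naive HMM;
    descendant fraction 0.3: breakpoint model only.  Normal fractions
    alternate between 0.4 and 0.6 across replicates.
    """
    config = FitConfig()
    out = {}
    out[0.2] = run_comparison(
        Scenario(descendant_fraction=0.2), config, n_replicates=20, seed=2,
        methods=("breakpoint", "naive"), normal_fractions=(0.4, 0.6))
    out[0.3] = run_comparison(
        Scenario(descendant_fraction=0.3), config, n_replicates=20, seed=3,
        methods=("breakpoint",), normal_fractions=(0.4, 0.6))
    return out
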
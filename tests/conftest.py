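import numpy as np
import pandas as pd
import pytest

from qpcrsig import CtTable, SampleMeta, default_cohort_spec, generate_cohort, qc_replicates


def make_table(data: dict[str, list[float]], groups: dict[str, str] | None = None,
               samples: list[str] | None = None) -> CtTable:
    """Build a CtTable from {gene: column} with optional group labels."""
    n = len(next(iter(data.values())))
    samples = samples or [f"S{i + 1}" for i in range(n)]
    ct = pd.DataFrame(data, index=pd.Index(samples, name="sample_id"), dtype=float)
    meta = pd.Series(groups).reindex(samples) if groups else None
    return CtTable(ct=ct, meta=meta)


@pytest.fixture(scope="session")
def default_cohort():
    measurements, meta, truth = generate_cohort(default_cohort_spec(), seed=1)
    table, report = qc_replicates(measurements, meta=meta)
    return table, report, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
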
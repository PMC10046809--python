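import numpy as np
import pandas as pd
import pytest

from rnatrends import reference
from rnatrends.aggregate import ExpressionDataset
from rnatrends.simulate import SimulationConfig, generate


@pytest.fixture(scope="session")
def hg_series():
    """Published per-age HG mean series (the desk-scale input table)."""
    return reference.hg_reference_series()


@pytest.fixture(scope="session")
def intg_series():
    return reference.intg_reference_series()


def make_dataset(values, tissues=("T1",), ages=(1.0, 3.0, 6.0), reps=2, genes=None):
    """Small in-memory dataset: ``values[g][t][a]`` replicated ``reps`` times.

    ``values`` is a dict gene -> callable(age) or gene -> scalar; every
    replicate equals the cell's value (noise-free helper for unit tests).
    """
    genes = list(values) if genes is None else genes
    cols, meta = [], []
    data = {g: [] for g in genes}
    for t in tissues:
        for a in ages:
            for k in range(reps):
                sid = f"{t}_{a:g}_{k}"
                cols.append(sid)
                meta.append((sid, t, a, "M" if k == 0 else "F"))
                for g in genes:
                    v = values[g]
                    data[g].append(float(v(a)) if callable(v) else float(v))
    matrix = pd.DataFrame(
        np.array([data[g] for g in genes]), index=pd.Index(genes, name="gene"), columns=cols
    )
    samples = pd.DataFrame(
        meta, columns=["sample", "tissue", "age_months", "sex"]
    ).set_index("sample")
    return ExpressionDataset(matrix=matrix, samples=samples)


@pytest.fixture()
def toy_dataset():
    return make_dataset({"Actb": 7.0, "Gapdh": lambda a: 10.0 + a, "Hoxa1": 2.0})


@pytest.fixture(scope="session")
def small_cohort():
    """One noisy synthetic cohort, shared across tests (read-only)."""
    cfg = SimulationConfig(n_genes=300, n_tissues=4, seed=11)
    return generate(cfg)
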
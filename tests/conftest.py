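import numpy as np
import pandas as pd
import pytest

from triomics.io import ExpressionMatrix
from triomics.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """One default-condition study shared by read-only tests."""
    return simulate_study(SimulationConfig(seed=0))


@pytest.fixture
def small_expr():
    """Deterministic 6-gene x 6-sample matrix with mixed locus types."""
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(6)]
    samples = [f"s{i}" for i in range(6)]
    values = pd.DataFrame(rng.normal(7, 1, size=(6, 6)), index=genes,
                          columns=samples)
    locus = pd.Series(["coding", "coding", "multiple_complex", "noncoding",
                       "other", "coding"], index=genes)
    return ExpressionMatrix(values, locus)


def make_metadata(groups, families, models=None, sample_ids=None):
    n = len(groups)
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    return pd.DataFrame({
        "sample_id": sample_ids,
        "group": groups,
        "family_id": families,
        "model": models or ["PBMC"] * n,
        "cftr_class": ["NA"] * n,
        "pancreatic": ["NA"] * n,
        "pa_infection": ["NA"] * n,
        "sweat_chloride": [np.nan] * n,
        "fev1_pct": [np.nan] * n,
    })


def make_de_frame(gene_ids, is_deg, log2fc=None, p=None):
    """Minimal DEResult-shaped frame for set-logic tests."""
    n = len(gene_ids)
    log2fc = np.asarray(log2fc if log2fc is not None
                        else np.where(np.asarray(is_deg), -2.0, 0.1))
    p = np.asarray(p if p is not None else np.where(is_deg, 1e-5, 0.5))
    return pd.DataFrame({
        "gene_id": gene_ids,
        "log2fc": log2fc,
        "s2": 0.1,
        "t_mod": log2fc * 10,
        "df_total": 10.0,
        "p_value": p,
        "fdr_q": p,
        "direction": np.where(log2fc < 0, "down", "up"),
        "is_deg": np.asarray(is_deg, dtype=bool),
    })
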
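import numpy as np
import pandas as pd
import pytest

from wccs.datamodel import ExpressionMatrix, PhenotypeTable, TargetSiteTable


def make_matrix(values, feature_ids=None, sample_ids=None, calls=None):
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    feature_ids = feature_ids or [f"f{i}" for i in range(p)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n)]
    calls_df = None
    if calls is not None:
        calls_df = pd.DataFrame(np.asarray(calls, dtype=object),
                                index=feature_ids, columns=sample_ids)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=feature_ids, columns=sample_ids),
        calls=calls_df,
    )


def make_pheno(groups_per_sample, covariates=None):
    """groups_per_sample: dict sample_id -> group."""
    df = pd.DataFrame({"group": pd.Series(groups_per_sample)})
    for name, vals in (covariates or {}).items():
        df[name] = pd.Series(vals)
    return PhenotypeTable(df)


def make_sites(rows):
    """rows: iterable of (mirna, gene, score) or (mirna, gene, site_type, score)."""
    records = []
    for r in rows:
        if len(r) == 3:
            records.append((r[0], r[1], "7mer-m8", float(r[2])))
        else:
            records.append((r[0], r[1], r[2], float(r[3])))
    return TargetSiteTable(
        pd.DataFrame(records, columns=["mirna_id", "gene_id", "site_type", "context_score"])
    )


def random_wccs_instance(rng, max_genes=50, max_mirnas=10):
    """A random small scoring instance: sites + direction/fold map."""
    n_genes = int(rng.integers(8, max_genes + 1))
    n_mirnas = int(rng.integers(2, max_mirnas + 1))
    genes = [f"G{i}" for i in range(n_genes)]
    mirnas = [f"m{i}" for i in range(n_mirnas)]
    changes = {
        m: (("up", "down")[int(rng.integers(2))], float(rng.uniform(1.0, 3.0)))
        for m in mirnas
    }
    n_sites = int(rng.integers(n_genes, 4 * n_genes))
    rows = []
    for _ in range(n_sites):
        rows.append(
            (
                mirnas[int(rng.integers(n_mirnas))],
                genes[int(rng.integers(n_genes))],
                float(-rng.uniform(0.01, 0.6)),
            )
        )
    return rows, changes


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
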
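import numpy as np
import pandas as pd
import pytest

from tmtde.io import AbundanceMatrix


def make_annotation(groups_by_batch, include_mp=True):
    """Annotation from {batch: [group, ...]}; channels auto-assigned."""
    rows = []
    counter = {}
    for batch, groups in groups_by_batch.items():
        for i, g in enumerate(groups):
            counter[g] = counter.get(g, 0) + 1
            sid = f"{g}{counter[g]:02d}" if g not in ("QC", "MP") else f"{g}_b{batch}"
            rows.append({"sample_id": sid, "group": g, "batch": batch, "channel": f"ch{i}"})
        if include_mp:
            rows.append({"sample_id": f"MP_b{batch}", "group": "MP",
                         "batch": batch, "channel": "chMP"})
    return pd.DataFrame(rows)


def make_matrix(values, annotation, scale="raw", accessions=None, genes=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if accessions is None:
        accessions = [f"P{i:04d}" for i in range(n)]
    idx = pd.Index(accessions, name="accession")
    if genes is None:
        genes = [f"G{i:04d}" for i in range(n)]
    data = pd.DataFrame(values, index=idx, columns=list(annotation["sample_id"]))
    return AbundanceMatrix(data, annotation, pd.Series(genes, index=idx, name="gene"),
                           scale=scale)


@pytest.fixture
def two_group_zmatrix():
    """Factory for a z-scale matrix with two subject groups and no batches
    to correct (single batch), handy for the DE statistics."""

    def build(values_a, values_b, group_a="PSP", group_b="HC", n_extra_rows=0, seed=0):
        values_a = np.atleast_2d(np.asarray(values_a, float))
        values_b = np.atleast_2d(np.asarray(values_b, float))
        X = np.concatenate([values_a, values_b], axis=1)
        if n_extra_rows:
            rng = np.random.default_rng(seed)
            X = np.vstack([X, rng.normal(size=(n_extra_rows, X.shape[1]))])
        ann = make_annotation(
            {1: [group_a] * values_a.shape[1] + [group_b] * values_b.shape[1]},
            include_mp=False)
        return make_matrix(X, ann, scale="zscore")

    return build
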
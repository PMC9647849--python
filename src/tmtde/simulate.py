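"""Synthetic multi-batch 11-plex TMT datasets with known ground truth.

Emulates the study design the rest of the package analyses: five batches of
11-plex TMT covering 45 subjects (15 PSP, 15 PD, 15 HC), with one master
pool (MP) reference channel and one pooled QC aliquot per batch.  The
generative model, per protein i and subject j in batch b, on the log2
scale::

    log2 x_ij = mu_i + effect_i(group_j) + gamma_b + delta_b * e_ij,
    e_ij ~ Normal(0, sigma)

where gamma_b is an additive batch shift and delta_b a multiplicative batch
scale factor on the noise (the ComBat generative model).  The MP channel is
the linear-scale mean of all subjects' noise-free abundances, perturbed by
the same batch effect; the QC channel is a replicate of that pool with
technical noise sigma_tech only.  Whole proteins drop out of whole batches
with probability ``p_batch_dropout``, reproducing the per-batch vs
in-common identification gap of multi-batch TMT.

Defaults are calibrated to the study scale: with n_proteins=8960 and
p_batch_dropout=0.05 the expected per-batch observed count is ~8,500 and
the expected five-batch-common count is ~6,900.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import AbundanceMatrix, write_abundance_table, write_annotation

#: 11-plex TMT reporter channel labels; the master pool takes the 11th.
TMT11_CHANNELS = ("126", "127N", "127C", "128N", "128C",
                  "129N", "129C", "130N", "130C", "131N", "131C")
MP_CHANNEL = "131C"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic TMT experiment.

    delta is the planted |log2 fold change| (default log2(1.5) = 0.585) and
    sigma the residual between-subject SD on the log2 scale (default 0.208,
    the in-house TMT residual the power analysis uses).  frac_de is the
    fraction of proteins carrying a planted effect; by default the effect
    is placed on the PSP group (de_group_weights), so frac_de is exactly
    the expected DE fraction for the PSP-vs-HC and PSP-vs-PD contrasts and
    the PD-vs-HC contrast is null.
    """

    n_proteins: int = 8960
    n_per_group: int = 15
    groups: tuple[str, ...] = ("PSP", "PD", "HC")
    n_batches: int = 5
    frac_de: float = 0.1
    delta: float = 0.585
    sigma: float = 0.208
    sigma_tech: float = 0.1
    batch_shift_sd: float = 0.3
    batch_scale_sd: float = 0.1
    p_batch_dropout: float = 0.05
    mu_mean: float = 16.0
    mu_sd: float = 2.0
    de_group_weights: dict[str, float] = field(default_factory=lambda: {"PSP": 1.0})
    include_qc: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must be in [0, 1]")
        if not 0.0 <= self.p_batch_dropout <= 1.0:
            raise ValueError("p_batch_dropout must be in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        n_subjects = self.n_per_group * len(self.groups)
        if n_subjects % self.n_batches != 0:
            raise ValueError(
                f"{n_subjects} subjects not evenly distributable over {self.n_batches} batches"
            )
        free = len(TMT11_CHANNELS) - 1 - (1 if self.include_qc else 0)
        if n_subjects // self.n_batches > free:
            raise ValueError(
                f"{n_subjects // self.n_batches} subjects per batch exceed the "
                f"{free} free TMT channels"
            )
        bad = set(self.de_group_weights) - set(self.groups)
        if bad:
            raise ValueError(f"de_group_weights names unknown groups: {sorted(bad)}")

    @property
    def contrasts(self) -> list[tuple[str, str]]:
        gs = list(self.groups)
        return [(gs[i], gs[j]) for i in range(len(gs)) for j in range(i + 1, len(gs))]


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated dataset.

    true_log2fc / is_de are proteins x contrasts frames (contrast columns
    named "A_vs_B"); group_effect holds the planted per-group log2 offsets;
    gamma/delta_scale are the per-batch additive shift and noise scale;
    observed marks which (protein, batch) pairs survived batch dropout.
    """

    true_log2fc: pd.DataFrame
    is_de: pd.DataFrame
    group_effect: pd.DataFrame
    gamma: np.ndarray
    delta_scale: np.ndarray
    observed: pd.DataFrame
    pooled_log2: pd.Series

    def de_accessions(self, contrast: tuple[str, str]) -> list[str]:
        col = f"{contrast[0]}_vs_{contrast[1]}"
        return list(self.is_de.index[self.is_de[col]])


def _assign_batches(config: SimulationConfig) -> pd.DataFrame:
    """Balanced subject -> batch allocation: each group is split as evenly
    as possible across batches (3+3+3 per batch in the default design)."""
    rows = []
    for g in config.groups:
        for k in range(config.n_per_group):
            rows.append({"sample_id": f"{g}{k + 1:02d}", "group": g,
                         "batch": k % config.n_batches + 1})
    return pd.DataFrame(rows)


def simulate_dataset(config: SimulationConfig) -> tuple[AbundanceMatrix, SyntheticTruth]:
    """Simulate one multi-batch TMT experiment.

    Returns the linear-scale abundance matrix (scale="raw", NaN where a
    protein dropped out of a batch) and the full ground truth.  The same
    config and seed reproduce the output bit for bit: a single RNG stream
    is consumed in a fixed order (baselines, DE flags, batch parameters,
    channel randomization, noise, dropout).
    """
    rng = np.random.default_rng(config.seed)
    n, B = config.n_proteins, config.n_batches
    accessions = pd.Index([f"P{i:05d}" for i in range(n)], name="accession")
    genes = pd.Series([f"GENE{i:05d}" for i in range(n)], index=accessions, name="gene")

    mu = rng.normal(config.mu_mean, config.mu_sd, size=n)

    # planted group effects
    effect = pd.DataFrame(0.0, index=accessions, columns=list(config.groups))
    de_flag = rng.random(n) < config.frac_de
    weights = np.array([config.de_group_weights.get(g, 0.0) for g in config.groups], float)
    if de_flag.any():
        if weights.sum() <= 0:
            raise ValueError("de_group_weights must have positive total weight when frac_de > 0")
        probs = weights / weights.sum()
        target = rng.choice(len(config.groups), size=n, p=probs)
        signs = rng.choice([-1.0, 1.0], size=n)
        for i in np.nonzero(de_flag)[0]:
            effect.iloc[i, target[i]] = signs[i] * config.delta
    else:
        # keep the stream layout identical so downstream draws line up
        rng.choice(len(config.groups), size=n, p=(weights / weights.sum()) if weights.sum() > 0 else None)
        rng.choice([-1.0, 1.0], size=n)

    gamma = rng.normal(0.0, config.batch_shift_sd, size=B) if config.batch_shift_sd > 0 else np.zeros(B)
    delta_scale = (np.exp(rng.normal(0.0, config.batch_scale_sd, size=B))
                   if config.batch_scale_sd > 0 else np.ones(B))

    subjects = _assign_batches(config)

    # randomized channel assignment within each batch (MP fixed to 131C)
    ann_rows = []
    for b in range(1, B + 1):
        members = list(subjects.loc[subjects["batch"] == b, "sample_id"])
        if config.include_qc:
            members = members + [f"QC_b{b}"]
        free_channels = [c for c in TMT11_CHANNELS if c != MP_CHANNEL]
        chans = list(rng.permutation(free_channels))[: len(members)]
        for sid, ch in zip(members, chans):
            grp = "QC" if sid.startswith("QC_") else subjects.set_index("sample_id").loc[sid, "group"]
            ann_rows.append({"sample_id": sid, "group": grp, "batch": b, "channel": ch})
        ann_rows.append({"sample_id": f"MP_b{b}", "group": "MP", "batch": b, "channel": MP_CHANNEL})
    annotation = pd.DataFrame(ann_rows)

    # noise-free subject log2 values and the pooled reference
    subj_ids = list(subjects["sample_id"])
    subj_group = subjects.set_index("sample_id")["group"]
    base = np.empty((n, len(subj_ids)))
    for j, sid in enumerate(subj_ids):
        base[:, j] = mu + effect[subj_group[sid]].to_numpy()
    pooled_lin = np.mean(2.0 ** base, axis=1)
    pooled_log2 = np.log2(pooled_lin)

    sample_ids = list(annotation["sample_id"])
    ann_idx = annotation.set_index("sample_id")
    log2x = np.empty((n, len(sample_ids)))
    col_of_subj = {sid: j for j, sid in enumerate(subj_ids)}
    for j, sid in enumerate(sample_ids):
        b = int(ann_idx.loc[sid, "batch"]) - 1
        grp = ann_idx.loc[sid, "group"]
        if grp == "MP":
            log2x[:, j] = pooled_log2 + gamma[b]
        elif grp == "QC":
            e = rng.normal(0.0, config.sigma_tech, size=n)
            log2x[:, j] = pooled_log2 + gamma[b] + delta_scale[b] * e
        else:
            e = rng.normal(0.0, config.sigma, size=n)
            log2x[:, j] = base[:, col_of_subj[sid]] + gamma[b] + delta_scale[b] * e

    values = 2.0 ** log2x

    observed = rng.random((n, B)) >= config.p_batch_dropout
    for b in range(1, B + 1):
        cols = [j for j, sid in enumerate(sample_ids) if int(ann_idx.loc[sid, "batch"]) == b]
        drop = ~observed[:, b - 1]
        values[np.ix_(drop, cols)] = np.nan

    data = pd.DataFrame(values, index=accessions, columns=sample_ids)
    matrix = AbundanceMatrix(data, annotation, genes, scale="raw")

    contrasts = config.contrasts
    fc = pd.DataFrame(index=accessions, columns=[f"{a}_vs_{b}" for a, b in contrasts], dtype=float)
    for a, b in contrasts:
        fc[f"{a}_vs_{b}"] = effect[a] - effect[b]
    truth = SyntheticTruth(
        true_log2fc=fc,
        is_de=fc != 0.0,
        group_effect=effect,
        gamma=gamma,
        delta_scale=delta_scale,
        observed=pd.DataFrame(observed, index=accessions,
                              columns=[f"batch{b}" for b in range(1, B + 1)]),
        pooled_log2=pd.Series(pooled_log2, index=accessions, name="pooled_log2"),
    )
    return matrix, truth


def export_fixture(matrix: AbundanceMatrix, truth: SyntheticTruth, out_dir,
                   overwrite: bool = False) -> None:
    """Write abundance.tsv, annotation.tsv and truth.tsv into ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    if not overwrite and any(os.scandir(out_dir)):
        raise FileExistsError(f"{out_dir} is not empty (pass overwrite=True)")
    write_abundance_table(matrix, os.path.join(out_dir, "abundance.tsv"))
    write_annotation(matrix.annotation, os.path.join(out_dir, "annotation.tsv"))
    tru = pd.concat([truth.true_log2fc.add_prefix("log2fc_"),
                     truth.is_de.add_prefix("is_de_"),
                     truth.observed], axis=1)
    tru.insert(0, "accession", tru.index)
    tru.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["groups"] = list(config.groups)
    return d
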
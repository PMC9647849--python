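"""Quality-control metrics: QC-replicate CV, signal-to-noise ratios and a
PCA-based batch-effect summary.

CV is computed on linear relative abundances (the median-ratio stage),
where SD/mean is meaningful; S/N compares between-subject to between-QC
spread on the log2 scale, where variances are stabilized.  The PCA check
quantifies how much of the 2D principal-component variance the batch
factor explains (eta^2), mirroring the usual before/after batch-correction
scatter plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import AbundanceMatrix


def qc_cv(matrix: AbundanceMatrix) -> pd.Series:
    """Coefficient of variation of the QC replicates, per protein.

    CV = SD/mean (sample SD, n-1) over the per-batch QC aliquots, computed
    on linear relative abundances.  Requires at least two QC samples.
    """
    matrix.require_scale("mp_ratio", "median_ratio")
    qc = matrix.data[matrix.qc_ids]
    if qc.shape[1] < 2:
        raise ValueError("qc_cv requires at least 2 QC samples")
    cv = qc.std(axis=1, ddof=1) / qc.mean(axis=1)
    cv.name = "cv_qc"
    return cv


def qc_sn(matrix: AbundanceMatrix, log_transform: bool = True) -> pd.Series:
    """Signal-to-noise per protein: SD(subjects) / SD(QC replicates).

    Computed on the log2 scale by default (pass a median-ratio matrix).
    A zero QC SD yields +inf, reported as such.
    """
    matrix.require_scale("mp_ratio", "median_ratio", "log2", "zscore")
    subj = matrix.data[matrix.subject_ids]
    qc = matrix.data[matrix.qc_ids]
    if subj.shape[1] < 2 or qc.shape[1] < 2:
        raise ValueError("qc_sn requires >=2 subject and >=2 QC samples")
    if log_transform and matrix.scale in ("mp_ratio", "median_ratio"):
        with np.errstate(invalid="ignore", divide="ignore"):
            subj = np.log2(subj.where(subj > 0))
            qc = np.log2(qc.where(qc > 0))
    sd_s = subj.std(axis=1, ddof=1)
    sd_q = qc.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sn = sd_s / sd_q
    sn[(sd_q == 0) & (sd_s > 0)] = np.inf
    sn.name = "sn_ratio"
    return sn


@dataclass
class PCAResult:
    """Sample scores on the first two PCs plus a batch-effect summary."""

    scores: pd.DataFrame            # sample_id -> PC1, PC2, group, batch
    variance_explained: np.ndarray  # fraction of total variance, length 2
    batch_eta2: float               # between-batch SS / total SS of PC1-2 scores


def pca_batch_check(matrix: AbundanceMatrix, subjects_only: bool = True) -> PCAResult:
    """PCA over samples (proteins as features) with a batch eta^2 summary.

    batch_eta2 is the fraction of the total PC1+PC2 score variance that
    lies between batch means — near 1 when batches form separate clusters,
    near 0 when they overlap.
    """
    ids = matrix.subject_ids if subjects_only else [s for s in matrix.data.columns]
    data = matrix.data[ids]
    if data.shape[1] < 3:
        raise ValueError("pca_batch_check requires at least 3 samples")
    if data.isna().any().any():
        raise ValueError("pca_batch_check requires a complete matrix")
    X = data.to_numpy(dtype=float).T  # samples x proteins
    if np.allclose(X.var(axis=0), 0):
        warnings.warn("all features have zero variance; PCA is degenerate")
        scores = np.zeros((X.shape[0], 2))
        var_exp = np.zeros(2)
    else:
        pca = PCA(n_components=2, svd_solver="full")
        scores = pca.fit_transform(X)
        var_exp = pca.explained_variance_ratio_
    ann = matrix.annotation.set_index("sample_id").loc[ids]
    frame = pd.DataFrame({"sample_id": ids, "PC1": scores[:, 0], "PC2": scores[:, 1],
                          "group": ann["group"].to_numpy(), "batch": ann["batch"].to_numpy()})
    total_ss = float((scores ** 2).sum())
    if total_ss == 0:
        eta2 = 0.0
    else:
        between = 0.0
        for _, sub in frame.groupby("batch"):
            m = sub[["PC1", "PC2"]].mean().to_numpy()
            between += len(sub) * float((m ** 2).sum())
        eta2 = between / total_ss
    return PCAResult(scores=frame, variance_explained=np.asarray(var_exp), batch_eta2=eta2)


@dataclass
class QCReport:
    """Per-protein QC metrics plus the headline summary fractions."""

    cv_qc: pd.Series
    sn_ratio: pd.Series
    frac_cv_below_30pct: float
    frac_sn_above_1: float
    pca: PCAResult | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.cv_qc, self.sn_ratio], axis=1)


def qc_report(matrix: AbundanceMatrix, pca: bool = False) -> QCReport:
    """Compute the full QC surface from a median-ratio-stage matrix."""
    cv = qc_cv(matrix)
    sn = qc_sn(matrix)
    pca_res = None
    if pca:
        pca_res = pca_batch_check(filter_complete(matrix))
    return QCReport(
        cv_qc=cv,
        sn_ratio=sn,
        frac_cv_below_30pct=float((cv.dropna() < 0.30).mean()),
        frac_sn_above_1=float((sn.dropna() > 1.0).mean()),
        pca=pca_res,
    )


def filter_complete(matrix: AbundanceMatrix) -> AbundanceMatrix:
    keep = ~matrix.data.isna().any(axis=1)
    return matrix.with_data(matrix.data.loc[keep])
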
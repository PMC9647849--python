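"""The normalization chain for multi-batch TMT reporter abundances.

Stages, in the only legal order (each operation asserts its input scale):

1. ``mp_normalize`` — divide every subject/QC channel by its batch's master
   pool (MP) channel, bridging batches onto a common relative scale.
2. ``median_scale`` — divide each protein row by its median relative
   abundance, centring every protein at 1.
3. ``log2_zscore`` — log2-transform, then z-score each protein row
   (sample SD, n-1).
4. ``filter_missing`` — keep only proteins quantified in every sample.
5. ``combat_correct`` — parametric empirical-Bayes location/scale batch
   correction (ComBat), optionally preserving group means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AbundanceMatrix, SUBJECT_GROUPS


def mp_normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Divide each sample's abundances by the batch's MP channel.

    MP columns are consumed (dropped from the result).  A missing or zero
    MP measurement makes the whole batch missing for that protein.
    """
    matrix.require_scale("raw")
    data = matrix.data
    out = {}
    ann = matrix.annotation.set_index("sample_id")
    mp_of_batch = {int(ann.loc[s, "batch"]): s for s in matrix.mp_ids}
    for sid in data.columns:
        grp = ann.loc[sid, "group"]
        if grp == "MP":
            continue
        mp_col = data[mp_of_batch[int(ann.loc[sid, "batch"])]]
        denom = mp_col.where(mp_col > 0)  # zero or missing MP -> NaN result
        out[sid] = data[sid] / denom
    return matrix.with_data(pd.DataFrame(out, index=data.index), scale="mp_ratio")


def median_scale(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Divide each protein row by the median of its non-missing values.

    Rows with at least one value end up with median exactly 1; all-missing
    rows pass through untouched.
    """
    matrix.require_scale("mp_ratio")
    med = matrix.data.median(axis=1, skipna=True)
    out = matrix.data.div(med, axis=0)
    all_missing = matrix.data.isna().all(axis=1)
    out.loc[all_missing] = np.nan
    return matrix.with_data(out, scale="median_ratio")


def log2_zscore(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """log2-transform, then z-score each protein row (mean 0, SD 1, n-1).

    Non-positive values cannot be log-transformed and become missing (with
    a warning); a zero-variance row z-scores to all zeros (with a warning).
    """
    matrix.require_scale("median_ratio")
    vals = matrix.data.to_numpy(copy=True)
    nonpos = np.isfinite(vals) & (vals <= 0)
    if nonpos.any():
        warnings.warn(f"{int(nonpos.sum())} non-positive value(s) set to missing before log2")
        vals[nonpos] = np.nan
    with np.errstate(invalid="ignore"):
        logv = np.log2(vals)
    mean = np.nanmean(logv, axis=1, keepdims=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(logv, axis=1, ddof=1, keepdims=True)
    zero_sd = (sd == 0).ravel() | ~np.isfinite(sd).ravel()
    z = np.where(np.isfinite(logv), (logv - mean) / np.where(sd > 0, sd, 1.0), np.nan)
    if zero_sd.any():
        warnings.warn(f"{int(zero_sd.sum())} constant row(s) z-scored to zeros")
        z[zero_sd & ~np.isnan(logv).all(axis=1)] = np.where(
            np.isfinite(logv[zero_sd & ~np.isnan(logv).all(axis=1)]), 0.0, np.nan)
    out = pd.DataFrame(z, index=matrix.data.index, columns=matrix.data.columns)
    return matrix.with_data(out, scale="zscore")


def filter_missing(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Keep exactly the proteins with no missing value in any sample.

    Row order is preserved.  Applied after the MP division, so "every
    sample" means all subjects plus the QC aliquots.
    """
    keep = ~matrix.data.isna().any(axis=1)
    return matrix.with_data(matrix.data.loc[keep], scale=matrix.scale)


@dataclass
class BatchCorrectionModel:
    """Fitted parametric empirical-Bayes batch-correction parameters.

    gamma_hat/gamma_star are per-protein x per-batch additive location
    estimates (raw and EB-shrunk); delta2_hat/delta2_star the variance
    scale estimates.  Hyperparameters are per batch: gamma_bar/t2 the
    normal prior on locations, a_prior/b_prior the inverse-gamma prior on
    variances.
    """

    gamma_hat: pd.DataFrame
    delta2_hat: pd.DataFrame
    gamma_star: pd.DataFrame
    delta2_star: pd.DataFrame
    gamma_bar: pd.Series
    t2: pd.Series
    a_prior: pd.Series
    b_prior: pd.Series
    n_iterations: pd.Series

    def to_frame(self) -> pd.DataFrame:
        parts = [self.gamma_hat.add_prefix("gamma_hat_"),
                 self.gamma_star.add_prefix("gamma_star_"),
                 self.delta2_hat.add_prefix("delta2_hat_"),
                 self.delta2_star.add_prefix("delta2_star_")]
        return pd.concat(parts, axis=1)


def _aprior(d2: np.ndarray) -> float:
    m, s2 = d2.mean(), d2.var(ddof=1)
    return (2 * s2 + m ** 2) / s2 if s2 > 0 else np.inf


def _bprior(d2: np.ndarray) -> float:
    m, s2 = d2.mean(), d2.var(ddof=1)
    return (m * s2 + m ** 3) / s2 if s2 > 0 else np.inf


def combat_correct(matrix: AbundanceMatrix, preserve_groups: bool = True,
                   tol: float = 1e-6, max_iter: int = 1000,
                   ) -> tuple[AbundanceMatrix, BatchCorrectionModel | None]:
    """Parametric empirical-Bayes location/scale batch correction (ComBat).

    Standardizes each protein with the grand model (optionally keeping
    group means in the design so biological signal is not absorbed into
    batch terms), estimates per-batch/per-protein additive shifts gamma
    and variance scales delta^2, shrinks both toward batch-level priors by
    the iterative parametric EB update, and adjusts the data.

    Operates on the subject samples only; QC columns (diagnostics) are
    excluded from estimation and dropped from the corrected output.

    Requires a complete matrix (run :func:`filter_missing` first) and at
    least two samples per batch.  A single-batch matrix is returned
    unchanged (nothing to correct).
    """
    matrix.require_scale("zscore", "log2", "median_ratio")
    subj = matrix.subject_ids
    data = matrix.data[subj]
    if data.isna().any().any():
        raise ValueError("combat_correct requires a complete matrix; run filter_missing first")
    ann = matrix.annotation.set_index("sample_id").loc[subj]
    batches = sorted(set(int(b) for b in ann["batch"]))
    if len(batches) == 1:
        return matrix.with_data(data.copy(), scale="batch_corrected"), None
    batch_idx = {b: np.flatnonzero((ann["batch"] == b).to_numpy()) for b in batches}
    for b, idx in batch_idx.items():
        if len(idx) < 2:
            raise ValueError(f"batch {b} has a single sample; batch variance inestimable")

    X = data.to_numpy(dtype=float)  # G x N
    G, N = X.shape
    n_b = np.array([len(batch_idx[b]) for b in batches])

    # design: batch one-hot plus (optionally) group dummies
    design_cols = [np.asarray((ann["batch"] == b).to_numpy(), float) for b in batches]
    if preserve_groups:
        grps = [g for g in SUBJECT_GROUPS if g in set(ann["group"])]
        for g in grps[1:]:  # drop reference level
            design_cols.append(np.asarray((ann["group"] == g).to_numpy(), float))
    D = np.column_stack(design_cols)  # N x p
    beta = np.linalg.solve(D.T @ D, D.T @ X.T)  # p x G

    nB = len(batches)
    grand_mean = (n_b / N) @ beta[:nB]  # G
    stand_mean = np.tile(grand_mean[:, None], (1, N))
    if D.shape[1] > nB:
        stand_mean = stand_mean + (D[:, nB:] @ beta[nB:]).T
    resid = X - (D @ beta).T
    var_pooled = (resid ** 2).mean(axis=1)  # G, ddof 0 as in the reference EB algorithm
    ok = var_pooled > 0
    sd = np.sqrt(np.where(ok, var_pooled, 1.0))
    Z = (X - stand_mean) / sd[:, None]

    gamma_hat = np.column_stack([Z[:, batch_idx[b]].mean(axis=1) for b in batches])
    delta2_hat = np.column_stack([Z[:, batch_idx[b]].var(axis=1, ddof=1) for b in batches])

    gamma_bar = gamma_hat.mean(axis=0)
    t2 = gamma_hat.var(axis=0, ddof=1)
    a_pr = np.array([_aprior(delta2_hat[:, k]) for k in range(nB)])
    b_pr = np.array([_bprior(delta2_hat[:, k]) for k in range(nB)])

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    iters = np.zeros(nB, int)
    for k, b in enumerate(batches):
        n = n_b[k]
        g_old = gamma_hat[:, k].copy()
        d_old = delta2_hat[:, k].copy()
        Zb = Z[:, batch_idx[b]]
        for it in range(max_iter):
            g_new = (n * t2[k] * gamma_hat[:, k] + d_old * gamma_bar[k]) / (n * t2[k] + d_old)
            sum2 = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sum2 + b_pr[k]) / (n / 2.0 + a_pr[k] - 1.0)
            change = max(np.max(np.abs(g_new - g_old)), np.max(np.abs(d_new - d_old)))
            g_old, d_old = g_new, d_new
            if change < tol:
                break
        iters[k] = it + 1
        gamma_star[:, k] = g_old
        delta2_star[:, k] = d_old

    Z_adj = Z.copy()
    for k, b in enumerate(batches):
        idx = batch_idx[b]
        Z_adj[:, idx] = (Z[:, idx] - gamma_star[:, k][:, None]) / np.sqrt(delta2_star[:, k])[:, None]
    X_corr = Z_adj * sd[:, None] + stand_mean
    X_corr[~ok] = X[~ok]  # zero-variance proteins pass through

    out = pd.DataFrame(X_corr, index=data.index, columns=data.columns)
    cols = [f"batch{b}" for b in batches]
    model = BatchCorrectionModel(
        gamma_hat=pd.DataFrame(gamma_hat, index=data.index, columns=cols),
        delta2_hat=pd.DataFrame(delta2_hat, index=data.index, columns=cols),
        gamma_star=pd.DataFrame(gamma_star, index=data.index, columns=cols),
        delta2_star=pd.DataFrame(delta2_star, index=data.index, columns=cols),
        gamma_bar=pd.Series(gamma_bar, index=cols),
        t2=pd.Series(t2, index=cols),
        a_prior=pd.Series(a_pr, index=cols),
        b_prior=pd.Series(b_pr, index=cols),
        n_iterations=pd.Series(iters, index=cols),
    )
    return matrix.with_data(out, scale="batch_corrected"), model


def normalize_pipeline(matrix: AbundanceMatrix, preserve_groups: bool = True,
                       ) -> dict[str, AbundanceMatrix]:
    """Run the full chain and return every intermediate stage by name."""
    stages: dict[str, AbundanceMatrix] = {}
    stages["mp_ratio"] = mp_normalize(matrix)
    stages["median_ratio"] = median_scale(stages["mp_ratio"])
    stages["zscore"] = log2_zscore(stages["median_ratio"])
    stages["filtered"] = filter_missing(stages["zscore"])
    corrected, model = combat_correct(stages["filtered"], preserve_groups=preserve_groups)
    stages["batch_corrected"] = corrected
    stages["combat_model"] = model  # type: ignore[assignment]
    return stages
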
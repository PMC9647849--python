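"""Bootstrap-ROC differential abundance: per-protein Mann-Whitney AUC,
bootstrap mean/SD of the AUC, and a permuted-label count-ratio q-value.

The AUC is the probability that a random group-A value exceeds a random
group-B value (ties counted half — the midrank convention), so
auc(A, B) + auc(B, A) = 1 exactly.  Bootstrapping resamples each group
with replacement (stratified, preserving group sizes) and summarizes the
AUC sampling distribution by its mean and SD.  The q-value compares, at
each AUC threshold swept from the extremes toward 0.5, the number of
permuted-label proteins beyond the threshold to the number of observed
proteins beyond it (N_null / N_obs, clipped to [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import AbundanceMatrix


@dataclass
class BrocConfig:
    n_bootstrap: int = 1000
    n_permutation_passes: int = 1
    q_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.n_permutation_passes < 1:
            raise ValueError("n_permutation_passes must be >= 1")
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must be in (0, 1)")


def auc(values_a, values_b) -> float:
    """Mann-Whitney AUC of A vs B with midrank tie handling."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("auc requires both groups non-empty")
    ranks = rankdata(np.concatenate([a, b]))
    ra = ranks[: a.size].sum()
    return float((ra - a.size * (a.size + 1) / 2.0) / (a.size * b.size))


def _auc_matrix(X: np.ndarray, na: int) -> np.ndarray:
    """Row-wise AUC of columns [:na] vs [na:] for a proteins x samples block."""
    nb = X.shape[1] - na
    ranks = rankdata(X, axis=1)
    ra = ranks[:, :na].sum(axis=1)
    return (ra - na * (na + 1) / 2.0) / (na * nb)


def bootstrap_auc(values_a, values_b, config: BrocConfig) -> tuple[float, float]:
    """Bootstrap mean and SD of the AUC for one protein.

    Each group is resampled with replacement independently (stratified)
    ``n_bootstrap`` times; returns (mean, SD) of the resampled AUCs.
    Deterministic given the config seed.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("bootstrap_auc requires groups of size >= 2")
    rng = np.random.default_rng(config.seed)
    ia = rng.integers(0, a.size, size=(config.n_bootstrap, a.size))
    ib = rng.integers(0, b.size, size=(config.n_bootstrap, b.size))
    X = np.concatenate([a[ia], b[ib]], axis=1)
    aucs = _auc_matrix(X, a.size)
    return float(aucs.mean()), float(aucs.std(ddof=1)) if config.n_bootstrap > 1 else 0.0


def _bootstrap_auc_all(X: np.ndarray, na: int, n_bootstrap: int,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap AUC mean/SD for every protein row of X (columns [:na] = A).

    Resample column indices are drawn once per bootstrap replicate and
    shared across proteins; each protein's marginal bootstrap distribution
    is unchanged and the sweep is one ranking per replicate.
    """
    G = X.shape[0]
    nb = X.shape[1] - na
    sums = np.zeros(G)
    sq = np.zeros(G)
    for _ in range(n_bootstrap):
        ia = rng.integers(0, na, size=na)
        ib = na + rng.integers(0, nb, size=nb)
        Xb = X[:, np.concatenate([ia, ib])]
        a = _auc_matrix(Xb, na)
        sums += a
        sq += a * a
    mean = sums / n_bootstrap
    if n_bootstrap > 1:
        var = (sq - n_bootstrap * mean ** 2) / (n_bootstrap - 1)
        sd = np.sqrt(np.clip(var, 0.0, None))
    else:
        sd = np.zeros(G)
    return mean, sd


def _count_ratio_q(obs: np.ndarray, null: np.ndarray, n_passes: int) -> np.ndarray:
    """q-values for one side (values already oriented so larger = more extreme).

    obs/null hold distances above 0.5 (or below, negated).  At each
    observed threshold, q = (null count beyond / n_passes) / (obs count
    beyond), clipped to [0, 1], then made monotone by suffix minimum so a
    protein's q is the best ratio among thresholds it passes.
    """
    order = np.argsort(-obs, kind="stable")
    thr = obs[order]
    null_sorted = np.sort(null)
    n_obs = len(obs) - np.searchsorted(np.sort(obs), thr, side="left")
    n_null = len(null) - np.searchsorted(null_sorted, thr, side="left")
    ratio = np.clip((n_null / n_passes) / n_obs, 0.0, 1.0)
    q_sorted = np.minimum.accumulate(ratio[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def broc_qvalues(matrix: AbundanceMatrix, contrast: tuple[str, str],
                 config: BrocConfig) -> pd.DataFrame:
    """Bootstrap-ROC q-values for one contrast.

    Returns a per-protein frame with auc_mean, auc_sd, q_broc and sig_broc.
    The null arm repeats the identical bootstrap procedure after permuting
    the pooled group labels (``n_permutation_passes`` independent shuffles,
    counts averaged).  Proteins with auc_mean exactly 0.5 get q = 1.
    """
    matrix.require_scale("log2", "zscore", "batch_corrected")
    a_ids = matrix.sample_ids((contrast[0],))
    b_ids = matrix.sample_ids((contrast[1],))
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError(f"contrast {contrast} needs >=2 samples per group")
    na = len(a_ids)
    X = matrix.data[a_ids + b_ids].to_numpy(dtype=float)
    rng = np.random.default_rng(config.seed)

    obs_mean, obs_sd = _bootstrap_auc_all(X, na, config.n_bootstrap, rng)

    null_means = []
    for _ in range(config.n_permutation_passes):
        perm = rng.permutation(X.shape[1])
        m, _ = _bootstrap_auc_all(X[:, perm], na, config.n_bootstrap, rng)
        null_means.append(m)
    null_mean = np.concatenate(null_means)

    q = np.ones(X.shape[0])
    up = obs_mean > 0.5
    down = obs_mean < 0.5
    if up.any():
        q[up] = _count_ratio_q(obs_mean[up] - 0.5,
                               np.clip(null_mean - 0.5, 0.0, None)[null_mean > 0.5],
                               config.n_permutation_passes)
    if down.any():
        q[down] = _count_ratio_q(0.5 - obs_mean[down],
                                 np.clip(0.5 - null_mean, 0.0, None)[null_mean < 0.5],
                                 config.n_permutation_passes)

    out = pd.DataFrame({
        "auc_mean": obs_mean,
        "auc_sd": obs_sd,
        "q_broc": q,
        "sig_broc": q < config.q_threshold,
    }, index=matrix.data.index)
    return out


def broc_plot_export(results: pd.DataFrame, config: BrocConfig) -> pd.DataFrame:
    """Plot-ready per-protein table: auc_mean with +-SD whiskers and the
    q-threshold band (proteins outside the band are the q < threshold calls)."""
    sig = results[results["sig_broc"]]
    upper = float(sig.loc[sig["auc_mean"] > 0.5, "auc_mean"].min()) if (sig["auc_mean"] > 0.5).any() else np.nan
    lower = float(sig.loc[sig["auc_mean"] < 0.5, "auc_mean"].max()) if (sig["auc_mean"] < 0.5).any() else np.nan
    out = results.copy()
    out["auc_lo"] = out["auc_mean"] - out["auc_sd"]
    out["auc_hi"] = out["auc_mean"] + out["auc_sd"]
    out.attrs["threshold_upper"] = upper
    out.attrs["threshold_lower"] = lower
    return out
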
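"""SAM-style differential expression: moderated d-statistic with a fudge
factor s0 and a permutation-based FDR, plus the curved volcano boundary.

The d-score is d = (mean_A - mean_B) / (se_pooled + s0), the pooled-SE
two-sample t statistic with s0 added to the denominator to stabilize
low-variance proteins (s0 = 0 recovers Student's t exactly).  The FDR at a
|d| threshold is the median, over random relabelings of the pooled
samples, of the number of permuted |d*| beyond the threshold, divided by
the observed count beyond it; a protein's q-value is the smallest FDR over
thresholds it passes, which makes q monotone non-increasing in |d|.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AbundanceMatrix


@dataclass
class SamConfig:
    s0: float = 0.1
    n_permutations: int = 250
    q_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError("s0 must be >= 0")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must be in (0, 1)")


def _group_arrays(matrix: AbundanceMatrix, contrast: tuple[str, str]) -> tuple[np.ndarray, int, int]:
    a_ids = matrix.sample_ids((contrast[0],))
    b_ids = matrix.sample_ids((contrast[1],))
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError(f"contrast {contrast} needs >=2 samples per group")
    X = matrix.data[a_ids + b_ids].to_numpy(dtype=float)
    return X, len(a_ids), len(b_ids)


def _diff_se(X: np.ndarray, in_a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row mean difference and pooled standard error for a 0/1 split."""
    A, B = X[:, in_a], X[:, ~in_a]
    na, nb = A.shape[1], B.shape[1]
    diff = A.mean(axis=1) - B.mean(axis=1)
    ss = A.var(axis=1, ddof=1) * (na - 1) + B.var(axis=1, ddof=1) * (nb - 1)
    sp2 = ss / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return diff, se


def ttest_fc(matrix: AbundanceMatrix, contrast: tuple[str, str]) -> pd.DataFrame:
    """Student's pooled-variance two-sample t-test with log2 fold change.

    log2fc = mean_A - mean_B on the (log2-consistent) working scale.
    Proteins with zero pooled variance get t = 0, p = 1 with a warning.
    """
    matrix.require_scale("log2", "zscore", "batch_corrected")
    X, na, nb = _group_arrays(matrix, contrast)
    in_a = np.zeros(na + nb, bool)
    in_a[:na] = True
    diff, se = _diff_se(X, in_a)
    zero = se == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} protein(s) with zero pooled variance: t=0, p=1")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, 0.0, diff / np.where(zero, 1.0, se))
    df = na + nb - 2
    p = np.where(zero, 1.0, 2.0 * stats.t.sf(np.abs(t), df))
    return pd.DataFrame({"log2fc": diff, "tstat": t, "pvalue": p}, index=matrix.data.index)


def sam_statistic(diff: np.ndarray, se: np.ndarray, s0: float) -> np.ndarray:
    """SAM d-score: mean difference over (pooled SE + s0)."""
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    denom = se + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
    return d


def _distinct_relabelings(n_total: int, na: int) -> int:
    return math.comb(n_total, na)


def _permutation_masks(na: int, nb: int, n_permutations: int,
                       rng: np.random.Generator) -> np.ndarray:
    """0/1 masks (n_perm x n) marking group-A membership per relabeling.

    If more permutations are requested than distinct relabelings exist, all
    distinct ones are enumerated instead (with a warning).
    """
    n = na + nb
    distinct = _distinct_relabelings(n, na)
    if n_permutations >= distinct:
        warnings.warn(
            f"{n_permutations} permutations requested but only {distinct} distinct "
            "relabelings exist; enumerating all of them")
        masks = np.zeros((distinct, n), bool)
        for i, comb in enumerate(itertools.combinations(range(n), na)):
            masks[i, list(comb)] = True
        return masks
    masks = np.zeros((n_permutations, n), bool)
    for i in range(n_permutations):
        perm = rng.permutation(n)
        masks[i, perm[:na]] = True
    return masks


def _counts_beyond(sorted_abs_asc: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """count of values >= each threshold, given values sorted ascending."""
    return len(sorted_abs_asc) - np.searchsorted(sorted_abs_asc, thresholds, side="left")


def sam_qvalues(matrix: AbundanceMatrix, contrast: tuple[str, str],
                config: SamConfig) -> pd.DataFrame:
    """Permutation-FDR q-values for the SAM d-statistic.

    Returns a per-protein frame with columns log2fc, tstat, pvalue, dstat,
    q_sam and sig_sam (q_sam < q_threshold).  Deterministic given the
    config seed.
    """
    matrix.require_scale("log2", "zscore", "batch_corrected")
    res = ttest_fc(matrix, contrast)
    X, na, nb = _group_arrays(matrix, contrast)
    in_a = np.zeros(na + nb, bool)
    in_a[:na] = True
    diff, se = _diff_se(X, in_a)
    d_obs = sam_statistic(diff, se, config.s0)

    rng = np.random.default_rng(config.seed)
    masks = _permutation_masks(na, nb, config.n_permutations, rng)

    abs_obs = np.abs(d_obs)
    order = np.argsort(-abs_obs, kind="stable")  # descending |d|
    thr = abs_obs[order]
    sorted_asc = np.sort(abs_obs)
    n_obs_at = _counts_beyond(sorted_asc, thr)

    perm_counts = np.empty((len(masks), len(thr)))
    for i, mask in enumerate(masks):
        pdiff, pse = _diff_se(X, mask)
        d_perm = np.abs(sam_statistic(pdiff, pse, config.s0))
        perm_counts[i] = _counts_beyond(np.sort(d_perm), thr)
    med_null = np.median(perm_counts, axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.clip(med_null / n_obs_at, 0.0, 1.0)
    # q at rank r = min FDR over thresholds at or below this protein's |d|
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    # ties in |d| must share the same q
    if len(thr) > 1:
        tie_frame = pd.Series(q, index=abs_obs).groupby(level=0).min()
        q = tie_frame.loc[abs_obs].to_numpy()

    out = res.copy()
    out["dstat"] = d_obs
    out["q_sam"] = q
    out["sig_sam"] = q < config.q_threshold
    return out


def volcano_boundary(results: pd.DataFrame, config: SamConfig,
                     n_points: int = 200) -> pd.DataFrame:
    """The curved (log2fc, -log10 p) locus separating q < threshold calls.

    d_crit is the smallest |d| among significant proteins; points on the
    boundary satisfy |log2fc| / (se + s0) = d_crit, traced over a grid of
    fold changes with p derived from the implied t statistic.  Returns an
    empty frame when nothing is significant.
    """
    sig = results[results["q_sam"] < config.q_threshold]
    if sig.empty:
        return pd.DataFrame(columns=["log2fc", "neg_log10_p", "side"])
    d_crit = float(np.abs(sig["dstat"]).min())
    # recover per-protein df from t and p of any non-degenerate row is not
    # needed: the boundary is parametric in se
    fc_max = float(np.abs(results["log2fc"]).max()) * 1.05
    fc_min = d_crit * config.s0 * 1.0001 if config.s0 > 0 else 1e-6
    rows = []
    for fc in np.linspace(max(fc_min, 1e-6), max(fc_max, fc_min * 2), n_points):
        se = fc / d_crit - config.s0
        if se <= 0:
            continue
        t = fc / se
        p = 2.0 * stats.t.sf(t, _infer_df(results))
        if p <= 0:
            continue
        rows.append({"log2fc": fc, "neg_log10_p": -math.log10(p), "side": "up"})
        rows.append({"log2fc": -fc, "neg_log10_p": -math.log10(p), "side": "down"})
    return pd.DataFrame(rows)


def _infer_df(results: pd.DataFrame) -> float:
    """Degrees of freedom consistent with the table's t and p columns."""
    ok = results[(results["tstat"] != 0) & (results["pvalue"] < 1)]
    if ok.empty:
        return 1.0
    row = ok.iloc[0]
    t, p = abs(float(row["tstat"])), float(row["pvalue"])
    grid = np.arange(1, 1001)
    err = np.abs(2.0 * stats.t.sf(t, grid) - p)
    return float(grid[int(np.argmin(err))])
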
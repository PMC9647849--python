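"""Consensus DE selection and gene-set overrepresentation.

The consensus rule intersects the SAM and bootstrap-ROC calls (a protein
is consensus-significant only when both tests call it), trading power for
robustness to either method's false positives.  Overrepresentation tests
each gene set against the DE list with a one-sided Fisher exact test on
the 2x2 table (DE-in-set, DE-not-in-set, set-not-DE, rest), with DAVID's
conservative EASE variant (overlap decremented by one) available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection


@dataclass
class VennCounts:
    sam_only: int
    both: int
    broc_only: int

    @property
    def union(self) -> int:
        return self.sam_only + self.both + self.broc_only


def consensus_select(sam_results: pd.DataFrame, broc_results: pd.DataFrame,
                     q_threshold: float = 0.05) -> tuple[pd.DataFrame, VennCounts]:
    """Intersect SAM and bootstrap-ROC significance over a shared universe.

    Returns the merged per-protein table with sig_sam, sig_broc and
    sig_consensus = sig_sam AND sig_broc, plus the Venn counts
    (SAM-only, both, bROC-only).  The two tables must cover exactly the
    same proteins.
    """
    sam_idx, broc_idx = set(sam_results.index), set(broc_results.index)
    if sam_idx != broc_idx:
        diff = sorted(sam_idx ^ broc_idx)
        raise ValueError(f"protein universes differ; symmetric difference: {diff[:20]}"
                         + ("..." if len(diff) > 20 else ""))
    merged = sam_results.join(broc_results, how="inner")
    merged["sig_sam"] = merged["q_sam"] < q_threshold
    merged["sig_broc"] = merged["q_broc"] < q_threshold
    merged["sig_consensus"] = merged["sig_sam"] & merged["sig_broc"]
    counts = VennCounts(
        sam_only=int((merged["sig_sam"] & ~merged["sig_broc"]).sum()),
        both=int(merged["sig_consensus"].sum()),
        broc_only=int((merged["sig_broc"] & ~merged["sig_sam"]).sum()),
    )
    return merged, counts


def enrich(de_genes, collection: GeneSetCollection, ease: bool = False,
           bh_correct: bool = False) -> pd.DataFrame:
    """Overrepresentation of ``de_genes`` in each set of the collection.

    Per term: Count (DE genes in the set), PH (set genes present in the
    universe), percent = 100*Count/PH, a one-sided Fisher exact p-value
    (hypergeometric upper tail), and the fold enrichment
    (Count/n_DE)/(PH/N_universe).  Rows are sorted by p ascending.  With
    ``ease=True`` the overlap is decremented by one before testing
    (DAVID's EASE score).  ``bh_correct`` adds a Benjamini-Hochberg
    adjusted column; raw p-values are reported either way.
    """
    if collection.universe is None:
        raise ValueError("collection has no background universe; call with_universe first")
    universe = set(collection.universe)
    de = {g.upper() for g in de_genes}
    outside = de - universe
    if outside:
        warnings.warn(f"{len(outside)} DE gene(s) not in the universe were dropped")
        de &= universe
    if not universe or not de:
        warnings.warn("empty universe or empty DE list; returning empty table")
        return pd.DataFrame(columns=["term", "description", "count", "ph",
                                     "percent", "pvalue", "fold_enrichment"])
    N, n_de = len(universe), len(de)
    rows = []
    for term, (desc, genes) in collection.sets.items():
        in_univ = genes & universe
        ph = len(in_univ)
        if ph == 0:
            continue
        count = len(de & in_univ)
        k = max(count - 1, 0) if ease else count
        # P(X >= k) under Hypergeom(N, ph, n_de)
        p = float(stats.hypergeom.sf(k - 1, N, ph, n_de)) if k > 0 else 1.0
        fe = (count / n_de) / (ph / N) if count else 0.0
        rows.append({"term": term, "description": desc, "count": count, "ph": ph,
                     "percent": round(100.0 * count / ph, 1), "pvalue": p,
                     "fold_enrichment": fe})
    out = pd.DataFrame(rows).sort_values("pvalue", kind="stable").reset_index(drop=True)
    if bh_correct and not out.empty:
        out["pvalue_bh"] = _benjamini_hochberg(out["pvalue"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out
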
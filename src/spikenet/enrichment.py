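"""Hypergeometric enrichment/depletion of gene sets within modules.

Used for TF-family composition of co-expression modules, spike-dominant
gene enrichment, and QTL-proximal gene sets.  Tails are exact sums of
the hypergeometric pmf: over-representation is the inclusive upper tail
P(X >= k), depletion the inclusive lower tail P(X <= k).  Module/family
scans flag raw P below alpha (default 0.01) without multiple-testing
correction, with an optional Benjamini-Hochberg switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .de import benjamini_hochberg
from .network import ModulePartition

__all__ = ["EnrichmentResult", "hypergeom_enrichment", "module_family_scan"]


@dataclass
class EnrichmentResult:
    """Exact hypergeometric enrichment of a category within a sample.

    N genes in the universe, K of them in the category; the sample of n
    genes contains k category members.  fold = (k/n) / (K/N).
    """

    N: int
    K: int
    n: int
    k: int
    fold: float
    p_over: float
    p_under: float


def hypergeom_enrichment(sample, category, universe) -> EnrichmentResult:
    """Exact enrichment/depletion of ``category`` genes within ``sample``.

    Both sets are intersected with the universe before counting, and the
    sample/category must be subsets of it.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    sample = set(sample)
    category = set(category)
    if not sample:
        raise ValueError("empty sample")
    if not sample <= universe:
        raise ValueError("sample is not a subset of the universe")
    if not category <= universe:
        raise ValueError("category is not a subset of the universe")
    N, K, n = len(universe), len(category), len(sample)
    k = len(sample & category)
    fold = (k / n) / (K / N) if K > 0 else 0.0
    p_over = float(stats.hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
    p_under = float(stats.hypergeom.cdf(k, N, K, n))  # P(X <= k)
    return EnrichmentResult(N, K, n, k, fold, min(p_over, 1.0), min(p_under, 1.0))


def module_family_scan(
    partition: ModulePartition,
    family_table: pd.Series,
    universe=None,
    alpha: float = 0.01,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Enrichment/depletion of every (module, TF family) combination.

    ``family_table`` maps gene id -> family label (NA for non-TF genes).
    The universe defaults to the genes entering the network (the
    partition's gene set).  Flags: ``enriched`` where p_over < alpha,
    ``depleted`` where p_under < alpha (raw P by default).
    """
    if universe is None:
        universe = set(partition.gene_ids)
    else:
        universe = set(universe)
    fam = family_table.dropna()
    fam = fam[fam.index.isin(universe)]
    rows = []
    for m in partition.module_ids:
        members = set(partition.members(m)) & universe
        if not members:
            continue
        for family in sorted(fam.unique()):
            cat = set(fam.index[fam == family])
            r = hypergeom_enrichment(members, cat, universe)
            rows.append(
                {"module": m, "family": family, "N": r.N, "K": r.K, "n": r.n, "k": r.k,
                 "fold": r.fold, "p_over": r.p_over, "p_under": r.p_under}
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    if bh_correct:
        out["p_over_adj"] = benjamini_hochberg(out["p_over"].to_numpy())
        out["p_under_adj"] = benjamini_hochberg(out["p_under"].to_numpy())
        out["enriched"] = out["p_over_adj"] < alpha
        out["depleted"] = out["p_under_adj"] < alpha
    else:
        out["enriched"] = out["p_over"] < alpha
        out["depleted"] = out["p_under"] < alpha
    return out
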
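"""Homoeolog-pair concordance and QTL-window proximity analyses.

In tetraploid wheat each gene typically has a counterpart on the other
subgenome (an A/B homoeolog pair).  Pairs whose members fall in the same
co-expression module, or in distinct modules whose eigengenes are highly
correlated, are 'co-clustered'; the remainder are divergent and may mark
regulatory variation in one homoeolog.  Per-stage paired t-tests compare
the two profiles replicate-by-replicate.  QTL proximity flags expressed
genes within a fixed window (default 500 kbp) of mapped yield-component
loci.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneAnnotation
from .network import ModulePartition

__all__ = ["classify_pairs", "paired_t_by_stage", "qtl_proximity", "star_bin"]

CLASSES = ("same_module", "similar_profile", "divergent")

_STARS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def star_bin(p: float) -> str:
    """Significance stars: < 0.05 (*), 0.01 (**), 0.001 (***), 0.0001 (****)."""
    if np.isnan(p):
        return "NA"
    for thr, stars in _STARS:
        if p < thr:
            return stars
    return ""


def classify_pairs(
    pairs: pd.DataFrame,
    partition: ModulePartition,
    expr: pd.DataFrame | None = None,
    similarity_threshold: float = 0.8,
) -> pd.DataFrame:
    """Classify homoeolog pairs as same_module / similar_profile / divergent.

    ``pairs`` needs columns gene_a, gene_b.  same_module requires equal
    nonzero module labels; similar_profile requires different modules
    with eigengene Pearson correlation >= ``similarity_threshold``.  A
    pair with both genes unassigned is classified by the correlation of
    the genes' own profiles against the same threshold (grey genes have
    no eigengene); a pair with exactly one unassigned gene falls back to
    the same gene-profile rule.  Pairs with a gene missing from the
    partition are dropped (recorded via the returned frame's attrs).
    """
    labels = partition.labels
    eig = partition.eigengenes
    rows = []
    dropped = []
    for _, row in pairs.iterrows():
        a, b = row["gene_a"], row["gene_b"]
        if a not in labels.index or b not in labels.index:
            dropped.append((a, b))
            continue
        ma, mb = int(labels[a]), int(labels[b])
        if ma == mb and ma != 0:
            cls, cor = "same_module", 1.0
        else:
            cor = np.nan
            if ma != 0 and mb != 0 and eig is not None and ma in eig.index and mb in eig.index:
                cor = float(np.corrcoef(eig.loc[ma], eig.loc[mb])[0, 1])
            elif expr is not None and a in expr.index and b in expr.index:
                xa, xb = expr.loc[a].to_numpy(float), expr.loc[b].to_numpy(float)
                if xa.std() > 0 and xb.std() > 0:
                    cor = float(np.corrcoef(xa, xb)[0, 1])
            cls = "similar_profile" if (not np.isnan(cor) and cor >= similarity_threshold) else "divergent"
        rows.append({"gene_a": a, "gene_b": b, "module_a": ma, "module_b": mb,
                     "profile_cor": cor, "class": cls,
                     "co_clustered": cls in ("same_module", "similar_profile")})
    out = pd.DataFrame(rows, columns=["gene_a", "gene_b", "module_a", "module_b",
                                      "profile_cor", "class", "co_clustered"])
    out.attrs["dropped_pairs"] = dropped
    return out


def paired_t_by_stage(expr_a, expr_b, design) -> pd.DataFrame:
    """Two-sided paired t-test of two genes' expression at each stage.

    Values are paired by replicate index within a stage; replicate
    counts must match.  Zero variance of the paired differences leaves p
    undefined (NA with a flag).
    """
    expr_a = np.asarray(expr_a, dtype=float)
    expr_b = np.asarray(expr_b, dtype=float)
    if expr_a.shape != expr_b.shape:
        raise ValueError("profiles must have matching shapes")
    rows = []
    pos = 0
    for stage in design.stages:
        n = design.replicates[stage]
        if n < 2:
            raise ValueError(f"stage {stage!r} needs >= 2 replicates for a paired test")
        xa, xb = expr_a[pos : pos + n], expr_b[pos : pos + n]
        pos += n
        diff = xa - xb
        if diff.std(ddof=1) == 0.0:  # exactly constant differences only
            t, p, degenerate = np.nan, np.nan, True
        else:
            res = stats.ttest_rel(xa, xb)
            t, p, degenerate = float(res.statistic), float(res.pvalue), False
        rows.append({"stage": stage, "t": t, "p_value": p, "stars": star_bin(p), "degenerate": degenerate})
    return pd.DataFrame(rows).set_index("stage")


def qtl_proximity(annotation: GeneAnnotation, loci: pd.DataFrame, window_kbp: float = 500.0,
                  interval_mode: bool = False) -> pd.DataFrame:
    """Gene-locus hits within ``window_kbp`` of each QTL position.

    ``loci`` needs columns chromosome, position (1-based bp) and
    optionally trait; BED-like interval input (chromosome, start, end)
    is reduced to the interval midpoint unless ``interval_mode`` is set,
    in which case distance is measured between the locus interval and
    the gene span.  A hit requires the same chromosome and a nearest-edge
    distance <= window_kbp * 1000, boundary inclusive; a position inside
    the gene span scores distance 0.
    """
    loci = loci.copy()
    if "position" not in loci.columns:
        if not {"start", "end"} <= set(loci.columns):
            raise ValueError("loci need a position column or start/end columns")
        if not interval_mode:
            loci["position"] = ((loci["start"] + loci["end"]) // 2).astype(int)
    window = float(window_kbp) * 1000.0
    genes = annotation.table
    rows = []
    for li, locus in loci.iterrows():
        chrom = locus["chromosome"]
        g = genes[genes["chromosome"] == chrom]
        if g.empty:
            continue
        gs = g["start"].to_numpy(float)
        ge = g["end"].to_numpy(float)
        if interval_mode and "start" in loci.columns:
            ls, le = float(locus["start"]), float(locus["end"])
            dist = np.maximum(0.0, np.maximum(gs - le, ls - ge))
        else:
            pos = float(locus["position"])
            dist = np.where(pos < gs, gs - pos, np.where(pos > ge, pos - ge, 0.0))
        hit = dist <= window
        for gene, d in zip(g.index[hit], dist[hit]):
            rows.append({"gene_id": gene, "locus": li, "trait": locus.get("trait", "other"),
                         "chromosome": chrom, "distance_bp": float(d)})
    return pd.DataFrame(rows, columns=["gene_id", "locus", "trait", "chromosome", "distance_bp"])
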
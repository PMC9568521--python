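"""Differential-expression selection for the spike time course.

Three routes into the network gene set:

* a consensus rule intersecting two externally produced pairwise DE tables
  (genes called at FDR <= 0.01 by *both* tools are pairwise DEGs);
* a built-in Welch t-test on log1p-TPM as a self-contained stand-in for
  those external tools when running on synthetic data (it does not emulate
  either count-based package);
* a longitudinal impulse-model likelihood-ratio test (FDR <= 0.05) that
  screens for genes with a temporal signal across the whole course.

PCA utilities summarise sample structure (percent variance explained per
component).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, StageDesign, stage_means

__all__ = [
    "DEResultTable",
    "ImpulseFit",
    "PcaResult",
    "benjamini_hochberg",
    "consensus_degs",
    "welch_pairwise",
    "impulse_profile",
    "fit_impulse_test",
    "impulse_screen",
    "pairwise_summary",
    "pca",
]


@dataclass
class DEResultTable:
    """One pairwise DE result per gene: logFC, p, BH-adjusted FDR.

    ``direction`` derives from the sign of the log fold change.  When the
    input lacks an ``fdr`` column it is filled by Benjamini-Hochberg from
    the p-values.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.name != "gene_id":
            if "gene_id" in t.columns:
                t = t.set_index("gene_id")
            else:
                raise ValueError("DE table needs a gene_id column or index")
        if t.index.duplicated().any():
            raise ValueError("DE table has more than one row for a gene")
        for col in ("log_fold_change", "p_value"):
            if col not in t.columns:
                raise ValueError(f"DE table missing column {col!r}")
        if "fdr" not in t.columns:
            t = t.assign(fdr=benjamini_hochberg(t["p_value"].to_numpy()))
        t = t.assign(direction=np.where(t["log_fold_change"] >= 0, "up", "down"))
        self.table = t

    def significant(self, alpha: float) -> pd.DataFrame:
        return self.table[self.table["fdr"] <= alpha]


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def consensus_degs(table_a: DEResultTable, table_b: DEResultTable, alpha: float = 0.01) -> pd.DataFrame:
    """Genes called DE at ``fdr <= alpha`` by both tables.

    Returns a frame indexed by gene with the direction from ``table_a``
    and a ``conflict`` flag where the two tables disagree on sign.  Genes
    present in only one table are excluded (they cannot be confirmed by
    both tools), never an error.
    """
    a = table_a.significant(alpha)
    b = table_b.significant(alpha)
    shared = a.index.intersection(b.index)
    out = pd.DataFrame(
        {
            "direction": a.loc[shared, "direction"],
            "conflict": a.loc[shared, "direction"].to_numpy() != b.loc[shared, "direction"].to_numpy(),
            "fdr_a": a.loc[shared, "fdr"],
            "fdr_b": b.loc[shared, "fdr"],
        }
    )
    out.index.name = "gene_id"
    return out.sort_index()


def welch_pairwise(em: ExpressionMatrix, stage_a: str, stage_b: str) -> DEResultTable:
    """Simple built-in pairwise test: Welch t on log1p values, stage B vs A.

    A deliberately plain stand-in used to drive the consensus rule on
    synthetic data; it is not a negative-binomial count model.
    """
    meta = em.sample_meta
    xa = np.log1p(em.values.loc[:, meta.index[meta["stage"] == stage_a]].to_numpy(float))
    xb = np.log1p(em.values.loc[:, meta.index[meta["stage"] == stage_b]].to_numpy(float))
    if xa.shape[1] < 2 or xb.shape[1] < 2:
        raise ValueError("Welch test needs >= 2 replicates per stage")
    res = stats.ttest_ind(xb, xa, axis=1, equal_var=False)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    lfc = (xb.mean(axis=1) - xa.mean(axis=1)) / math.log(2)
    return DEResultTable(pd.DataFrame({"log_fold_change": lfc, "p_value": p}, index=em.values.index.rename("gene_id")))


# ---------------------------------------------------------------------------
# impulse model


def impulse_profile(t, h0: float, h1: float, h2: float, t1: float, t2: float, beta: float):
    """Double-sigmoid impulse: onset toward h1 at t1, decay toward h2 at t2.

    f(t) = (1/h1) * [h0 + (h1-h0)*sigma(beta (t-t1))]
                  * [h2 + (h1-h2)*sigma(-beta (t-t2))]
    """
    t = np.asarray(t, dtype=float)
    s1 = 1.0 / (1.0 + np.exp(-beta * (t - t1)))
    s2 = 1.0 / (1.0 + np.exp(beta * (t - t2)))
    return (h0 + (h1 - h0) * s1) * (h2 + (h1 - h2) * s2) / h1


@dataclass
class ImpulseFit:
    """Fitted impulse parameters and the LRT against a constant model."""

    h0: float
    h1: float
    h2: float
    t1: float
    t2: float
    beta: float
    loglik_impulse: float
    loglik_constant: float
    lrt_statistic: float
    p_value: float
    degenerate: bool = False
    converged: bool = True

    N_PARAMS = 6
    DF = 5  # impulse (6) minus constant (1)


def _gaussian_loglik(rss: float, n: int) -> float:
    # profile log-likelihood at the MLE sigma^2 = rss/n
    if rss <= 0:
        rss = 1e-300
    return -0.5 * n * (math.log(2 * math.pi * rss / n) + 1.0)


# internal parameterization: (h0, h1, h2, t1, t2, log beta)
_LOGBETA_LO, _LOGBETA_HI = math.log(1e-3), math.log(64.0)


def _impulse_f_batch(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Impulse profile for a (..., 6) parameter batch at stage times t."""
    h0, h1, h2, t1, t2, lb = (theta[..., i, None] for i in range(6))
    beta = np.exp(lb)
    with np.errstate(over="ignore"):
        s1 = 1.0 / (1.0 + np.exp(-beta * (t - t1)))
        s2 = 1.0 / (1.0 + np.exp(beta * (t - t2)))
    h1s = np.where(np.abs(h1) > 1e-6, h1, np.where(h1 >= 0, 1e-6, -1e-6))
    return (h0 + (h1 - h0) * s1) * (h2 + (h1 - h2) * s2) / h1s


def _lm_fit_batch(theta: np.ndarray, t: np.ndarray, ybar: np.ndarray, w: np.ndarray,
                  n_iter: int = 60) -> tuple[np.ndarray, np.ndarray]:
    """Batched Levenberg-Marquardt on the weighted stage-mean residuals.

    ``theta`` is (B, 6) start points, ``ybar`` (B, S) stage means, ``w``
    the sqrt(replicate-count) weights.  Returns (theta, rss) per batch
    row after a fixed iteration budget with per-row damping.
    """
    span = float(t[-1] - t[0]) if t[-1] > t[0] else 1.0
    t_lo, t_hi = t[0] - span, t[-1] + span

    def clipped(th):
        th = th.copy()
        th[..., 3] = np.clip(th[..., 3], t_lo, t_hi)
        th[..., 4] = np.clip(th[..., 4], t_lo, t_hi)
        th[..., 5] = np.clip(th[..., 5], _LOGBETA_LO, _LOGBETA_HI)
        return th

    def resid(th):
        return (ybar - _impulse_f_batch(th, t)) * w

    theta = clipped(theta)
    r = resid(theta)
    rss = (r * r).sum(-1)
    lam = np.full(theta.shape[0], 1e-2)
    eye = np.eye(6)
    for _ in range(n_iter):
        J = np.empty(theta.shape[:1] + (t.size, 6))
        for j in range(6):
            tp = theta.copy()
            tp[..., j] += 1e-6
            J[..., j] = (resid(tp) - r) / 1e-6
        A = np.einsum("bsi,bsj->bij", J, J)
        g = np.einsum("bsi,bs->bi", J, r)
        A = A + (lam[:, None, None] + 1e-9) * eye
        try:
            step = np.linalg.solve(A, -g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            A = A + 1e-6 * eye
            step = np.linalg.solve(A, -g[..., None])[..., 0]
        cand = clipped(theta + step)
        r_cand = resid(cand)
        rss_cand = (r_cand * r_cand).sum(-1)
        better = rss_cand < rss
        theta = np.where(better[:, None], cand, theta)
        r = np.where(better[:, None], r_cand, r)
        rss = np.where(better, rss_cand, rss)
        lam = np.where(better, lam / 3.0, lam * 4.0)
        lam = np.clip(lam, 1e-10, 1e8)
    return theta, rss


def _impulse_starts(ybar: np.ndarray, t: np.ndarray, n_restarts: int, rng) -> np.ndarray:
    """Deterministic shape-based start plus seeded random restarts (B, 6)."""
    S = t.size
    grand = ybar.mean()
    spread = 0.5 + ybar.std()
    starts = [
        [ybar[0], ybar[np.argmax(np.abs(ybar - grand))], ybar[-1], t[S // 3], t[2 * S // 3], math.log(2.0)]
    ]
    for _ in range(max(0, n_restarts - 1)):
        tt = np.sort(rng.uniform(t[0], t[-1], size=2))
        starts.append(
            [rng.normal(ybar[0], spread), rng.normal(ybar.max(), spread), rng.normal(ybar[-1], spread),
             tt[0], tt[1], math.log(rng.uniform(0.5, 8.0))]
        )
    return np.asarray(starts)


def fit_impulse_test(
    y,
    design: StageDesign,
    time_values=None,
    n_restarts: int = 10,
    seed: int = 0,
) -> ImpulseFit:
    """Fit the impulse model to one gene's log1p values and LRT vs constant.

    ``y`` holds per-replicate values ordered stage-major following
    ``design``.  Stage times default to ranks 0..S-1 (``time_values``
    overrides, e.g. for the unequally spaced Waddington scale).  The fit
    is Gaussian least squares with ``n_restarts`` random restarts from a
    seeded RNG; because the residual sum of squares depends on the stage
    means only, fitting uses the sqrt(n_s)-weighted stage means plus the
    within-stage sum of squares, which is exactly equivalent and fast.
    The LRT statistic is referred to chi-square with df = 5.
    """
    y = np.log1p(np.asarray(y, dtype=float))
    stages = design.stages
    S = len(stages)
    if S < 3:
        raise ValueError("impulse test needs >= 3 stages")
    n_per = np.array([design.replicates[s] for s in stages])
    n = int(n_per.sum())
    if y.size != n:
        raise ValueError(f"expected {n} values, got {y.size}")
    t = np.arange(S, dtype=float) if time_values is None else np.asarray(time_values, dtype=float)

    # sufficient statistics
    idx = np.repeat(np.arange(S), n_per)
    ybar = np.array([y[idx == s].mean() for s in range(S)])
    ss_within = float(sum(((y[idx == s] - ybar[s]) ** 2).sum() for s in range(S)))
    w = np.sqrt(n_per.astype(float))

    grand = float(y.mean())
    rss0 = float(((y - grand) ** 2).sum())
    if rss0 <= 1e-12:
        ll = _gaussian_loglik(rss0, n)
        return ImpulseFit(grand, grand, grand, t[0], t[-1], 1.0, ll, ll, 0.0, 1.0, degenerate=True)

    rng = np.random.default_rng(seed)
    starts = _impulse_starts(ybar, t, n_restarts, rng)
    thetas, rsses = _lm_fit_batch(starts, t, np.tile(ybar, (starts.shape[0], 1)), w)
    best = int(np.argmin(rsses))
    h0, h1, h2, t1, t2, logbeta = thetas[best]
    if t1 > t2:  # canonical order of transition times
        t1, t2 = t2, t1
    rss1 = min(float(rsses[best]) + ss_within, rss0)
    ll1 = _gaussian_loglik(rss1, n)
    ll0 = _gaussian_loglik(rss0, n)
    lrt = max(0.0, 2.0 * (ll1 - ll0))
    p = float(stats.chi2.sf(lrt, ImpulseFit.DF))
    return ImpulseFit(float(h0), float(h1), float(h2), float(t1), float(t2), float(np.exp(logbeta)),
                      ll1, ll0, lrt, p)


def impulse_screen(
    em: ExpressionMatrix,
    alpha: float = 0.05,
    time_values=None,
    n_restarts: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Impulse LRT over all genes with BH adjustment; DE at fdr <= alpha.

    All genes are fitted in one vectorized batch (restarts included);
    zero-variance genes are flagged degenerate with p = 1.
    """
    design = em.design()
    stages = design.stages
    S = len(stages)
    n_per = np.array([design.replicates[s] for s in stages])
    n = int(n_per.sum())
    t = np.arange(S, dtype=float) if time_values is None else np.asarray(time_values, dtype=float)
    w = np.sqrt(n_per.astype(float))

    y = np.log1p(em.values.to_numpy(dtype=float))  # genes x samples, stage-major
    idx = np.repeat(np.arange(S), n_per)
    ybar = np.stack([y[:, idx == s].mean(axis=1) for s in range(S)], axis=1)
    ss_within = np.stack([((y[:, idx == s] - ybar[:, [s]]) ** 2).sum(axis=1) for s in range(S)], axis=1).sum(axis=1)
    grand = y.mean(axis=1)
    rss0 = ((y - grand[:, None]) ** 2).sum(axis=1)

    rng = np.random.default_rng(seed)
    G = y.shape[0]
    starts = np.stack([_impulse_starts(ybar[g], t, n_restarts, rng) for g in range(G)])  # (G, R, 6)
    R = starts.shape[1]
    thetas, rsses = _lm_fit_batch(
        starts.reshape(G * R, 6), t, np.repeat(ybar, R, axis=0), w
    )
    rss1 = np.minimum(rsses.reshape(G, R).min(axis=1) + ss_within, rss0)

    degenerate = rss0 <= 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        lrt = np.where(degenerate, 0.0, n * np.log(np.maximum(rss0, 1e-300) / np.maximum(rss1, 1e-300)))
    lrt = np.maximum(lrt, 0.0)
    p = np.where(degenerate, 1.0, stats.chi2.sf(lrt, ImpulseFit.DF))
    out = pd.DataFrame({"lrt": lrt, "p_value": p, "degenerate": degenerate},
                       index=em.values.index.rename("gene_id"))
    out["fdr"] = benjamini_hochberg(out["p_value"].to_numpy())
    out["de"] = out["fdr"] <= alpha
    return out


def pairwise_summary(deg_tables: dict[str, pd.DataFrame], tf_genes: set[str]) -> pd.DataFrame:
    """Per-comparison totals: DEG count, up/down counts and percents, TF share.

    Percentages are reported to one decimal place; ``down = total - up``.
    Empty comparisons yield all-zero rows rather than division errors.
    """
    rows = []
    for name, degs in deg_tables.items():
        total = len(degs)
        up = int((degs["direction"] == "up").sum()) if total else 0
        down = total - up
        n_tf = sum(1 for g in degs.index if g in tf_genes) if total else 0
        rows.append(
            {
                "comparison": name,
                "total": total,
                "up": up,
                "down": down,
                "up_pct": round(100.0 * up / total, 1) if total else 0.0,
                "down_pct": round(100.0 * down / total, 1) if total else 0.0,
                "tf_count": n_tf,
                "tf_pct": round(100.0 * n_tf / total, 1) if total else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("comparison")


@dataclass
class PcaResult:
    """Per-sample PC coordinates and percent variance explained per PC."""

    coordinates: pd.DataFrame  # samples x PCs
    pve: np.ndarray  # percent variance explained, non-increasing


def pca(em: ExpressionMatrix, gene_subset=None, n_components: int | None = None) -> PcaResult:
    """Gene-centred PCA over samples; PVE_k = 100 * lambda_k / sum(lambda)."""
    values = em.values if gene_subset is None else em.values.loc[list(gene_subset)]
    x = values.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("PCA needs >= 2 samples")
    xc = x - x.mean(axis=1, keepdims=True)
    total = float((xc**2).sum())
    if total <= 0:
        raise ValueError("constant matrix: variance undefined for PCA")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    lam = s**2
    pve = 100.0 * lam / lam.sum()
    k = len(s) if n_components is None else min(n_components, len(s))
    coords = pd.DataFrame(
        (vt[:k].T * s[:k]),
        index=values.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PcaResult(coords, pve[:k])
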
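"""Tau tissue-specificity screening against multi-tissue reference atlases.

The focal spike time course contributes one context — the maximum stage
mean across its developmental stages — which is compared with the mean
expression of each tissue in one or more whole-plant atlases.  Tau runs
from 0 (ubiquitous) to 1 (restricted to a single context).  Genes with
tau > 0.9 whose maximal context is the spike course are called
``spike_dominant``; genes with exactly zero expression in every atlas
tissue (tau = 1) are ``spike_specific``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, stage_means

__all__ = ["SpecificityProfile", "tau", "classify", "build_specificity_table"]

FOCAL_CONTEXT = "focal"


def tau(x) -> float:
    """Tissue-specificity index over N >= 2 contexts.

    tau = sum_i (1 - x_i / max(x)) / (N - 1); requires max(x) > 0 and
    all components non-negative.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("tau needs >= 2 contexts")
    if (x < 0).any():
        raise ValueError("tau requires non-negative expression")
    m = x.max()
    if m <= 0:
        raise ValueError("tau undefined for an all-zero vector")
    return float((1.0 - x / m).sum() / (x.size - 1))


def classify(tau_values, argmax_is_focal: bool, atlas_all_zero) -> str:
    """Combine per-atlas tau into a class, requiring every atlas to agree.

    ``spike_specific`` needs all non-focal contexts exactly zero in every
    atlas (tau = 1 by construction, tested on the raw values rather than
    floating-point equality); ``spike_dominant`` needs tau > 0.9 in every
    atlas with the focal context maximal; anything else is ``none``.
    """
    tau_values = list(tau_values)
    atlas_all_zero = list(atlas_all_zero)
    if not tau_values:
        raise ValueError("no tau values supplied")
    if all(atlas_all_zero) and argmax_is_focal:
        return "spike_specific"
    if argmax_is_focal and all(t > 0.9 for t in tau_values):
        return "spike_dominant"
    return "none"


@dataclass
class SpecificityProfile:
    gene_id: str
    tau_per_atlas: dict[str, float]
    argmax_context: str
    cls: str
    contexts: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


def build_specificity_table(
    focal: ExpressionMatrix,
    atlases: dict[str, pd.DataFrame],
    exclude_tissues: dict[str, list[str]] | None = None,
    combine: str = "all",
) -> pd.DataFrame:
    """Tau per (gene, atlas) plus a combined spike-specificity class.

    Each atlas is a genes x tissue-means TPM table.  Tissues overlapping
    the focal tissue can be removed per atlas via ``exclude_tissues``.
    Genes absent from an atlas are treated as zero expression there
    (recorded in the ``missing_from`` column).  ``combine="all"``
    (default) requires the classification in every atlas independently;
    ``combine="concat"`` computes a single tau over the concatenated
    context vector of all atlases.
    """
    if not atlases:
        raise ValueError("at least one atlas table is required")
    exclude_tissues = exclude_tissues or {}
    focal_max = stage_means(focal).max(axis=1)

    trimmed = {}
    for name, table in atlases.items():
        drop = [c for c in exclude_tissues.get(name, []) if c in table.columns]
        trimmed[name] = table.drop(columns=drop)

    rows = []
    for gene in focal.gene_ids:
        f = float(focal_max.loc[gene])
        taus: dict[str, float] = {}
        zeros: list[bool] = []
        missing: list[str] = []
        argmax_focal = True
        concat = [f]
        for name, table in trimmed.items():
            if gene in table.index:
                x_at = table.loc[gene].to_numpy(dtype=float)
            else:
                x_at = np.zeros(table.shape[1])
                missing.append(name)
            vec = np.concatenate([[f], x_at])
            if vec.max() <= 0:
                taus[name] = np.nan
                zeros.append(False)
                continue
            taus[name] = tau(vec)
            zeros.append(bool((x_at == 0).all()))
            if x_at.size and x_at.max() > f:
                argmax_focal = False
            concat.extend(x_at.tolist())
        valid = {k: v for k, v in taus.items() if not np.isnan(v)}
        if combine == "concat":
            cvec = np.asarray(concat)
            ctau = tau(cvec) if cvec.max() > 0 else np.nan
            if np.isnan(ctau):
                cls = "none"
            else:
                cls = classify([ctau], argmax_focal, [bool((cvec[1:] == 0).all())])
        elif not valid or len(valid) < len(taus):
            cls = "none"
        else:
            cls = classify(valid.values(), argmax_focal, zeros)
        row = {"gene_id": gene, "argmax_is_focal": argmax_focal, "class": cls,
               "missing_from": ",".join(missing)}
        for name in atlases:
            row[f"tau_{name}"] = taus.get(name, np.nan)
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")
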
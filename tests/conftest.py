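"""Shared fixtures: small expression matrices and seeded synthetic data."""

import numpy as np
import pandas as pd
import pytest

from spikenet import ExpressionMatrix, StageDesign, counts_to_tpm
from spikenet.simulate import SyntheticSpec, generate_timecourse

STAGES = ["W1", "W2", "W3.0", "W3.25", "W3.5"]

#: archetypes with mutually low/negative correlation — separable planted
#: structure for recovery tests (the up_after_DR / TS_peak pair is r~0.8
#: by design, emulating genuinely similar module profiles, and is
#: therefore excluded from recovery fixtures)
SEPARABLE = ("down_after_DR", "W3.0_peak", "TS_peak")


def make_matrix(values: np.ndarray, stages=None, n_reps=None, gene_ids=None, unit="counts"):
    """Wrap a genes x samples array into an ExpressionMatrix with a stage sheet."""
    g, s = values.shape
    if stages is None:
        n_reps = n_reps or 1
        n_stages = s // n_reps
        stages = [f"S{i + 1}" for i in range(n_stages)]
    n_reps = s // len(stages)
    cols = [f"{st}_r{j + 1}" for st in stages for j in range(n_reps)]
    meta = pd.DataFrame(
        {"stage": np.repeat(stages, n_reps), "replicate": list(range(1, n_reps + 1)) * len(stages)},
        index=pd.Index(cols, name="sample_id"),
    )
    genes = gene_ids if gene_ids is not None else [f"g{i}" for i in range(g)]
    return ExpressionMatrix(pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=cols), meta, unit)


@pytest.fixture(scope="session")
def design_5x4():
    return StageDesign.uniform(STAGES, 4)


@pytest.fixture(scope="session")
def planted_dataset():
    """3 separable planted modules x 80 genes with pairs and atlases."""
    spec = SyntheticSpec(
        n_modules=3, genes_per_module=80, archetypes=SEPARABLE,
        n_homoeolog_pairs=100, seed=11,
    )
    return generate_timecourse(spec)


@pytest.fixture(scope="session")
def planted_tpm(planted_dataset):
    return counts_to_tpm(planted_dataset.counts, planted_dataset.annotation)
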
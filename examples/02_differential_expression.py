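"""Differential-expression screens: consensus rule, impulse LRT, PCA.

Runs the built-in Welch stand-in on two stages, intersects two DE tables
with the consensus rule (FDR <= 0.01 in both), screens the whole course
with the impulse-model likelihood-ratio test (FDR <= 0.05) and
summarises sample structure with PCA.
"""

from spikenet import (
    consensus_degs,
    counts_to_tpm,
    impulse_screen,
    pairwise_summary,
    pca,
    welch_pairwise,
)
from spikenet.simulate import SyntheticSpec, generate_timecourse

spec = SyntheticSpec(n_modules=3, genes_per_module=80,
                     archetypes=("down_after_DR", "W3.0_peak", "TS_peak"), seed=2)
ds = generate_timecourse(spec)
tpm = counts_to_tpm(ds.counts, ds.annotation)

# two pairwise tables from different routes (TPM-scale and count-scale
# Welch tests stand in for the two external count-model tools; the
# consensus rule accepts any two DE tables)
table_a = welch_pairwise(tpm, "W1", "W3.0")
table_b = welch_pairwise(ds.counts, "W1", "W3.0")
degs = consensus_degs(table_a, table_b, alpha=0.01)
print(f"consensus W1-W3.0 DEGs (FDR<=0.01 in both tables): {len(degs)}")

summary = pairwise_summary({"W1-W3.0": degs}, ds.annotation.tf_genes())
print(summary[["total", "up", "down", "down_pct", "tf_pct"]])
# down_pct is the share of DEGs falling as the meristem transitions.

imp = impulse_screen(tpm, alpha=0.05, seed=0)
print(f"impulse-DE genes (FDR<=0.05): {int(imp['de'].sum())} of {len(imp)}")

res = pca(tpm)
print("PVE of PC1/PC2 (%):", res.pve[:2].round(1))
# PC1 carries the dominant stage-to-stage transcriptome shift.
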
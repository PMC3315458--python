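"""Cluster treatment-responsive transcripts into covariant modules.

Class I transcripts covary across treatments; this script sex-centers the
expression matrix, computes correlations of the stacked per-sex treatment
profiles, and partitions the transcripts by modularity maximization on a
sharpened |r| graph.
"""

import warnings

import plasticlass as pl

cfg = pl.SimulationConfig(n_transcripts=600, seed=2)
outbred, truth = pl.simulate_outbred(cfg)
panel = pl.simulate_inbred_panel(cfg, truth)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    run = pl.classify_transcriptome(outbred, panel)

centered = pl.sex_center(outbred)
class1 = run.classes.ids("classI")
ids, r = pl.treatment_correlations(centered, ids=class1)
partition = pl.mmc_cluster(ids, r, seed=0)
summary, cross = pl.module_diagnostics(partition, r)

print(f"{len(ids)} Class I transcripts -> {partition.n_modules} covariant modules")
print(f"modularity {partition.modularity:.3f} at sharpening sigma {partition.sigma:.3f}\n")
print("strongest modules (ordered by mean within-module |r|):")
print(summary.head(8).to_string(float_format=lambda v: f"{v:.3f}"))

off_diag = cross.values[~(cross.index.values[:, None] == cross.columns.values)]
print(f"\nmean within-module |r|: {summary['within_mean_abs_r'].mean():.3f}")
print(f"mean cross-module |r|:  {off_diag.mean():.3f}")

# Modules collect transcripts with parallel treatment responses (e.g. those
# planted with effects in overlapping treatment subsets). Within-module |r|
# well above the cross-module mean shows real covariant structure, not an
# artifact of the partitioning.
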
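"""Negative-binomial LRTs for lineage-specific and time-dependent expression.

Simulates a three-lineage differentiation time course in which 10% of genes
carry a lineage-specific spline trajectory and 10% a constant lineage shift,
then runs the two nested-model tests:

* one-vs-rest LRT (intercept + lineage indicator vs intercept, df = 1) —
  detects any expression difference, constant or not;
* lineage-spline LRT (adds lineage x spline interaction terms, df = K) —
  detects *trajectory* differences only; constant shifts stay null.
"""

from ntve.glm import lineage_spline_lrt, one_vs_rest_lrt, timecourse_spline_lrt
from ntve.simulate import TimecourseConfig, simulate_timecourse_counts

config = TimecourseConfig(
    n_genes=300, lineages=("mesoderm", "ectoderm", "endoderm"),
    fraction_lineage_specific=0.1, fraction_constant_shift=0.1,
    spline_effect_size=1.5, constant_shift_effect=1.5, seed=21,
)
counts, truth = simulate_timecourse_counts(config)
meta = counts.sample_meta

ovr = one_vs_rest_lrt(counts, meta["lineage"], "mesoderm")
spline = lineage_spline_lrt(counts, meta["lineage"], meta["time_days"], "mesoderm", K=4)

for effect in ("none", "shift", "spline"):
    genes = truth.index[truth["effect"] == effect]
    print(
        f"{effect:>6} genes (n={len(genes)}):  one-vs-rest hits {int((ovr.loc[genes, 'padj'] < 0.05).sum()):>3}"
        f"   trajectory hits {int((spline.loc[genes, 'padj'] < 0.05).sum()):>3}"
    )
# Constant-shift genes are found by the one-vs-rest axis but not the
# trajectory axis; spline genes light up the trajectory test.  This is the
# two-axis classification used to separate level effects from shape effects.

# single-course time-dependence: spline vs time-invariant null, df = K
target = counts.subset_samples(counts.samples_where(lineage="mesoderm"))
tc = timecourse_spline_lrt(target, target.sample_meta["time_days"], target.sample_meta["replicate"], K=4)
print(f"time-dependent genes in the target lineage at FDR < 0.05: {int((tc['padj'] < 0.05).sum())}")
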
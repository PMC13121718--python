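"""Reproduce the supernatant-vs-lysate 3'-coverage contrast on synthetic reads.

Vesicle-exported RNA bound via poly(A) shows read depth decaying with
distance from the transcript 3' end; lysate coverage is flat.  This script
simulates both compartments, builds AUC-normalized metagene profiles
anchored at the 3' terminus, and prints the per-distance coverage ratio.
"""

import warnings

import numpy as np

from ntve.coverage import auc_normalize, coverage_ratio, metagene_3prime, per_position_depth
from ntve.simulate import SimulationConfig, simulate_aligned_reads, simulate_transcriptome

config = SimulationConfig(n_genes=40, length_range=(3500, 5000), three_prime_decay_length=500, seed=4)
_, annotations = simulate_transcriptome(config)

profiles = {}
for compartment in ("supernatant", "lysate"):
    records = simulate_aligned_reads(config, annotations, compartment, n_pairs=30_000)
    depth, _ = per_position_depth(records, annotations)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        normalized = [p for p in (auc_normalize(d) for d in depth.values()) if p is not None]
    profiles[compartment] = metagene_3prime(normalized, window=3000, bin_size=10, group=compartment)

ratio = coverage_ratio(profiles["supernatant"], profiles["lysate"])
for start in (300, 600, 1200, 2400):
    b = start // 10
    print(
        f"{start:>5} nt upstream of 3' end:  supernatant {profiles['supernatant'].mean_coverage[b]:.3f}  "
        f"lysate {profiles['lysate'].mean_coverage[b]:.3f}  ratio {ratio[b]:.3f}"
    )
# Ratios > 1 near the 3' end and << 1 far from it quantify the 3' bias of
# the exported fraction; the lysate profile stays near 1 throughout.
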
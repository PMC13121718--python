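"""Synthetic-data generators emulating vesicle-export RNA-seq structure.

Every downstream stage of the pipeline is testable against data from this
module, which emulates the statistical signatures of supernatant (vesicle)
versus lysate sequencing:

* paired negative-binomial counts with a sharply peaked log10 export-ratio
  distribution and strong mitochondrial depletion in the supernatant,
* 3'-biased positional read coverage in the exported fraction (fragment
  3'-ends decay exponentially away from the poly(A) site) versus uniform
  lysate coverage,
* low-complexity and PCR-duplicate read artifacts,
* a known-mass spike-in transcript,
* multi-lineage time-course counts with spline-shaped lineage-specific
  trajectories, and two-condition counts with known log2 fold changes.

All generators are deterministic under a fixed seed, and every generator
returns the ground truth (export ratios, effect labels, coefficients) next to
the data so recovery tests are possible in every downstream module.

The negative binomial is parameterized by mean mu and dispersion alpha with
variance mu + alpha * mu**2, the convention of the differential-expression
literature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AlignmentRecord, CountMatrix
from .splines import NaturalCubicSplineBasis

__all__ = [
    "SimulationConfig",
    "TimecourseConfig",
    "simulate_transcriptome",
    "simulate_paired_counts",
    "simulate_aligned_reads",
    "simulate_timecourse_counts",
    "simulate_two_condition",
    "nb_sample",
]


@dataclass
class SimulationConfig:
    """Parameters of the paired supernatant/lysate generator.

    Defaults reflect the study conditions the pipeline targets: triplicate
    supernatant/lysate pairs, 1 pg of spike-in, a sharply peaked export-ratio
    distribution, strong mitochondrial depletion in the exported fraction,
    and an exponential 3'-coverage bias in the supernatant.
    """

    n_genes: int = 1000
    isoforms_per_gene: int = 1
    length_range: tuple[int, int] = (500, 5000)
    n_replicates: int = 3
    mean_library_size: float = 1e6
    dispersion: float = 0.05
    export_log10_ratio_sd: float = 0.15
    mito_fraction: float = 0.01
    mito_depletion_factor: float = 0.02
    three_prime_decay_length: float = 500.0
    spikein_mass_pg: float = 1.0
    spikein_read_fraction: float = 0.01
    duplicate_rate: float = 0.0
    lowcomplexity_rate: float = 0.0
    read_length: int = 100
    fragment_length: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo > hi:
            raise ValueError(f"length_range min {lo} > max {hi}")
        for name in ("mito_fraction", "spikein_read_fraction", "duplicate_rate", "lowcomplexity_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if lo < 1:
            raise ValueError("transcript lengths must be positive")
        if self.export_log10_ratio_sd < 0:
            raise ValueError("export_log10_ratio_sd must be non-negative")


@dataclass
class TimecourseConfig:
    """Parameters of the multi-lineage spline time-course generator."""

    lineages: tuple[str, ...] = ("ectoderm", "mesoderm", "endoderm")
    time_points: tuple[float, ...] = (0, 1, 2, 3, 4, 5, 6)
    replicates: int = 3
    n_genes: int = 500
    fraction_lineage_specific: float = 0.1
    fraction_constant_shift: float = 0.1
    spline_effect_size: float = 1.5
    constant_shift_effect: float = 1.0
    baseline_mean: float = 500.0
    shared_trajectory_sd: float = 0.3
    dispersion: float = 0.05
    spline_df: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.lineages) < 2:
            raise ValueError("need at least 2 lineages")
        if len(set(self.time_points)) < 4:
            raise ValueError("need at least 4 distinct time points for spline identifiability")
        if len(set(self.time_points)) < self.spline_df + 1:
            raise ValueError("fewer time points than spline degrees of freedom")


def nb_sample(rng: np.random.Generator, mean, alpha):
    """Draw negative-binomial counts with variance mean + alpha*mean**2.

    alpha below 1e-12 falls back to the Poisson limit.
    """
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    poisson = alpha < 1e-12
    if poisson.any():
        out[poisson] = rng.poisson(mean[poisson])
    if (~poisson).any():
        a = alpha[~poisson]
        m = mean[~poisson]
        r = 1.0 / a
        p = r / (r + m)
        out[~poisson] = rng.negative_binomial(r, p)
    return out


_BASES = np.array(list("ACGT"))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


SPIKEIN_ID = "spikein_mGL"


def simulate_transcriptome(config: SimulationConfig):
    """Generate transcript sequences and annotations.

    Returns ``(sequences, annotations)`` where ``sequences`` maps transcript
    id to its sequence string and ``annotations`` is the annotation DataFrame
    (same schema as :func:`ntve.io.read_gtf`).  One extra spike-in transcript
    is always appended; the first ``round(mito_fraction * n_genes)`` genes
    are flagged mitochondrial.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    n_mito = int(round(config.mito_fraction * config.n_genes))
    rows = []
    sequences = {}
    for g in range(config.n_genes):
        gid = f"gene{g:05d}"
        for iso in range(config.isoforms_per_gene):
            tid = f"{gid}.t{iso + 1}"
            length = int(rng.integers(lo, hi + 1))
            sequences[tid] = _random_sequence(rng, length)
            rows.append(
                {
                    "transcript_id": tid,
                    "gene_id": gid,
                    "gene_symbol": gid.upper(),
                    "length": length,
                    "biotype": "protein_coding",
                    "is_mitochondrial": g < n_mito,
                    "is_spikein": False,
                }
            )
    spike_len = min(hi, max(lo, 1000))
    sequences[SPIKEIN_ID] = _random_sequence(rng, spike_len)
    rows.append(
        {
            "transcript_id": SPIKEIN_ID,
            "gene_id": SPIKEIN_ID,
            "gene_symbol": "mGL",
            "length": spike_len,
            "biotype": "synthetic",
            "is_mitochondrial": False,
            "is_spikein": True,
        }
    )
    annotations = pd.DataFrame(rows).set_index("transcript_id")
    return sequences, annotations


def write_fasta(sequences: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def simulate_paired_counts(config: SimulationConfig, annotations: pd.DataFrame):
    """Gene-level NB counts for paired supernatant/lysate replicates.

    Lysate gene means are drawn log-uniform; the matched supernatant mean is
    the lysate mean times ``10**N(0, export_log10_ratio_sd)`` and, for
    mitochondrial genes, times ``mito_depletion_factor``.  Lysate means are
    scaled so each lysate library has ``mean_library_size`` expected reads;
    supernatant libraries inherit the export-scaled total.

    Returns ``(CountMatrix, truth)`` with truth columns ``lysate_mean``,
    ``supernatant_mean``, ``true_log10_ratio`` (including the mitochondrial
    factor) and ``is_mitochondrial``.
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = annotations.loc[~annotations["is_spikein"], "gene_id"].unique()
    gene_mito = annotations.loc[~annotations["is_spikein"]].groupby("gene_id")["is_mitochondrial"].any()
    gene_mito = gene_mito.reindex(genes)
    n = len(genes)

    lam = 10 ** rng.uniform(0, 4, size=n)
    lam *= config.mean_library_size / lam.sum()
    log10_ratio = rng.normal(0.0, config.export_log10_ratio_sd, size=n)
    factor = np.where(gene_mito.to_numpy(), config.mito_depletion_factor, 1.0)
    sn_mean = lam * (10**log10_ratio) * factor

    cols = {}
    meta_rows = []
    for rep in range(1, config.n_replicates + 1):
        sid = f"supernatant_rep{rep}"
        cols[sid] = nb_sample(rng, sn_mean, config.dispersion)
        meta_rows.append({"sample_id": sid, "compartment": "supernatant", "condition": "control", "replicate": rep})
    for rep in range(1, config.n_replicates + 1):
        sid = f"lysate_rep{rep}"
        cols[sid] = nb_sample(rng, lam, config.dispersion)
        meta_rows.append({"sample_id": sid, "compartment": "lysate", "condition": "control", "replicate": rep})
    values = pd.DataFrame(cols, index=pd.Index(genes, name="feature_id"))
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = pd.DataFrame(
        {
            "lysate_mean": lam,
            "supernatant_mean": sn_mean,
            "true_log10_ratio": log10_ratio + np.log10(factor),
            "is_mitochondrial": gene_mito.to_numpy(),
        },
        index=pd.Index(genes, name="feature_id"),
    )
    return CountMatrix(values, meta, unit="counts"), truth


def simulate_aligned_reads(
    config: SimulationConfig,
    annotations: pd.DataFrame,
    compartment: str,
    sequences: dict | None = None,
    n_pairs: int = 10_000,
) -> list[AlignmentRecord]:
    """Generate proper-paired alignment records in transcript coordinates.

    For ``compartment == 'supernatant'`` the fragment 3'-end distance from
    the transcript 3' terminus follows a truncated exponential with scale
    ``three_prime_decay_length``; for ``'lysate'`` it is uniform.  A
    ``duplicate_rate`` fraction of pairs are exact sequence duplicates of a
    previous pair, a ``lowcomplexity_rate`` fraction get homopolymer
    sequences, and a ``spikein_read_fraction`` fraction map to the spike-in
    transcript.  Transcripts shorter than the fragment length are skipped
    with a warning.
    """
    if compartment not in ("supernatant", "lysate"):
        raise ValueError(f"compartment must be 'supernatant' or 'lysate', got {compartment!r}")
    rng = np.random.default_rng(config.seed + (2 if compartment == "supernatant" else 3))
    frag = max(config.fragment_length, config.read_length)

    usable = annotations[annotations["length"] >= frag]
    n_skipped = len(annotations) - len(usable)
    if n_skipped:
        warnings.warn(f"{n_skipped} transcript(s) shorter than the fragment length were skipped", stacklevel=2)
    if usable.empty:
        raise ValueError("no transcript is long enough for the configured fragment length")
    regular = usable.index[~usable["is_spikein"]].to_numpy()
    spikes = usable.index[usable["is_spikein"]].to_numpy()

    lengths = usable["length"]
    records: list[AlignmentRecord] = []
    pair_buffer: list[tuple[AlignmentRecord, AlignmentRecord]] = []
    read_len = config.read_length

    for i in range(n_pairs):
        qname = f"pair{i:07d}"
        if pair_buffer and rng.random() < config.duplicate_rate:
            src1, src2 = pair_buffer[rng.integers(0, len(pair_buffer))]
            r1 = AlignmentRecord(qname, True, True, src1.reference_name, src1.position, list(src1.cigar), src1.sequence)
            r2 = AlignmentRecord(qname, False, True, src2.reference_name, src2.position, list(src2.cigar), src2.sequence)
            records.extend([r1, r2])
            continue
        if len(spikes) and rng.random() < config.spikein_read_fraction:
            tid = spikes[rng.integers(0, len(spikes))]
        else:
            tid = regular[rng.integers(0, len(regular))]
        length = int(lengths[tid])
        max_dist = length - frag
        if compartment == "supernatant":
            dist = int(rng.exponential(config.three_prime_decay_length))
            dist = min(dist, max_dist)
        else:
            dist = int(rng.integers(0, max_dist + 1))
        frag_start0 = length - dist - frag  # 0-based fragment start
        pos1 = frag_start0 + 1
        pos2 = frag_start0 + frag - read_len + 1
        if rng.random() < config.lowcomplexity_rate:
            seq1 = seq2 = "A" * read_len
        elif sequences is not None and tid in sequences:
            s = sequences[tid]
            seq1 = s[frag_start0 : frag_start0 + read_len]
            seq2 = s[pos2 - 1 : pos2 - 1 + read_len]
        else:
            seq1 = _random_sequence(rng, read_len)
            seq2 = _random_sequence(rng, read_len)
        cig = [("M", read_len)]
        r1 = AlignmentRecord(qname, True, True, tid, pos1, list(cig), seq1)
        r2 = AlignmentRecord(qname, False, True, tid, pos2, list(cig), seq2)
        records.extend([r1, r2])
        pair_buffer.append((r1, r2))
    return records


def simulate_timecourse_counts(config: TimecourseConfig):
    """Multi-lineage NB time-course counts with spline-shaped trajectories.

    The first lineage is the designated target.  Per gene, the log mean is

        log mu = log(baseline) + u_g + beta1 * L + sum_k gamma_k b_k(t)
                 + sum_k delta_k * L * b_k(t)

    with L = 1 for target-lineage samples.  ``fraction_constant_shift`` of
    genes carry a beta1-only effect, ``fraction_lineage_specific`` carry
    delta effects; the rest are null on both axes.  All genes share a small
    random gamma trajectory.  Returns ``(CountMatrix, truth)`` with truth
    columns ``effect`` in {none, shift, spline}, ``beta1`` and
    ``delta_amplitude``.
    """
    rng = np.random.default_rng(config.seed)
    times = np.array(sorted(config.time_points), dtype=float)
    basis = NaturalCubicSplineBasis.from_times(times, config.spline_df)

    sample_rows = []
    for lin in config.lineages:
        for t in times:
            for rep in range(1, config.replicates + 1):
                sample_rows.append(
                    {
                        "sample_id": f"{lin}_d{t:g}_rep{rep}",
                        "lineage": lin,
                        "compartment": "supernatant",
                        "condition": "timecourse",
                        "time_days": t,
                        "replicate": rep,
                    }
                )
    meta = pd.DataFrame(sample_rows).set_index("sample_id")
    t_s = meta["time_days"].to_numpy(dtype=float)
    L_s = (meta["lineage"] == config.lineages[0]).to_numpy(dtype=float)
    B = basis(t_s)  # (samples, K)
    K = B.shape[1]

    n = config.n_genes
    n_spline = int(round(config.fraction_lineage_specific * n))
    n_shift = int(round(config.fraction_constant_shift * n))
    effect = np.array(["none"] * n, dtype=object)
    effect[:n_spline] = "spline"
    effect[n_spline : n_spline + n_shift] = "shift"

    u = rng.normal(0.0, 0.5, size=n)  # per-gene baseline offset, natural log
    beta1 = np.where(effect == "shift", config.constant_shift_effect * rng.choice([-1.0, 1.0], size=n), 0.0)
    gamma = rng.normal(0.0, config.shared_trajectory_sd, size=(n, K))
    delta = np.zeros((n, K))
    spline_mask = effect == "spline"
    delta[spline_mask] = config.spline_effect_size * rng.choice([-1.0, 1.0], size=(spline_mask.sum(), K)) * rng.uniform(
        0.5, 1.0, size=(spline_mask.sum(), K)
    )

    log_mu = (
        np.log(config.baseline_mean)
        + u[:, None]
        + beta1[:, None] * L_s[None, :]
        + gamma @ B.T
        + (delta @ B.T) * L_s[None, :]
    )
    counts = nb_sample(rng, np.exp(log_mu), config.dispersion)
    features = pd.Index([f"gene{i:05d}" for i in range(n)], name="feature_id")
    values = pd.DataFrame(counts, index=features, columns=meta.index)
    truth = pd.DataFrame(
        {
            "effect": effect,
            "beta1": beta1,
            "delta_amplitude": np.abs(delta).max(axis=1),
        },
        index=features,
    )
    return CountMatrix(values, meta, unit="counts"), truth


def simulate_two_condition(
    n_genes: int,
    n_per_group: tuple[int, int],
    true_lfc,
    dispersion: float = 0.05,
    mean_count: float = 500.0,
    seed: int = 0,
):
    """Two-condition NB counts with known per-gene log2 fold changes.

    ``n_per_group`` gives (reference, treatment) replicate counts; unbalanced
    designs (e.g. 6 vs 3) are supported.  Returns ``(CountMatrix, truth)``
    where truth holds the true log2 fold change per gene (treatment over
    reference).
    """
    n_ref, n_trt = n_per_group
    if n_ref < 2 or n_trt < 2:
        raise ValueError("each group needs at least 2 replicates")
    true_lfc = np.broadcast_to(np.asarray(true_lfc, dtype=float), (n_genes,)).copy()
    rng = np.random.default_rng(seed)
    base = mean_count * 10 ** rng.uniform(-1, 1, size=n_genes)
    trt_mean = base * 2.0**true_lfc

    cols = {}
    meta_rows = []
    for rep in range(1, n_ref + 1):
        sid = f"reference_rep{rep}"
        cols[sid] = nb_sample(rng, base, dispersion)
        meta_rows.append({"sample_id": sid, "condition": "reference", "compartment": "lysate", "replicate": rep})
    for rep in range(1, n_trt + 1):
        sid = f"treatment_rep{rep}"
        cols[sid] = nb_sample(rng, trt_mean, dispersion)
        meta_rows.append({"sample_id": sid, "condition": "treatment", "compartment": "lysate", "replicate": rep})
    features = pd.Index([f"gene{i:05d}" for i in range(n_genes)], name="feature_id")
    values = pd.DataFrame(cols, index=features)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = pd.DataFrame({"true_lfc": true_lfc}, index=features)
    return CountMatrix(values, meta, unit="counts"), truth
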
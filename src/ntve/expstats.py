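"""Supernatant-versus-lysate summary statistics.

This module quantifies how faithfully the exported (supernatant) fraction
mirrors the cellular (lysate) transcriptome: normalization to CPM/TPM,
per-gene export-ratio distributions, detection rates across expression
quantiles, length-binned rank concordance, replicate variability, detection
overlap, and absolute RNA quantification from a known-mass spike-in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CountMatrix

__all__ = [
    "SpikeInConfig",
    "cpm_normalize",
    "tpm_from_counts",
    "renormalize_tpm",
    "ExportRatioResult",
    "export_ratio_distribution",
    "detection_rate_by_quantile",
    "length_binned_spearman",
    "cv_per_gene",
    "detection_overlap",
    "spikein_absolute_rna",
    "filter_samples_by_reads",
]

AVOGADRO = 6.02214076e23
DALTON_G = 1.0 / AVOGADRO  # grams per dalton


def cpm_normalize(counts: CountMatrix, pseudocount: float = 0.0) -> CountMatrix:
    """Counts per million: value * 1e6 / column sum, plus an optional
    pseudocount added *after* scaling (for log display, e.g. 1e-3)."""
    sums = counts.values.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"sample(s) with all-zero counts cannot be CPM-normalized: {', '.join(map(str, zero.index))}")
    values = counts.values * 1e6 / sums + pseudocount
    return CountMatrix(values, counts.sample_meta, unit="CPM")


def tpm_from_counts(counts: CountMatrix, lengths) -> CountMatrix:
    """Transcripts per million from raw counts and feature lengths.

    rate = count / length; TPM = rate * 1e6 / sum(rate) per sample.
    """
    if isinstance(lengths, pd.DataFrame):
        lengths = lengths["length"]
    lengths = pd.Series(lengths).reindex(counts.feature_ids)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise ValueError(f"no length for feature {missing!r}")
    rates = counts.values.div(lengths, axis=0)
    sums = rates.sum(axis=0)
    if (sums == 0).any():
        bad = sums.index[sums == 0][0]
        raise ValueError(f"sample {bad!r} has zero total rate")
    return CountMatrix(rates * 1e6 / sums, counts.sample_meta, unit="TPM")


def renormalize_tpm(tpm: CountMatrix) -> CountMatrix:
    """Rescale a (subset of a) TPM matrix so each column sums to 1e6 again,
    as done after restricting to a feature subset such as coding genes."""
    sums = tpm.values.sum(axis=0)
    if (sums == 0).any():
        bad = sums.index[sums == 0][0]
        raise ValueError(f"sample {bad!r} has zero total expression in the subset")
    return CountMatrix(tpm.values * 1e6 / sums, tpm.sample_meta, unit=tpm.unit)


@dataclass
class ExportRatioResult:
    """Per-replicate log10 export-ratio histograms on a shared grid plus the
    across-replicate mean density with a 95% CI (mean +/- 1.96 * SEM)."""

    bin_edges: np.ndarray  # shared grid, n_bins + 1 edges
    densities: np.ndarray  # (n_pairs, n_bins) per-replicate-pair densities
    mean_density: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    log10_ratios: list[np.ndarray]  # per pair, post-filter
    n_genes_per_pair: np.ndarray

    @property
    def pooled_sd(self) -> float:
        """Standard deviation of all replicate pairs' log10 ratios pooled."""
        return float(np.std(np.concatenate(self.log10_ratios), ddof=1))


def export_ratio_distribution(
    paired: CountMatrix,
    min_lysate: float = 1.0,
    bins: int = 70,
) -> ExportRatioResult:
    """Distribution of per-gene log10(supernatant / lysate) expression.

    Replicate pairs are matched by the ``replicate`` metadata column across
    ``compartment`` supernatant/lysate.  Within each pair, genes with lysate
    expression below ``min_lysate`` are excluded, the log10 ratio is
    computed for the rest, and a density histogram is taken on a 70-bin grid
    shared across pairs.  The summary curve is the per-bin mean density with
    a 95% normal CI across pairs.
    """
    if paired.sample_meta is None:
        raise ValueError("paired matrix needs compartment/replicate metadata")
    meta = paired.sample_meta
    reps = sorted(set(meta.loc[meta["compartment"] == "supernatant", "replicate"]))
    pairs = []
    for rep in reps:
        sn = meta.index[(meta["compartment"] == "supernatant") & (meta["replicate"] == rep)]
        lys = meta.index[(meta["compartment"] == "lysate") & (meta["replicate"] == rep)]
        if len(sn) == 1 and len(lys) == 1:
            pairs.append((sn[0], lys[0]))
    if not pairs:
        raise ValueError("no matched supernatant/lysate replicate pairs found")

    ratios = []
    for sn_id, lys_id in pairs:
        sn = paired.values[sn_id].to_numpy(dtype=float)
        lys = paired.values[lys_id].to_numpy(dtype=float)
        keep = (lys >= min_lysate) & (sn > 0)
        if not keep.any():
            raise ValueError(f"no gene passes the lysate >= {min_lysate} filter for pair {sn_id}/{lys_id}")
        ratios.append(np.log10(sn[keep] / lys[keep]))

    pooled = np.concatenate(ratios)
    edges = np.histogram_bin_edges(pooled, bins=bins)
    dens = np.vstack([np.histogram(r, bins=edges, density=True)[0] for r in ratios])
    mean = dens.mean(axis=0)
    sem = dens.std(axis=0, ddof=1) / np.sqrt(len(ratios)) if len(ratios) > 1 else np.zeros_like(mean)
    return ExportRatioResult(
        bin_edges=edges,
        densities=dens,
        mean_density=mean,
        ci_low=mean - 1.96 * sem,
        ci_high=mean + 1.96 * sem,
        log10_ratios=ratios,
        n_genes_per_pair=np.array([len(r) for r in ratios]),
    )


def detection_rate_by_quantile(
    source: CountMatrix,
    target: CountMatrix,
    n_quantiles: int = 50,
    direction: str = "desc",
    min_source_expression: float = 1.0,
) -> pd.DataFrame:
    """Detection rate in the target compartment across source-expression
    quantiles.

    Genes with mean source expression below ``min_source_expression`` are
    excluded; the rest are ranked by mean source expression (``desc`` =
    highest first), split into ``n_quantiles`` near-equal groups, and a
    gene counts as detected when its expression is > 0 in *all* target
    replicates.  Ties in expression are broken by feature id so grouping is
    deterministic.  Mitochondrial/biotype filtering is the caller's duty.
    """
    if direction not in ("desc", "asc"):
        raise ValueError("direction must be 'desc' or 'asc'")
    common = source.feature_ids.intersection(target.feature_ids)
    src = source.values.loc[common]
    tgt = target.values.loc[common]
    mean_src = src.mean(axis=1)
    keep = mean_src >= min_source_expression
    mean_src = mean_src[keep]
    detected = (tgt.loc[keep.index[keep]] > 0).all(axis=1)

    order = pd.DataFrame({"expr": mean_src}).sort_index().sort_values("expr", ascending=(direction == "asc"), kind="stable")
    groups = np.array_split(np.arange(len(order)), n_quantiles)
    rows = []
    for q, idx in enumerate(groups, start=1):
        genes = order.index[idx]
        rate = float(detected.loc[genes].mean()) * 100 if len(genes) else np.nan
        rows.append({"quantile": q, "n_genes": len(genes), "detection_rate_pct": rate})
    return pd.DataFrame(rows).set_index("quantile")


def length_binned_spearman(
    sn: CountMatrix,
    lys: CountMatrix,
    lengths,
    bin_edges,
    min_expression: float = 1.0,
) -> pd.DataFrame:
    """Spearman correlation of supernatant vs lysate abundance by length bin.

    Transcripts must exceed ``min_expression`` in *all* replicates of both
    fractions.  Within each length bin, the rank correlation is computed for
    every supernatant-replicate x lysate-replicate pair (3x3 = 9 for
    triplicates) and summarized as mean +/- sd; bins with fewer than 3
    transcripts report NaN.
    """
    if isinstance(lengths, pd.DataFrame):
        lengths = lengths["length"]
    common = sn.feature_ids.intersection(lys.feature_ids)
    lengths = pd.Series(lengths).reindex(common)
    snv = sn.values.loc[common]
    lyv = lys.values.loc[common]
    keep = (snv > min_expression).all(axis=1) & (lyv > min_expression).all(axis=1) & lengths.notna()
    snv, lyv, lengths = snv[keep], lyv[keep], lengths[keep]

    bin_edges = np.asarray(bin_edges, dtype=float)
    bin_idx = np.digitize(lengths.to_numpy(), bin_edges) - 1
    rows = []
    for b in range(len(bin_edges) - 1):
        in_bin = bin_idx == b
        n = int(in_bin.sum())
        if n < 3:
            rows.append({"bin_start": bin_edges[b], "bin_end": bin_edges[b + 1], "n_transcripts": n,
                         "mean_rho": np.nan, "sd_rho": np.nan})
            continue
        rhos = []
        for sc in snv.columns:
            for lc in lyv.columns:
                rho = sps.spearmanr(snv.loc[in_bin, sc], lyv.loc[in_bin, lc]).statistic
                rhos.append(rho)
        rows.append(
            {
                "bin_start": bin_edges[b],
                "bin_end": bin_edges[b + 1],
                "n_transcripts": n,
                "mean_rho": float(np.mean(rhos)),
                "sd_rho": float(np.std(rhos, ddof=1)),
            }
        )
    return pd.DataFrame(rows)


def cv_per_gene(matrix: CountMatrix) -> tuple[pd.Series, float]:
    """Per-gene coefficient of variation across replicates and the median.

    CV = sample sd (ddof=1) / mean; genes with mean 0 are excluded rather
    than reported as NaN.
    """
    if matrix.values.shape[1] < 2:
        raise ValueError("need at least 2 replicates for a CV")
    mean = matrix.values.mean(axis=1)
    sd = matrix.values.std(axis=1, ddof=1)
    keep = mean > 0
    cv = (sd[keep] / mean[keep]).rename("cv")
    return cv, float(cv.median())


def detection_overlap(set_a, set_b) -> dict:
    """Set overlap of detected genes: shared, exclusive counts and the
    intersection-over-union as a percentage."""
    a, b = set(set_a), set(set_b)
    union = a | b
    inter = a & b
    return {
        "both": len(inter),
        "only_a": len(a - b),
        "only_b": len(b - a),
        "iou_pct": 100.0 * len(inter) / len(union) if union else float("nan"),
    }


@dataclass
class SpikeInConfig:
    """Constants for spike-in absolute quantification.

    ``spike_mass_pg``: known mass of the spiked transcript (default 1 pg).
    ``mean_mrna_length_nt`` and ``avg_nt_mass_da`` convert mass to molecule
    counts (340 Da is the average ribonucleotide-monophosphate residue mass;
    an approximation knob).  ``divisions_during_culture`` feeds the
    cell-days integration; ``monomers_per_particle`` converts capsid-protein
    monomer counts to particle counts (2500 monomers per particle).
    """

    spike_id: str = "spikein_mGL"
    spike_mass_pg: float = 1.0
    mean_mrna_length_nt: float = 1500.0
    divisions_during_culture: int = 2
    monomers_per_particle: int = 2500
    avg_nt_mass_da: float = 340.0

    def __post_init__(self) -> None:
        for name in ("spike_mass_pg", "mean_mrna_length_nt", "monomers_per_particle", "avg_nt_mass_da"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def spikein_absolute_rna(
    fragment_counts: pd.Series,
    config: SpikeInConfig,
    seeded_cells: float | None = None,
    monomer_count: float | None = None,
) -> dict:
    """Absolute RNA quantification from a known-mass spike-in.

    ``fragment_counts`` maps transcript/gene id to fragment count for one
    sample and must include the spike-in id.  The sample's RNA mass follows
    from the spike fraction:

        sample_rna_pg = spike_mass_pg * (non-spike fragments / spike fragments)

    Molecule count uses the mean mRNA length and per-nucleotide mass.  With
    ``seeded_cells`` the per-cell-per-day export rate is computed using
    cell-days = n0 * sum(2**i for i in 0..divisions) (7 * n0 for two
    divisions, one term per culture day).  With ``monomer_count`` (capsid
    monomers measured by immunoassay) the mRNAs-per-particle figure is added.
    """
    if config.spike_id not in fragment_counts.index:
        raise ValueError(f"spike-in {config.spike_id!r} absent from the count vector")
    spike = float(fragment_counts[config.spike_id])
    if spike <= 0:
        raise ValueError("zero spike-in fragments: cannot calibrate absolute amounts")
    sample = float(fragment_counts.drop(config.spike_id).sum())
    sample_rna_pg = config.spike_mass_pg * sample / spike
    mass_per_molecule_g = config.mean_mrna_length_nt * config.avg_nt_mass_da * DALTON_G
    sample_molecules = sample_rna_pg * 1e-12 / mass_per_molecule_g
    out = {
        "spike_fragments": spike,
        "sample_fragments": sample,
        "sample_rna_pg": sample_rna_pg,
        "sample_molecules": sample_molecules,
    }
    if seeded_cells is not None:
        cell_days = seeded_cells * sum(2**i for i in range(config.divisions_during_culture + 1))
        out["cell_days"] = cell_days
        out["per_cell_per_day"] = sample_molecules / cell_days
    if monomer_count is not None:
        particles = monomer_count / config.monomers_per_particle
        out["particle_count"] = particles
        out["mrnas_per_particle"] = sample_molecules / particles
    return out


def filter_samples_by_reads(matrix: CountMatrix, min_reads: float = 1e5) -> CountMatrix:
    """Drop samples whose total read count is below ``min_reads`` (inclusive
    threshold: exactly ``min_reads`` is kept)."""
    sums = matrix.values.sum(axis=0)
    keep = sums[sums >= min_reads].index
    dropped = [s for s in matrix.sample_ids if s not in set(keep)]
    if dropped:
        warnings.warn(f"removed {len(dropped)} sample(s) below {min_reads:g} reads: {', '.join(map(str, dropped))}", stacklevel=2)
    if not len(keep):
        raise ValueError(f"no sample reaches {min_reads:g} reads; review the threshold")
    return matrix.subset_samples(list(keep))
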
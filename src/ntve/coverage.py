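"""Per-position transcript coverage, AUC normalization, and 3'-anchored
metagene profiles.

The exported (supernatant) fraction of a poly(A)-binding export system is
expected to over-represent transcript 3' ends; the lysate is approximately
uniform.  To compare compartments, the per-position depth C_ij of transcript
j is normalized per transcript by the area under its coverage curve,

    C'_ij = C_ij / sum_m C_mj ,

then rescaled by the transcript length L_j so the normalized coverage
averages exactly 1 per position.  Normalized profiles are anchored at the
transcript 3' terminus (distance 0 = last base), aggregated into fixed-width
bins up to a window upstream of the transcript end site, and averaged across
transcripts and replicates.  A per-bin supernatant/lysate ratio then shows
relative enrichment or depletion at each distance from the 3' end.

Transcripts shorter than the window contribute only to the bins they reach;
the per-position contributing-transcript count is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AlignmentRecord

__all__ = [
    "CoverageProfile",
    "MetageneProfile",
    "select_dominant_isoforms",
    "per_position_depth",
    "auc_normalize",
    "metagene_3prime",
    "coverage_ratio",
]


@dataclass
class CoverageProfile:
    """Raw (and optionally AUC-normalized) per-position depth of a transcript.

    ``depth`` has one entry per transcript position (zeros included);
    ``normalized`` is ``depth / sum(depth) * length`` and averages 1.
    """

    transcript_id: str
    length: int
    depth: np.ndarray
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if len(self.depth) != self.length:
            raise ValueError(f"{self.transcript_id}: depth has {len(self.depth)} entries for length {self.length}")
        if (self.depth < 0).any():
            raise ValueError(f"{self.transcript_id}: negative depth")


@dataclass
class MetageneProfile:
    """Binned mean normalized coverage as a function of distance upstream of
    the transcript 3' terminus (distance 0 = last transcript base)."""

    bin_edges: np.ndarray  # len n_bins + 1, in nt upstream of the 3' end
    mean_coverage: np.ndarray  # len n_bins; NaN where no transcript reaches
    n_transcripts: np.ndarray  # per *position* contributing-transcript count
    group: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "group": self.group,
                "mean_coverage": self.mean_coverage,
            }
        )


def select_dominant_isoforms(quant: pd.DataFrame, annotations: pd.DataFrame, threshold: float = 0.9) -> pd.DataFrame:
    """Map each gene to its dominant isoform, if it has one.

    A gene's dominant isoform is the transcript carrying at least
    ``threshold`` (default 90%) of the gene's summed TPM.  ``quant`` needs
    columns ``transcript_id`` and ``tpm``; the gene grouping comes from
    ``annotations`` (indexed by transcript_id, column ``gene_id``).  Genes
    with zero total TPM or no isoform reaching the threshold are absent from
    the result.  Returns a DataFrame indexed by gene_id with columns
    ``transcript_id``, ``share``, ``tpm``.
    """
    df = quant[["transcript_id", "tpm"]].copy()
    df["gene_id"] = annotations["gene_id"].reindex(df["transcript_id"]).to_numpy()
    df = df.dropna(subset=["gene_id"])
    total = df.groupby("gene_id")["tpm"].transform("sum")
    df = df[total > 0].copy()
    df["share"] = df["tpm"] / total[total > 0]
    hits = df[df["share"] >= threshold]
    # at most one isoform can hold >= 90% of a positive total when threshold > 0.5
    hits = hits.sort_values("share", ascending=False).drop_duplicates("gene_id")
    out = hits.set_index("gene_id")[["transcript_id", "share", "tpm"]]
    return out.sort_index()


def per_position_depth(
    records,
    lengths,
    transcripts=None,
):
    """Per-position read depth for each transcript.

    ``lengths`` maps transcript id to length (a dict or a Series; the
    ``length`` column of an annotation frame works).  ``transcripts``
    optionally restricts the output (e.g. the most abundant transcripts, or
    dominant isoforms); by default every transcript with a known length gets
    a profile, including all-zero ones.  Depth counts reference-consuming
    CIGAR ops (M, =, X, D, N); soft clips and insertions do not cover.
    Records referencing unknown transcripts are counted and skipped.

    Returns ``(profiles, n_unknown)`` where profiles is a dict keyed by
    transcript id.
    """
    if isinstance(lengths, pd.DataFrame):
        lengths = lengths["length"]
    lengths = dict(pd.Series(lengths).items())
    keep = set(transcripts) if transcripts is not None else set(lengths)

    # difference arrays: depth = cumsum(diff)
    diffs: dict[str, np.ndarray] = {}
    n_unknown = 0
    for rec in records:
        tid = rec.reference_name
        if tid not in lengths:
            n_unknown += 1
            continue
        if tid not in keep:
            continue
        L = int(lengths[tid])
        d = diffs.get(tid)
        if d is None:
            d = diffs[tid] = np.zeros(L + 1)
        start = rec.position - 1  # to 0-based
        pos = start
        for op, n in rec.cigar:
            if op in ("M", "=", "X", "D", "N"):
                lo = min(max(pos, 0), L)
                hi = min(pos + n, L)
                if hi > lo:
                    d[lo] += 1
                    d[hi] -= 1
                pos += n
            # I, S, H, P do not consume the reference
    profiles: dict[str, CoverageProfile] = {}
    for tid in keep:
        L = int(lengths[tid])
        d = diffs.get(tid)
        depth = np.cumsum(d[:-1]) if d is not None else np.zeros(L)
        profiles[tid] = CoverageProfile(tid, L, depth)
    return profiles, n_unknown


def auc_normalize(profile: CoverageProfile) -> CoverageProfile | None:
    """AUC-normalize a profile and rescale to transcript length.

    normalized[i] = depth[i] / sum(depth) * length, so the mean over all
    positions is exactly 1.  A profile with zero total depth cannot be
    normalized; it is excluded (returns None) with a warning rather than
    emitting NaNs.
    """
    total = profile.depth.sum()
    if total <= 0:
        warnings.warn(f"transcript {profile.transcript_id!r} has zero coverage; excluded from normalization", stacklevel=2)
        return None
    normalized = profile.depth / total * profile.length
    return CoverageProfile(profile.transcript_id, profile.length, profile.depth, normalized)


def metagene_3prime(profiles, window: int = 3000, bin_size: int = 10, group: str = "") -> MetageneProfile:
    """Aggregate normalized profiles anchored at the 3' terminus.

    ``profiles`` is an iterable of normalized :class:`CoverageProfile`
    objects (pool all replicates of one group).  Position d upstream of the
    3' end takes the value ``normalized[L - 1 - d]``; transcripts shorter
    than the window contribute only up to their length.  Values are averaged
    per position across contributing profiles and then per ``bin_size``-nt
    bin over [0, window).
    """
    if window < bin_size:
        raise ValueError(f"window ({window}) must be at least bin_size ({bin_size})")
    n_bins = window // bin_size
    window = n_bins * bin_size
    pos_sum = np.zeros(window)
    pos_n = np.zeros(window, dtype=int)
    for prof in profiles:
        if prof.normalized is None:
            raise ValueError(f"profile {prof.transcript_id!r} is not normalized; call auc_normalize first")
        m = min(prof.length, window)
        tail = prof.normalized[::-1][:m]  # index d = distance from 3' end
        pos_sum[:m] += tail
        pos_n[:m] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        pos_mean = np.where(pos_n > 0, pos_sum / np.maximum(pos_n, 1), np.nan)
    binned = pos_mean.reshape(n_bins, bin_size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        mean_cov = np.nanmean(binned, axis=1)
    edges = np.arange(n_bins + 1) * bin_size
    return MetageneProfile(edges, mean_cov, pos_n, group)


def coverage_ratio(supernatant: MetageneProfile, lysate: MetageneProfile) -> np.ndarray:
    """Per-bin supernatant/lysate mean-coverage ratio.

    Bins where the lysate mean is 0 or undefined are reported as NaN
    (undefined), never infinity.
    """
    if not np.array_equal(supernatant.bin_edges, lysate.bin_edges):
        raise ValueError("profiles have different bin structures")
    sn = supernatant.mean_coverage
    lys = lysate.mean_coverage
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where((lys > 0) & np.isfinite(lys) & np.isfinite(sn), sn / np.where(lys > 0, lys, 1.0), np.nan)
    return ratio
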
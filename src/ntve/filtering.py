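"""Read-pair quality filtering for low-input vesicle RNA-seq libraries.

Amplification-heavy, low-input library preparation produces two artifact
classes the standard aligner flags do not catch: low-complexity (repetitive
or homopolymer) reads, and reads whose alignment is fragmented into short
mapped stretches.  The filter here drops a read *pair* when either mate

* has a within-read unique k-mer fraction below a threshold (default 0.8) —
  all overlapping k-mers of the read are tabulated and the fraction of k-mer
  positions whose k-mer occurs exactly once is computed, or
* (optionally) lacks a consecutive mapped CIGAR stretch of at least 80 nt, or
* is not flagged as part of a proper pair.

Exact PCR duplicates are removed separately by matching the (mate1, mate2)
sequence pair, keeping the first occurrence.

The k-mer length is not a sharp parameter: homopolymer and low-complexity
artifacts fail the threshold at any reasonable k, so the default k = 21 (a
standard short-read k-mer size) is exposed but rarely worth changing.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import asdict, dataclass

from .io import AlignmentRecord

__all__ = [
    "KmerFilterConfig",
    "FilterReport",
    "kmer_unique_fraction",
    "longest_mapped_stretch",
    "filter_pairs",
    "dedup_pairs",
]

MAPPED_OPS = {"M", "=", "X"}


@dataclass
class KmerFilterConfig:
    k: int = 21
    min_unique_fraction: float = 0.8
    min_mapped_stretch: int = 80
    cigar_check_enabled: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be positive")
        if not 0 < self.min_unique_fraction <= 1:
            raise ValueError("min_unique_fraction must be in (0, 1]")


@dataclass
class FilterReport:
    """Pair-level accounting of the filter; one pair counts once, attributed
    to the first criterion it fails (unpaired/not-proper, then complexity,
    then mapped stretch)."""

    pairs_in: int = 0
    pairs_out: int = 0
    dropped_low_complexity: int = 0
    dropped_short_stretch: int = 0
    dropped_unpaired: int = 0
    duplicates_removed: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def kmer_unique_fraction(sequence: str, k: int) -> float:
    """Fraction of k-mer positions whose k-mer occurs exactly once in the read.

    A read shorter than k has no k-mers; it is scored 0 (and will be dropped)
    with a warning.
    """
    n_pos = len(sequence) - k + 1
    if n_pos < 1:
        warnings.warn(f"read of length {len(sequence)} shorter than k={k}; unique fraction defined as 0", stacklevel=2)
        return 0.0
    counts = Counter(sequence[i : i + k] for i in range(n_pos))
    unique_positions = sum(c for c in counts.values() if c == 1)
    return unique_positions / n_pos


def longest_mapped_stretch(cigar) -> int:
    """Longest run of consecutive reference-matched bases (ops M, =, X).

    Adjacent mapped ops merge into one stretch; any other op breaks the run.
    An empty CIGAR yields 0.
    """
    best = 0
    run = 0
    for op, length in cigar:
        if op in MAPPED_OPS:
            run += length
            best = max(best, run)
        else:
            run = 0
    return best


def _group_pairs(records):
    """Group records into (mate1, mate2) pairs by query_name, preserving the
    order of first appearance.  Groups without exactly two mates are invalid."""
    groups: dict[str, list[AlignmentRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.query_name not in groups:
            groups[rec.query_name] = []
            order.append(rec.query_name)
        groups[rec.query_name].append(rec)
    return [(name, groups[name]) for name in order]


def filter_pairs(records, config: KmerFilterConfig | None = None):
    """Apply the pair-level complexity and mapped-stretch filter.

    A pair is retained iff both mates are proper-paired, both have a unique
    k-mer fraction >= ``min_unique_fraction``, and (when the CIGAR check is
    enabled) both have a mapped stretch >= ``min_mapped_stretch``.  Both
    boundaries are inclusive on retention.  Returns ``(retained_records,
    FilterReport)``; retained records keep their input order.
    """
    config = config or KmerFilterConfig()
    report = FilterReport()
    retained: list[AlignmentRecord] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # short-read warnings are per-pair noise here
        for name, mates in _group_pairs(records):
            report.pairs_in += 1
            if len(mates) != 2 or not all(m.is_proper_pair for m in mates):
                report.dropped_unpaired += 1
                continue
            if any(kmer_unique_fraction(m.sequence, config.k) < config.min_unique_fraction for m in mates):
                report.dropped_low_complexity += 1
                continue
            if config.cigar_check_enabled and any(
                longest_mapped_stretch(m.cigar) < config.min_mapped_stretch for m in mates
            ):
                report.dropped_short_stretch += 1
                continue
            report.pairs_out += 1
            retained.extend(mates)
    return retained, report


def dedup_pairs(records):
    """Remove exact PCR duplicates: pairs with identical (mate1, mate2)
    sequences.  The first encountered pair survives; order is preserved.
    Returns ``(retained_records, n_removed)``."""
    seen: set[tuple[str, str]] = set()
    retained: list[AlignmentRecord] = []
    n_removed = 0
    for name, mates in _group_pairs(records):
        if len(mates) != 2:
            retained.extend(mates)  # dedup only defined on pairs; pass through
            continue
        m1 = next((m for m in mates if m.is_read1), mates[0])
        m2 = next((m for m in mates if not m.is_read1), mates[1])
        key = (m1.sequence, m2.sequence)
        if key in seen:
            n_removed += 1
            continue
        seen.add(key)
        retained.extend(mates)
    return retained, n_removed
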
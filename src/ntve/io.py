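"""Readers and writers for the text formats the pipeline touches.

The pipeline operates in *transcript coordinates*: reads are aligned against a
reference transcriptome, so SAM reference names are transcript ids and
positions are 1-based offsets into the transcript.  Internally all coverage
arrays are 0-based half-open; conversion happens only at the I/O boundary.

Supported formats: text SAM (header optional, bare transcript reference
names), GTF (exon features), quant.sf-style TSV quantification tables,
feature-by-sample count TSVs, and GMT gene sets.  BAM/CRAM and
genome-coordinate (spliced) alignments are out of scope.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd

__all__ = [
    "AlignmentRecord",
    "SamParseError",
    "read_sam",
    "write_sam",
    "read_gtf",
    "read_quant_table",
    "write_quant_table",
    "read_gmt",
    "CountMatrix",
]

# SAM flag bits used by the pipeline
_FLAG_PAIRED = 0x1
_FLAG_PROPER = 0x2
_FLAG_UNMAPPED = 0x4
_FLAG_READ1 = 0x40
_FLAG_READ2 = 0x80

_CIGAR_OPS = set("MIDNSHP=X")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
# ops that consume the query sequence / the reference, per the SAM standard
QUERY_OPS = set("MIS=X")
REFERENCE_OPS = set("MDN=X")


class SamParseError(ValueError):
    """Raised for malformed SAM lines; carries the 1-based line number."""


@dataclass
class AlignmentRecord:
    """One aligned read in transcript coordinates.

    ``position`` is the 1-based leftmost mapped base on the transcript;
    ``cigar`` is an ordered list of ``(op, length)`` tuples with op one of
    M, I, D, N, S, H, P, =, X.
    """

    query_name: str
    is_read1: bool
    is_proper_pair: bool
    reference_name: str
    position: int
    cigar: list[tuple[str, int]] = field(default_factory=list)
    sequence: str = ""

    def query_length(self) -> int:
        return sum(n for op, n in self.cigar if op in QUERY_OPS)

    def reference_span(self) -> int:
        """Number of reference bases consumed (for coverage)."""
        return sum(n for op, n in self.cigar if op in REFERENCE_OPS)


def parse_cigar(text: str) -> list[tuple[str, int]]:
    if text == "*":
        return []
    ops = _CIGAR_RE.findall(text)
    if "".join(f"{n}{op}" for n, op in ops) != text:
        raise ValueError(f"malformed CIGAR string: {text!r}")
    return [(op, int(n)) for n, op in ops]


def cigar_to_string(cigar: Sequence[tuple[str, int]]) -> str:
    if not cigar:
        return "*"
    return "".join(f"{n}{op}" for op, n in cigar)


def read_sam(path) -> list[AlignmentRecord]:
    """Read a text SAM file into :class:`AlignmentRecord` objects.

    Header lines are ignored (and optional).  Unmapped records (flag 0x4 set
    or reference ``*``) are skipped.  Pair linkage is recoverable via
    ``query_name``.
    """
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise SamParseError(f"line {lineno}: expected >= 11 fields, got {len(fields)}")
            try:
                flag = int(fields[1])
                pos = int(fields[3])
            except ValueError as exc:
                raise SamParseError(f"line {lineno}: non-integer flag or position") from exc
            if flag & _FLAG_UNMAPPED or fields[2] == "*":
                continue
            try:
                cigar = parse_cigar(fields[5])
            except ValueError as exc:
                raise SamParseError(f"line {lineno}: {exc}") from exc
            seq = "" if fields[9] == "*" else fields[9]
            records.append(
                AlignmentRecord(
                    query_name=fields[0],
                    is_read1=bool(flag & _FLAG_READ1) or not flag & _FLAG_READ2,
                    is_proper_pair=bool(flag & _FLAG_PROPER),
                    reference_name=fields[2],
                    position=pos,
                    cigar=cigar,
                    sequence=seq,
                )
            )
    return records


def write_sam(records: Iterable[AlignmentRecord], path, reference_lengths: Mapping[str, int] | None = None) -> None:
    """Write records as text SAM.

    When ``reference_lengths`` is given, @SQ header lines are emitted so that
    standard tools (samtools, pysam) can consume the file.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        if reference_lengths is not None:
            for name, length in reference_lengths.items():
                fh.write(f"@SQ\tSN:{name}\tLN:{int(length)}\n")
        for rec in records:
            flag = _FLAG_PAIRED
            flag |= _FLAG_READ1 if rec.is_read1 else _FLAG_READ2
            if rec.is_proper_pair:
                flag |= _FLAG_PROPER
            fh.write(
                "\t".join(
                    [
                        rec.query_name,
                        str(flag),
                        rec.reference_name,
                        str(rec.position),
                        "60",
                        cigar_to_string(rec.cigar),
                        "*",
                        "0",
                        "0",
                        rec.sequence or "*",
                        "*",
                    ]
                )
                + "\n"
            )


DEFAULT_MITO_SEQNAMES = frozenset({"MT", "chrM", "chrMT", "M"})


def read_gtf(
    path,
    mito_seqnames: Iterable[str] = DEFAULT_MITO_SEQNAMES,
    spikein_ids: Iterable[str] = (),
) -> pd.DataFrame:
    """Parse transcript annotations from a GTF file.

    Only exon features are used.  Per-transcript length is the sum of exon
    lengths (end - start + 1; GTF is 1-based inclusive).  Returns a DataFrame
    indexed by ``transcript_id`` with columns ``gene_id``, ``gene_symbol``,
    ``length``, ``biotype``, ``is_mitochondrial``, ``is_spikein``.

    Transcripts without exons (declared via a transcript feature only) are
    dropped with a warning; a transcript_id whose exons span more than one
    seqname or strand raises ``ValueError``.
    """
    mito = set(mito_seqnames)
    spike = set(spikein_ids)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        keep_order=True,
        disable_infer_transcripts=True,
        disable_infer_genes=True,
        verbose=False,
    )
    rows: dict[str, dict] = {}
    declared: set[str] = set()
    for feat in db.features_of_type("transcript"):
        declared.update(feat.attributes.get("transcript_id", []))
    for ex in db.features_of_type("exon"):
        tid = ex.attributes.get("transcript_id", [None])[0]
        if tid is None:
            raise ValueError("exon feature without transcript_id attribute")
        gid = ex.attributes.get("gene_id", [tid])[0]
        sym = (ex.attributes.get("gene_name") or ex.attributes.get("gene_symbol") or [gid])[0]
        biotype = (ex.attributes.get("gene_biotype") or ex.attributes.get("transcript_biotype") or [""])[0]
        row = rows.get(tid)
        if row is None:
            rows[tid] = {
                "gene_id": gid,
                "gene_symbol": sym,
                "length": ex.end - ex.start + 1,
                "biotype": biotype,
                "seqname": ex.seqid,
                "strand": ex.strand,
            }
        else:
            if row["seqname"] != ex.seqid or row["strand"] != ex.strand:
                raise ValueError(f"transcript {tid!r} has conflicting exon coordinates")
            row["length"] += ex.end - ex.start + 1
    for tid in sorted(declared - set(rows)):
        warnings.warn(f"transcript {tid!r} has no exon features; dropped", stacklevel=2)
    if not rows:
        return pd.DataFrame(
            columns=["gene_id", "gene_symbol", "length", "biotype", "is_mitochondrial", "is_spikein"]
        )
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "transcript_id"
    df["is_mitochondrial"] = df["seqname"].isin(mito)
    df["is_spikein"] = df.index.isin(spike)
    return df[["gene_id", "gene_symbol", "length", "biotype", "is_mitochondrial", "is_spikein"]]


DEFAULT_QUANT_COLUMNS = {"transcript_id": "Name", "length": "Length", "tpm": "TPM", "reads": "NumReads"}


def read_quant_table(path, columns: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a quant.sf-style TSV transcript quantification table.

    ``columns`` maps internal names (transcript_id, length, tpm, reads) to the
    header names in the file; the default is the Salmon quant.sf dialect.
    Returns a DataFrame with internal column names, one row per transcript.
    """
    colmap = dict(DEFAULT_QUANT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t")
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise ValueError(f"quant table is missing mandatory column(s): {', '.join(missing)}")
    out = pd.DataFrame({k: df[v] for k, v in colmap.items()})
    for col in ("length", "tpm", "reads"):
        out[col] = pd.to_numeric(out[col])
        if (out[col] < 0).any():
            bad = out.loc[out[col] < 0, "transcript_id"].iloc[0]
            raise ValueError(f"negative {col} for transcript {bad!r}")
    return out


def write_quant_table(df: pd.DataFrame, path, columns: Mapping[str, str] | None = None) -> None:
    colmap = dict(DEFAULT_QUANT_COLUMNS)
    if columns:
        colmap.update(columns)
    out = pd.DataFrame({v: df[k] for k, v in colmap.items()})
    out.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, set[str]]:
    """Read GMT gene sets: ``set-name<TAB>description<TAB>member...`` per line.

    Members are deduplicated within a set; a duplicated set name is an error.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: expected at least name and description")
            name = parts[0]
            if name in sets:
                raise ValueError(f"line {lineno}: duplicate gene set name {name!r}")
            sets[name] = set(m for m in parts[2:] if m)
    return sets


class CountMatrix:
    """Features-by-samples expression matrix with per-sample metadata.

    ``values`` is a DataFrame (rows = feature ids, columns = sample ids) of
    non-negative numbers; ``unit`` records whether they are raw counts, CPM,
    or TPM.  ``sample_meta`` is an optional DataFrame indexed by sample id
    with columns such as ``compartment`` (supernatant/lysate), ``condition``,
    ``lineage``, ``time_days`` and ``replicate``.
    """

    def __init__(self, values: pd.DataFrame, sample_meta: pd.DataFrame | None = None, unit: str = "counts"):
        values = pd.DataFrame(values)
        arr = values.to_numpy()
        if arr.size and np.nanmin(arr) < 0:
            raise ValueError("count matrix contains negative values")
        if sample_meta is not None:
            sample_meta = pd.DataFrame(sample_meta)
            if not sample_meta.index.equals(values.columns):
                sample_meta = sample_meta.reindex(values.columns)
                if sample_meta.isna().all(axis=1).any():
                    raise ValueError("sample_meta index does not match sample ids")
        self.values = values
        self.sample_meta = sample_meta
        self.unit = unit

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        meta = self.sample_meta.loc[list(sample_ids)] if self.sample_meta is not None else None
        return CountMatrix(self.values[list(sample_ids)], meta, self.unit)

    def subset_features(self, feature_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.values.loc[list(feature_ids)], self.sample_meta, self.unit)

    def samples_where(self, **criteria) -> list[str]:
        """Sample ids whose metadata match all keyword criteria."""
        if self.sample_meta is None:
            raise ValueError("no sample metadata attached")
        mask = pd.Series(True, index=self.sample_meta.index)
        for key, val in criteria.items():
            mask &= self.sample_meta[key] == val
        return list(self.sample_meta.index[mask])

    def to_tsv(self, path, meta_path=None) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature_id")
        if meta_path is not None and self.sample_meta is not None:
            self.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path, meta_path=None, unit: str = "counts") -> "CountMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0) if meta_path is not None else None
        return cls(values, meta, unit)

    def __repr__(self) -> str:
        return f"CountMatrix({self.values.shape[0]} features x {self.values.shape[1]} samples, unit={self.unit!r})"
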
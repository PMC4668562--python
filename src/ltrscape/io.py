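"""Genome and annotation I/O with a single internal coordinate convention.

All coordinates inside the package are 0-based half-open.  Conversion to
the 1-based inclusive convention of GFF3 happens only in the writer and
reader of that format, so no other module ever does coordinate arithmetic
for an external file format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")

__all__ = [
    "GenomeSequence",
    "IntervalAnnotation",
    "read_fasta",
    "write_fasta",
    "write_gff3",
    "read_gff3",
    "read_marker_map",
]


@dataclass
class GenomeSequence:
    """A named chromosome or scaffold, normalized to the {A,C,G,T,N} alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - _VALID
        if bad:
            raise ValueError(f"unnormalized residues in {self.id}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class IntervalAnnotation:
    """A located feature; start/end are 0-based half-open on seq_id."""

    seq_id: str
    start: int
    end: int
    kind: str = "region"
    strand: str = "."
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def normalize_residues(raw: str) -> tuple[str, int]:
    """Uppercase, map U->T, collapse every other non-ACGTN letter to N.

    Returns the normalized string and the number of replaced letters.
    Ambiguity codes are deliberately not preserved: downstream detection
    treats N as a universal mismatch, which is the only degeneracy an
    assembled genome with gap runs actually needs.
    """
    s = raw.upper().replace("U", "T")
    n_replaced = sum(1 for c in s if c not in _VALID)
    if n_replaced:
        s = "".join(c if c in _VALID else "N" for c in s)
    return s, n_replaced


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a multi-record FASTA into normalized GenomeSequence records.

    Duplicate record ids and empty files are hard errors; non-ACGTN
    letters are replaced by N with a logged count.
    """
    path = Path(path)
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    total_replaced = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues, n_replaced = normalize_residues(str(rec.seq))
        total_replaced += n_replaced
        records.append(GenomeSequence(rec.id, residues))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if total_replaced:
        logger.warning("replaced %d non-ACGTN residues with N in %s", total_replaced, path)
    return records


def write_fasta(sequences: list[GenomeSequence], path: str | Path, width: int = 70) -> None:
    recs = [SeqRecord(Seq(g.residues), id=g.id, description="") for g in sequences]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def write_gff3(
    annotations: list[IntervalAnnotation],
    path: str | Path,
    seq_lengths: dict[str, int] | None = None,
) -> None:
    """Emit GFF3 (1-based inclusive columns) from internal half-open intervals."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            if seq_lengths is not None:
                limit = seq_lengths.get(a.seq_id)
                if limit is not None and a.end > limit:
                    raise ValueError(
                        f"interval [{a.start},{a.end}) exceeds length {limit} of {a.seq_id}"
                    )
            attrs = ";".join(f"{k}={v}" for k, v in a.attributes.items()) or "."
            fh.write(
                f"{a.seq_id}\tltrscape\t{a.kind}\t{a.start + 1}\t{a.end}\t.\t"
                f"{a.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> list[IntervalAnnotation]:
    """Read a GFF3 file back into internal 0-based half-open intervals."""
    out: list[IntervalAnnotation] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = {}
            if cols[8] != ".":
                for item in cols[8].split(";"):
                    if item:
                        k, _, v = item.partition("=")
                        attrs[k] = v
            out.append(
                IntervalAnnotation(
                    seq_id=cols[0],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    kind=cols[2],
                    strand=cols[6],
                    attributes=attrs,
                )
            )
    return out


def read_marker_map(path: str | Path) -> pd.DataFrame:
    """Read a genetic-map marker table (chrom, bp, cM).

    Rows come back sorted by (chrom, bp); duplicate physical positions on a
    chromosome are collapsed to their mean cM.  Chromosomes with fewer than
    two markers are kept but flagged unusable for rate estimation.
    """
    df = pd.read_csv(path, sep="\t")
    expected = ["chrom", "bp", "cM"]
    if list(df.columns[:3]) != expected:
        raise ValueError(f"marker table must have columns {expected}, got {list(df.columns)}")
    df = df[expected].copy()
    df["bp"] = df["bp"].astype(float)
    df["cM"] = df["cM"].astype(float)
    if (df["bp"] < 0).any() or (df["cM"] < 0).any():
        raise ValueError("negative marker positions")
    df = (
        df.groupby(["chrom", "bp"], as_index=False)["cM"]
        .mean()
        .sort_values(["chrom", "bp"], kind="mergesort")
        .reset_index(drop=True)
    )
    counts = df.groupby("chrom")["bp"].transform("size")
    df["usable"] = counts >= 2
    return df
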
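"""Readers and writers for the standard formats used by the pipeline.

Coordinate conventions
----------------------
Internally everything is 0-based, half-open.  BED and bedGraph output keep
that convention; TSV reports and GFF3 use 1-based inclusive coordinates.

The central derived quantity is the genomic position of the nascent-RNA
3' end of each RNase-protected footprint: for a plus-strand alignment it is
the last aligned base (``end - 1``), for a minus-strand alignment the first
(``start``).  Footprint length is the aligned reference span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A file violates its format contract."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """One reference sequence (uppercase DNA alphabet)."""

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise FormatError(
                f"record {self.id!r}: illegal characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "GenomeSequence":
        return GenomeSequence(self.id, reverse_complement(self.sequence), self.circular)


@dataclass
class FeatureRecord:
    """A strand-annotated genomic feature (0-based half-open)."""

    gene_id: str
    reference_id: str
    start: int
    end: int
    strand: str
    feature_type: str = "ORF"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"{self.gene_id}: bad interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FootprintRead:
    """One RNase-protected nascent-RNA footprint."""

    reference_id: str
    strand: str
    end3: int
    length: int


class ReadSet:
    """Column-oriented container for footprint reads on one reference.

    Iterating yields :class:`FootprintRead`; the arrays are exposed for
    vectorised pileup and length-histogram work.
    """

    def __init__(self, reference_id: str, strand: np.ndarray, end3: np.ndarray,
                 length: np.ndarray):
        self.reference_id = reference_id
        self.strand = np.asarray(strand)
        self.end3 = np.asarray(end3, dtype=np.int64)
        self.length = np.asarray(length, dtype=np.int64)
        if not (len(self.strand) == len(self.end3) == len(self.length)):
            raise ValueError("column lengths differ")

    def __len__(self) -> int:
        return len(self.end3)

    def __iter__(self) -> Iterator[FootprintRead]:
        for s, e, l in zip(self.strand, self.end3, self.length):
            yield FootprintRead(self.reference_id, str(s), int(e), int(l))

    @classmethod
    def from_reads(cls, reads: Iterable[FootprintRead],
                   reference_id: str | None = None) -> "ReadSet":
        reads = list(reads)
        if reference_id is None:
            reference_id = reads[0].reference_id if reads else ""
        return cls(
            reference_id,
            np.array([r.strand for r in reads], dtype="U1"),
            np.array([r.end3 for r in reads], dtype=np.int64),
            np.array([r.length for r in reads], dtype=np.int64),
        )

    @classmethod
    def from_bed(cls, path: str | Path) -> "ReadSet":
        """Fast path for single-reference BED6 files."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["ref", "start", "end", "name", "score", "strand"],
                         dtype={"ref": str, "strand": str})
        if df.empty:
            return cls("", np.array([], dtype="U1"),
                       np.array([], dtype=np.int64), np.array([], dtype=np.int64))
        refs = df["ref"].unique()
        if len(refs) > 1:
            raise FormatError(f"ReadSet.from_bed expects one reference, got {list(refs)}")
        plus = (df["strand"] == "+").to_numpy()
        end3 = np.where(plus, df["end"].to_numpy() - 1, df["start"].to_numpy())
        return cls(str(refs[0]), df["strand"].to_numpy(dtype="U1"),
                   end3, (df["end"] - df["start"]).to_numpy())

    def to_bed(self, path: str | Path) -> None:
        start = np.where(self.strand == "+", self.end3 - self.length + 1, self.end3)
        end = start + self.length
        df = pd.DataFrame({
            "ref": self.reference_id, "start": start, "end": end,
            "name": [f"r{i}" for i in range(len(self))],
            "score": 0, "strand": self.strand,
        })
        df.to_csv(path, sep="\t", header=False, index=False)

    def subset(self, mask: np.ndarray) -> "ReadSet":
        return ReadSet(self.reference_id, self.strand[mask], self.end3[mask],
                       self.length[mask])


# ---------------------------------------------------------------------------
# FASTA

def read_genome(path: str | Path) -> dict[str, GenomeSequence]:
    """Parse a FASTA file into GenomeSequence records (order preserved).

    Sequences are upper-cased and U is mapped to T; anything outside
    {A,C,G,T,N} raises :class:`FormatError` naming the offending record.
    """
    records: dict[str, GenomeSequence] = {}
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    for rec in parsed:
        seq = str(rec.seq).upper().replace("U", "T")
        if len(seq) == 0:
            raise FormatError(f"record {rec.id!r}: empty sequence")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(f"record {rec.id!r}: illegal characters {sorted(bad)!r}")
        records[rec.id] = GenomeSequence(rec.id, seq)
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_genome(genomes: Iterable[GenomeSequence], path: str | Path,
                 width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Alignments (BED6 / SAM / BAM)

def read_alignments(path: str | Path, fmt: str | None = None,
                    stats: dict | None = None) -> Iterator[FootprintRead]:
    """Stream footprint reads from a BED6 or SAM/BAM file.

    Malformed records (missing strand, empty interval) are skipped, counted
    in ``stats['skipped']`` and logged; unmapped/secondary/supplementary SAM
    records are skipped and counted in ``stats['unaligned']``.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "bed" if suffix in (".bed", ".bed6") else "sam"
    if stats is None:
        stats = {}
    stats.setdefault("skipped", 0)
    stats.setdefault("unaligned", 0)

    if fmt == "bed":
        yield from _read_bed(path, stats)
    elif fmt == "sam":
        yield from _read_sam(path, stats)
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")
    if stats["skipped"] or stats["unaligned"]:
        log.info("%s: skipped %d malformed and %d unaligned records",
                 path, stats["skipped"], stats["unaligned"])


def _read_bed(path: Path, stats: dict) -> Iterator[FootprintRead]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                stats["skipped"] += 1
                log.warning("%s:%d: fewer than 6 BED fields", path, lineno)
                continue
            ref, start_s, end_s, _name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                stats["skipped"] += 1
                continue
            if strand not in ("+", "-") or end <= start:
                stats["skipped"] += 1
                continue
            end3 = end - 1 if strand == "+" else start
            yield FootprintRead(ref, strand, end3, end - start)


def _read_sam(path: Path, stats: dict) -> Iterator[FootprintRead]:
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                stats["unaligned"] += 1
                continue
            span = aln.reference_length  # CIGAR M/D/=/X; soft clips excluded
            if not span:
                stats["skipped"] += 1
                continue
            if aln.is_reverse:
                yield FootprintRead(aln.reference_name, "-", aln.reference_start, span)
            else:
                yield FootprintRead(aln.reference_name, "+", aln.reference_end - 1, span)


# ---------------------------------------------------------------------------
# bedGraph

def write_bedgraph(reference_id: str, counts: np.ndarray, path: str | Path) -> None:
    """Run-length encode a per-position count array (zero runs omitted)."""
    counts = np.asarray(counts)
    if counts.size and counts.min() < 0:
        raise ValueError("bedGraph counts must be nonnegative")
    with open(path, "w") as fh:
        if counts.size == 0:
            return
        boundaries = np.flatnonzero(np.diff(counts)) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [counts.size]])
        for s, e in zip(starts, ends):
            v = counts[s]
            if v != 0:
                fh.write(f"{reference_id}\t{s}\t{e}\t{v}\n")


def read_bedgraph(path: str | Path, length: int) -> np.ndarray:
    counts = np.zeros(length, dtype=np.int64)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            _ref, s, e, v = line.split("\t")
            counts[int(s):int(e)] = int(float(v))
    return counts


# ---------------------------------------------------------------------------
# GFF3 features

_GFF_TYPE_MAP = {
    "CDS": "ORF", "gene": "ORF", "ORF": "ORF",
    "five_prime_UTR": "5UTR", "three_prime_UTR": "3UTR",
    "antisense_RNA": "antisense_unit",
}


def read_features(path: str | Path) -> list[FeatureRecord]:
    """Parse GFF3 (1-based inclusive on disk -> 0-based half-open)."""
    features: list[FeatureRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            ref, _src, ftype, start, end, _score, strand, _frame, attrs = cols
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: feature without strand")
            gene_id = ""
            for kv in attrs.split(";"):
                kv = kv.strip()
                for key in ("ID=", "gene_id=", "locus_tag="):
                    if kv.startswith(key):
                        gene_id = kv[len(key):]
                        break
                if gene_id:
                    break
            features.append(FeatureRecord(
                gene_id=gene_id or f"feature_{lineno}",
                reference_id=ref,
                start=int(start) - 1,
                end=int(end),
                strand=strand,
                feature_type=_GFF_TYPE_MAP.get(ftype, "other"),
            ))
    return features


_GFF_TYPE_OUT = {"ORF": "CDS", "5UTR": "five_prime_UTR", "3UTR": "three_prime_UTR",
                 "antisense_unit": "antisense_RNA"}


def write_features(features: Iterable[FeatureRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write("\t".join([
                f.reference_id, "rnetseq", _GFF_TYPE_OUT.get(f.feature_type, "region"),
                str(f.start + 1), str(f.end), ".", f.strand, ".", f"ID={f.gene_id}",
            ]) + "\n")
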
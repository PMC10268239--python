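"""Strand-specific 3'-end pileups, pause scoring, pause calling and annotation.

The pause score of a genomic position is the fold enrichment of its 3'-end
read count over the mean count in a flanking window (focal position
excluded).  It is scale invariant: multiplying all counts by a constant
leaves every score unchanged, so scores are comparable across libraries of
different depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import FeatureRecord, FootprintRead, ReadSet

STRONG_SCORE = 50.0   # "strong pause" cutoff used in reporting
SCORE_CAP = 1e6       # serialized stand-in for an infinite score (zero flank)


@dataclass
class EndCoverage:
    """Per-strand counts of nascent-RNA 3' ends at each genomic position."""

    reference_id: str
    plus: np.ndarray
    minus: np.ndarray

    def __post_init__(self) -> None:
        self.plus = np.asarray(self.plus, dtype=np.int64)
        self.minus = np.asarray(self.minus, dtype=np.int64)
        if self.plus.shape != self.minus.shape:
            raise ValueError("strand arrays must have equal length")
        if (self.plus < 0).any() or (self.minus < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def length(self) -> int:
        return len(self.plus)

    @property
    def total_mapped(self) -> int:
        return int(self.plus.sum() + self.minus.sum())

    def counts(self, strand: str) -> np.ndarray:
        if strand == "+":
            return self.plus
        if strand == "-":
            return self.minus
        raise ValueError(f"bad strand {strand!r}")


@dataclass
class PauseSite:
    """A called pause: a position whose 3'-end count is locally enriched."""

    reference_id: str
    position: int
    strand: str
    count: int
    score: float
    strong: bool = False
    context: str = ""
    gene_id: str = ""
    dist_to_start: int | None = None

    def __post_init__(self) -> None:
        self.strong = self.score > STRONG_SCORE


def pileup_3prime_ends(reads: ReadSet | Iterable[FootprintRead],
                       reference_length: int,
                       reference_id: str | None = None) -> EndCoverage:
    """Count reads by 3'-end position, per strand."""
    if not isinstance(reads, ReadSet):
        reads = ReadSet.from_reads(reads, reference_id=reference_id)
    if reference_id is None:
        reference_id = reads.reference_id
    if len(reads) and (reads.end3.min() < 0 or reads.end3.max() >= reference_length):
        raise ValueError("read 3' end beyond reference bounds")
    is_plus = reads.strand == "+"
    plus = np.bincount(reads.end3[is_plus], minlength=reference_length)
    minus = np.bincount(reads.end3[~is_plus], minlength=reference_length)
    return EndCoverage(reference_id, plus, minus)


def compute_pause_score(coverage: EndCoverage, position: int, strand: str,
                        window_half: int = 100) -> float:
    """Fold enrichment of the focal count over the flanking-window mean.

    The window is ``position +/- window_half`` intersected with the
    reference, with the focal position excluded.  A positive focal count
    over a zero flank returns the :data:`SCORE_CAP` sentinel; a zero focal
    count scores 0.
    """
    counts = coverage.counts(strand)
    n = len(counts)
    if not 0 <= position < n:
        raise ValueError(f"position {position} out of range [0, {n})")
    lo = max(0, position - window_half)
    hi = min(n, position + window_half + 1)
    focal = float(counts[position])
    flank_n = hi - lo - 1
    if flank_n <= 0:
        raise ValueError("flanking window is empty")
    flank_mean = (counts[lo:hi].sum() - focal) / flank_n
    if focal == 0:
        return 0.0
    if flank_mean == 0:
        return SCORE_CAP
    return min(focal / flank_mean, SCORE_CAP)


def score_track(counts: np.ndarray, window_half: int = 100) -> np.ndarray:
    """Vectorised pause score at every position of one strand."""
    c = np.asarray(counts, dtype=float)
    n = len(c)
    idx = np.arange(n)
    lo = np.maximum(0, idx - window_half)
    hi = np.minimum(n, idx + window_half + 1)
    cum = np.concatenate([[0.0], np.cumsum(c)])
    flank_sum = cum[hi] - cum[lo] - c
    flank_n = hi - lo - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        flank_mean = flank_sum / flank_n
        score = np.where(c == 0, 0.0,
                         np.where(flank_mean == 0, SCORE_CAP, c / flank_mean))
    return np.minimum(score, SCORE_CAP)


def call_pauses(coverage: EndCoverage, min_score: float = 20.0,
                min_count: int = 10, cluster_radius: int = 2,
                window_half: int = 100) -> list[PauseSite]:
    """Call pause sites from a 3'-end pileup.

    Positions passing both the count and score thresholds are grouped into
    clusters of candidates closer than ``cluster_radius`` on the same
    strand; each cluster is reduced to its maximum-count position (ties
    break to the smallest coordinate).
    """
    pauses: list[PauseSite] = []
    for strand in ("+", "-"):
        counts = coverage.counts(strand)
        scores = score_track(counts, window_half)
        cand = np.flatnonzero((counts >= min_count) & (scores >= min_score))
        if cand.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(cand) >= cluster_radius) + 1
        for cluster in np.split(cand, breaks):
            best = cluster[np.argmax(counts[cluster])]  # argmax -> smallest coord on tie
            pauses.append(PauseSite(
                coverage.reference_id, int(best), strand,
                int(counts[best]), float(scores[best]),
            ))
    pauses.sort(key=lambda p: (p.position, p.strand))
    return pauses


# ---------------------------------------------------------------------------
# Annotation

_CONTEXT_PRIORITY = ("ORF", "5UTR", "3UTR")


def annotate_pauses(pauses: Sequence[PauseSite],
                    features: Sequence[FeatureRecord]) -> list[PauseSite]:
    """Attach genomic context and distance-to-start-codon to pause calls.

    A pause overlapping a same-strand feature gets that feature's type
    (ORF before UTRs when several overlap); a pause covered only by
    opposite-strand features is ``antisense``; otherwise ``intergenic``.
    ``dist_to_start`` is the signed distance, in transcription orientation,
    from the first base of the start codon of the containing (else nearest
    downstream) same-strand ORF; negative means upstream of the start.
    """
    by_strand: dict[str, list[FeatureRecord]] = {"+": [], "-": []}
    for f in features:
        by_strand[f.strand].append(f)
    orf_starts = {}  # strand -> sorted array of start-codon coordinates
    for strand, fs in by_strand.items():
        starts = [f.start if strand == "+" else f.end - 1
                  for f in fs if f.feature_type == "ORF"]
        orf_starts[strand] = np.sort(np.array(starts, dtype=np.int64))

    other = {"+": "-", "-": "+"}
    annotated = []
    for p in pauses:
        same = [f for f in by_strand[p.strand] if f.start <= p.position < f.end]
        opposite = [f for f in by_strand[other[p.strand]]
                    if f.start <= p.position < f.end]
        context = "intergenic"
        gene_id = ""
        hit = None
        for ftype in _CONTEXT_PRIORITY:
            hit = next((f for f in same if f.feature_type == ftype), None)
            if hit is not None:
                context = ftype
                gene_id = hit.gene_id
                break
        if hit is None and opposite:
            context = "antisense"
            gene_id = opposite[0].gene_id

        dist = None
        containing_orf = next((f for f in same if f.feature_type == "ORF"), None)
        if containing_orf is not None:
            start = containing_orf.start if p.strand == "+" else containing_orf.end - 1
            dist = (p.position - start) if p.strand == "+" else (start - p.position)
        else:
            starts = orf_starts[p.strand]
            if starts.size:
                if p.strand == "+":
                    i = np.searchsorted(starts, p.position, side="left")
                    if i < starts.size:
                        dist = p.position - int(starts[i])
                else:
                    i = np.searchsorted(starts, p.position, side="right") - 1
                    if i >= 0:
                        dist = int(starts[i]) - p.position
        annotated.append(PauseSite(p.reference_id, p.position, p.strand, p.count,
                                   p.score, context=context, gene_id=gene_id,
                                   dist_to_start=dist))
    return annotated


def pause_density_profile(pauses: Sequence[PauseSite],
                          features: Sequence[FeatureRecord],
                          half_window: int = 20) -> np.ndarray:
    """Pause counts per start-codon offset in ``[-half_window, half_window]``,
    normalized by the number of annotated ORFs (pauses per gene)."""
    n_orfs = sum(1 for f in features if f.feature_type == "ORF")
    if n_orfs == 0:
        raise ValueError("no annotated ORFs")
    profile = np.zeros(2 * half_window + 1)
    for p in pauses:
        if p.dist_to_start is not None and abs(p.dist_to_start) <= half_window:
            profile[p.dist_to_start + half_window] += 1
    return profile / n_orfs


def pauses_to_frame(pauses: Sequence[PauseSite]):
    """Pause table with 1-based positions, ready for TSV serialization."""
    import pandas as pd

    return pd.DataFrame({
        "reference": [p.reference_id for p in pauses],
        "position_1based": [p.position + 1 for p in pauses],
        "strand": [p.strand for p in pauses],
        "count": [p.count for p in pauses],
        "score": [p.score for p in pauses],
        "strong": [p.strong for p in pauses],
        "context": [p.context for p in pauses],
        "gene_id": [p.gene_id for p in pauses],
        "dist_to_start": [p.dist_to_start for p in pauses],
    })
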
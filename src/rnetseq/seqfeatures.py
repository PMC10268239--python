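"""Sequence context of pause sites: windows, position matrices, consensus
motif scoring, and upstream stem-loop (pause hairpin) detection.

Window offsets follow the logo convention of the field: offset -1 is the
3'-end base of the paused nascent RNA, -k is k-1 bases upstream of it, +1
is the next template-encoded base downstream; there is no offset 0.
Minus-strand windows are reverse-complemented so they read 5'->3' along
the nascent RNA.

The consensus pause motif is G at -10 and -9, a pyrimidine (C/T) at -1 and
G at +1.  Pause hairpins are perfect maximal stems (Watson-Crick pairs,
optionally G.U) closing a short loop; the hairpin-to-3'-end distance counts
the nucleotides from the 3'-most paired base to the 3'-end base (adjacent
bases are at distance 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomeSequence, reverse_complement
from .pause_calling import PauseSite

log = logging.getLogger(__name__)

_WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU_PAIRS = {("G", "T"), ("T", "G")}

CONSENSUS_ELEMENTS = {-10: "G", -9: "G", -1: "CT", 1: "G"}


@dataclass
class PauseWindow:
    """Strand-aware sequence window around one pause 3' end."""

    reference_id: str
    position: int
    strand: str
    upstream: int     # bases at offsets -upstream .. -1
    downstream: int   # bases at offsets +1 .. +downstream
    seq: str          # nascent-RNA sense, 5' -> 3'

    def base(self, offset: int) -> str:
        if offset == 0:
            raise ValueError("offset 0 does not exist")
        if offset < 0:
            if offset < -self.upstream:
                raise IndexError(f"offset {offset} outside window")
            return self.seq[self.upstream + offset]
        if offset > self.downstream:
            raise IndexError(f"offset {offset} outside window")
        return self.seq[self.upstream + offset - 1]

    @property
    def offsets(self) -> list[int]:
        return [o for o in range(-self.upstream, self.downstream + 1) if o != 0]

    @property
    def upstream_seq(self) -> str:
        """The window up to and including the 3'-end base (offset -1)."""
        return self.seq[:self.upstream]


def extract_windows(genome: GenomeSequence, pauses: Sequence[PauseSite],
                    upstream: int = 16, downstream: int = 2) -> list[PauseWindow]:
    """Extract nascent-sense windows around pause 3' ends.

    Pauses whose window would run off the reference are skipped with a
    warning (count logged).
    """
    seq = genome.sequence
    n = len(seq)
    out: list[PauseWindow] = []
    skipped = 0
    for p in pauses:
        if p.strand == "+":
            lo, hi = p.position - upstream + 1, p.position + downstream + 1
            if lo < 0 or hi > n:
                skipped += 1
                continue
            window = seq[lo:hi]
        else:
            lo, hi = p.position - downstream, p.position + upstream
            if lo < 0 or hi > n:
                skipped += 1
                continue
            window = reverse_complement(seq[lo:hi])
        out.append(PauseWindow(genome.id, p.position, p.strand,
                               upstream, downstream, window))
    if skipped:
        log.warning("%d pause windows fell outside the reference and were skipped",
                    skipped)
    return out


@dataclass
class PositionMatrix:
    """Per-offset base counts, frequencies and information content."""

    offsets: list[int]
    counts: pd.DataFrame        # index offsets, columns ACGT
    frequencies: pd.DataFrame
    information: pd.Series      # bits in [0, 2] vs uniform background

    def to_frame(self) -> pd.DataFrame:
        df = self.counts.add_prefix("n_").join(self.frequencies.add_prefix("f_"))
        df["ic_bits"] = self.information
        df.index.name = "offset"
        return df


def build_pfm(windows: Sequence[PauseWindow],
              stratify_by: dict | None = None) -> PositionMatrix | dict[str, PositionMatrix]:
    """Position frequency matrix (and IC) from aligned pause windows.

    ``stratify_by`` optionally maps (position, strand) -> stratum label
    (e.g. the pause's dominant footprint-length class); one matrix per
    non-empty stratum is returned.
    """
    if stratify_by is not None:
        strata: dict[str, list[PauseWindow]] = {}
        for w in windows:
            label = stratify_by.get((w.position, w.strand))
            if label is not None:
                strata.setdefault(label, []).append(w)
        out = {}
        for label, ws in strata.items():
            if ws:
                out[label] = build_pfm(ws)
            else:
                log.warning("stratum %r empty, dropped", label)
        return out

    if not windows:
        raise ValueError("need at least one window")
    offsets = windows[0].offsets
    bases = ["A", "C", "G", "T"]
    counts = pd.DataFrame(0, index=offsets, columns=bases)
    for w in windows:
        if w.offsets != offsets:
            raise ValueError("windows have inconsistent spans")
        for o in offsets:
            b = w.base(o)
            if b in counts.columns:
                counts.loc[o, b] += 1
    totals = counts.sum(axis=1)
    freqs = counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = freqs * np.log2(freqs.where(freqs > 0, 1.0))
    ic = 2.0 + plogp.sum(axis=1)
    return PositionMatrix(offsets, counts, freqs, ic)


def consensus_match(window: PauseWindow) -> tuple[int, dict[int, bool]]:
    """Score a window against the consensus pause motif (one point per
    matching element: -10G, -9G, -1Y, +1G)."""
    if window.upstream < 10 or window.downstream < 1:
        raise ValueError("window must cover offsets -10 .. +1")
    hits = {off: window.base(off) in allowed
            for off, allowed in CONSENSUS_ELEMENTS.items()}
    return sum(hits.values()), hits


# ---------------------------------------------------------------------------
# Hairpins

@dataclass(frozen=True)
class HairpinCall:
    """A perfect maximal stem-loop within a nascent-sense sequence."""

    arm5_start: int    # index of the first paired base of the 5' arm
    stem_length: int
    loop_length: int
    arm3_end: int      # index of the 3'-most paired base
    distance: int      # nt from arm3_end to the sequence 3' end (adjacent = 1)


def _pairs(a: str, b: str, allow_GU: bool) -> bool:
    return (a, b) in _WC_PAIRS or (allow_GU and (a, b) in _GU_PAIRS)


def find_hairpins(seq: str, stem_min: int = 5, loop_range: tuple[int, int] = (3, 8),
                  allow_GU: bool = True) -> list[HairpinCall]:
    """Exhaustively enumerate perfect maximal stem-loops.

    A candidate is (arm5_start i, stem s >= stem_min, loop l in range) with
    every stem pair complementary (Watson-Crick, or G.U when enabled).  Only
    maximal stems are reported: not extendable outward (flanking bases
    non-pairing or at a boundary) nor inward (the loop-flanking bases pair
    and the shrunken loop would still be a legal loop).
    """
    seq = seq.upper()
    n = len(seq)
    loop_min, loop_max = loop_range
    calls: list[HairpinCall] = []
    for loop in range(loop_min, loop_max + 1):
        for i in range(n):
            # longest run of pairs closing this loop, starting outward from i
            max_stem = (n - i - loop) // 2
            for s in range(stem_min, max_stem + 1):
                j = i + 2 * s + loop - 1  # index of 3'-most paired base
                ok = all(_pairs(seq[i + k], seq[j - k], allow_GU) for k in range(s))
                if not ok:
                    continue
                # outward extension
                if i > 0 and j + 1 < n and _pairs(seq[i - 1], seq[j + 1], allow_GU):
                    continue
                # inward extension (only if the shrunken loop stays legal)
                if loop - 2 >= loop_min and _pairs(seq[i + s], seq[i + s + loop - 1],
                                                   allow_GU):
                    continue
                calls.append(HairpinCall(i, s, loop, j, (n - 1) - j))
    calls.sort(key=lambda h: (h.arm5_start, h.loop_length, h.stem_length))
    return calls


def scramble(seq: str, rng: np.random.Generator) -> str:
    """Composition-preserving base shuffle."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    rng.shuffle(arr)
    return arr.tobytes().decode()


def hairpin_distance_profile(sequences: Sequence[str], stem_min: int = 5,
                             loop_range: tuple[int, int] = (3, 8),
                             allow_GU: bool = True, scramble_n: int = 1,
                             seed: int | None = None) -> pd.DataFrame:
    """Hairpin counts per hairpin-to-3'-end distance, for the real sequences
    and for composition-preserving scrambled controls.

    All sequences must share the same 3'-end anchoring (their last base is
    the pause 3' end).  Returns a frame indexed by distance with columns
    ``real_count``, ``scrambled_mean`` and ``enrichment``.
    """
    if scramble_n < 1:
        raise ValueError("scramble_n must be >= 1")
    rng = np.random.default_rng(seed)
    max_d = max((len(s) for s in sequences), default=0)
    real = np.zeros(max_d, dtype=float)
    for s in sequences:
        for h in find_hairpins(s, stem_min, loop_range, allow_GU):
            real[h.distance] += 1
    scram = np.zeros(max_d, dtype=float)
    for _ in range(scramble_n):
        for s in sequences:
            for h in find_hairpins(scramble(s, rng), stem_min, loop_range, allow_GU):
                scram[h.distance] += 1
    scram /= scramble_n
    with np.errstate(divide="ignore", invalid="ignore"):
        enrich = np.where(scram > 0, real / scram, np.nan)
    df = pd.DataFrame({"real_count": real, "scrambled_mean": scram,
                       "enrichment": enrich})
    df.index.name = "distance"
    return df
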
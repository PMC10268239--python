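"""Translocation-register inference from footprint-length distributions.

The length of the RNase-protected nascent-RNA footprint reports the
translocation register of the paused polymerase: 16-17 nt post-translocated,
18 nt pre-translocated, >18 nt backtracked (the 3' end has been extruded).
Lengths below 16 nt are degraded sub-footprints and are kept as a separate
bin so they cannot silently inflate either register fraction.

A pause is called ``backtracked`` when its >18-nt read fraction exceeds
0.5 and ``nonbacktracked`` below 0.2 (strict inequalities; the boundary
values fall into ``intermediate``).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ReadSet

BACKTRACKED_MIN_FRAC = 0.5
NONBACKTRACKED_MAX_FRAC = 0.2

POST_LENGTHS = (16, 17)
PRE_LENGTH = 18


@dataclass
class RegisterCall:
    n_reads: int
    frac_sub: float
    frac_post: float
    frac_pre: float
    frac_backtracked: float
    mean_backtrack_depth: float  # mean of (length - 18) over lengths > 18; NaN if none
    backtrack_class: str


def length_histogram(reads: ReadSet, position: int, strand: str) -> Counter:
    """Footprint-length histogram of the reads whose 3' end is exactly at
    (position, strand); reads elsewhere are ignored."""
    mask = (reads.end3 == position) & (reads.strand == strand)
    if not mask.any():
        raise ValueError(f"no reads at called pause {strand}{position}")
    return Counter(reads.length[mask].tolist())


def length_histograms(reads: ReadSet,
                      sites: Iterable[tuple[int, str]]) -> dict[tuple[int, str], Counter]:
    """One-pass length histograms for many (position, strand) sites."""
    sites = set(sites)
    out: dict[tuple[int, str], Counter] = {}
    df = pd.DataFrame({"end3": reads.end3, "strand": reads.strand,
                       "length": reads.length})
    for (pos, strand), grp in df.groupby(["end3", "strand"], sort=False):
        key = (int(pos), str(strand))
        if key in sites:
            out[key] = Counter(grp["length"].tolist())
    return out


def register_fractions(hist: Mapping[int, int]) -> RegisterCall:
    """Register fractions (sub / post / pre / backtracked) from a length
    histogram; the four fractions sum to 1."""
    total = sum(hist.values())
    if total <= 0:
        raise ValueError("empty length histogram")
    sub = sum(c for l, c in hist.items() if l < POST_LENGTHS[0])
    post = sum(c for l, c in hist.items() if l in POST_LENGTHS)
    pre = hist.get(PRE_LENGTH, 0)
    long_items = [(l, c) for l, c in hist.items() if l > PRE_LENGTH]
    bt = sum(c for _, c in long_items)
    depth = (sum((l - PRE_LENGTH) * c for l, c in long_items) / bt
             if bt else float("nan"))
    frac_bt = bt / total
    return RegisterCall(
        n_reads=total,
        frac_sub=sub / total, frac_post=post / total,
        frac_pre=pre / total, frac_backtracked=frac_bt,
        mean_backtrack_depth=depth,
        backtrack_class=classify_backtracked(frac_bt),
    )


def classify_backtracked(frac_backtracked: float) -> str:
    if not 0 <= frac_backtracked <= 1:
        raise ValueError("fraction out of [0, 1]")
    if frac_backtracked > BACKTRACKED_MIN_FRAC:
        return "backtracked"
    if frac_backtracked < NONBACKTRACKED_MAX_FRAC:
        return "nonbacktracked"
    return "intermediate"


def cumulative_long_fraction(fractions: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF of the backtracked (>18 nt) read fraction across pauses.

    Returns (sorted fractions, cumulative probabilities); two conditions can
    be overlaid by calling this once per pause set.
    """
    x = np.sort(np.asarray(fractions, dtype=float))
    if x.size == 0:
        raise ValueError("need at least one pause")
    return x, np.arange(1, x.size + 1) / x.size


def group_by_backtrack_change(frac_wt: Sequence[float], frac_dep: Sequence[float],
                              delta_threshold: float = 0.1) -> np.ndarray:
    """Group pauses by the change in backtracked fraction upon depletion.

    delta = frac_backtracked(depleted) - frac_backtracked(WT); ``positive``
    when delta > threshold, ``negative`` when delta < -threshold, else
    ``negligible`` (boundaries inclusive into negligible).
    """
    fw = np.asarray(frac_wt, dtype=float)
    fd = np.asarray(frac_dep, dtype=float)
    if fw.shape != fd.shape:
        raise ValueError("condition arrays must align")
    if np.isnan(fw).any() or np.isnan(fd).any():
        raise ValueError("missing register call in a condition")
    delta = fd - fw
    out = np.full(delta.shape, "negligible", dtype="U10")
    out[delta > delta_threshold] = "positive"
    out[delta < -delta_threshold] = "negative"
    return out


def register_table(reads: ReadSet, sites: Sequence[tuple[int, str]]) -> pd.DataFrame:
    """Register calls for many pauses as a 1-based TSV-ready table."""
    hists = length_histograms(reads, sites)
    rows = []
    for pos, strand in sites:
        h = hists.get((pos, strand))
        if h is None:
            continue
        rc = register_fractions(h)
        rows.append({
            "position_1based": pos + 1, "strand": strand, "n_reads": rc.n_reads,
            "frac_sub": rc.frac_sub, "frac_post": rc.frac_post,
            "frac_pre": rc.frac_pre, "frac_backtracked": rc.frac_backtracked,
            "mean_backtrack_depth": rc.mean_backtrack_depth,
            "backtrack_class": rc.backtrack_class,
        })
    return pd.DataFrame(rows, columns=[
        "position_1based", "strand", "n_reads", "frac_sub", "frac_post", "frac_pre",
        "frac_backtracked", "mean_backtrack_depth", "backtrack_class"])
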
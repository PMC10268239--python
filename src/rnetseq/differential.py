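"""Condition-paired pause analysis: TPM normalization, matching, log2FC and
NusG-class assignment.

Differential pause strength (log2FC-Pause-TPM) is the log2 fold change,
between the depleted and WT conditions, of the pause score normalized to
the transcript abundance (TPM) of the gene carrying the pause.  Classes:

* ``suppressed``   log2FC > 2        (at least fourfold increase)
* ``independent``  -1.5 <= log2FC <= 1.5
* ``stimulated``   log2FC < -1.5     (more than 2.8-fold decrease)
* ``unassigned``   1.5 < log2FC <= 2 (the printed intervals leave a gap)
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import FeatureRecord
from .pause_calling import EndCoverage, PauseSite, compute_pause_score

log = logging.getLogger(__name__)

SUPPRESSED_MIN_LOG2FC = 2.0
INDEPENDENT_BAND = 1.5


def compute_tpm(coverage: EndCoverage, features: Sequence[FeatureRecord],
                exclude: Sequence[tuple[str, int]] | None = None) -> dict[str, float]:
    """Transcripts-per-million per gene from same-strand 3'-end counts.

    ``exclude`` optionally lists (strand, position) pairs — typically the
    pause positions under study — to omit from the gene counts, so that a
    pause's abundance normalizer is not dominated by the pause's own reads.
    """
    if not features:
        raise ValueError("no features")
    masked = {"+": coverage.plus, "-": coverage.minus}
    excluded = {"+": np.zeros(coverage.length, dtype=bool),
                "-": np.zeros(coverage.length, dtype=bool)}
    if exclude:
        masked = {s: arr.copy() for s, arr in masked.items()}
        for strand, pos in exclude:
            masked[strand][pos] = 0
            excluded[strand][pos] = True
    rates = {}
    for f in features:
        counts = masked[f.strand][f.start:f.end].sum()
        # excluded positions leave the denominator too: the rate is
        # estimated from the gene's non-pause positions only
        eff_len = f.length - int(excluded[f.strand][f.start:f.end].sum())
        rates[f.gene_id] = counts / eff_len if eff_len > 0 else 0.0
    total = sum(rates.values())
    if total == 0:
        log.warning("all-zero coverage: TPM undefined, returning zeros")
        return {g: 0.0 for g in rates}
    return {g: 1e6 * r / total for g, r in rates.items()}


def match_pause_sets(pauses_wt: Sequence[PauseSite], pauses_dep: Sequence[PauseSite],
                     coverage_wt: EndCoverage | None = None,
                     coverage_dep: EndCoverage | None = None,
                     union: bool = True, window_half: int = 100,
                     tolerance: int = 0) -> pd.DataFrame:
    """Match pause calls across conditions on exact (strand, position).

    In union mode, a pause called in only one condition is re-quantified
    (count and score) from the other condition's coverage, which must then
    be supplied.  ``tolerance`` > 0 additionally accepts the nearest call
    within that many nt (off by default: single-nt matching is the method's
    resolution).
    """
    def key(p: PauseSite) -> tuple[str, int]:
        return (p.strand, p.position)

    wt = {key(p): p for p in pauses_wt}
    dep = {key(p): p for p in pauses_dep}

    def find(d: dict, k: tuple[str, int]) -> PauseSite | None:
        if k in d:
            return d[k]
        for delta in range(1, tolerance + 1):
            for cand in ((k[0], k[1] - delta), (k[0], k[1] + delta)):
                if cand in d:
                    return d[cand]
        return None

    rows = []
    for k in sorted(set(wt) | set(dep)):
        pw, pdp = find(wt, k), find(dep, k)
        shared = pw is not None and pdp is not None
        if not union and not shared:
            continue
        strand, pos = k
        if pw is None:
            if coverage_wt is None:
                raise ValueError("union mode needs coverage_wt to re-quantify")
            count_wt = int(coverage_wt.counts(strand)[pos])
            score_wt = compute_pause_score(coverage_wt, pos, strand, window_half)
        else:
            count_wt, score_wt = pw.count, pw.score
        if pdp is None:
            if coverage_dep is None:
                raise ValueError("union mode needs coverage_dep to re-quantify")
            count_dep = int(coverage_dep.counts(strand)[pos])
            score_dep = compute_pause_score(coverage_dep, pos, strand, window_half)
        else:
            count_dep, score_dep = pdp.count, pdp.score
        src = pw if pw is not None else pdp
        rows.append({
            "position": pos, "strand": strand,
            "count_wt": count_wt, "count_dep": count_dep,
            "score_wt": score_wt, "score_dep": score_dep,
            "gene_id": src.gene_id, "context": src.context,
            "shared": shared,
        })
    return pd.DataFrame(rows, columns=["position", "strand", "count_wt", "count_dep",
                                       "score_wt", "score_dep", "gene_id", "context",
                                       "shared"])


def log2fc_pause_tpm(score_wt: float, score_dep: float, tpm_wt: float,
                     tpm_dep: float, pseudocount: float = 1.0) -> float:
    """log2 of the TPM-normalized pause-score ratio, regularized to stay
    finite at zero counts (pseudocount added to every term)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    e = pseudocount
    return float(np.log2(((score_dep + e) / (tpm_dep + e))
                         / ((score_wt + e) / (tpm_wt + e))))


def classify_pause(log2fc: float) -> str:
    """Assign the NusG class from the printed log2FC intervals (the
    (1.5, 2] gap is reported as ``unassigned``, never merged)."""
    if not np.isfinite(log2fc):
        raise ValueError("log2fc must be finite")
    if log2fc > SUPPRESSED_MIN_LOG2FC:
        return "suppressed"
    if log2fc < -INDEPENDENT_BAND:
        return "stimulated"
    if log2fc <= INDEPENDENT_BAND:
        return "independent"
    return "unassigned"


def differential_table(matched: pd.DataFrame, tpm_wt: dict[str, float],
                       tpm_dep: dict[str, float],
                       pseudocount: float = 1.0) -> pd.DataFrame:
    """Complete the matched table with TPMs, log2FC-Pause-TPM and class."""
    df = matched.copy()
    df["tpm_wt"] = [tpm_wt.get(g, 0.0) for g in df["gene_id"]]
    df["tpm_dep"] = [tpm_dep.get(g, 0.0) for g in df["gene_id"]]
    df["log2fc"] = [
        log2fc_pause_tpm(r.score_wt, r.score_dep, r.tpm_wt, r.tpm_dep, pseudocount)
        for r in df.itertuples()
    ]
    df["pause_class"] = df["log2fc"].map(classify_pause)
    return df
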
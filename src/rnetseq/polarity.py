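"""Transcriptional polarity: 5'->3' decline of nascent-transcript coverage.

Premature (classically Rho-dependent) termination depletes 3'-end coverage
toward the ends of genes.  The per-gene statistic here is the ratio of mean
coverage in the 3' half to mean coverage in the 5' half (in transcription
orientation); a genome-wide view is given by a length-scaled metagene
profile.  Both are scale free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import FeatureRecord
from .pause_calling import EndCoverage


@dataclass
class PolarityRecord:
    gene_id: str
    mean_cov_5half: float
    mean_cov_3half: float
    polarity_index: float   # 3'-half mean / 5'-half mean; NaN when undefined
    log2_index: float
    n_positions: int
    defined: bool


def _gene_profile(coverage: EndCoverage, gene: FeatureRecord) -> np.ndarray:
    """Per-position 3'-end counts in transcription orientation."""
    arr = coverage.counts(gene.strand)[gene.start:gene.end].astype(float)
    return arr if gene.strand == "+" else arr[::-1]


def polarity_index(coverage: EndCoverage, gene: FeatureRecord) -> PolarityRecord:
    """Ratio of 3'-half to 5'-half mean coverage for one gene.

    The gene is split at its midpoint in transcription orientation (odd
    lengths put the middle base in the 5' half).  A zero 5'-half mean makes
    the index undefined; the record is flagged and excluded from aggregates.
    """
    if gene.length < 2:
        raise ValueError(f"{gene.gene_id}: gene too short for halves")
    prof = _gene_profile(coverage, gene)
    n5 = (len(prof) + 1) // 2
    m5 = float(prof[:n5].mean())
    m3 = float(prof[n5:].mean())
    defined = m5 > 0
    idx = m3 / m5 if defined else float("nan")
    return PolarityRecord(gene.gene_id, m5, m3, idx,
                          float(np.log2(idx)) if defined and idx > 0 else float("nan"),
                          len(prof), defined)


def polarity_table(coverage: EndCoverage,
                   features: Sequence[FeatureRecord]) -> pd.DataFrame:
    recs = [polarity_index(coverage, f) for f in features if f.length >= 2]
    return pd.DataFrame({
        "gene_id": [r.gene_id for r in recs],
        "mean_cov_5half": [r.mean_cov_5half for r in recs],
        "mean_cov_3half": [r.mean_cov_3half for r in recs],
        "polarity_index": [r.polarity_index for r in recs],
        "log2_index": [r.log2_index for r in recs],
        "n_positions": [r.n_positions for r in recs],
        "defined": [r.defined for r in recs],
    })


def metagene_profile(coverage: EndCoverage, features: Sequence[FeatureRecord],
                     n_bins: int = 50) -> np.ndarray:
    """Mean length-scaled coverage profile across genes.

    Each gene's oriented coverage is averaged into ``n_bins`` equal-width
    bins of scaled gene length and normalized to the gene's own mean, then
    averaged across genes (genes with zero coverage are skipped).
    """
    profiles = []
    for gene in features:
        if gene.length < n_bins:
            continue
        prof = _gene_profile(coverage, gene)
        mean = prof.mean()
        if mean == 0:
            continue
        edges = np.linspace(0, len(prof), n_bins + 1).astype(int)
        binned = np.array([prof[edges[i]:edges[i + 1]].mean() for i in range(n_bins)])
        profiles.append(binned / mean)
    if not profiles:
        raise ValueError("no usable genes for metagene profile")
    return np.mean(profiles, axis=0)
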
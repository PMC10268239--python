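"""Ground-truth simulator: genomes, annotations and condition-paired reads.

The generator emulates the statistical structure of an RNET-seq experiment
on a NusG-depletion pair:

* pause enrichment weights drawn from an exponential law, so the downstream
  score histogram has the negative-exponential tail the score-distribution
  model expects;
* per-class condition effects (suppressed pauses gain weight upon
  depletion, stimulated pauses lose it, independent pauses are unchanged);
* per-pause footprint-length mixtures over the translocation registers
  (post-translocated 16-17 nt, pre-translocated 18 nt, backtracked >18 nt
  with a geometric tail);
* optionally planted consensus pause motifs (G at -10 and -9, a pyrimidine
  at -1, G at +1) and perfect upstream stem-loops at a controlled
  hairpin-to-3'-end distance.

Defaults are a scaled-down E. coli experiment: a 1 Mb genome at 51% GC
carrying 500 non-overlapping ORFs, 1,000 pauses whose class mixture matches
the 1971/1662/201 suppressed/independent/stimulated proportions, and
2 x 10^6 footprints per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import FeatureRecord, GenomeSequence, ReadSet

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimConfig:
    """Simulation parameters (defaults are the package's study conditions)."""

    seed: int = 0
    genome_length: int = 1_000_000
    gc_fraction: float = 0.51
    n_genes: int = 500
    n_pauses: int = 1000
    # suppressed / independent / stimulated proportions (1971/1662/201)
    class_mixture: tuple[float, float, float] = (0.514, 0.434, 0.052)
    effect_log2fc: dict = field(default_factory=lambda: {
        "suppressed": 2.5, "independent": 0.0, "stimulated": -2.5})
    base_strength_rate: float = 0.02          # exponential rate of pause weights
    register_mixture: tuple[float, float, float] = (0.45, 0.35, 0.20)  # post/pre/backtracked
    register_concentration: float = 8.0       # Dirichlet spread of per-pause mixtures
    backtrack_tail_p: float = 0.5             # geometric tail of lengths > 18 nt
    hairpin_fraction: float = 0.3
    hairpin_distance_range: tuple[int, int] = (11, 13)
    consensus_fraction: float = 0.6
    depth_per_condition: int = 2_000_000
    min_pause_spacing: int = 250              # keeps scoring windows disjoint
    reference_id: str = "simchr"

    def __post_init__(self) -> None:
        if abs(sum(self.class_mixture) - 1) > 1e-6:
            raise ValueError("class_mixture must sum to 1")
        if abs(sum(self.register_mixture) - 1) > 1e-6:
            raise ValueError("register_mixture must sum to 1")
        if self.base_strength_rate <= 0 or self.depth_per_condition <= 0:
            raise ValueError("rates and depths must be positive")
        if not 0 < self.backtrack_tail_p <= 1:
            raise ValueError("backtrack_tail_p must be in (0, 1]")


CLASSES = ("suppressed", "independent", "stimulated")

HAIRPIN_STEM = 6
HAIRPIN_LOOP = 4


def _offset_to_genomic(position: int, strand: str, off: int) -> int:
    """Genomic coordinate of a pause-window offset.

    Offsets follow the logo convention: -1 is the 3'-end base, -k is k-1
    bases upstream of it, +1 the next downstream base (no offset 0).
    """
    if off == 0:
        raise ValueError("offset 0 does not exist")
    delta = off + 1 if off < 0 else off  # -1 -> 0, -k -> -(k-1), +k -> +k
    return position + delta if strand == "+" else position - delta


def _plant(genome_arr: list, position: int, strand: str, last_offset: int,
           subseq: str) -> None:
    """Plant a nascent-sense subsequence whose 3'-most base sits at
    ``last_offset`` in the pause window (strand-aware, complementing on -).

    ``last_offset`` and all covered offsets must be on one side of the
    (nonexistent) offset 0.
    """
    for i, base in enumerate(subseq):
        off = last_offset - (len(subseq) - 1 - i)
        g = _offset_to_genomic(position, strand, off)
        genome_arr[g] = base if strand == "+" else _COMP[base]


def simulate_genome(config: SimConfig):
    """Generate a genome, its ORF annotation and the planted-pause truth.

    Returns ``(GenomeSequence, list[FeatureRecord], pandas.DataFrame)``.
    The truth table has one row per planted pause with its class, planted
    excess weight per condition, register mixture, hairpin distance and
    consensus-motif flag.
    """
    rng = np.random.default_rng(config.seed)
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    genome = rng.choice(list("ACGT"), size=config.genome_length, p=probs)

    # --- genes: non-overlapping ORFs with explicit start/stop codons
    features: list[FeatureRecord] = []
    pos = int(rng.integers(50, 200))
    for i in range(config.n_genes):
        length = int(rng.integers(200, 501)) * 3
        if pos + length + 60 > config.genome_length:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = pos, pos + length
        if strand == "+":
            genome[start:start + 3] = list("ATG")
            genome[end - 3:end] = list("TAA")
        else:
            genome[end - 3:end] = list("CAT")    # revcomp ATG
            genome[start:start + 3] = list("TTA")  # revcomp TAA
        features.append(FeatureRecord(f"gene{i:04d}", config.reference_id,
                                      start, end, strand, "ORF"))
        pos = end + int(rng.integers(100, 401))

    # --- candidate pause positions: inside genes, away from edges, spaced
    margin = 50
    candidates: list[tuple[int, str, str]] = []
    for f in features:
        lo, hi = f.start + margin, f.end - 10
        p = lo
        while p < hi:
            candidates.append((p, f.strand, f.gene_id))
            p += config.min_pause_spacing
    if len(candidates) < config.n_pauses:
        raise ValueError(
            f"pauses requested ({config.n_pauses}) exceed genome capacity "
            f"({len(candidates)} candidate sites)")
    chosen = rng.choice(len(candidates), size=config.n_pauses, replace=False)
    chosen.sort()

    # --- per-pause truth
    n = config.n_pauses
    class_counts = rng.multinomial(n, config.class_mixture)
    labels = np.repeat(CLASSES, class_counts)
    rng.shuffle(labels)
    weights = rng.exponential(1.0 / config.base_strength_rate, size=n)
    mixtures = rng.dirichlet(
        config.register_concentration * np.asarray(config.register_mixture), size=n)
    has_hairpin = rng.random(n) < config.hairpin_fraction
    hp_lo, hp_hi = config.hairpin_distance_range
    hairpin_dist = rng.integers(hp_lo, hp_hi + 1, size=n)
    has_consensus = rng.random(n) < config.consensus_fraction

    genome_list = genome.tolist()
    rows = []
    for k, ci in enumerate(chosen):
        position, strand, gene_id = candidates[ci]
        label = labels[k]
        effect = config.effect_log2fc[label]
        w = weights[k]
        w_dep = w * 2.0 ** effect  # effect is 0 for independent pauses
        if has_consensus[k]:
            _plant(genome_list, position, strand, -9, "GG")     # -10G, -9G
            y = "C" if rng.random() < 0.5 else "T"
            _plant(genome_list, position, strand, -1, y)        # -1Y
            _plant(genome_list, position, strand, +1, "G")      # +1G
        dist = -1
        if has_hairpin[k]:
            dist = int(hairpin_dist[k])
            stem = "".join(rng.choice(list("ACGT"), size=HAIRPIN_STEM,
                                      p=[0.15, 0.35, 0.35, 0.15]))
            loop = "".join(rng.choice(list("AT"), size=HAIRPIN_LOOP))
            rc = "".join(_COMP[b] for b in reversed(stem))
            # 3'-most paired base `dist` nt upstream of the 3' end
            _plant(genome_list, position, strand, -(dist + 1), stem + loop + rc)
        rows.append({
            "position": position, "strand": strand, "gene_id": gene_id,
            "pause_class": label, "weight": w, "weight_wt": w, "weight_dep": w_dep,
            "frac_post": mixtures[k, 0], "frac_pre": mixtures[k, 1],
            "frac_backtracked": mixtures[k, 2],
            "hairpin": bool(has_hairpin[k]), "hairpin_distance": dist,
            "consensus": bool(has_consensus[k]),
        })

    truth = pd.DataFrame(rows)
    seq = GenomeSequence(config.reference_id, "".join(genome_list))
    return seq, features, truth


def _sample_lengths(rng: np.random.Generator, n: int,
                    mixture: np.ndarray, tail_p: float) -> np.ndarray:
    """Draw footprint lengths from a (post, pre, backtracked) mixture."""
    cat = rng.choice(3, size=n, p=mixture)
    lengths = np.full(n, 18, dtype=np.int64)
    post = cat == 0
    lengths[post] = rng.integers(16, 18, size=int(post.sum()))
    bt = cat == 2
    lengths[bt] = 18 + rng.geometric(tail_p, size=int(bt.sum()))
    return lengths


def simulate_reads(truth: pd.DataFrame, condition: str, config: SimConfig,
                   seed: int) -> ReadSet:
    """Draw ``depth_per_condition`` footprints for one condition.

    3'-end positions are multinomial over all (position, strand) cells with
    weight 1 at background cells and ``1 + w * 2**effect`` at planted
    pauses; footprint lengths come from the pause's register mixture at
    pause cells and from the genome-wide default mixture elsewhere.
    """
    if condition not in ("WT", "depleted"):
        raise ValueError("condition must be 'WT' or 'depleted'")
    if config.depth_per_condition <= 0:
        raise ValueError("zero depth")
    rng = np.random.default_rng(seed)
    L = config.genome_length
    weights = np.ones(2 * L)  # [plus | minus]
    wcol = "weight_wt" if condition == "WT" else "weight_dep"
    pause_cell = {}
    for row in truth.itertuples():
        cell = row.position + (0 if row.strand == "+" else L)
        weights[cell] += getattr(row, wcol)
        pause_cell[cell] = (np.array([row.frac_post, row.frac_pre,
                                      row.frac_backtracked]))
    counts = rng.multinomial(config.depth_per_condition, weights / weights.sum())
    cells = np.flatnonzero(counts)
    end3_cells = np.repeat(cells, counts[cells])

    default_mix = np.asarray(config.register_mixture, dtype=float)
    lengths = _sample_lengths(rng, len(end3_cells), default_mix,
                              config.backtrack_tail_p)
    # overwrite lengths of pause reads with the pause's own mixture
    for cell, mix in pause_cell.items():
        lo = np.searchsorted(end3_cells, cell, side="left")
        hi = np.searchsorted(end3_cells, cell, side="right")
        if hi > lo:
            lengths[lo:hi] = _sample_lengths(rng, hi - lo, mix / mix.sum(),
                                             config.backtrack_tail_p)

    plus = end3_cells < L
    end3 = np.where(plus, end3_cells, end3_cells - L)
    strand = np.where(plus, "+", "-").astype("U1")
    # clip footprints protruding past the reference ends
    avail = np.where(plus, end3 + 1, L - end3)
    lengths = np.minimum(lengths, avail)
    return ReadSet(config.reference_id, strand, end3, lengths)
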
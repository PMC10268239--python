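# Methods

This note documents the models and procedures implemented in `rnetseq`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the simulator does and does not emulate.

## Footprints and coordinates

A footprint read carries a reference, strand, the genomic coordinate of the
nascent-RNA 3' end (0-based) and the footprint length.  For a plus-strand
alignment the 3' end is the last aligned base (`end − 1` of the half-open
interval); for minus-strand the first (`start`).  From SAM input the
footprint length is the aligned reference span (CIGAR M/D/=/X), not the
query length — soft-clipped bases were never protected by the polymerase.
Only primary alignments are used, so a multi-mapping fragment cannot count
toward two pause sites.  Internally all coordinates are 0-based half-open;
BED/bedGraph output keeps that convention, GFF3 and TSV reports are 1-based
inclusive.

## Pause score and calling

The pause score of a position is its 3'-end count divided by the mean count
in a ±`window_half` flank (default 100 nt, focal position excluded).  This
local fold enrichment is the established NET-seq pause statistic: it is
invariant to sequencing depth and to multiplying all counts by a constant,
and insensitive to gene-level expression differences because the flank and
the focal position share the same transcription unit at this scale.  A zero
focal count scores 0; a positive count over an all-zero flank is reported as
the cap 10⁶ so tables stay finite and sortable.  Whether a median flank or
within-gene normalization would behave better on real data is untested here;
the flank mean is the implemented and documented choice.

Calling keeps positions with `count ≥ min_count` (default 10) and
`score ≥ min_score` (default 20).  Only the strong-pause cut (score > 50)
is an established reporting convention; the calling thresholds are free
parameters and are exposed on the CLI.  Candidates closer than
`cluster_radius` (default 2 nt) on the same strand are reduced to the
maximum-count position, ties breaking to the smaller coordinate — paused
polymerases can present several clustered 3' ends, and determinism requires
an explicit tie rule.  Raising `min_score` can only remove calls
(monotonicity), which the tests assert.

Sensitivity: the test suite re-runs the differential classification at
`window_half` ∈ {50, 100, 200} and reports the per-window accuracies; on
simulated data the class calls are stable to this choice because the score
is a local ratio.

## Differential classification

Pause strength is compared across conditions after normalizing to
transcript abundance: `log2FC = log2[((S_dep+ε)/(TPM_dep+ε)) /
((S_wt+ε)/(TPM_wt+ε))]` with pseudocount ε = 1 on every term so the value
is finite when a pause is absent in one condition.  The pseudocount is
symmetric, so swapping the conditions exactly negates the statistic.
Class boundaries: suppressed (> 2), independent (−1.5 … 1.5), stimulated
(< −1.5); values in (1.5, 2] belong to no printed class and are reported
as `unassigned` rather than silently merged.

TPM is computed per gene from same-strand 3'-end counts divided by gene
length, scaled to 10⁶.  Two open choices were fixed as follows:

* **Which abundance normalizes a pause.**  The TPM of the gene containing
  the pause (same strand) is used; pauses outside any gene get TPM 0 and
  survive through the pseudocount.
* **Pause reads inside the abundance estimate.**  The pipeline excludes the
  matched pause positions (count and length denominator) from the gene
  counts before computing TPM.  A strong pause can contribute a large share
  of its gene's 3'-end reads, and normalizing a pause score by an abundance
  that contains the pause's own reads pulls every log2FC toward zero in a
  strength-dependent way.  Excluding the focal positions makes the
  abundance an estimate of polymerase flux through the gene rather than of
  its pausing.  `compute_tpm(..., exclude=None)` gives the unexcluded
  variant.

Matching across conditions is at exact (strand, position) — single-nt
resolution is the point of the method; a ±1-nt tolerance mode exists behind
a flag.  In union mode, positions called in only one condition are
re-quantified (count, score) from the other condition's coverage, so the
fold change is defined for condition-specific pauses.

## Translocation register

Footprint lengths map to registers: 16–17 nt post-translocated, 18 nt
pre-translocated, >18 nt backtracked.  Lengths below 16 nt are degraded
sub-footprints; they are kept as a fourth fraction of the denominator and
never attributed to a register, so the four fractions sum to 1.  The mean
backtrack depth is the mean of (length − 18) over the >18-nt reads.
Backtracking calls use strict inequalities — backtracked above 0.5,
nonbacktracked below 0.2 — with both boundary values falling into
`intermediate`.  Reads are pooled across input (no replicate averaging).
The change-on-depletion grouping (positive / negligible / negative) uses a
free threshold on Δ(backtracked fraction), default 0.1.

The method cannot distinguish half-translocated from post-translocated
registers; no attempt is made to.

## Score-distribution model

Binned pause-score counts decay approximately exponentially.  The model is
a log-linear fit of ln(count) on bin-center score over non-empty bins, and
the once-per-genome threshold is the score where the fitted expected count
crosses 1: `s* = log_amplitude / λ`.

Two numerical choices matter:

* **Weighting.**  The fit is weighted least squares with weights equal to
  the bin counts (the inverse-variance weighting for the log of a Poisson
  count).  An unweighted fit lets far-tail bins containing a single pause
  dominate the slope through leverage, and its rate estimate is unstable at
  the ±20 % level on samples of 10⁴ scores; with count weighting the rate
  and threshold are recovered to within a few percent.
* **Bin width.**  With bin width *w*, the fitted amplitude of an
  Exponential(λ) sample of size *N* is `N·2sinh(λw/2)`, which equals *N* —
  making `s* = ln(N)/λ`, the score whose expected exceedance count is one —
  when `λw ≈ 1`, i.e. when the bin width is about the mean score.  The
  recommended (and acceptance-script) bin width is therefore on the order
  of the mean score; the default parameter is 50 score units and both the
  width and an optional score floor are exposed.

Zero-count bins are excluded (ln 0 undefined), with no continuity
correction.

## Sequence context

Window offsets follow the logo convention: −1 is the 3'-end base of the
paused RNA, −k is k−1 bases upstream, +1 the next template-encoded base;
there is no offset 0, which pins the motif coordinates (−10G −9G −1Y +1G)
without off-by-one ambiguity.  Minus-strand windows are
reverse-complemented so they read 5'→3' along the nascent RNA, and the
whole calling pipeline is strand symmetric: running on the reverse
complement of a genome reproduces the mirrored pause table exactly (tested).

Information content uses a uniform background (2 + Σ f·log₂ f bits per
offset, in [0, 2]); a genome-composition background is a flag away.
Matrices can be stratified by a per-pause label, e.g. dominant
footprint-length class, to contrast backtracked versus cleaved/processed
pause populations.

The hairpin scanner enumerates **perfect maximal stems**: every
(arm start, stem ≥ `stem_min`, loop in `loop_range`) combination whose stem
pairs are all Watson–Crick (G·U allowed by default), reported only if the
stem can be extended neither outward (flanking bases pair) nor inward
(loop-flanking bases pair and the shrunken loop would still be legal).
There are no bulges, mismatches or thermodynamics: the analysis target is
the *distance* statistic — the number of nucleotides from the 3'-most
paired base to the pause 3' end (adjacent = 1), where pause hairpins
concentrate at 11–13 nt — not folding free energy, and a deterministic
scanner can be verified exactly against brute-force enumeration (the test
suite does so on 200 random 40-mers, and the profile mode is robust to
`stem_min` 5 vs 6 on planted data).  Null profiles come from per-sequence
composition-preserving shuffles (seeded); the default stem/loop limits
(stem ≥ 5, loop 3–8) are free parameters.

## Polarity

Per gene: mean 3'-end coverage of the 3' half divided by the 5' half, in
transcription orientation (odd lengths put the middle base in the 5' half);
undefined (and excluded from aggregates) when the 5'-half mean is zero.
The ratio is scale free and strand symmetric; its log2 is reported
alongside.  The genome-wide view is a length-scaled metagene profile: each
gene's coverage is averaged into `n_bins` (default 50) equal-width bins of
scaled length, normalized to the gene's own mean, and averaged across
genes.  Both the per-gene ratio and the metagene slope are provided because
either can serve as the polarity readout.

## Pause kinetics

Single-round time courses are fitted to `P(t) = E·2^(−t/T)` — single
exponential escape from one paused state — by bounded least squares with a
log-linear seed for `T` and a small multi-start around it.  `E` is the
fitted amplitude and is deliberately unconstrained above 1 (finite early
sampling can extrapolate past 100 %); no zero-time re-anchoring is applied.
The chase lane is excluded by default (it is run under different
conditions).  A time course with no decay yields `converged = False` with
an infinite half-life rather than a spurious fit.  A double-exponential
mode (two species) is behind a flag and reports the dominant-amplitude
component plus both components.  Time-unit equivariance (scaling times
scales `T`, leaves `E`) is tested.

## The simulator

`simulate_genome` draws an i.i.d. genome at the configured GC content
(default 51 %), places non-overlapping ORFs with explicit start/stop codons
on random strands, and plants pauses inside genes at a minimum spacing of
250 nt so scoring windows do not overlap.  Per pause it draws an excess
weight `w ~ Exponential(rate)` (default rate 0.02, mean 50 — giving the
score distribution its exponential tail), a class (defaults in the
proportions 0.514/0.434/0.052 suppressed/independent/stimulated), a
register mixture from a Dirichlet around the genome-wide default
(post 0.45 / pre 0.35 / backtracked 0.20), and optionally writes the
consensus motif and/or a perfect 6-bp-stem, 4-nt-loop hairpin whose
3'-most paired base sits 11–13 nt upstream of the 3' end.

`simulate_reads` draws exactly `depth_per_condition` 3'-end positions
(default 2×10⁶) from a multinomial with weight 1 at background cells and
`1 + w·2^Δ` at pauses, where Δ is +effect for suppressed pauses in the
depleted condition, −effect for stimulated, 0 otherwise (default effect
2.5 log2 units).  Backtracked lengths are 18 + Geometric(p), p = 0.5 —
the simplest monotone tail consistent with ">18 nt".  Genome and read
generation take separate seeds so one genome can carry many read
replicates.

Deliberately not modeled: base-composition bias, sequencing error, PCR
duplicates, RNase sequence preference, paired-end mate merging (reads are
emitted as already-collapsed footprints), and any planted polarity.
Consequently, passing recovery tests demonstrates the estimators are
correct under the generative model — exponential pause strengths, clean
multinomial sampling, exact 3'-end positions — not that they are robust to
the artifacts of real libraries.

## Problem sizes used by tests and the acceptance script

* Pause calling: 1 Mb genome, 500 genes, 1,000 pauses, 2×10⁶ reads per
  condition (the package defaults; a ~¼-scale bacterial genome at roughly
  the observed pause density).  Precision counts any called position
  present in the truth; recall is over plants with excess weight ≥ 30,
  the weakest plants that the default thresholds are designed to reach.
* Differential classification: 500 kb, 600 pauses in equal thirds,
  weight rate 0.005 and depth 2×10⁶ so that pauses of every class reach
  the ≥200-read evaluation condition; accuracy and per-class mean log2FC
  are computed over pauses with ≥200 reads in their better-covered
  condition.
* Register: 100 kb, 200 pauses, a broader Dirichlet
  (base 0.3/0.3/0.4, concentration 2.5) so both unambiguous regimes
  (planted backtracked fraction ≤0.1 and ≥0.6) are populated; evaluation
  over pauses with ≥100 reads.  The ±0.05 recovery bound is applied to the
  mean absolute error across pauses: at 100 reads the binomial standard
  error of a single fraction is itself ≈0.05, so a per-pause hard bound
  would fail a third of the time for a perfect estimator.
* Score distribution: 10⁴ Exponential(0.01) scores per seed over 5 seeds,
  bin width 100 (≈ the mean score, see above).
* Kinetics: noiseless 5-point course (exact recovery), then 100 seeded
  courses of 8 points at σ = 0.02.
* Strand symmetry: 100 kb, 4×10⁵ reads, full calling + annotation on the
  genome and its reverse complement.

## Known limitations

* The pause-score flank statistic is the mean; a median variant may be more
  robust to clustered pauses on real data and is not implemented.
* TPM from 3'-end counts equates footprint density with abundance; on real
  data an independent RNA-seq abundance would be preferable when available.
* The hairpin model ignores energetics: a thermodynamically marginal
  perfect stem counts as much as a stable one.
* Register fractions at a pause include the background reads mapping to the
  same position; at low pause enrichment this shrinks the estimated
  mixture toward the genome-wide default.
* Condition pairs are compared without replicate-level significance
  testing; classification is by thresholding only.
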
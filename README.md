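# rnetseq

Analysis toolkit for **RNET-seq** — the RNase-footprinted variant of native
elongating transcript sequencing in which only the RNAP-protected 3'-proximal
fragment of each nascent RNA is sequenced.  The 3'-end coordinate of a
footprint marks the position of a (possibly paused) RNA polymerase at
single-nucleotide resolution, and the footprint *length* reports its
translocation register: 16–17 nt post-translocated, 18 nt pre-translocated,
&gt;18 nt backtracked.

The package is aimed at bacterial transcription labs comparing pausing
between two conditions (e.g. wild type versus depletion of an elongation
factor such as NusG).  It provides:

* **Pause calling and scoring** — strand-specific 3'-end pileups; the pause
  score of position *i* is the fold enrichment of its 3'-end count over the
  local background, `score(i) = c_i / mean(c_j, j in i±w, j≠i)` with
  `w = 100` nt by default.  Scores are scale invariant, so comparable across
  libraries.  Pauses with score &gt; 50 are flagged *strong*.
* **Differential pause classification** — pause scores normalized to
  transcript abundance (TPM), `log2FC = log2[(S_dep/TPM_dep)/(S_wt/TPM_wt)]`
  (pseudocount-regularized); classes: *suppressed* (log2FC &gt; 2, at least
  fourfold up on depletion), *independent* (−1.5 ≤ log2FC ≤ 1.5),
  *stimulated* (log2FC &lt; −1.5), with the printed gap (1.5, 2] kept explicit
  as *unassigned*.
* **Translocation-register inference** — per-pause footprint-length
  histograms → fractions of sub/post/pre/backtracked reads; a pause is
  *backtracked* when its &gt;18-nt fraction exceeds 0.5 and *nonbacktracked*
  below 0.2.
* **Score-distribution modeling** — the binned pause-score histogram decays
  roughly exponentially; a weighted log-linear fit gives the decay rate λ
  and the score `s* = ln(A)/λ` beyond which a pause is expected less than
  once per genome.
* **Sequence context** — strand-aware windows around the pause 3' end
  (offset −1 = the 3'-end base, no offset 0), position frequency/information
  matrices, scoring of the consensus pause motif (−10G −9G −1Y +1G), and an
  exhaustive perfect-stem scanner that profiles hairpin-to-3'-end distances
  against composition-preserving scrambles (pause hairpins sit 11–13 nt
  upstream of the 3' end).
* **Transcription polarity** — per-gene 3'-half/5'-half coverage ratio and a
  length-scaled metagene profile.
* **Pause kinetics** — least-squares fit of single-round in vitro time
  courses to `P(t) = E·2^(−t/T)` for pause efficiency `E` (may exceed 1)
  and half-life `T`.
* **A ground-truth simulator** — genomes, ORF annotations and
  condition-paired reads with planted pause classes, register mixtures,
  consensus motifs and hairpins, used by the test suite to verify that every
  stage recovers what was planted.

## Worked example

Run the whole pipeline on a simulated depletion experiment (200 planted
pauses, 5×10⁵ reads per condition on a 200 kb genome):

```python
from rnetseq import RunConfig, SimConfig, run_pipeline

config = RunConfig(sim=SimConfig(seed=42, genome_length=200_000, n_genes=100,
                                 n_pauses=200, depth_per_condition=500_000))
result = run_pipeline(config, "demo_run")
print(result["counts"])
print(result["report"])
```

prints (abridged):

```
{'reads': {'WT': 500000, 'depleted': 500000},
 'pauses': {'WT': 135, 'depleted': 150},
 'matched': 160, 'shared': 125,
 'classes': {'suppressed': 87, 'independent': 57, 'unassigned': 8, 'stimulated': 8}}
{'pause_precision': 1.0, 'pause_recall': 1.0, ...
 'classes': {'suppressed': {'n': 95, 'mean_log2fc': 2.45, 'class_accuracy': 0.92},
             'independent': {'n': 57, 'mean_log2fc': 0.008, 'class_accuracy': 1.0},
             'stimulated': {'n': 8, 'mean_log2fc': -2.26, 'class_accuracy': 1.0}},
 'register_mae': 0.052}
```

Every called pause present in the truth table counts toward precision; the
planted per-class effects (+2.5 / 0 / −2.5 log2 units) are recovered in the
per-class mean `log2fc`, and the mean absolute error of the register
fractions is ~0.05 at this depth.  `demo_run/` contains the pause tables,
the differential table, register tables, bedGraph coverage, the score
distribution fit, the suppressed-pause position matrix and hairpin-distance
profile, polarity tables, and a JSON manifest.

Fitting an in vitro time course:

```python
from rnetseq import simulate_timecourse, fit_pause_kinetics

tc = simulate_timecourse(0.8, 20.0, [5, 10, 20, 40, 80], noise_sd=0.02, seed=1)
print(fit_pause_kinetics(tc).summary())
```

```
Pause kinetics fit: P(t) = E * 2^(-t/T)
---------------------------------------
efficiency E   0.8219
half-life T    19.25 s
RSS            0.00108
points fitted  5
converged      True
```

The same functionality is exposed on the command line
(`rnetseq simulate | call | diff | register | scoredist | logo | hairpin |
polarity | kinetics | run | evaluate`); `rnetseq run --config run.yaml
--outdir out` executes the full pipeline from one YAML file.

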
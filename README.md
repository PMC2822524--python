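# profhmm

Profile hidden Markov model training for DNA sequence families, built
around two estimation algorithms that resist the local optima that trap
plain Baum-Welch — **Conditional Baum-Welch** (CBW) and **Dynamic Model
Surgery** (DMS) — together with the simulation harness that
demonstrates them and a transitive-alignment metric for evaluating
transposon hits across two genomes.

## Who this is for

Modeling DNA repeat families (transposable elements in particular) with
profile HMMs is hard: the four-letter alphabet makes the Baum-Welch
(BW) likelihood surface riddled with local optima in which model
positions are *misaligned* against the family.  This package is for
people who want to (a) estimate Plan 7 profile HMMs from unaligned DNA
sequences with algorithms that escape those optima, (b) study the
algorithms' behaviour under controlled conservation levels, or (c)
search genomic sequence for family members and score cross-genome hit
pairs transitively through a genome-genome alignment.

## The model and the algorithms

A **Plan 7 profile HMM** with `n` positions has states `M_p` (Match,
position-specific emission `e_p(a)`), `I_p` (Insertion, shared emission)
and `D_p` (silent Deletion), with the seven transitions
`M→M, M→I, M→D, I→M, I→I, D→M, D→D` per position (no `I↔D`), plus
Begin/End and two flanking deletion chains (DeletionIn/DeletionOut) that
implement *local* entry and exit — `3n + 4` states in total.  Under the
canonical state ordering (Begin, DeletionIn, `M_1 I_1 D_1, …`,
DeletionOut, End) every strictly-advancing transition spans at most 5
ordering slots (the `M_p → D_{p+1}` edge); this *bandedness* is what
makes the row-wise algorithms below possible.

* **BW** — classical EM: forward-backward expected counts
  `E[#uses of each emission/transition | data, Θ]`, then every
  parameter group is re-estimated as `(counts + pseudocounts)`
  normalised (MAP under Dirichlet priors), floored at `10⁻⁵`.
* **CBW** — the ECM variant: each position's parameter group is
  re-estimated *conditionally on all the others*, sweeping positions in
  ascending order, then the state-independent parameters.  Because the
  transition kernel is banded, the forward lattice can be recomputed
  row-by-row as the sweep advances, so one CBW sweep costs the same
  order as one BW iteration while taking `n + 1` monotone ECM steps.
* **DMS** — on-line structural correction: while the updates are being
  computed, the per-sequence expected insertion/deletion counts at each
  position are compared to a threshold ξ; if more than a fraction ν of
  the sequences exceed it at position `j`, a position is added after
  `j` (insertions) or position `j` is removed (deletions), immediately,
  mid-training.  ξ escalates whenever the edits cycle.

Convergence is declared when the average Euclidean distance of all free
parameter groups between successive iterations drops below `10⁻⁵`
(simulation regime) or `10⁻⁷` (transposon regime).

## Worked example

Simulate a family at conservation 0.7 (each match position emits its
consensus residue with probability .7), train a profile with CBW+DMS
from a random start, and scan held-out sequences:

```
$ profhmm simulate --length 30 --conservation 0.7 --n-train 50 \
    --n-test 50 --seed 7 --out-dir sim
simulated truth bundle at conservation 0.7 into sim

$ profhmm train --fasta sim/train.fasta --algorithm CBW --dms \
    --regime simulation --length 30 --seed 3 --max-iterations 300 \
    --out-profile mir.profile --trace trace.tsv
trained CBW+DMS: 101 iterations, final length 29, final log-posterior -2117.595

$ profhmm scan --profile mir.profile --target sim/test.fasta \
    --shuffle-seed 1 --out-hits hits.tsv
converting global-mode profile to a local search model
sim0: threshold -3.041 (1 null windows), 2 hits
sim1: threshold -2.415 (1 null windows), 2 hits
...
```

The training trace (`trace.tsv`) records one line per iteration —
log-likelihood, log-posterior, parameter distance, model length, DMS
actions and the current ξ:

```
iteration  log_likelihood  log_posterior  distance   model_length  dms_actions  xi
1          -2259.169       -2749.832      1.278e-01  30            -            0.01
...
101        -1625.985       -2117.595      8.873e-06  29            -            0.27
```

Here training improved the data log-likelihood from −2259 to −1626
nats over 101 sweeps, DMS settled on model length 29 (the truth was
30), and the run stopped when the average parameter movement fell
below 10⁻⁵.  Each scanned test sequence reports a score threshold
calibrated so that only 5% of hit scores on a shuffled copy exceed it,
and the hits that clear it.

`profhmm transitive` projects two hit sets through a genome-genome
fragment map (a documented TSV of gapped fragment alignments) and
reports the number of transitive alignments and their
matches + transitions score; `profhmm report` aggregates traces and
summaries into a per-algorithm comparison table.

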
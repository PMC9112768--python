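# Methods

This note documents the models, parameter choices and numerical conventions
behind `tebench`, and what its synthetic benchmarks do and do not show about
real transposable-element data.

## Tree generation

Both generators grow a rooted tree until it has `n_leaves` extant nodes
(default 100), then stretch every terminal branch so that each root-to-leaf
path equals `root_to_leaf_target` (default 100 time units, float tolerance
1e-9) — modelling the post-extinction phase in which every surviving copy
decays for the same amount of time.

* **DNA-transposon model.**  Each step attaches a new child to a parent
  chosen uniformly among *all* existing nodes (leaves and internal alike),
  with branch length uniform on [0, 10].  Because most attachments hit the
  shallow core, the adjusted trees are star-like: across seeds, more than
  half the total tree length sits in terminal branches.
* **Master-gene model.**  Each step attaches a batch of children (uniform on
  {1,2,3} by default; configurable, including a fixed batch size) to the
  current *master* node and promotes one child to be the next master, so all
  internal nodes lie on a single backbone.  Master-branch lengths are
  uniform on [0, min(5, remaining depth budget)]: a ~100-step backbone with
  unconstrained U(0,5) branches would accumulate ~250 depth units and
  overshoot any reachable target, making non-negative leaf adjustment
  impossible.  The budget cap lets the backbone approach the target
  asymptotically, so dead-end copies arise at every age — a master lineage
  active across the family's whole lifespan, which is the intended LINE
  picture.  Hand-built trees whose internal paths exceed the target still
  raise an error in `adjust_leaf_branches`.

Branch lengths are relative time only; the simulator's GPUT parameter
(generations per unit time) fixes the mutational clock.

## Sequence evolution

Substitutions follow a continuous-time Markov process simulated exactly with
the Gillespie algorithm.  Site *i* mutates at rate
`RATE_SCALE × total_rate(triplet_i)` per generation, where the 64×64
trinucleotide table is normalised so the mean total rate over the 64 source
triplets is 1, and `RATE_SCALE = 1e-6` is the single documented scaling
constant: with tree depth 100, GPUT values of 100 / 500 / 3000 / 6000 land
at roughly 1% / 5% / 28% / 50% mean Kimura divergence on a kb-scale seed.
Context is re-evaluated after every event, so overlapping triplet effects
(e.g. a CpG created by a neighbouring substitution) are handled exactly.
Sequence edges marginalise the missing flank over the four bases; a centre
base of `N` is immutable and `N` is never introduced by mutation.

Indels are coupled to realised substitutions: after each substitution, an
insertion occurs with probability 0.08 and a deletion with probability 0.12
(independent Bernoulli draws), giving the configured 0.20 indel events per
substitution as a directly measurable event-count ratio.  Lengths are drawn
from a Zipf distribution truncated to {1..20} whose exponent is calibrated
by bisection (to 1e-9 in the mean) so the mean is 1.7 bp; the degenerate
boundary mean→1 is capped at exponent 64 (all mass at length 1).  Inserted
bases are drawn i.i.d. from the current sequence's composition (uniform
composition is available) to avoid drift artifacts.  A lineage whose
sequence shrinks below 1 bp is flagged empty and excluded from the output
(recorded in `EvolutionResult.dropped`).

Every residue carries an immutable, totally ordered column key; insertions
allocate fresh keys strictly between their neighbours' keys (with a serial
tie-break so independent insertions in sibling lineages never share a
column).  Sorting the union of leaf keys yields the ground-truth reference
MSA: two residues share a column iff they descend from the same ancestral
residue.  The invariant "each reference row ungaps to its extant sequence"
is asserted in the tests for every simulation.

**Fragmentation** draws an arithmetic-moment-matched log-normal length
(default sd 300 bp), clamps it to [min_fragment, parent length] (default
floor 50 bp) and selects a uniform start window.  The first
`min_full_length` leaves emitted (default 2) stay full-length.  Start
positions are unbiased; 5′-biased truncation and solo-LTR-style
recombination are out of scope.

**Kimura divergence** is the two-parameter distance
K = −½·ln((1−2p−q)·√(1−2q)) over gap-free compared columns, reported per
leaf against the seed through the shared column keys; saturation (log-domain
violation) returns +∞, which mean summaries skip.

## MSA metrics

SPS and CS are computed from residue identities (sequence id + ungapped
coordinate), not symbols, so a column only counts as reconstructed when the
*same residues* co-occur — symbol-level comparison would over-credit.  SPS
with a pair-free reference returns 1.0 (vacuous truth).  Pairwise alignment
uses affine gap scoring (gap of length k costs `open + k·extend`) with the
pinned default nucleotide table: match +10, transition −6, transversion −10,
N neutral (0), gap open −25, extend −5.  The magnitudes follow neutral-DNA
comparison matrices; CSL is a ratio of scores under one table, so the exact
values are a reproducibility pin rather than a tuned quantity.  The
Needleman–Wunsch and Smith–Waterman engines are Biopython's C pairwise
aligner behind this package's interfaces; tests verify their scores against
independent plain-Python dynamic programming and, at very short lengths,
full alignment-path enumeration.  Tie-breaks among co-optimal tracebacks
follow the engine's canonical enumeration order and are deterministic.

## Refiner

The refinement loop is expectation–maximisation on a discrete consensus:

1. **Template** — the input sequence with the best cumulative pairwise local
   alignment score (ties: lowest input index; all-zero scores: longest
   sequence).
2. **Local alignment** — best local alignment per query, then recursive
   re-alignment of the unaligned query prefix/suffix (segments ≥15 bp, up to
   16 fragments, score floor 30 ≈ three net matches), so fragmented copies
   contribute multiple alignments.  Per query, a best-score-first *colinear*
   subset is kept (query and template intervals ordered consistently);
   residues of rejected alignments fall through to padding.
3. **Transitive MSA** — one anchored column per covered template position;
   insertion runs at the same template junction are left-justified into
   shared columns (the residues are "arbitrarily aligned"; any deterministic
   convention works and this one is the simplest).
4. **Padding** — residues outside any alignment become private single-residue
   columns placed adjacent to their nearest aligned neighbour (prefix runs
   sit directly before the row's first anchored column — placing them at the
   alignment edge instead would extend the row's voting extent across
   unrelated columns and poison consensus calling).  The output always
   ungaps to the input sequences; this is asserted at run time.
5. **Consensus** — stage one scores each candidate in {A,C,G,T,N,−} against
   the column's votes, counting only rows whose alignment extent spans the
   column (a fragment casts no votes outside itself).  Gap votes use the
   pinned scores gap-vs-gap +10 and gap-vs-base −25, mirroring the metric
   table, so a column is dropped when weighted gap evidence outweighs base
   evidence (~50% occupancy at equal weights).  Ties prefer A>C>G>T>N>−.
   Stage two restores CpG sites: methylated CG decays predominantly into CA
   and TG, so any consensus dinucleotide whose aligned pairs are ≥50% CA+TG
   *and* whose literal call is rarer than those products is reassigned to
   CG (scanning left to right, non-overlapping).  Both constants are
   configurable; the threshold direction is fixed by the mutational
   mechanism, the exact value is a pin.
6. **Convergence** — exact consensus-string repetition, including
   oscillation (any previously seen consensus), with `max_iterations = 20`.

## Benchmark harness

Sweeps run along GPUT or mean fragment length.  Replicate *r* reuses seed
`base_seed + r` for tree and simulation across axis values and tools, so
scores are paired; aggregation uses Student-t 95% confidence intervals on
replicate means.  Kruskal–Wallis is computed across tools per sweep value
and Wilcoxon signed-rank (exact) on paired replicates; all-identical inputs
make the H test trivial (reported as p = 1) and the signed-rank test
undefined (reported as NaN with a note).  A Bonferroni-corrected copy of the
pairwise p-values is included; no stronger multiplicity claim is made.
External aligners are invoked through a declarative adapter (command
template, FASTA in / aligned FASTA out) and skipped with a warning when
absent — none are bundled or required.

Desk-scale problem sizes are used throughout the test suite (6–30 sequences,
150–1200 bp seeds, 2–3 replicates); the full-scale parameterization
(10 replicates × 100 sequences, 1.2–3 kb seeds, GPUT 100–6000, fragment
means 75–1200) is the `SweepSpec` default and runs unchanged, just longer.

## Synthetic fixtures, and what passing tests do not show

Seed sequences are first-order Markov chains with a target GC fraction and a
CpG enrichment multiplier; rate matrices are K2P-like (transition:transversion
2:1) with the CpG deamination transitions (C→T before G, G→A after C)
multiplied by a configurable factor (default 10) and renormalised.  These
reproduce the two properties the toolkit exercises — composition-dependent
mutation and CpG hypermutability — but not the low-complexity runs, internal
repeats, mixed ancestral forms, or biased fragmentation of real TE copies.
Results on these benchmarks therefore bound alignment difficulty from below:
a method that fails here will fail on real copies, but success here does not
guarantee success on, say, LINE 5′-truncation patterns or nested insertions
of other elements.

## Numerical conventions

Coordinates are 0-based half-open everywhere.  All randomness flows through
`numpy.random.default_rng` seeds carried in the config objects; identical
configs give bit-identical outputs (Newick text, MSAs, event logs).  Column
keys are exact rationals, so reference-MSA column order never depends on
floating-point comparisons.  Root-to-leaf path equality is checked to 1e-9;
Zipf calibration bisects to 1e-9 in the mean; the log-normal fragment
distribution is parameterised by its arithmetic mean/sd (moment-matched to
the underlying normal).
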
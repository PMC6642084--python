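# Methods

## Presence calling from HMM hit tables

A hit record is one profile-HMM match to one transcript of one sample, with
its bitscore. A sample is called positive for a family when at least one of
its transcripts scores **strictly above** the threshold (default 10 bits).
"Above" is read as a strict inequality; this is a documented choice, and the
threshold is configurable, because the convention at exactly 10.0 bits is
not fixed by the data. Duplicate rows per transcript are tolerated (the
maximum per transcript is used): HMM searches routinely report several
domains per transcript. Samples known to the analysis (from the clade map or
tree) but absent from the hit file are retained as all-zero rows —
non-detection is treated as absence, which is exactly the phenomenon the
statistics then have to cope with.

For families embedded in large superfamilies a single threshold cannot
separate the target activity from its relatives (the canonical case being a
CbbX-type Rubisco activase inside the AAA+ ATPase superfamily). The
dual-HMM ratio rule scores a transcript positive only when its target-family
bitscore b_T is strictly above the floor **and** b_T ≥ factor · b_R, where
b_R is the transcript's best score against the broad reference HMM (default
factor 5). The comparison is per transcript, on the linear bitscore scale,
using each transcript's best score per HMM — the least surprising reading of
"comparing the bitscores". When a transcript has no reference hit at all,
b_R is imputed as the floor so that absent reference evidence cannot
disqualify a strong target hit. Ratio-rule positives are provably a subset
of plain-threshold positives at the same floor.

## The exact 2×K test

Margins are conditioned on both sides: group sizes n₁..n_K and total
positives T. The two-sided p-value is the total conditional probability of
tables whose point probability is ≤ the observed one; ties are included
using a relative tolerance of 1e-7 on the log scale, which protects against
floating-point misses of exactly tied tables deep in the tail (mirror-image
tables are exact ties in exact arithmetic but not always in floating point).

Implementation notes:

* All point probabilities are computed via log-gamma and accumulated with
  log-sum-exp; p is reported both as a real and as log10, and the two agree
  to 1e-9 relative whenever p is representable.
* The table space is traversed depth-first over positive-count vectors with
  two prunings: a subtree whose *minimum* attainable log-probability exceeds
  the tie threshold is skipped, and a subtree whose *maximum* attainable
  log-probability is within the threshold is absorbed in one step, because
  the total mass of its completions has the closed form C(Σ remaining nᵢ, r)
  (Vandermonde's identity). Suffix minima/maxima come from a small dynamic
  program over (group, remaining positives).
* The exact number of feasible tables is counted beforehand (integer DP) and
  guarded at 10⁷ by default; exceeding the guard raises an error rather than
  silently approximating. Monte Carlo p-values are deliberately not
  provided — the exactness of the tail is the point. The five-group tables
  that arise in practice have ~10⁴–10⁵ feasible tables and evaluate in
  milliseconds.
* Degenerate margins (K = 1, T = 0, T = N) admit a single table and return
  p = 1 exactly.

The clade scan runs this test per family with clades as groups and sorts by
p (ties broken by family id). The concordance test for an enzyme pair uses
the 2×2 with groups = samples positive/negative for enzyme A and positives
= samples positive for enzyme B; this conditions on both enzymes' marginal
detection rates. Raw p-values are reported by default (Benjamini–Hochberg
adjustment is available behind a flag, via scipy's
`false_discovery_control`).

## Tree scan and simplification

Trees are rooted, may contain polytomies, and branch lengths are ignored by
all statistics — the tests are purely topological. The cut sequence starts
at the root split and expands one internal node per level in breadth-first
(shallowest-first) order, ties broken by preorder index, ending at the
all-singletons partition; each partition strictly refines the previous one.
Root polytomies simply yield more than two clusters at level 1.

At each level, the newly exposed clusters are tested cluster-vs-rest with
the exact 2×2 test. This per-branch statistic (rather than a single K-group
test over the whole partition) is what makes the minimal-p branch
interpretable as the location of a gain or loss: a clean loss of an m-leaf
clade out of N leaves attains the closed-form minimum p = 1/C(N, m), the
unique most-extreme table for that branch. The minimal-p cluster per family
is flagged `best` (ties resolved to the earliest cut level, then lowest
preorder rank), and `significant` means p < α (default 10⁻³).

Simplification collapses nodes that do not earn their keep. A clade is
*qualified* when, for at least one family, its segregation p is below α and
below its parent clade's p divided by the improvement factor (default 10 —
"substantially improves" made operational; both knobs are exposed).
Terminal clusters are formed by assigning every sample to its deepest
qualified ancestor; samples with none are merged upward into a single
residual cluster attributed to the root. This reproduces the intended
behaviour on the canonical cases: a uniform matrix yields one cluster of
everything, and a clean clade loss yields exactly two clusters (the lost
clade and the rest). Merging upward — rather than folding leftover branches
downward into the nearest significant cluster — is a deliberate choice:
folding a fully-present sibling branch into a fully-absent significant
cluster would destroy the very signal the cluster represents. When no clade
qualifies anywhere, the residual is the whole leaf set.

## Synthetic data

The generator is first-class, tested code, and its defaults are the study
conditions used throughout the test suite and the acceptance script:

* **Tree**: Yule (pure birth, rate 1) or fully balanced with unit branch
  lengths; leaves t1..tn; deterministic given the seed.
* **Trait**: two-state CTMC per branch — loss rate 0.1 while present, gain
  rate 0.01 while absent, per unit branch length. The asymmetry makes losses
  common and regains rare (Dollo-like), which is the regime the scan is
  meant for. The root state defaults to present; a stationary draw is
  available. Clade losses can also be *planted* deterministically on a named
  branch, which is how power experiments control ground truth.
* **Observation**: each truly present (sample, gene) is detected i.i.d. with
  probability 0.9 by default — a deliberately pessimistic per-gene
  transcriptome completeness; detected hits score threshold + 1 +
  Exponential(scale 20) bits, spurious hits arrive Poisson(0.1) per
  sample-gene uniformly below the threshold, exercising the strict
  inequality at the calling edge without ever flipping a call.
* **Clade map**: the shallowest tree cut with ≥ 5 clusters, echoing a survey
  split into a handful of major clades of very different sizes.
* **Lipids** (optional): every sample gets PC species (lognormal AUCs);
  samples truly carrying the marker gene also get DGTS at a total abundance
  lognormally centred at 3× their PC total, so marker-positive samples have
  more DGTS than PC.

What the simulator does **not** emulate: sequence-level realism (no
transcripts or HMM emissions), correlated dropout between genes (dropout is
i.i.d.; a per-sample depth multiplier is not modelled by default), clade
structure in detection rates, or lipid measurement noise beyond the
lognormal abundances. Passing tests therefore demonstrate the statistical
machinery under its own stated assumptions — uniform sampling under the
null, independent dropout — not robustness to systematically uneven
sequencing depth across taxa.

Everything is keyed to a single integer seed through
`numpy.random.SeedSequence.spawn`, and `generate_dataset` output is
byte-identical across runs with the same config (headers record seed and
parameters; no timestamps inside data files).

## Scoring detectors

`evaluate_detection` compares a branch scan against the simulator's truth:
**power** is the fraction of event-carrying genes whose best split is
significant *and* whose cluster equals a true event's clade;
**branch accuracy** drops the significance requirement;
the **null rate** is the fraction of event-free genes whose best split is
nonetheless significant. The null rate of the *best* split is a minimum over
many per-branch tests, so it is not bounded by α per branch; empirically
(and in the acceptance script) it stays at or below ~1% at α = 10⁻³ because
exact conditional tests on sparse 2×2 tables are strongly conservative.

## Problem sizes

The test suite and acceptance script use 32-leaf trees, 100-replicate power
runs, 1000-gene calibration runs, and 200 random simplification fixtures.
These sizes give three-standard-error Monte Carlo resolution on the rates
being checked while keeping the whole suite in the tens of seconds; all of
them are parameters, not limits of the implementation (the exact test
handles the 175-sample, five-clade tables of a real survey in
milliseconds).

## Known limitations

* `fisher_exact_2xk` errors out above the feasible-table guard instead of
  approximating; very fine partitions with many positives are out of scope.
* The simplification rule evaluates each clade against its immediate parent
  only; a signal that only emerges two levels down from an uninformative
  ancestor is still found (qualification does not require the ancestor to
  qualify), but pathological matrices could in principle qualify nested
  clades whose joint interpretation is ambiguous — provenance node ids are
  reported so such cases can be inspected.
* Lipid abundances are used as provided; internal-standard normalization is
  upstream of this package.
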
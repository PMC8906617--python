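# Methods

This note documents the models, estimators and numerical choices behind
`iqgrn`, the assumptions they rest on, and what the synthetic benchmark
does and does not demonstrate.

## Model family

A GRN is a set of genes with one Boolean update rule per gene. The strict
family is `g = (A1 ∧ … ∧ Ak) ∧ ¬(R1 ∨ … ∨ Rm)` with 1 ≤ k ≤ 4 activators
and 0 ≤ m ≤ 2 repressors: activation requires every activator, repression
needs only one repressor. A *relaxed* mode additionally tries the opposite
combinator inside each multi-literal group (OR-activators, AND-repressors),
quadrupling those rules; it is off by default because the strict family is
the biologically motivated prior and the search stays small (≤ 60 rules
per gene at full in-degree). Degenerate rules (`constant 0/1`) exist only
as flagged fallbacks for genes with an empty candidate pool. The search
backend is exhaustive enumeration — at these sizes it is exact,
deterministic, and trivially verifiable against the closed form
`nRules = [Σ_{k=1..4} C(N,k)]·[Σ_{j=0..2} C(M,j)]`; a constraint-solver
backend would add a dependency without changing the contract.

## Pipeline stages and parameters

**Imputation** (`impute.k = 15`, `impute.t = 3`, on by default).
Distances between cells are computed only over coordinates where both
cells are nonzero: an exact zero is a dropout candidate, and counting it
as evidence of dissimilarity makes dropout cells cluster with each other
(at 8 genes and 40% dropout the dropout pattern otherwise dominates the
metric entirely). Affinities use an adaptive Gaussian kernel (bandwidth =
distance to the k-th neighbour), symmetrized and row-normalized; only
zero entries are filled, each with the weighted mean of the *nonzero*
values in its `M^t` diffusion neighbourhood. Two deliberate departures
from a plain `M^t X` smoother, both load-bearing: (1) replacing observed
values wipes out per-cell measurement noise and induces spurious
gene-gene correlations that directly corrupt the downstream MI and sign
estimates — in our benchmark full-replacement smoothing *reduced* edge
recall at every diffusion depth, while zeros-only filling raised it; (2)
letting neighbours' own zeros vote drags every filled value toward a
spurious mid-range mode. A corollary of zeros-only filling: on
dropout-free data imputation is exactly the identity.

**Binarization** (`binarize.method = kmeans`). The per-gene two-cluster
split is solved exactly by scanning all n−1 split points of the sorted
values (prefix sums; first optimum on ties), which removes seed dependence
from iterative k-means; τ is the centroid midpoint and a cell is *on* iff
its value exceeds τ. A two-cluster split is only meaningful for bimodal
expression, so each gene is first screened with Sarle's bimodality
coefficient `(skew² + 1)/kurtosis` against the 0.555 uniform benchmark
(two-point mixtures score ≈ 1 at any mixing fraction, mildly skewed
unimodal lognormals ≈ 0.4): non-bimodal genes — e.g. a constitutively
expressed regulator whose only variation is noise — are thresholded
against the dataset-wide pooled two-cluster split instead of having their
noise split in half. Zero-variance genes are called all-on if positive,
all-off otherwise. The alternative `mean` method thresholds at the
per-gene mean with no screening.

**Density and hierarchy** (`density.window = auto`). On/off calls are
smoothed by a centered moving average along the pseudo-time ordering;
`auto` uses `L = max(3, round(N_cells/N_genes))`. End windows are
truncated and divided by their actual size — padding would invent data.
Transition points are crossings of the 0.5 density level; a gene's primary
point is its first crossing, with always-high genes pinned to −∞ (top of
the hierarchy) and never-high genes to +∞. Edges are admissible only from
an earlier- (or equally-) transitioning regulator to a later target; ties
permit both directions, so co-transitioning genes may regulate each other.
This filter encodes the core causal assumption of the method — regulators
switch before their targets along the trajectory. Its known blind spot:
a repressor necessarily transitions *after* a target that rose first, so
repressive edges onto transiently expressed genes are systematically
excluded; the benchmark quantifies this honestly rather than working
around it.

**Mutual information** (`network.grid = 20`). Dependence is estimated on a
20×20 histogram with conditional resampling: occupied regulator columns
(≥ 3 points; a variance control) get uniform weight, so the estimate is
not dominated by the most populated expression regime;
`I = H(Y) − H(Y|X)` in bits on that resampled joint, symmetrized by
taking the larger direction. Both entropies carry the Miller–Madow
bias correction `(m−1)/(2n ln 2)`: without it the per-column conditional
entropies (~100 points each at n = 2000) are biased low far more than
H(Y), inflating independent-pair MI to ≈ 0.14 bits; corrected, independent
pairs score ≤ 0.03 bits and a deterministic two-level copy scores 1.000.
The estimator assumes log-scale expression — on raw counts the *on* mode
sprawls across most of the grid while the *off* mode collapses into one
column, and the column-resampling balance breaks.

**Sign assignment** (`network.sign_threshold = 0.05`). Pearson correlation
signs each interaction; |r| below the threshold is dropped as
sign-ambiguous. The default is deliberately permissive: the threshold's
purpose is removing ambiguity, not pruning the network.

**Rule scoring and selection** (`agreement_cutoff = 80`, `lag = 1`).
Agreement is teacher-forced next-cell prediction: the rule evaluated on
the observed binarized state at cell *i* is compared with the target's
call at cell *i + lag*, over all ordered pairs. Among rules at or above
the cutoff, the highest **average** MI of the rule's edges wins, with
self-activation edges contributing 0 — averaging makes a self-loop a pure
penalty, included only when no other rule survives the cutoff. Ties
prefer fewer regulators, then lexicographic names. A gene with survivors
below the cutoff falls back to its single best-agreement rule (flagged);
a gene with no candidates gets a flagged constant-majority rule. The
cutoff value is a genuine free parameter of the method (it trades
single-regulator approximations against full rules); it is recorded in
the model's provenance. Note a structural property of max-average-MI:
adding a second true activator *lowers* the average unless its MI exceeds
the current mean, so AND-rules are only selected when the single-activator
approximation fails the agreement cutoff.

**Simulation.** Asynchronous semantics: one uniformly chosen non-clamped
gene updates per step. Attractors are restricted to fixed points (states
invariant under every non-clamped rule), found exhaustively up to 24 free
genes and by ensemble terminal-state collection (flagged non-exhaustive)
beyond. Ensembles draw initial states uniformly; absorbed trajectories
are padded with their fixed point so `average_exp` is defined across
trajectories of different lengths. `asp` of a state is its first-visit
step normalized by trajectory length, averaged over visiting trajectories;
the attractor of an absorbed trajectory scores 1 by construction. Removing
the last activator by link perturbation yields a constant-0 rule — an
empty conjunction would conventionally be true, but "all activators are
necessary" implies no activator can fire the gene — and the rule is
flagged loudly. Each ensemble uses one seeded generator recorded in
provenance for exact replay.

## Synthetic benchmark: what it emulates and what it shows

`generate_random_grn` draws models inside the inference family, shaped for
*identifiability* — the benchmark measures the method, so the truth must
be recoverable in principle:

- One self-activating root models a constitutive upstream signal (e.g. a
  culture-provided ligand); it is always on, carries no usable variation,
  and its single outgoing edge is therefore unrecoverable by any
  data-driven method — a known, counted loss of one edge per model.
- Multi-activator sets are drawn cross-branch (pairwise non-ancestral):
  in a latching cascade `A1 ∧ A2` with `A1` an ancestor of `A2` equals
  `A2` on every reachable state, so such an edge would be untestable.
- Activator sets are unique up to one singleton fork: genes with
  identical regulator sets are mutually indistinguishable from their true
  regulators, and the fork (two genes sharing one parent) is the minimal
  branching motif that still exercises branch structure.
- Repressors come from genes at least two cascade levels below the
  target's activators, so repression switches on well after activation
  and the target shows a wide transient on-window; repressed genes are
  terminal, because feeding a shut-down program forward collapses all
  downstream genes into rarely visited states.

`simulate_to_expression` runs a 200-trajectory asynchronous ensemble
(horizon 4·n_genes, leaving ≈ 25% of sampled cells in the terminal
attractor, matching the 2–3× terminal over-representation typical of real
differentiation datasets), samples cells uniformly over trajectories and
padded steps, and assigns each cell the asp of its state plus Gaussian
jitter (sd 0.02) as pseudo-time. Expression is a lognormal on/off mixture
— medians 0.2 and 3.0, log-sd 0.25, i.e. *well separated*: under 1% of
either component falls on the wrong side of the midpoint threshold — then
log1p-transformed, since the data containers and estimators assume
library-normalized log expression. Dropout zeroes entries independently.

What the benchmark does **not** emulate: UMI count noise (negative
binomial capture), branching trajectories, pseudo-time estimation error
(pseudo-time is derived from the generating dynamics itself), doublets,
batch effects, or regulon-scale gene counts. Passing it therefore shows
the pipeline recovers identifiable Boolean structure from clean
pseudo-temporal data at realistic dropout — not that it will match
curated networks on real tissue.

Measured under the default conditions (8 genes, 2000 cells, in-degree
≤ 3, 10 seeds): mean directed-edge recall ≈ 0.76–0.80 and precision
≈ 0.67–0.72, the residual losses being the structural root edge, the
hierarchy-blocked repressor edges, and max-average-MI dropping the
lower-MI member of an AND-pair when the single rule clears the agreement
cutoff. With 40% dropout, enabling imputation raises mean recall by
≈ 0.07–0.13 in every seed batch tested.

## Numerical and degenerate-input choices

- Pseudo-time ties: stable sort, input order preserved.
- Binarization ties: first optimal split point; τ strictly between
  distinct centroids.
- Constant vectors: MI 0 by convention; sign dropped (zero variance).
- Hierarchy ranks are tie-broken alphabetically for reporting; the edge
  filter compares raw transition points so tied genes stay mutually
  admissible.
- Initial-state majority over the earliest cells resolves an exact tie
  to *on*.
- Edge ranking for AUPRC breaks score ties lexicographically by
  (regulator, target); an edge in several rules takes its best score.
- All stochastic components (simulation, synthesis) take explicit seeds;
  derived seeds stay below 2³¹.

## Known limitations

- Fixed-point attractors only; limit cycles are reported as
  non-converging, not analyzed.
- The hierarchy filter cannot admit repressors of transiently expressed
  genes (first-transition ordering), and constitutively expressed
  regulators are invisible to edge inference.
- Agreement's teacher-forced lag-1 semantics assumes adjacent cells in
  pseudo-time are one regulatory "step" apart; the lag is configurable
  but no principled estimator for it is provided.
- The exhaustive fixed-point scan is capped at 24 free genes; the
  simulation fallback under-reports attractors with small basins.
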
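# Methods

## The problem

Case–control single-cell RNA-seq studies profile the same tissue in two
states (diseased vs healthy, old vs young) across repeated samples. Beyond
per-gene differences, the *composition* of the tissue carries signal: if an
abundant regulatory population suppresses a target population, their
abundances co-vary across samples. This package infers a directed network
over cell types from exactly that covariation, calls the edges that differ
between conditions, and then asks which ligands could mediate each inferred
interaction.

## Stage 1 — compositions and their binarization

For each sample, the fraction of cells annotated to each cell type is
computed with the *full* annotated cell count as denominator — including
cells of types later dropped by the `min_cells` filter (default 100 cells
pooled across samples, applied once over both conditions so case and
control networks share a vocabulary). This keeps retained fractions stable
under the filter.

Each cell type's fraction vector across samples is then binarized into
low/high abundance states by a two-component univariate Gaussian mixture
fitted with EM (max 500 iterations, convergence threshold 1e-4 on the
log-likelihood, variance floor 1e-8). Numerical choices:

- **Initialization** is a deterministic 1-D 2-means (Lloyd) from the
  quartiles. EM on 1-D mixtures readily collapses a component onto a pair
  of outliers (the likelihood is unbounded as a variance shrinks); the
  balanced deterministic start avoids that failure mode, which we observed
  routinely with likelihood-maximizing random restarts. Extra seeded
  k-means++ restarts are available via `n_init`.
- **Labelling** assigns 1 to the higher-mean component by posterior argmax,
  but is forced to be *monotone* in the fraction: with unequal component
  variances the raw posterior rule can label a high outlier 0. When that
  happens, labels are re-derived from a single cutoff at the posterior
  decision boundary between the two means (the root of the quadratic
  equating weighted component densities, restricted to the interval between
  the means; midpoint fallback if no root lies there). Consequence: the
  sample with the largest fraction is never labelled 0.
- **Degenerate columns** (all values identical) fall back to the
  distribution-free midpoint split [min, (min+max)/2] rather than aborting
  a whole bootstrap iteration; the midpoint split is also available as an
  explicit strategy.

`loo_stability` quantifies how much each cell type's cutoff depends on
single samples (leave-one-out refit agreement).

## Stage 2 — network structure over abundance states

A discrete Bayesian network is learned on the binary states by a
restrict-maximize scheme:

- **Restrict** (Hiton parents-and-children): per target, other variables
  are ranked by marginal G² association and admitted greedily when p <
  alpha (default 0.05); any admitted variable that becomes conditionally
  independent of the target given a subset (size ≤ 3) of the other admitted
  variables is removed. Tests in which any stratum has an expected count
  below 1 are declared unresolved and never count as evidence of
  independence. The skeleton keeps a–b only if each endpoint is in the
  other's set.
- **Maximize**: greedy hill climbing from the empty graph over add /
  delete / reverse moves, additions restricted to the skeleton, scored by
  BIC = log P(D | Θ̂, G) − ½·Dim(G)·log N with Dim(G) = Σ_q 2^{|Pa(q)|}
  (one free parameter per parent configuration per binary node). The score
  is decomposable; move deltas touch only the changed family and are cached.
  Every accepted move must strictly increase BIC.

**Tie-breaking is randomized (seeded).** The two orientations of a newly
added edge often have exactly equal score deltas (Markov equivalence); a
deterministic tie-break would stamp a name-dependent orientation onto every
such edge, and the bootstrap direction counts downstream would then measure
node names rather than data. Ties are therefore broken uniformly at random
with the run's seed; runs are reproducible given the seed.

On all 3-node problems the greedy search attains the exhaustive 25-DAG BIC
optimum (verified over randomized sweeps in the test suite).

## Stage 3 — bootstrap edge confidence and differential edges

Per condition, each of `n_iter` (default 100) iterations subsamples 80% of
the condition's cells without replacement, recomputes fractions,
re-binarizes, relearns the network, and tallies each *directed* edge. An
undirected tally (summing orientations) is emitted as a diagnostic.
Differential edges between case and control are the pairs whose larger
count reaches the threshold (default 20), scored case − control and sorted
by |score|. Enhancement analysis recomputes those signed scores after an
independent cohort is added: a pair is enhanced when the sign is preserved
and the magnitude strictly grows.

The permutation test destroys the new cohort's type–type covariation while
preserving each sample's composition value multiset: per sample, a random
bijection of cell-type labels is applied at the cell level (equivalent to
shuffling the sample's fraction vector across types, but it keeps cells
available so the bootstrap machinery runs unchanged). The p-value uses the
add-one estimator (1 + #{null ≥ observed}) / (1 + n_perm), never exactly 0.
An alternative axis (shuffling samples within each type) is provided.

## Stage 4 — ligand–target regression (LTR)

For a directed pair sender → receiver, the model explains target-gene
changes in the receiver from ligand changes in the sender folded through a
regulatory-potential prior I (targets × ligands):

    min_α Σ_t ( Σ_l I[t,l]·L[l]·α[l] − T[t] )² + λ‖α‖₁

with a *single* activity coefficient per ligand shared across all targets —
which is what makes held-out-target cross-validation meaningful. L and T
are natural-log fold changes of condition means (pseudocount 1); a raw-level
mode is available. The target universe is the genes shared by the prior and
the expression data minus the ligand genes themselves (no leakage). Columns
of the design are deliberately not standardized, so α stays interpretable
against the regulatory-potential scale.

Cross-validation: targets are partitioned into 5 folds; within each fold λ
is chosen on a 50/50 split of the training targets from a 100-point grid
log-spaced over four decades down from λ_max (the smallest penalty with an
all-zero solution on the training rows), taking the *largest* λ within one
standard error of the minimum validation MSE. The parsimony rule matters:
with plain argmin, pure-chance associations on a shuffled prior yield
non-degenerate fits; with the 1-SE rule the shuffled-prior control collapses
to bias-only models, as it should. Fits whose coefficients are zero in every
fold are flagged degenerate and excluded from all correlation summaries.
Ligands are ranked by |mean over folds of L[l]·α_fold[l]|.

Controls: the autocrine model (sender := receiver) and the shuffled-prior
control (entries of I globally permuted, default 20 shuffles). The
network/regression agreement view plots log(edge count, taken in the
condition where the pair is stronger) against the pair's mean fold Pearson,
dropping pairs under the count threshold and degenerate fits, and reports
the correlation between the two (undefined and flagged below 3 pairs).

## The synthetic-data generator

The generator works top-down from a known Bayesian network over cell-type
abundance states, so every pipeline stage can be scored against ground
truth. Defaults (and why):

- **10 cell types, 6 directed edges.** Edges are placed by pairing nodes
  disjointly first, then wiring remaining edges between covered nodes under
  a degree cap of 2. Hub nodes with many noisy-OR parents have near-constant
  states — their edges are undetectable in principle — and nodes untouched
  by any edge are cheap targets for spurious additions, so spread-out
  truths are both fairer and more realistic.
- **Noisy-OR CPTs with heterogeneous strengths.** Roots are Bernoulli(0.5);
  a child is high with probability 1 − (1 − leak)·Π(1 − s_e) over its
  active parents (leak 0.1). Edge transmission strengths cycle through a
  ladder (0.85 ×4, 0.6, 0.25): real interaction strengths are heterogeneous,
  and a generator in which every interaction is equally strong says nothing
  about behaviour at the detection margin. The near-threshold edge is, by
  construction, the one a correct implementation should miss.
- **Composition model.** A type's state maps to a raw mass drawn from
  N(0.03, σ) (low) or N(0.12, σ) (high), σ = 0.025; a stable background
  population ("Other") carries raw mass 2.0; the vector is renormalized to
  sum to 1 (exactly). The background matters: without it, the modeled types
  are the whole denominator, and how many of them are high swings every
  fraction by ±40% — the abundance states stop being separable no matter
  how clean the expression data are. Real tissues are dominated by
  populations whose abundance does not track the interactions of interest.
  The composition noise σ is deliberately non-negligible: it sets a
  persistent state-label noise floor that suppresses marginal chance
  correlations (at N = 60 samples the BIC hurdle for a first parent is a G²
  of log N ≈ 4.1, which ~4% of null pairs clear by chance when labels are
  noise-free).
- **Expression.** 200 genes; 5 disjoint marker genes per type (background
  included); cells draw Poisson counts at rate 1.8 on their type's markers
  and 0.2 elsewhere; dropout zeroes each count independently with the given
  probability. Dropout reaches the pipeline only through annotation: the
  recovery experiments re-assign each cell to the type with the highest
  summed marker expression, so noisier expression means noisier
  compositions. (With the generator's true labels, dropout could not affect
  any downstream quantity.)

What the generator does *not* emulate: library-size variation, batch
effects, doublets, realistic gene–gene correlation beyond marker structure,
or ambient RNA. Passing recovery tests therefore demonstrates that the
inference machinery works when its compositional assumptions hold, not that
those assumptions hold in any particular real tissue.

## Recovery experiments and problem sizes

The headline recovery experiment simulates 30 samples per condition from
one truth (both conditions share it), 1000 cells per sample, re-annotates,
runs the 100-iteration bootstrap on the pooled 60 samples, and scores the
thresholded counts (threshold 20) against the truth, replicated 5 times
with fresh truths; the median replicate is reported. Matching is undirected
by default (edge orientation within a Markov equivalence class is not
identifiable from observational data), but the threshold always applies to
a single directed count, so a pair must be consistently present in one
orientation to be called. Precision is 1.0 by convention (and flagged) when
nothing is predicted.

## Known limitations

- The method needs many repeated samples; composition covariation across
  ~60 samples is the entire signal.
- Self-interactions are invisible (the network disallows self-edges).
- Bootstrap counts are not calibrated probabilities; the count threshold is
  a heuristic control, and no multiple-testing correction is applied across
  edges.
- At these sample sizes the BIC margin admits a few-percent rate of chance
  adjacencies per run; the bootstrap, direction-consistency thresholding
  and the generator's noise floor suppress but cannot eliminate them.
- The LTR identifies ligand *associations* consistent with the prior; it
  does not establish mechanism, and its resolution is bounded by the
  prior's quality.
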
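# Methods

This note records the models the package implements, the conventions it
fixes where several readings are defensible, what the synthetic-data
generator does and does not emulate, and the numerical choices that affect
results.

## Consistency: per-role jackknife predictors

The consistency engine treats a genome's annotation as a vector of role
multiplicities and asks, for each role, whether its count can be predicted
from all the other counts. Training data is a genomes × roles matrix of
non-negative integers. Candidate roles must (1) belong to subsystems,
(2) be present (multiplicity > 0) in at least 10% of training genomes
(closed bound), and (3) never exceed multiplicity 5 in *any* training
genome. Filter (3) is applied as an exclusion, not a cap: its purpose is to
remove mobile-element-like roles with highly variable counts, and capping
would hide exactly that variability. The three filters are per-role and
independent, hence order-independent.

For each candidate role, a model is trained to predict that role's
multiplicity from all other columns (the role's own count is never an input
to its own model — the jackknife property, preserved at scoring time).
Accuracy is estimated by 5-fold cross-validation: fold accuracy is the
fraction of exact multiplicity matches. Fold assignment sorts genome ids,
applies one seeded shuffle, and reuses the same folds for every target role
of an iteration, so results are reproducible, comparable across roles, and
invariant to input row order. Per-role training tasks are independent and
may run in parallel (`n_jobs`); results are identical to serial execution
because every task carries its own seed.

A role is **strongly predictable** when the Tukey trimean of its fold
accuracies exceeds 0.93 and their interquartile range is below 0.05 — both
strict inequalities ("better than", "less than"). Quartiles use linear
interpolation between order statistics (the "type 7" scheme, the default in
mainstream numerical software; no particular convention is canonical for
five values, so we document this one and test it against an independently
coded quantile routine). Selection is iterated: select, restrict the matrix
columns to the selection, repeat. Because selection is deterministic given
the matrix and the model spec, a pass that selects every current column is
a fixed point and training stops; a cap of 10 iterations (with a warning)
guards against oscillation, which we have not observed. Final models are
retrained on the converged matrix. An empty selection raises an error
carrying the iteration log.

Supported model families: random-forest classifier (the default; 100 trees,
unlimited depth), random-forest regressor, extremely randomized trees,
logistic regression, linear discriminant analysis, and gradient-boosted
trees (scikit-learn's histogram-based implementation is the package's GBT
of choice because it natively handles non-contiguous integer labels).
Regression outputs are rounded to the nearest integer, half away from zero,
then clipped to [0, 5] — the multiplicity cap the training filters enforce.
If a fold's model cannot be fitted at all (e.g. linear discriminant
analysis when the within-class scatter is singular), the fold falls back to
predicting the training majority class rather than aborting the whole
selection; the role then simply scores what such a degenerate predictor
earns.

Scoring: fine consistency is the percentage of reliable roles whose
annotated multiplicity exactly matches the prediction; coarse consistency
is the percentage whose presence/absence matches. Both are computed over
the *same* converged reliable-role set. The denominator for the coarse
score is a genuine design choice (an "all annotated roles" reading would
change absolute values); using the reliable set keeps the two scores
directly comparable and guarantees coarse ≥ fine, since an exact match
implies a presence match. Genome roles outside the training universe carry
no predictor; they are excluded from both scores and surfaced as
`n_unscored_roles`.

Model-comparison runs (`compare_models`) report, per family, the number of
roles passing the criterion after a *single* selection pass and the mean
trimean accuracy over **all** candidate roles (not only the selected ones)
— the comparison is about how families rank, and averaging over all
candidates avoids conditioning the average on each family's own selection.

## Completeness and contamination: weighted marker roles

For each taxonomic grouping at species, genus and family level, a marker
role is one annotated exactly once in ≥ 97% of the grouping's genomes
(closed bound; all supplied reference genomes count, with a configurable
minimum grouping size, default 2). Marker roles are clustered by pairwise
co-occurrence: an edge links two markers when both are *present*
(multiplicity ≥ 1 — co-occurrence is about joint presence, not single-copy
status) in ≥ 90% of the grouping's genomes, and clusters are the connected
components (single linkage — the simplest scheme consistent with pairwise
co-occurrence, and the one we fix since none is canonical). Each member of
a cluster of size N weighs 1/N, so a block of collocated roles counts as
one unit of evidence.

With M the marker set, O the occurring markers, n_x the genome's count of
marker x and N_x its cluster size:

* contamination = 100 · [Σ_{x∈O} (n_x−1)/N_x] / [Σ_{x∈O} n_x/N_x]
* completeness = 100 · [Σ_{x∈O} 1/N_x] / [Σ_{x∈M} 1/N_x]

Contamination is bounded below 100 for finite counts (uniform count k gives
100·(k−1)/k). When no marker occurs at all, both scores are defined as 0
and the result is flagged `no_markers_found`. One subtlety worth stating:
contamination is monotone when an *occurring* marker gains a copy, but a
0 → 1 increment adds a clean single-copy marker and can lower it — the
denominator grows while the numerator does not. That is a property of the
score, not a defect. Marker counts come from the annotations already on the
evaluated genome; there is no gene-calling or alignment phase.

Ranks are read off the lineage at fixed positions from the specific end
(species = last entry, genus, family), configurable via `rank_positions`.
A genome is scored against the most granular available grouping on its
lineage, falling back to coarser ranks; a lineage matching no grouping is
an error, since the scores are undefined without a reference expectation.

## Simulated degradation

Incompleteness lowers round(pct/100 · n_roles) *distinct* uniformly chosen
role counts by one (counts already at zero are selected but unchanged);
contamination draws round(pct/100 · n_roles) roles uniformly *with*
replacement and increments each draw, so the vector total grows by exactly
the number of draws. The percentage is taken over the whole role-vector
length, zeros included, and rounding is half-up. When both are applied,
incompleteness precedes contamination. Each genome is degraded
independently, re-randomized per seed.

The degradation experiment trains on an 80/20 seeded genome split
(train/validation overlap is an error), then, per grid condition and seed,
degrades every validation vector, recomputes predictions from the degraded
vector, and records (a) the fine consistency of the degraded annotation
against its own predictions and (b) the fraction of role predictions
identical to the undegraded baseline. The (0, 0) condition consumes no
randomness and reproduces the baseline exactly.

## The synthetic corpus generator

The generator is first-class, tested code: it is the ground truth against
which selection, marker derivation and degradation behavior are judged.
Each genome activates each latent subsystem independently with probability
0.7 (subsystems are all-or-none blocks, which is what makes their roles
mutually predictable); an active subsystem contributes one PEG per member
role, duplicated with probability 0.02 (gene duplication is rare in real
genomes; this keeps structured roles predictable at roughly the 97–99%
level rather than trivially at 100%). Noise roles take multiplicities
uniform on {0..5}, independent of everything — their best achievable
prediction accuracy is the max class frequency (~1/6), far below the
selection threshold, so they are the negatives of the selection problem.
Universal roles are single-copy in ~98% of each grouping by construction
(the exceptional genomes alternate between deletion and duplication, so
both completeness loss and contamination gain occur in intact corpora);
they are near-constant and therefore *also* strongly predictable, so the
ground-truth "predictable" label is structured ∪ universal roles. The
generator's RoleSet flags every generated role as a subsystem member so
that the accuracy criterion, not the subsystem filter, must reject the
noise. The first universal role is the pheS alpha chain, emitted with an
in-range protein length. Genomes carry contigs and 1-based coordinates
(features laid out sequentially on four contigs), three species-level
groupings with genus and family structure above them, and are bit-identical
under a fixed seed.

What the generator does **not** emulate: annotation errors and vocabulary
drift, fragmented or chimeric contigs, operon-level gene order,
compositional biases, and — importantly — the heavy zero-inflation of real
role vectors (thousands of vocabulary roles absent from any one genome).
Passing tests therefore demonstrate the machinery's correctness and its
qualitative behavior (score levels, monotone degradation response, marker
recovery), not quantitative performance on real corpora. One visible
consequence: simulated incompleteness changes more predictions here than on
real genomes, because a larger fraction of our role counts are nonzero.

## Problem sizes and defaults used in the shipped studies

The recovery study uses the generator's default corpus: 300 genomes, 20
subsystems × 10 roles, 100 noise roles, 20 universal roles, three groupings
of 100. The degradation study uses 150 genomes, 8 subsystems × 6 roles, 30
noise roles, 10 universal roles. Both use random forests with 20 trees: on
matrices of a few hundred columns, accuracy estimates are saturated well
below the default 100 trees, and the smaller forests keep the full studies
comfortably reproducible on a laptop. The acceptance script
(`scripts/acceptance.py`) recomputes every reported quantity from scratch
with these sizes, seeded entirely from `--seed`.

## Report conventions

The problematic-roles table has one row per reliable role whose predicted
and annotated multiplicities differ. Comments begin with "Universal role."
when the role is in the active marker set, then list each implementing
feature with its contig and flags. The flag thresholds are package
defaults, deliberately configurable because no standard values exist:
short contig < 1000 bp; near contig edge < 5 bp between feature and contig
boundary; short feature < 50% of the mean length of features implementing
the same role (computed over the scored genome plus the reference genome,
when given). For roles annotated fewer times than predicted, the reference
genome's implementing features are listed when available. Contigs carrying
no reliable role are reported alongside the table. External genome-browser
links are replaced by plain identifiers unless a URL template is
configured.

Good / good-seed classification uses closed bounds throughout:
contamination ≤ 10, fine consistency ≥ 87, completeness ≥ 80; exactly one
pheS alpha-chain PEG (matched by role name, tolerating an EC-number
suffix) with protein length in [209, 405] aa for bacteria or [293, 652] aa
for archaea. An unknown domain makes good-seed indeterminate; it is
reported as False with a warning.

## Known limitations

* The function→role grammar (separators `" / "`, `" @ "`, `"; "`, comment
  marker `" # "`) is a convention of this package; annotation sources vary
  and no authoritative grammar exists.
* One global predictor set is trained; there are no taxonomy-specific
  consistency models.
* Marker derivation uses all supplied reference genomes of a grouping; it
  does not pre-filter the references by their own quality.
* Accuracy statistics come from a single 5-fold CV run, not repeated CV;
  with five fold accuracies the trimean/IQR are coarse summaries by design
  (robustness over efficiency).
* The deep-learning predictor family is out of scope; the supported
  families are the classical ones listed above.
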
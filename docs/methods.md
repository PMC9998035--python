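# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `armroot`.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Presence/absence profiles and co-occurrence

A profile matrix holds three-valued cells: present, absent, unknown.
Unknown models the asymmetry of transcriptome evidence — a subunit missing
from a transcriptome is weak evidence of genomic absence — and is excluded
from every denominator; unknowns never drive exclusivity calls.

Two presence-call thresholds serve different roles and are deliberately
not merged: display/analysis presence is ≥ 1 detected subunit, while
dataset inclusion for survey-style screens uses ≥ 4 subunits
(`min_subunits_for_species_inclusion`).  All co-occurrence counts are
conditioned on species possessing a hub gene (default `Ndc80`) so that
species contributing no kinetochore signal at all do not inflate the
"neither" class.  Because a headline "percentage with either complex" is
ambiguous, the summary reports both the inclusive (A or B or both) and the
exclusive (exactly one) reading instead of choosing.

**Mutual exclusivity** is formalised as a one-sided permutation test:
permute complex-A presence labels among conditioning-positive species,
statistic = number of species with both complexes, with the add-one
estimator `p = (1 + #{perm ≤ obs}) / (1 + n_perm)`.  Species are
phylogenetically dependent, so an optional tree-aware null replaces
permutation: it redraws single-gain Dollo loss histories for both
complexes conditioned on the observed minimal loss counts, sampling
loss-edge sets of that cardinality uniformly among antichains of tree
edges (no edge ancestral to another — each lineage loses a complex at most
once).  The permutation null is the default because it is
assumption-free; the tree null is the conservative check.

## Dollo loss reconstruction

Under a single-gain (Dollo) model the minimal reconstruction is exact and
closed-form: one loss on each maximal subtree below the gain node that
contains no present leaf.  Clades are identified by the frozenset of leaf
labels they subtend, making outputs independent of node ordering.
Policies:

- gain placement: fixed at the root by default (the ancestral-origin
  hypothesis under test); `mrca_of_present` for the alternative.  The MRCA
  is unique, and with free unknowns the rootmost optimum is taken, which
  is the MRCA of the strict presents.
- unknown leaves: counted as absent but flagged (default), or "free" —
  assigned whichever state avoids a loss, so all-unknown clades never cost
  one.

Planted-history recovery is bounded, not exact: the minimal count can
never exceed the number of simulated losses, and equals it except when
sibling losses cover a whole parent clade and merge into one ancestral
loss.  The suite asserts the bound always and exact equality in the
majority of simulated histories; with per-subunit observation dropout and
the strict ≥ 4 call, spurious extra losses appear, which the suite
measures rather than hides.

## Paralogy networks

Profile-search E-value tables are asymmetric; reciprocal-best-match logic
uses the directional values (ties broken toward the lexicographically
smallest target label, documented and deterministic), while the homology
graph collapses direction by taking the smaller E-value as the edge
weight.  The significance threshold is a surfaced parameter, not a
constant, because the interesting deep-homology signals live at weak
("grey-zone") E-values; edges are anti-monotone in the threshold.  The
module never runs profile searches itself — it consumes their tabular
output.

## Structural superposition

Kabsch superposition via SVD of the cross-covariance matrix, with the sign
of the smallest singular component corrected so only proper rotations are
returned (protein chains are chiral).  RMSD is unweighted over all
supplied Cα pairs with no trimming or outlier rejection — trimmed variants
change numbers unpredictably and are therefore out of scope.
Correspondence between paralogous chains comes from the gap-free columns
of a global BLOSUM62 alignment (gap open −11, extend −1), or strict
one-to-one pairing for pre-matched traces.  Collinear point sets are
rejected: the rotation about the common axis is undetermined.

## Arm supermatrix

The merge of a subunit alignment with its cross-arm paralog's alignment is
a profile–profile global alignment over columns with affine gaps
(column score = mean pairwise BLOSUM62 over jointly non-gap residues;
open −11, extend −1; traceback ties resolve match > gap-in-B > gap-in-A).
Because the DP only inserts whole gap columns, every input column survives
unsplit and in order — deleting the partner's rows and the resulting
all-gap columns recovers each input exactly.  This contract is what makes
the concatenation sound; the suite checks it on random instances and
checks DP optimality against exhaustive alignment enumeration on short
inputs.  Externally produced merged alignments are accepted as-is through
the `merged_alignments` argument.

Trimming keeps a column iff its non-gap fraction ≥ `trim_keep_fraction`
(default 0.05).  The boundary is ≥, verified by a vendored synthetic
fixture encoding that rule (30 rows: a 1-residue column is removed, a
2-residue column kept).

Species enter the arm supermatrix only with ≥ `min_subunits_per_arm`
(default 2) present subunits in *both* arms, counting only paired
subunits — the two subunits without validated cross-arm homology (Spc19,
Spc34 in the default map) are excluded entirely.  Pseudo-taxa are named
`<species>__arm1` / `__arm2`; the double underscore is reserved and
validated so names round-trip through newick.  Partition blocks follow the
paralog-map file order, since no principled ordering exists, and are
reported 1-based inclusive (the common phylogenetics convention).  Locus
coordinates, by contrast, are 0-based half-open (BED convention); PDB
residue numbering is preserved 1-based.

## Likelihood model and tree search

Substitution models: Poisson (equal exchangeabilities, uniform
frequencies) and LG, with optional empirical (+F) frequencies and
discrete-gamma rate classes (default 4, class means of equal-probability
bins of Gamma(α, α)).  The rate matrix is scaled to one expected
substitution per unit branch length.  The published analyses this
re-implements used free-rate models (LG+F+R5, VT+F+R7) and ultrafast
bootstrap inside an external inference tool; free-rate fitting and UFBoot
are features of that tool, while the hypotheses being compared need only
per-site log-likelihoods, which discrete-gamma + RELL provide at desk
scale.  The substitution is recorded verbatim in every provenance block.
Ambiguity codes (B, Z, X) and gaps are missing data (partial likelihood 1
in every state).

Likelihoods use post-order pruning with per-node scaling; gamma mixtures
are averaged per site in log space.  Branch lengths are optimised
coordinate-wise (bounded Brent per edge, sweeps until the total
log-likelihood gain < tol); the total never decreases.  Tree search is NJ
(Poisson closed-form distances, or per-pair 1-D ML distances for LG;
negative NJ lengths clamped to 0) followed by NNI hill climbing in a
canonical rooted-at-leaf representation, best strict improvement per
sweep, candidates re-optimised coarsely before comparison.  NNI-only
search (no SPR) is a documented limitation, adequate at the tree sizes
this package targets.  A constraint tree is honoured by rejecting any
move whose topology, pruned to the constraint's taxa, fails to contain
every constraint bipartition.

## Topology tests

RELL resamples site indices with replacement; at scale *r* each replicate
draws ⌈r·n⌉ sites.  KH tests each topology against its best competitor
with centred replicate differences at scale 1.  AU follows the multiscale
formulation: bootstrap proportions BP_r over the default scales 0.5–1.4
(step 0.1, always containing 1.0), weighted least squares on
Φ⁻¹(1 − BP_r) ≈ d√r + c/√r with binomial-variance weights,
p = 1 − Φ(d − c), clamped to [0, 1].  Exact replicate ties split their win
equally between topologies, so two topologies with identical site vectors
get p ≈ 0.5 rather than 1 and 0.  A topology that never wins a replicate
at any scale is flagged degenerate with p = 0; one that never loses gets
p = 1.  Bootstrap proportions are clamped to [1/(2B), 1 − 1/(2B)] before
the inverse-normal transform.  All test stages are seed-reproducible.

Support for the arm split is reported as the scale-1 RELL proportion of
the observed topology against its two NNI rearrangements across that
branch — a local, hypothesis-focused support value consistent with the
testing framework used everywhere else.

## Genomic co-localization

Species are classed by distinct-scaffold count among their subunit loci
(`all_distinct`, `partial_shared`, `single_scaffold`; fewer than two loci
= `insufficient`, reported, never silently dropped).  "Distance apart" is
defined as the intergenic gap, max(0, later.start − earlier.end), because
midpoint distance conflates gene length with spacing; overlapping genes
get gap 0 with an overlap flag, and the per-pair table lets users compute
any other metric.  The clustering verdict is deliberately blunt —
"clustered" only when a configurable majority of classifiable species are
single-scaffold *and* the mean gap is below a configurable bound — with
thresholds echoed in the output.

## Synthetic generator: what it emulates, and what not

- **Species trees**: birth–death (default pure-birth), conditioned on a
  tip count or run unconditioned for a fixed time; ultrametric, extant
  taxa only.
- **Coupled Dollo losses**: both complexes present at the root; per
  branch, loss is the first arrival of a Poisson process (at most one loss
  per lineage per complex); once one complex is lost, the other's rate is
  multiplied by max(0, 1 + coupling).  Defaults — loss rates 0.6 and 0.45
  per unit branch length, coupling −0.9, 10% per-subunit observation
  dropout — were chosen once so that a default-sized simulation
  reproduces the qualitative extant pattern the real complexes show:
  roughly 40–55% of species with exactly one complex, a few percent with
  both, and a minority with neither.  No quantitative loss-rate estimates
  exist to fit to, so these are testability conditions, not biological
  estimates.
- **Sequences**: the duplication tree (proto-subunit → two arm ancestors →
  balanced within-arm splits) is grafted above a copy of the species tree
  per terminal subunit, pruned by the complex's loss clades; sequences
  evolve by exact per-branch CTMC transition sampling (matrix exponential
  via the reversible eigendecomposition — exactness over Gillespie speed
  at these sizes).  Per-site gamma classes are fixed across the tree.
  Subfunctionalisation is represented only as divergence time; arms are
  monophyletic in the generator's duplication tree because that is the
  property the rooting test needs.
- **Loci**: clustered layouts place all subunits on one scaffold with
  exponential intergenic spacing; dispersed layouts assign scaffolds
  uniformly at random.

Not modelled: indels (merge and trim are exercised by construction and by
dedicated fixtures instead), across-lineage rate variation, horizontal
transfer (regrafting in tests can emulate it), and any sequence-level
signature of subfunctionalisation.  Passing recovery tests therefore show
correctness of the inference machinery under the model's assumptions, not
robustness to alignment error or rate heterogeneity in real data.

## Problem sizes and calibration conditions

The suite and acceptance script use deliberately small, fixed problem
sizes chosen for sharp oracle checks: Dollo minimality is verified against
exhaustive search on 1000 random trees of 4–10 leaves; pruning likelihoods
against full ancestral-state summation on 4-taxon, 10-site fixtures
(tolerance 1e-10); merge optimality against exhaustive alignment
enumeration up to length 8.  AU/KH calibration uses 500 exchangeable-null
datasets of 100 sites at 1000 RELL replicates (nominal 0.05, three
standard errors).  Arm-root recovery uses 6-species trees: 200-site
alignments with species-tree height 0.4 and arm divergence 1.0 for the
strong-signal condition (≥ 95/100 seeds), and a noisy 50-site,
height-1.4 regime to show recovery decaying as the duplication divergence
shrinks toward zero.  In that generator, arm pseudo-taxa remain closer to
their own arm than to the other even at zero duplication divergence (both
arms mirror the same species tree), so degradation appears only when
stochastic estimation noise competes with that structural signal — hence
the short alignments in the degradation condition.

## Known limitations

- The pipeline consumes curated presence calls and E-value tables; it
  does not perform homology searches, and misannotation upstream
  propagates.
- Dollo minimal counts are lower bounds on true loss counts by
  construction.
- The AU implementation follows the standard multiscale formulation but
  is not a re-implementation of any specific external tool's numerics;
  p-values agree in calibration, not bit-for-bit with other software.
- NNI-only search can stall in local optima on larger trees; the intended
  scale is tens of pseudo-taxa.
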
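# Methods

This note records the model, the numerical conventions, the synthetic
data generator and the deliberate design choices behind `protovar`. It
states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scope and assumptions

`protovar` is a per-gene supervised framework: it assumes a curated set
of labelled missense variants for one protein (pathogenic vs benign),
a 3D structure or homology model covering part of the sequence, and
per-position annotation tracks produced by upstream tools (conservation
grades, disorder probabilities, stability/interaction effect scores,
UniProt-style domains, topology and functional sites). It does not
recompute those upstream predictions, does not ingest genomic
coordinates or VCF, and works on a single chain with PDB residue
numbers equal to 1-based protein positions (a constant offset flag
covers renumbered structures). Genes with fewer than 70 pathogenic
variants are excluded by the dataset filter — per-gene training below
that scale is statistically fragile, and the cut-off mirrors the
curation rule of the cohort design this package targets. Benign sets
are accepted as curated (e.g. hemizygous-only population variants);
the only dataset-level rule recomputed here is the removal of benign
records whose (gene, position, ref, alt) key also appears in the
pathogenic set.

## The 22-feature catalogue

Sequence features: conservation grade (1–9, 9 most conserved), signed
Richards-scale volume change and its category (|ΔV| ≥ 40 Å³ counts as
large — roughly one CH₂-rich side-chain step; the downstream supervised
discretization makes models insensitive to the exact constant),
hydrophobic↔polar transition against the strong set {V, I, L, F, M, W,
C} (configurable; the scale used identifies seven strongly hydrophobic
residues), formal charge change, and three residue-specific rules:
proline introduced at a β-strand position, glycine gained or lost at a
buried position, cysteine gained or lost in an extracellular region.

Structure features: relative side-chain solvent accessibility
(below), burial class (buried < 9%, intermediate 9–36%, exposed > 36%;
Naccess-derived practice, configurable), molecular goodness-of-fit
violation (buried site and ΔV > 40 Å³), secondary structure (track
values win; otherwise a φ/ψ-dihedral fallback assigns H for sustained
helical windows (φ ∈ (−100°, −30°), ψ ∈ (−80°, −5°), runs ≥ 4) and E
for extended windows (φ ∈ (−180°, −80°), ψ ∈ (60°, 180°), runs ≥ 3) —
deliberately simpler than DSSP, matching the role of a visualization
tool's cartoon assignment), modelled status, 3D clustering (count of
*other* pathogenic-variant positions with Cα within 8 Å — leave-one-out,
so the feature never encodes the variant's own label) and the analogous
sequence-window count (±5 residues). Consumed tracks contribute
disorder probability and its flag (cutoff 0.5, closed), stability and
interaction effect scores, functional-site flag, domain and topology
categories.

Unmodelled variants keep their sequence features; every structure-only
feature becomes an explicit missing value, and missingness is carried
as its own category through training rather than imputed.

The clustering features are computed once per dataset from all labelled
pathogenic variants. Under cross-validation this means a training-set
statistic touches test-fold *positions* (not labels of the test
variants themselves, which leave-one-out excludes); the alternative —
recomputing cluster counts inside each fold — would change the feature
definition between training and deployment. We keep the global
definition and note the residual optimism it can carry for clustered
genes.

## Solvent accessibility

SASA is Shrake–Rupley (Biopython's engine) with probe radius 1.4 Å and
300 sphere points per atom. Side-chain accessibility is the summed
area of non-backbone atoms (glycine, and any residue whose side-chain
atoms are absent, falls back to the Cα convention). Relative
accessibility divides by a per-residue reference area. The default
reference is **self-consistent**: the same residue's side-chain area
recomputed by the same engine with all other residues removed, so an
isolated residue scores exactly 100% regardless of how many side-chain
atoms the model carries. Classic fixed extended-tripeptide constants
are available (`reference="tripeptide"`) and appropriate for full-atom
structures; they are wrong for reduced representations, which is why
they are not the default. Quadrature noise at 300 points is ~1–2 Å²
per residue (about 2 percentage points of a Cβ-sized reference); the
convergence test shows values stable to < 2 pp under point-count
doubling in the converged regime (960 points). Fixed-sphere-point SASA
is exactly translation invariant but only statistically rotation
invariant; burial bins are insensitive at this noise scale.

## Preprocessing

**Class balancing.** The minority class weights are multiplied by
N_majority / N_minority, leaving the majority at weight 1, so both
classes carry the majority's total weight (20/80 → ×4, totals 80/80).
This follows the filter's documented worked example rather than the
alternative normalization that rescales both classes to N/2; only the
relative class weighting matters downstream.

**Supervised discretization.** Fayyad–Irani recursive binary splitting
on weighted class entropy. Candidate cuts are midpoints between
adjacent distinct values; a cut is accepted iff

    Gain > (log2(N−1) + log2(3^k − 2) − k·Ent(S) + k1·Ent(S1) + k2·Ent(S2)) / N

with N the total instance weight and k the number of classes present.
Features failing at the root keep a single bin (which removes them from
the model); bin convention is x ≤ cut → lower bin; values beyond the
fitted range go to the nearest end bin; missing values are ignored
during the search and form their own category. Both filters are fitted
inside each cross-validation training fold — the leak-free reading of a
"filter first, then cross-validate" pipeline; the acceptance suite
demonstrates that fitting the cuts globally on pure noise inflates CV
MCC while fold-internal fitting keeps it at chance.

## Classifiers

All three respect instance weights exactly as replication and are
deterministic given data order and seed.

**LogitBoost (decision stumps).** Two-class convention F(x) = Σ 0.5·f_m,
p = 1/(1+e^(−2F)). Per iteration: working responses
z = (y − p)/(p(1−p)) clamped to ±3 with p clipped to [1e−5, 1−1e−5],
case weights w·p(1−p), and one weighted least-squares regression stump
(best feature × best threshold by explained weighted SSE; missing
values get their own leaf). M = 10 iterations — the named algorithm's
canonical default.

**Simple logistic.** The same boosting machinery with single-attribute
weighted linear regressions as base learners; categorical attributes
are one-hot expanded, all attributes standardized by weighted moments
with missing values imputed at the standardized mean (zero). The
boosting length (max 30) is chosen by internal stratified 5-fold
cross-validated log-loss, which is what guards it against irrelevant
features. The ±3 response clamp leaves a small Newton residual, so an
intercept-only model converges to the class prevalence only to ~0.01.

**Hoeffding tree.** An incremental tree over nominal attributes (the
pipeline discretizes numerics first; raw numeric values act as distinct
nominal levels). A leaf attempts a split after every 200 units of
accumulated instance weight: the information-gain lead of the best
attribute over the runner-up must exceed the Hoeffding bound
ε = sqrt(ln(1/δ)/(2n)) with δ = 1e−7 and range R = log₂(2 classes) = 1,
or ε must have shrunk below the 0.05 tie threshold. Leaves predict
Laplace-smoothed class probabilities; rows are consumed in input order
(documented for reproducibility). On per-gene datasets of a few hundred
instances the bound is rarely met — the tree then predicts the
(balanced) prior and scores MCC 0, which is faithful small-sample
behaviour of the algorithm rather than a defect; it becomes competitive
at thousands of instances.

## Evaluation and selection

MCC is computed from the confusion matrix with the 0-on-degenerate-
denominator convention. ROC AUC is the Mann–Whitney pair probability,
PR AUC the average-precision sweep (both via scikit-learn, verified
against brute-force pair counting / sweep oracles to 1e−12 in the
tests). Repeated stratified k-fold CV (defaults k = 10, repeats = 10)
reshuffles per repeat; per repeat the fold predictions are pooled into
one confusion matrix (not averaged per fold — an explicit test
separates the two) and the report carries mean and SD over repeats. k
is reduced with a warning when a class is smaller than k.

Algorithm selection returns the argmax mean CV MCC with fixed tie
precedence (logitboost, simple logistic, Hoeffding tree). Feature
selection ranks features by |Pearson r| with the class (missing values
pairwise-deleted, constants scoring 0) and greedily drops the
lowest-ranked remaining feature whenever the drop does not lower the
CV MCC (tolerance 1e−9; search CV uses 3 repeats; passes repeat until
no drop survives; at least one feature always remains). Exhaustive
subset search over 2²² subsets is out of the question; the greedy
procedure is a reproducible automation of correlation-guided manual
exclusion. Selection reuses per-fold preprocessing across candidate
subsets and algorithms — valid because balancing is feature-independent
and MDL cuts are per-column — and a test asserts the cached path equals
the full per-fold pipeline bit for bit.

Kruskal–Wallis (tie-corrected H, χ² p on g−1 df) and the Wilcoxon
signed-rank test (zeros dropped; exact p for n ≤ 25 without ties, else
corrected normal approximation) are thin wrappers over scipy with the
degenerate cases pinned (identical groups → H = 0, p = 1; all-zero
differences → p = 1).

## Gene-specific thresholds

The candidate grid is the 21 uniform values {0.00, 0.05, …, 1.00};
classification is pathogenic iff score ≥ t, ties break toward the
lowest qualifying threshold. Per repeat (n = 10), scores are shuffled
and stratified into 5 folds; per fold the grid argmax-MCC threshold is
fitted on the 80% training share and its MCC measured on the held-out
20%. The reported gene-specific threshold is the **median** of the 50
training thresholds (the aggregation rule is our choice; a single
per-gene threshold must summarize 50 fits) and the optimized MCC the
**mean** of the 50 held-out MCCs — one defensible way to turn repeated
subsampled fits into a single optimized score. The default MCC is
the whole-data MCC at the tool's published threshold. Degenerate
single-class folds trigger a reshuffle with an incremented seed (up to
10 retries). Balanced mode undersamples the majority class to the
minority size (uniform, without replacement, seeded) before the whole
procedure. When the majority class is pathogenic and high-scoring —
the typical composition of disease-gene cohorts — the imbalanced-mode
threshold is dragged low and balancing shifts it back up; the test
suite encodes that direction.

## Synthetic data generator

The generator targets the statistical structure of per-gene cohorts,
not biophysics. Toy structures: ideal helices (φ = −57°, ψ = −47°) and
strands (φ = −120°, ψ = 130°) built with standard backbone geometry
(NeRF placement, Cβ side-chain proxy, glycine-free sequences so every
residue keeps its proxy), and a "packed globule" — residues on a
5.2 Å lattice ball with jitter, giving a genuine buried core and a
realistic buried/intermediate/exposed mix. Valid PDB text is emitted
and re-parsed through the package's own reader.

A gene simulation (`GeneSimSpec`) draws a sequence, models the head of
it as a globule (the `unmodelled_fraction` tail has no coordinates),
and places variants: pathogenic preferentially at buried positions
(probability 0.6 vs 0.1 benign) and rarely unmodelled (0.05 vs 0.3);
positions are mostly class-coherent (`position_coherence` 0.9 — the
probability of rejecting a position already owned by the other class),
which is what creates the 3D/sequence clustering signal. Per-position
tracks are class-conditional at variant positions (conservation grade
8–9 with probability 0.9 at pathogenic vs 0.2 at benign sites; disorder
Beta(1,6) vs Beta(3,3); stability Beta(5,2) vs Beta(2,5); interaction
Beta(3,3) vs Beta(2,6); functional sites 0.3 vs 0.05). `EffectProfile
.null()` collapses every one of these onto the benign values *and*
zeroes the position coherence, making the two classes exactly
exchangeable — the null-calibration tests depend on that exactness.
Score tables draw class-conditional Beta samples; the analytic density
crossing (root of the log-density difference) is recorded as the
ground-truth optimal threshold. Everything is deterministic under the
spec seed.

What the generator does not emulate: mutation spectra, residue-type
biases of real pathogenic variants, correlated annotation errors,
homology-model inaccuracy, and label noise. Passing tests therefore
show the machinery is correct and calibrated, not that real-data
performance will match the synthetic MCCs.

The default panel spans 21 genes with 70–600 pathogenic and 15–200
benign variants each (sequence lengths 150–400, unmodelled fractions
0.05–0.35) — the cohort-scale envelope the method is designed for. The
acceptance script runs this panel end to end; these sizes are the
package's chosen study conditions.

## Known limitations

- Numeric parity with any particular WEKA version is not a goal; the
  algorithms follow their published forms with pinned defaults.
- The Hoeffding tree is effectively a prior predictor below a few
  hundred weighted instances per leaf (by design of its bound).
- Cluster features use the full labelled pathogenic set (see above).
- Probabilities are calibrated on the balanced training distribution,
  not the natural class prevalence.
- The SASA quadrature noise (~2 pp at default settings) is negligible
  for burial bins but matters if raw percentages are consumed at finer
  resolution; raise `sasa.n_points` for that.
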
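# Methods

## Problem and model

The package discriminates two phenotype classes among germline protein
variants already known to be disease-associated: cancer predisposition
vs. other genetic disorders. The working hypothesis is that this
distinction is largely a property of the *protein* — its biological
role — rather than of the individual substitution. Accordingly the
core statistic is a per-protein GO-score, and the classifier augments
it with substitution-level features so that differently labelled
variants on the same protein can still be separated.

### GO-term log-odds

For a training set with `n_C` cancer-labelled and `n_O` other-labelled
variations, each GO term *t* of sub-ontology aspect *a* ∈ {C, F, P}
receives

    s(t) = ln[(c_t + κ)/(n_C + 2κ)] − ln[(o_t + κ)/(n_O + 2κ)]

with `c_t` (`o_t`) the number of cancer (other) variations whose
protein is annotated with *t*. Counting is at the **variation level**:
a protein with ten labelled variations contributes its terms ten
times. This weights terms by the amount of labelled evidence; a
protein-level counting mode exists (`per_protein=True`) but is off by
default. The Laplace pseudocount κ = 1 (configurable) keeps log-odds
finite for terms seen in only one class; it shrinks rare-term scores
toward 0, which is the behaviour wanted for terms with one observation.
A protein's GO-score per aspect is the sum of `s(t)` over its annotated
terms present in the table; absent terms contribute nothing and do not
count toward coverage. No GO-DAG ancestor propagation is performed by
default — term sets are used exactly as annotated.

GO-only classification is a sign rule: score > 0 ⇒ cancer, ties to the
majority class (other). Single-aspect modes return "unpredicted" for
proteins with no table-resident term in that aspect; the CFP mode
averages the *covered* aspects only, so any annotated protein is
predicted and coverage is total.

### Feature encodings and SVM

Vectors are composed in the fixed segment order [mut | E | Wx | GO]:

* `mut` (20): −1 at the wild-type index, +1 at the mutant index.
* `E` (4): the PSSM row at the mutated position, read as wt/mut
  substitution log-odds (scaled by 1/10, giving values in roughly
  [−2, 2]) and wt/mut observed frequencies (scaled to [0, 1]). The
  legacy two-block ASCII profile contributes one wt and one mut value
  per block; this reading and its scaling are configurable design
  choices, as is the use of the frequency block (not log-odds) for the
  window.
* `Wx` (20·x): frequency rows for the x positions centred on the
  mutation, zero-padded where the window crosses a sequence end.
* `GO` (3): the protein's C, F, P GO-scores from the fold's tables.

Features are z-standardised with training-fold statistics (RBF kernels
need comparable scales; test rows reuse the training parameters — a
leakage guard asserted in tests). The SVM uses an RBF kernel with
class weights inversely proportional to training-class frequency,
which is what lets a ~16%-prevalence class reach useful recall, and a
hard decision threshold at 0.

### Identity-aware cross-validation

Folds must not let homology leak label information. Pairwise identity
is defined by contract — best local alignment under BLOSUM62 with
affine gaps 11/1, identity = identical columns / aligned columns —
implemented with Biopython's `PairwiseAligner`, and significance is a
Karlin–Altschul E-value with the standard gapped BLOSUM62 parameters
(λ = 0.267, K = 0.041). Any engine honouring the same contract can be
substituted behind `pairwise_identity`. Proteins joined by an edge
with identity ≥ 25% and E < 10⁻³ are forced into the same fold
(single-linkage closure); components are dealt heaviest-first onto the
lightest fold to balance variation counts, with the seed shuffling
equal-weight order. Every produced split can be audited with
`check_fold_validity`, an exhaustive scan. Inside cross-validation the
GO tables, the scaler and the SVM are fitted per round on the nine
training folds only, with (C, γ) from an inner stratified 5-fold
search maximising MCC over a default grid C ∈ {0.5, 1, 2, 4, 8},
γ ∈ {0.01, 0.05, 0.1, 0.5, 1}; an assertion verifies that no test
protein sits in the GO tables' training partition. Pooled metrics are
computed on summed fold counts (per-fold summaries are also kept).

### Transfer-by-similarity baseline

Hits for a query are all other dataset proteins with a reported
alignment (permissive ceiling E ≤ 100, as a deliberately generous
baseline), sorted by ascending E-value with ties broken by higher
identity then identifier. The overall best hit is retained only when
its identity does not exceed the sweep threshold (the alternative
"first hit under the bound" is available behind a flag). The hit's
majority variant label is transferred to *all* query variants; an
equal split predicts the majority class (other). Queries without a
retained hit are unpredicted and counted in the protein-coverage
column.

### Evaluation indices

With cancer as the positive class: Q2 = (TP+TN)/N;
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)), reported as 0
with a flag when a marginal is empty; per class, Sp is the class
predictive value TP_c/(TP_c+FP_c) and Sn the class recall
TP_c/(TP_c+FN_c). This Sp/Sn convention is isolated in one module so
it can be swapped; unpredicted variants are excluded from counts and
reported as coverage.

## Synthetic benchmark generator

The generator emulates the structure the method exploits: proteins
carrying batches of same-labelled variations whose GO annotations are
class-conditionally skewed. Per aspect, a flat vocabulary (default 60
terms) is halved; a term slot of a cancer protein falls in the
informative half with probability σ(δ) and uniformly within the half,
so every informative term has true log-odds exactly +δ and every other
term −δ. Term sets are drawn as a binomial informative count with
distinct terms per half, which makes the GO-only Bayes-optimal
accuracy an exact binomial expression (`bayes_accuracy`, enumerating
the 8 aspect-coverage patterns); it is defined only for single-class
datasets, since dual-class proteins draw terms uniformly (their
functional signal is deliberately absent — these are the variants only
the substitution features can separate). Sequences are i.i.d. uniform
residues with no class signal, so substitution-only encodings have a
chance-level ground truth and encoding ablations have a known ordering.
Profiles favour the wild-type residue via a Dirichlet concentration
(default 10) and are emitted in the legacy two-block ASCII dialect.

Default conditions: 592 proteins, 2–20 variations each (mean ≈ 11),
16% cancer proteins, 3.4% dual-class proteins (whose variations are
47% cancer), per-aspect annotation coverage (0.89, 0.98, 0.96) for
C/F/P, δ = 2.0 — a strong but imperfect signal chosen once as the
realistic regime for a curated disease set. What the generator does
*not* emulate: a real GO DAG (flat vocabularies suffice for log-odds
arithmetic), realistic protein families and homology structure
(synthetic sequences are essentially all unrelated, so identity-based
fold constraints are exercised mainly through constructed fixture
graphs), or annotation-bias correlations between classes. Passing
tests therefore demonstrate the estimators and the protocol, not
performance on real curated variant data.

## Problem sizes and numerical choices

Tests and the acceptance script scale the conditions down to keep
single-CPU runs short: typically 150–400 proteins with 2–8 variations
each for cross-validation experiments, 300 proteins for the end-to-end
benchmark, and reduced hyperparameter grids where the grid is not the
quantity under test; these sizes are stated in each test. Null
calibration pools confusion counts over 5 seeded runs before computing
MCC, because at a few hundred effectively-independent proteins a
per-seed MCC has standard deviation ≈ 0.05–0.09 and would not support
a meaningful ±0.1 assertion. Determinism is end-to-end: one
`numpy` generator per dataset seed, seeded fold shuffles and inner CV
splits, sorted iteration everywhere a dict could reorder, and
tie-breaks fixed (equal inner-CV MCC → first grid entry; equal
discriminative log-odds → term identifier; equal best-hit E-values →
higher identity then identifier). Model bundles serialise with a
version-stamped pickle payload carrying the GO tables, scaler
parameters, encoding config and hyperparameters, so a loaded bundle
reproduces decision values bit-exactly.

## Known limitations

* The ≥25% identity / E < 10⁻³ fold constraint follows the standard
  redundancy convention; at very short alignment lengths percent
  identity is a noisy quantity and the E-value filter is what carries
  the significance decision.
* The Sp/Sn convention (predictive value / recall per class) is one of
  two plausible readings of class-wise "specificity/sensitivity"
  reporting; both can be derived from the emitted confusion counts.
* The cascade interface consumes an upstream disease/neutral call
  table; it does not re-implement any upstream predictor.
* All-against-all alignment is quadratic in the number of proteins and
  intended for curated-set scale (hundreds), not proteome scans.
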
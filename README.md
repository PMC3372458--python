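# mutgo

Classify disease-associated germline protein variants into
**cancer-associated** vs. **other genetic diseases**.

Most variant-effect predictors stop at "disease vs. neutral". For a
curated set of germline amino-acid substitutions already known to be
disease-related, the next question is *which* phenotype — and for
cancer-predisposition variants the answer turns out to live largely in
the protein's function, as described by its Gene Ontology (GO)
annotation. `mutgo` implements this idea end to end for
bioinformaticians who curate or prioritise germline variant sets:

* **GO-score** — for each GO sub-ontology (Cellular Component C,
  Molecular Function F, Biological Process P) and each term *t*, a
  training set defines a log-odds

  ```
  s(t) = ln[(c_t + κ)/(n_C + 2κ)] − ln[(o_t + κ)/(n_O + 2κ)]
  ```

  where `c_t` / `o_t` count the cancer- / other-labelled variations
  whose protein carries *t*, `n_C` / `n_O` are the class totals and
  κ = 1 a Laplace pseudocount. A protein's GO-score per aspect is the
  sum of `s(t)` over its annotated terms; positive means cancer-like.
* **Feature encodings** — the variant itself (`mut`: −1 at the wild
  type, +1 at the mutant in a 20-vector), evolutionary information from
  a PSI-BLAST PSSM (`E`: the wt/mut log-odds and frequency columns;
  `Wx`: a profile window of width *x*), and the three GO-scores (`GO`),
  composed into the named encodings `mut_E_W1` … `mut_GO`.
* **RBF-kernel SVM** with class weights for the ~16% cancer class,
  hyperparameters from an inner 5-fold search maximising MCC.
* **Identity-aware 10-fold cross-validation** — folds are
  single-linkage components of the ≥25%-identity graph (local
  alignment, BLOSUM62, gaps 11/1, E < 0.001), so no test protein has a
  detectable homolog in training, and the GO tables are re-fitted per
  fold on training data only.
* **Transfer-by-similarity baseline** — each query protein inherits the
  majority variant label of its best database hit, swept over identity
  thresholds.
* **Evaluation** — overall accuracy Q2, Matthews correlation
  coefficient, and class-wise Sp (predictive value) and Sn (recall),
  with explicit coverage columns for methods that cannot predict every
  variant.
* **Synthetic benchmark generator** — variants, FASTA, GO tables and
  PSSMs with controllable class-conditional GO-term frequencies
  (effect size δ) whose Bayes-optimal accuracy is known in closed
  form, so every claim above is testable offline.

## Worked example

Generate a benchmark with a strong functional signal and evaluate the
full method on it:

```sh
mutgo simulate --n-proteins 300 --effect-size 2.0 --seed 1 --outdir fixtures
mutgo crossval --variants fixtures/variants.tsv --fasta fixtures/sequences.fasta \
      --go fixtures/annotations.tsv --pssm-dir fixtures/pssm \
      --encoding mut_GO --encoding OnlyGO --encoding mut \
      --k 10 --seed 1 --outdir run
cat run/svm.tsv
```

The run takes a few minutes (the all-against-all identity scan and the
inner hyperparameter search dominate) and printed:

```
row     n     coverage  Q       MCC     Sp(C)   Sn(C)   Sp(O)   Sn(O)
mut_GO  3433  1.0000    0.9921  0.9715  0.9928  0.9599  0.9920  0.9986
OnlyGO  3433  1.0000    0.9924  0.9726  0.9928  0.9616  0.9924  0.9986
mut     3433  1.0000    0.6976  0.0159  0.1784  0.2251  0.8362  0.7923
```

Read: with GO-scores in the input the classifier recovers the
generator's functional signal almost perfectly (Q = 0.99, MCC = 0.97 on
3433 variants), while the substitution-only encoding is at chance
(MCC ≈ 0) — by construction, since the generator puts no signal in the
sequences. The gap between the first two rows and the last is the
package's central claim: protein function, not the substitution itself,
carries the cancer-vs-other information. `run/baseline.tsv` and
`run/go_only.tsv` hold the similarity-transfer sweep and the
GO-score-only rows with their coverage columns.

A trained model can also screen an external variant set it has never
seen (e.g. somatic calls expected to look unlike germline cancer
variants): `mutgo train … && mutgo screen …` prints the fraction
predicted per class.

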
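# Methods

## Model and assumptions

The predictor treats epitope immunogenicity as a binary classification
problem on 9-mer peptide sequences over the 20 standard amino acids.
Three assumptions shape the design:

* the signal is in the primary sequence (plus per-residue structure
  *predictions*), not in MHC-peptide complex structures;
* no single sequence representation suffices, so diversity of encoders
  matters more than depth of any one of them;
* feature sets are partially redundant, so the ensemble over a *subset*
  of encoders can beat the ensemble over all of them, making subset
  selection part of model fitting.

An ensemble is defined entirely by its feature subset: each selected
encoder gets an independent random-forest base classifier, and the
ensemble score of a peptide is the unweighted arithmetic mean of the
base classifiers' positive-class probabilities. Probability averaging
(rather than vote averaging) is used because AUC, a ranking metric, is
the primary objective throughout. The ensemble score is therefore
bounded by the minimum and maximum base score, and adding an
uninformative base shrinks all scores toward 0.5.

## Feature encoders

Encoder layouts and widths are documented in `immunoga.features`. Choices
that were genuinely open:

* **Sparse profile (F4)** is 9×20 = 180 wide — one one-hot block per
  position. A 20-wide variant would collapse to composition and lose
  exactly the positional information this encoder exists to carry.
* **Position-wise physicochemical (F1)** is position-major: for residue
  position i = 1..9 the 11 scale values are emitted consecutively.
  The same layout is used for the contact-potential (F6, 9×40) and QTMS
  (F7, 9×21) encoders.
* **λ-parameterised encoders** (F11–F16) accept 1 ≤ λ ≤ 8 (sequence
  length − 1). Defaults are the per-feature optima from the published λ
  sweep on the IMMA2 benchmark: λ = 7 for the three autocorrelations,
  8 for QSO and PseAA, 2 for AmPseAA.
* **Autocorrelation scales** are z-scored over the 20 letters with the
  population standard deviation before use; on a homopolymer the
  Moran/Geary denominators vanish and the affected entries are emitted
  as 0 with a logged warning (keeps vectors finite; unreachable for
  realistic peptides).
* **QSO/PseAA weights** default to w = 0.1 and w = 0.05 respectively,
  the customary defaults of those descriptor families. At w = 0 both
  reduce exactly to amino-acid composition, which the tests exploit.
* **Smith–Waterman similarity (F5)** uses BLOSUM62 with gap open 10 and
  extension 1 (a gap of length n costs 10 + (n−1)), raw scores, computed
  through biotite's optimal-alignment routine behind the encoder
  surface. The reference set is always the current training fold, so
  the feature's width varies by fold and the fitted reference travels
  inside the model. Pairwise scores are cached process-wide; repeated
  cross-validation reuses them heavily.
* **CTD** uses the seven conventional attribute partitions
  (hydrophobicity, normalized van der Waals volume, polarity,
  polarizability, charge, secondary-structure propensity, solvent
  accessibility), giving the canonical 21/21/105 widths. Distribution
  ranks use ceil(frac·m) with the first occurrence at frac = 0.

### Stand-in lookup tables

Three inputs of the original feature set are not redistributable or not
reconstructable offline, and are replaced by documented stand-ins:

* the 11 named AAindex accessions resolve to 11 bundled published
  scales (Kyte–Doolittle hydropathy, Hopp–Woods hydrophilicity,
  side-chain masses, Grantham polarity/volume/composition, side-chain
  charge, isoelectric points, Chothia accessible surface areas,
  Chou–Fasman helix and sheet propensities);
* the 40 contact-potential scales (F6) and the 20×21 QTMS table (F7)
  ship as *seeded synthetic* tables of the correct shape (flagged in
  their filenames and headers) and are replaceable via
  `FeatureContext(contact_potentials=…, qtms_table=…)`;
* the second QSO distance matrix is a synthetic physicochemical
  Euclidean distance (z-scored hydropathy/polarity/volume space)
  alongside Grantham's chemical distance, which is computed from his
  published formula (α = 1.833, β = 0.1018, γ = 0.000399, ρ = 50.723).

Structure annotations for F17/F18 normally come from an external
secondary-structure/accessibility predictor; the bundled
`SurrogateAnnotator` is a deterministic per-letter propensity map
(rescaled Chothia ASA; argmax of Chou–Fasman helix/sheet/turn) and is
explicitly **not** a structure predictor — with it, F17/F18 degenerate
to residue-identity recodings. Real predictor output can be supplied as
a section-based report or TSV (`immunoga.annotate`).

## Genetic-algorithm subset search

A chromosome is the 18-bit subset indicator; fitness is the AUC of the
pooled out-of-fold predictions of the subset's ensemble under an
internal stratified 5-fold cross-validation of the training set.
Key observation: a base predictor depends only on (feature, fold
split), never on the rest of the subset. The evaluator therefore
computes one pooled out-of-fold score vector per candidate feature and
scores any chromosome as the AUC of the mean of its selected vectors —
mathematically identical to retraining per chromosome, and cheap enough
that exhaustive enumeration becomes feasible for small pools (the tests
use this as an oracle). Fitness values are additionally memoised per
bit pattern.

Operator defaults (overridable in `GAConfig`): population 100, at most
100 generations, elitism of 2, crossover fraction 0.8 (uniform
crossover between rank-selected parents), per-bit mutation rate 1/18,
stall termination when the best fitness improves by less than 1e-6 over
a 50-generation window. All-zero offspring are repaired by setting one
uniformly random bit, since an empty ensemble has no fitness. Ranking
ties break on the bit pattern so runs are exactly reproducible; the
internal fold split derives from the run seed and is fixed within a
run.

## Evaluation protocol

Stratified 10-fold cross-validation repeated over independently seeded
runs (20 in the full protocol). Stratification is used even though the
split could be fully random, because the benchmark class ratios (e.g.
278/101) otherwise risk degenerate folds. Per fold, scores are
thresholded at 0.5 (ties positive) for SN/SP/ACC/MCC and a fold-level
AUC is recorded; the run-level AUC pools the out-of-fold scores of the
whole run. Fold-level AUCs (200 points in the full protocol) feed the
between-feature |Pearson| correlation analysis; run-level AUCs feed the
t-tests. Zero-denominator metrics and zero-variance test statistics are
reported as NaN with a logged warning and excluded from averages rather
than silently clamped.

With the GA in the loop, the subset is re-selected on every training
fold; the per-feature selection frequencies over runs × folds subsets
summarise which encoders the data consistently favours.

## Synthetic data generator

The generator produces duplicate-free labelled 9-mer datasets with a
known planted signal and an exact null at effect size 0:

* *composition-bias* — positives drawn from a multinomial exponentially
  tilted on a residue subset (default ILVF);
* *positional-motif* — a residue planted at a fixed position in
  positives and at a random other position in negatives, so expected
  compositions match and only position-aware encoders can discriminate;
* *property-shift* — positive residues tilted toward high values of a
  chosen scale (default Kyte–Doolittle), spreading signal over many
  physicochemistry-driven encoders.

Backgrounds are uniform over the 20 letters — deliberately simpler than
real HLA-A2 ligands, which have anchor-position preferences and
non-uniform residue usage. Passing tests on this generator therefore
demonstrates that the machinery recovers known signal and is calibrated
under the null; it does not certify real-data accuracy, which also
depends on the stand-in tables and real structure annotations above.

## Problem sizes

Library defaults are full-scale (500 trees, GA 100×100, 20×10 CV). The
test suite and `scripts/acceptance.py` run the same code at
demonstration scale — datasets of 150–400 peptides, 15–100 trees,
populations of 8–30 over ≤ 20 generations, 3–5 runs of 3–10 folds —
chosen so the whole suite completes in a couple of minutes on one CPU
while keeping every statistical check well-powered at its stated
tolerance. The two benchmark-reproduction tests state their reduced
budgets (5 runs; GA 30×30) in the test module and require the original
published datasets, which users must supply under `data/`.

## Known limitations

* Benchmark fidelity: without the published AAindex scales, contact
  potentials, QTMS descriptors and a real structure predictor, the
  numerical reproduction of published per-feature AUCs is approximate
  by construction; machinery, protocol and formulas are exact.
* Forest defaults approximate "toolbox defaults" of the original
  implementation ecosystem; `mtry`/`ntree` equivalence cannot be
  verified and both are exposed in configuration.
* The abstract-level description of the fitness uses 10-fold internal
  CV in one place and 5-fold in the methods; this package implements
  the 5-fold internal CV and exposes `internal_folds`.
* Peptide length is fixed at 9; the encoders are written against a
  length constant but only 9-mers are validated and tested.
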
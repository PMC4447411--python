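# immunoga

Sequence-based prediction of **immunogenic T-cell epitopes**: given a 9-mer
peptide presented by MHC class I (the benchmarks are HLA-A2-restricted), decide
whether it actually triggers a cytotoxic T-cell response. Binding an MHC
molecule is necessary but not sufficient for immunogenicity, so this is a
binary classification problem on peptide sequences — positives are
experimentally immunogenic epitopes, negatives are presented but
non-immunogenic peptides.

The package is aimed at immunoinformatics practitioners who want either the
trained-model interface (encode → train → score) or the full benchmarking
protocol (repeated cross-validation, correlation and significance analysis).

## Method

1. **Feature encoders.** Eighteen sequence-derived encoders F1–F18 map each
   9-mer to a numeric vector: position-wise physicochemical scales (99),
   amino-acid composition (20), dipeptide profile (400), sparse one-hot
   profile (9×20), Smith–Waterman similarity profile against the training
   sequences (*n*), per-residue contact potentials (360) and QTMS descriptors
   (189), CTD composition/transition/distribution (21/21/105), Moran, Geary
   and Moreau–Broto autocorrelations (8×λ each), quasi-sequence-order
   (40+2λ), pseudo and amphiphilic pseudo amino-acid composition (20+λ,
   20+2λ), and predicted per-residue RASA (9) and secondary structure (27).
2. **Base predictors and ensemble.** Each selected encoder drives its own
   random-forest classifier; the ensemble score is the unweighted mean of the
   selected forests' positive-class probabilities.
3. **Feature-subset search.** A subset is a chromosome
   V = (v₁, …, v₁₈) ∈ {0,1}¹⁸ (2¹⁸ = 262 144 subsets). Its fitness is the
   AUC of the subset's ensemble under an internal stratified 5-fold
   cross-validation of the training set. A genetic algorithm (elitism,
   rank selection, uniform crossover, per-bit mutation) maximises this
   fitness; the best subset's ensemble, retrained on the whole training set,
   is the final model.
4. **Evaluation.** Repeated stratified 10-fold cross-validation (20 runs in
   the full protocol) reporting SN, SP, ACC, MCC and AUC, with the subset
   re-selected on every training fold when the GA is in the loop; paired or
   one-sample t-tests compare per-run AUCs between methods.

## Worked example

`examples/03_ga_feature_selection.py` plants a positional motif that only a
position-aware encoder can see, then lets the GA pick from six encoders:

```
candidate pool: ['F2', 'F4', 'F8', 'F9', 'F15', 'F16']
best subset:    ['F4']
best fitness (internal 5-fold CV AUC): 0.926
distinct subsets evaluated: 30 (of 63 possible)
best-fitness trajectory: [0.885, 0.885, 0.922, 0.922, 0.926, 0.926] ...
```

The search recovers the planted truth: F4 (the sparse one-hot profile) is the
only encoder that can represent *where* a residue occurs, and the best subset
contains it, at a fitness close to the generator's detectability ceiling for
this effect size. The other examples cover encoding (`01`), training and
prediction (`02`), the full repeated-CV benchmark with t-tests (`04`) and a
null-data calibration check (`05`).

A command-line interface mirrors the library:

```bash
immunoga synth --mechanism positional-motif --effect 0.8 --npos 200 --nneg 200 --seed 5 --out synth.csv
immunoga ga-select --dataset synth.csv --pop 30 --gens 20 --seed 3 --out result.json
immunoga evaluate --dataset synth.csv --mode single-feature --features F4 --runs 5 --folds 10 --seed 11 --report report.tsv
```

## Bundled data and stand-ins

All lookup tables ship as plain text under `src/immunoga/data/`. Published
scales (Kyte–Doolittle, Hopp–Woods, Grantham, Chou–Fasman, Chothia) are used
verbatim; the 40 contact-potential scales and the 21 per-residue QTMS
descriptors are *synthetic stand-ins* with the correct shape and are
replaceable via `FeatureContext`; the structure annotator used by F17/F18
defaults to a deterministic per-letter surrogate and accepts real predictor
reports (see `immunoga.annotate`). Details and caveats: `docs/methods.md`.
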
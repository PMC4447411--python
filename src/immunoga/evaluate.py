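"""Evaluation protocol: repeated 10-fold CV, metrics, correlation and t-tests.

The benchmark protocol is 20 independently seeded runs of stratified
10-fold cross-validation.  Within a run, each fold's test predictions
are scored at threshold 0.5 for SN/SP/ACC/MCC plus a fold-level AUC;
the run-level AUC pools the out-of-fold scores of all ten folds.  When
the genetic algorithm is in the loop, the feature subset is re-selected
on every training fold, giving runs x folds selected subsets whose
feature frequencies can be counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .features import FeatureBlock, FeatureContext, build_feature_blocks, default_encoder_specs
from .model import DEFAULT_N_TREES, EnsembleModel, _forest, train_ensemble_for_specs
from .peptides import PeptideDataset

logger = logging.getLogger(__name__)

#: Published mean AUCs of earlier immunogenicity predictors on the two
#: benchmarks, used as references for the one-sample t-tests (the
#: methods themselves are not re-implemented here).
PUBLISHED_MEAN_AUC: dict[str, dict[str, float]] = {
    "IMMA2": {
        "POPI": 0.64,
        "POPISK": 0.74,
        "PAAQD": 0.747,
        "previous_ensemble": 0.766,
    },
    "PAAQD": {
        "PAAQD": 0.749,
        "previous_ensemble": 0.773,
    },
}


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricSet:
    SN: float
    SP: float
    ACC: float
    MCC: float
    AUC: float | None = None


def confusion_from_scores(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    """Threshold scores (ties go positive) and count the confusion cells."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pred = (scores >= threshold).astype(int)
    return ConfusionCounts(
        TP=int(((pred == 1) & (labels == 1)).sum()),
        TN=int(((pred == 0) & (labels == 0)).sum()),
        FP=int(((pred == 1) & (labels == 0)).sum()),
        FN=int(((pred == 0) & (labels == 1)).sum()),
    )


def _ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("undefined metric %s (zero denominator)", what)
        return float("nan")
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """SN, SP, ACC and MCC from confusion counts (AUC needs scores).

    Zero-denominator cases yield NaN and a logged warning, and are
    excluded from downstream averages.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    sn = _ratio(c.TP, c.TP + c.FN, "SN")
    sp = _ratio(c.TN, c.TN + c.FP, "SP")
    acc = (c.TP + c.TN) / c.total
    denom = (c.TP + c.FN) * (c.TP + c.FP) * (c.TN + c.FP) * (c.TN + c.FN)
    mcc = _ratio(c.TP * c.TN - c.FP * c.FN, float(np.sqrt(denom)), "MCC")
    return MetricSet(SN=sn, SP=sp, ACC=acc, MCC=mcc)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC via the rank (Mann–Whitney) statistic; ties contribute 1/2."""
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


# ---------------------------------------------------------------------------
# Pipelines: what gets fitted on each training fold
# ---------------------------------------------------------------------------

class FixedSubsetPipeline:
    """Ensemble over a fixed feature list (no subset search)."""

    def __init__(
        self,
        indices: Sequence[int],
        lambdas: dict[int, int] | None = None,
        n_trees: int = DEFAULT_N_TREES,
    ):
        self.indices = list(indices)
        self.lambdas = lambdas
        self.n_trees = n_trees

    def fit(self, train: PeptideDataset, seed: int) -> "FittedModel":
        specs = default_encoder_specs(self.indices, self.lambdas)
        model = train_ensemble_for_specs(train, specs, seed=seed, n_trees=self.n_trees)
        return FittedModel(model, subset_bits=model.bits)


class MergedVectorPipeline:
    """Single forest on the concatenation of the listed feature blocks."""

    def __init__(
        self,
        indices: Sequence[int],
        lambdas: dict[int, int] | None = None,
        n_trees: int = DEFAULT_N_TREES,
    ):
        self.indices = list(indices)
        self.lambdas = lambdas
        self.n_trees = n_trees

    def fit(self, train: PeptideDataset, seed: int) -> "FittedMerged":
        specs = default_encoder_specs(self.indices, self.lambdas)
        context = FeatureContext()
        if any(s.requires_fit for s in specs):
            context = context.with_similarity(train)
        blocks = build_feature_blocks(train, specs, context)
        X = np.hstack([b.matrix for b in blocks])
        clf = _forest(seed, self.n_trees)
        clf.fit(X, train.labels())
        return FittedMerged(clf, [b.spec for b in blocks], context)


class GAPipeline:
    """GA-in-the-loop: re-select the subset on every training fold."""

    def __init__(self, cfg, specs=None, n_trees: int = DEFAULT_N_TREES):
        self.cfg = cfg
        self.specs = specs
        self.n_trees = n_trees

    def fit(self, train: PeptideDataset, seed: int) -> "FittedModel":
        from .ga import optimize  # late import to avoid a module cycle

        cfg = replace(self.cfg, seed=int(seed) % (2**31))
        result = optimize(train, cfg, specs=self.specs, n_trees=self.n_trees)
        return FittedModel(result.model, subset_bits=result.model.bits)


class FittedModel:
    def __init__(self, model: EnsembleModel, subset_bits: tuple[int, ...]):
        self.model = model
        self.subset_bits = subset_bits

    def score(self, ds: PeptideDataset) -> np.ndarray:
        return self.model.score_dataset(ds)


class FittedMerged:
    subset_bits = None

    def __init__(self, clf, specs, context: FeatureContext):
        self.clf = clf
        self.specs = specs
        self.context = context

    def score(self, ds: PeptideDataset) -> np.ndarray:
        blocks = build_feature_blocks(ds, self.specs, self.context)
        X = np.hstack([b.matrix for b in blocks])
        pos_col = list(self.clf.classes_).index(1)
        return self.clf.predict_proba(X)[:, pos_col]


# ---------------------------------------------------------------------------
# Repeated cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Per-fold records, per-run pooled AUCs and the selected subsets."""

    records: pd.DataFrame  # run, fold, TP..FN, SN, SP, ACC, MCC, AUC, subset_bits
    run_aucs: pd.DataFrame  # run, auc (pooled out-of-fold scores)
    folds: int
    runs: int
    seed: int

    def mean_metrics(self) -> dict[str, float]:
        """Mean of the defined per-fold metrics plus the mean per-run AUC."""
        out = {
            m: float(np.nanmean(self.records[m])) for m in ("SN", "SP", "ACC", "MCC")
        }
        out["AUC"] = float(self.run_aucs["auc"].mean())
        return out

    def fold_aucs(self) -> np.ndarray:
        return self.records["AUC"].to_numpy()

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def run_repeated_cv(
    ds: PeptideDataset,
    pipeline,
    folds: int = 10,
    runs: int = 20,
    seed: int = 0,
    threshold: float = 0.5,
) -> CVReport:
    """Repeated stratified k-fold CV of any pipeline.

    Each sample is tested exactly once per run.  Fold/run RNG and the
    per-fold pipeline seeds all derive from ``seed``, so a fixed seed
    reproduces the report bit-identically.
    """
    if len(ds) < folds:
        raise ValueError(f"dataset of size {len(ds)} cannot be split into {folds} folds")
    y = ds.labels()
    if np.bincount(y, minlength=2).min() < folds:
        raise ValueError("each class needs at least `folds` members for stratified CV")
    ss = np.random.SeedSequence([int(seed), 0xCF])
    run_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(runs)]
    rows: list[dict] = []
    run_rows: list[dict] = []
    for run, run_seed in enumerate(run_seeds):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=run_seed)
        pooled_scores = np.full(len(ds), np.nan)
        fold_ss = np.random.SeedSequence([run_seed, 0xF0])
        fold_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in fold_ss.spawn(folds)]
        for fold, (tr, te) in enumerate(skf.split(np.zeros(len(ds)), y)):
            fitted = pipeline.fit(ds.subset(tr), fold_seeds[fold])
            scores = fitted.score(ds.subset(te))
            pooled_scores[te] = scores
            counts = confusion_from_scores(scores, y[te], threshold)
            ms = compute_metrics(counts)
            rows.append(
                {
                    "run": run,
                    "fold": fold,
                    "TP": counts.TP,
                    "TN": counts.TN,
                    "FP": counts.FP,
                    "FN": counts.FN,
                    "SN": ms.SN,
                    "SP": ms.SP,
                    "ACC": ms.ACC,
                    "MCC": ms.MCC,
                    "AUC": roc_auc(scores, y[te]),
                    "subset_bits": (
                        "".join(map(str, fitted.subset_bits))
                        if fitted.subset_bits is not None
                        else ""
                    ),
                }
            )
        run_rows.append({"run": run, "auc": roc_auc(pooled_scores, y)})
    return CVReport(
        records=pd.DataFrame(rows),
        run_aucs=pd.DataFrame(run_rows),
        folds=folds,
        runs=runs,
        seed=seed,
    )


def merged_vector_model(
    ds: PeptideDataset,
    indices: Sequence[int],
    lambdas: dict[int, int] | None = None,
    folds: int = 10,
    runs: int = 20,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> CVReport:
    """Evaluate a merged-feature-vector baseline under repeated CV."""
    if not indices:
        raise ValueError("merged model needs a non-empty feature list")
    return run_repeated_cv(
        ds, MergedVectorPipeline(indices, lambdas, n_trees), folds=folds, runs=runs, seed=seed
    )


# ---------------------------------------------------------------------------
# Correlation, significance and subset-frequency analyses
# ---------------------------------------------------------------------------

def correlation_table(fold_aucs: np.ndarray | pd.DataFrame) -> np.ndarray:
    """|Pearson r| between the fold-level AUC series of feature models.

    ``fold_aucs`` has one row per feature model and one column per
    observation (fold x run).  Zero-variance rows give NaN entries.
    """
    A = np.asarray(fold_aucs, dtype=float)
    if A.ndim != 2 or A.shape[1] < 3:
        raise ValueError("need a 2-D array with at least 3 paired observations")
    sd = A.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(A)
    corr = np.abs(corr)
    corr[np.diag_indices_from(corr)] = 1.0
    for i in np.where(sd == 0)[0]:
        corr[i, :] = np.nan
        corr[:, i] = np.nan
        corr[i, i] = 1.0
        logger.warning("zero-variance AUC series for row %d; correlations undefined", i)
    return corr


def significance_tests(
    samples_a: Sequence[float],
    reference: Sequence[float] | float,
) -> float:
    """Two-sided p-value for a paired t-test (sequence reference) or a
    one-sample t-test against a published mean (scalar reference).

    Zero-variance differences make the statistic undefined; NaN is
    returned with a logged warning.
    """
    a = np.asarray(samples_a, dtype=float)
    if a.size < 2:
        raise ValueError("need at least two samples")
    if np.isscalar(reference):
        if a.std(ddof=1) == 0:
            logger.warning("zero-variance sample; one-sample t-test undefined")
            return float("nan")
        return float(stats.ttest_1samp(a, float(reference)).pvalue)
    b = np.asarray(reference, dtype=float)
    if b.shape != a.shape:
        raise ValueError("paired samples must have equal length")
    if np.std(a - b, ddof=1) == 0:
        logger.warning("zero-variance paired differences; t-test undefined")
        return float("nan")
    return float(stats.ttest_rel(a, b).pvalue)


def subset_frequencies(report: CVReport) -> np.ndarray:
    """Count, per feature, how many selected subsets include it."""
    bits_col = [b for b in report.records["subset_bits"] if b]
    if not bits_col:
        raise ValueError("report carries no selected subsets (not GA-in-the-loop?)")
    mat = np.array([[int(ch) for ch in b] for b in bits_col])
    return mat.sum(axis=0)
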
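"""Per-feature base classifiers and the score-averaging ensemble.

Each selected feature encoder gets its own random-forest base
predictor trained on that encoder's vectors; the ensemble predicts the
unweighted arithmetic mean of the base predictors' positive-class
probabilities.  Defaults mirror the usual random-forest toolbox
settings: 500 trees, sqrt(m) candidate features per split, no depth
cap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .features import (
    EncoderSpec,
    FeatureBlock,
    FeatureContext,
    build_feature_blocks,
)
from .peptides import Peptide, PeptideDataset, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_N_TREES = 500

MODEL_FORMAT = "immunoga-ensemble"
MODEL_FORMAT_VERSION = 1


class ModelIOError(IOError):
    """Model file missing, truncated, or of an incompatible version."""


def _forest(seed: int, n_trees: int, n_jobs: int = 1) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        max_depth=None,
        oob_score=False,
        random_state=int(seed) % (2**31),
        n_jobs=n_jobs,
    )


@dataclass
class BasePredictor:
    """A fitted single-feature random forest emitting P(positive)."""

    spec: EncoderSpec
    classifier: RandomForestClassifier
    seed: int
    n_trees: int

    def score(self, X: np.ndarray) -> np.ndarray:
        """Positive-class probability for each row of ``X``."""
        X = np.asarray(X, dtype=float)
        proba = self.classifier.predict_proba(X)
        pos_col = list(self.classifier.classes_).index(1)
        return proba[:, pos_col]


def train_base(
    block: FeatureBlock,
    labels: np.ndarray,
    seed: int,
    n_trees: int = DEFAULT_N_TREES,
    n_jobs: int = 1,
) -> BasePredictor:
    """Fit one base predictor on a feature block; deterministic given seed."""
    y = np.asarray(labels, dtype=int)
    if block.matrix.shape[0] != y.shape[0]:
        raise ValueError(
            f"{block.spec.code}: {block.matrix.shape[0]} rows vs {y.shape[0]} labels"
        )
    if len(np.unique(y)) < 2:
        raise ValueError(f"{block.spec.code}: training labels contain a single class")
    clf = _forest(seed, n_trees, n_jobs)
    clf.fit(block.matrix, y)
    return BasePredictor(spec=block.spec, classifier=clf, seed=seed, n_trees=n_trees)


@dataclass
class EnsembleModel:
    """Average-scoring ensemble over the selected features.

    ``bits`` is the 18-long selection indicator; ``bases`` holds one
    fitted predictor per set bit, in feature-index order.  The fitted
    :class:`FeatureContext` (including the similarity reference for F5)
    travels with the model so prediction works on raw peptides.
    """

    bits: tuple[int, ...]
    specs: list[EncoderSpec]
    bases: list[BasePredictor]
    context: FeatureContext
    seed: int = 0
    n_trees: int = DEFAULT_N_TREES

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.specs):
            raise ValueError("one base predictor per selected spec required")
        if sum(self.bits) != len(self.bases):
            raise ValueError("bases count must equal the number of set bits")

    @property
    def selected_indices(self) -> list[int]:
        return [s.index for s in self.specs]

    def score_dataset(self, ds: PeptideDataset) -> np.ndarray:
        """Mean base-predictor score for every peptide in ``ds``."""
        blocks = build_feature_blocks(ds, self.specs, self.context)
        scores = np.stack([b.score(bl.matrix) for b, bl in zip(self.bases, blocks)])
        return scores.mean(axis=0)

    def score_peptides(self, peptides: Sequence[Peptide | str]) -> np.ndarray:
        ds = PeptideDataset(
            name="query",
            peptides=[p if isinstance(p, Peptide) else Peptide(p) for p in peptides],
        )
        return self.score_dataset(ds)


def train_ensemble_for_specs(
    train: PeptideDataset,
    specs: Sequence[EncoderSpec],
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    context: FeatureContext | None = None,
    n_jobs: int = 1,
) -> EnsembleModel:
    """Train the average-scoring ensemble over an explicit list of encoders.

    The similarity reference (F5) is fitted on ``train`` when needed;
    per-feature forest seeds are derived deterministically from ``seed``.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("at least one feature must be selected")
    context = context or FeatureContext()
    if any(s.requires_fit for s in specs) and context.similarity is None:
        context = context.with_similarity(train)
    y = train.labels()
    blocks = build_feature_blocks(train, specs, context)
    ss = np.random.SeedSequence([int(seed), 0xB10C])
    child_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(len(blocks))]
    bases = [
        train_base(bl, y, s, n_trees=n_trees, n_jobs=n_jobs)
        for bl, s in zip(blocks, child_seeds)
    ]
    bits = [0] * 18
    for s in specs:
        bits[s.index - 1] = 1
    return EnsembleModel(
        bits=tuple(bits),
        specs=[bl.spec for bl in blocks],
        bases=bases,
        context=context,
        seed=seed,
        n_trees=n_trees,
    )


def train_ensemble(
    train: PeptideDataset,
    bits: Sequence[int],
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    context: FeatureContext | None = None,
    lambdas: dict[int, int] | None = None,
    n_jobs: int = 1,
) -> EnsembleModel:
    """Train the ensemble for an 18-bit feature-subset indicator."""
    from .features import default_encoder_specs

    bits = tuple(int(b) for b in bits)
    if len(bits) != 18 or any(b not in (0, 1) for b in bits):
        raise ValueError("bits must be an 18-long 0/1 vector")
    if sum(bits) == 0:
        raise ValueError("at least one feature must be selected")
    indices = [i + 1 for i, b in enumerate(bits) if b]
    specs = default_encoder_specs(indices, lambdas)
    return train_ensemble_for_specs(
        train, specs, seed=seed, n_trees=n_trees, context=context, n_jobs=n_jobs
    )


def ensemble_score(model: EnsembleModel, p: Peptide | str) -> float:
    """Unweighted mean of the base predictors' positive-class scores."""
    return float(model.score_peptides([p])[0])


def classify(model: EnsembleModel, p: Peptide | str, threshold: float = 0.5) -> str:
    """Label a peptide: positive iff score >= threshold (ties go positive)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    return "positive" if ensemble_score(model, p) >= threshold else "negative"


def save_model(model: EnsembleModel, path: str | Path) -> None:
    """Serialise a trained ensemble to a single versioned container file."""
    payload = {
        "format": MODEL_FORMAT,
        "format_version": MODEL_FORMAT_VERSION,
        "model": model,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> EnsembleModel:
    path = Path(path)
    if not path.is_file() or path.stat().st_size == 0:
        raise ModelIOError(f"model file missing or empty: {path}")
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelIOError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT:
        raise ModelIOError(f"{path} is not an {MODEL_FORMAT} container")
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelIOError(
            f"model format version {payload.get('format_version')} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return payload["model"]
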
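"""Genetic-algorithm search over feature subsets.

A chromosome is a binary indicator over the candidate feature encoders
(18 bits for the full pool, 2^18 = 262144 subsets).  Its fitness is the
AUC of the subset's average-scoring ensemble under an internal
stratified 5-fold cross-validation on the training set, computed on the
pooled out-of-fold predictions.

Because every base predictor depends only on its feature and the fold
split — never on which other features are selected — the evaluator
first computes one pooled out-of-fold score vector per candidate
feature, after which any chromosome's fitness is the AUC of the mean of
its selected vectors.  This is mathematically identical to retraining
the ensemble per chromosome and makes the subset search cheap.

The population update follows the common elitist scheme: the best
``elite_count`` chromosomes survive unchanged, a ``crossover_fraction``
of the remainder is produced by uniform crossover between rank-selected
parents, and the rest are mutation children with an independent
per-bit flip probability.  All-zero chromosomes are repaired by setting
one random bit (an empty ensemble has no fitness).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .evaluate import roc_auc
from .features import (
    EncoderSpec,
    FeatureContext,
    FeatureBlock,
    build_feature_blocks,
    default_encoder_specs,
    sw_score,
)
from .model import (
    DEFAULT_N_TREES,
    EnsembleModel,
    train_base,
    train_ensemble_for_specs,
)
from .peptides import PeptideDataset

logger = logging.getLogger(__name__)

N_FEATURES = 18


@dataclass
class GAConfig:
    """Search and internal-validation settings for the subset GA."""

    population_size: int = 100
    max_generations: int = 100
    stall_tolerance: float = 1e-6
    stall_window: int = 50
    elite_count: int = 2
    crossover_fraction: float = 0.8
    mutation_rate: float = 1.0 / N_FEATURES
    internal_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("crossover_fraction", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0 <= self.elite_count <= self.population_size:
            raise ValueError("elite_count must lie in [0, population_size]")
        if self.internal_folds < 2:
            raise ValueError("internal_folds must be >= 2")


@dataclass
class Chromosome:
    """A feature-subset indicator with (optionally) cached fitness."""

    bits: tuple[int, ...]
    fitness: float | None = None

    def __post_init__(self) -> None:
        bits = tuple(int(b) for b in self.bits)
        if any(b not in (0, 1) for b in bits):
            raise ValueError("chromosome bits must be 0/1")
        object.__setattr__(self, "bits", bits)


@dataclass
class GAResult:
    """Outcome of one subset optimisation run."""

    best: Chromosome
    model: EnsembleModel | None
    history: list[dict]  # per generation: {"generation", "best", "mean"}
    evaluations: int  # distinct chromosomes evaluated
    specs: list[EncoderSpec] = field(default_factory=list)


class FitnessEvaluator:
    """Internal-CV fitness with per-feature out-of-fold memoisation.

    Parameters
    ----------
    train
        The (outer) training set; both classes must be present and each
        class must have at least ``cfg.internal_folds`` members.
    specs
        Candidate encoders; chromosome bit *k* toggles ``specs[k]``.
    """

    def __init__(
        self,
        train: PeptideDataset,
        cfg: GAConfig,
        specs: Sequence[EncoderSpec] | None = None,
        n_trees: int = DEFAULT_N_TREES,
        context: FeatureContext | None = None,
    ):
        self.train = train
        self.cfg = cfg
        self.specs = list(specs) if specs is not None else default_encoder_specs()
        self.n_trees = n_trees
        self.context = context or FeatureContext()
        self.y = train.labels()
        counts = np.bincount(self.y, minlength=2)
        if counts.min() < cfg.internal_folds:
            raise ValueError(
                f"each class needs >= {cfg.internal_folds} members for internal CV"
            )
        self._cache: dict[tuple[int, ...], float] = {}
        self.training_passes = 0
        self._oof = self._pooled_oof_scores()

    # -- internal machinery -------------------------------------------------

    def _similarity_matrix(self) -> np.ndarray:
        seqs = self.train.sequences()
        n = len(seqs)
        S = np.zeros((n, n))
        for i in range(n):
            for j in range(i, n):
                S[i, j] = S[j, i] = sw_score(seqs[i], seqs[j])
        return S

    def _pooled_oof_scores(self) -> dict[int, np.ndarray]:
        """One pooled out-of-fold positive-class score vector per feature."""
        n = len(self.train)
        needs_sim = any(s.requires_fit for s in self.specs)
        S = self._similarity_matrix() if needs_sim else None
        static: dict[int, np.ndarray] = {}
        for spec in self.specs:
            if not spec.requires_fit:
                static[spec.index] = build_feature_blocks(
                    self.train, [spec], self.context
                )[0].matrix
        ss = np.random.SeedSequence([int(self.cfg.seed), 0xF17])
        fold_seed = int(ss.generate_state(1)[0] % (2**31))
        skf = StratifiedKFold(
            n_splits=self.cfg.internal_folds, shuffle=True, random_state=fold_seed
        )
        oof = {spec.index: np.full(n, np.nan) for spec in self.specs}
        rf_seeds = iter(
            int(c.generate_state(1)[0] % (2**31))
            for c in ss.spawn(self.cfg.internal_folds * len(self.specs))
        )
        for tr, va in skf.split(np.zeros(n), self.y):
            for spec in self.specs:
                if spec.requires_fit:
                    X_tr = S[np.ix_(tr, tr)]
                    X_va = S[np.ix_(va, tr)]
                else:
                    X_tr = static[spec.index][tr]
                    X_va = static[spec.index][va]
                block = FeatureBlock(
                    spec=spec if not spec.requires_fit else
                    EncoderSpec(spec.index, spec.name, spec.lam, len(tr), True, False),
                    matrix=X_tr,
                )
                base = train_base(block, self.y[tr], next(rf_seeds), n_trees=self.n_trees)
                oof[spec.index][va] = base.score(X_va)
                self.training_passes += 1
        return oof

    # -- public API ---------------------------------------------------------

    @property
    def evaluations(self) -> int:
        return len(self._cache)

    def evaluate(self, bits: Sequence[int]) -> float:
        """Fitness (pooled internal-CV AUC) of a bit pattern; memoised."""
        key = tuple(int(b) for b in bits)
        if len(key) != len(self.specs):
            raise ValueError(f"expected {len(self.specs)} bits, got {len(key)}")
        if sum(key) == 0:
            raise ValueError("fitness undefined for an empty feature subset")
        if key not in self._cache:
            selected = [
                self._oof[spec.index] for spec, b in zip(self.specs, key) if b
            ]
            ensemble = np.mean(selected, axis=0)
            self._cache[key] = roc_auc(ensemble, self.y)
        return self._cache[key]


def fitness_eval(
    c: Chromosome | Sequence[int],
    train: PeptideDataset,
    cfg: GAConfig,
    **kwargs,
) -> float:
    """One-shot fitness of a chromosome (builds a fresh evaluator)."""
    bits = c.bits if isinstance(c, Chromosome) else tuple(c)
    return FitnessEvaluator(train, cfg, **kwargs).evaluate(bits)


# ---------------------------------------------------------------------------
# Population mechanics
# ---------------------------------------------------------------------------

def _repair(bits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if bits.sum() == 0:
        bits[rng.integers(len(bits))] = 1
    return bits


def random_population(n_bits: int, cfg: GAConfig, rng: np.random.Generator) -> list[Chromosome]:
    pop = []
    for _ in range(cfg.population_size):
        bits = _repair(rng.integers(0, 2, size=n_bits), rng)
        pop.append(Chromosome(tuple(int(b) for b in bits)))
    return pop


def _sorted_by_fitness(pop: list[Chromosome]) -> list[Chromosome]:
    # deterministic: fitness desc, then bits as tie-break
    return sorted(pop, key=lambda c: (-(c.fitness or 0.0), c.bits))


def evolve(pop: list[Chromosome], cfg: GAConfig, rng: np.random.Generator) -> list[Chromosome]:
    """One generation step: elitism, rank selection, uniform crossover,
    per-bit flip mutation.  All parents must have fitness set; offspring
    (other than surviving elites) have fitness unset."""
    if any(c.fitness is None for c in pop):
        raise ValueError("all chromosomes must be evaluated before evolve()")
    n_bits = len(pop[0].bits)
    ranked = _sorted_by_fitness(pop)
    elites = [Chromosome(c.bits, c.fitness) for c in ranked[: cfg.elite_count]]
    n_rest = cfg.population_size - len(elites)
    n_xover = int(round(cfg.crossover_fraction * n_rest))
    n_mut = n_rest - n_xover

    # linear rank weights: best gets weight N, worst 1
    weights = np.arange(len(ranked), 0, -1, dtype=float)
    probs = weights / weights.sum()

    def pick() -> np.ndarray:
        i = rng.choice(len(ranked), p=probs)
        return np.array(ranked[i].bits)

    children: list[Chromosome] = []
    for _ in range(n_xover):
        p1, p2 = pick(), pick()
        mask = rng.integers(0, 2, size=n_bits).astype(bool)
        child = np.where(mask, p1, p2)
        children.append(Chromosome(tuple(int(b) for b in _repair(child, rng))))
    for _ in range(n_mut):
        child = pick()
        flip = rng.random(n_bits) < cfg.mutation_rate
        child = np.where(flip, 1 - child, child)
        children.append(Chromosome(tuple(int(b) for b in _repair(child, rng))))
    return elites + children


def _ga_search(
    fitness_fn: Callable[[Sequence[int]], float],
    n_bits: int,
    cfg: GAConfig,
    rng: np.random.Generator,
) -> tuple[Chromosome, list[dict]]:
    pop = random_population(n_bits, cfg, rng)
    history: list[dict] = []
    best_overall: Chromosome | None = None
    for gen in range(cfg.max_generations + 1):
        for c in pop:
            if c.fitness is None:
                c.fitness = fitness_fn(c.bits)
        ranked = _sorted_by_fitness(pop)
        gen_best = ranked[0]
        if best_overall is None or gen_best.fitness > best_overall.fitness:
            best_overall = Chromosome(gen_best.bits, gen_best.fitness)
        history.append(
            {
                "generation": gen,
                "best": best_overall.fitness,
                "mean": float(np.mean([c.fitness for c in pop])),
            }
        )
        if gen == cfg.max_generations:
            break
        if gen >= cfg.stall_window:
            improvement = history[-1]["best"] - history[-1 - cfg.stall_window]["best"]
            if improvement < cfg.stall_tolerance:
                logger.info("GA stalled at generation %d (best %.6f)", gen, best_overall.fitness)
                break
        pop = evolve(pop, cfg, rng)
    return best_overall, history


def optimize(
    train: PeptideDataset,
    cfg: GAConfig,
    specs: Sequence[EncoderSpec] | None = None,
    n_trees: int = DEFAULT_N_TREES,
    context: FeatureContext | None = None,
    fit_final_model: bool = True,
) -> GAResult:
    """Run the GA on a training set and (optionally) train the final model.

    The final model is the average-scoring ensemble for the best subset,
    trained on the *entire* training set.  Identical seed + data + config
    give an identical result.
    """
    evaluator = FitnessEvaluator(train, cfg, specs=specs, n_trees=n_trees, context=context)
    rng = np.random.default_rng(cfg.seed)
    best, history = _ga_search(evaluator.evaluate, len(evaluator.specs), cfg, rng)
    model = None
    if fit_final_model:
        selected = [s for s, b in zip(evaluator.specs, best.bits) if b]
        model = train_ensemble_for_specs(
            train, selected, seed=cfg.seed, n_trees=n_trees, context=context
        )
    return GAResult(
        best=best,
        model=model,
        history=history,
        evaluations=evaluator.evaluations,
        specs=evaluator.specs,
    )


def exhaustive_search(evaluator: FitnessEvaluator) -> tuple[tuple[int, ...], float]:
    """Enumerate every non-empty subset; tractable for small pools."""
    n = len(evaluator.specs)
    best_bits, best_fit = None, -np.inf
    for code in range(1, 2**n):
        bits = tuple((code >> k) & 1 for k in range(n))
        fit = evaluator.evaluate(bits)
        if fit > best_fit or (fit == best_fit and bits < best_bits):
            best_bits, best_fit = bits, fit
    return best_bits, best_fit
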
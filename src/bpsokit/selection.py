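"""Wrapper feature selection driven by swarm search.

Estimators follow the scikit-learn selector protocol (``fit(X, y)``,
``get_support``, ``transform``) and share one cross-validated wrapper fitness
(:class:`~bpsokit.fitness.SubsetFitness`):

* :class:`BPSOFeatureSelector` — binary particle swarm search, either the
  sigmoid-transfer variant or the mutation/recombination variant.
* :class:`SFFSSelector` — sequential floating forward selection.
* :class:`LevyBPSOSelector` — binary PSO with heavy-tailed extra bit flips
  (an experimental baseline).
* :class:`ExhaustiveSelector` — full enumeration, usable up to 15 features;
  serves as the oracle the heuristics are checked against.

The module-level functions (``bpso_select`` etc.) are thin wrappers taking a
:class:`FeatureTable` plus config/spec objects and returning a
:class:`SelectionResult`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .fitness import FitnessSpec, SubsetFitness, repair_empty_mask
from .swarm import OptimizationResult, SwarmConfig, run_levy_optimizer, run_optimizer

METHODS = ("bpso", "standard_bpso", "sffs", "levy_bpso", "exhaustive")

LABEL_COLUMN = "label"


@dataclass
class FeatureTable:
    """A samples × features matrix with binary labels.

    ``labels`` use 0 = benign, 1 = malignant semantics.  Synthetic tables
    carry the ground-truth ``informative_mask`` so selection quality can be
    scored against it.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list
    informative_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels).astype(int)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if self.labels.shape[0] != self.values.shape[0]:
            raise ValueError("labels length must match the number of samples")
        if set(np.unique(self.labels)) != {0, 1}:
            raise ValueError("labels must contain both classes 0 and 1")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length must match the number of features")
        if self.informative_mask is not None:
            self.informative_mask = np.asarray(self.informative_mask).astype(bool)
            if self.informative_mask.shape[0] != self.values.shape[1]:
                raise ValueError("informative_mask length must match the number of features")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df[LABEL_COLUMN] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path)
        if LABEL_COLUMN not in df.columns:
            raise ValueError(f"CSV must contain a final {LABEL_COLUMN!r} column")
        names = [c for c in df.columns if c != LABEL_COLUMN]
        return cls(values=df[names].to_numpy(float), labels=df[LABEL_COLUMN].to_numpy(), feature_names=names)


@dataclass
class SelectionResult:
    """A selected subset with its reproducibility context."""

    mask: np.ndarray
    fitness: float
    history: np.ndarray = field(repr=False)
    method: str = "bpso"
    seed: int = 0
    feature_names: Optional[list] = None
    n_evaluations: int = 0

    def selected_names(self) -> list:
        if self.feature_names is None:
            return [str(i) for i in np.flatnonzero(self.mask)]
        return [self.feature_names[i] for i in np.flatnonzero(self.mask)]

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "seed": self.seed,
                "fitness": self.fitness,
                "n_selected": int(np.sum(self.mask)),
                "selected_features": self.selected_names(),
            },
            indent=2,
        )


def informative_recall(mask: np.ndarray, informative_mask: np.ndarray) -> float:
    """Fraction of truly informative features present in the selected mask."""
    mask = np.asarray(mask).astype(bool)
    truth = np.asarray(informative_mask).astype(bool)
    if truth.sum() == 0:
        raise ValueError("informative_mask selects no features")
    return float((mask & truth).sum() / truth.sum())


def informative_f1(mask: np.ndarray, informative_mask: np.ndarray) -> float:
    """F1 of the selected mask against the ground-truth informative set."""
    mask = np.asarray(mask).astype(bool)
    truth = np.asarray(informative_mask).astype(bool)
    tp = (mask & truth).sum()
    if tp == 0:
        return 0.0
    prec = tp / mask.sum()
    rec = tp / truth.sum()
    return float(2 * prec * rec / (prec + rec))


class _BaseWrapperSelector(SelectorMixin, BaseEstimator):
    """Shared fit plumbing: validation, fitness construction, fitted attrs."""

    def _fitness_spec(self) -> FitnessSpec:
        return FitnessSpec(
            classifier=self.classifier,
            cv_folds=self.cv_folds,
            parsimony_alpha=self.parsimony_alpha,
            seed=self.cv_random_state,
        )

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        fitness = SubsetFitness(X, y, self._fitness_spec())
        mask, best, history, evals = self._search(fitness, X.shape[1])
        self.support_ = np.asarray(mask, dtype=bool)
        if self.support_.sum() == 0:
            raise RuntimeError("search returned an empty mask")
        self.fitness_ = float(best)
        self.history_ = np.asarray(history, dtype=float)
        self.n_evaluations_ = int(evals)
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_

    def _search(self, fitness: SubsetFitness, d: int):  # pragma: no cover
        raise NotImplementedError


class BPSOFeatureSelector(_BaseWrapperSelector):
    """Feature selection by binary particle swarm search.

    ``variant="modified_binary"`` (default) evolves positions by mutating and
    recombining personal/global bests with linearly decaying mutation counts;
    ``variant="standard_binary"`` is the classical sigmoid-transfer update.
    All-zero candidate subsets are repaired by activating one random feature.
    """

    def __init__(
        self,
        n_particles: int = 30,
        n_iterations: int = 100,
        variant: str = "modified_binary",
        w_max: float = 0.9,
        w_min: float = 0.4,
        d1: float = 2.0,
        d2: float = 2.0,
        m1_base: Optional[float] = None,
        m2_base: Optional[float] = None,
        v_clamp: object = "auto",
        combine_threshold: float = 1.0 / 3.0,
        classifier: str = "nearest_neighbor",
        cv_folds: int = 5,
        parsimony_alpha: float = 0.01,
        random_state: int = 0,
        cv_random_state: int = 0,
    ):
        self.n_particles = n_particles
        self.n_iterations = n_iterations
        self.variant = variant
        self.w_max = w_max
        self.w_min = w_min
        self.d1 = d1
        self.d2 = d2
        self.m1_base = m1_base
        self.m2_base = m2_base
        self.v_clamp = v_clamp
        self.combine_threshold = combine_threshold
        self.classifier = classifier
        self.cv_folds = cv_folds
        self.parsimony_alpha = parsimony_alpha
        self.random_state = random_state
        self.cv_random_state = cv_random_state

    def _swarm_config(self, d: int) -> SwarmConfig:
        return SwarmConfig(
            n_particles=self.n_particles,
            dims=d,
            n_iterations=self.n_iterations,
            variant=self.variant,
            w_max=self.w_max,
            w_min=self.w_min,
            d1=self.d1,
            d2=self.d2,
            m1_base=self.m1_base,
            m2_base=self.m2_base,
            v_clamp=self.v_clamp,
            combine_threshold=self.combine_threshold,
            seed=self.random_state,
        )

    def _search(self, fitness, d):
        res = run_optimizer(fitness, self._swarm_config(d), repair=repair_empty_mask)
        return res.best_position.astype(bool), res.best_fitness, res.fitness_history, fitness.n_calls


class LevyBPSOSelector(BPSOFeatureSelector):
    """Binary PSO with Mantegna-style heavy-tailed extra bit flips.

    Experimental baseline: the per-particle flip count is drawn from a
    Levy(alpha) step distribution on top of the sigmoid-transfer update.
    """

    def __init__(self, alpha: float = 1.5, **kwargs):
        kwargs.setdefault("variant", "standard_binary")
        super().__init__(**kwargs)
        self.alpha = alpha

    def _search(self, fitness, d):
        res = run_levy_optimizer(
            fitness, self._swarm_config(d), alpha=self.alpha, repair=repair_empty_mask
        )
        return res.best_position.astype(bool), res.best_fitness, res.fitness_history, fitness.n_calls


def sffs_search(
    score: Callable[[tuple], float], d: int, k_max: int
) -> tuple:
    """Sequential floating forward selection over index subsets.

    Greedy forward inclusion of the best-scoring feature, followed by
    conditional backward exclusions accepted only when they strictly improve
    the best score recorded for the smaller subset size (which guarantees
    termination).  Ties break toward the lowest feature index.  Returns
    ``(best_mask_tuple, best_score, trace)`` where the mask is the best
    subset of size <= k_max and trace is the best score after each forward
    step.
    """
    if not (1 <= k_max <= d):
        raise ValueError("k_max must lie in [1, n_features]")
    best_by_size: dict = {}
    current: list = []
    trace = []

    def mask_of(indices) -> tuple:
        m = [0] * d
        for i in indices:
            m[i] = 1
        return tuple(m)

    while len(current) < k_max:
        candidates = [j for j in range(d) if j not in current]
        scores = [(score(mask_of(current + [j])), -j) for j in candidates]
        s_best, neg_j = max(scores)
        j = -neg_j
        current.append(j)
        size = len(current)
        if size not in best_by_size or s_best > best_by_size[size][0]:
            best_by_size[size] = (s_best, mask_of(current))
        # floating backward exclusions
        while len(current) > 2:
            rm_scores = [
                (score(mask_of([i for i in current if i != j2])), -j2) for j2 in current
            ]
            s_rm, neg_j2 = max(rm_scores)
            j2 = -neg_j2
            smaller = len(current) - 1
            if smaller in best_by_size and s_rm <= best_by_size[smaller][0]:
                break
            current.remove(j2)
            best_by_size[smaller] = (s_rm, mask_of(current))
        trace.append(max(v[0] for v in best_by_size.values()))
    best_score, best_mask = max(
        best_by_size.values(), key=lambda v: (v[0], -sum(v[1]))
    )
    return best_mask, best_score, trace


class SFFSSelector(_BaseWrapperSelector):
    """Sequential floating forward selection with the shared wrapper fitness."""

    def __init__(
        self,
        k_max: Optional[int] = None,
        classifier: str = "nearest_neighbor",
        cv_folds: int = 5,
        parsimony_alpha: float = 0.01,
        cv_random_state: int = 0,
    ):
        self.k_max = k_max
        self.classifier = classifier
        self.cv_folds = cv_folds
        self.parsimony_alpha = parsimony_alpha
        self.cv_random_state = cv_random_state

    def _search(self, fitness, d):
        k_max = d if self.k_max is None else self.k_max
        mask, best, trace = sffs_search(lambda m: fitness(np.array(m)), d, k_max)
        return np.array(mask, dtype=bool), best, np.array(trace), fitness.n_calls


class ExhaustiveSelector(_BaseWrapperSelector):
    """Enumerate every non-empty subset (n_features <= 15); the oracle.

    Ties in fitness resolve to the lexicographically smallest bit tuple.
    """

    MAX_FEATURES = 15

    def __init__(
        self,
        classifier: str = "nearest_neighbor",
        cv_folds: int = 5,
        parsimony_alpha: float = 0.01,
        cv_random_state: int = 0,
    ):
        self.classifier = classifier
        self.cv_folds = cv_folds
        self.parsimony_alpha = parsimony_alpha
        self.cv_random_state = cv_random_state

    def _search(self, fitness, d):
        if d > self.MAX_FEATURES:
            raise ValueError(
                f"exhaustive enumeration refused for n_features={d} > {self.MAX_FEATURES}"
            )
        best_score = -np.inf
        best_mask: Optional[tuple] = None
        trace = []
        for bits in product((0, 1), repeat=d):
            if not any(bits):
                continue
            s = fitness(np.array(bits))
            if s > best_score or (s == best_score and bits < best_mask):
                best_score, best_mask = s, bits
            trace.append(best_score)
        return np.array(best_mask, dtype=bool), best_score, np.array(trace), fitness.n_calls


def subset_fitness(table: FeatureTable, mask: np.ndarray, spec: FitnessSpec | None = None) -> float:
    """Score one subset of a table's features (see :class:`SubsetFitness`)."""
    return SubsetFitness(table.values, table.labels, spec or FitnessSpec())(mask)


def _result_from_estimator(est, table: FeatureTable, method: str, seed: int) -> SelectionResult:
    est.fit(table.values, table.labels)
    return SelectionResult(
        mask=est.support_,
        fitness=est.fitness_,
        history=est.history_,
        method=method,
        seed=seed,
        feature_names=list(table.feature_names),
        n_evaluations=est.n_evaluations_,
    )


def _check_dims(table: FeatureTable, config: SwarmConfig) -> None:
    if config.dims != table.n_features:
        raise ValueError(
            f"config.dims={config.dims} does not match n_features={table.n_features}"
        )


def bpso_select(
    table: FeatureTable, config: SwarmConfig, spec: FitnessSpec | None = None
) -> SelectionResult:
    """Select features with the mutation/recombination binary swarm."""
    spec = spec or FitnessSpec()
    _check_dims(table, config)
    est = BPSOFeatureSelector(
        n_particles=config.n_particles,
        n_iterations=config.n_iterations,
        variant=config.variant if config.variant != "continuous" else "modified_binary",
        w_max=config.w_max,
        w_min=config.w_min,
        d1=config.d1,
        d2=config.d2,
        m1_base=config.m1_base,
        m2_base=config.m2_base,
        v_clamp=config.v_clamp if config.v_clamp is not None else "auto",
        combine_threshold=config.combine_threshold,
        classifier=spec.classifier,
        cv_folds=spec.cv_folds,
        parsimony_alpha=spec.parsimony_alpha,
        random_state=config.seed,
        cv_random_state=spec.seed,
    )
    method = "standard_bpso" if config.variant == "standard_binary" else "bpso"
    return _result_from_estimator(est, table, method, config.seed)


def sffs_select(
    table: FeatureTable, spec: FitnessSpec | None = None, k_max: Optional[int] = None
) -> SelectionResult:
    """Select features with sequential floating forward selection."""
    spec = spec or FitnessSpec()
    est = SFFSSelector(
        k_max=k_max,
        classifier=spec.classifier,
        cv_folds=spec.cv_folds,
        parsimony_alpha=spec.parsimony_alpha,
        cv_random_state=spec.seed,
    )
    return _result_from_estimator(est, table, "sffs", spec.seed)


def levy_bpso_select(
    table: FeatureTable, config: SwarmConfig, spec: FitnessSpec | None = None, alpha: float = 1.5
) -> SelectionResult:
    """Select features with the heavy-tailed binary swarm baseline."""
    spec = spec or FitnessSpec()
    _check_dims(table, config)
    est = LevyBPSOSelector(
        alpha=alpha,
        n_particles=config.n_particles,
        n_iterations=config.n_iterations,
        w_max=config.w_max,
        w_min=config.w_min,
        d1=config.d1,
        d2=config.d2,
        v_clamp=config.v_clamp if config.v_clamp is not None else "auto",
        classifier=spec.classifier,
        cv_folds=spec.cv_folds,
        parsimony_alpha=spec.parsimony_alpha,
        random_state=config.seed,
        cv_random_state=spec.seed,
    )
    return _result_from_estimator(est, table, "levy_bpso", config.seed)


def exhaustive_select(table: FeatureTable, spec: FitnessSpec | None = None) -> SelectionResult:
    """Enumerate all subsets (oracle); n_features <= 15 only."""
    spec = spec or FitnessSpec()
    est = ExhaustiveSelector(
        classifier=spec.classifier,
        cv_folds=spec.cv_folds,
        parsimony_alpha=spec.parsimony_alpha,
        cv_random_state=spec.seed,
    )
    return _result_from_estimator(est, table, "exhaustive", spec.seed)
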
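"""Wrapper feature selection driven by the quantum-inspired GA.

Feature subsets are encoded as bitstrings (bit i = keep column i).  A
candidate subset is scored by the stratified cross-validated accuracy of a
lightweight multinomial-logistic probe trained on the masked columns,
minus a sparsity penalty ``lambda * (selected / d)``; the QGA searches the
2^d mask space for the best-scoring subset.  The final model is then
retrained on the selected columns only, and evaluated once on a held-out
split that never participates in the search.

:class:`QGAFeatureSelector` follows the scikit-learn selector API
(``fit`` / ``transform`` / ``get_support``) and composes with pipelines;
:func:`run_selection` is the batteries-included split -> select -> retrain
-> evaluate driver.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.utils.validation import check_is_fitted, check_X_y

from . import qga
from .head import SoftmaxHeadClassifier
from .metrics import MetricsReport, full_report

__all__ = [
    "FeatureMatrix",
    "FeatureMask",
    "FSConfig",
    "SelectionResult",
    "subset_fitness",
    "apply_mask",
    "QGAFeatureSelector",
    "qga_select_features",
    "run_selection",
    "derive_seeds",
]


# --------------------------------------------------------------------------
# containers and I/O


@dataclass
class FeatureMatrix:
    """n x d numeric features with integer class labels.

    ``informative_mask`` records ground truth for synthetic matrices: which
    columns actually carry class signal.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str] | None = None
    informative_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        n, d = self.values.shape
        if self.labels.shape != (n,):
            raise ValueError("labels must have one entry per row")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")
        classes, counts = np.unique(self.labels, return_counts=True)
        if not np.array_equal(classes, np.arange(classes.size)):
            raise ValueError("labels must cover a contiguous 0..C-1 range")
        if counts.min() < 2:
            raise ValueError("every class needs at least 2 samples")
        if self.feature_names is None:
            self.feature_names = [f"f{i}" for i in range(d)]
        if len(self.feature_names) != d:
            raise ValueError("one name per feature column is required")
        if self.informative_mask is not None:
            self.informative_mask = np.asarray(self.informative_mask, dtype=bool)
            if self.informative_mask.shape != (d,):
                raise ValueError("informative_mask must have length d")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df["label"] = self.labels
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # pandas raises several parser types
            raise ValueError(f"cannot parse feature matrix {path}: {exc}") from exc
        if "label" not in df.columns:
            raise ValueError(f"{path}: missing required 'label' column")
        labels = df.pop("label").to_numpy()
        if not np.issubdtype(np.asarray(labels).dtype, np.number):
            raise ValueError(f"{path}: 'label' column must be integer")
        bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
        if len(bad):
            raise ValueError(f"{path}: non-numeric feature columns {list(bad)}")
        return cls(
            values=df.to_numpy(dtype=np.float64),
            labels=np.asarray(labels, dtype=np.int64),
            feature_names=list(df.columns),
        )

    def to_npz(self, path: str | Path) -> None:
        """Binary round-trip (numpy ``.npz``) for large matrices."""
        extra = {}
        if self.informative_mask is not None:
            extra["informative_mask"] = self.informative_mask
        np.savez(
            path,
            values=self.values,
            labels=self.labels,
            feature_names=np.asarray(self.feature_names),
            **extra,
        )

    @classmethod
    def from_npz(cls, path: str | Path) -> "FeatureMatrix":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                values=z["values"],
                labels=z["labels"],
                feature_names=[str(s) for s in z["feature_names"]],
                informative_mask=z.get("informative_mask"),
            )


@dataclass
class FeatureMask:
    """A 0/1 column-selection vector."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits).astype(np.int8)
        if self.bits.ndim != 1:
            raise ValueError("mask bits must be 1-D")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("mask bits must be 0 or 1")

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())

    def as_bool(self) -> np.ndarray:
        return self.bits.astype(bool)


def apply_mask(matrix: FeatureMatrix, mask: FeatureMask | np.ndarray) -> FeatureMatrix:
    """Column-subset a matrix, preserving labels, row order and names."""
    if not isinstance(mask, FeatureMask):
        mask = FeatureMask(np.asarray(mask))
    if mask.bits.shape[0] != matrix.d:
        raise ValueError(
            f"mask length {mask.bits.shape[0]} != feature count {matrix.d}"
        )
    if mask.n_selected == 0:
        raise ValueError("all-zero mask would produce an empty matrix")
    keep = mask.as_bool()
    return FeatureMatrix(
        values=matrix.values[:, keep],
        labels=matrix.labels.copy(),
        feature_names=[n for n, k in zip(matrix.feature_names, keep) if k],
        informative_mask=(
            matrix.informative_mask[keep]
            if matrix.informative_mask is not None
            else None
        ),
    )


# --------------------------------------------------------------------------
# fitness


def _default_probe() -> LogisticRegression:
    # Multinomial logistic probe: cheap, deterministic, convex.
    return LogisticRegression(max_iter=200)


def subset_fitness(
    X: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray,
    *,
    estimator: BaseEstimator | None = None,
    cv: int = 5,
    sparsity_weight: float = 0.01,
    random_state: int = 0,
) -> float:
    """Penalized CV accuracy of a probe classifier on the masked columns.

    Returns ``mean stratified k-fold accuracy - sparsity_weight *
    (n_selected / d)``.  The all-zero mask scores 0 without training.
    Folds are stratified and seeded, so the score is a deterministic
    function of (data, mask, seed); if a class is too small for ``cv``
    folds the fold count is reduced, and a class with fewer than 2 members
    is an error.
    """
    mask = np.asarray(mask).astype(bool)
    d = X.shape[1]
    if mask.shape[0] != d:
        raise ValueError("mask length must equal feature count")
    n_sel = int(mask.sum())
    if n_sel == 0:
        return 0.0
    counts = np.bincount(np.asarray(y, dtype=np.int64))
    min_count = counts[counts > 0].min()
    if min_count < 2:
        raise ValueError("stratified CV impossible: a class has < 2 samples")
    n_splits = int(min(cv, min_count))
    folds = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=random_state)
    probe = clone(estimator) if estimator is not None else _default_probe()
    scores = cross_val_score(probe, X[:, mask], y, cv=folds, scoring="accuracy")
    return float(scores.mean()) - sparsity_weight * n_sel / d


# --------------------------------------------------------------------------
# the selector estimator


class QGAFeatureSelector(SelectorMixin, BaseEstimator):
    """Feature selection by quantum-inspired genetic search over masks.

    Each population member is a qubit register over d genes; observed
    bitstrings are feature masks scored by :func:`subset_fitness`.  Elitism
    keeps the best mask ever observed, and the registers are rotated toward
    it each generation.

    Parameters largely mirror :class:`qgafs.qga.QGAConfig` plus the fitness
    settings (``cv`` folds, ``sparsity_weight``, probe ``estimator``).

    Attributes
    ----------
    support_ : bool ndarray of shape (d,)
        The best mask found.
    best_fitness_ : float
    fitness_history_ : ndarray
        Best-so-far fitness per generation (non-decreasing).
    run_state_ : qgafs.qga.RunState
    n_distinct_masks_ : int
        Number of distinct masks actually scored (fitness values are
        memoized, so repeated masks cost nothing).
    """

    def __init__(
        self,
        estimator: BaseEstimator | None = None,
        population_size: int = 20,
        max_generations: int = 50,
        mutation_rate: float = 0.01,
        rotation_magnitude: float = 0.05 * np.pi,
        stall_patience: int | None = None,
        cv: int = 5,
        sparsity_weight: float = 0.01,
        random_state: int = 0,
        fitness_random_state: int | None = None,
        fitness_cache: dict | None = None,
    ):
        self.estimator = estimator
        self.population_size = population_size
        self.max_generations = max_generations
        self.mutation_rate = mutation_rate
        self.rotation_magnitude = rotation_magnitude
        self.stall_patience = stall_patience
        self.cv = cv
        self.sparsity_weight = sparsity_weight
        self.random_state = random_state
        # Fold assignment defaults to random_state; setting it separately
        # fixes the fitness landscape while the search seed varies.
        self.fitness_random_state = fitness_random_state
        # An externally supplied mapping lets several fits on the same data
        # share memoized mask scores.
        self.fitness_cache = fitness_cache

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        d = X.shape[1]
        if d < 2:
            raise ValueError("need at least 2 features to select from")
        cache = self.fitness_cache if self.fitness_cache is not None else {}
        fitness_seed = (
            self.fitness_random_state
            if self.fitness_random_state is not None
            else self.random_state
        )

        def fitness(bits: np.ndarray) -> float:
            key = bits.tobytes()
            if key not in cache:
                cache[key] = subset_fitness(
                    X,
                    y,
                    bits.astype(bool),
                    estimator=self.estimator,
                    cv=self.cv,
                    sparsity_weight=self.sparsity_weight,
                    random_state=fitness_seed,
                )
            return cache[key]

        config = qga.QGAConfig(
            population_size=self.population_size,
            max_generations=self.max_generations,
            mutation_rate=self.mutation_rate,
            rotation_magnitude=self.rotation_magnitude,
            stall_patience=self.stall_patience,
            seed=self.random_state,
        )
        state = qga.run(fitness, d, config)
        self.run_state_ = state
        self.support_ = state.best.bits.astype(bool)
        self.best_fitness_ = state.best.fitness
        self.fitness_history_ = state.best_history.copy()
        self.n_distinct_masks_ = len(cache)
        self.n_features_in_ = d
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


# --------------------------------------------------------------------------
# end-to-end driver


@dataclass
class FSConfig:
    """Configuration of the full select -> retrain -> evaluate run."""

    qga: qga.QGAConfig = field(default_factory=qga.QGAConfig)
    cv: int = 5
    sparsity_weight: float = 0.01
    test_fraction: float = 0.2
    head: dict = field(default_factory=dict)  # SoftmaxHeadClassifier kwargs
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.cv < 2:
            raise ValueError("cv must be >= 2")
        if self.sparsity_weight < 0:
            raise ValueError("sparsity_weight must be >= 0")


@dataclass
class SelectionResult:
    """Outcome of a full feature-selection run."""

    mask: FeatureMask
    selected_names: list[str]
    best_fitness: float
    fitness_history: np.ndarray
    report: MetricsReport
    config: dict
    seed: int

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": self.config,
            "mask_bits": "".join(str(int(b)) for b in self.mask.bits),
            "n_selected": self.mask.n_selected,
            "selected_names": self.selected_names,
            "best_fitness": float(self.best_fitness),
            "fitness_history": [float(v) for v in self.fitness_history],
            "metrics": self.report.to_dict(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def derive_seeds(seed: int, n: int) -> list[int]:
    """Fan a single experiment seed out into independent sub-seeds.

    Children are spawned from a ``numpy.random.SeedSequence`` so that the
    split, the mask search and the head training consume statistically
    independent streams, all reproducible from one integer.
    """
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31 - 1)) for child in ss.spawn(n)]


def _evaluate_holdout(
    model, X_test: np.ndarray, y_test: np.ndarray, class_names: list[str] | None
) -> MetricsReport:
    """The single point where held-out data is consumed."""
    y_pred = model.predict(X_test)
    return full_report(y_test, y_pred, class_names=class_names)


def run_selection(
    matrix: FeatureMatrix,
    config: FSConfig | None = None,
    class_names: list[str] | None = None,
) -> SelectionResult:
    """Split, search, retrain, evaluate — the full QGA-FS experiment.

    The data is split into a stratified train/test partition (default
    80/20).  The QGA mask search and its CV fitness run on the training
    portion only; the softmax head is then retrained on the selected
    training columns and evaluated exactly once on the held-out portion.
    """
    config = config or FSConfig()
    split_seed, search_seed, head_seed = derive_seeds(config.seed, 3)

    X_tr, X_te, y_tr, y_te = train_test_split(
        matrix.values,
        matrix.labels,
        test_size=config.test_fraction,
        stratify=matrix.labels,
        random_state=split_seed,
    )

    selector = QGAFeatureSelector(
        population_size=config.qga.population_size,
        max_generations=config.qga.max_generations,
        mutation_rate=config.qga.mutation_rate,
        rotation_magnitude=config.qga.rotation_magnitude,
        stall_patience=config.qga.stall_patience,
        cv=config.cv,
        sparsity_weight=config.sparsity_weight,
        random_state=search_seed,
    )
    selector.fit(X_tr, y_tr)
    mask = FeatureMask(selector.support_.astype(np.int8))

    head = SoftmaxHeadClassifier(random_state=head_seed, **config.head)
    head.fit(X_tr[:, selector.support_], y_tr)
    report = _evaluate_holdout(head, X_te[:, selector.support_], y_te, class_names)

    config_echo = {
        "qga": dict(config.qga.__dict__),
        "cv": config.cv,
        "sparsity_weight": config.sparsity_weight,
        "test_fraction": config.test_fraction,
        "head": dict(config.head),
        "derived_seeds": {
            "split": split_seed,
            "search": search_seed,
            "head": head_seed,
        },
    }
    return SelectionResult(
        mask=mask,
        selected_names=[
            n for n, keep in zip(matrix.feature_names, selector.support_) if keep
        ],
        best_fitness=selector.best_fitness_,
        fitness_history=selector.fitness_history_,
        report=report,
        config=config_echo,
        seed=config.seed,
    )


def qga_select_features(
    matrix: FeatureMatrix,
    config: FSConfig | None = None,
    class_names: list[str] | None = None,
) -> SelectionResult:
    """Alias for :func:`run_selection` (the operation-style entry point)."""
    return run_selection(matrix, config, class_names)
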
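"""Per-role jackknife multiplicity predictors and reliable-role selection.

Annotation consistency is scored against a set of *strongly predictable*
roles: roles whose multiplicity can be predicted from the multiplicities of
all other roles (a jackknife predictor) with a Tukey-trimean 5-fold CV
accuracy better than 93% and an accuracy IQR below 5%.  Training iterates:
select the reliable roles of the current matrix, restrict the matrix to
them, and repeat until the selected set stops changing; the final per-role
models are then retrained on the converged matrix.

:class:`ConsistencyPredictor` packages this loop as a scikit-learn style
estimator (``fit`` / ``predict`` / ``get_params``); the module-level
functions expose the individual steps.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    ExtraTreesClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import LogisticRegression

from .matrix import RoleMultiplicityMatrix
from .stats import AccuracyStats

__all__ = [
    "MAX_MULTIPLICITY",
    "ModelSpec",
    "ConsistencyPredictor",
    "EmptySelectionError",
    "UnknownRolesError",
    "crossval_role_accuracy",
    "select_reliable_roles",
    "train_to_convergence",
    "compare_models",
]

logger = logging.getLogger(__name__)

#: multiplicities are capped at 5 by the training filters, so predictions are too
MAX_MULTIPLICITY = 5

_REGRESSOR_KINDS = frozenset({"random_forest_regressor"})


class EmptySelectionError(ValueError):
    """No role met the strong-predictability criterion."""

    def __init__(self, message: str, iteration_log: list[int] | None = None):
        super().__init__(message)
        self.iteration_log = iteration_log or []


class UnknownRolesError(ValueError):
    """Input counts named roles outside the predictor's role universe."""

    def __init__(self, unknown: Sequence[str]):
        self.unknown = sorted(unknown)
        preview = ", ".join(self.unknown[:5])
        super().__init__(
            f"{len(self.unknown)} role(s) not in the training role universe: {preview}"
        )


@dataclass(frozen=True)
class ModelSpec:
    """A model family, its hyperparameters, and the seed for folds and fits."""

    model_kind: str = "random_forest_classifier"
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def build(self):
        return make_model(self)

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "hyperparameters": dict(self.hyperparameters),
            "seed": self.seed,
        }


def make_model(spec: ModelSpec):
    """Instantiate the sklearn estimator for a :class:`ModelSpec`."""
    params = dict(spec.hyperparameters)
    kind = spec.model_kind
    if kind == "random_forest_classifier":
        params.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **params)
    if kind == "random_forest_regressor":
        params.setdefault("n_estimators", 100)
        return RandomForestRegressor(random_state=spec.seed, n_jobs=1, **params)
    if kind == "extra_trees_classifier":
        params.setdefault("n_estimators", 100)
        return ExtraTreesClassifier(random_state=spec.seed, n_jobs=1, **params)
    if kind == "logistic_regression":
        params.setdefault("max_iter", 1000)
        return LogisticRegression(random_state=spec.seed, **params)
    if kind == "linear_discriminant":
        return LinearDiscriminantAnalysis(**params)
    if kind == "gradient_boosted_trees":
        return HistGradientBoostingClassifier(random_state=spec.seed, **params)
    raise ValueError(f"unsupported model kind {spec.model_kind!r}")


def _round_to_multiplicity(values: np.ndarray) -> np.ndarray:
    """Round half away from zero, then clip to the valid multiplicity range."""
    rounded = np.sign(values) * np.floor(np.abs(values) + 0.5)
    return np.clip(rounded, 0, MAX_MULTIPLICITY).astype(int)


def _predict_counts(model, X: np.ndarray, is_regressor: bool) -> np.ndarray:
    pred = model.predict(X)
    if is_regressor:
        return _round_to_multiplicity(np.asarray(pred, dtype=float))
    return np.asarray(pred, dtype=int)


def fold_assignments(
    genome_ids: Sequence[str], folds: int, seed: int
) -> list[np.ndarray]:
    """Partition genome row positions into CV folds.

    Genomes are sorted by id before the seeded shuffle, so fold membership
    is a function of (genome ids, seed) and invariant to row order.  The
    same folds are reused for every target role of an iteration.
    """
    ids = np.asarray(genome_ids, dtype=object)
    if len(ids) < folds:
        raise ValueError(f"need at least {folds} genomes for {folds}-fold CV")
    order = np.argsort(ids, kind="stable")
    rng = np.random.default_rng(seed)
    shuffled = order[rng.permutation(len(ids))]
    return np.array_split(shuffled, folds)


def _fold_accuracies(
    X: np.ndarray,
    col: int,
    spec: ModelSpec,
    fold_sets: Sequence[np.ndarray],
) -> list[float]:
    y = X[:, col]
    features = np.delete(X, col, axis=1)
    is_reg = spec.model_kind in _REGRESSOR_KINDS
    prototype = make_model(spec)
    accuracies: list[float] = []
    for k, test_idx in enumerate(fold_sets):
        train_idx = np.concatenate(
            [fold_sets[j] for j in range(len(fold_sets)) if j != k]
        )
        y_train = y[train_idx]
        if np.all(y_train == y_train[0]):
            # degenerate fold: a single class needs no model
            pred = np.full(len(test_idx), y_train[0], dtype=int)
        else:
            model = clone(prototype)
            try:
                model.fit(features[train_idx], y_train)
                pred = _predict_counts(model, features[test_idx], is_reg)
            except Exception as exc:  # e.g. LDA on zero within-class scatter
                logger.debug("fold fit failed (%s); falling back to majority", exc)
                values, freq = np.unique(y_train, return_counts=True)
                pred = np.full(len(test_idx), values[np.argmax(freq)], dtype=int)
        accuracies.append(float(np.mean(pred == y[test_idx])))
    return accuracies


def crossval_role_accuracy(
    matrix: RoleMultiplicityMatrix,
    target_role: str,
    model_spec: ModelSpec,
    folds: int = 5,
) -> AccuracyStats:
    """Jackknife CV accuracy of predicting one role from all the others.

    Fold accuracy is the fraction of genomes whose annotated multiplicity
    is matched exactly (regression outputs are rounded half away from zero
    and clipped to [0, 5] first).
    """
    if target_role not in matrix.roles:
        raise KeyError(f"role {target_role!r} is not a matrix column")
    fold_sets = fold_assignments(matrix.genome_ids, folds, model_spec.seed)
    col = matrix.roles.index(target_role)
    accs = _fold_accuracies(matrix.values, col, model_spec, fold_sets)
    return AccuracyStats.from_fold_accuracies(accs)


def select_reliable_roles(
    matrix: RoleMultiplicityMatrix,
    model_spec: ModelSpec,
    accuracy_threshold: float = 0.93,
    iqr_threshold: float = 0.05,
    folds: int = 5,
    n_jobs: int = 1,
) -> tuple[list[str], dict[str, AccuracyStats]]:
    """Roles whose CV trimean accuracy and IQR pass the strict thresholds.

    Selection requires ``trimean > accuracy_threshold`` and
    ``iqr < iqr_threshold`` (both strict: "better than" / "less than").
    Returns the selected roles (in matrix column order) together with
    the stats of every candidate role.  Per-role tasks are independent;
    with ``n_jobs > 1`` they run in parallel with results identical to
    serial execution.
    """
    fold_sets = fold_assignments(matrix.genome_ids, folds, model_spec.seed)
    X = matrix.values
    all_accs = joblib.Parallel(n_jobs=n_jobs)(
        joblib.delayed(_fold_accuracies)(X, col, model_spec, fold_sets)
        for col in range(len(matrix.roles))
    )
    stats = {
        role: AccuracyStats.from_fold_accuracies(accs)
        for role, accs in zip(matrix.roles, all_accs)
    }
    selected = [
        role
        for role in matrix.roles
        if stats[role].trimean > accuracy_threshold
        and stats[role].iqr < iqr_threshold
    ]
    if not selected:
        logger.warning("no role met the strong-predictability criterion")
    return selected, stats


class ConsistencyPredictor(BaseEstimator):
    """Annotation-consistency predictor over strongly predictable roles.

    ``fit`` runs the iterative reliable-role selection to convergence on a
    role-multiplicity matrix and retrains one jackknife model per converged
    role; ``predict`` returns integer multiplicity predictions for those
    roles, each computed from the annotated counts of all *other* roles.

    Parameters
    ----------
    model : str
        One of ``random_forest_classifier`` (default), ``random_forest_regressor``,
        ``extra_trees_classifier``, ``logistic_regression``,
        ``linear_discriminant``, ``gradient_boosted_trees``.
    model_params : dict or None
        Hyperparameters forwarded to the sklearn estimator
        (random forests default to 100 trees, unlimited depth).
    seed : int
        Seeds both the fold shuffle and the model fits.
    folds : int
        Cross-validation folds used during selection.
    accuracy_threshold, iqr_threshold : float
        Strict bounds of the strong-predictability criterion.
    max_iterations : int
        Cap on selection iterations (with a warning if reached).
    n_jobs : int
        Parallelism over per-role training tasks.

    Attributes
    ----------
    reliable_roles_ : list of str
        The converged strongly predictable roles (also the input feature
        universe of the final models).
    models_ : dict role -> fitted sklearn estimator
    stats_ : dict role -> AccuracyStats for the converged matrix
    iteration_log_ : list of int, selected-set size per iteration
    converged_ : bool
    training_genome_ids_ : list of str
    """

    def __init__(
        self,
        model: str = "random_forest_classifier",
        model_params: dict | None = None,
        seed: int = 0,
        folds: int = 5,
        accuracy_threshold: float = 0.93,
        iqr_threshold: float = 0.05,
        max_iterations: int = 10,
        n_jobs: int = 1,
    ):
        self.model = model
        self.model_params = model_params
        self.seed = seed
        self.folds = folds
        self.accuracy_threshold = accuracy_threshold
        self.iqr_threshold = iqr_threshold
        self.max_iterations = max_iterations
        self.n_jobs = n_jobs

    # -- fitting ----------------------------------------------------------

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            model_kind=self.model,
            hyperparameters=self.model_params or {},
            seed=self.seed,
        )

    @staticmethod
    def _as_matrix(X) -> RoleMultiplicityMatrix:
        if isinstance(X, RoleMultiplicityMatrix):
            return X
        if isinstance(X, pd.DataFrame):
            return RoleMultiplicityMatrix(X)
        raise TypeError(
            "X must be a RoleMultiplicityMatrix or a genomes x roles DataFrame"
        )

    def fit(self, X, y=None) -> "ConsistencyPredictor":
        """Iterate reliable-role selection to convergence and train models."""
        matrix = self._as_matrix(X)
        spec = self._spec()
        current = matrix
        self.iteration_log_ = []
        converged = False
        stats: dict[str, AccuracyStats] = {}
        for iteration in range(self.max_iterations):
            selected, stats = select_reliable_roles(
                current,
                spec,
                accuracy_threshold=self.accuracy_threshold,
                iqr_threshold=self.iqr_threshold,
                folds=self.folds,
                n_jobs=self.n_jobs,
            )
            if not selected:
                raise EmptySelectionError(
                    f"selection became empty at iteration {iteration + 1}; "
                    f"previous iteration sizes: {self.iteration_log_}",
                    iteration_log=self.iteration_log_,
                )
            self.iteration_log_.append(len(selected))
            logger.info(
                "iteration %d: %d/%d roles reliable",
                iteration + 1, len(selected), len(current.roles),
            )
            if len(selected) == len(current.roles):
                # selection is deterministic given (matrix, spec), so a
                # fixed point here is a fixed point forever
                converged = True
                break
            current = current.restrict(selected)
        if not converged:
            warnings.warn(
                f"reliable-role selection did not converge within "
                f"{self.max_iterations} iterations",
                stacklevel=2,
            )
        self.converged_ = converged
        self.reliable_roles_ = list(current.roles)
        self.stats_ = {r: stats[r] for r in self.reliable_roles_}
        self.training_genome_ids_ = list(current.genome_ids)
        self._train_final_models(current, spec)
        return self

    def _train_final_models(
        self, matrix: RoleMultiplicityMatrix, spec: ModelSpec
    ) -> None:
        X = matrix.values
        is_reg = spec.model_kind in _REGRESSOR_KINDS
        prototype = make_model(spec)

        def _fit_one(col: int):
            y = X[:, col]
            if np.all(y == y[0]):
                return ("constant", int(y[0]))
            model = clone(prototype)
            try:
                model.fit(np.delete(X, col, axis=1), y)
            except Exception as exc:
                logger.debug(
                    "final fit failed for column %d (%s); using majority", col, exc
                )
                values, freq = np.unique(y, return_counts=True)
                return ("constant", int(values[np.argmax(freq)]))
            return ("model", model)

        fitted = joblib.Parallel(n_jobs=self.n_jobs)(
            joblib.delayed(_fit_one)(col) for col in range(len(matrix.roles))
        )
        self.models_ = dict(zip(matrix.roles, fitted))
        self._is_regressor_ = is_reg

    # -- prediction -------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "models_"):
            raise RuntimeError("ConsistencyPredictor is not fitted")

    def _align(self, X: pd.DataFrame, ignore_unknown: bool) -> pd.DataFrame:
        """Align columns to the role universe by name; missing roles are 0."""
        universe = set(self.reliable_roles_)
        unknown = [c for c in X.columns if c not in universe]
        if unknown and not ignore_unknown:
            raise UnknownRolesError(unknown)
        known = [c for c in X.columns if c in universe]
        aligned = pd.DataFrame(
            0, index=X.index, columns=self.reliable_roles_, dtype=int
        )
        aligned[known] = X[known].astype(int)
        return aligned

    def predict(self, X, *, ignore_unknown: bool = False) -> pd.DataFrame:
        """Predicted multiplicity of each reliable role for each genome row.

        Each role's prediction is computed from the annotated counts of all
        other roles (the role's own count is never an input to its model).
        Columns are aligned by role name; roles missing from ``X`` count 0.
        Columns outside the role universe raise :class:`UnknownRolesError`
        unless ``ignore_unknown`` is set (they carry no predictor).
        """
        self._check_fitted()
        if isinstance(X, RoleMultiplicityMatrix):
            X = X.data
        if isinstance(X, Mapping) or isinstance(X, pd.Series):
            X = pd.DataFrame([dict(X)])
        aligned = self._align(X, ignore_unknown)
        values = aligned.to_numpy()
        out = np.empty_like(values)
        for col, role in enumerate(self.reliable_roles_):
            kind, payload = self.models_[role]
            if kind == "constant":
                out[:, col] = payload
            else:
                out[:, col] = _predict_counts(
                    payload, np.delete(values, col, axis=1), self._is_regressor_
                )
        return pd.DataFrame(out, index=aligned.index, columns=self.reliable_roles_)

    def predict_vector(self, counts: Mapping[str, int]) -> dict[str, int]:
        """Predictions for a single genome's role-count mapping."""
        frame = pd.DataFrame([dict(counts)]) if counts else pd.DataFrame(
            np.zeros((1, 0), dtype=int)
        )
        pred = self.predict(frame)
        return {role: int(v) for role, v in pred.iloc[0].items()}

    # -- persistence ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Persist as a directory: JSON manifest + serialized models."""
        self._check_fitted()
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "params": self.get_params(),
            "reliable_roles": self.reliable_roles_,
            "stats": {r: s.to_dict() for r, s in self.stats_.items()},
            "iteration_log": self.iteration_log_,
            "converged": self.converged_,
            "training_genome_ids": self.training_genome_ids_,
            "is_regressor": self._is_regressor_,
        }
        with open(directory / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        joblib.dump(self.models_, directory / "models.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "ConsistencyPredictor":
        directory = Path(directory)
        with open(directory / "manifest.json") as fh:
            manifest = json.load(fh)
        predictor = cls(**manifest["params"])
        predictor.reliable_roles_ = list(manifest["reliable_roles"])
        predictor.stats_ = {
            r: AccuracyStats.from_dict(d) for r, d in manifest["stats"].items()
        }
        predictor.iteration_log_ = list(manifest["iteration_log"])
        predictor.converged_ = bool(manifest["converged"])
        predictor.training_genome_ids_ = list(manifest["training_genome_ids"])
        predictor._is_regressor_ = bool(manifest["is_regressor"])
        predictor.models_ = joblib.load(directory / "models.joblib")
        return predictor


def train_to_convergence(
    matrix: RoleMultiplicityMatrix,
    model_spec: ModelSpec | None = None,
    accuracy_threshold: float = 0.93,
    iqr_threshold: float = 0.05,
    folds: int = 5,
    max_iterations: int = 10,
    n_jobs: int = 1,
) -> ConsistencyPredictor:
    """Functional wrapper over :meth:`ConsistencyPredictor.fit`."""
    spec = model_spec or ModelSpec()
    predictor = ConsistencyPredictor(
        model=spec.model_kind,
        model_params=dict(spec.hyperparameters),
        seed=spec.seed,
        folds=folds,
        accuracy_threshold=accuracy_threshold,
        iqr_threshold=iqr_threshold,
        max_iterations=max_iterations,
        n_jobs=n_jobs,
    )
    return predictor.fit(matrix)


def compare_models(
    matrix: RoleMultiplicityMatrix,
    model_specs: Sequence[ModelSpec],
    accuracy_threshold: float = 0.93,
    iqr_threshold: float = 0.05,
    folds: int = 5,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """First-iteration comparison of model families on one matrix.

    For each spec, runs a single selection pass and reports the number of
    roles passing the strong-predictability criterion and the mean trimean
    accuracy over *all* candidate roles (as a percentage).
    """
    if not model_specs:
        raise ValueError("need at least one ModelSpec")
    rows = []
    for spec in model_specs:
        selected, stats = select_reliable_roles(
            matrix,
            spec,
            accuracy_threshold=accuracy_threshold,
            iqr_threshold=iqr_threshold,
            folds=folds,
            n_jobs=n_jobs,
        )
        rows.append(
            {
                "model_kind": spec.model_kind,
                "seed": spec.seed,
                "reliable_roles": len(selected),
                "mean_trimean_accuracy_pct": 100.0
                * float(np.mean([s.trimean for s in stats.values()])),
            }
        )
    return pd.DataFrame(rows)
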
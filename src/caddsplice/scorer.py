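"""Model fitting and scoring.

An L2-regularised logistic regression is trained to separate proxy-benign
(evolutionarily derived, label 0) from proxy-deleterious (simulated, label 1)
variants on the expanded design matrix. Continuous columns (numeric
annotations and the consequence-interaction products) are standardised with
training-set statistics; indicator columns stay raw. The regularisation
strength is chosen by grid search on a held-out split scored by log-loss,
then the model is refit on the full training set.

Raw scores are the linear predictor (log-odds of the proxy-deleterious
class; higher = more deleterious-like). For reporting, raw scores are ranked
against a reference score distribution and PHRED-scaled:
``scaled = -10 * log10(rank / N)`` with descending ranks and ties sharing the
worst (largest) rank, so the top-ranked variant of a 100-score reference gets
20.0 and the median gets about 3.0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import train_test_split

from .core_model import FeatureSchema, ModelWeights
from .design_matrix import DesignMatrix

__all__ = [
    "TrainingSet",
    "FitConfig",
    "ScoringModel",
    "fit",
    "raw_score",
    "phred_scale",
    "percentile_rank",
]


@dataclass
class TrainingSet:
    """A design matrix with aligned 0/1 proxy labels."""

    matrix: DesignMatrix
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.labels) != self.matrix.n_rows:
            raise ValueError(
                f"{len(self.labels)} labels for {self.matrix.n_rows} rows"
            )
        classes = np.unique(self.labels)
        if not np.array_equal(classes, [0, 1]):
            raise ValueError(
                "training set must contain both classes (labels 0 and 1), "
                f"got {classes.tolist()}"
            )


@dataclass
class FitConfig:
    """Hyperparameters of the regularised fit.

    ``c_grid`` is searched by held-out log-loss (25% validation split drawn
    with ``seed``); ``tol``/``max_iter`` go to the solver. Non-convergence is
    an error.
    """

    c_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    val_fraction: float = 0.25
    seed: int = 0
    tol: float = 1e-6
    max_iter: int = 2000
    standardize: bool = True


def _continuous_column_mask(matrix: DesignMatrix, schema: FeatureSchema) -> np.ndarray:
    """Continuous columns: numeric annotations and interaction products.

    One-hot, substitution, exchange, and W columns are 0/1 indicators and
    stay on their natural scale.
    """
    mask = np.zeros(matrix.n_columns, dtype=bool)
    x_slice = matrix.group_slice("X")
    mask[x_slice.start:x_slice.start + len(schema.numeric_annotation_names)] = True
    mask[matrix.group_slice("interactions")] = True
    return mask


@dataclass
class ScoringModel:
    """A fitted model artifact: weights plus the transforms to apply them.

    Bundles the column layout, the standardisation parameters computed on the
    training data, the coefficient vector, and fit metadata so that scoring
    applies exactly the transforms used in training.
    """

    columns: list[str]
    column_groups: dict[str, list[str]]
    coef: np.ndarray
    intercept: float
    center: np.ndarray
    scale: np.ndarray
    metadata: dict = field(default_factory=dict)

    def weights(self, schema: FeatureSchema) -> ModelWeights:
        """Unpack the flat coefficient vector into the five named groups."""
        groups = {}
        start = 0
        for name, cols in self.column_groups.items():
            groups[name] = self.coef[start:start + len(cols)]
            start += len(cols)
        n_cat = len(schema.consequence_categories)
        n_d = len(schema.interaction_set)
        weights = ModelWeights(
            beta0=self.intercept,
            beta=groups["X"],
            gamma=groups["base_pairs"],
            delta=groups["aa_exchange"],
            tau=groups["W"],
            alpha=groups["interactions"].reshape(n_cat, n_d),
        )
        weights.validate_against(schema)
        return weights

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.center) / self.scale

    def raw_scores(self, matrix: DesignMatrix) -> np.ndarray:
        if matrix.columns != self.columns:
            raise ValueError("matrix columns do not match the fitted model")
        return self.transform(matrix.values) @ self.coef + self.intercept

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "columns": self.columns,
                    "column_groups": self.column_groups,
                    "coef": self.coef.tolist(),
                    "intercept": self.intercept,
                    "center": self.center.tolist(),
                    "scale": self.scale.tolist(),
                    "metadata": self.metadata,
                },
                fh,
            )

    @classmethod
    def load(cls, path) -> "ScoringModel":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            columns=data["columns"],
            column_groups=data["column_groups"],
            coef=np.asarray(data["coef"]),
            intercept=float(data["intercept"]),
            center=np.asarray(data["center"]),
            scale=np.asarray(data["scale"]),
            metadata=data.get("metadata", {}),
        )


def _fit_single(X, y, c, config) -> LogisticRegression:
    # L2 penalty (the sklearn default), strength 1/C
    model = LogisticRegression(
        C=c, solver="lbfgs", tol=config.tol, max_iter=config.max_iter,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model.fit(X, y)
        except ConvergenceWarning as exc:
            raise RuntimeError(
                f"logistic regression did not converge at C={c}: {exc}"
            ) from exc
    return model


def fit(
    train: TrainingSet,
    schema: FeatureSchema,
    config: FitConfig | None = None,
) -> ScoringModel:
    """Fit the five-term logistic model on proxy labels.

    Standardisation statistics come from the training data only; the L2
    strength is selected from ``config.c_grid`` by log-loss on a held-out
    split and the winner is refit on everything. Deterministic for a fixed
    seed and configuration.
    """
    config = config or FitConfig()
    values = train.matrix.values
    y = train.labels

    if config.standardize:
        mask = _continuous_column_mask(train.matrix, schema)
        center = np.where(mask, values.mean(axis=0), 0.0)
        sd = values.std(axis=0)
        scale = np.where(mask & (sd > 0), sd, 1.0)
    else:
        center = np.zeros(values.shape[1])
        scale = np.ones(values.shape[1])
    X = (values - center) / scale

    if len(config.c_grid) > 1:
        X_tr, X_val, y_tr, y_val = train_test_split(
            X, y, test_size=config.val_fraction,
            random_state=config.seed, stratify=y,
        )
        losses = {}
        for c in config.c_grid:
            model = _fit_single(X_tr, y_tr, c, config)
            losses[c] = log_loss(y_val, model.predict_proba(X_val)[:, 1])
        best_c = min(config.c_grid, key=lambda c: losses[c])
    else:
        best_c = config.c_grid[0]
        losses = {}

    final = _fit_single(X, y, best_c, config)
    return ScoringModel(
        columns=train.matrix.columns,
        column_groups=train.matrix.column_groups,
        coef=final.coef_[0].copy(),
        intercept=float(final.intercept_[0]),
        center=center,
        scale=scale,
        metadata={
            "seed": config.seed,
            "c_grid": list(config.c_grid),
            "selected_c": best_c,
            "validation_log_loss": {str(k): v for k, v in losses.items()},
            "tol": config.tol,
            "n_training_rows": int(train.matrix.n_rows),
        },
    )


def raw_score(model: ScoringModel, row: np.ndarray) -> float:
    """Linear predictor for a single encoded row."""
    row = np.asarray(row, dtype=float)
    if row.shape != (len(model.columns),):
        raise ValueError(
            f"row has shape {row.shape}, model expects ({len(model.columns)},)"
        )
    return float(model.transform(row) @ model.coef + model.intercept)


def _reference_ranks(scores: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Descending rank of each score in the reference distribution.

    The rank is the number of reference scores >= the score (ties therefore
    share the worst, i.e. largest, rank), clipped to at least 1 so scores
    above the whole reference rank first.
    """
    ref_sorted = np.sort(np.asarray(reference, dtype=float))
    n = len(ref_sorted)
    below = np.searchsorted(ref_sorted, np.asarray(scores, dtype=float), side="left")
    return np.maximum(n - below, 1)


def percentile_rank(scores, reference) -> np.ndarray:
    """Fractional descending rank (rank/N) of scores within a reference."""
    reference = np.asarray(reference, dtype=float)
    if reference.size == 0:
        raise ValueError("reference distribution is empty")
    return _reference_ranks(np.asarray(scores), reference) / reference.size


def phred_scale(raw_scores, reference_distribution) -> np.ndarray:
    """PHRED-like scaling: ``-10 * log10(rank / N)`` against a reference.

    The highest score of an N=100 reference maps to 20.0; a score ranked at
    the median maps to about 3.01; when all scores tie they share rank N and
    scale to 0.
    """
    frac = percentile_rank(raw_scores, reference_distribution)
    return -10.0 * np.log10(frac)
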
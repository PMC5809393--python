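"""Cell-cycle phase classification: decision tree initialization + GMM/EM refinement.

Four markers jointly identify cell-cycle phase in mass cytometry: IdU
(incorporated during DNA replication, marks S), cyclin B1 (accumulates
through G2, peaks in early mitosis), phospho-histone H3 (mitotic spike) and
phospho-Rb (increases from late G1 onward).  Classification is a hybrid of

1. a decision tree trained on manually gated cells, which encodes the
   gating logic as interpretable if-else rules and pins each cluster to its
   known phase label, and
2. a four-component Gaussian mixture initialized from the tree's
   predictions (component means, covariances and weights taken from the
   per-phase moments of the tree-labelled cells) and refined by EM.

The tree contributes a labelled initial guess close to the optimum, which
matters because phase prevalences differ by an order of magnitude (G0/G1
around half the population, M only a few percent) and an unconstrained
mixture fit can both label-switch and swallow the mitotic component.  The
component-to-phase correspondence is frozen at initialization and never
re-matched after EM.  Cells are assigned to the maximal-posterior component,
and the posterior matrix is kept for uncertainty inspection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import logsumexp
from sklearn.model_selection import cross_val_score
from sklearn.tree import DecisionTreeClassifier, export_text

from .data import (
    CELL_CYCLE_ROLES,
    PHASES,
    ChannelMap,
    DataError,
    DegenerateChannelError,
    ExpressionMatrix,
    Stage,
)

__all__ = [
    "StandardizationStats",
    "PhaseModel",
    "PhaseAssignment",
    "standardize",
    "train_tree",
    "init_gmm_from_tree",
    "refine_em",
    "assign_phases",
    "fit_phase_model",
    "score_vs_reference",
    "default_model",
]

_MIN_CELLS_PER_COMPONENT = 5


@dataclass(frozen=True)
class StandardizationStats:
    """Per-channel (mean, sd) recorded at standardization time.

    Stored so held-out cells or a second batch can be projected into exactly
    the same standardized space as the cells the model was fitted on.
    """

    channels: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray


def standardize(
    matrix: ExpressionMatrix,
    channel_map: ChannelMap,
    stats: StandardizationStats | None = None,
) -> tuple[ExpressionMatrix, StandardizationStats]:
    """Zero-mean / unit-variance scale the four cell-cycle channels.

    Standardization removes per-antibody scale differences (concentration,
    affinity) before classification.  Other channels are left untouched.
    Pass previously recorded ``stats`` to reuse a training batch's scaling.
    """
    matrix.require_stage(Stage.TRANSFORMED, Stage.STANDARDIZED)
    channels = channel_map.cellcycle_in_order
    cols = matrix.column_index(channels)
    values = matrix.values.copy()
    if stats is None:
        means = values[:, cols].mean(axis=0)
        sds = values[:, cols].std(axis=0, ddof=1)
        for name, sd in zip(channels, sds):
            if not sd > 0:
                raise DegenerateChannelError(
                    f"cell-cycle channel {name!r} has zero variance"
                )
        stats = StandardizationStats(tuple(channels), means, sds)
    else:
        if tuple(stats.channels) != tuple(channels):
            raise DataError("standardization stats were recorded for different channels")
    values[:, cols] = (values[:, cols] - stats.means) / stats.sds
    return matrix.with_values(values, Stage.STANDARDIZED), stats


@dataclass
class PhaseModel:
    """Hybrid tree + Gaussian-mixture phase classifier.

    ``component_phases`` is the component-to-phase bijection fixed when the
    mixture is initialized from the tree; EM refines the component
    parameters but never re-matches components to phases.
    """

    tree: DecisionTreeClassifier | None = None
    training_accuracy: float | None = None
    means: np.ndarray | None = None  # (4, 4)
    covariances: np.ndarray | None = None  # (4, 4, 4), symmetric PD
    weights: np.ndarray | None = None  # simplex 4-vector
    component_phases: tuple[str, ...] = PHASES
    converged: bool = False
    n_iter: int = 0
    loglik_trace: list[float] = field(default_factory=list)
    standardization: StandardizationStats | None = None

    @property
    def has_gmm(self) -> bool:
        return self.means is not None

    def tree_rules(self) -> str:
        """Human-readable if-else rules of the fitted tree."""
        if self.tree is None:
            return ""
        return export_text(self.tree, feature_names=list(CELL_CYCLE_ROLES))

    def to_json(self) -> str:
        """Serialize to a structured text document.

        The GMM parameters and standardization statistics round-trip exactly
        and fully restore classification behaviour (assignment uses only the
        mixture posteriors).  The tree is stored as its exported rule text
        for provenance, not re-loadable as an estimator.
        """
        doc = {
            "component_phases": list(self.component_phases),
            "tree_rules": self.tree_rules(),
            "training_accuracy": self.training_accuracy,
            "means": None if self.means is None else self.means.tolist(),
            "covariances": None if self.covariances is None else self.covariances.tolist(),
            "weights": None if self.weights is None else self.weights.tolist(),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "loglik_trace": [float(x) for x in self.loglik_trace],
            "standardization": None
            if self.standardization is None
            else {
                "channels": list(self.standardization.channels),
                "means": self.standardization.means.tolist(),
                "sds": self.standardization.sds.tolist(),
            },
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhaseModel":
        doc = json.loads(text)
        std = doc.get("standardization")
        return cls(
            tree=None,
            training_accuracy=doc.get("training_accuracy"),
            means=None if doc["means"] is None else np.asarray(doc["means"]),
            covariances=None if doc["covariances"] is None else np.asarray(doc["covariances"]),
            weights=None if doc["weights"] is None else np.asarray(doc["weights"]),
            component_phases=tuple(doc["component_phases"]),
            converged=doc["converged"],
            n_iter=doc["n_iter"],
            loglik_trace=list(doc.get("loglik_trace", [])),
            standardization=None
            if std is None
            else StandardizationStats(
                tuple(std["channels"]), np.asarray(std["means"]), np.asarray(std["sds"])
            ),
        )


@dataclass
class PhaseAssignment:
    """Per-cell phase labels with posterior probabilities.

    ``labels`` holds phase strings from the fixed order G0/G1 < S < G2 < M;
    ``posteriors`` is row-stochastic, one column per phase in that order.
    """

    labels: np.ndarray
    posteriors: np.ndarray
    source: str  # "tree" | "gmm" | "manual"
    cell_ids: np.ndarray | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        self.posteriors = np.asarray(self.posteriors, dtype=float)
        if self.posteriors.shape != (self.labels.shape[0], len(PHASES)):
            raise DataError("posteriors must be n x 4")
        rowsums = self.posteriors.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise DataError("posterior rows must sum to 1")
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.labels.shape[0], dtype=np.int64)
        unknown = set(self.labels) - set(PHASES)
        if unknown:
            raise DataError(f"unknown phase labels {sorted(unknown)}")

    @classmethod
    def from_labels(cls, labels, source: str = "manual", cell_ids=None) -> "PhaseAssignment":
        labels = np.asarray(labels, dtype=object)
        post = np.zeros((labels.shape[0], len(PHASES)))
        for k, phase in enumerate(PHASES):
            post[labels == phase, k] = 1.0
        return cls(labels, post, source, cell_ids)

    @property
    def codes(self) -> np.ndarray:
        """Integer phase codes 1..4 in phase order (for FCS export)."""
        lut = {p: i + 1 for i, p in enumerate(PHASES)}
        return np.asarray([lut[p] for p in self.labels], dtype=np.int64)

    def proportions(self) -> np.ndarray:
        return np.asarray([(self.labels == p).mean() for p in PHASES])

    def subset(self, index) -> "PhaseAssignment":
        return PhaseAssignment(
            self.labels[index], self.posteriors[index], self.source, self.cell_ids[index]
        )


def _check_training_labels(labels: np.ndarray) -> None:
    present = set(labels)
    missing = [p for p in PHASES if p not in present]
    if missing:
        raise DataError(f"training data has no cells in phase(s) {missing}")


def train_tree(
    X: np.ndarray, labels: np.ndarray, seed: int = 0
) -> tuple[DecisionTreeClassifier, float]:
    """Fit a CART tree on the standardized 4-marker space.

    Gini impurity, depth capped at 6, cost-complexity pruning strength
    chosen by 5-fold cross-validation.  A shallow tree suffices: manual
    cell-cycle gating is itself a short cascade of threshold decisions, and
    on cleanly gated data the tree reaches four pure terminal nodes.
    Returns the tree and its training accuracy.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object)
    _check_training_labels(labels)
    base = DecisionTreeClassifier(criterion="gini", max_depth=6, random_state=seed)
    path = base.cost_complexity_pruning_path(X, labels)
    alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
    if alphas.size > 8:  # keep CV cheap; pruning strengths beyond a few matter little
        alphas = np.quantile(alphas, np.linspace(0, 0.5, 8))
    best_alpha, best_score = 0.0, -np.inf
    for alpha in alphas:
        clf = DecisionTreeClassifier(
            criterion="gini", max_depth=6, ccp_alpha=float(alpha), random_state=seed
        )
        score = cross_val_score(clf, X, labels, cv=5).mean()
        if score > best_score + 1e-12:
            best_alpha, best_score = float(alpha), score
    tree = DecisionTreeClassifier(
        criterion="gini", max_depth=6, ccp_alpha=best_alpha, random_state=seed
    )
    tree.fit(X, labels)
    accuracy = float((tree.predict(X) == labels).mean())
    return tree, accuracy


def _ridge(cov: np.ndarray) -> np.ndarray:
    d = cov.shape[0]
    eps = 1e-6 * np.trace(cov) / d
    return cov + max(eps, 1e-12) * np.eye(d)


def init_gmm_from_tree(X: np.ndarray, predictions: np.ndarray) -> PhaseModel:
    """Moment-match a 4-component mixture to the tree-predicted phases.

    Component k's mean/covariance/weight are the sample moments of the cells
    the tree placed in phase k; the component-to-phase bijection is fixed
    here.  A predicted phase with fewer than 5 cells cannot support a
    covariance estimate and raises :class:`DataError` (callers fall back to
    tree-only assignment).
    """
    X = np.asarray(X, dtype=float)
    predictions = np.asarray(predictions, dtype=object)
    d = X.shape[1]
    means = np.zeros((len(PHASES), d))
    covs = np.zeros((len(PHASES), d, d))
    weights = np.zeros(len(PHASES))
    for k, phase in enumerate(PHASES):
        mask = predictions == phase
        n_k = int(mask.sum())
        if n_k < _MIN_CELLS_PER_COMPONENT:
            raise DataError(
                f"tree predicted only {n_k} cells in phase {phase!r}; "
                f"need >= {_MIN_CELLS_PER_COMPONENT} to initialize a component"
            )
        sub = X[mask]
        means[k] = sub.mean(axis=0)
        covs[k] = _ridge(np.cov(sub, rowvar=False))
        weights[k] = n_k / X.shape[0]
    return PhaseModel(means=means, covariances=covs, weights=weights, component_phases=PHASES)


def _log_gaussian(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    chol = np.linalg.cholesky(cov)
    z = solve_triangular(chol, (X - mean).T, lower=True)
    maha = np.einsum("ij,ij->j", z, z)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def _log_prob_matrix(model: PhaseModel, X: np.ndarray) -> np.ndarray:
    parts = []
    for k in range(len(PHASES)):
        parts.append(np.log(model.weights[k]) + _log_gaussian(X, model.means[k], model.covariances[k]))
    return np.column_stack(parts)


def loglikelihood(model: PhaseModel, X: np.ndarray) -> float:
    """Total mixture log-likelihood of the data under the model."""
    return float(logsumexp(_log_prob_matrix(model, X), axis=1).sum())


def refine_em(
    model: PhaseModel, X: np.ndarray, tol: float = 1e-6, max_iter: int = 500
) -> PhaseModel:
    """Refine mixture parameters by EM until the relative log-likelihood
    change drops below ``tol`` or ``max_iter`` is reached.

    The log-likelihood is non-decreasing by construction and is asserted so
    every iteration; covariances are ridge-regularized each M step, and a
    covariance that stays singular aborts the refinement, returning the
    last valid parameters with a warning.
    """
    if not model.has_gmm:
        raise DataError("model has no mixture initialization to refine")
    X = np.asarray(X, dtype=float)
    means = model.means.copy()
    covs = model.covariances.copy()
    weights = model.weights.copy()
    state = PhaseModel(
        tree=model.tree,
        training_accuracy=model.training_accuracy,
        means=means,
        covariances=covs,
        weights=weights,
        component_phases=model.component_phases,
        standardization=model.standardization,
    )
    trace = [loglikelihood(state, X)]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        log_prob = _log_prob_matrix(state, X)
        log_norm = logsumexp(log_prob, axis=1)
        resp = np.exp(log_prob - log_norm[:, None])
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):
            warnings.warn("a mixture component collapsed to zero weight; stopping EM")
            break
        new_means = (resp.T @ X) / nk[:, None]
        new_covs = np.empty_like(covs)
        try:
            for k in range(len(PHASES)):
                diff = X - new_means[k]
                cov = (diff * resp[:, [k]]).T @ diff / nk[k]
                new_covs[k] = _ridge(cov)
                np.linalg.cholesky(new_covs[k])
        except np.linalg.LinAlgError:
            warnings.warn("singular covariance during EM; returning last valid parameters")
            break
        state.means, state.covariances, state.weights = new_means, new_covs, nk / X.shape[0]
        ll = loglikelihood(state, X)
        prev = trace[-1]
        if ll < prev - 1e-8 * max(1.0, abs(prev)):
            raise AssertionError(
                f"EM log-likelihood decreased at iteration {n_iter}: {prev} -> {ll}"
            )
        trace.append(ll)
        if abs(ll - prev) < tol * abs(prev):
            converged = True
            break
    state.converged = converged
    state.n_iter = n_iter
    state.loglik_trace = trace
    return state


def assign_phases(model: PhaseModel, X: np.ndarray, cell_ids=None) -> PhaseAssignment:
    """Assign each cell to the maximal-posterior mixture component.

    For a tree-only model (mixture unavailable) the tree prediction is used
    with one-hot posteriors.
    """
    X = np.asarray(X, dtype=float)
    if model.has_gmm:
        log_prob = _log_prob_matrix(model, X)
        log_norm = logsumexp(log_prob, axis=1)
        post = np.exp(log_prob - log_norm[:, None])
        post /= post.sum(axis=1, keepdims=True)
        labels = np.asarray(model.component_phases, dtype=object)[post.argmax(axis=1)]
        return PhaseAssignment(labels, post, "gmm", cell_ids)
    if model.tree is None:
        raise DataError("model has neither a mixture nor a tree")
    labels = model.tree.predict(X).astype(object)
    assignment = PhaseAssignment.from_labels(labels, "tree", cell_ids)
    return assignment


def fit_phase_model(
    X: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    standardization: StandardizationStats | None = None,
) -> PhaseModel:
    """Full hybrid fit: tree on manual gates, mixture init from the tree, EM.

    If the tree leaves a phase with too few cells to initialize a component,
    the model degrades to tree-only assignment with a warning.
    """
    tree, accuracy = train_tree(X, labels, seed=seed)
    predictions = tree.predict(X).astype(object)
    try:
        model = init_gmm_from_tree(X, predictions)
    except DataError as err:
        warnings.warn(f"GMM skipped, using tree-only assignment: {err}")
        return PhaseModel(
            tree=tree, training_accuracy=accuracy, standardization=standardization
        )
    model.tree = tree
    model.training_accuracy = accuracy
    model.standardization = standardization
    return refine_em(model, X, tol=tol, max_iter=max_iter)


def classify(
    matrix: ExpressionMatrix,
    channel_map: ChannelMap,
    model: PhaseModel,
) -> PhaseAssignment:
    """Classify a standardized matrix using a fitted model."""
    matrix.require_stage(Stage.STANDARDIZED)
    X = matrix.values[:, matrix.column_index(channel_map.cellcycle_in_order)]
    return assign_phases(model, X, cell_ids=matrix.cell_ids)


def score_vs_reference(
    assignment: PhaseAssignment, reference: PhaseAssignment
) -> tuple[float, pd.DataFrame]:
    """Accuracy and 4x4 confusion table against a reference labelling.

    Rows of the confusion table are the reference phases, columns the
    assignment's.  Cell ids must match element-wise.
    """
    if not np.array_equal(assignment.cell_ids, reference.cell_ids):
        raise DataError("assignments cover different cells (cell id mismatch)")
    accuracy = float((assignment.labels == reference.labels).mean())
    table = pd.DataFrame(0, index=list(PHASES), columns=list(PHASES), dtype=int)
    for ref, pred in zip(reference.labels, assignment.labels):
        table.loc[ref, pred] += 1
    return accuracy, table


_DEFAULT_MODEL_CACHE: dict[int, PhaseModel] = {}


def default_model(seed: int = 0) -> PhaseModel:
    """A phase model trained on the package's synthetic reference population.

    Useful when no manually gated training set is available; retraining on
    user gates via :func:`fit_phase_model` is preferred when gates exist.
    """
    if seed not in _DEFAULT_MODEL_CACHE:
        from . import synthetic
        from .volume import volume_pipeline

        config = synthetic.GeneratorConfig(n_cells=8000, seed=seed)
        sample = synthetic.generate(config)
        transformed, _ = volume_pipeline(sample.matrix, sample.channel_map)
        standardized, stats = standardize(transformed, sample.channel_map)
        X = standardized.values[
            :, standardized.column_index(sample.channel_map.cellcycle_in_order)
        ]
        _DEFAULT_MODEL_CACHE[seed] = fit_phase_model(
            X, sample.truth["phase"].to_numpy(), seed=seed, standardization=stats
        )
    return _DEFAULT_MODEL_CACHE[seed]
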
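"""Supervised 1-D cell-cycle pseudotime via linear programming.

Cells progress continuously through the cycle, so discrete phase labels
under-represent the data.  Given the standardized four-marker vectors
``y_i`` and phase labels with the known order G0/G1 < S < G2 < M, we seek a
non-negative linear embedding

    f_alpha(y_i) = sum_j alpha_j * y_{i,j},     alpha_j >= 0,

whose values respect the phase order: for every pair of cells ``(i_p, i_q)``
in adjacent phases ``p < q`` we want ``f(y_{i_p}) < f(y_{i_q})``.  Because
the projection cannot always separate overlapping clusters perfectly, each
ordering constraint gets a non-negative slack variable measuring its
violation, and the weighted sum of slacks is minimized.  With the strict
inequality encoded as a margin ``eps`` and alpha constrained to the simplex
(sum alpha = 1, making the scale identifiable), this is a plain LP:

    min   sum_pairs w * xi
    s.t.  alpha . (y_q - y_p) >= eps - xi     for all adjacent-phase pairs
          sum alpha = 1,  alpha >= 0,  xi >= 0.

Slack makes every instance feasible, and when a zero-slack alpha exists the
optimum orders every adjacent-phase pair correctly by design.  Because the
pair count grows quadratically, the LP is solved on a per-phase stratified
random subsample; the resulting alpha is then applied to every cell.
Ordering the cells by pseudotime gives per-marker single-cell trajectories,
smoothed by a sliding-window mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linprog
from scipy.stats import linregress

from .data import PHASES, DataError, ExpressionMatrix
from .phases import PhaseAssignment

__all__ = [
    "ADJACENT_PAIRS",
    "OrderingLP",
    "EmbeddingWeights",
    "Trajectory",
    "build_ordering_lp",
    "ordering_objective",
    "solve_lp",
    "solve_ordering_lp",
    "embed",
    "mean_trajectory",
    "default_window",
    "validate_trajectories",
]

#: Adjacent phase pairs contributing ordering constraints, in cycle order.
ADJACENT_PAIRS = tuple(zip(PHASES[:-1], PHASES[1:]))


@dataclass
class OrderingLP:
    """An ordering LP instance in difference form.

    ``diffs[k] = y_q - y_p`` for the k-th adjacent-phase cell pair;
    ``pair_weights[k]`` is the slack weight of that pair.
    """

    diffs: np.ndarray  # (n_pairs, 4)
    pair_weights: np.ndarray  # (n_pairs,)
    margin: float
    pairs_per_class: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def n_constraints(self) -> int:
        return self.diffs.shape[0]


@dataclass
class EmbeddingWeights:
    """Solved embedding coefficients alpha with LP diagnostics."""

    alpha: np.ndarray  # simplex 4-vector
    margin: float
    total_slack: float
    n_constraints: int
    subsample_fraction: float = 1.0

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (4,) or np.any(self.alpha < -1e-9):
            raise DataError("alpha must be a non-negative 4-vector")
        total = self.alpha.sum()
        if not total > 0:
            raise DataError("alpha must not be identically zero")
        self.alpha = np.clip(self.alpha, 0.0, None) / np.clip(self.alpha, 0.0, None).sum()


@dataclass
class Trajectory:
    """Per-cell pseudotime and the induced cell ordering.

    ``pseudotime`` is aligned with the input rows and rescaled to [0, 1];
    ``order`` is the permutation of row positions sorting pseudotime
    non-decreasingly with ties broken by ascending cell id, so the output is
    deterministic and invariant to the input's original row order.
    """

    pseudotime: np.ndarray
    order: np.ndarray
    cell_ids: np.ndarray
    weights: EmbeddingWeights | None = None


def build_ordering_lp(
    X: np.ndarray,
    assignment: PhaseAssignment,
    margin: float = 0.01,
    weights_scheme: str = "balanced",
) -> OrderingLP:
    """Assemble ordering constraints between all adjacent-phase cell pairs.

    ``weights_scheme='balanced'`` weights each pair by the reciprocal of its
    class pair's pair count, so each adjacent-phase boundary contributes
    equally to the objective despite order-of-magnitude phase imbalance
    (the mitotic class is only a few percent of cells); ``'uniform'`` weights
    every pair 1.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 4:
        raise DataError("ordering LP expects an n x 4 marker table")
    labels = assignment.labels
    present = [p for p in PHASES if np.any(labels == p)]
    if len(present) < 2:
        raise DataError("ordering LP needs cells in at least two phases")
    if weights_scheme not in {"balanced", "uniform"}:
        raise DataError(f"unknown weights_scheme {weights_scheme!r}")
    blocks, weight_blocks = [], []
    pairs_per_class: dict[tuple[str, str], int] = {}
    for p, q in ADJACENT_PAIRS:
        lo = X[labels == p]
        hi = X[labels == q]
        n_pairs = lo.shape[0] * hi.shape[0]
        pairs_per_class[(p, q)] = n_pairs
        if n_pairs == 0:
            continue
        # all (i_p, i_q) differences: hi broadcast against lo
        diff = (hi[None, :, :] - lo[:, None, :]).reshape(n_pairs, 4)
        blocks.append(diff)
        w = 1.0 / n_pairs if weights_scheme == "balanced" else 1.0
        weight_blocks.append(np.full(n_pairs, w))
    if not blocks:
        raise DataError("no adjacent-phase pairs available for ordering constraints")
    return OrderingLP(
        np.vstack(blocks), np.concatenate(weight_blocks), float(margin), pairs_per_class
    )


def ordering_objective(instance: OrderingLP, alpha: np.ndarray) -> float:
    """Closed-form weighted slack of a candidate alpha.

    For fixed alpha the optimal slack of each constraint is
    ``max(0, margin - alpha . diff)``; this evaluates the LP objective
    without solving anything.
    """
    alpha = np.asarray(alpha, dtype=float)
    viol = np.clip(instance.margin - instance.diffs @ alpha, 0.0, None)
    return float(instance.pair_weights @ viol)


def solve_lp(instance: OrderingLP) -> tuple[np.ndarray, float]:
    """Solve the ordering LP exactly; returns (alpha, total weighted slack).

    Feasibility is guaranteed by construction (slacks absorb any violation),
    so solver failure indicates a numerical problem and is surfaced.
    """
    n_pairs = instance.n_constraints
    c = np.concatenate([np.zeros(4), instance.pair_weights])
    # alpha . d + xi >= margin   <=>   -d . alpha - xi <= -margin
    A_ub = sp.hstack(
        [sp.csr_matrix(-instance.diffs), -sp.identity(n_pairs, format="csr")],
        format="csr",
    )
    b_ub = np.full(n_pairs, -instance.margin)
    A_eq = sp.csr_matrix(
        (np.ones(4), (np.zeros(4, dtype=int), np.arange(4))), shape=(1, 4 + n_pairs)
    )
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=[1.0], method="highs")
    if not res.success:
        raise DataError(f"ordering LP solver failed: {res.message}")
    alpha = np.clip(res.x[:4], 0.0, None)
    return alpha, float(res.fun)


def _stratified_subsample(
    labels: np.ndarray, fraction: float, seed, min_per_phase: int = 50
) -> np.ndarray:
    if not 0 < fraction <= 1:
        raise DataError("subsample_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for phase in PHASES:
        idx = np.where(labels == phase)[0]
        if idx.size == 0:
            continue
        k = min(idx.size, max(int(np.ceil(fraction * idx.size)), min_per_phase))
        keep.append(np.sort(rng.choice(idx, size=k, replace=False)))
    return np.concatenate(keep)


def solve_ordering_lp(
    X: np.ndarray,
    assignment: PhaseAssignment,
    margin: float = 0.01,
    weights_scheme: str = "balanced",
    subsample_fraction: float = 0.1,
    seed: int | None = 0,
    min_per_phase: int = 50,
) -> EmbeddingWeights:
    """Estimate alpha on a per-phase stratified random subsample.

    Each phase contributes ``max(ceil(fraction * n_phase), min_per_phase)``
    cells (all of them if fewer), drawn without replacement under the given
    seed.  The LP scales quadratically in cells per phase, while its
    solution is robust to subsampling, so a small fraction suffices.
    """
    X = np.asarray(X, dtype=float)
    if subsample_fraction < 1.0:
        idx = _stratified_subsample(assignment.labels, subsample_fraction, seed, min_per_phase)
        instance = build_ordering_lp(X[idx], assignment.subset(idx), margin, weights_scheme)
    else:
        instance = build_ordering_lp(X, assignment, margin, weights_scheme)
    alpha, slack = solve_lp(instance)
    return EmbeddingWeights(
        alpha, margin, slack, instance.n_constraints, subsample_fraction
    )


def embed(weights: EmbeddingWeights, X: np.ndarray, cell_ids=None) -> Trajectory:
    """Project every cell onto pseudotime t_i = alpha . y_i, rescaled to [0, 1].

    Cells left out of the LP subsample are embedded too — alpha is global.
    If all projections coincide the pseudotime is all zeros (degenerate
    rescale guard).  The ordering permutation breaks ties by cell id.
    """
    X = np.asarray(X, dtype=float)
    if cell_ids is None:
        cell_ids = np.arange(X.shape[0], dtype=np.int64)
    cell_ids = np.asarray(cell_ids, dtype=np.int64)
    t = X @ weights.alpha
    span = t.max() - t.min()
    t = (t - t.min()) / span if span > 0 else np.zeros_like(t)
    order = np.lexsort((cell_ids, t))
    return Trajectory(t, order, cell_ids, weights)


def default_window(n: int) -> int:
    """Default sliding-window width: ~1% of cells, at least 51, forced odd."""
    w = max(51, int(round(n / 100)))
    if w > n:
        w = n
    if w % 2 == 0:
        w = w - 1 if w > 1 else 1
    return w


def _sliding_mean(ordered: np.ndarray, window: int) -> np.ndarray:
    if window == 1:
        return ordered.copy()
    n = ordered.shape[0]
    half = window // 2
    cs = np.concatenate([np.zeros((1,) + ordered.shape[1:]), np.cumsum(ordered, axis=0)])
    k = np.arange(n)
    lo = np.clip(k - half, 0, n - 1)
    hi = np.clip(k + half, 0, n - 1)
    return (cs[hi + 1] - cs[lo]) / (hi - lo + 1)[:, None]


def mean_trajectory(
    traj: Trajectory,
    matrix: ExpressionMatrix,
    window: int | None = None,
    channels: list[str] | None = None,
) -> pd.DataFrame:
    """Sliding-window mean of each marker along the pseudotime order.

    Each cell's value is replaced by the mean of its window of neighbours in
    the ordering (the window shrinks symmetrically at the edges).  Returns a
    table indexed by order position with cell id, pseudotime and one column
    per marker, ready for export.
    """
    n = matrix.n_cells
    if not np.array_equal(traj.cell_ids, matrix.cell_ids):
        raise DataError("trajectory and matrix cover different cells")
    if window is None:
        window = default_window(n)
    if window < 1 or window > n:
        raise DataError(f"window must be in [1, {n}], got {window}")
    names = list(channels) if channels is not None else list(matrix.channels)
    cols = matrix.column_index(names)
    ordered = matrix.values[traj.order][:, cols]
    smoothed = _sliding_mean(ordered, window)
    out = pd.DataFrame(smoothed, columns=names)
    out.insert(0, "pseudotime", traj.pseudotime[traj.order])
    out.insert(0, "cell_id", traj.cell_ids[traj.order])
    out.index.name = "order_position"
    return out


def validate_trajectories(
    traj: Trajectory,
    matrix: ExpressionMatrix,
    holdout_markers: list[str],
    assignment: PhaseAssignment,
    window: int | None = None,
    trend_p: float = 0.01,
) -> pd.DataFrame:
    """Shape report for held-out markers that did not inform the embedding.

    For each marker: the pseudotime at which its smoothed trajectory peaks,
    and the signed trend (slope sign, 0 when not significant at ``trend_p``
    by a per-segment linear regression on the raw ordered values) within
    each phase segment of the ordering.  Independent markers with known
    peak positions (e.g. a cyclin E-like marker peaking at the G1/S
    transition) validate the reconstructed ordering.
    """
    smooth = mean_trajectory(traj, matrix, window, holdout_markers)
    phase_in_order = assignment.labels[traj.order]
    positions = np.arange(matrix.n_cells)
    rows = []
    for marker in holdout_markers:
        curve = smooth[marker].to_numpy()
        argmax_pos = int(np.argmax(curve))
        row: dict = {
            "marker": marker,
            "argmax_position": argmax_pos,
            "argmax_pseudotime": float(smooth["pseudotime"].iloc[argmax_pos]),
            "argmax_phase": phase_in_order[argmax_pos],
        }
        raw_ordered = matrix.values[traj.order, matrix.column_index([marker])[0]]
        for phase in PHASES:
            mask = phase_in_order == phase
            if mask.sum() < 3:
                row[f"trend_{phase}"] = 0
                continue
            fit = linregress(positions[mask], raw_ordered[mask])
            row[f"trend_{phase}"] = int(np.sign(fit.slope)) if fit.pvalue < trend_p else 0
        rows.append(row)
    return pd.DataFrame(rows).set_index("marker")
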
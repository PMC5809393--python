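"""Diagnostics quantifying how much confounding the corrections removed.

Three complementary views:

* per-channel coefficients of variation — volume correction should shrink
  the spread of any marker whose concentration is roughly constant;
* pairwise marker associations (Pearson and Spearman) — volume-driven
  marker-marker relationships should weaken after correction;
* a PCA confounding check — principal components of the functional-marker
  submatrix are regressed on the cell-cycle phase index (1-4) and on the
  experimental condition; the variance explained (R^2) per component shows
  whether cell cycle, rather than condition, dominates the leading
  components, and whether cycle correction eliminated that.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr
from sklearn.decomposition import PCA

from .data import DataError, ExpressionMatrix
from .pseudotime import Trajectory, mean_trajectory

__all__ = [
    "coefficient_of_variation",
    "association_report",
    "pca_confounding_r2",
    "variance_explained_by_pseudotime",
]


def coefficient_of_variation(
    matrix: ExpressionMatrix, channels: list[str] | None = None
) -> pd.Series:
    """CV_j = sd_j / mean_j per channel (sample sd, ddof=1).

    Requires strictly positive channel means.
    """
    names = list(channels) if channels is not None else list(matrix.channels)
    cols = matrix.column_index(names)
    sub = matrix.values[:, cols]
    means = sub.mean(axis=0)
    if np.any(means <= 0):
        bad = [n for n, m in zip(names, means) if m <= 0]
        raise DataError(f"non-positive mean for channels {bad}; CV undefined")
    return pd.Series(sub.std(axis=0, ddof=1) / means, index=names, name="cv")


def association_report(
    matrix: ExpressionMatrix, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Pearson and Spearman coefficients for the requested channel pairs."""
    if matrix.n_cells < 3:
        raise DataError("association report needs at least 3 cells")
    rows = []
    for a, b in pairs:
        x = matrix.column(a)
        y = matrix.column(b)
        rows.append(
            {
                "channel_a": a,
                "channel_b": b,
                "pearson": pearsonr(x, y).statistic,
                "spearman": spearmanr(x, y).statistic,
                "n": matrix.n_cells,
            }
        )
    return pd.DataFrame(rows)


def _r2_single_regressor(x: np.ndarray, y: np.ndarray) -> float:
    x = np.column_stack([np.ones_like(x, dtype=float), x])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    total = ((y - y.mean()) ** 2).sum()
    if total == 0:
        return 0.0
    return float(1.0 - (resid**2).sum() / total)


def _r2_onehot(codes: np.ndarray, y: np.ndarray) -> float:
    groups = np.unique(codes)
    fitted = np.empty_like(y, dtype=float)
    for g in groups:
        fitted[codes == g] = y[codes == g].mean()
    total = ((y - y.mean()) ** 2).sum()
    if total == 0:
        return 0.0
    return float(1.0 - ((y - fitted) ** 2).sum() / total)


def pca_confounding_r2(
    matrix: ExpressionMatrix,
    phase_codes: np.ndarray,
    condition: np.ndarray,
    functional_channels: list[str],
    n_components: int = 5,
    coding: str = "numeric",
) -> pd.DataFrame:
    """Variance of each principal component explained by phase and condition.

    PCA is computed on the functional-marker submatrix (cell-cycle and
    volume channels excluded), centred and unit-scaled.  Each component's
    scores are then regressed on (a) the cell-cycle phase index coded 1-4 as
    a single numeric regressor (``coding='numeric'``, default; a one-hot
    group-means fit is available with ``coding='onehot'``) and (b) the
    condition indicator.  Returns one row per component with columns
    ``r2_phase``, ``r2_condition`` and ``explained_variance_ratio``.
    """
    phase_codes = np.asarray(phase_codes, dtype=float)
    condition = np.asarray(condition, dtype=float)
    if np.unique(phase_codes).size < 2 or np.unique(condition).size < 2:
        raise DataError("need >= 2 distinct phase codes and >= 2 condition values")
    cols = matrix.column_index(functional_channels)
    sub = matrix.values[:, cols]
    if matrix.n_cells < n_components:
        raise DataError("fewer cells than requested components")
    sds = sub.std(axis=0, ddof=1)
    if np.any(sds == 0):
        raise DataError("constant functional channel; cannot unit-scale for PCA")
    scaled = (sub - sub.mean(axis=0)) / sds
    n_components = min(n_components, len(functional_channels))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(scaled)
    rows = []
    for k in range(n_components):
        y = scores[:, k]
        if coding == "numeric":
            r2p = _r2_single_regressor(phase_codes, y)
        elif coding == "onehot":
            r2p = _r2_onehot(phase_codes, y)
        else:
            raise DataError(f"unknown coding {coding!r}")
        rows.append(
            {
                "component": k + 1,
                "r2_phase": r2p,
                "r2_condition": _r2_single_regressor(condition, y),
                "explained_variance_ratio": float(pca.explained_variance_ratio_[k]),
            }
        )
    return pd.DataFrame(rows).set_index("component")


def variance_explained_by_pseudotime(
    matrix: ExpressionMatrix,
    traj: Trajectory,
    channel: str,
    window: int | None = None,
) -> float:
    """R^2 of a marker against its own sliding-window mean trajectory.

    Measures how much of the marker's single-cell variance is attributable
    to cell-cycle pseudotime: the smoothed trajectory serves as a
    nonparametric regression of the marker on pseudotime.  After cycle
    correction this should collapse toward zero.
    """
    smooth = mean_trajectory(traj, matrix, window, [channel])
    y = matrix.values[traj.order, matrix.column_index([channel])[0]]
    return max(0.0, _r2_single_regressor(smooth[channel].to_numpy(), y))
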
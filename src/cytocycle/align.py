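"""Multi-sample phase-proportion alignment and cell-cycle correction.

Different samples (cell lines, stimulation time points) spend different
fractions of time in each cell-cycle phase, so naive pooled comparisons mix
phase-composition differences into every marker.  Alignment equalizes the
phase proportions across samples by stratified subsampling — never by
fabricating cells — against either the mean proportion vector or a
user-chosen reference sample.

Cycle correction then removes cell-cycle-driven variation within a sample:
for each marker, its sliding-window mean trajectory is rescaled around 1 by
dividing by the marker's overall mean, and each cell's value is divided by
the rescaled mean at its position in the ordering.  A marker whose mean
trajectory is flat is left unchanged; a strongly cycle-modulated marker has
its modulation divided out while its overall mean is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import PHASES, DataError, DegenerateChannelError, ExpressionMatrix, Stage
from .phases import PhaseAssignment
from .pseudotime import Trajectory, mean_trajectory

__all__ = [
    "Sample",
    "compute_target_proportions",
    "align_samples",
    "correct_cycle",
]

#: Floor applied to the rescaled mean trajectory before dividing, so markers
#: that genuinely vanish over part of the cycle (IdU outside S) do not blow
#: up the corrected values.  Binding events are counted in the report.
DEFAULT_DIVISOR_FLOOR = 0.05


@dataclass
class Sample:
    """One sample's matrix with its phase assignment (and trajectory, if computed)."""

    name: str
    matrix: ExpressionMatrix
    assignment: PhaseAssignment
    trajectory: Trajectory | None = None

    def __post_init__(self):
        if not np.array_equal(self.matrix.cell_ids, self.assignment.cell_ids):
            raise DataError(f"sample {self.name!r}: matrix/assignment cell id mismatch")

    def proportions(self) -> np.ndarray:
        return self.assignment.proportions()


def compute_target_proportions(
    samples: list[Sample], mode: str = "mean", reference: str | None = None
) -> np.ndarray:
    """Target phase-proportion vector for alignment.

    ``mode='mean'`` averages the per-sample proportion vectors (renormalized);
    ``mode='reference'`` uses one named sample's proportions verbatim.
    """
    if not samples:
        raise DataError("no samples given")
    if mode == "mean":
        target = np.mean([s.proportions() for s in samples], axis=0)
        return target / target.sum()
    if mode == "reference":
        if reference is None:
            raise DataError("mode='reference' requires a reference sample name")
        for s in samples:
            if s.name == reference:
                return s.proportions()
        raise DataError(f"reference sample {reference!r} not found")
    raise DataError(f"unknown alignment mode {mode!r}")


@dataclass
class AlignmentReport:
    """Kept/discarded cell counts per phase per sample."""

    target: np.ndarray
    kept: pd.DataFrame
    discarded: pd.DataFrame
    warnings: list[str] = field(default_factory=list)


def align_samples(
    samples: list[Sample], target: np.ndarray, seed: int | None = 0
) -> tuple[list[Sample], AlignmentReport]:
    """Subsample every sample to the target phase proportions.

    Each sample keeps the largest subset (drawn without replacement,
    stratified by phase) whose proportions match the target within one cell
    per phase: the binding phase determines the total size
    ``N = min_p floor(count_p / target_p)`` and phase ``p`` keeps
    ``floor(target_p * N)`` cells.  Samples missing a phase with positive
    target are aligned as well as possible with that phase at zero, and a
    warning is recorded.  Cell ids are preserved, so outputs are verifiable
    subsets of inputs.
    """
    target = np.asarray(target, dtype=float)
    if target.shape != (len(PHASES),) or np.any(target < 0):
        raise DataError("target must be a non-negative 4-vector")
    if not np.isclose(target.sum(), 1.0):
        raise DataError("target proportions must sum to 1")
    rng = np.random.default_rng(seed)
    aligned: list[Sample] = []
    kept_rows, disc_rows, warns = [], [], []
    for sample in samples:
        labels = sample.assignment.labels
        counts = np.asarray([(labels == p).sum() for p in PHASES])
        usable = target > 0
        empty = usable & (counts == 0)
        if empty.any():
            missing = [p for p, e in zip(PHASES, empty) if e]
            warns.append(
                f"sample {sample.name!r} has no cells in {missing}; "
                "aligned with those phases at zero"
            )
            usable &= counts > 0
        n_total = int(np.floor((counts[usable] / target[usable]).min()))
        quota = np.where(usable, target * n_total, 0.0)
        # largest-remainder apportionment: sum of kept counts equals n_total
        # (restricted to usable phases) and each count is within 1 of quota
        base = np.floor(quota).astype(int)
        short = int(round(quota.sum())) - base.sum()
        if short > 0:
            order = np.argsort(-(quota - base))
            base[order[:short]] += 1
        keep_idx: list[np.ndarray] = []
        kept_counts = {}
        for k, phase in enumerate(PHASES):
            n_keep = min(int(base[k]), int(counts[k]))
            idx = np.where(labels == phase)[0]
            chosen = np.sort(rng.choice(idx, size=n_keep, replace=False))
            keep_idx.append(chosen)
            kept_counts[phase] = n_keep
        keep = np.sort(np.concatenate(keep_idx))
        aligned.append(
            Sample(
                sample.name,
                sample.matrix.subset(keep),
                sample.assignment.subset(keep),
            )
        )
        kept_rows.append({"sample": sample.name, **kept_counts})
        disc_rows.append(
            {
                "sample": sample.name,
                **{p: int(c) - kept_counts[p] for p, c in zip(PHASES, counts)},
            }
        )
    report = AlignmentReport(
        target,
        pd.DataFrame(kept_rows).set_index("sample"),
        pd.DataFrame(disc_rows).set_index("sample"),
        warns,
    )
    return aligned, report


def correct_cycle(
    matrix: ExpressionMatrix,
    traj: Trajectory,
    channels: list[str],
    window: int | None = None,
    divisor_floor: float = DEFAULT_DIVISOR_FLOOR,
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Divide each marker by its rescaled mean trajectory.

    For marker ``j`` at order position ``k``::

        corrected = y[k, j] / max(floor, mean_traj[k, j] / mean_j)

    where ``mean_j`` is the marker's grand mean, so the rescaled trajectory
    fluctuates around 1 and the correction preserves the marker's overall
    level while flattening its dependence on cell-cycle position.  Values
    are returned in the original cell order.  The four cell-cycle marker
    channels should normally be excluded (flattening them would destroy the
    information phases are derived from); the caller chooses ``channels``.
    Returns the corrected matrix and the per-channel count of positions
    where the divisor floor was binding.
    """
    if not channels:
        raise DataError("no channels selected for cycle correction")
    smooth = mean_trajectory(traj, matrix, window, list(channels))
    values = matrix.values.copy()
    floor_counts: dict[str, int] = {}
    inverse = np.empty(matrix.n_cells, dtype=int)
    inverse[traj.order] = np.arange(matrix.n_cells)
    for name in channels:
        j = matrix.column_index([name])[0]
        mean_j = matrix.values[:, j].mean()
        if mean_j <= 0:
            raise DegenerateChannelError(
                f"channel {name!r} has non-positive mean; cannot rescale trajectory"
            )
        rescaled = smooth[name].to_numpy() / mean_j
        binding = rescaled < divisor_floor
        floor_counts[name] = int(binding.sum())
        divisor = np.maximum(rescaled, divisor_floor)
        values[:, j] = matrix.values[:, j] / divisor[inverse]
    return matrix.with_values(values, Stage.CYCLE_CORRECTED), floor_counts
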
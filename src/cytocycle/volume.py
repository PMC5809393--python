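"""Cell-volume normalization and asinh transform.

Larger cells contain more of every protein, so raw ion counts confound
abundance with cell size.  A total-protein stain (e.g. an amine-reactive
ruthenium complex read out on several Ru isotope channels) gives a per-cell
volume proxy.  Each volume channel is first normalized to its population
mean,

    y_norm[i, v] = y[i, v] / mean_i(y[i, v]),

and every channel of every cell is then divided by that cell's mean
normalized volume signal,

    y_corr[i, j] = y[i, j] / ((1/l) * sum_v y_norm[i, v]),

turning counts into relative concentrations.  Because the divisor is a pure
per-cell factor, multiplying a cell's entire row by any constant leaves its
corrected values unchanged.  Zeros are substituted by the channel mean first
so the divisor is always positive.  Finally selected channels go through the
asinh(x / cofactor) transform (cofactor 5 by convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import (
    ChannelMap,
    DataError,
    DegenerateChannelError,
    ExpressionMatrix,
    Stage,
    TransformParams,
)

__all__ = [
    "substitute_zeros",
    "normalize_volume_channels",
    "correct_volume",
    "asinh_transform",
    "volume_pipeline",
]


def substitute_zeros(
    matrix: ExpressionMatrix, channels: list[str] | None = None
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Replace zero entries with their channel mean (taken over all cells).

    Returns the new matrix and a per-channel count of substitutions.  The
    channel mean includes the zeros themselves.  A channel that is zero in
    every cell has no meaningful mean and raises
    :class:`DegenerateChannelError`.

    ``channels`` restricts the substitution; the pipeline applies it to the
    volume channels only, where a zero would break the per-cell divisor.
    Zeros in ordinary marker channels are legitimate measurements (a low
    marker's ion count frequently is zero) and substituting them with the
    channel mean would move those cells to the middle of the distribution.
    """
    values = matrix.values.copy()
    counts: dict[str, int] = {}
    means = values.mean(axis=0)
    selected = set(channels) if channels is not None else None
    for j, name in enumerate(matrix.channels):
        if selected is not None and name not in selected:
            continue
        zero = values[:, j] == 0.0
        n_zero = int(zero.sum())
        if n_zero == matrix.n_cells:
            raise DegenerateChannelError(f"channel {name!r} is identically zero")
        if n_zero:
            values[zero, j] = means[j]
        counts[name] = n_zero
    return ExpressionMatrix(values, matrix.channels, matrix.stage, matrix.cell_ids.copy()), counts


def normalize_volume_channels(matrix: ExpressionMatrix, channel_map: ChannelMap) -> np.ndarray:
    """Normalize each volume channel to unit population mean.

    Returns the ``n x l`` table ``y_norm[i, v] = y[i, v] / mean_i(y[i, v])``;
    every column has mean exactly 1 up to floating error.
    """
    if not channel_map.volume_channels:
        raise DataError("volume correction requested but no volume channels configured")
    cols = matrix.column_index(channel_map.volume_channels)
    sub = matrix.values[:, cols]
    means = sub.mean(axis=0)
    for name, mu in zip(channel_map.volume_channels, means):
        if mu <= 0:
            raise DegenerateChannelError(
                f"volume channel {name!r} has non-positive mean {mu}"
            )
    return sub / means


def correct_volume(
    matrix: ExpressionMatrix, channel_map: ChannelMap
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Divide every channel of every cell by the cell's mean normalized volume.

    All ``m`` channels are corrected, including the volume channels
    themselves (whose corrected values collapse toward their means — a useful
    diagnostic).  Returns the corrected matrix and the per-cell divisors.
    Zeros must have been substituted beforehand; a non-positive divisor
    raises :class:`DataError` naming the offending cell id.
    """
    matrix.require_stage(Stage.RAW)
    y_norm = normalize_volume_channels(matrix, channel_map)
    divisor = y_norm.mean(axis=1)
    bad = np.where(divisor <= 0)[0]
    if bad.size:
        raise DataError(
            f"non-positive volume divisor for cell ids {matrix.cell_ids[bad[:5]].tolist()}"
            " — substitute zeros before correcting"
        )
    corrected = matrix.values / divisor[:, None]
    return matrix.with_values(corrected, Stage.VOLUME_CORRECTED), divisor


def asinh_transform(
    matrix: ExpressionMatrix,
    channel_map: ChannelMap,
    params: TransformParams = TransformParams(),
) -> ExpressionMatrix:
    """Apply asinh(x / cofactor) to selected channels.

    By default all non-volume channels are transformed (the volume channels
    have served their purpose once the correction is applied); pass
    ``params.channels_to_transform`` to override.  The transform is strictly
    increasing, 0 maps to 0, and it compresses values beyond roughly the
    cofactor logarithmically.
    """
    matrix.require_stage(Stage.VOLUME_CORRECTED, Stage.RAW)
    if params.channels_to_transform is None:
        selected = [c for c in matrix.channels if c not in channel_map.volume_channels]
    else:
        selected = list(params.channels_to_transform)
    cols = matrix.column_index(selected)
    values = matrix.values.copy()
    values[:, cols] = np.arcsinh(values[:, cols] / params.cofactor)
    return matrix.with_values(values, Stage.TRANSFORMED)


@dataclass
class VolumeReport:
    """Log of what the volume stage did to a sample."""

    zero_substitutions: dict[str, int]
    divisors: np.ndarray


def volume_pipeline(
    matrix: ExpressionMatrix,
    channel_map: ChannelMap,
    params: TransformParams = TransformParams(),
) -> tuple[ExpressionMatrix, VolumeReport]:
    """substitute_zeros (volume channels) -> correct_volume -> asinh_transform."""
    matrix, counts = substitute_zeros(matrix, list(channel_map.volume_channels))
    matrix, divisors = correct_volume(matrix, channel_map)
    matrix = asinh_transform(matrix, channel_map, params)
    return matrix, VolumeReport(counts, divisors)
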
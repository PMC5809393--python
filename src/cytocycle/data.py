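"""Core in-memory containers shared by every pipeline stage.

A mass cytometry run is an ``n cells x m channels`` table of non-negative ion
counts.  :class:`ExpressionMatrix` carries that table together with stable
per-cell identifiers and a *stage* tag recording how far along the pipeline
the values are.  :class:`ChannelMap` binds raw FCS channel names to semantic
roles: total-protein (volume) stain channels, the four canonical cell-cycle
markers, functional readouts, and channels to drop.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Stage",
    "CELL_CYCLE_ROLES",
    "PHASES",
    "PHASE_CODES",
    "ChannelMap",
    "ExpressionMatrix",
    "TransformParams",
    "ConfigurationError",
    "DataError",
    "DegenerateChannelError",
]

#: Canonical role keys for the four cell-cycle markers, in pipeline order.
CELL_CYCLE_ROLES = ("IdU", "cyclinB1", "pHH3", "pRB")

#: Ordered cell-cycle phases; the ordering G0/G1 < S < G2 < M is fixed.
PHASES = ("G0/G1", "S", "G2", "M")

#: Integer codes used when exporting phase labels into an FCS parameter.
PHASE_CODES = {phase: i + 1 for i, phase in enumerate(PHASES)}


class ConfigurationError(ValueError):
    """A channel map or config references something that does not exist."""


class DataError(ValueError):
    """Input values violate an operation's precondition."""


class DegenerateChannelError(DataError):
    """A channel is constant/zero where the operation needs variation."""


class Stage(enum.Enum):
    """Pipeline stage of an :class:`ExpressionMatrix`, in processing order."""

    RAW = "raw"
    VOLUME_CORRECTED = "volume_corrected"
    TRANSFORMED = "transformed"
    STANDARDIZED = "standardized"
    CYCLE_CORRECTED = "cycle_corrected"

    @property
    def order(self) -> int:
        return _STAGE_ORDER[self]


_STAGE_ORDER = {s: i for i, s in enumerate(Stage)}


@dataclass(frozen=True)
class ChannelMap:
    """Assignment of FCS channels to semantic roles.

    Parameters
    ----------
    volume_channels
        Channels carrying total-protein (cell-volume proxy) signal, e.g. the
        ruthenium isotope channels of an amine-reactive total-protein stain.
    cellcycle_channels
        Mapping from the four role keys ``IdU, cyclinB1, pHH3, pRB`` to the
        channel names bound to them.  Each role must be bound to exactly one
        distinct channel.
    functional_channels
        Any other channels carried through the pipeline.
    excluded_channels
        Channels dropped at read time (DNA intercalators, barcodes, beads,
        event length, time, ...).
    """

    volume_channels: tuple[str, ...] = ()
    cellcycle_channels: Mapping[str, str] = field(default_factory=dict)
    functional_channels: tuple[str, ...] = ()
    excluded_channels: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "volume_channels", tuple(self.volume_channels))
        object.__setattr__(self, "functional_channels", tuple(self.functional_channels))
        object.__setattr__(self, "excluded_channels", tuple(self.excluded_channels))
        object.__setattr__(self, "cellcycle_channels", dict(self.cellcycle_channels))
        cc = self.cellcycle_channels
        if set(cc) != set(CELL_CYCLE_ROLES):
            missing = set(CELL_CYCLE_ROLES) - set(cc)
            extra = set(cc) - set(CELL_CYCLE_ROLES)
            raise ConfigurationError(
                f"cell-cycle roles must be exactly {CELL_CYCLE_ROLES}; "
                f"missing={sorted(missing)} unknown={sorted(extra)}"
            )
        if len(set(cc.values())) != 4:
            raise ConfigurationError(
                f"the four cell-cycle roles must map to distinct channels, got {cc}"
            )
        groups = [
            list(self.volume_channels),
            list(cc.values()),
            list(self.functional_channels),
            list(self.excluded_channels),
        ]
        flat = [name for g in groups for name in g]
        seen: set[str] = set()
        for name in flat:
            if name in seen:
                raise ConfigurationError(f"channel {name!r} assigned to more than one role")
            seen.add(name)

    @property
    def pipeline_channels(self) -> tuple[str, ...]:
        """Deterministic column order: volume, cell-cycle (role order), functional."""
        cc = tuple(self.cellcycle_channels[r] for r in CELL_CYCLE_ROLES)
        return self.volume_channels + cc + self.functional_channels

    @property
    def cellcycle_in_order(self) -> tuple[str, ...]:
        return tuple(self.cellcycle_channels[r] for r in CELL_CYCLE_ROLES)

    @classmethod
    def from_yaml(cls, path) -> "ChannelMap":
        """Load a channel map from a YAML file.

        Schema::

            volume: [ASCQ_102Ru, ASCQ_104Ru]
            cell_cycle: {IdU: IdU_127, cyclinB1: CycB1_166, pHH3: pHH3_175, pRB: pRB_150}
            functional: [pS6_172, pERK_167]
            excluded: [Time, Event_length, DNA1_191]
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "ChannelMap":
        if not isinstance(raw, Mapping):
            raise ConfigurationError("channel map must be a mapping")
        return cls(
            volume_channels=tuple(raw.get("volume", []) or []),
            cellcycle_channels=dict(raw.get("cell_cycle", {}) or {}),
            functional_channels=tuple(raw.get("functional", []) or []),
            excluded_channels=tuple(raw.get("excluded", []) or []),
        )

    def to_dict(self) -> dict:
        return {
            "volume": list(self.volume_channels),
            "cell_cycle": dict(self.cellcycle_channels),
            "functional": list(self.functional_channels),
            "excluded": list(self.excluded_channels),
        }


@dataclass
class ExpressionMatrix:
    """``n cells x m channels`` expression table with provenance.

    ``values[i, j]`` is the abundance of channel ``channels[j]`` in the cell
    with identifier ``cell_ids[i]``.  Cell ids are stable: every per-cell
    transformation and every subsampling preserves them, so subsets always
    reference the original cells.
    """

    values: np.ndarray
    channels: tuple[str, ...]
    stage: Stage = Stage.RAW
    cell_ids: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D array")
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise DataError("matrix must have at least one cell and one channel")
        self.channels = tuple(self.channels)
        if len(self.channels) != m:
            raise DataError(
                f"{len(self.channels)} channel names for {m} columns"
            )
        if len(set(self.channels)) != m:
            raise DataError("channel names must be unique")
        if self.cell_ids is None:
            self.cell_ids = np.arange(n, dtype=np.int64)
        else:
            self.cell_ids = np.asarray(self.cell_ids, dtype=np.int64)
            if self.cell_ids.shape != (n,):
                raise DataError("cell_ids length must equal the number of cells")
        if self.stage is Stage.RAW and np.any(self.values < 0):
            raise DataError("raw-stage values must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def column_index(self, names: Iterable[str]) -> np.ndarray:
        idx = []
        for name in names:
            if name not in self.channels:
                raise ConfigurationError(f"channel {name!r} not in matrix")
            idx.append(self.channels.index(name))
        return np.asarray(idx, dtype=int)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_index([name])[0]]

    def require_stage(self, *stages: Stage) -> None:
        if self.stage not in stages:
            wanted = " or ".join(s.value for s in stages)
            raise DataError(f"operation requires stage {wanted}, got {self.stage.value}")

    def with_values(self, values: np.ndarray, stage: Stage) -> "ExpressionMatrix":
        """New matrix with replaced values; stage must not move backwards."""
        if stage.order < self.stage.order:
            raise DataError(
                f"stage transition {self.stage.value} -> {stage.value} is not monotone"
            )
        return ExpressionMatrix(values, self.channels, stage, self.cell_ids.copy())

    def subset(self, row_mask_or_index) -> "ExpressionMatrix":
        """Row subset preserving cell ids and stage."""
        return ExpressionMatrix(
            self.values[row_mask_or_index],
            self.channels,
            self.stage,
            self.cell_ids[row_mask_or_index],
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, columns=list(self.channels),
                            index=pd.Index(self.cell_ids, name="cell_id"))


@dataclass(frozen=True)
class TransformParams:
    """Parameters of the asinh(x / cofactor) variance-stabilizing transform.

    The cofactor defaults to 5, the CyTOF community's standard scale constant:
    the transform is linear for counts well below the cofactor and logarithmic
    above it, compressing the heavy right tail of ion-count distributions.
    """

    cofactor: float = 5.0
    channels_to_transform: tuple[str, ...] | None = None  # None = all non-volume

    def __post_init__(self):
        if not self.cofactor > 0:
            raise ConfigurationError("cofactor must be positive")
        if self.channels_to_transform is not None:
            object.__setattr__(
                self, "channels_to_transform", tuple(self.channels_to_transform)
            )
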
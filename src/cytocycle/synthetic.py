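"""Synthetic CyTOF-like single-cell populations with known ground truth.

Every cell carries a latent cell-cycle position ``u in [0, 1]``; the phase
label (G0/G1, S, G2, M) is the segment of ``u`` under the cumulative phase
proportions, which default to 55/25/15/5% — G0/G1 dominant, mitosis rare,
matching typical cultured-line compositions.  Marker *concentrations* are
deterministic shapes of ``u`` plus Gaussian noise on the asinh scale (so
noise is multiplicative-ish on the linear scale, as in real ion-count
data), and the *raw count* of every channel is the concentration times a
per-cell lognormal volume factor — the same factor for all channels of a
cell, exactly the confounding structure total-protein normalization is
meant to remove.  Volume factors are normalized to unit sample mean, making
"concentration" well defined relative to the population.

Cell-cycle marker shapes (piecewise linear in ``u``, asinh scale):

* IdU — near zero everywhere except a high S-phase plateau (sharply
  bimodal: DNA-synthesizing cells incorporate the analogue, others do not);
* cyclin B1 — low through G1, climbing from late S through G2, peaking in
  early M, then dropping steeply as it is degraded at anaphase;
* p-HH3 — flat and low until a slight late-G2 rise, then a mitotic spike;
* p-RB — monotone increase from mid-G1 through M.

Two held-out validation markers with known peak positions are included by
default: a cyclin E-like shape peaking exactly at the G1/S boundary and a
p-CDK1(Tyr15)-like shape peaking at the G2/M boundary.  Functional markers
are configurable (baseline, cycle-modulation amplitude and shape, condition
effect, noise), so condition contrasts can be planted and recovered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CELL_CYCLE_ROLES, PHASES, ChannelMap, DataError, ExpressionMatrix, Stage
from . import fcs as fcs_io

__all__ = [
    "FunctionalMarkerSpec",
    "GeneratorConfig",
    "SyntheticSample",
    "generate",
    "write_fixture",
    "HOLDOUT_CHANNELS",
]

HOLDOUT_CHANNELS = ("CyclinE_like", "pCDK1_like")


@dataclass(frozen=True)
class FunctionalMarkerSpec:
    """One functional channel: concentration model and noise.

    Linear-scale concentration is
    ``baseline * (1 + amplitude * shape(u)) * (1 + condition_effect * condition)``
    with ``shape`` one of ``ramp`` (2u - 1), ``halfsine`` (sin(pi u)),
    ``fullsine`` (sin(2 pi u)) or ``flat`` (0); noise is Gaussian on the
    asinh scale with sd ``noise_sd``.
    """

    name: str
    baseline: float = 20.0
    amplitude: float = 0.0
    shape: str = "flat"
    condition_effect: float = 0.0
    noise_sd: float = 0.15

    def modulation(self, u: np.ndarray) -> np.ndarray:
        if self.shape == "ramp":
            g = 2.0 * u - 1.0
        elif self.shape == "halfsine":
            g = np.sin(np.pi * u)
        elif self.shape == "fullsine":
            g = np.sin(2.0 * np.pi * u)
        elif self.shape == "flat":
            g = np.zeros_like(u)
        else:
            raise DataError(f"unknown modulation shape {self.shape!r}")
        return 1.0 + self.amplitude * g


DEFAULT_FUNCTIONAL_SPECS = (
    FunctionalMarkerSpec("pS6", 25.0, 0.40, "ramp"),
    FunctionalMarkerSpec("pERK", 18.0, 0.40, "halfsine"),
    FunctionalMarkerSpec("pCREB", 30.0, 0.35, "ramp"),
    FunctionalMarkerSpec("pAKT", 20.0, 0.50, "fullsine"),
    FunctionalMarkerSpec("pP38", 15.0, 0.40, "ramp", condition_effect=0.3),
    FunctionalMarkerSpec("pNFkB", 22.0, 0.0, "flat"),
)


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic sample.

    Defaults: 10 000 cells, phase proportions (0.55, 0.25, 0.15, 0.05),
    lognormal volume factor with sigma 0.3, cell-cycle marker noise sd 0.2
    and functional noise sd 0.15 on the asinh scale, two total-protein
    (volume) channels, asinh cofactor 5.
    """

    n_cells: int = 10_000
    phase_proportions: tuple[float, float, float, float] = (0.55, 0.25, 0.15, 0.05)
    volume_sigma: float = 0.3
    n_volume_channels: int = 2
    volume_baseline: float = 400.0
    volume_noise_sd: float = 0.05
    cc_noise_sd: float = 0.2
    functional_markers: tuple[FunctionalMarkerSpec, ...] = DEFAULT_FUNCTIONAL_SPECS
    include_holdouts: bool = True
    holdout_noise_sd: float = 0.2
    condition: int = 0
    cofactor: float = 5.0
    seed: int = 0

    def __post_init__(self):
        props = np.asarray(self.phase_proportions, dtype=float)
        if props.shape != (4,) or np.any(props <= 0) or not np.isclose(props.sum(), 1.0):
            raise DataError("phase_proportions must be 4 positive values summing to 1")
        if self.volume_sigma < 0 or self.cc_noise_sd < 0:
            raise DataError("noise scales must be non-negative")
        if self.n_volume_channels < 1:
            raise DataError("need at least one volume channel")

    @property
    def boundaries(self) -> np.ndarray:
        """Cumulative phase boundaries (b1, b2, b3) on the u axis."""
        return np.cumsum(self.phase_proportions)[:3]


def _phase_coords(u: np.ndarray, boundaries: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map latent position u to (phase index 0-3, within-phase fraction)."""
    edges = np.concatenate([[0.0], boundaries, [1.0]])
    idx = np.clip(np.searchsorted(boundaries, u, side="right"), 0, 3)
    lo = edges[idx]
    width = edges[idx + 1] - lo
    return idx, (u - lo) / width


def _cellcycle_shapes(u: np.ndarray, boundaries: np.ndarray) -> dict[str, np.ndarray]:
    """Noise-free asinh-scale profiles of the four cell-cycle markers."""
    idx, frac = _phase_coords(u, boundaries)
    g1, s, g2, m = (idx == 0), (idx == 1), (idx == 2), (idx == 3)

    # IdU uptake switches on/off fast relative to S-phase duration, so the
    # entry/exit ramps cover only 4% of the phase each: the S population is
    # sharply bimodal against the rest, as in real IdU-pulsed data.
    idu = np.full_like(u, 0.3)
    ramp_up = np.clip(frac / 0.04, 0, 1)
    ramp_down = np.clip((frac - 0.96) / 0.04, 0, 1)
    idu[s] = 0.3 + 2.7 * (ramp_up[s] - ramp_down[s])

    cycb = np.full_like(u, 0.3)
    cycb[s] = 0.3 + 0.7 * np.clip((frac[s] - 0.6) / 0.4, 0, 1)
    cycb[g2] = 1.0 + 1.8 * frac[g2]
    rise = 2.8 + 0.4 * np.clip(frac / 0.3, 0, 1)
    fall = 2.6 * np.clip((frac - 0.3) / 0.7, 0, 1)
    cycb[m] = rise[m] - fall[m]

    phh3 = np.full_like(u, 0.3)
    phh3[g2] = 0.3 + 0.5 * np.clip((frac[g2] - 0.8) / 0.2, 0, 1)
    phh3[m] = 0.8 + 2.7 * np.clip(frac[m] / 0.15, 0, 1)

    prb = np.empty_like(u)
    prb[g1] = 0.5 + 0.8 * np.clip((frac[g1] - 0.4) / 0.6, 0, 1)
    prb[s] = 1.3 + 0.7 * frac[s]
    prb[g2] = 2.0 + 0.5 * frac[g2]
    prb[m] = 2.5 + 0.3 * frac[m]

    shapes = {"IdU": idu, "cyclinB1": cycb, "pHH3": phh3, "pRB": prb}
    # self-check of the construction the tests rely on
    order = np.argsort(u)
    if np.any(np.diff(prb[order]) < -1e-12):
        raise AssertionError("pRB profile must be non-decreasing in u")
    return shapes


def _holdout_shapes(u: np.ndarray, boundaries: np.ndarray) -> dict[str, np.ndarray]:
    idx, frac = _phase_coords(u, boundaries)
    g1, s, g2, m = (idx == 0), (idx == 1), (idx == 2), (idx == 3)

    cyce = np.full_like(u, 0.3)
    cyce[g1] = 0.3 + 2.7 * frac[g1]  # peak exactly at the G1/S boundary
    cyce[s] = 3.0 - 2.7 * frac[s]

    pcdk = np.full_like(u, 0.3)
    pcdk[s] = 0.3 + 1.2 * frac[s]
    pcdk[g2] = 1.5 + 1.5 * frac[g2]  # peak exactly at the G2/M boundary
    pcdk[m] = 3.0 - 2.7 * np.clip(frac[m] / 0.4, 0, 1)

    return {"CyclinE_like": cyce, "pCDK1_like": pcdk}


@dataclass
class SyntheticSample:
    """A generated sample: raw matrix, channel map, and full ground truth.

    ``truth`` has one row per cell: phase label, latent position ``u``,
    volume factor and condition.  ``concentrations`` holds the per-channel
    concentration values (noise included, volume factor not applied) in the
    matrix's column order.
    """

    matrix: ExpressionMatrix
    channel_map: ChannelMap
    truth: pd.DataFrame
    concentrations: np.ndarray
    config: GeneratorConfig
    n_clipped: int = 0


def generate(config: GeneratorConfig) -> SyntheticSample:
    """Draw one synthetic sample under the given conditions.

    Deterministic for a fixed seed.  With ``volume_sigma = 0`` the raw
    counts equal the concentrations exactly; with all noise sds zero the
    concentrations equal the noise-free profiles exactly.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    c = config.cofactor

    u = rng.uniform(0.0, 1.0, size=n)
    boundaries = config.boundaries
    phase_idx, _ = _phase_coords(u, boundaries)
    phase = np.asarray(PHASES, dtype=object)[phase_idx]

    if config.volume_sigma > 0:
        vol = rng.lognormal(mean=-0.5 * config.volume_sigma**2, sigma=config.volume_sigma, size=n)
        vol = vol / vol.mean()  # volume is defined relative to the population mean
    else:
        vol = np.ones(n)

    names: list[str] = []
    conc_cols: list[np.ndarray] = []

    def add(name: str, transformed_clean: np.ndarray, noise_sd: float):
        noisy = transformed_clean + (
            rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0
        )
        conc = np.sinh(noisy) * c
        names.append(name)
        conc_cols.append(conc)

    vol_trans = np.arcsinh(config.volume_baseline / c)
    volume_names = [f"ASCQ_Ru{100 + 2 * k}" for k in range(config.n_volume_channels)]
    for name in volume_names:
        add(name, np.full(n, vol_trans), config.volume_noise_sd)

    for role, profile in _cellcycle_shapes(u, boundaries).items():
        add(role, profile, config.cc_noise_sd)

    functional_names = []
    for spec in config.functional_markers:
        conc_clean = spec.baseline * spec.modulation(u)
        if spec.condition_effect and config.condition:
            conc_clean = conc_clean * (1.0 + spec.condition_effect)
        add(spec.name, np.arcsinh(conc_clean / c), spec.noise_sd)
        functional_names.append(spec.name)

    if config.include_holdouts:
        for name, profile in _holdout_shapes(u, boundaries).items():
            add(name, profile, config.holdout_noise_sd)
            functional_names.append(name)

    concentrations = np.column_stack(conc_cols)
    raw = concentrations * vol[:, None]
    n_clipped = int((raw < 0).sum())
    raw = np.clip(raw, 0.0, None)

    channel_map = ChannelMap(
        volume_channels=tuple(volume_names),
        cellcycle_channels={role: role for role in CELL_CYCLE_ROLES},
        functional_channels=tuple(functional_names),
    )
    matrix = ExpressionMatrix(raw, tuple(names), Stage.RAW)
    truth = pd.DataFrame(
        {
            "cell_id": matrix.cell_ids,
            "phase": phase,
            "u": u,
            "volume_factor": vol,
            "condition": config.condition,
        }
    ).set_index("cell_id")
    return SyntheticSample(matrix, channel_map, truth, concentrations, config, n_clipped)


def write_fixture(sample: SyntheticSample, directory) -> dict[str, Path]:
    """Write a self-contained fixture: FCS file, truth table, channel map.

    The truth table is keyed by cell id so any later stage (which preserves
    ids through subsetting) can be joined back to it.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "fcs": directory / "sample.fcs",
        "truth": directory / "truth.tsv",
        "channel_map": directory / "channel_map.yaml",
    }
    fcs_io.write_fcs(sample.matrix, paths["fcs"])
    sample.truth.to_csv(paths["truth"], sep="\t")
    import yaml

    with open(paths["channel_map"], "w") as fh:
        yaml.safe_dump(sample.channel_map.to_dict(), fh, sort_keys=False)
    return paths
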
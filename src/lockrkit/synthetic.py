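"""Synthetic data generators with known ground truth.

Every input the toolkit consumes can be generated here: two-channel
microscopy stacks of cells with a FRET-ratio step response and bright
puncta; noisy switch dose-response titrations; and MaxQuant-dialect
proteomics tables with planted enrichments and intensity-dependent
missingness.  Generators are bit-reproducible from (config, seed) and emit
the ground truth alongside the data so recovery can be scored exactly.

These are idealised stand-ins for live-cell acquisitions and LC-MS runs:
cells are ellipses with flat interiors, noise is signal-proportional
Gaussian plus an additive floor, and no optics (PSF, bleaching) or MS peak
physics is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk, ellipse as draw_ellipse

from .fret_quant import ChannelStack, RegionOfInterest
from .switch_thermo import DoseResponse, SwitchParams, Totals, signal

__all__ = [
    "MicroscopySimConfig",
    "DoseSimConfig",
    "ProteomicsSimConfig",
    "MicroscopySim",
    "DoseSim",
    "ProteomicsSim",
    "simulate_microscopy",
    "simulate_dose_response",
    "simulate_proteomics",
]


# ---------------------------------------------------------------------------
# Microscopy


@dataclass(frozen=True)
class MicroscopySimConfig:
    """Synthetic two-channel timelapse of step-responding cells.

    Cells are ellipses on a grid with per-cell donor brightness; the FRET
    channel is donor times the local true ratio (baseline, stepping by
    ``step_amplitude`` at ``stimulus_frame``; puncta multiply the ratio by
    ``puncta_ratio_multiplier``).  Noise is multiplicative Gaussian with
    coefficient of variation ``noise_cv`` plus an additive floor, and a
    constant background offset is added to every channel so background
    subtraction is exercised.
    """

    seed: int
    image_shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.3
    n_frames: int = 20
    n_cells: int = 6
    cell_axes_um: tuple[float, float] = (8.0, 6.0)
    donor_level: float = 1000.0
    baseline_ratio: float = 1.0
    step_amplitude: float = 0.10
    stimulus_frame: int = 10
    n_puncta_per_cell: int = 0
    puncta_radius_um: float = 1.0
    puncta_ratio_multiplier: float = 1.5
    noise_cv: float = 0.0
    noise_floor: float = 0.0
    background_level: float = 100.0
    acceptor_level: float = 500.0
    bright_outlier_cell: int | None = None  # index of a planted QC outlier
    bright_outlier_factor: float = 5.0

    def __post_init__(self) -> None:
        if self.noise_cv < 0 or self.noise_floor < 0:
            raise ValueError("noise parameters must be non-negative")
        if min(self.image_shape) <= 0 or self.pixel_size_um <= 0:
            raise ValueError("image geometry must be positive")
        ry = self.cell_axes_um[0] / self.pixel_size_um
        if self.n_puncta_per_cell and self.puncta_radius_um / self.pixel_size_um >= min(
            ry, self.cell_axes_um[1] / self.pixel_size_um
        ):
            raise ValueError("puncta larger than cells")


@dataclass
class MicroscopySim:
    """Stack plus ground truth from :func:`simulate_microscopy`."""

    stack: ChannelStack
    cell_rois: list[RegionOfInterest]
    background_roi: RegionOfInterest
    true_traces: pd.DataFrame  # cell_id, frame, true_ratio
    puncta_masks: dict[str, np.ndarray]
    true_acceptor: pd.Series  # per-cell mean acceptor intensity (noise-free)
    config: MicroscopySimConfig


def _cell_centers(
    cfg: MicroscopySimConfig, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Jittered grid placement keeping ellipses inside the frame, no overlap."""
    H, W = cfg.image_shape
    ry = cfg.cell_axes_um[0] / cfg.pixel_size_um
    rx = cfg.cell_axes_um[1] / cfg.pixel_size_um
    cols = int(np.ceil(np.sqrt(cfg.n_cells)))
    rows = int(np.ceil(cfg.n_cells / cols))
    if rows * 2.6 * ry > H or cols * 2.6 * rx > W:
        raise ValueError("cells do not fit the frame; enlarge image_shape")
    centers = []
    for i in range(cfg.n_cells):
        r, c = divmod(i, cols)
        cy = (r + 0.5) * H / rows
        cx = (c + 0.5) * W / cols
        cy += rng.uniform(-0.1, 0.1) * ry
        cx += rng.uniform(-0.1, 0.1) * rx
        centers.append((cy, cx))
    return centers


def simulate_microscopy(config: MicroscopySimConfig) -> MicroscopySim:
    """Generate a donor/FRET/acceptor stack with full ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.image_shape
    ry = cfg.cell_axes_um[0] / cfg.pixel_size_um
    rx = cfg.cell_axes_um[1] / cfg.pixel_size_um
    r_punct = cfg.puncta_radius_um / cfg.pixel_size_um

    donor_true = np.zeros((cfg.n_frames, H, W))
    ratio_true = np.full((cfg.n_frames, H, W), np.nan)
    acceptor_true = np.zeros((H, W))
    cell_rois: list[RegionOfInterest] = []
    puncta_masks: dict[str, np.ndarray] = {}
    truth_rows = []
    acceptor_means = {}

    step = np.where(
        np.arange(cfg.n_frames) >= cfg.stimulus_frame, cfg.step_amplitude, 0.0
    )
    for i, (cy, cx) in enumerate(_cell_centers(cfg, rng)):
        label = f"cell{i:02d}"
        rr, cc = draw_ellipse(cy, cx, ry, rx, shape=(H, W))
        mask = np.zeros((H, W), bool)
        mask[rr, cc] = True
        cell_rois.append(RegionOfInterest(label, mask, "cell"))

        pmask = np.zeros((H, W), bool)
        for j in range(cfg.n_puncta_per_cell):
            # place puncta on a ring well inside the cell, non-overlapping
            ang = 2 * np.pi * j / max(cfg.n_puncta_per_cell, 1)
            py = cy + 0.5 * ry * np.sin(ang)
            px = cx + 0.5 * rx * np.cos(ang)
            prr, pcc = draw_disk((py, px), r_punct, shape=(H, W))
            pmask[prr, pcc] = True
        puncta_masks[label] = pmask

        donor_true[:, mask] = cfg.donor_level
        cell_ratio = cfg.baseline_ratio + step  # (T,)
        ratio_true[:, mask] = cell_ratio[:, None]
        ratio_true[:, pmask] = (cell_ratio * cfg.puncta_ratio_multiplier)[:, None]
        acc = cfg.acceptor_level * (
            cfg.bright_outlier_factor if i == cfg.bright_outlier_cell else 1.0
        )
        acceptor_true[mask] = acc
        acceptor_means[label] = acc
        # ROI-mean true ratio accounts for the puncta pixels
        roi_ratio = ratio_true[:, mask].mean(axis=1)
        for t in range(cfg.n_frames):
            truth_rows.append(
                {"cell_id": label, "frame": t, "true_ratio": roi_ratio[t]}
            )

    fret_true = donor_true * np.nan_to_num(ratio_true)

    def noisy(x: np.ndarray) -> np.ndarray:
        out = x * (1.0 + cfg.noise_cv * rng.standard_normal(x.shape))
        if cfg.noise_floor > 0:
            out = out + cfg.noise_floor * rng.standard_normal(x.shape)
        return out + cfg.background_level

    channels = {
        "donor": noisy(donor_true),
        "fret": noisy(fret_true),
        "acceptor_direct": noisy(
            np.broadcast_to(acceptor_true, donor_true.shape).copy()
        ),
    }
    stack = ChannelStack(
        channels,
        pixel_size_um=cfg.pixel_size_um,
        time_index_of_stimulus=cfg.stimulus_frame,
    )
    # background ROI: the cell-free border strip
    occupied = np.zeros((H, W), bool)
    for roi in cell_rois:
        occupied |= roi.mask
    border = np.zeros((H, W), bool)
    border[:4, :] = border[-4:, :] = True
    border[:, :4] = border[:, -4:] = True
    bg = RegionOfInterest("bg", border & ~occupied, "background")
    return MicroscopySim(
        stack=stack,
        cell_rois=cell_rois,
        background_roi=bg,
        true_traces=pd.DataFrame(truth_rows),
        puncta_masks=puncta_masks,
        true_acceptor=pd.Series(acceptor_means, name="acceptor"),
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Dose response


@dataclass(frozen=True)
class DoseSimConfig:
    """Noisy replicate titrations of a known switch parameter set."""

    params: SwitchParams
    totals: Totals
    dose_grid: tuple[float, ...]
    n_replicates: int = 3
    measurement_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.measurement_cv < 0:
            raise ValueError("CV must be non-negative")


@dataclass
class DoseSim:
    doses: np.ndarray
    replicates: np.ndarray  # (n_replicates, n_doses) noisy signal
    true_signal: np.ndarray
    config: DoseSimConfig


def simulate_dose_response(config: DoseSimConfig) -> DoseSim:
    """Evaluate the switch model per dose, then apply lognormal noise.

    The multiplicative noise factor is exp(sigma*Z - sigma^2/2) with sigma
    chosen so the coefficient of variation equals ``measurement_cv``, i.e.
    unit mean.
    """
    rng = np.random.default_rng(config.seed)
    doses = np.asarray(config.dose_grid, dtype=float)
    true = np.array(
        [
            signal(config.params, replace(config.totals, T_tot=float(d)))
            for d in doses
        ]
    )
    cv = config.measurement_cv
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        factors = np.exp(
            sigma * rng.standard_normal((config.n_replicates, doses.size))
            - sigma**2 / 2.0
        )
    else:
        factors = np.ones((config.n_replicates, doses.size))
    return DoseSim(doses, true * factors, true, config)


def fit_kd_target(
    sim: DoseSim, *, log10_bounds: tuple[float, float] = (-10.0, -4.0)
) -> float:
    """Refit Kd_target from noisy titration data, all else known.

    Least squares on the replicate-mean signal over log10(Kd_target), by
    golden-section search (the 1-D objective is smooth and unimodal in the
    tested regimes).
    """
    from scipy.optimize import minimize_scalar

    mean_sig = sim.replicates.mean(axis=0)
    p, tot = sim.config.params, sim.config.totals

    def sse(log10_kd: float) -> float:
        trial = replace(p, Kd_target=10.0**log10_kd)
        pred = np.array(
            [signal(trial, replace(tot, T_tot=float(d))) for d in sim.doses]
        )
        return float(((pred - mean_sig) ** 2).sum())

    res = minimize_scalar(sse, bounds=log10_bounds, method="bounded")
    return float(10.0**res.x)


# ---------------------------------------------------------------------------
# Proteomics


@dataclass(frozen=True)
class ProteomicsSimConfig:
    """MaxQuant-dialect table with planted enrichments and MNAR censoring.

    Raw intensities are lognormal: per-protein baseline log2 means drawn
    from N(``baseline_log2_mean``, ``baseline_log2_sd``), replicate noise of
    ``replicate_log2_sd`` log2 units.  ``n_enriched`` proteins gain
    ``effect_log2`` in the first condition.  Missingness is
    intensity-dependent: cells are censored with probability
    ``sigmoid((miss_mid - x) / miss_scale)`` scaled to ``miss_max``, so low
    intensities go missing preferentially (the regime that motivates
    downshifted imputation).
    """

    seed: int
    n_proteins: int = 1000
    conditions: tuple[str, ...] = ("granule", "untargeted")
    n_replicates: int = 4
    baseline_log2_mean: float = 25.0
    baseline_log2_sd: float = 2.0
    replicate_log2_sd: float = 0.5
    n_enriched: int = 50
    effect_log2: float = 2.0
    miss_mid: float = 22.0
    miss_scale: float = 1.0
    miss_max: float = 0.0
    n_contaminants: int = 0
    n_reverse: int = 0
    n_only_by_site: int = 0

    def __post_init__(self) -> None:
        if self.n_enriched > self.n_proteins:
            raise ValueError("planted set larger than the proteome")
        if not 0 <= self.miss_max <= 1:
            raise ValueError("miss_max must be a probability")


@dataclass
class ProteomicsSim:
    table: pd.DataFrame  # MaxQuant-dialect, raw intensities with zeros
    sample_sheet: pd.DataFrame
    enriched_proteins: list[str]
    true_log2: pd.DataFrame  # pre-censoring log2 intensities
    config: ProteomicsSimConfig

    def write(self, table_path: str | Path, sheet_path: str | Path) -> None:
        self.table.to_csv(table_path, sep="\t", index=False)
        self.sample_sheet.to_csv(sheet_path, index=False)


def simulate_proteomics(config: ProteomicsSimConfig) -> ProteomicsSim:
    """Draw a protein x sample intensity table with known ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    proteins = [f"P{i:05d}" for i in range(cfg.n_proteins)]
    enriched = proteins[: cfg.n_enriched]
    samples, conditions, replicates = [], [], []
    for cond in cfg.conditions:
        for r in range(1, cfg.n_replicates + 1):
            samples.append(f"{cond}_{r}")
            conditions.append(cond)
            replicates.append(r)
    base = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_proteins)
    log2 = np.empty((cfg.n_proteins, len(samples)))
    for j, cond in enumerate(conditions):
        shift = np.where(
            np.isin(proteins, enriched) & (cond == cfg.conditions[0]),
            cfg.effect_log2,
            0.0,
        )
        log2[:, j] = base + shift + rng.normal(
            0.0, cfg.replicate_log2_sd, cfg.n_proteins
        )
    # intensity-dependent censoring
    if cfg.miss_max > 0:
        p_miss = cfg.miss_max / (1.0 + np.exp((log2 - cfg.miss_mid) / cfg.miss_scale))
        missing = rng.uniform(size=log2.shape) < p_miss
    else:
        missing = np.zeros_like(log2, dtype=bool)
    raw = np.round(2.0**log2, 1)
    raw[missing] = 0.0

    n_extra = cfg.n_contaminants + cfg.n_reverse + cfg.n_only_by_site
    table = pd.DataFrame({"Protein IDs": proteins})
    for j, s in enumerate(samples):
        table[f"Intensity {s}"] = raw[:, j]
    for flag in ("Potential contaminant", "Reverse", "Only identified by site"):
        table[flag] = ""
    if n_extra:
        extra_rows = []
        k = 0
        for flag, n in (
            ("Potential contaminant", cfg.n_contaminants),
            ("Reverse", cfg.n_reverse),
            ("Only identified by site", cfg.n_only_by_site),
        ):
            for _ in range(n):
                row = {"Protein IDs": f"FLAGGED{k:03d}"}
                for s in samples:
                    row[f"Intensity {s}"] = float(
                        np.round(2.0 ** rng.normal(cfg.baseline_log2_mean, 1.0), 1)
                    )
                for f2 in ("Potential contaminant", "Reverse", "Only identified by site"):
                    row[f2] = "+" if f2 == flag else ""
                extra_rows.append(row)
                k += 1
        table = pd.concat([table, pd.DataFrame(extra_rows)], ignore_index=True)
    sheet = pd.DataFrame(
        {"sample": samples, "condition": conditions, "replicate": replicates}
    )
    return ProteomicsSim(
        table=table,
        sample_sheet=sheet,
        enriched_proteins=enriched,
        true_log2=pd.DataFrame(log2, index=proteins, columns=samples),
        config=cfg,
    )
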
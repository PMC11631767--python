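"""Ratiometric FRET timecourse quantification for two-channel image stacks.

The pipeline mirrors standard live-cell biosensor practice: subtract the
mean intensity of a cell-free background region from every frame and
channel, compute the per-cell ratio R_t of the FRET channel to the donor
channel within each cell ROI, anchor R0 to the frame immediately preceding
stimulation, then normalise (R/R0 per cell, dataset min-max, or
reference-minimum).  A signal-to-noise ratio (maximum post-stimulus rise
over baseline standard deviation), a brightness-based QC exclusion rule
(acceptor intensity > mean + 3 s.d. of the population), and pixel-wise
pseudocolour ratio images complete the toolkit.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
from matplotlib import colormaps
from skimage.draw import polygon as draw_polygon, ellipse as draw_ellipse

__all__ = [
    "ChannelStack",
    "RegionOfInterest",
    "FRETTrace",
    "QCResult",
    "background_subtract",
    "ratio_trace",
    "normalize",
    "snr",
    "qc_exclude",
    "ratio_image",
    "read_stack_tiff",
    "write_stack_tiff",
    "rois_from_json",
    "traces_to_frame",
]

CHANNEL_ORDER = ("donor", "fret", "acceptor_direct")


@dataclass
class ChannelStack:
    """Time-ordered frames per named channel.

    ``channels`` maps channel name to a (T, Y, X) float array; all channels
    share shape and frame count.  ``time_index_of_stimulus`` is the frame at
    which the stimulus is added (R0 is taken one frame earlier).
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    time_index_of_stimulus: int = 0
    frame_interval_s: float = 1.0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {c: a.shape for c, a in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for c, a in self.channels.items():
            self.channels[c] = np.asarray(a, dtype=float)

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape[1:]


@dataclass
class RegionOfInterest:
    label: str
    mask: np.ndarray  # boolean over the frame grid
    kind: str = "cell"  # "cell" or "background"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"ROI {self.label!r} has an empty mask")
        if self.kind not in ("cell", "background"):
            raise ValueError("ROI kind must be 'cell' or 'background'")


@dataclass
class FRETTrace:
    """Per-cell ratio timecourse (raw R, basal R0, optional normalisation)."""

    label: str
    R: np.ndarray
    stim_frame: int
    condition: str = ""
    undefined: np.ndarray = field(default=None)  # type: ignore[assignment]
    normalized: np.ndarray | None = None
    normalize_mode: str | None = None

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if self.undefined is None:
            self.undefined = ~np.isfinite(self.R)
        if not 0 <= self.stim_frame <= self.R.size:
            raise ValueError("stimulus frame outside trace")

    @property
    def R0(self) -> float:
        """Basal ratio: the frame immediately preceding stimulation."""
        anchor = max(self.stim_frame - 1, 0)
        return float(self.R[anchor])


def background_subtract(stack: ChannelStack, bg_roi: RegionOfInterest) -> ChannelStack:
    """Subtract the per-frame, per-channel mean over the background ROI.

    Values may go slightly negative after subtraction; they are left as-is
    (clipping is a display concern only).
    """
    if bg_roi.kind != "background":
        raise ValueError("background_subtract requires a background-kind ROI")
    if bg_roi.mask.shape != stack.frame_shape:
        raise ValueError("background ROI shape does not match frames")
    out: dict[str, np.ndarray] = {}
    for name, arr in stack.channels.items():
        bg = arr[:, bg_roi.mask].mean(axis=1)  # (T,)
        out[name] = arr - bg[:, None, None]
    return ChannelStack(
        out,
        stack.pixel_size_um,
        stack.time_index_of_stimulus,
        stack.frame_interval_s,
    )


def ratio_trace(
    stack: ChannelStack,
    cell_roi: RegionOfInterest,
    *,
    fret_channel: str = "fret",
    donor_channel: str = "donor",
    condition: str = "",
    max_undefined_fraction: float = 0.2,
) -> FRETTrace:
    """Mean-FRET over mean-donor ratio within the ROI, per frame.

    Frames with non-positive donor mean are flagged undefined (NaN); the
    whole trace fails if more than ``max_undefined_fraction`` of frames are
    undefined.
    """
    fret = stack.channels[fret_channel][:, cell_roi.mask].mean(axis=1)
    donor = stack.channels[donor_channel][:, cell_roi.mask].mean(axis=1)
    R = np.full(stack.n_frames, np.nan)
    ok = donor > 0
    R[ok] = fret[ok] / donor[ok]
    undefined = ~ok
    if undefined.mean() > max_undefined_fraction:
        raise ValueError(
            f"trace {cell_roi.label!r}: {undefined.sum()} of {R.size} frames "
            "have non-positive donor signal"
        )
    return FRETTrace(
        label=cell_roi.label,
        R=R,
        stim_frame=stack.time_index_of_stimulus,
        condition=condition,
        undefined=undefined,
    )


def normalize(traces: Sequence[FRETTrace], mode: str) -> list[FRETTrace]:
    """Normalise a dataset of traces in place of their ``normalized`` field.

    Modes
    -----
    ``r0``
        Divide each trace by its own basal ratio R0 (the pre-stimulus
        anchor frame maps to exactly 1).
    ``minmax``
        Affinely map the pooled dataset so its lowest ratio is 0 and its
        highest is 1.
    ``ref_min``
        Subtract the pooled dataset minimum, so 0 marks the lowest ratio in
        the whole dataset (attained in the reference condition — the one
        with the largest decrease).
    """
    if not traces:
        raise ValueError("no traces to normalize")
    out: list[FRETTrace] = []
    if mode == "r0":
        for t in traces:
            r0 = t.R0
            if not (math.isfinite(r0) and r0 > 0):
                raise ValueError(f"trace {t.label!r}: basal ratio undefined")
            out.append(_with_norm(t, t.R / r0, mode))
        return out
    pooled = np.concatenate([t.R[np.isfinite(t.R)] for t in traces])
    lo, hi = pooled.min(), pooled.max()
    if mode == "minmax":
        if hi == lo:
            raise ValueError("degenerate dataset: max equals min")
        for t in traces:
            out.append(_with_norm(t, (t.R - lo) / (hi - lo), mode))
        return out
    if mode == "ref_min":
        for t in traces:
            out.append(_with_norm(t, t.R - lo, mode))
        return out
    raise ValueError(f"unknown normalization mode {mode!r}")


def _with_norm(t: FRETTrace, values: np.ndarray, mode: str) -> FRETTrace:
    return FRETTrace(
        label=t.label,
        R=t.R,
        stim_frame=t.stim_frame,
        condition=t.condition,
        undefined=t.undefined,
        normalized=values,
        normalize_mode=mode,
    )


def snr(trace: FRETTrace, baseline_window: tuple[int, int]) -> float:
    """Max post-stimulus ratio change over baseline standard deviation.

    ``baseline_window`` is a [start, stop) frame range that must lie before
    the stimulus and contain at least 3 frames.  A zero baseline s.d. is
    reported as +inf with a warning.
    """
    start, stop = baseline_window
    if stop > trace.stim_frame or stop - start < 3:
        raise ValueError("baseline window must be pre-stimulus with >= 3 frames")
    base = trace.R[start:stop]
    post = trace.R[trace.stim_frame :]
    if post.size == 0:
        raise ValueError("no post-stimulus frames")
    sd = float(np.nanstd(base, ddof=1))
    max_change = float(np.nanmax(post - trace.R0))
    if sd == 0.0:
        warnings.warn("baseline s.d. is zero; SNR reported as inf", stacklevel=2)
        return math.inf
    return max_change / sd


@dataclass
class QCResult:
    kept: list[str]
    excluded: list[str]
    rule: str
    threshold: float | None = None


def qc_exclude(
    cells: Sequence[str], acceptor_intensities: Sequence[float]
) -> QCResult:
    """Exclude over-bright cells: acceptor intensity > mean + 3 s.d.

    The mean and s.d. are taken over the provided population.  The
    inequality is strict, so a cell sitting exactly at mean + 3 s.d. is
    kept.  With fewer than 3 cells the rule is skipped with a warning.
    """
    cells = list(cells)
    x = np.asarray(acceptor_intensities, dtype=float)
    if len(cells) != x.size:
        raise ValueError("cells and intensities must align")
    if len(cells) < 3:
        warnings.warn("fewer than 3 cells; brightness QC skipped", stacklevel=2)
        return QCResult(kept=cells, excluded=[], rule="skipped (<3 cells)")
    cutoff = float(x.mean() + 3.0 * x.std(ddof=1))
    excluded = [c for c, v in zip(cells, x) if v > cutoff]
    kept = [c for c, v in zip(cells, x) if not v > cutoff]
    return QCResult(
        kept=kept,
        excluded=excluded,
        rule="acceptor intensity > mean + 3 s.d.",
        threshold=cutoff,
    )


def ratio_image(
    fret_frame: np.ndarray,
    donor_frame: np.ndarray,
    *,
    colormap: str = "inferno",
    vmin: float | None = None,
    vmax: float | None = None,
) -> tuple[np.ma.MaskedArray, np.ndarray, int]:
    """Pixel-wise FRET/donor ratio field plus a pseudocoloured RGBA render.

    Pixels with non-positive donor signal are masked.  Returns
    ``(ratio_field, rgba, n_masked)``; the numeric field is what downstream
    quantification should use, the RGBA array is display-only.
    """
    fret_frame = np.asarray(fret_frame, dtype=float)
    donor_frame = np.asarray(donor_frame, dtype=float)
    if fret_frame.shape != donor_frame.shape:
        raise ValueError("frame shapes differ")
    invalid = donor_frame <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        field_ = np.ma.masked_array(fret_frame / donor_frame, mask=invalid)
    lo = field_.min() if vmin is None else vmin
    hi = field_.max() if vmax is None else vmax
    span = hi - lo if hi > lo else 1.0
    cmap = colormaps[colormap]
    rgba = cmap(np.clip((field_.filled(lo) - lo) / span, 0, 1))
    rgba[invalid] = (0, 0, 0, 1)
    return field_, rgba, int(invalid.sum())


# ---------------------------------------------------------------------------
# I/O helpers


def write_stack_tiff(stack: ChannelStack, path: str | Path) -> None:
    """Write a multi-page TIFF, one page per (frame, channel), with metadata."""
    names = sorted(stack.channels)
    pages = np.stack(
        [stack.channels[c] for c in names], axis=1
    )  # (T, C, Y, X)
    tifffile.imwrite(
        str(path),
        pages.astype(np.float32),
        photometric="minisblack",
        metadata={
            "axes": "TCYX",
            "channels": names,
            "pixel_size_um": stack.pixel_size_um,
            "time_index_of_stimulus": stack.time_index_of_stimulus,
            "frame_interval_s": stack.frame_interval_s,
        },
    )


def read_stack_tiff(path: str | Path) -> ChannelStack:
    """Read a stack written by :func:`write_stack_tiff`."""
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    names = meta.get("channels")
    if names is None or data.ndim != 4:
        raise ValueError("TIFF lacks the expected (T, C, Y, X) layout/metadata")
    channels = {c: data[:, i] for i, c in enumerate(names)}
    return ChannelStack(
        channels,
        pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
        time_index_of_stimulus=int(meta.get("time_index_of_stimulus", 0)),
        frame_interval_s=float(meta.get("frame_interval_s", 1.0)),
    )


def rois_from_json(path: str | Path, frame_shape: tuple[int, int]) -> list[RegionOfInterest]:
    """Load ROIs from a JSON list of polygon/ellipse specs.

    Each entry: ``{"label": ..., "kind": "cell"|"background",
    "shape": "polygon", "vertices": [[r, c], ...]}`` or
    ``{"shape": "ellipse", "center": [r, c], "radii": [ry, rx]}``.
    """
    specs = json.loads(Path(path).read_text())
    rois = []
    for spec in specs:
        mask = np.zeros(frame_shape, dtype=bool)
        if spec["shape"] == "polygon":
            rr_cc = np.asarray(spec["vertices"], dtype=float)
            rr, cc = draw_polygon(rr_cc[:, 0], rr_cc[:, 1], shape=frame_shape)
        elif spec["shape"] == "ellipse":
            r, c = spec["center"]
            ry, rx = spec["radii"]
            rr, cc = draw_ellipse(r, c, ry, rx, shape=frame_shape)
        else:
            raise ValueError(f"unknown ROI shape {spec['shape']!r}")
        mask[rr, cc] = True
        rois.append(
            RegionOfInterest(spec["label"], mask, spec.get("kind", "cell"))
        )
    return rois


def traces_to_frame(traces: Sequence[FRETTrace], frame_interval_s: float = 1.0):
    """Tidy per-frame table (cell_id, frame, time_s, R, R_over_R0, normalized)."""
    import pandas as pd

    rows = []
    for t in traces:
        for i, r in enumerate(t.R):
            rows.append(
                {
                    "cell_id": t.label,
                    "condition": t.condition,
                    "frame": i,
                    "time_s": i * frame_interval_s,
                    "R": r,
                    "R_over_R0": r / t.R0 if t.R0 else np.nan,
                    "normalized": (
                        t.normalized[i] if t.normalized is not None else np.nan
                    ),
                    "mode": t.normalize_mode or "",
                }
            )
    return pd.DataFrame(rows)
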
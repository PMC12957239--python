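"""Chart digitization: grid removal, trace extraction and model-input prep.

The pipeline turns a gridded CTG report page back into physical-unit time
series:

1. grayscale conversion + global threshold at 65 (grid and shadow pixels sit
   below it, trace pixels above);
2. per-panel column-wise trace extraction (median foreground row per sampled
   column);
3. linear pixel-row -> value mapping v = vmin + y'/(h-1) * (vmax - vmin),
   with y' the row offset measured upward from the bottom of the panel's
   valid region (image rows grow downward, values grow upward);
4. chronological splicing of the two 10-minute segments per channel;
5. re-rendering of the reconstructed pair to a Z-scored 3x224x224 tensor.

Gaps (columns with no foreground) are filled by linear interpolation between
the nearest valid columns, edge gaps held at the nearest valid value; the
validity mask is preserved so downstream consumers can exclude filled samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .chart_synthesis import ChartImage, ChartLayout, TRACE_THRESHOLD
from .signals import CHANNEL_RANGES, TraceSignal

DEFAULT_OUT_RATE = 4.0  # Hz, the external-dataset sampling convention


@dataclass
class BinaryMask:
    """Boolean foreground mask with the shape of its source image."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def source_shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class RegionSpec:
    """One curve panel: pixel box plus its value-axis calibration."""

    box: tuple[int, int, int, int]  # (left, top, width, height)
    channel: str
    segment_index: int
    vmin: float = None
    vmax: float = None

    def __post_init__(self) -> None:
        if self.vmin is None or self.vmax is None:
            self.vmin, self.vmax = CHANNEL_RANGES[self.channel]
        if not self.vmin < self.vmax:
            raise ValueError("vmin must be < vmax")
        if self.box[2] <= 0 or self.box[3] <= 0:
            raise ValueError("region box must have positive size")

    @property
    def ymin(self) -> int:
        """First image row of the valid region."""
        return self.box[1]

    @property
    def h(self) -> int:
        """Pixel height of the valid region."""
        return self.box[3]

    @classmethod
    def from_layout(cls, layout: ChartLayout) -> list["RegionSpec"]:
        return [
            cls(box=tuple(box), channel=ch, segment_index=seg)
            for box, ch, seg in zip(layout.region_boxes, layout.channels,
                                    layout.segment_indices)
        ]


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """8-bit luminance; RGB collapses with ITU-R 601 weights."""
    arr = np.asarray(pixels)
    if arr.ndim == 3:
        arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def binarize(image: "ChartImage | np.ndarray",
             threshold: int = TRACE_THRESHOLD) -> BinaryMask:
    """Global-threshold binarization keeping pixels with gray >= threshold.

    Grid lines and shadow areas print darker than the trace in grayscale, so
    thresholding at 65 filters the background while keeping the curves.
    """
    pixels = image.pixels if isinstance(image, ChartImage) else image
    gray = to_grayscale(pixels)
    if gray.size == 0:
        raise ValueError("empty image")
    return BinaryMask(gray >= threshold)


def pixel_to_value(y: "float | np.ndarray", region: RegionSpec) -> "float | np.ndarray":
    """Map image row(s) to physical value(s) by the panel's linear calibration.

    The bottom row of the valid region maps to ``vmin`` and the top row to
    ``vmax``; fractional rows (e.g. the median of an even run) interpolate
    linearly.
    """
    y = np.asarray(y, dtype=float)
    bottom = region.ymin + region.h - 1
    if np.any(y < region.ymin) or np.any(y > bottom):
        raise ValueError("row outside the region's valid rows")
    y_up = bottom - y
    v = region.vmin + y_up / (region.h - 1) * (region.vmax - region.vmin)
    return float(v) if v.ndim == 0 else v


def _fill_gaps(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linear interpolation across invalid samples; edges held constant."""
    if valid.all():
        return values
    idx = np.arange(len(values))
    return np.interp(idx, idx[valid], values[valid])


def extract_trace(mask: BinaryMask, region: RegionSpec, duration_s: float,
                  out_rate: float = DEFAULT_OUT_RATE) -> TraceSignal:
    """Column-wise trace extraction from a binarized panel.

    Columns are sampled at fixed horizontal intervals set by the panel width
    and the recording duration; in each sampled column the trace row is the
    median foreground row (robust to trace thickness and speckle), mapped to
    a physical value by the linear calibration.  Empty columns are marked
    invalid and filled by interpolation.
    """
    if out_rate <= 0:
        raise ValueError("out_rate must be positive")
    x0, y0, bw, bh = region.box
    rows, cols = mask.source_shape
    if x0 < 0 or y0 < 0 or x0 + bw > cols or y0 + bh > rows:
        raise ValueError("region extends outside the mask")

    panel = mask.pixels[y0:y0 + bh, x0:x0 + bw]
    n_out = int(round(duration_s * out_rate))
    # pixel-column centers for each output sample
    xs = np.minimum((np.floor((np.arange(n_out) + 0.5) * bw / n_out)).astype(int),
                    bw - 1)

    values = np.zeros(n_out)
    valid = np.zeros(n_out, dtype=bool)
    col_rows = [np.flatnonzero(panel[:, x]) for x in range(bw)]
    for i, x in enumerate(xs):
        fg = col_rows[x]
        if fg.size:
            values[i] = pixel_to_value(y0 + float(np.median(fg)), region)
            valid[i] = True
    if not valid.any():
        raise ValueError("no trace found in region")
    values = _fill_gaps(values, valid)
    return TraceSignal(values, out_rate, region.channel, valid=valid,
                       start_time=region.segment_index * duration_s)


def splice_segments(seg1: TraceSignal, seg2: TraceSignal) -> TraceSignal:
    """Concatenate consecutive segments of the same channel chronologically."""
    if len(seg2) == 0:
        return seg1
    if seg1.channel != seg2.channel:
        raise ValueError("cannot splice different channels")
    if seg1.sample_rate != seg2.sample_rate:
        raise ValueError("cannot splice different sample rates")
    return TraceSignal(
        np.concatenate([seg1.values, seg2.values]),
        seg1.sample_rate,
        seg1.channel,
        valid=np.concatenate([seg1.valid, seg2.valid]),
        start_time=seg1.start_time,
    )


@dataclass
class ModelInput:
    """3x224x224 (by default) Z-scored tensor plus its normalization record."""

    tensor: np.ndarray
    normalization: tuple[float, float]  # (mean, sd) removed by the Z-score

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.ndim != 3 or not np.isfinite(self.tensor).all():
            raise ValueError("tensor must be 3-D and finite")


def _plot_half(canvas: np.ndarray, signal: TraceSignal, top: int, height: int) -> None:
    vmin, vmax = signal.value_range
    width = canvas.shape[1]
    tcol = signal.start_time + (np.arange(width) + 0.5) / width * signal.duration_s
    vals = signal.value_at(tcol)
    frac = np.clip((vals - vmin) / (vmax - vmin), 0.0, 1.0)
    rows = top + (height - 1) - np.rint(frac * (height - 1)).astype(int)
    prev = rows[0]
    for x in range(width):
        lo, hi = sorted((rows[x], prev))
        canvas[lo:hi + 1, x] = 1.0
        prev = rows[x]


def standardize_to_input(fhr: TraceSignal, uc: TraceSignal,
                         size: int = 224,
                         eps: float = 1e-8) -> ModelInput:
    """Re-render a reconstructed FHR/UC pair as the network's square input.

    FHR occupies the upper half and UC the lower half of a blank canvas, each
    with the same linear value axis used on the chart.  The canvas is
    replicated to 3 channels and Z-score normalized per image; a zero-variance
    canvas yields an all-zero tensor via the epsilon guard.
    """
    for sig in (fhr, uc):
        if len(sig) < 2:
            raise ValueError("signal too short")
    if abs(fhr.duration_s - uc.duration_s) > 1.0 / fhr.sample_rate:
        raise ValueError("FHR and UC must cover the same duration")

    canvas = np.zeros((size, size))
    half = size // 2
    _plot_half(canvas, fhr, 0, half)
    _plot_half(canvas, uc, half, size - half)

    mean = float(canvas.mean())
    sd = float(canvas.std())
    if sd < eps:
        norm = np.zeros_like(canvas)
    else:
        norm = (canvas - mean) / sd
    tensor = np.broadcast_to(norm, (3, size, size)).copy()
    return ModelInput(tensor=tensor, normalization=(mean, sd))


def digitize_chart(image: "ChartImage | np.ndarray",
                   layout: ChartLayout | None = None,
                   out_rate: float = DEFAULT_OUT_RATE,
                   threshold: int = TRACE_THRESHOLD) -> tuple[TraceSignal, TraceSignal]:
    """Full chart -> signals pipeline: binarize, extract the four panels,
    splice each channel's two 10-minute segments chronologically.

    Returns the 20-minute ``(fhr, uc)`` pair at ``out_rate``.
    """
    if isinstance(image, ChartImage) and layout is None:
        layout = image.layout
    if layout is None:
        raise ValueError("a ChartLayout is required")
    mask = binarize(image, threshold)
    regions = RegionSpec.from_layout(layout)
    segs = {"fhr": {}, "uc": {}}
    for region in regions:
        segs[region.channel][region.segment_index] = extract_trace(
            mask, region, layout.seconds_per_region, out_rate)
    fhr = splice_segments(segs["fhr"][0], segs["fhr"][1])
    uc = splice_segments(segs["uc"][0], segs["uc"][1])
    return fhr, uc


def detect_region_boxes(mask: BinaryMask, n_regions: int = 4,
                        min_gap: int = 3) -> list:
    """Best-effort panel localization from the horizontal projection profile.

    Groups consecutive rows containing foreground into bands and returns the
    ``n_regions`` tallest bands as (left, top, width, height) boxes.  Intended
    as a convenience when no layout sidecar is available; config-driven
    layouts remain the reliable path.
    """
    rowsum = mask.pixels.sum(axis=1)
    active = rowsum > 0
    bands, start = [], None
    gap = 0
    for y, a in enumerate(active):
        if a:
            if start is None:
                start = y
            gap = 0
        elif start is not None:
            gap += 1
            if gap > min_gap:
                bands.append((start, y - gap))
                start, gap = None, 0
    if start is not None:
        bands.append((start, len(active) - 1))
    bands.sort(key=lambda b: b[1] - b[0], reverse=True)
    bands = sorted(bands[:n_regions])
    boxes = []
    for top, bottom in bands:
        cols = np.flatnonzero(mask.pixels[top:bottom + 1].any(axis=0))
        boxes.append((int(cols[0]), int(top),
                      int(cols[-1] - cols[0] + 1), int(bottom - top + 1)))
    return boxes


def load_chart_image(path) -> np.ndarray:
    """Read a PNG/JPEG chart page as an 8-bit grayscale array."""
    with Image.open(path) as im:
        return to_grayscale(np.asarray(im.convert("L")))
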
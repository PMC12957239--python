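"""Synthetic CTG recordings rendered as gridded chart pages with ground truth.

Clinical fetal-monitoring reports print four curve panels per 20-minute page:
FHR and UC for the first ten minutes on top, FHR and UC for the second ten
minutes below, over a grid of faint calibration lines and shaded bands.  This
module simulates class-conditional FHR/UC morphology (accelerations,
contraction-lagged decelerations, baseline variability), renders it to such a
page, and returns the exact trace-pixel mask so the digitization stage can be
tested against known ground truth.

Gray-level contract: every rendered trace pixel is >= 65 and every grid or
shadow pixel is < 65, so a global threshold at 65 separates them exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter1d

from .signals import FHR_RANGE, UC_RANGE, TraceSignal

REASSURING = "reassuring"
NON_REASSURING = "non_reassuring"

#: Gray threshold separating trace (>=) from grid/shadow background (<).
TRACE_THRESHOLD = 65


@dataclass
class SignalParams:
    """Morphology parameters for one simulated 20-minute recording.

    Event tuples follow the conventions:

    * ``accel_events``: ``(onset_s, duration_s, amplitude_bpm)``
    * ``decel_events``: ``(onset_s, duration_s, depth_bpm, lag_after_uc_peak_s)``
      where onset is absolute and the lag records the distance from the
      contraction peak the deceleration was placed after (late-deceleration
      bookkeeping; it does not shift the bump again).
    * ``uc_events``: ``(peak_time_s, duration_s, peak_mmhg)``
    """

    baseline_bpm: float = 140.0
    variability_amp: float = 10.0  # peak-to-peak band, bpm
    accel_events: list = field(default_factory=list)
    decel_events: list = field(default_factory=list)
    uc_events: list = field(default_factory=list)
    uc_tone: float = 10.0
    duration_s: float = 1200.0
    sample_rate: float = 4.0
    label: str = REASSURING
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.uc_tone < 0:
            raise ValueError("uc_tone must be non-negative")
        if self.label not in (REASSURING, NON_REASSURING):
            raise ValueError(f"unknown label {self.label!r}")


def _check_event_window(onset: float, duration: float, total: float) -> None:
    if onset < 0 or onset + duration > total:
        raise ValueError(
            f"event [{onset}, {onset + duration}] s lies outside the "
            f"recording duration {total} s"
        )


def _gauss_bump(t: np.ndarray, center: float, duration: float) -> np.ndarray:
    # sigma = duration/4 puts ~95% of the bump inside the stated window
    sigma = max(duration / 4.0, 1e-6)
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def simulate_fhr(params: SignalParams) -> TraceSignal:
    """Simulate a fetal-heart-rate series: baseline + band-limited
    variability + Gaussian acceleration bumps - deceleration bumps,
    clipped to the chart range 60-210 bpm.  Deterministic for a fixed seed."""
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.sample_rate))
    t = np.arange(n) / params.sample_rate

    values = np.full(n, float(params.baseline_bpm), dtype=float)
    if params.variability_amp > 0:
        # white noise smoothed to the 0.1-0.5 Hz band typical of short-term
        # variability, rescaled so the peak-to-peak band ~ variability_amp
        noise = rng.standard_normal(n)
        noise = gaussian_filter1d(noise, sigma=params.sample_rate)
        sd = noise.std()
        if sd > 0:
            values = values + noise / sd * (params.variability_amp / 4.0)

    for onset, duration, amplitude in params.accel_events:
        _check_event_window(onset, duration, params.duration_s)
        values = values + amplitude * _gauss_bump(t, onset + duration / 2, duration)
    for onset, duration, depth, _lag in params.decel_events:
        _check_event_window(onset, duration, params.duration_s)
        values = values - depth * _gauss_bump(t, onset + duration / 2, duration)

    np.clip(values, *FHR_RANGE, out=values)
    return TraceSignal(values, params.sample_rate, "fhr")


def simulate_uc(params: SignalParams) -> TraceSignal:
    """Simulate a uterine-contraction pressure series: resting tone +
    Gaussian contraction bumps peaking at the stated pressure, clipped to
    0-100 mmHg."""
    n = int(round(params.duration_s * params.sample_rate))
    t = np.arange(n) / params.sample_rate

    values = np.full(n, float(params.uc_tone), dtype=float)
    for peak_time, duration, peak in params.uc_events:
        _check_event_window(peak_time - duration / 2, duration, params.duration_s)
        values = values + (peak - params.uc_tone) * _gauss_bump(t, peak_time, duration)

    np.clip(values, *UC_RANGE, out=values)
    return TraceSignal(values, params.sample_rate, "uc")


@dataclass
class ChartLayout:
    """Page geometry tying pixels to the time/value axes.

    ``region_boxes`` are ``(left, top, width, height)`` rectangles in reading
    order: FHR first 10 min, UC first 10 min, FHR second 10 min, UC second
    10 min.  Each box spans exactly 10 minutes horizontally; within a box the
    bottom pixel row maps to the channel minimum and the top row to the
    channel maximum.
    """

    page_size: tuple[int, int] = (1200, 800)  # (width, height) px
    region_boxes: list = None
    grid_spacing: tuple[int, int] = (25, 20)
    seconds_per_region: float = 600.0
    grid_gray: int = 40
    shadow_gray: int = 55
    trace_gray: int = 255
    trace_thickness: int = 2
    background_gray: int = 12

    def __post_init__(self) -> None:
        if self.region_boxes is None:
            self.region_boxes = self._default_boxes()
        if not (self.grid_gray < TRACE_THRESHOLD and self.shadow_gray < TRACE_THRESHOLD
                and self.background_gray < TRACE_THRESHOLD):
            raise ValueError("grid/shadow/background gray must be < 65")
        if self.trace_gray < TRACE_THRESHOLD:
            raise ValueError("trace_gray must be >= 65")
        if len(self.region_boxes) != 4:
            raise ValueError("exactly four region boxes required")
        self._check_disjoint()

    def _default_boxes(self) -> list:
        w, h = self.page_size
        margin_x, margin_y, gap = 50, 30, 20
        # FHR panels taller than UC (150 bpm vs 100 mmHg spans)
        usable = h - 2 * margin_y - 3 * gap
        fhr_h = int(round(usable * 0.32))
        uc_h = (usable - 2 * fhr_h) // 2
        bw = w - 2 * margin_x
        boxes, y = [], margin_y
        for rh in (fhr_h, uc_h, fhr_h, uc_h):
            boxes.append((margin_x, y, bw, rh))
            y += rh + gap
        return boxes

    def _check_disjoint(self) -> None:
        for i, (x0, y0, bw, bh) in enumerate(self.region_boxes):
            for x1, y1, cw, ch in self.region_boxes[i + 1:]:
                if x0 < x1 + cw and x1 < x0 + bw and y0 < y1 + ch and y1 < y0 + bh:
                    raise ValueError("region boxes must be disjoint")

    @property
    def channels(self) -> list:
        return ["fhr", "uc", "fhr", "uc"]

    @property
    def segment_indices(self) -> list:
        return [0, 0, 1, 1]


@dataclass
class ChartImage:
    """Raster chart page (8-bit grayscale) plus its layout metadata."""

    pixels: np.ndarray
    layout: ChartLayout

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)


@dataclass
class GroundTruth:
    """Exact simulated signals, label and rendered trace-pixel mask."""

    fhr: TraceSignal
    uc: TraceSignal
    label: str
    trace_pixel_mask: np.ndarray
    params: SignalParams = None


def value_to_row_offset(v: np.ndarray, vmin: float, vmax: float, h: int) -> np.ndarray:
    """Map physical values to integer row offsets measured up from the
    bottom row of an h-row panel (0 -> vmin, h-1 -> vmax)."""
    frac = (np.asarray(v, dtype=float) - vmin) / (vmax - vmin)
    k = np.rint(frac * (h - 1)).astype(int)
    return np.clip(k, 0, h - 1)


def _draw_region(page: np.ndarray, mask: np.ndarray, signal: TraceSignal,
                 box: tuple, seg_start: float, seg_len: float,
                 gray: int, thickness: int) -> None:
    x0, y0, bw, bh = box
    vmin, vmax = signal.value_range
    # sample the signal at each pixel-column center
    tcol = seg_start + (np.arange(bw) + 0.5) / bw * seg_len
    vals = signal.value_at(tcol)
    k = value_to_row_offset(vals, vmin, vmax, bh)
    rows = y0 + (bh - 1) - k  # image rows grow downward
    prev = rows[0]
    for x in range(bw):
        r = rows[x]
        lo, hi = (r, prev) if r <= prev else (prev, r)
        hi = min(hi + thickness - 1, y0 + bh - 1)
        page[lo:hi + 1, x0 + x] = gray
        mask[lo:hi + 1, x0 + x] = True
        prev = r


def render_chart(fhr: TraceSignal, uc: TraceSignal,
                 layout: ChartLayout | None = None,
                 label: str = REASSURING,
                 params: SignalParams | None = None) -> tuple[ChartImage, GroundTruth]:
    """Render a 20-minute FHR/UC pair onto a four-panel gridded page.

    The first ten minutes go to the upper FHR/UC panels and the second ten
    to the lower pair.  The value-to-row placement is the exact inverse of
    the linear pixel-to-value mapping used by the digitization stage, with
    nearest-row placement (no anti-aliasing) so thresholding at 65 recovers
    precisely the returned trace-pixel mask.
    """
    layout = layout or ChartLayout()
    if abs(fhr.duration_s - uc.duration_s) > 1.0 / fhr.sample_rate:
        raise ValueError("FHR and UC must cover the same duration")
    n_seg = len(layout.region_boxes) // 2
    seg_len = layout.seconds_per_region
    if abs(fhr.duration_s - n_seg * seg_len) > 1.0 / fhr.sample_rate:
        raise ValueError(
            f"signals cover {fhr.duration_s} s but the layout expects "
            f"{n_seg * seg_len} s ({n_seg} regions x {seg_len} s)"
        )

    w, h = layout.page_size
    page = np.full((h, w), layout.background_gray, dtype=np.uint8)
    mask = np.zeros((h, w), dtype=bool)

    for box in layout.region_boxes:
        x0, y0, bw, bh = box
        # shaded band across the lower half of the panel, then grid lines
        page[y0 + bh // 2: y0 + bh, x0: x0 + bw] = layout.shadow_gray
        gx, gy = layout.grid_spacing
        for x in range(x0, x0 + bw, gx):
            page[y0: y0 + bh, x] = layout.grid_gray
        for y in range(y0, y0 + bh, gy):
            page[y, x0: x0 + bw] = layout.grid_gray

    signals = {"fhr": fhr, "uc": uc}
    for box, channel, seg in zip(layout.region_boxes, layout.channels,
                                 layout.segment_indices):
        _draw_region(page, mask, signals[channel], box, seg * seg_len, seg_len,
                     layout.trace_gray, layout.trace_thickness)

    chart = ChartImage(page, layout)
    truth = GroundTruth(fhr=fhr, uc=uc, label=label, trace_pixel_mask=mask,
                        params=params)
    return chart, truth


def _reassuring_params(rng: np.random.Generator, seed: int) -> SignalParams:
    duration = 1200.0
    baseline = rng.uniform(125, 155)
    n_acc = rng.integers(2, 5)
    accels = []
    for onset in np.sort(rng.uniform(60, duration - 120, n_acc)):
        accels.append((float(onset), float(rng.uniform(15, 30)),
                       float(rng.uniform(15, 25))))
    uc_events = _contraction_train(rng, duration)
    return SignalParams(
        baseline_bpm=baseline,
        variability_amp=float(rng.uniform(6, 15)),
        accel_events=accels,
        uc_events=uc_events,
        uc_tone=float(rng.uniform(5, 15)),
        label=REASSURING,
        seed=seed,
    )


def _non_reassuring_params(rng: np.random.Generator, seed: int) -> SignalParams:
    duration = 1200.0
    baseline = rng.uniform(120, 150)
    uc_events = _contraction_train(rng, duration)
    decels = []
    for peak_time, _dur, _amp in uc_events:
        lag = float(rng.uniform(20, 60))
        d = float(rng.uniform(30, 60))
        onset = peak_time + lag - d / 2
        if onset >= 0 and onset + d <= duration:
            decels.append((onset, d, float(rng.uniform(20, 40)), lag))
    return SignalParams(
        baseline_bpm=baseline,
        variability_amp=float(rng.uniform(0.5, 3.0)),
        decel_events=decels,
        uc_events=uc_events,
        uc_tone=float(rng.uniform(5, 15)),
        label=NON_REASSURING,
        seed=seed,
    )


def _contraction_train(rng: np.random.Generator, duration: float) -> list:
    events, t = [], float(rng.uniform(90, 200))
    while t < duration - 100:
        events.append((t, float(rng.uniform(60, 90)), float(rng.uniform(40, 80))))
        t += float(rng.uniform(150, 260))
    return events


def make_dataset(n: int, class_ratio: float, seed: int,
                 layout: ChartLayout | None = None) -> list:
    """Generate ``n`` chart/ground-truth pairs with ``round(n * class_ratio)``
    non-reassuring recordings, reproducibly from ``seed``.

    Reassuring recordings carry moderate variability (6-15 bpm) and
    accelerations; non-reassuring ones reduced variability (<= 3 bpm) and
    decelerations lagging contraction peaks by 20-60 s (late decelerations).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 < class_ratio < 1:
        raise ValueError("class_ratio must be in (0, 1)")
    layout = layout or ChartLayout()
    n_pos = int(round(n * class_ratio))
    labels = np.array([NON_REASSURING] * n_pos + [REASSURING] * (n - n_pos))
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    child_seeds = np.random.SeedSequence(seed).spawn(n)

    out = []
    for i, label in enumerate(labels):
        srng = np.random.default_rng(child_seeds[i])
        sig_seed = int(srng.integers(0, 2**31 - 1))
        if label == NON_REASSURING:
            params = _non_reassuring_params(srng, sig_seed)
        else:
            params = _reassuring_params(srng, sig_seed)
        fhr = simulate_fhr(params)
        uc = simulate_uc(params)
        out.append(render_chart(fhr, uc, layout, label=label, params=params))
    return out


def save_chart(chart: ChartImage, truth: GroundTruth, stem: Path) -> None:
    """Write a chart as PNG plus ground-truth CSVs and a JSON sidecar."""
    stem = Path(stem)
    Image.fromarray(chart.pixels).save(stem.with_suffix(".png"))
    for sig, name in ((truth.fhr, "fhr"), (truth.uc, "uc")):
        data = np.column_stack([sig.times, sig.values])
        np.savetxt(stem.parent / f"{stem.name}_{name}.csv", data,
                   delimiter=",", header="time_s,value", comments="")
    sidecar = {
        "label": truth.label,
        "seed": truth.params.seed if truth.params else None,
        "layout": {
            "page_size": list(chart.layout.page_size),
            "region_boxes": [list(b) for b in chart.layout.region_boxes],
            "grid_spacing": list(chart.layout.grid_spacing),
            "trace_thickness": chart.layout.trace_thickness,
        },
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
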
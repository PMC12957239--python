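"""Minimal WFDB (MIT-format) reader/writer for CTG signal records.

Supports the subset of the standard header+signal convention this package
needs: a ``.hea`` text header (record line ``name nsig fs nsamp``, one signal
line per channel with ``file format gain(baseline)/units ... description``,
and ``#`` comment lines carrying metadata such as ``# pH:7.23``) plus a
format-16 ``.dat`` file of interleaved little-endian 16-bit integers.
Physical values are reconstructed as ``(raw - baseline) / gain``.

FHR dropout samples (raw value 0, i.e. the transducer lost the signal) are
marked invalid and filled by linear interpolation, matching the digitization
module's gap policy.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .pipeline_labels import RecordLabel, map_label
from .signals import TraceSignal

_DEFAULT_WINDOW_S = 1200.0


@dataclass
class _SignalSpec:
    file: str
    fmt: int
    gain: float
    baseline: int
    units: str
    description: str


def _parse_header(hea_path: Path) -> tuple[str, int, float, int, list, dict]:
    lines = [ln.strip() for ln in hea_path.read_text().splitlines()]
    comments = {}
    body = []
    for ln in lines:
        if not ln:
            continue
        if ln.startswith("#"):
            m = re.match(r"#\s*([\w ]+?)\s*[:=]\s*(\S+)", ln)
            if m:
                comments[m.group(1).strip().lower()] = m.group(2)
        else:
            body.append(ln)
    name, nsig, fs, nsamp = body[0].split()[:4]
    specs = []
    for ln in body[1:1 + int(nsig)]:
        parts = ln.split()
        file, fmt = parts[0], int(parts[1])
        gain_field = parts[2]
        m = re.match(r"([-\d.]+)(?:\(([-\d]+)\))?(?:/(\S+))?", gain_field)
        gain = float(m.group(1)) if m.group(1) else 200.0
        baseline = int(m.group(2)) if m.group(2) else 0
        units = m.group(3) or ""
        description = " ".join(parts[8:]) if len(parts) > 8 else parts[-1]
        specs.append(_SignalSpec(file, fmt, gain, baseline, units, description))
    return name, int(nsig), float(fs), int(nsamp), specs, comments


def write_wfdb_record(path: Path, fhr: np.ndarray, uc: np.ndarray,
                      fs: float = 4.0, ph: float | None = None,
                      gain: float = 100.0) -> None:
    """Write a two-channel FHR/UC record in MIT header + format-16 layout."""
    path = Path(path)
    fhr = np.asarray(fhr, dtype=float)
    uc = np.asarray(uc, dtype=float)
    if len(fhr) != len(uc):
        raise ValueError("channels must have equal length")
    raw = np.empty((len(fhr), 2), dtype="<i2")
    raw[:, 0] = np.rint(fhr * gain).astype(int)
    raw[:, 1] = np.rint(uc * gain).astype(int)
    dat_name = path.with_suffix(".dat").name
    header = [f"{path.stem} 2 {fs:g} {len(fhr)}"]
    for units, desc in (("bpm", "FHR"), ("mmHg", "UC")):
        header.append(f"{dat_name} 16 {gain:g}(0)/{units} 0 0 0 0 0 {desc}")
    if ph is not None:
        header.append(f"# pH:{ph:g}")
    path.with_suffix(".hea").write_text("\n".join(header) + "\n")
    path.with_suffix(".dat").write_bytes(raw.tobytes())


def load_wfdb_record(path: "str | Path",
                     window_s: float = _DEFAULT_WINDOW_S
                     ) -> tuple[TraceSignal, TraceSignal, RecordLabel]:
    """Load a CTG record: 4 Hz (or header-stated) FHR/UC series plus a
    pH-derived Reassuring/Non-Reassuring label.

    Records longer than ``window_s`` are cropped to their final
    ``window_s`` seconds (the stretch closest to delivery).  FHR dropout
    (zero) samples are marked invalid and interpolated.
    """
    path = Path(path)
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"header not found: {hea}")
    name, nsig, fs, nsamp, specs, comments = _parse_header(hea)

    if "ph" not in comments:
        raise ValueError(f"record {name}: no pH metadata in header comments")
    ph = float(comments["ph"])

    dat = path.parent / specs[0].file
    raw = np.frombuffer(dat.read_bytes(), dtype="<i2").reshape(-1, nsig)

    channels = {}
    for i, spec in enumerate(specs):
        desc = spec.description.upper()
        if "FHR" in desc:
            channels["fhr"] = (raw[:, i], spec)
        elif "UC" in desc or "UA" in desc:
            channels["uc"] = (raw[:, i], spec)
    for needed in ("fhr", "uc"):
        if needed not in channels:
            raise ValueError(
                f"record {name}: missing {needed.upper()} channel")

    out = {}
    n_keep = min(int(round(window_s * fs)), len(raw))
    for ch, (col, spec) in channels.items():
        col = col[-n_keep:]
        valid = col != 0 if ch == "fhr" else np.ones(len(col), dtype=bool)
        values = (col.astype(float) - spec.baseline) / spec.gain
        if valid.any() and not valid.all():
            idx = np.arange(len(values))
            values = np.interp(idx, idx[valid], values[valid])
        out[ch] = TraceSignal(values, fs, ch, valid=valid)

    label = RecordLabel(record_id=name, ph=ph,
                        binary=map_label(ph=ph, scheme="ph_threshold"))
    return out["fhr"], out["uc"], label
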
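"""Pupillometry preprocessing: blink/outlier masking and interpolation.

Blinks are logged by the tracker as exact zeros.  Cleaning masks zero
samples plus samples outside the per-participant 99% normal-theory
interval (mean ± 2.576·sd over all valid samples of the whole recording),
then replaces masked runs with shape-preserving piecewise cubic Hermite
interpolation (PCHIP) anchored at the nearest valid neighbours — a
monotone scheme, so interpolated values never overshoot their anchors.
Leading/trailing gaps take the nearest valid value.  Unmasked samples pass
through bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.stats import norm

from .behavior import TRIAL_S

__all__ = ["PupilTrace", "preprocess_pupil", "aggregate_pupil", "read_eyelink_ascii"]


class UnrecoverableTraceError(ValueError):
    """Trace has fewer than two valid samples — nothing to anchor on."""


@dataclass(frozen=True)
class PupilTrace:
    """Uniform 1 kHz pupil samples with gap annotations."""

    t_ms: np.ndarray
    raw: np.ndarray  # arbitrary tracker units; 0 during blinks
    mm: np.ndarray
    px_per_mm: float = 13.0
    gap_mask: np.ndarray | None = field(default=None)
    cleaned: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.t_ms, dtype=float)
        if t.ndim != 1 or t.size != np.asarray(self.mm).size:
            raise ValueError("t_ms and samples must be 1-D of equal length")
        dt = np.diff(t)
        if t.size > 1 and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("timestamps must be strictly increasing and uniform")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, px_per_mm: float = 13.0) -> "PupilTrace":
        return cls(
            t_ms=df["t_ms"].to_numpy(dtype=float),
            raw=df["pupil_raw"].to_numpy(dtype=float),
            mm=df["pupil_mm"].to_numpy(dtype=float),
            px_per_mm=px_per_mm,
        )


def preprocess_pupil(
    trace: PupilTrace, ci_level: float = 0.99, pad_ms: float = 0.0
) -> PupilTrace:
    """Mask blinks/outliers and interpolate; see module docstring.

    ``pad_ms`` widens each blink gap symmetrically before interpolation
    (blink edges are partially occluded in real data); default 0.
    """
    if trace.cleaned:
        return trace
    mm = np.asarray(trace.mm, dtype=float)
    t = np.asarray(trace.t_ms, dtype=float)
    zero = mm == 0.0
    if pad_ms > 0 and zero.any():
        step = t[1] - t[0] if t.size > 1 else 1.0
        pad = int(round(pad_ms / step))
        idx = np.flatnonzero(zero)
        for i in idx:
            zero[max(0, i - pad) : i + pad + 1] = True
    valid = ~zero
    if valid.sum() < 2:
        raise UnrecoverableTraceError("fewer than two valid pupil samples")
    z = norm.ppf(0.5 + ci_level / 2.0)
    mu, sd = mm[valid].mean(), mm[valid].std(ddof=0)
    outlier = valid & (np.abs(mm - mu) > z * sd)
    mask = zero | outlier
    good = ~mask
    if good.sum() < 2:
        raise UnrecoverableTraceError("fewer than two valid pupil samples")

    out = mm.copy()
    gi = np.flatnonzero(good)
    interior = mask & (np.arange(mm.size) > gi[0]) & (np.arange(mm.size) < gi[-1])
    if interior.any():
        interp = PchipInterpolator(t[gi], mm[gi])
        out[interior] = interp(t[interior])
    out[: gi[0]] = mm[gi[0]]  # leading gap → first valid value
    out[gi[-1] + 1 :] = mm[gi[-1]]  # trailing gap → last valid value
    return replace(
        trace,
        mm=out,
        raw=out * trace.px_per_mm,
        gap_mask=mask,
        cleaned=True,
    )


def aggregate_pupil(
    traces: dict[tuple, PupilTrace],
    session: pd.DataFrame,
    trial_s: float = TRIAL_S,
) -> pd.DataFrame:
    """Mean cleaned pupil size per subject × task × light.

    ``traces`` is keyed by (subject, block, run, task-number); each trace
    covers that run's task period (one trial = 0.5 s letter + 1.5 s ISI).
    Cells with no samples are omitted with a recorded warning column.
    """
    cells: dict[tuple, list] = {}
    for (subject, block, run, task), trace in traces.items():
        if not trace.cleaned:
            trace = preprocess_pupil(trace)
        sel = session[
            (session.subject == subject)
            & (session.block == block)
            & (session.run == run)
            & (session.task == f"{task}-back")
        ]
        if sel.empty:
            continue
        light = sel.light.iloc[0]
        cells.setdefault((subject, f"{task}-back", light), []).append(trace.mm.mean())
    rows = [
        {"subject": s, "task": task, "light": light, "mean_mm": float(np.mean(v))}
        for (s, task, light), v in sorted(cells.items())
    ]
    return pd.DataFrame(rows)


def read_eyelink_ascii(path, px_per_mm: float = 13.0) -> PupilTrace:
    """Parse EyeLink-ASC-style sample lines: ``timestamp  x  y  pupil``.

    Non-sample lines (events, comments starting with letters) are skipped;
    missing-data markers (``.``) and zero pupil values become blink zeros.
    """
    ts, pupils = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or not parts[0].lstrip("-").isdigit():
                continue
            ts.append(float(parts[0]))
            try:
                pupils.append(float(parts[3]))
            except (IndexError, ValueError):
                pupils.append(0.0)
    raw = np.asarray(pupils)
    return PupilTrace(
        t_ms=np.asarray(ts), raw=raw, mm=raw / px_per_mm, px_per_mm=px_per_mm
    )
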
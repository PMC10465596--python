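"""Calcium-imaging trace quantification and anatomical density normalization.

Traces are ROI-mean fluorescence per frame. The response pipeline is:
optional Gaussian low-pass (sigma in frames), optional single-exponential
bleach correction fitted to pre-onset plus final-second samples, baseline F0
as the mean over the 2 s before stimulus onset, dF/F = (F - F0)/F0, then the
peak dF/F within [onset, onset + 1 s] and the Simpson's-rule area under the
baseline-subtracted dF/F over the same window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import simpson
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import OptimizeWarning, curve_fit

from .model import InputError


@dataclass
class FluorescenceTrace:
    """Raw fluorescence per frame for one (glomerulus, animal, trial)."""

    values: np.ndarray
    frame_rate: float            # Hz
    onset_frame: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise InputError("trace values must be finite and non-negative")
        if self.frame_rate <= 0:
            raise InputError("frame_rate must be positive")
        if not (0 <= self.onset_frame < len(self.values)):
            raise InputError("onset_frame must lie within the trace")
        if len(self.values) < self.onset_frame + int(round(self.frame_rate)) + 1:
            raise InputError("trace must extend at least 1 s past onset")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.frame_rate


@dataclass
class ResponseMetrics:
    f0: float
    dff: np.ndarray
    frame_rate: float
    onset_frame: int
    peak: float | None = None
    auc: float | None = None


def _bleach_correct(values: np.ndarray, frame_rate: float, onset: int) -> np.ndarray:
    """Divide out a single-exponential fit to pre-onset + final-second frames."""
    n = len(values)
    tail = max(n - int(round(frame_rate)), onset)
    idx = np.concatenate([np.arange(onset), np.arange(tail, n)])
    t = idx / frame_rate

    def model(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    a0 = max(values[idx][0] - values[idx][-1], 1e-6)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(model, t, values[idx],
                                p0=[a0, max(n / frame_rate, 1.0), values[idx][-1]],
                                maxfev=5000)
        fit = model(np.arange(n) / frame_rate, *popt)
    except RuntimeError:
        return values
    if np.any(fit <= 0):
        return values
    return values / fit * fit[:onset].mean()


def compute_dff(trace: FluorescenceTrace, smoothing_sigma: float = 1.0,
                bleach_correct: bool = False) -> ResponseMetrics:
    """Baseline-normalized dF/F for one trace.

    ``smoothing_sigma`` is the Gaussian low-pass sigma in frames (0 disables).
    F0 is the mean over the 2 s immediately before onset; at least 2 s of
    pre-onset frames are required and F0 must be positive.
    """
    baseline_frames = int(round(2.0 * trace.frame_rate))
    if trace.onset_frame < baseline_frames:
        raise InputError(
            f"need >= 2 s ({baseline_frames} frames) before onset, "
            f"have {trace.onset_frame}"
        )
    values = trace.values.astype(float)
    if smoothing_sigma > 0:
        values = gaussian_filter1d(values, sigma=smoothing_sigma)
    if bleach_correct:
        values = _bleach_correct(values, trace.frame_rate, trace.onset_frame)
    f0 = float(values[trace.onset_frame - baseline_frames:trace.onset_frame].mean())
    if f0 <= 0:
        raise InputError("non-positive baseline fluorescence")
    dff = (values - f0) / f0
    return ResponseMetrics(f0, dff, trace.frame_rate, trace.onset_frame)


def simpson_auc(y: np.ndarray, dx: float) -> float:
    """Composite Simpson integral; an odd final interval is closed by trapezoid."""
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        return 0.0
    n_intervals = len(y) - 1
    if n_intervals % 2 == 0:
        return float(simpson(y, dx=dx))
    if len(y) == 2:
        return float(0.5 * dx * (y[0] + y[1]))
    body = simpson(y[:-1], dx=dx)
    return float(body + 0.5 * dx * (y[-2] + y[-1]))


def response_metrics(metrics: ResponseMetrics, window: float = 1.0,
                     window_from_onset: bool = True) -> ResponseMetrics:
    """Fill in peak and AUC over the response window.

    peak = max dF/F in [onset, onset + window]. AUC integrates, by Simpson's
    rule, the dF/F minus its mean over the 1 s before onset, from onset (or
    from the trace start when ``window_from_onset`` is False) to onset +
    window.
    """
    onset = metrics.onset_frame
    n_window = int(round(window * metrics.frame_rate))
    end = onset + n_window
    if end >= len(metrics.dff):
        raise InputError("response window extends past the end of the trace")
    n_base = int(round(metrics.frame_rate))  # 1 s pre-onset baseline
    baseline = float(metrics.dff[max(onset - n_base, 0):onset].mean()) if onset else 0.0
    start = onset if window_from_onset else 0
    segment = metrics.dff[start:end + 1] - baseline
    metrics.peak = float(metrics.dff[onset:end + 1].max())
    metrics.auc = simpson_auc(segment, dx=1.0 / metrics.frame_rate)
    return metrics


def quantify_trace(trace: FluorescenceTrace, smoothing_sigma: float = 1.0,
                   bleach_correct: bool = False, window: float = 1.0,
                   window_from_onset: bool = True) -> ResponseMetrics:
    """compute_dff followed by response_metrics."""
    m = compute_dff(trace, smoothing_sigma=smoothing_sigma,
                    bleach_correct=bleach_correct)
    return response_metrics(m, window=window, window_from_onset=window_from_onset)


def pool_trials(per_trial: list[ResponseMetrics]) -> dict[str, float]:
    """Within-animal averaging of trial metrics before cross-animal pooling."""
    if not per_trial:
        raise InputError("no trials to pool")
    return {
        "peak": float(np.mean([m.peak for m in per_trial])),
        "auc": float(np.mean([m.auc for m in per_trial])),
    }


def normalize_density(table: pd.DataFrame) -> pd.DataFrame:
    """Within-indicator max normalization of anatomical signal densities.

    ``table`` has columns (indicator, glomerulus, raw_density); the result
    adds ``normalized`` = raw / max(raw within the indicator), so each
    indicator's densest glomerulus scores exactly 1.
    """
    for col in ("indicator", "glomerulus", "raw_density"):
        if col not in table.columns:
            raise InputError(f"density table missing column {col!r}")
    out = table.copy()
    maxima = out.groupby("indicator")["raw_density"].transform("max")
    zero = out.loc[maxima <= 0, "indicator"].unique()
    if len(zero):
        raise InputError(f"indicator(s) with all-zero density: {sorted(zero)}")
    out["normalized"] = out["raw_density"] / maxima
    return out


def read_traces(path: str | Path) -> list[FluorescenceTrace]:
    """Read traces from delimited text: metadata columns + one row per frame.

    Expected columns: glomerulus, animal, trial, frame_rate, onset_frame,
    frame, value. One trace per (glomerulus, animal, trial).
    """
    df = pd.read_csv(path, sep="\t")
    traces = []
    for (glom, animal, trial), grp in df.groupby(["glomerulus", "animal", "trial"]):
        grp = grp.sort_values("frame")
        traces.append(FluorescenceTrace(
            values=grp["value"].to_numpy(float),
            frame_rate=float(grp["frame_rate"].iloc[0]),
            onset_frame=int(grp["onset_frame"].iloc[0]),
            metadata={"glomerulus": glom, "animal": animal, "trial": trial},
        ))
    return traces


def write_traces(traces: list[FluorescenceTrace], path: str | Path) -> None:
    rows = []
    for tr in traces:
        for i, v in enumerate(tr.values):
            rows.append({
                "glomerulus": tr.metadata.get("glomerulus", ""),
                "animal": tr.metadata.get("animal", ""),
                "trial": tr.metadata.get("trial", 0),
                "frame_rate": tr.frame_rate,
                "onset_frame": tr.onset_frame,
                "frame": i,
                "value": v,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
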
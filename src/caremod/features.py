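"""Feature extraction from single-cell fura-2 ratio traces.

A recording follows a three-phase protocol: resting baseline in
Ca2+-containing medium, ER store depletion by a SERCA inhibitor (CPA)
in Ca2+-free medium, and Ca2+ re-addition that triggers store-operated
Ca2+ entry (SOCE).  Per cell we summarise the F340/F380 ratio trace as

* ``resting``     -- median ratio over the baseline window,
* ``store_dmax``  / ``store_auc`` -- peak increment and trapezoidal
  area of the baseline-subtracted CPA release transient (a proxy for
  Ca2+ store content),
* ``soce_dmax``   / ``soce_auc``  -- same two metrics over the Ca2+
  re-addition window (SOCE magnitude).

All windows are half-open ``[start, end)`` in seconds from recording
start.  Baseline references for the release and SOCE windows are local
pre-window medians, robust to slow drift.  Negative excursions are not
clipped, so AUC can be negative for cells that drift downwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRACE_COLUMNS = ["cell_id", "day", "coverslip", "line", "treatment", "time_s", "ratio"]

#: metadata carried from traces to the feature table
META_COLUMNS = ["cell_id", "day", "coverslip", "line", "treatment"]

FEATURE_NAMES = ["resting", "store_dmax", "store_auc", "soce_dmax", "soce_auc"]


@dataclass(frozen=True)
class Protocol:
    """Timing of the three-phase Ca2+ imaging protocol (seconds).

    Parameters
    ----------
    baseline_end : end of the resting window ``[0, baseline_end)``.
    readdition_start : start of Ca2+ re-addition; the CPA release
        window is ``[baseline_end, readdition_start)``.
    recording_end : end of the SOCE window ``[readdition_start, recording_end)``.
    resting_window : window for the resting-level median (default first 30 s).
    baseline_span : length of the pre-window span whose median serves
        as the local baseline reference for dmax/AUC (default 15 s).
    """

    baseline_end: float
    readdition_start: float
    recording_end: float
    resting_window: tuple[float, float] = (0.0, 30.0)
    baseline_span: float = 15.0

    def __post_init__(self) -> None:
        if not (0.0 < self.baseline_end < self.readdition_start < self.recording_end):
            raise ValueError(
                "protocol phase times must satisfy "
                "0 < baseline_end < readdition_start < recording_end"
            )
        lo, hi = self.resting_window
        if not (0.0 <= lo < hi):
            raise ValueError("invalid resting window")
        if self.baseline_span <= 0:
            raise ValueError("baseline_span must be positive")

    @property
    def release_window(self) -> tuple[float, float]:
        return (self.baseline_end, self.readdition_start)

    @property
    def soce_window(self) -> tuple[float, float]:
        return (self.readdition_start, self.recording_end)


DEFAULT_PROTOCOL = Protocol(baseline_end=180.0, readdition_start=600.0, recording_end=960.0)


@dataclass
class Trace:
    """A single-cell ratio time series with its experimental metadata."""

    cell_id: str
    day: str
    coverslip: str
    line: str
    treatment: str
    times: np.ndarray
    ratios: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.times.shape != self.ratios.shape:
            raise ValueError("times and ratios must have equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


def traces_from_frame(frame: pd.DataFrame) -> list[Trace]:
    """Split a long-format trace table (one row per sample) into traces."""
    missing = [c for c in TRACE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"trace table missing columns: {missing}")
    traces = []
    for cell_id, sub in frame.groupby("cell_id", sort=True):
        sub = sub.sort_values("time_s")
        first = sub.iloc[0]
        traces.append(
            Trace(
                cell_id=str(cell_id),
                day=str(first["day"]),
                coverslip=str(first["coverslip"]),
                line=str(first["line"]),
                treatment=str(first["treatment"]),
                times=sub["time_s"].to_numpy(float),
                ratios=sub["ratio"].to_numpy(float),
            )
        )
    return traces


def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (times >= lo) & (times < hi)


def resting_level(trace: Trace, protocol: Protocol = DEFAULT_PROTOCOL) -> float:
    """Median ratio over the resting window (default first 30 s)."""
    mask = _window_mask(trace.times, protocol.resting_window)
    if mask.sum() < 2:
        raise ValueError(
            f"cell {trace.cell_id}: fewer than 2 samples in resting window"
        )
    return float(np.median(trace.ratios[mask]))


def _baseline_reference(trace: Trace, window_start: float, span: float) -> float:
    mask = _window_mask(trace.times, (window_start - span, window_start))
    if not mask.any():
        raise ValueError(
            f"cell {trace.cell_id}: no samples in the {span:g} s preceding t={window_start:g}"
        )
    return float(np.median(trace.ratios[mask]))


def response_metrics(
    trace: Trace,
    window: tuple[float, float],
    baseline_ref: float,
) -> tuple[float, float]:
    """Peak increment and trapezoidal AUC of the baseline-subtracted signal.

    ``dmax = max(ratio - baseline_ref)`` over the window and
    ``auc = trapezoid(ratio - baseline_ref)`` over the samples falling in
    the window.  The trapezoid handles non-uniform sampling; AUC units are
    ratio*seconds.
    """
    mask = _window_mask(trace.times, window)
    if mask.sum() < 2:
        raise ValueError(
            f"cell {trace.cell_id}: fewer than 2 samples in window {window}"
        )
    t = trace.times[mask]
    y = trace.ratios[mask] - baseline_ref
    dmax = float(np.max(y))
    auc = float(np.trapezoid(y, t))
    return dmax, auc


def extract_cell_features(trace: Trace, protocol: Protocol = DEFAULT_PROTOCOL) -> dict:
    """Compute the five per-cell summary features for one trace."""
    resting = resting_level(trace, protocol)
    rel_lo, _ = protocol.release_window
    soce_lo, _ = protocol.soce_window
    store_ref = _baseline_reference(trace, rel_lo, protocol.baseline_span)
    soce_ref = _baseline_reference(trace, soce_lo, protocol.baseline_span)
    store_dmax, store_auc = response_metrics(trace, protocol.release_window, store_ref)
    soce_dmax, soce_auc = response_metrics(trace, protocol.soce_window, soce_ref)
    row = {
        "cell_id": trace.cell_id,
        "day": trace.day,
        "coverslip": trace.coverslip,
        "line": trace.line,
        "treatment": trace.treatment,
        "resting": resting,
        "store_dmax": store_dmax,
        "store_auc": store_auc,
        "soce_dmax": soce_dmax,
        "soce_auc": soce_auc,
    }
    return row


@dataclass
class FeatureExtraction:
    """Result of a batch feature-extraction run."""

    features: pd.DataFrame
    rejects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["cell_id", "reason"])
    )


def extract_features(
    traces: list[Trace] | pd.DataFrame,
    protocol: Protocol = DEFAULT_PROTOCOL,
) -> FeatureExtraction:
    """Extract features for every cell; cells failing preconditions are
    reported in ``rejects`` and the run continues."""
    if isinstance(traces, pd.DataFrame):
        traces = traces_from_frame(traces)
    rows, rejects = [], []
    for trace in traces:
        try:
            rows.append(extract_cell_features(trace, protocol))
        except ValueError as exc:
            rejects.append({"cell_id": trace.cell_id, "reason": str(exc)})
    features = pd.DataFrame(rows, columns=META_COLUMNS + FEATURE_NAMES)
    features = features.sort_values("cell_id").reset_index(drop=True)
    return FeatureExtraction(
        features=features,
        rejects=pd.DataFrame(rejects, columns=["cell_id", "reason"]),
    )
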
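"""Physiological classification of taste cells from ratiometric calcium imaging.

Type III (presynaptic) taste cells express voltage-gated calcium channels and
respond to a depolarizing stimulus (50 mM KCl) with a large, prolonged rise in
intracellular calcium, read out as the fura-2 F340/F380 ratio in arbitrary
units (AU). A cell is called a responder when its ratio rises more than
``k_sd`` standard deviations above the pre-stimulus baseline and stays there
for at least ``min_duration_s`` seconds.

Traces are irregularly sampled: acquisition typically runs at 2 s during the
stimulus, 4-8 s during the slow recovery, and 30-60 s between stimuli. The
"consecutive" requirement is therefore defined on samples: a run is a maximal
stretch of suprathreshold samples with no inter-sample gap larger than
``max_gap_s``, and its duration is last-sample time minus first-sample time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CalciumTrace",
    "StimulusEvent",
    "BaselineStats",
    "ResponseCall",
    "DetectorConfig",
    "InsufficientBaselineError",
    "compute_baseline",
    "detect_response",
    "classify_cells",
]


class InsufficientBaselineError(ValueError):
    """Raised when fewer than two samples fall in the baseline window."""


@dataclass(frozen=True)
class CalciumTrace:
    """One cell's F340/F380 ratio time series (irregular sampling allowed)."""

    cell_id: str
    time_s: np.ndarray
    ratio_au: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        r = np.asarray(self.ratio_au, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "ratio_au", r)
        if t.ndim != 1 or r.shape != t.shape:
            raise ValueError("time_s and ratio_au must be 1-D and equally long")
        if t.size < 2:
            raise ValueError("a trace needs at least 2 samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
            raise ValueError("trace contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, "ratio_au": self.ratio_au})


@dataclass(frozen=True)
class StimulusEvent:
    onset_s: float
    duration_s: float
    label: str = "KCl 50 mM"

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("stimulus duration must be positive")


@dataclass(frozen=True)
class BaselineStats:
    mean_au: float
    sd_au: float
    window: tuple[float, float]
    n_samples: int


@dataclass(frozen=True)
class ResponseCall:
    responded: bool
    threshold_au: float
    max_run_duration_s: float
    peak_au: float
    run_start_s: float | None = None
    run_end_s: float | None = None


@dataclass(frozen=True)
class DetectorConfig:
    """Detection rule parameters.

    k_sd
        Threshold in baseline standard deviations above the baseline mean
        (strict inequality).
    min_duration_s
        Minimum first-to-last-sample duration of a suprathreshold run.
    baseline_window_s
        Length of the pre-stimulus window used for baseline statistics.
    max_gap_s
        Largest inter-sample gap allowed inside a run; defaults to the
        maximum recovery-phase sampling interval (8 s).
    """

    k_sd: float = 10.0
    min_duration_s: float = 10.0
    baseline_window_s: float = 120.0
    max_gap_s: float = 8.0

    def __post_init__(self) -> None:
        for name in ("k_sd", "min_duration_s", "baseline_window_s", "max_gap_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def compute_baseline(
    trace: CalciumTrace, stim: StimulusEvent, cfg: DetectorConfig = DetectorConfig()
) -> BaselineStats:
    """Baseline mean/SD over the window before stimulus onset.

    The window is ``[onset - baseline_window_s, onset)``; a sample exactly at
    onset belongs to the response, not the baseline. SD uses the n-1
    denominator. Fewer than two in-window samples raise
    :class:`InsufficientBaselineError`.
    """
    lo = stim.onset_s - cfg.baseline_window_s
    mask = (trace.time_s >= lo) & (trace.time_s < stim.onset_s)
    vals = trace.ratio_au[mask]
    if vals.size < 2:
        raise InsufficientBaselineError(
            f"cell {trace.cell_id!r}: {vals.size} baseline sample(s) in "
            f"[{lo:g}, {stim.onset_s:g}); need >= 2"
        )
    return BaselineStats(
        mean_au=float(np.mean(vals)),
        sd_au=float(np.std(vals, ddof=1)),
        window=(lo, stim.onset_s),
        n_samples=int(vals.size),
    )


def _runs(times: np.ndarray, above: np.ndarray, max_gap_s: float) -> list[tuple[int, int]]:
    """Maximal runs of suprathreshold samples with gaps <= max_gap_s.

    Returns (start_index, end_index) pairs, inclusive, into `times`.
    """
    runs: list[tuple[int, int]] = []
    start = None
    prev = None
    for i, ok in enumerate(above):
        if ok:
            if start is None:
                start = i
            elif times[i] - times[prev] > max_gap_s:
                runs.append((start, prev))
                start = i
            prev = i
        else:
            if start is not None:
                runs.append((start, prev))
                start = None
    if start is not None:
        runs.append((start, prev))
    return runs


def detect_response(
    trace: CalciumTrace,
    stim: StimulusEvent,
    base: BaselineStats,
    cfg: DetectorConfig = DetectorConfig(),
    window_end_s: float | None = None,
) -> ResponseCall:
    """Apply the >k_sd-SD / min_duration rule to the post-stimulus samples.

    Samples from stimulus onset (inclusive) to ``window_end_s`` (exclusive;
    default: end of trace) are examined against the threshold
    ``mean + k_sd * sd`` (strict). ``window_end_s`` is normally the onset of
    the next stimulus.
    """
    threshold = base.mean_au + cfg.k_sd * base.sd_au
    if window_end_s is None:
        mask = trace.time_s >= stim.onset_s
    else:
        mask = (trace.time_s >= stim.onset_s) & (trace.time_s < window_end_s)
    t = trace.time_s[mask]
    r = trace.ratio_au[mask]
    if t.size == 0:
        return ResponseCall(False, threshold, 0.0, float("nan"))
    above = r > threshold
    runs = _runs(t, above, cfg.max_gap_s)
    best = 0.0
    hit: tuple[int, int] | None = None
    for i, j in runs:
        dur = float(t[j] - t[i])
        if dur > best:
            best = dur
        if dur >= cfg.min_duration_s and hit is None:
            hit = (i, j)
    if hit is not None:
        return ResponseCall(
            True, threshold, best, float(r.max()), float(t[hit[0]]), float(t[hit[1]])
        )
    return ResponseCall(False, threshold, best, float(r.max()))


def classify_cells(
    traces: Iterable[CalciumTrace],
    events: Mapping[str, Sequence[StimulusEvent]],
    cfg: DetectorConfig = DetectorConfig(),
    stimulus_label: str = "KCl",
) -> pd.DataFrame:
    """Label cells as type III by their KCl response.

    `events` maps cell_id to that cell's stimulus presentations; the first
    event whose label contains `stimulus_label` is used. Cells whose baseline
    cannot be computed are labelled ``unclassifiable`` rather than dropped.

    Returns a DataFrame with columns cell_id, responded, peak_au, max_run_s,
    label (``TypeIII`` / ``unclassified`` / ``unclassifiable``).
    """
    rows = []
    for trace in traces:
        try:
            evs = events[trace.cell_id]
        except KeyError:
            raise KeyError(f"no stimulus events for cell {trace.cell_id!r}") from None
        kcl = [e for e in evs if stimulus_label in e.label]
        if not kcl:
            raise ValueError(f"cell {trace.cell_id!r} has no {stimulus_label!r} event")
        stim = kcl[0]
        later = sorted(e.onset_s for e in evs if e.onset_s > stim.onset_s)
        end = later[0] if later else None
        try:
            base = compute_baseline(trace, stim, cfg)
        except InsufficientBaselineError:
            rows.append(
                dict(cell_id=trace.cell_id, responded=pd.NA, peak_au=np.nan,
                     max_run_s=np.nan, label="unclassifiable")
            )
            continue
        call = detect_response(trace, stim, base, cfg, window_end_s=end)
        rows.append(
            dict(
                cell_id=trace.cell_id,
                responded=call.responded,
                peak_au=call.peak_au,
                max_run_s=call.max_run_duration_s,
                label="TypeIII" if call.responded else "unclassified",
            )
        )
    return pd.DataFrame(rows, columns=["cell_id", "responded", "peak_au", "max_run_s", "label"])
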
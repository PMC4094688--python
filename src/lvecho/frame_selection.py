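"""Best-frame selection in 20-second intervals from contrast arrival.

The image series of one injection is divided into contiguous 20-s windows
anchored at the detected inflow of contrast into the left ventricle; from
each window the frame with the highest and most homogeneous cavity
enhancement is picked. "Highest and most homogeneous" is operationalized as

    score = mean(ROI) − λ · CV(ROI),      λ = 0.5 by default,

which is monotone in both desiderata with a single trade-off parameter.
The duration of clinically useful enhancement is the last contiguous
interval whose selected frame still scores above a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import FrameSequence

INTERVAL_S = 20.0


class NoInflowError(RuntimeError):
    """No frame's ROI intensity rises above baseline — no inflow detected."""


@dataclass(frozen=True)
class IntervalSelection:
    interval_index: int
    interval_bounds: tuple[float, float]  # [start, end) in seconds
    selected_frame: int
    enhancement_score: float


def roi_means(seq: FrameSequence, roi: np.ndarray) -> np.ndarray:
    if not roi.any():
        raise ValueError("ROI is empty")
    return np.array([float(f[roi].mean()) for f in seq.frames])


def detect_arrival(
    seq: FrameSequence, roi: np.ndarray, threshold_frac: float = 0.2
) -> float:
    """Timestamp of contrast arrival in the ROI.

    Baseline is the mean ROI intensity over the frames before any rise;
    arrival is the first frame whose mean exceeds
    baseline + threshold_frac·(max − baseline). The definition is relative,
    hence invariant to a uniform intensity offset.
    """
    if len(seq) == 0:
        raise ValueError("empty sequence")
    m = roi_means(seq, roi)
    m_max = m.max()
    # frames before any rise: those preceding the first clear departure
    # (5% of the full swing) from the initial level
    rise = np.nonzero(m > m[0] + 0.05 * (m_max - m[0]))[0]
    baseline = m[: rise[0]].mean() if len(rise) and rise[0] > 0 else m[0]
    swing = m_max - baseline
    if swing <= 1e-12 or not np.isfinite(swing):
        raise NoInflowError("no inflow detected")
    above = np.nonzero(m > baseline + threshold_frac * swing)[0]
    if len(above) == 0:
        raise NoInflowError("no inflow detected")
    return float(seq.timestamps[above[0]])


def score_enhancement(frame: np.ndarray, roi: np.ndarray, lam: float = 0.5) -> float:
    """mean − λ·CV of the ROI intensities; higher is better."""
    if not roi.any():
        raise ValueError("ROI is empty")
    vals = frame[roi]
    mean = float(vals.mean())
    if mean <= 0:
        return mean
    cv = float(vals.std()) / mean
    return mean - lam * cv


def select_frames(
    seq: FrameSequence,
    roi: np.ndarray,
    lam: float = 0.5,
    threshold_frac: float = 0.2,
) -> list[IntervalSelection]:
    """One selection per 20-s window between arrival and the last frame.

    Within each window the frame maximizing :func:`score_enhancement` is
    chosen; ties break to the earliest frame (argmax convention).
    """
    t_arrival = detect_arrival(seq, roi, threshold_frac)
    t_last = float(seq.timestamps[-1])
    n_intervals = int(np.floor((t_last - t_arrival) / INTERVAL_S)) + 1
    selections = []
    for k in range(n_intervals):
        lo = t_arrival + k * INTERVAL_S
        hi = lo + INTERVAL_S
        idx = np.nonzero((seq.timestamps >= lo) & (seq.timestamps < hi))[0]
        if len(idx) == 0:
            continue
        scores = [score_enhancement(seq.frames[i], roi, lam) for i in idx]
        best = idx[int(np.argmax(scores))]
        selections.append(
            IntervalSelection(
                interval_index=k,
                interval_bounds=(lo, hi),
                selected_frame=int(best),
                enhancement_score=float(max(scores)),
            )
        )
    return selections


def useful_duration(
    selections: list[IntervalSelection], min_score: float = 0.25
) -> str:
    """Label of the last contiguous interval (from arrival) whose selected
    frame scores at least ``min_score``; "none" if the first interval fails.

    Labels follow the clinical convention "0–20 s", "20–40 s", ...
    """
    if not selections:
        raise ValueError("no interval selections")
    last = -1
    for sel in sorted(selections, key=lambda s: s.interval_index):
        if sel.interval_index != last + 1:
            break
        if sel.enhancement_score >= min_score:
            last = sel.interval_index
        else:
            break
    if last < 0:
        return "none"
    return f"{int(last * INTERVAL_S)}–{int((last + 1) * INTERVAL_S)} s"


def useful_duration_end_s(selections, min_score: float = 0.25) -> float:
    """Upper bound (s) of the useful-duration label; 0 for "none"."""
    label = useful_duration(selections, min_score)
    if label == "none":
        return 0.0
    return float(label.split("–")[1].split()[0])
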
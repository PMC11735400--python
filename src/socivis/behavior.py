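"""Behavior-epoch quantification and stimulus-locked fluorescence metrics.

Works on three inputs: per-frame, per-trajectory classifier scores (an
ethogram, JAABA-style), a stimulus protocol (acclimation followed by
alternating stimulus-on/off blocks), and raw fluorescence traces.

Aggression is an arena-level quantity: it is the interaction of several
flies, so the percentage aggression sums scores across trajectories and
normalizes by the number of flies in the arena, never per fly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ETHOGRAM_COLUMNS = ("frame", "fly_id", "behavior", "score")


@dataclass
class Ethogram:
    """Per-frame, per-trajectory behavior scores.

    ``data`` has columns ``frame, fly_id, behavior, score``; scores are in
    [0, 1] (continuous classifier scores or binary labels).
    """

    data: pd.DataFrame
    fps: float

    def __post_init__(self) -> None:
        missing = [c for c in ETHOGRAM_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"ethogram missing columns {missing}")
        s = self.data["score"]
        if ((s < 0) | (s > 1)).any():
            raise ValueError("ethogram scores must lie in [0, 1]")

    def behavior_matrix(self, behavior: str) -> pd.DataFrame:
        """frames x flies score matrix for one behavior (missing -> 0)."""
        sub = self.data[self.data["behavior"] == behavior]
        mat = sub.pivot_table(index="frame", columns="fly_id", values="score",
                              aggfunc="last")
        frames = np.arange(self.data["frame"].min(), self.data["frame"].max() + 1)
        return mat.reindex(frames).fillna(0.0)


@dataclass(frozen=True)
class StimulusProtocol:
    """Acclimation then alternating constant-stimulus on/off blocks.

    Defaults: 30 s acclimation, six 30 s stimulus blocks separated by 30 s
    off periods, at the tracker's 170 fps.
    """

    acclimation_s: float = 30.0
    n_blocks: int = 6
    on_s: float = 30.0
    off_s: float = 30.0
    fps: float = 170.0

    @property
    def total_frames(self) -> int:
        total_s = self.acclimation_s + self.n_blocks * self.on_s \
            + (self.n_blocks - 1) * self.off_s
        return int(round(total_s * self.fps))


@dataclass
class FluorescenceTrace:
    """A fluorescence series with its baseline and normalized response."""

    F: np.ndarray
    rate_hz: float
    onset_index: int
    F0: float | None = None
    dff: np.ndarray | None = field(default=None)


# ---------------------------------------------------------------------------
# aggression percentage


def percent_aggression(ethogram: Ethogram, n_flies: int,
                       window: tuple[int, int] | None = None,
                       behavior: str = "aggression",
                       binarize: bool = True, threshold: float = 0.5,
                       ) -> tuple[pd.Series, float]:
    """Percentage aggression per frame, and its mean over a window.

    Per frame: the sum of aggression scores over all trajectories currently
    performing aggression, divided by the number of flies in the arena,
    times 100. With ``binarize`` (default) continuous scores become 0/1 at
    ``threshold``; otherwise raw scores are summed.

    ``window`` is a half-open frame interval; None means the whole series.
    Returns ``(per_frame_series, scalar_mean)``.
    """
    if n_flies < 1:
        raise ValueError("n_flies must be >= 1")
    mat = ethogram.behavior_matrix(behavior)
    scores = (mat >= threshold).astype(float) if binarize else mat
    series = scores.sum(axis=1) / n_flies * 100.0
    series.name = "percent_aggression"
    if window is not None:
        lo, hi = window
        in_win = series.loc[(series.index >= lo) & (series.index < hi)]
        if in_win.empty:
            raise ValueError("window lies outside the recording")
        scalar = float(in_win.mean())
    else:
        scalar = float(series.mean())
    return series, scalar


# ---------------------------------------------------------------------------
# stimulus windows and paired comparisons


def stimulus_windows(protocol: StimulusProtocol,
                     ) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Half-open frame intervals for stimulus-on and stimulus-off periods.

    The first on-window starts when acclimation ends; off-windows are the
    inter-stimulus gaps (the acclimation itself is not an off-window).
    """
    fps = protocol.fps
    on_f = int(round(protocol.on_s * fps))
    off_f = int(round(protocol.off_s * fps))
    t = int(round(protocol.acclimation_s * fps))
    on, off = [], []
    for b in range(protocol.n_blocks):
        on.append((t, t + on_f))
        t += on_f
        if b < protocol.n_blocks - 1:
            off.append((t, t + off_f))
            t += off_f
    return on, off


def pre_post_comparison(series: pd.Series, protocol: StimulusProtocol,
                        pre_mode: str = "three_periods",
                        n_analyzed: int = 3) -> tuple[float, float]:
    """Paired (pre, during) values of an arena-level metric.

    ``during`` is the metric's mean over the first ``n_analyzed``
    stimulus-on windows. ``pre`` depends on the mode:

    * ``"three_periods"`` — mean over the periods immediately preceding each
      analyzed stimulus window (the acclimation tail before the first block,
      then the off periods);
    * ``"first_15s"`` — only the first 15 s of the first pre-stimulus period
      (used when earlier stimuli contaminate later off periods).

    The pair feeds a standard paired nonparametric test (e.g. Wilcoxon
    signed-rank across arenas); the test itself is not re-implemented here.
    """
    on, _ = stimulus_windows(protocol)
    if len(series) < on[min(n_analyzed, len(on)) - 1][1]:
        raise ValueError("metric series is shorter than the protocol")
    analyzed = on[:n_analyzed]
    fps = protocol.fps

    def win_mean(lo: int, hi: int) -> float:
        return float(series.loc[(series.index >= lo) & (series.index < hi)].mean())

    during = float(np.mean([win_mean(lo, hi) for lo, hi in analyzed]))
    pre_windows = []
    for lo, hi in analyzed:
        length = hi - lo
        pre_windows.append((max(lo - length, 0), lo))
    if pre_mode == "three_periods":
        pre = float(np.mean([win_mean(lo, hi) for lo, hi in pre_windows]))
    elif pre_mode == "first_15s":
        lo, _hi = pre_windows[0]
        pre = win_mean(lo, lo + int(round(15.0 * fps)))
    else:
        raise ValueError(f"unknown pre_mode {pre_mode!r}")
    return pre, during


def bin_timecourse(series: np.ndarray | pd.Series, bin_frames: int = 60) -> np.ndarray:
    """Means of non-overlapping bins (default 60 frames = 0.35 s at 170 fps);
    a trailing partial bin is averaged over the frames it has."""
    if bin_frames < 1:
        raise ValueError("bin_frames must be >= 1")
    x = np.asarray(series, dtype=float)
    n_full = len(x) // bin_frames
    out = []
    if n_full:
        out.append(x[: n_full * bin_frames].reshape(n_full, bin_frames).mean(axis=1))
    if len(x) % bin_frames:
        out.append([x[n_full * bin_frames:].mean()])
    return np.concatenate(out) if out else np.array([])


# ---------------------------------------------------------------------------
# courtship epochs


def detect_courtship_epochs(distance_mm: np.ndarray | pd.Series,
                            fixation_angle_deg: np.ndarray | pd.Series,
                            fps: float,
                            dist_thresh_mm: float = 3.0,
                            angle_thresh_deg: float = 20.0,
                            min_dur_s: float = 60.0,
                            end_frame: int | None = None,
                            ) -> list[tuple[int, int]]:
    """First-instance courtship epoch from a dyad's distance/fixation series.

    The epoch starts at the first frame opening a run with inter-fly
    distance < ``dist_thresh_mm`` and |fixation angle| < ``angle_thresh_deg``
    lasting strictly longer than ``min_dur_s``; it ends at ``end_frame``
    (e.g. a copulation label) or the end of the series. Returns [] when no
    run qualifies.
    """
    d = np.asarray(distance_mm, dtype=float)
    ang = np.asarray(fixation_angle_deg, dtype=float)
    if d.shape != ang.shape:
        raise ValueError("distance and angle series must align")
    ok = (d < dist_thresh_mm) & (np.abs(ang) < angle_thresh_deg)
    min_frames = int(np.floor(min_dur_s * fps)) + 1  # strictly longer
    run_start = None
    for i, flag in enumerate(np.concatenate([ok, [False]])):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start >= min_frames:
                end = end_frame if end_frame is not None else len(d)
                return [(run_start, int(end))]
            run_start = None
    return []


# ---------------------------------------------------------------------------
# fluorescence


def delta_f_over_f(trace: FluorescenceTrace, baseline_s: float = 10.0,
                   background: np.ndarray | None = None) -> FluorescenceTrace:
    """ΔF/F with a pre-stimulation baseline.

    F0 is the mean fluorescence over the ``baseline_s`` seconds before the
    stimulation onset; ΔF/F = (F - F0) / F0. An optional background-ROI
    trace is subtracted from F before normalization.
    """
    F = np.asarray(trace.F, dtype=float)
    if background is not None:
        F = F - np.asarray(background, dtype=float)
    n_base = int(round(baseline_s * trace.rate_hz))
    if trace.onset_index < n_base:
        raise ValueError(
            f"need >= {baseline_s} s of pre-onset samples ({n_base}), "
            f"onset at {trace.onset_index}")
    F0 = float(F[trace.onset_index - n_base: trace.onset_index].mean())
    if F0 <= 0:
        raise ValueError(f"non-positive baseline F0={F0}")
    return FluorescenceTrace(F=F, rate_hz=trace.rate_hz,
                             onset_index=trace.onset_index,
                             F0=F0, dff=(F - F0) / F0)
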
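"""Egocentric visual features of a target fly in a subject fly's frame.

Trackers fit each fly with an oriented ellipse per frame. From two such
poses we compute, in the subject's reference frame (subject centroid at the
origin, facing 0°):

* angular position θ = atan2(y', x') and angular velocity φ = dθ/dt,
* angular width  w = 2·arctan(R/d) where R is half the target-ellipse chord
  perpendicular to the line of sight and d the subject-nose-to-target-centroid
  distance,
* angular height h = 2·arctan((H/2)/d) with real fly height H fixed at 1 mm,
* the occluded angle: the angle between the two lines through the subject's
  nose point tangent to the target's fitted ellipse.

Angles are held in radians internally and reported in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

TRAJECTORY_COLUMNS = ("frame", "fly_id", "x_mm", "y_mm", "heading_rad", "a_mm", "b_mm")

#: assumed real height of a fly, mm
DEFAULT_FLY_HEIGHT_MM = 1.0


@dataclass(frozen=True)
class Pose:
    """One fly on one frame: centroid, heading and fitted ellipse (mm, rad).

    ``a`` and ``b`` are the semi-major and semi-minor axes; the nose point is
    the anterior-most point of the ellipse along the heading axis.
    """

    x: float
    y: float
    heading: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError(f"need a >= b > 0, got a={self.a}, b={self.b}")

    @property
    def nose(self) -> tuple[float, float]:
        return (self.x + self.a * math.cos(self.heading),
                self.y + self.a * math.sin(self.heading))

    @property
    def body_length(self) -> float:
        return 2.0 * self.a


@dataclass
class TrajectorySet:
    """Per-frame poses for all flies in an arena (FlyTracker-like layout)."""

    data: pd.DataFrame  # columns TRAJECTORY_COLUMNS
    fps: float
    arena_diameter_mm: float = 53.3

    def __post_init__(self) -> None:
        missing = [c for c in TRAJECTORY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trajectory table missing columns {missing}")
        self.data = self.data.sort_values(["fly_id", "frame"]).reset_index(drop=True)

    @property
    def fly_ids(self) -> list:
        return sorted(self.data["fly_id"].unique().tolist())

    @property
    def frames(self) -> np.ndarray:
        return np.sort(self.data["frame"].unique())

    def pose(self, fly_id, frame) -> Pose:
        row = self.data[(self.data["fly_id"] == fly_id) & (self.data["frame"] == frame)]
        if row.empty:
            raise KeyError(f"no pose for fly {fly_id} at frame {frame}")
        r = row.iloc[0]
        return Pose(r.x_mm, r.y_mm, r.heading_rad, r.a_mm, r.b_mm)

    def fly(self, fly_id) -> pd.DataFrame:
        return self.data[self.data["fly_id"] == fly_id].set_index("frame")


# ---------------------------------------------------------------------------
# frame transforms and scalar features


def to_egocentric(subject: Pose, target_xy: tuple[float, float]) -> tuple[float, float]:
    """Map a world point into the subject's frame (subject centroid at the
    origin, heading along +x). A rigid transform: distances are preserved."""
    dx = target_xy[0] - subject.x
    dy = target_xy[1] - subject.y
    c, s = math.cos(-subject.heading), math.sin(-subject.heading)
    return (c * dx - s * dy, s * dx + c * dy)


def angular_position(x: float, y: float) -> float:
    """Full-quadrant angular position θ in degrees, in (-180, 180].

    Returns NaN (flagged undefined) for the origin.
    """
    if x == 0.0 and y == 0.0:
        return math.nan
    theta = math.degrees(math.atan2(y, x))
    return 180.0 if theta == -180.0 else theta


def angular_velocity(theta_deg: np.ndarray, fps: float) -> np.ndarray:
    """Angular velocity φ = dθ/dt in degrees/s from a θ series in degrees.

    The series is unwrapped before differencing so ±180° crossings do not
    produce spikes; central differences interior, one-sided at the ends.
    NaN frames propagate NaN into every difference that touches them.
    """
    theta_deg = np.asarray(theta_deg, dtype=float)
    if fps <= 0:
        raise ValueError("fps must be positive")
    if theta_deg.ndim != 1 or theta_deg.size < 2:
        raise ValueError("need a 1-D series of length >= 2")
    # unwrap each contiguous valid run separately: a blanket np.unwrap would
    # let one NaN poison the cumulative correction for the rest of the series
    unwrapped = np.full_like(theta_deg, np.nan)
    valid = np.isfinite(theta_deg)
    if valid.any():
        edges = np.flatnonzero(np.diff(np.concatenate(([False], valid, [False]))))
        for start, stop in edges.reshape(-1, 2):
            seg = theta_deg[start:stop]
            unwrapped[start:stop] = np.degrees(np.unwrap(np.radians(seg)))
    phi = np.gradient(unwrapped) * fps
    phi[~valid] = np.nan  # gradient would otherwise bridge across a NaN frame
    return phi


def cross_section_half_length(target: Pose, sight_from: tuple[float, float]) -> float:
    """Half-length R of the target-ellipse chord through the centroid,
    perpendicular to the line of sight from ``sight_from`` (the subject's
    nose) to the target centroid. Always b <= R <= a.
    """
    if target.a <= 0 or target.b <= 0:
        raise ValueError("degenerate target ellipse")
    ux = target.x - sight_from[0]
    uy = target.y - sight_from[1]
    if ux == 0 and uy == 0:
        raise ValueError("sight line is degenerate (coincident points)")
    # chord direction is perpendicular to the sight line; express its angle
    # alpha relative to the ellipse's major axis
    sight_angle = math.atan2(uy, ux)
    alpha = (sight_angle + math.pi / 2.0) - target.heading
    ca, sa = math.cos(alpha), math.sin(alpha)
    # polar radius of an axis-aligned ellipse in direction alpha
    return (target.a * target.b /
            math.hypot(target.b * ca, target.a * sa))


def angular_width(R: float, d: float) -> float:
    """w = 2·arctan(R/d), degrees."""
    if R <= 0:
        raise ValueError("R must be positive")
    if d <= 0:
        return math.nan
    return math.degrees(2.0 * math.atan(R / d))


def angular_height(d: float, fly_height_mm: float = DEFAULT_FLY_HEIGHT_MM) -> float:
    """h = 2·arctan((height/2)/d), degrees; real fly height fixed at 1 mm."""
    if d <= 0:
        return math.nan
    return math.degrees(2.0 * math.atan((fly_height_mm / 2.0) / d))


def angle_subtended_tangents(nose_point: tuple[float, float], target: Pose,
                             inside: str = "nan") -> float:
    """Occluded angle: angle in degrees between the two lines through
    ``nose_point`` tangent to the target's fitted ellipse.

    For a nose point inside or on the ellipse the angle is undefined;
    ``inside`` selects NaN (default) or ``"full"`` -> 360°.
    """
    if target.a <= 0 or target.b <= 0:
        raise ValueError("degenerate target ellipse")
    # move to the ellipse's axis frame
    dx = nose_point[0] - target.x
    dy = nose_point[1] - target.y
    c, s = math.cos(-target.heading), math.sin(-target.heading)
    px = c * dx - s * dy
    py = s * dx + c * dy
    a2, b2 = target.a ** 2, target.b ** 2
    s1 = px * px / a2 + py * py / b2 - 1.0
    if s1 <= 0:
        if inside == "full":
            return 360.0
        return math.nan
    # pair of tangents S*S1 = T^2; quadratic part Ax^2 + 2Hxy + By^2
    A = s1 / a2 - (px * px) / (a2 * a2)
    B = s1 / b2 - (py * py) / (b2 * b2)
    H = -(px * py) / (a2 * b2)
    disc = H * H - A * B
    disc = max(disc, 0.0)
    return math.degrees(math.atan2(2.0 * math.sqrt(disc), A + B))


# ---------------------------------------------------------------------------
# whole-arena queries


def nearest_conspecific(trajectories: TrajectorySet, subject, frame):
    """(target id, distance): the fly minimizing subject-nose-to-centroid
    distance on a frame. Ties break to the lower id; NaN positions are
    excluded from candidacy."""
    sub = trajectories.pose(subject, frame)
    nose = sub.nose
    frame_rows = trajectories.data[trajectories.data["frame"] == frame]
    best = None
    for _, r in frame_rows.sort_values("fly_id").iterrows():
        if r.fly_id == subject or not (np.isfinite(r.x_mm) and np.isfinite(r.y_mm)):
            continue
        d = math.hypot(r.x_mm - nose[0], r.y_mm - nose[1])
        if best is None or d < best[1]:
            best = (r.fly_id, d)
    if best is None:
        raise ValueError(f"no valid conspecific at frame {frame}")
    return best


def flies_within_body_lengths(trajectories: TrajectorySet, subject, frame,
                              k: float = 2.0) -> int:
    """Count of other flies with centroid-to-centroid distance at most
    ``k`` subject body lengths (body length = 2 x subject semi-major axis)."""
    sub = trajectories.pose(subject, frame)
    radius = k * sub.body_length
    if radius <= 0:
        return 0
    frame_rows = trajectories.data[trajectories.data["frame"] == frame]
    n = 0
    for _, r in frame_rows.iterrows():
        if r.fly_id == subject or not (np.isfinite(r.x_mm) and np.isfinite(r.y_mm)):
            continue
        if math.hypot(r.x_mm - sub.x, r.y_mm - sub.y) <= radius:
            n += 1
    return n


# ---------------------------------------------------------------------------
# per-frame feature table


def compute_features(trajectories: TrajectorySet, subject, target=None,
                     fly_height_mm: float = DEFAULT_FLY_HEIGHT_MM) -> pd.DataFrame:
    """Per-frame egocentric features of ``target`` (or, when None, the
    nearest conspecific chosen per frame) as seen by ``subject``.

    Returns a frame-indexed table with columns
    ``target_id, theta_deg, phi_deg_s, w_deg, h_deg, anglesub_deg, d_mm, R_mm``.
    """
    frames = trajectories.frames
    rows = []
    for f in frames:
        sub = trajectories.pose(subject, f)
        if target is None:
            tid, _ = nearest_conspecific(trajectories, subject, f)
        else:
            tid = target
        tgt = trajectories.pose(tid, f)
        nose = sub.nose
        d = math.hypot(tgt.x - nose[0], tgt.y - nose[1])
        ex, ey = to_egocentric(sub, (tgt.x, tgt.y))
        theta = angular_position(ex, ey)
        if d > 0:
            R = cross_section_half_length(tgt, nose)
            w = angular_width(R, d)
            h = angular_height(d, fly_height_mm)
            asub = angle_subtended_tangents(nose, tgt)
        else:
            R = w = h = asub = math.nan
        rows.append((f, tid, theta, w, h, asub, d, R))
    out = pd.DataFrame(rows, columns=["frame", "target_id", "theta_deg", "w_deg",
                                      "h_deg", "anglesub_deg", "d_mm", "R_mm"])
    out["phi_deg_s"] = angular_velocity(out["theta_deg"].to_numpy(), trajectories.fps)
    return out.set_index("frame")[
        ["target_id", "theta_deg", "phi_deg_s", "w_deg", "h_deg",
         "anglesub_deg", "d_mm", "R_mm"]]


def summarize_features(features: pd.DataFrame,
                       epoch_mask: np.ndarray | pd.Series,
                       columns: Iterable[str] = ("w_deg", "h_deg", "theta_deg", "d_mm"),
                       ) -> pd.DataFrame:
    """NaN-aware mean and s.d. of selected feature columns over masked frames.

    Returns a table indexed by feature with columns ``mean, sd, n_frames``.
    """
    mask = np.asarray(epoch_mask, dtype=bool)
    if mask.shape[0] != len(features):
        raise ValueError("mask length must match feature table length")
    if not mask.any():
        raise ValueError("empty epoch mask: summary undefined")
    sel = features.loc[mask, list(columns)]
    out = pd.DataFrame({
        "mean": sel.mean(skipna=True),
        "sd": sel.std(skipna=True, ddof=1),
        "n_frames": sel.notna().sum(),
    })
    return out
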
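"""Frame-to-frame linking of localizations into trajectories.

Between each pair of consecutive frames the linker solves a global
assignment problem: over all one-to-one matchings whose links are all
shorter than ``max_disp_nm``, it minimises the total squared
displacement (equivalently, it minimises
``sum(d^2) + max_disp^2 * n_unmatched``, which always prefers a feasible
link over leaving both ends loose).  This is solved exactly with the
Hungarian algorithm on an augmented cost matrix, so the result is
deterministic and independent of the order of localizations within a
frame.

Tracks that find no continuation within ``max_gap_frames`` terminate
(default 0: a particle that disappears for one frame ends its
trajectory).  Detections never linked to any other frame are
**single-frame events** — a distinct physical class of sub-frame surface
encounters — and are reported separately from trajectories, which
require at least two frames.  The dwell time of either is its frame
count times the frame period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import InvalidParameterError
from .polymer import frame_period_ms

__all__ = [
    "LinkConfig",
    "Trajectory",
    "link",
    "dwell_time",
    "trajectories_to_dataframe",
    "trajectory_summary",
]

_BIG = 1e30


@dataclass(frozen=True)
class LinkConfig:
    """Linking parameters.

    ``max_disp_nm`` bounds consecutive-frame links.  When
    ``max_gap_frames > 0``, a track missing for up to that many frames
    may be re-acquired, but only within ``gap_max_disp_nm`` (default:
    same as ``max_disp_nm``).  A tighter gap radius is appropriate when
    the per-frame radius is deliberately generous — e.g. to ride through
    centroid excursions of transiently overlapping blobs — while a
    re-acquired molecule should be nearly where it was lost.
    """

    max_disp_nm: float
    max_gap_frames: int = 0
    gap_max_disp_nm: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.max_disp_nm) or self.max_disp_nm <= 0:
            raise InvalidParameterError(
                f"max_disp_nm must be finite and > 0, got {self.max_disp_nm}"
            )
        if self.max_gap_frames < 0:
            raise InvalidParameterError("max_gap_frames must be >= 0")
        if self.gap_max_disp_nm is not None and self.gap_max_disp_nm <= 0:
            raise InvalidParameterError("gap_max_disp_nm must be > 0")

    @property
    def effective_gap_disp_nm(self) -> float:
        return (
            self.gap_max_disp_nm
            if self.gap_max_disp_nm is not None
            else self.max_disp_nm
        )


@dataclass
class Trajectory:
    """A time-linked sequence of localizations of one molecule."""

    trajectory_id: int
    frames: np.ndarray
    x_nm: np.ndarray
    y_nm: np.ndarray
    mean_abs_contrast: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x_nm = np.asarray(self.x_nm, dtype=float)
        self.y_nm = np.asarray(self.y_nm, dtype=float)
        if self.mean_abs_contrast is None:
            self.mean_abs_contrast = np.full(len(self.frames), np.nan)
        if np.any(np.diff(self.frames) < 1):
            raise InvalidParameterError("trajectory frames must strictly increase")

    @property
    def n_frames(self) -> int:
        """Number of localizations (equals the span when no gaps)."""
        return len(self.frames)

    @property
    def span_frames(self) -> int:
        """Frames from first to last detection inclusive.

        With gap closing a bridged frame still counts toward the dwell:
        the molecule was present, merely missed.
        """
        return int(self.frames[-1] - self.frames[0] + 1)

    @property
    def steps_nm(self) -> np.ndarray:
        """(n-1, 2) per-frame displacement vectors."""
        return np.column_stack([np.diff(self.x_nm), np.diff(self.y_nm)])

    def dwell_ms(self, frame_rate_hz: float) -> float:
        return dwell_time(self, frame_rate_hz)


def dwell_time(traj: Trajectory, frame_rate_hz: float) -> float:
    """Dwell time = frame span times the frame period (ms).

    Without gap closing the span equals the localization count, the
    trajectory-duration definition used throughout.
    """
    return traj.span_frames * frame_period_ms(frame_rate_hz)


def _assign(
    prev_xy: np.ndarray,
    cur_xy: np.ndarray,
    max_disp_nm: float,
    head_radius_nm: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Globally optimal matching between two point sets.

    Returns (prev_index, cur_index) pairs; minimises total squared
    displacement with an unmatched penalty of ``max_disp^2`` per loose
    end, with no link longer than each head's radius (``max_disp_nm``
    unless ``head_radius_nm`` tightens it).
    """
    n, m = len(prev_xy), len(cur_xy)
    if n == 0 or m == 0:
        return []
    d2 = ((prev_xy[:, None, :] - cur_xy[None, :, :]) ** 2).sum(axis=2)
    b = max_disp_nm**2
    limit2 = (
        np.full((n, 1), b)
        if head_radius_nm is None
        else (head_radius_nm[:, None] ** 2)
    )
    feasible = d2 <= limit2
    cost = np.full((n + m, n + m), 0.0)
    cost[:n, :m] = np.where(feasible, d2, _BIG)
    cost[:n, m:] = _BIG
    cost[np.arange(n), m + np.arange(n)] = b  # track left unmatched
    cost[n:, :m] = _BIG
    cost[n + np.arange(m), np.arange(m)] = b  # new localization unmatched
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(i), int(j))
        for i, j in zip(rows, cols)
        if i < n and j < m and feasible[i, j]
    ]


def link(
    locs: pd.DataFrame, cfg: LinkConfig
) -> tuple[list[Trajectory], pd.DataFrame]:
    """Partition a localization table into trajectories and single-frame events.

    ``locs`` needs columns ``frame``, ``x_nm``, ``y_nm`` (and optionally
    ``mean_abs_contrast``).  Every input row ends up in exactly one
    trajectory (>= 2 frames) or in the single-frame-event table; row
    counts are conserved.
    """
    if len(locs) == 0:
        return [], locs.copy()
    locs = locs.sort_values("frame", kind="stable").reset_index(drop=True)
    has_contrast = "mean_abs_contrast" in locs.columns
    frames = locs["frame"].to_numpy(dtype=int)
    xy = locs[["x_nm", "y_nm"]].to_numpy(dtype=float)

    # active track: dict with row indices, last frame, last xy
    active: list[dict] = []
    finished: list[dict] = []
    for f in range(frames.min(), frames.max() + 1):
        cur_idx = np.flatnonzero(frames == f)
        # sort current detections by label order for deterministic tie-breaks
        heads = [tr for tr in active if f - tr["last_frame"] <= cfg.max_gap_frames + 1]
        head_ids = {id(tr) for tr in heads}
        finished.extend(tr for tr in active if id(tr) not in head_ids)
        matched_cur: set[int] = set()
        if heads and len(cur_idx):
            prev_xy = np.array([tr["last_xy"] for tr in heads])
            radii = np.array(
                [
                    cfg.max_disp_nm
                    if f - tr["last_frame"] == 1
                    else cfg.effective_gap_disp_nm
                    for tr in heads
                ]
            )
            pairs = _assign(prev_xy, xy[cur_idx], cfg.max_disp_nm, radii)
            for i, j in pairs:
                tr = heads[i]
                row = int(cur_idx[j])
                tr["rows"].append(row)
                tr["last_frame"] = f
                tr["last_xy"] = xy[row]
                matched_cur.add(j)
        # unmatched current localizations start new tracks
        for j, row in enumerate(cur_idx):
            if j not in matched_cur:
                active_new = {
                    "rows": [int(row)],
                    "last_frame": f,
                    "last_xy": xy[row],
                }
                heads.append(active_new)
        active = heads
    finished.extend(active)
    # deterministic output order: by first frame then first row index
    finished.sort(key=lambda tr: (frames[tr["rows"][0]], tr["rows"][0]))

    trajectories: list[Trajectory] = []
    single_rows: list[int] = []
    tid = 0
    for tr in finished:
        rows = tr["rows"]
        if len(rows) == 1:
            single_rows.append(rows[0])
            continue
        sub = locs.iloc[rows]
        trajectories.append(
            Trajectory(
                trajectory_id=tid,
                frames=sub["frame"].to_numpy(dtype=int),
                x_nm=sub["x_nm"].to_numpy(dtype=float),
                y_nm=sub["y_nm"].to_numpy(dtype=float),
                mean_abs_contrast=(
                    sub["mean_abs_contrast"].to_numpy(dtype=float)
                    if has_contrast
                    else None
                ),
            )
        )
        tid += 1
    singles = locs.iloc[sorted(single_rows)].reset_index(drop=True)
    return trajectories, singles


def trajectories_to_dataframe(trajs: list[Trajectory]) -> pd.DataFrame:
    """Long-format table: one row per (trajectory, frame)."""
    if not trajs:
        return pd.DataFrame(
            columns=["trajectory_id", "frame", "x_nm", "y_nm", "mean_abs_contrast"]
        )
    parts = [
        pd.DataFrame(
            {
                "trajectory_id": t.trajectory_id,
                "frame": t.frames,
                "x_nm": t.x_nm,
                "y_nm": t.y_nm,
                "mean_abs_contrast": t.mean_abs_contrast,
            }
        )
        for t in trajs
    ]
    return pd.concat(parts, ignore_index=True)


def trajectory_summary(trajs: list[Trajectory], frame_rate_hz: float) -> pd.DataFrame:
    """Per-trajectory summary: frame count and dwell time."""
    return pd.DataFrame(
        {
            "trajectory_id": [t.trajectory_id for t in trajs],
            "n_frames": [t.n_frames for t in trajs],
            "dwell_ms": [dwell_time(t, frame_rate_hz) for t in trajs],
        }
    )
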
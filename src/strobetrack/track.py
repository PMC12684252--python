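"""Linking localizations into per-cell diffusion trajectories.

Two-stage linear-assignment linking in the spirit of established
particle-tracking toolkits: stage 1 links detections between consecutive
frames by minimum-total-cost one-to-one assignment (cost = squared
distance, links beyond the search radius forbidden, non-link alternative
cost = radius^2); stage 2 joins track-segment ends to later segment
starts across 1..max_gap missing frames under the same radius.  Linking
is strictly per cell and fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "Trajectory",
    "enforce_density",
    "link",
    "filter_trajectories",
    "trajectories_to_table",
]

_BIG = 1e12


@dataclass
class Trajectory:
    """Time-ordered localizations of one molecule within one cell."""

    trajectory: int
    cell: int
    frames: np.ndarray  # observed frames, strictly increasing
    x: np.ndarray  # px
    y: np.ndarray  # px
    photons: np.ndarray
    gap_frames: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_observed(self) -> int:
        return len(self.frames)


def enforce_density(locs: pd.DataFrame, max_dots: int = 3) -> pd.DataFrame:
    """Drop every localization of any (cell, frame) holding more than
    ``max_dots`` dots; the frame becomes a gap candidate for that cell."""
    if locs.empty:
        return locs.copy()
    counts = locs.groupby(["cell", "frame"])["x_px"].transform("size")
    return locs[counts <= max_dots].reset_index(drop=True)


def _stage1_assign(cost: np.ndarray, radius2: float) -> list[tuple[int, int]]:
    """Jaqaman-style rectangular LAP with birth/death alternatives.

    ``cost`` holds squared distances (np.inf where the link is forbidden).
    Returns the list of (i, j) links in the optimal assignment.
    """
    n1, n2 = cost.shape
    full = np.full((n1 + n2, n1 + n2), _BIG)
    tl = np.where(np.isfinite(cost), cost, _BIG)
    full[:n1, :n2] = tl
    full[:n1, n2:] = np.where(np.eye(n1, dtype=bool), radius2, _BIG)
    full[n1:, :n2] = np.where(np.eye(n2, dtype=bool), radius2, _BIG)
    full[n1:, n2:] = 0.0
    rows, cols = linear_sum_assignment(full)
    return [
        (int(i), int(j))
        for i, j in zip(rows, cols)
        if i < n1 and j < n2 and full[i, j] < _BIG
    ]


def stage1_cost(points_a: np.ndarray, points_b: np.ndarray, radius: float) -> float:
    """Objective value of the optimal frame-pair assignment.

    Sum of squared link distances plus radius^2 for every unlinked point
    on either side — the quantity the LAP minimizes; exposed so it can be
    checked against exhaustive enumeration.
    """
    a, b = np.atleast_2d(points_a), np.atleast_2d(points_b)
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    cost = np.where(d2 <= radius**2, d2, np.inf)
    links = _stage1_assign(cost, radius**2)
    total = sum(cost[i, j] for i, j in links)
    total += radius**2 * (len(a) - len(links)) + radius**2 * (len(b) - len(links))
    return float(total)


def link(
    locs: pd.DataFrame,
    search_radius_px: float = 20.0,
    max_gap: int = 2,
) -> list[Trajectory]:
    """Link cell-assigned localizations into trajectories.

    ``locs`` must carry columns cell, frame, x_px, y_px, photons (the
    density rule should already have been applied).  Gap closing bridges
    1..``max_gap`` missing frames at the same search radius; bridged
    frames are recorded in ``gap_frames``.  Output ordering is
    deterministic: by (cell, first frame, first x).
    """
    r2 = search_radius_px**2
    segments: list[dict] = []
    if not locs.empty:
        locs = locs.sort_values(["cell", "frame", "x_px", "y_px"], kind="mergesort")
        for cell, sub in locs.groupby("cell", sort=True):
            segments.extend(_link_cell(sub, int(cell), search_radius_px))
    # stage 2: gap closing on segment ends/starts, per cell
    segments = _close_gaps(segments, search_radius_px, max_gap)
    segments.sort(key=lambda s: (s["cell"], s["frames"][0], s["x"][0]))
    out = []
    for i, s in enumerate(segments):
        out.append(
            Trajectory(
                trajectory=i,
                cell=s["cell"],
                frames=np.asarray(s["frames"], dtype=int),
                x=np.asarray(s["x"], dtype=float),
                y=np.asarray(s["y"], dtype=float),
                photons=np.asarray(s["photons"], dtype=float),
                gap_frames=np.asarray(sorted(s["gaps"]), dtype=int),
            )
        )
    return out


def _link_cell(sub: pd.DataFrame, cell: int, radius: float) -> list[dict]:
    r2 = radius**2
    frames = np.sort(sub["frame"].unique())
    open_segs: dict[int, dict] = {}  # index in previous frame -> segment
    done: list[dict] = []
    prev_pts: np.ndarray | None = None
    prev_frame = None
    for f in frames:
        rows = sub[sub["frame"] == f]
        pts = rows[["x_px", "y_px"]].to_numpy()
        ph = rows["photons"].to_numpy()
        links: dict[int, int] = {}
        if prev_pts is not None and f == prev_frame + 1 and len(prev_pts):
            d2 = ((prev_pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
            cost = np.where(d2 <= r2, d2, np.inf)
            links = dict(_stage1_assign(cost, r2))
        new_open: dict[int, dict] = {}
        for j in range(len(pts)):
            i = next((i for i, jj in links.items() if jj == j), None)
            if i is not None and i in open_segs:
                seg = open_segs.pop(i)
            else:
                seg = {"cell": cell, "frames": [], "x": [], "y": [], "photons": [], "gaps": set()}
            seg["frames"].append(int(f))
            seg["x"].append(float(pts[j, 0]))
            seg["y"].append(float(pts[j, 1]))
            seg["photons"].append(float(ph[j]))
            new_open[j] = seg
        done.extend(open_segs.values())
        open_segs = new_open
        prev_pts = pts
        prev_frame = f
    done.extend(open_segs.values())
    return done


def _close_gaps(segments: list[dict], radius: float, max_gap: int) -> list[dict]:
    if max_gap < 1 or len(segments) < 2:
        return segments
    r2 = radius**2
    by_cell: dict[int, list[int]] = {}
    for i, s in enumerate(segments):
        by_cell.setdefault(s["cell"], []).append(i)
    successor: dict[int, int] = {}
    has_pred: set[int] = set()
    for cell, idxs in sorted(by_cell.items()):
        ends = idxs
        starts = idxs
        cost = np.full((len(ends), len(starts)), np.inf)
        for a, ie in enumerate(ends):
            fe = segments[ie]["frames"][-1]
            xe, ye = segments[ie]["x"][-1], segments[ie]["y"][-1]
            for b, js in enumerate(starts):
                if ie == js:
                    continue
                fs = segments[js]["frames"][0]
                gap = fs - fe - 1
                if not (1 <= gap <= max_gap):
                    continue
                d2 = (xe - segments[js]["x"][0]) ** 2 + (ye - segments[js]["y"][0]) ** 2
                if d2 <= r2:
                    cost[a, b] = d2
        if np.isfinite(cost).any():
            for a, b in _stage1_assign(cost, r2):
                successor[ends[a]] = starts[b]
                has_pred.add(starts[b])
    merged: list[dict] = []
    consumed: set[int] = set()
    for i, s in enumerate(segments):
        if i in has_pred or i in consumed:
            continue
        cur = dict(s)
        cur["frames"] = list(s["frames"])
        cur["x"], cur["y"] = list(s["x"]), list(s["y"])
        cur["photons"] = list(s["photons"])
        cur["gaps"] = set(s["gaps"])
        j = i
        while j in successor:
            k = successor[j]
            nxt = segments[k]
            cur["gaps"].update(range(cur["frames"][-1] + 1, nxt["frames"][0]))
            cur["frames"] += list(nxt["frames"])
            cur["x"] += list(nxt["x"])
            cur["y"] += list(nxt["y"])
            cur["photons"] += list(nxt["photons"])
            cur["gaps"].update(nxt["gaps"])
            consumed.add(k)
            j = k
        merged.append(cur)
    return merged


def filter_trajectories(trajs: list[Trajectory], min_frames: int = 5) -> list[Trajectory]:
    """Keep trajectories with at least ``min_frames`` observed frames."""
    return [t for t in trajs if t.n_observed >= min_frames]


def trajectories_to_table(trajs: list[Trajectory]) -> pd.DataFrame:
    """Long-format trajectory table (one row per observed or gap frame)."""
    rows = []
    for t in trajs:
        for f, x, y, p in zip(t.frames, t.x, t.y, t.photons):
            rows.append((t.cell, t.trajectory, int(f), x, y, p, False))
        for f in t.gap_frames:
            rows.append((t.cell, t.trajectory, int(f), np.nan, np.nan, np.nan, True))
    df = pd.DataFrame(
        rows, columns=["cell", "trajectory", "frame", "x_px", "y_px", "photons", "is_gap"]
    )
    return df.sort_values(["cell", "trajectory", "frame"]).reset_index(drop=True)
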
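"""Footstep isolation by spatio-temporal gap clustering.

Footsteps are connected components of the thresholded voxel set
``{(t, row, col) : p >= p_threshold_kpa}`` under a gap-bridging adjacency:
two voxels are neighbours when they differ by at most
``spatial_gap_cells + 1`` in each in-plane axis and at most
``temporal_gap_frames + 1`` in time.  This is the 6-neighbourhood dilated by
the configured gaps: a gap of up to ``spatial_gap_cells`` empty cells (or
``temporal_gap_frames`` empty frames) between two active voxels is bridged.

The defaults (threshold 5 kPa; 2 cells ~ 2.7 cm; 10 frames = 0.1 s at
100 Hz; 20 voxels minimum) are chosen so adult-elephant prints (~40 cm)
never split and successive footfalls never merge.  Two footsteps may overlap
in time if spatially distant, or reuse the same plate area if temporally
distant — the adjacency requires proximity in space AND time.

Foot identity (FL/FR/HL/HR) is assigned heuristically: left/right by
mediolateral position relative to the trackway centreline, fore/hind by
footfall order within a spatial cluster of prints (elephant hind feet land
near the preceding ipsilateral forefoot print, so within a cluster the
earlier print is the forefoot).  Ambiguous steps are labelled ``unknown``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from elefoot.errors import ConsistencyError
from elefoot.pressure_io import PlateSpec, PressureRecord, TrialMeta

__all__ = [
    "SegmentationConfig",
    "FootstepSeries",
    "segment_steps",
    "assess_completeness",
    "classify_feet",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds and gap sizes for footstep isolation."""

    p_threshold_kpa: float = 5.0
    spatial_gap_cells: int = 2
    temporal_gap_frames: int = 10
    min_voxels: int = 20

    def __post_init__(self) -> None:
        if self.p_threshold_kpa <= 0:
            raise ValueError("p_threshold_kpa must be positive")
        if self.spatial_gap_cells < 0 or self.temporal_gap_frames < 0:
            raise ValueError("gap sizes must be non-negative")
        if self.min_voxels < 1:
            raise ValueError("min_voxels must be at least 1")


@dataclass
class FootstepSeries:
    """One isolated footstep: the voxels of a single ground contact.

    ``voxels`` is an ``(n, 3)`` int array of (t, row, col) with parallel
    ``pressures`` in kPa.  The series keeps a reference to the plate spec so
    physical coordinates and timing stay available downstream.
    """

    spec: PlateSpec
    voxels: np.ndarray
    pressures: np.ndarray
    n_record_frames: int
    foot_label: str = "unknown"
    complete_spatial: bool | None = None
    complete_temporal: bool | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=int).reshape(-1, 3)
        self.pressures = np.asarray(self.pressures, dtype=float).ravel()
        if len(self.voxels) != len(self.pressures):
            raise ValueError("voxels and pressures must have equal length")
        if len(self.voxels) == 0:
            raise ValueError("a footstep must contain at least one voxel")

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    @property
    def onset_frame(self) -> int:
        return int(self.voxels[:, 0].min())

    @property
    def offset_frame(self) -> int:
        return int(self.voxels[:, 0].max())

    @property
    def onset_s(self) -> float:
        return self.onset_frame / self.spec.freq_hz

    @property
    def duration_s(self) -> float:
        return (self.offset_frame - self.onset_frame + 1) / self.spec.freq_hz

    @property
    def active_frames(self) -> np.ndarray:
        return np.unique(self.voxels[:, 0])

    @property
    def bbox(self) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
        """((t0, t1), (r0, r1), (c0, c1)) inclusive bounds."""
        lo = self.voxels.min(axis=0)
        hi = self.voxels.max(axis=0)
        return ((int(lo[0]), int(hi[0])), (int(lo[1]), int(hi[1])), (int(lo[2]), int(hi[2])))

    def centroid_xy_m(self) -> tuple[float, float]:
        """Pressure-weighted spatial centroid over the whole step, in metres."""
        w = self.pressures
        x = (self.voxels[:, 2] + 0.5) * self.spec.pitch_x_m
        y = (self.voxels[:, 1] + 0.5) * self.spec.pitch_y_m
        return (float((w * x).sum() / w.sum()), float((w * y).sum() / w.sum()))

    def frame(self, t: int) -> np.ndarray:
        """Dense full-plate grid of this step's pressures at frame ``t``."""
        out = np.zeros(self.spec.shape)
        sel = self.voxels[:, 0] == t
        out[self.voxels[sel, 1], self.voxels[sel, 2]] = self.pressures[sel]
        return out

    def voxel_set(self) -> set[tuple[int, int, int]]:
        return set(map(tuple, self.voxels.tolist()))

    def total_pressure(self) -> float:
        return float(self.pressures.sum())


class _DisjointSet:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _cell_intervals(frames_by_cell: dict[tuple[int, int], np.ndarray], reach_t: int):
    """Split each cell's sorted active-frame list at gaps wider than reach_t.

    Within a resulting interval every consecutive pair of active frames is
    within ``reach_t``, so the interval envelope [first, last] is an exact
    summary for the adjacency test (see segment_steps).
    """
    nodes = []  # (row, col, t_first, t_last, frames)
    for (r, c), ts in frames_by_cell.items():
        start = 0
        for i in range(1, len(ts) + 1):
            if i == len(ts) or ts[i] - ts[i - 1] > reach_t:
                nodes.append((r, c, int(ts[start]), int(ts[i - 1])))
                start = i
    return nodes


def segment_steps(
    record: PressureRecord, config: SegmentationConfig | None = None
) -> list[FootstepSeries]:
    """Isolate footsteps as gap-bridging connected components of active voxels.

    Returns steps in order of onset frame (ties broken by spatial position).
    Clusters smaller than ``config.min_voxels`` are discarded.
    """
    config = config or SegmentationConfig()
    reach_s = config.spatial_gap_cells + 1
    reach_t = config.temporal_gap_frames + 1

    t, r, c = np.nonzero(record.frames >= config.p_threshold_kpa)
    if t.size == 0:
        return []
    pressures = record.frames[t, r, c]

    # group voxels by cell, split each cell's time series at bridgeable gaps
    order = np.lexsort((t, c, r))
    t, r, c, pressures = t[order], r[order], c[order], pressures[order]
    frames_by_cell: dict[tuple[int, int], np.ndarray] = {}
    cell_ids = r.astype(np.int64) * record.spec.n_cols + c
    boundaries = np.flatnonzero(np.diff(cell_ids)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(cell_ids)]))
    voxel_slices: dict[tuple[int, int], tuple[int, int]] = {}
    for s_i, e_i in zip(starts, ends):
        key = (int(r[s_i]), int(c[s_i]))
        frames_by_cell[key] = t[s_i:e_i]
        voxel_slices[key] = (int(s_i), int(e_i))

    nodes = _cell_intervals(frames_by_cell, reach_t)
    node_index: dict[tuple[int, int], list[int]] = {}
    for i, (nr, nc, _, _) in enumerate(nodes):
        node_index.setdefault((nr, nc), []).append(i)

    # two interval-nodes are linked when their cells are within the spatial
    # reach and their time envelopes come within the temporal reach; because
    # frames inside an interval never gap by more than reach_t this is
    # equivalent to voxel-level adjacency
    ds = _DisjointSet(len(nodes))
    for i, (nr, nc, t0, t1) in enumerate(nodes):
        for dr in range(-reach_s, reach_s + 1):
            for dc in range(-reach_s, reach_s + 1):
                if dr == 0 and dc == 0:
                    continue
                for j in node_index.get((nr + dr, nc + dc), ()):
                    if j <= i:
                        continue
                    _, _, u0, u1 = nodes[j]
                    if u0 <= t1 + reach_t and t0 <= u1 + reach_t:
                        ds.union(i, j)
        # intervals within the same cell: the split guarantees gaps > reach_t,
        # so same-cell intervals are never directly linked

    # map voxels to their interval-node, then to components
    comp_voxels: dict[int, list[int]] = {}
    for i, (nr, nc, t0, t1) in enumerate(nodes):
        root = ds.find(i)
        s_i, e_i = voxel_slices[(nr, nc)]
        sel = np.flatnonzero((t[s_i:e_i] >= t0) & (t[s_i:e_i] <= t1)) + s_i
        comp_voxels.setdefault(root, []).extend(sel.tolist())

    steps: list[FootstepSeries] = []
    for idxs in comp_voxels.values():
        if len(idxs) < config.min_voxels:
            continue
        idxs = np.array(idxs)
        steps.append(
            FootstepSeries(
                spec=record.spec,
                voxels=np.column_stack((t[idxs], r[idxs], c[idxs])),
                pressures=pressures[idxs],
                n_record_frames=record.n_frames,
            )
        )
    steps.sort(key=lambda s: (s.onset_frame, s.centroid_xy_m()[1], s.centroid_xy_m()[0]))
    return steps


def assess_completeness(
    step: FootstepSeries,
    record: PressureRecord,
    config: SegmentationConfig | None = None,
) -> tuple[bool, bool]:
    """Spatio-temporal completeness of a step.

    A step is spatially incomplete when any voxel lies on the outermost
    sensor row or column (part of the print may be off-plate) and temporally
    incomplete when it is active in the record's first or last frame (the
    stance may be clipped).
    """
    if record.n_frames != step.n_record_frames or record.spec != step.spec:
        raise ConsistencyError("step does not belong to this record")
    vox = step.voxels
    if vox[:, 0].max() >= record.n_frames or vox[:, 1].max() >= record.spec.n_rows:
        raise ConsistencyError("step voxels outside record bounds")
    spatial = not (
        np.any(vox[:, 1] == 0)
        or np.any(vox[:, 1] == record.spec.n_rows - 1)
        or np.any(vox[:, 2] == 0)
        or np.any(vox[:, 2] == record.spec.n_cols - 1)
    )
    temporal = not (np.any(vox[:, 0] == 0) or np.any(vox[:, 0] == record.n_frames - 1))
    return bool(spatial), bool(temporal)


def _walking_direction(steps: Sequence[FootstepSeries], meta: TrialMeta | None) -> float:
    """+1 when the animal travels toward +y, -1 otherwise."""
    if meta is not None and meta.side_hint in ("+y", "-y"):
        return 1.0 if meta.side_hint == "+y" else -1.0
    if len(steps) < 2:
        return 1.0
    onsets = np.array([s.onset_frame for s in steps], dtype=float)
    ys = np.array([s.centroid_xy_m()[1] for s in steps])
    slope = np.polyfit(onsets, ys, 1)[0] if np.ptp(onsets) > 0 else 0.0
    return 1.0 if slope >= 0 else -1.0


def classify_feet(
    steps: Sequence[FootstepSeries],
    meta: TrialMeta | None = None,
    *,
    cluster_radius_m: float = 0.6,
) -> list[FootstepSeries]:
    """Assign FL/FR/HL/HR labels; ambiguous steps get ``unknown``.

    Left/right: mediolateral position relative to the trackway centreline
    (median x of all step centroids); for an animal walking toward +y the
    left feet are at smaller x.  Fore/hind: steps are clustered spatially
    (centroids within ``cluster_radius_m``); in a cluster of two successive
    prints the earlier is the forefoot.  A single step, or a cluster that is
    not a fore/hind pair, cannot be resolved and is labelled unknown.
    """
    if not steps:
        return []
    labelled = [
        FootstepSeries(
            spec=s.spec,
            voxels=s.voxels.copy(),
            pressures=s.pressures.copy(),
            n_record_frames=s.n_record_frames,
            foot_label="unknown",
            complete_spatial=s.complete_spatial,
            complete_temporal=s.complete_temporal,
        )
        for s in steps
    ]
    if len(labelled) == 1:
        return labelled

    cents = np.array([s.centroid_xy_m() for s in labelled])
    direction = _walking_direction(labelled, meta)
    centreline = float(np.median(cents[:, 0]))
    # side: walking +y, left is smaller x; walking -y, left is larger x
    sides = []
    for x, _ in cents:
        if abs(x - centreline) < 1e-9:
            sides.append(None)
        elif (x < centreline) == (direction > 0):
            sides.append("L")
        else:
            sides.append("R")

    # greedy spatial clustering by centroid distance
    cluster_of = [-1] * len(labelled)
    clusters: list[list[int]] = []
    for i in np.argsort([s.onset_frame for s in labelled]):
        placed = False
        for ci, members in enumerate(clusters):
            ref = cents[members[0]]
            if np.hypot(*(cents[i] - ref)) <= cluster_radius_m:
                members.append(int(i))
                cluster_of[i] = ci
                placed = True
                break
        if not placed:
            cluster_of[i] = len(clusters)
            clusters.append([int(i)])

    fh: list[str | None] = [None] * len(labelled)
    for members in clusters:
        if len(members) == 2:
            a, b = sorted(members, key=lambda i: labelled[i].onset_frame)
            fh[a], fh[b] = "F", "H"
        # singleton or over-full clusters stay unresolved

    for i, s in enumerate(labelled):
        if fh[i] is not None and sides[i] is not None:
            s.foot_label = fh[i] + sides[i]
    return labelled
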
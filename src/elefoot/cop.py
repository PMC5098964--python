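"""Centre-of-pressure trajectories and their comparison.

The centre of pressure (COP) at an instant is the pressure-weighted centroid
of the plantar pressure field — the mean path of the vertical ground
reaction force over the contact area.  Per footstep the COP is computed per
active frame, time-normalized to a fixed number of stance-percent samples
(101 by convention in gait analysis), and averaged across steps of the same
foot.  Mean trajectories are compared pairwise with

* Pearson correlations of the mediolateral (``x_r``) and cranio-caudal
  (``y_r``) coordinate sequences,
* RMSE on untransformed (but centred) data, and
* RMSD after ordinary Procrustes analysis (OPA) with scaling and reflection
  allowed, mirroring comparisons between feet of different sizes and between
  cohorts measured on different equipment.

OPA here is full (asymmetric): the source configuration is translated,
rotated/reflected and scaled onto the fixed target by least squares, with
the optimal rotation obtained in closed form from the singular value
decomposition of the cross-covariance matrix.  RMSD uses the number of
points (not 2k coordinates) as denominator, so it reads as a mean per-point
distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from elefoot.errors import DegenerateShapeError
from elefoot.pressure_io import PlateSpec
from elefoot.segment import FootstepSeries

__all__ = [
    "COPTrajectory",
    "TrajectoryComparison",
    "cop_frame",
    "cop_trajectory",
    "time_normalize",
    "mean_trajectory",
    "compare_untransformed",
    "procrustes_opa",
    "compare_feet",
    "DEFAULT_PAIRS",
]

DEFAULT_PAIRS = ("FL-FR", "FL-HL", "FL-HR", "FR-HL", "FR-HR", "HL-HR")


@dataclass
class COPTrajectory:
    """Ordered COP positions over one stance (or a mean of stances)."""

    points: np.ndarray  # (n, 2) of (x_m, y_m)
    times: np.ndarray  # stance fractions in [0, 1] (or raw seconds)
    total_force_proxy: np.ndarray | None = None  # per-point summed pressure
    frame_count: int = 0
    foot_label: str = "unknown"
    frames: np.ndarray | None = None  # absolute record frame index per point

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.times = np.asarray(self.times, dtype=float).ravel()
        if len(self.points) < 2:
            raise ValueError("a trajectory needs at least two points")
        if len(self.times) != len(self.points):
            raise ValueError("times and points must align")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def centred(self) -> "COPTrajectory":
        """Translate so the trajectory centroid sits at the origin."""
        return COPTrajectory(
            points=self.points - self.points.mean(axis=0),
            times=self.times.copy(),
            total_force_proxy=None
            if self.total_force_proxy is None
            else self.total_force_proxy.copy(),
            frame_count=self.frame_count,
            foot_label=self.foot_label,
        )


@dataclass(frozen=True)
class TrajectoryComparison:
    """Pairwise trajectory metrics: correlations, RMSE and Procrustes RMSD."""

    pair: str
    x_r: float
    y_r: float
    rmse: float
    rmsd: float
    scale_used: bool = True
    reflect_used: bool = True


def cop_frame(
    frame: np.ndarray, threshold_kpa: float, spec: PlateSpec
) -> tuple[float, float] | None:
    """Pressure-weighted centroid of cells at or above threshold, in metres.

    Returns ``None`` when no cell passes the threshold (inactive frame).
    """
    frame = np.asarray(frame, dtype=float)
    mask = frame >= threshold_kpa
    if not mask.any():
        return None
    p = frame[mask]
    rr, cc = np.nonzero(mask)
    total = p.sum()
    x = float((p * (cc + 0.5)).sum() / total) * spec.pitch_x_m
    y = float((p * (rr + 0.5)).sum() / total) * spec.pitch_y_m
    return (x, y)


def cop_trajectory(step: FootstepSeries, threshold_kpa: float = 5.0) -> COPTrajectory:
    """COP per active frame of one footstep, in time order.

    Stance fraction of a frame is ``(frame - first_active) /
    (last_active - first_active)``.  Frames with no cell at or above the
    threshold are skipped.
    """
    pts, forces, frames = [], [], []
    for t in step.active_frames:
        frame = step.frame(int(t))
        xy = cop_frame(frame, threshold_kpa, step.spec)
        if xy is None:
            continue
        pts.append(xy)
        forces.append(float(frame[frame >= threshold_kpa].sum()))
        frames.append(int(t))
    if len(pts) < 2:
        raise ValueError("fewer than two active frames above threshold")
    frames_arr = np.array(frames, dtype=float)
    fractions = (frames_arr - frames_arr[0]) / (frames_arr[-1] - frames_arr[0])
    return COPTrajectory(
        points=np.array(pts),
        times=fractions,
        total_force_proxy=np.array(forces),
        frame_count=len(frames),
        foot_label=step.foot_label,
        frames=np.array(frames, dtype=int),
    )


def time_normalize(traj: COPTrajectory, n_points: int = 101) -> COPTrajectory:
    """Resample by linear interpolation at uniform stance fractions.

    Endpoints are preserved exactly.
    """
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    frac = np.linspace(0.0, 1.0, n_points)
    t = traj.times
    if t[-1] == t[0]:
        raise ValueError("degenerate time axis")
    t = (t - t[0]) / (t[-1] - t[0])
    x = np.interp(frac, t, traj.x)
    y = np.interp(frac, t, traj.y)
    force = (
        np.interp(frac, t, traj.total_force_proxy)
        if traj.total_force_proxy is not None
        else None
    )
    return COPTrajectory(
        points=np.column_stack((x, y)),
        times=frac,
        total_force_proxy=force,
        frame_count=traj.frame_count,
        foot_label=traj.foot_label,
    )


def mean_trajectory(trajs: Sequence[COPTrajectory]) -> COPTrajectory:
    """Pointwise mean of time-normalized trajectories of one foot."""
    if not trajs:
        raise ValueError("mean_trajectory needs at least one trajectory")
    n = len(trajs[0])
    if any(len(t) != n for t in trajs):
        raise ValueError("all trajectories must be normalized to equal length")
    pts = np.mean([t.points for t in trajs], axis=0)
    return COPTrajectory(
        points=pts,
        times=trajs[0].times.copy(),
        frame_count=n,
        foot_label=trajs[0].foot_label,
    )


def compare_untransformed(
    a: COPTrajectory, b: COPTrajectory
) -> tuple[float, float, float]:
    """Axis-wise Pearson correlations and RMSE of two centred trajectories.

    Both trajectories are centred on their centroids first: plate coordinates
    are arbitrary per trial, and the common centroid frame is the only frame
    two feet share.  A zero-variance axis yields ``nan`` for that
    correlation.
    """
    if len(a) != len(b):
        raise ValueError("trajectories must have equal length")
    pa, pb = a.centred().points, b.centred().points
    x_r = _pearson(pa[:, 0], pb[:, 0])
    y_r = _pearson(pa[:, 1], pb[:, 1])
    rmse = float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))
    return x_r, y_r, rmse


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    if np.std(u) == 0 or np.std(v) == 0:
        return float("nan")
    return float(sps.pearsonr(u, v).statistic)


def procrustes_opa(
    target: COPTrajectory | np.ndarray,
    source: COPTrajectory | np.ndarray,
    scale: bool = True,
    reflect: bool = True,
) -> tuple[np.ndarray, float]:
    """Ordinary Procrustes superimposition of ``source`` onto ``target``.

    Both configurations are centred; the source is then rotated (orthogonal
    matrix — determinant unconstrained when ``reflect`` is allowed,
    constrained to +1 otherwise) and, when ``scale`` is set, uniformly
    scaled, to minimize the sum of squared point distances.  The optimum is
    closed-form via the SVD of the cross-covariance matrix.

    Returns the superimposed source points (in the target's centred frame)
    and the RMSD, ``sqrt(mean_i ||target_i - fitted_i||^2)``.

    Raises
    ------
    DegenerateShapeError
        If either configuration has zero centroid size.
    """
    a = target.points if isinstance(target, COPTrajectory) else np.asarray(target, float)
    b = source.points if isinstance(source, COPTrajectory) else np.asarray(source, float)
    a = a.reshape(-1, 2)
    b = b.reshape(-1, 2)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("configurations must be equal-shaped with >= 2 points")
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    na = np.linalg.norm(a0)
    nb = np.linalg.norm(b0)
    if na == 0 or nb == 0:
        raise DegenerateShapeError("zero centroid size")
    m = b0.T @ a0  # cross-covariance (source x target)
    u, s, vt = np.linalg.svd(m)
    d = np.ones(len(s))
    if not reflect and np.linalg.det(u @ vt) < 0:
        d[-1] = -1.0
    r = u @ np.diag(d) @ vt
    trace = float((s * d).sum())
    beta = trace / (nb**2) if scale else 1.0
    fitted = beta * b0 @ r
    rmsd = float(np.sqrt(np.mean(np.sum((a0 - fitted) ** 2, axis=1))))
    return fitted, rmsd


def compare_feet(
    mean_trajs: Mapping[str, COPTrajectory],
    pairs: Iterable[str] = DEFAULT_PAIRS,
    *,
    scale: bool = True,
    reflect: bool = True,
) -> pd.DataFrame:
    """Pairwise comparison table for labelled mean trajectories.

    Each requested pair ``"A-B"`` yields Pearson ``x_r``/``y_r`` and RMSE on
    centred untransformed data plus the Procrustes RMSD of B superimposed
    onto A.

    Raises
    ------
    KeyError
        If a pair names a missing trajectory label.
    """
    rows = []
    for pair in pairs:
        name_a, name_b = pair.split("-")
        if name_a not in mean_trajs or name_b not in mean_trajs:
            missing = name_a if name_a not in mean_trajs else name_b
            raise KeyError(f"no mean trajectory for foot {missing!r}")
        a, b = mean_trajs[name_a], mean_trajs[name_b]
        x_r, y_r, rmse = compare_untransformed(a, b)
        _, rmsd = procrustes_opa(a, b, scale=scale, reflect=reflect)
        rows.append(
            TrajectoryComparison(
                pair=pair,
                x_r=x_r,
                y_r=y_r,
                rmse=rmse,
                rmsd=rmsd,
                scale_used=scale,
                reflect_used=reflect,
            )
        )
    return pd.DataFrame(
        [
            {
                "pair": r.pair,
                "x_r": r.x_r,
                "y_r": r.y_r,
                "rmse": r.rmse,
                "rmsd": r.rmsd,
                "scale": r.scale_used,
                "reflect": r.reflect_used,
            }
            for r in rows
        ]
    )
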
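"""Rigid registration of footprint images to a per-foot template.

In pedobarographic practice every footstep image of a foot is aligned
(translated and rotated) to a template image — the first spatio-temporally
complete step — so that pixels correspond anatomically across steps and a
mean image can be formed.  Registration of elephant prints is hard for
generic automatic methods because the prints are nearly symmetric; manual
keyboard-driven alignment is the published workflow and performs as well as
optimal algorithmic registration.  This module keeps a manual mode (apply an
explicit transform) and adds an automated substitute: an exhaustive coarse
grid search over a bounded window (translation +-10 cells, rotation +-20
degrees, well inside the symmetry-flip failure mode) followed by local
refinement, minimizing the mean squared pressure difference over the union
support.

Transforms operate in grid units: ``dx_cells`` along columns (mediolateral),
``dy_cells`` along rows (cranio-caudal), rotation about the active-pixel
centroid of the image being transformed (which decouples rotation from
translation in the search).  Images are resampled bilinearly with zero fill
outside the grid; nearest-neighbour resampling is available for mass
conservation checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from elefoot.errors import RegistrationError, SelectionError
from elefoot.pressure_io import PlateSpec
from elefoot.segment import FootstepSeries

__all__ = [
    "PeakPressureImage",
    "TemplateImage",
    "RigidTransform2D",
    "peak_pressure_image",
    "select_template",
    "apply_transform",
    "register_to_template",
    "apply_transform_to_series",
]


@dataclass
class PeakPressureImage:
    """Per-pixel maximum pressure over the stance phase of one footstep."""

    values: np.ndarray  # (n_rows, n_cols) kPa
    spec: PlateSpec
    foot_label: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("peak image must be 2-D")

    def active_centroid(self, threshold: float = 0.0) -> tuple[float, float]:
        """(row, col) centroid of pixels above ``threshold``."""
        mask = self.values > threshold
        if not mask.any():
            raise ValueError("image has no active pixels")
        rr, cc = np.nonzero(mask)
        return (float(rr.mean()), float(cc.mean()))

    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class TemplateImage:
    """The per-foot template: a peak image plus its isocontour mask."""

    image: PeakPressureImage
    foot_label: str
    iso_threshold_kpa: float = 5.0

    @property
    def mask(self) -> np.ndarray:
        return self.image.values >= self.iso_threshold_kpa


@dataclass(frozen=True)
class RigidTransform2D:
    """Translation + rotation (optionally reflection) on the image grid.

    The forward map, in (row, col) coordinates, is
    ``q' = A(theta) S (q - c) + c + (dy, dx)`` where ``c`` is the rotation
    centre and ``S`` mirrors the column axis when ``reflect`` is set.
    Reflection is off for within-foot registration.
    """

    dx_cells: float = 0.0
    dy_cells: float = 0.0
    theta_deg: float = 0.0
    reflect: bool = False

    def _rot_rc(self) -> np.ndarray:
        th = math.radians(self.theta_deg)
        c, s = math.cos(th), math.sin(th)
        return np.array([[c, s], [-s, c]])

    def matrix(self) -> np.ndarray:
        m = self._rot_rc()
        if self.reflect:
            m = m @ np.diag([1.0, -1.0])
        return m

    def apply_points(self, pts_rc: np.ndarray, centre_rc: tuple[float, float]) -> np.ndarray:
        """Map (n, 2) points in (row, col) coordinates forward."""
        pts = np.asarray(pts_rc, dtype=float).reshape(-1, 2)
        c = np.asarray(centre_rc, dtype=float)
        d = np.array([self.dy_cells, self.dx_cells])
        return (self.matrix() @ (pts - c).T).T + c + d

    def inverse(self) -> "RigidTransform2D":
        """Inverse transform about the same centre."""
        m_inv = np.linalg.inv(self.matrix())
        d = np.array([self.dy_cells, self.dx_cells])
        d_inv = -m_inv @ d
        theta_inv = self.theta_deg if self.reflect else -self.theta_deg
        return RigidTransform2D(
            dx_cells=float(d_inv[1]),
            dy_cells=float(d_inv[0]),
            theta_deg=theta_inv,
            reflect=self.reflect,
        )


def peak_pressure_image(
    step: FootstepSeries, foot_label: str | None = None
) -> PeakPressureImage:
    """Maximum pressure attained at each cell over the step's frames."""
    out = np.zeros(step.spec.shape)
    r, c = step.voxels[:, 1], step.voxels[:, 2]
    np.maximum.at(out, (r, c), step.pressures)
    return PeakPressureImage(
        values=out, spec=step.spec, foot_label=foot_label or step.foot_label
    )


def select_template(
    images: list[PeakPressureImage],
    flags: list[tuple[bool, bool]],
    iso_threshold_kpa: float = 5.0,
    min_voxels: int = 20,
) -> TemplateImage:
    """First spatio-temporally complete image, in acquisition order."""
    if len(images) != len(flags):
        raise ValueError("images and flags must align")
    for img, (spatial, temporal) in zip(images, flags):
        if spatial and temporal:
            if int((img.values >= iso_threshold_kpa).sum()) < min_voxels:
                continue
            return TemplateImage(
                image=img, foot_label=img.foot_label, iso_threshold_kpa=iso_threshold_kpa
            )
    raise SelectionError("no spatio-temporally complete image to use as template")


def _resample(
    values: np.ndarray,
    tf: RigidTransform2D,
    centre_rc: tuple[float, float],
    order: int,
) -> np.ndarray:
    # affine_transform needs the inverse map output -> input
    m_fwd = tf.matrix()
    m_inv = np.linalg.inv(m_fwd)
    c = np.asarray(centre_rc, dtype=float)
    d = np.array([tf.dy_cells, tf.dx_cells])
    offset = c - m_inv @ (c + d)
    return ndimage.affine_transform(
        values, m_inv, offset=offset, order=order, mode="constant", cval=0.0
    )


def apply_transform(
    image: PeakPressureImage,
    tf: RigidTransform2D,
    *,
    centre_rc: tuple[float, float] | None = None,
    order: int = 1,
) -> PeakPressureImage:
    """Resample ``image`` under ``tf`` on the same grid (zero outside).

    Pure integer translations are applied losslessly.  The rotation centre
    defaults to the image's active-pixel centroid.
    """
    if (
        tf.theta_deg == 0.0
        and not tf.reflect
        and float(tf.dx_cells).is_integer()
        and float(tf.dy_cells).is_integer()
    ):
        out = np.zeros_like(image.values)
        dy, dx = int(tf.dy_cells), int(tf.dx_cells)
        src = image.values
        r0, r1 = max(0, dy), min(src.shape[0], src.shape[0] + dy)
        c0, c1 = max(0, dx), min(src.shape[1], src.shape[1] + dx)
        out[r0:r1, c0:c1] = src[r0 - dy : r1 - dy, c0 - dx : c1 - dx]
        return replace_values(image, out)
    centre = centre_rc if centre_rc is not None else image.active_centroid()
    return replace_values(image, _resample(image.values, tf, centre, order))


def replace_values(image: PeakPressureImage, values: np.ndarray) -> PeakPressureImage:
    return PeakPressureImage(values=values, spec=image.spec, foot_label=image.foot_label)


def _mse_union(a: np.ndarray, b: np.ndarray) -> float:
    support = (a > 0) | (b > 0)
    if not support.any():
        return math.inf
    diff = a[support] - b[support]
    return float(np.mean(diff * diff))


def register_to_template(
    source: PeakPressureImage,
    template: TemplateImage,
    *,
    translation_range: int = 10,
    rotation_range_deg: float = 20.0,
    coarse_rotation_step_deg: float = 2.0,
) -> RigidTransform2D:
    """Find the rigid transform aligning ``source`` onto the template.

    Coarse stage: exhaustive search over integer translations within
    ``+-translation_range`` cells and rotations within
    ``+-rotation_range_deg`` (step ``coarse_rotation_step_deg``).  Fine
    stage: pattern search shrinking to 0.1 cell / 0.25 degree steps.  The
    bounded rotation window avoids locking onto a symmetry flip of the
    near-symmetric footprint.
    """
    # crop both images to the joint footprint bounding box (plus the search
    # range) — the transform parameters are unchanged by a common crop
    union = (source.values > 0) | (template.image.values > 0)
    if not union.any():
        raise RegistrationError("both images are empty")
    rr, cc = np.nonzero(union)
    pad = translation_range + 4
    r0 = max(0, rr.min() - pad)
    r1 = min(union.shape[0], rr.max() + pad + 1)
    c0 = max(0, cc.min() - pad)
    c1 = min(union.shape[1], cc.max() + pad + 1)
    src = source.values[r0:r1, c0:c1]
    tmpl = template.image.values[r0:r1, c0:c1]
    full_centre = source.active_centroid()
    centre = (full_centre[0] - r0, full_centre[1] - c0)
    angles = np.arange(
        -rotation_range_deg, rotation_range_deg + 1e-9, coarse_rotation_step_deg
    )
    best: tuple[float, float, float, float] = (math.inf, 0.0, 0.0, 0.0)
    span = range(-translation_range, translation_range + 1)
    for theta in angles:
        rot = _resample(src, RigidTransform2D(theta_deg=float(theta)), centre, order=1)
        for dy in span:
            shifted_rows = _shift_int(rot, dy, axis=0)
            for dx in span:
                cand = _shift_int(shifted_rows, dx, axis=1)
                mse = _mse_union(cand, tmpl)
                if mse < best[0]:
                    best = (mse, float(dx), float(dy), float(theta))
    if not math.isfinite(best[0]):
        raise RegistrationError("no overlapping support within the search window")

    def cost(params: tuple[float, float, float]) -> float:
        dx, dy, theta = params
        tf = RigidTransform2D(dx_cells=dx, dy_cells=dy, theta_deg=theta)
        return _mse_union(_resample(src, tf, centre, order=1), tmpl)

    cur = (best[1], best[2], best[3])
    cur_cost = cost(cur)
    for step_t, step_r in ((0.5, 1.0), (0.2, 0.5), (0.1, 0.25)):
        improved = True
        iters = 0
        while improved and iters < 60:
            improved = False
            iters += 1
            for delta in (
                (step_t, 0, 0),
                (-step_t, 0, 0),
                (0, step_t, 0),
                (0, -step_t, 0),
                (0, 0, step_r),
                (0, 0, -step_r),
            ):
                cand = (cur[0] + delta[0], cur[1] + delta[1], cur[2] + delta[2])
                c = cost(cand)
                if c < cur_cost - 1e-12:
                    cur, cur_cost = cand, c
                    improved = True
    return RigidTransform2D(dx_cells=cur[0], dy_cells=cur[1], theta_deg=cur[2])


def _shift_int(arr: np.ndarray, k: int, axis: int) -> np.ndarray:
    """Integer shift with zero fill."""
    if k == 0:
        return arr
    out = np.zeros_like(arr)
    if axis == 0:
        if k > 0:
            out[k:, :] = arr[:-k, :]
        else:
            out[:k, :] = arr[-k:, :]
    else:
        if k > 0:
            out[:, k:] = arr[:, :-k]
        else:
            out[:, :k] = arr[:, -k:]
    return out


def apply_transform_to_series(
    step: FootstepSeries, tf: RigidTransform2D, *, order: int = 1
) -> FootstepSeries:
    """Re-apply a transform found on the peak image to every frame.

    All frames share one rotation centre (the step's peak-image active
    centroid), so the peak image of the output matches applying the same
    transform to the peak image of the input, up to interpolation.
    """
    peak = peak_pressure_image(step)
    centre = peak.active_centroid()
    ts, rs, cs, ps = [], [], [], []
    for t in step.active_frames:
        frame = step.frame(int(t))
        moved = _resample(frame, tf, centre, order=order)
        r, c = np.nonzero(moved > 0)
        ts.append(np.full(r.shape, int(t)))
        rs.append(r)
        cs.append(c)
        ps.append(moved[r, c])
    voxels = np.column_stack(
        (np.concatenate(ts), np.concatenate(rs), np.concatenate(cs))
    )
    return FootstepSeries(
        spec=step.spec,
        voxels=voxels,
        pressures=np.concatenate(ps),
        n_record_frames=step.n_record_frames,
        foot_label=step.foot_label,
        complete_spatial=step.complete_spatial,
        complete_temporal=step.complete_temporal,
    )
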
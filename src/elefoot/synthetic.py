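"""Synthetic pressure records with known ground truth.

The generator emulates the measurement situation of an adult elephant walking
over a 44 x 160 sensor plate (0.605 m x 2.122 m, 100 Hz): four sequential,
temporally overlapping footfalls, each a smooth pressure field with five digit
peaks on the cranial arc of the footprint and a broader, lower-pressure
central/caudal pad, modulated by a single-peaked stance loading envelope.

Each footstep's field is a mixture of isotropic Gaussians truncated at an
elliptical foot outline.  The mixture weights drift linearly over stance from
the pad and lateral digits toward the digits and medial side, which produces
the characteristic centre-of-pressure path: caudal-to-cranial progression with
a lateral deviation at impact and a medial shift through mid-stance.

Ground truth shipped with every record:

* per-step spatio-temporal voxel masks (cells at or above the activation
  threshold in the noise-free field),
* foot identities (FL/FR/HL/HR) and completeness flags,
* the true COP path, computed by dense numerical integration of the
  continuous generating field (4x oversampling of the sensor grid),
* true regional peak pressures at the seven anatomical loci (five digit
  centres, pad centre, caudal heel point).

With the random seed fixed, generation is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from elefoot.errors import GeometryError
from elefoot.pressure_io import PlateSpec, PressureRecord, TrialMeta

__all__ = [
    "FootModel",
    "Footfall",
    "GaitPlan",
    "StepTruth",
    "GroundTruth",
    "default_foot_models",
    "default_gait_plan",
    "generate_footstep",
    "generate_trial",
]

FOOT_LABELS = ("FL", "FR", "HL", "HR")

#: activation threshold used both for truth masks and downstream segmentation
TRUTH_THRESHOLD_KPA = 5.0

#: oversampling factor for the dense-integration COP truth
_OVERSAMPLE = 4


@dataclass(frozen=True)
class FootModel:
    """Geometric/pressure model of one foot.

    The foot frame has x pointing lateral (away from the body midline) and
    y pointing cranial (direction of travel).  Digit centres sit on the
    cranial arc of the elliptical outline, digit i most medial, digit v most
    lateral.  Default amplitudes put the highest peaks on the lateral digits
    (iii-v) and the lowest on the pad, the loading pattern reported for both
    African and Asian elephants, with magnitudes in the 200-320 kPa band
    typical of adult animals.
    """

    foot_type: str  # "fore" | "hind"
    side: str  # "left" | "right"
    outline_semi_x_m: float = 0.16
    outline_semi_y_m: float = 0.18
    digit_centres: tuple[tuple[float, float], ...] = ()
    digit_amplitudes: tuple[float, ...] = (160.0, 175.0, 250.0, 230.0, 215.0)
    pad_amplitude: float = 95.0
    # the pad centre sits slightly lateral: elephants load the lateral side
    # of the foot at impact, when the pad carries most of the weight
    pad_centre: tuple[float, float] = (0.035, -0.05)
    digit_sigma_m: float = 0.018
    pad_sigma_m: float = 0.065

    def __post_init__(self) -> None:
        if self.foot_type not in ("fore", "hind"):
            raise ValueError(f"foot_type must be 'fore' or 'hind', got {self.foot_type!r}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if len(self.digit_amplitudes) != 5:
            raise ValueError("exactly five digit amplitudes required")
        if any(a < 0 for a in self.digit_amplitudes) or self.pad_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if not self.digit_centres:
            object.__setattr__(self, "digit_centres", self._default_digit_centres())
        if len(self.digit_centres) != 5:
            raise ValueError("exactly five digit centres required")

    def _default_digit_centres(self) -> tuple[tuple[float, float], ...]:
        # five digits on the cranial arc, medial (i) to lateral (v)
        angles_deg = (-56.0, -28.0, 0.0, 28.0, 56.0)
        r = 0.82
        return tuple(
            (
                r * self.outline_semi_x_m * math.sin(math.radians(a)),
                r * self.outline_semi_y_m * math.cos(math.radians(a)),
            )
            for a in angles_deg
        )

    @property
    def label(self) -> str:
        return ("F" if self.foot_type == "fore" else "H") + (
            "L" if self.side == "left" else "R"
        )

    @property
    def heel_point(self) -> tuple[float, float]:
        """Caudal-most locus of the sole, on the foot midline."""
        return (0.0, -0.82 * self.outline_semi_y_m)

    def roi_loci(self) -> dict[str, tuple[float, float]]:
        """The seven anatomical loci in foot-frame coordinates.

        roi1-roi5: digit nail midpoints (medial to lateral), roi6: mid-sole
        (pad centre), roi7: caudal heel point.
        """
        loci = {f"roi{i + 1}": c for i, c in enumerate(self.digit_centres)}
        loci["roi6"] = self.pad_centre
        loci["roi7"] = self.heel_point
        return loci


@dataclass(frozen=True)
class COPPathSpec:
    """Linear drift of mixture-component weights over stance fraction tau.

    Weight of component k is ``max(w0 + slope * tau, 0)``.  Defaults start
    with the load on the caudal pad and the lateral digits (lateral COP at
    impact) and shift it cranially and medially through stance.
    """

    pad_w0: float = 2.20
    pad_slope: float = -2.00
    medial_w0: float = 0.05
    medial_slope: float = 1.55
    lateral_w0: float = 0.45
    lateral_slope: float = 1.15

    def weights(self, tau: float) -> np.ndarray:
        """Component weights at stance fraction tau: digits i-v then pad."""
        med = max(self.medial_w0 + self.medial_slope * tau, 0.0)
        lat = max(self.lateral_w0 + self.lateral_slope * tau, 0.0)
        pad = max(self.pad_w0 + self.pad_slope * tau, 0.0)
        return np.array([med, med, lat, lat, lat, pad])


@dataclass(frozen=True)
class Footfall:
    """One planned ground contact: foot label, plate position and timing."""

    label: str
    x_m: float
    y_m: float
    onset_s: float
    heading_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in FOOT_LABELS:
            raise ValueError(f"label must be one of {FOOT_LABELS}, got {self.label!r}")


@dataclass(frozen=True)
class GaitPlan:
    """Timing, placement, COP-path and noise parameters for one trial.

    Defaults describe a slow walk (1.2 m/s, Froude number about 0.07 for an
    adult): 0.8 s stance per foot at 100 Hz, fore and hind footfalls of each
    body side clustered spatially (the hind foot lands just caudal to the
    prior forefoot print) but separated in time.
    """

    stance_s: float = 0.8
    speed_ms: float = 1.2
    step_sequence: tuple[Footfall, ...] = ()
    cop_path_spec: COPPathSpec = field(default_factory=COPPathSpec)
    noise_sd_kpa: float = 1.0
    seed: int = 0
    margin_frames: int = 5

    def __post_init__(self) -> None:
        if self.stance_s <= 0:
            raise ValueError("stance_s must be positive")
        if self.noise_sd_kpa < 0:
            raise ValueError("noise_sd_kpa must be non-negative")
        by_label: dict[str, list[float]] = {}
        for f in self.step_sequence:
            by_label.setdefault(f.label, []).append(f.onset_s)
        for label, onsets in by_label.items():
            if any(b <= a for a, b in zip(onsets, onsets[1:])):
                raise ValueError(f"onset times for {label} must be strictly increasing")


def default_foot_models() -> dict[str, FootModel]:
    """Four feet with fore amplitudes about 7% above hind.

    The fore/hind contrast mirrors the forelimbs carrying roughly 60% of
    body weight; hind feet are slightly narrower and longer.
    """
    fore = dict(
        digit_amplitudes=(160.0, 175.0, 250.0, 230.0, 215.0),
        pad_amplitude=95.0,
        outline_semi_x_m=0.160,
        outline_semi_y_m=0.180,
    )
    hind_scale = 1.0 / 1.07
    hind = dict(
        digit_amplitudes=tuple(round(a * hind_scale, 1) for a in fore["digit_amplitudes"]),
        pad_amplitude=round(95.0 * hind_scale, 1),
        outline_semi_x_m=0.150,
        outline_semi_y_m=0.190,
    )
    return {
        "FL": FootModel(foot_type="fore", side="left", **fore),
        "FR": FootModel(foot_type="fore", side="right", **fore),
        "HL": FootModel(foot_type="hind", side="left", **hind),
        "HR": FootModel(foot_type="hind", side="right", **hind),
    }


def default_gait_plan(
    spec: PlateSpec | None = None,
    *,
    seed: int = 0,
    noise_sd_kpa: float = 1.0,
    stance_s: float = 0.8,
    speed_ms: float = 1.2,
) -> GaitPlan:
    """Four footfalls of a single stride crossing the plate in +y.

    Right feet track at larger x, left at smaller x (animal walking toward
    +y).  Within each body side the forefoot lands first; the hind foot lands
    near the forefoot print about a stance later, so fore/hind pairs are
    clustered in space but well separated in time.
    """
    spec = spec or PlateSpec()
    x_left, x_right = 0.185, 0.42
    seq = (
        Footfall("FR", x_right, 0.55, onset_s=0.0),
        Footfall("FL", x_left, 1.55, onset_s=0.5),
        Footfall("HR", x_right, 0.43, onset_s=1.3),
        Footfall("HL", x_left, 1.43, onset_s=1.8),
    )
    return GaitPlan(
        stance_s=stance_s,
        speed_ms=speed_ms,
        step_sequence=seq,
        noise_sd_kpa=noise_sd_kpa,
        seed=seed,
    )


@dataclass
class StepTruth:
    """Ground truth for one generated footstep."""

    label: str
    footfall: Footfall
    mask: set[tuple[int, int, int]]  # (t, row, col) voxels >= threshold, noise-free
    cop_frames: np.ndarray  # frame indices with a defined true COP
    cop_xy_m: np.ndarray  # (n, 2) true COP positions
    roi_peaks_kpa: dict[str, float]  # locus name -> true regional peak
    roi_xy_m: dict[str, tuple[float, float]]  # locus name -> plate position
    roi_cells: dict[str, tuple[int, int]]  # locus name -> (row, col) grid cell
    complete_spatial: bool = True
    complete_temporal: bool = True


@dataclass
class GroundTruth:
    """Ground truth for a whole trial: one :class:`StepTruth` per footfall."""

    steps: list[StepTruth]
    threshold_kpa: float = TRUTH_THRESHOLD_KPA

    def by_label(self, label: str) -> list[StepTruth]:
        return [s for s in self.steps if s.label == label]


def _envelope(tau: np.ndarray | float) -> np.ndarray | float:
    """Raised-cosine stance loading envelope, zero at touch-down and lift-off."""
    return 0.5 * (1.0 - np.cos(2.0 * math.pi * np.clip(tau, 0.0, 1.0)))


def _foot_to_plate(model: FootModel, footfall: Footfall) -> tuple[np.ndarray, np.ndarray]:
    """Rotation matrix and offset mapping foot-frame points to plate (x, y).

    Left feet mirror the lateral axis so that lateral means smaller x for a
    left foot of an animal walking toward +y.
    """
    s = 1.0 if model.side == "right" else -1.0
    th = math.radians(footfall.heading_deg)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    mirror = np.array([[s, 0.0], [0.0, 1.0]])
    return rot @ mirror, np.array([footfall.x_m, footfall.y_m])


def _field_on_points(
    model: FootModel,
    footfall: Footfall,
    weights: np.ndarray,
    xs: np.ndarray,
    ys: np.ndarray,
) -> np.ndarray:
    """Noise-free mixture field (before the envelope) at plate points (xs, ys)."""
    m, offset = _foot_to_plate(model, footfall)
    # inverse map: foot = M^-1 (plate - offset); M is orthogonal up to mirror
    inv = np.linalg.inv(m)
    fx = inv[0, 0] * (xs - offset[0]) + inv[0, 1] * (ys - offset[1])
    fy = inv[1, 0] * (xs - offset[0]) + inv[1, 1] * (ys - offset[1])
    inside = (fx / model.outline_semi_x_m) ** 2 + (fy / model.outline_semi_y_m) ** 2 <= 1.0
    out = np.zeros_like(fx)
    centres = list(model.digit_centres) + [model.pad_centre]
    amps = list(model.digit_amplitudes) + [model.pad_amplitude]
    sigmas = [model.digit_sigma_m] * 5 + [model.pad_sigma_m]
    for w, (cx, cy), a, sig in zip(weights, centres, amps, sigmas):
        if w <= 0 or a <= 0:
            continue
        d2 = (fx - cx) ** 2 + (fy - cy) ** 2
        out += w * a * np.exp(-d2 / (2.0 * sig * sig))
    out[~inside] = 0.0
    return out


def _grid_points(spec: PlateSpec, oversample: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Cell-centre coordinate grids at the given oversampling factor."""
    n_r = spec.n_rows * oversample
    n_c = spec.n_cols * oversample
    ys = (np.arange(n_r) + 0.5) * (spec.length_m / n_r)
    xs = (np.arange(n_c) + 0.5) * (spec.width_m / n_c)
    return np.meshgrid(xs, ys)


def _check_placement(model: FootModel, footfall: Footfall, spec: PlateSpec) -> None:
    if not (0.0 <= footfall.x_m <= spec.width_m and 0.0 <= footfall.y_m <= spec.length_m):
        raise GeometryError(
            f"footfall centre ({footfall.x_m}, {footfall.y_m}) outside the "
            f"{spec.width_m} x {spec.length_m} m plate"
        )


def _step_frames(
    model: FootModel,
    plan: GaitPlan,
    footfall: Footfall,
    spec: PlateSpec,
    n_frames: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free frames for one footstep plus the frame indices of stance."""
    n_stance = int(round(plan.stance_s * spec.freq_hz))
    if n_stance < 5:
        raise ValueError("stance must span at least 5 frames")
    f0 = int(round(footfall.onset_s * spec.freq_hz))
    frames = np.zeros((n_frames, spec.n_rows, spec.n_cols))
    gx, gy = _grid_points(spec)
    # restrict evaluation to the footprint bounding box (+3 pad sigmas)
    pad = 3.0 * max(model.pad_sigma_m, model.digit_sigma_m)
    r_ext = max(model.outline_semi_x_m, model.outline_semi_y_m) + pad
    rows = np.where(np.abs(gy[:, 0] - footfall.y_m) <= r_ext)[0]
    cols = np.where(np.abs(gx[0, :] - footfall.x_m) <= r_ext)[0]
    if rows.size == 0 or cols.size == 0:
        raise GeometryError("footfall placement has no footprint on the plate")
    rs, cs = np.ix_(rows, cols)
    sub_x, sub_y = gx[rs, cs], gy[rs, cs]
    stance = np.arange(n_stance)
    for k in stance:
        f = f0 + k
        if not (0 <= f < n_frames):
            continue
        tau = k / (n_stance - 1)
        env = float(_envelope(tau))
        if env <= 0:
            continue
        w = plan.cop_path_spec.weights(tau)
        frames[f][rs, cs] = env * _field_on_points(model, footfall, w, sub_x, sub_y)
    return frames, f0 + stance


def _dense_cop(
    model: FootModel,
    plan: GaitPlan,
    footfall: Footfall,
    spec: PlateSpec,
    stance_frames: np.ndarray,
    n_frames: int,
    threshold: float,
) -> tuple[np.ndarray, np.ndarray]:
    """True COP per frame by dense integration of the generating field.

    The same activation threshold applied downstream is applied to the dense
    samples, so the truth matches the measured quantity's definition.
    """
    n_stance = stance_frames.size
    gx, gy = _grid_points(spec, _OVERSAMPLE)
    pad = 3.0 * max(model.pad_sigma_m, model.digit_sigma_m)
    r_ext = max(model.outline_semi_x_m, model.outline_semi_y_m) + pad
    rows = np.where(np.abs(gy[:, 0] - footfall.y_m) <= r_ext)[0]
    cols = np.where(np.abs(gx[0, :] - footfall.x_m) <= r_ext)[0]
    rs, cs = np.ix_(rows, cols)
    sub_x, sub_y = gx[rs, cs], gy[rs, cs]
    out_f, out_xy = [], []
    for k in range(n_stance):
        f = int(stance_frames[k])
        if not (0 <= f < n_frames):
            continue
        tau = k / (n_stance - 1)
        env = float(_envelope(tau))
        if env <= 0:
            continue
        field_vals = env * _field_on_points(
            model, footfall, plan.cop_path_spec.weights(tau), sub_x, sub_y
        )
        active = field_vals >= threshold
        total = field_vals[active].sum()
        if total <= 0:
            continue
        out_f.append(f)
        out_xy.append(
            (
                float((field_vals * sub_x)[active].sum() / total),
                float((field_vals * sub_y)[active].sum() / total),
            )
        )
    return np.array(out_f, dtype=int), np.array(out_xy, dtype=float)


def _peak_field_at(
    model: FootModel,
    plan: GaitPlan,
    footfall: Footfall,
    xs: np.ndarray,
    ys: np.ndarray,
    n_stance: int,
) -> np.ndarray:
    """Max over stance of the noise-free generating field at given points."""
    best = np.zeros_like(np.asarray(xs, dtype=float))
    for k in range(n_stance):
        tau = k / (n_stance - 1)
        env = float(_envelope(tau))
        if env <= 0:
            continue
        v = env * _field_on_points(
            model, footfall, plan.cop_path_spec.weights(tau), xs, ys
        )
        np.maximum(best, v, out=best)
    return best


def _kernel_weights_3x3() -> np.ndarray:
    off = np.arange(-1, 2)
    dr, dc = np.meshgrid(off, off, indexing="ij")
    w = np.exp(-(dr**2 + dc**2) / 2.0)
    return w / w.sum()


def _roi_truth(
    model: FootModel,
    plan: GaitPlan,
    footfall: Footfall,
    spec: PlateSpec,
    n_stance: int,
    threshold: float,
) -> tuple[dict[str, float], dict[str, tuple[float, float]], dict[str, tuple[int, int]]]:
    """True regional peaks at the seven anatomical loci.

    The measured quantity is a regional one — a 3x3, sigma = 1 px Gaussian
    kernel applied to the stance-maximum pressure — so the truth evaluates
    the same regional functional analytically on the generating field.  Loci
    are snapped to the sensor grid: digit nails at the digit centres, the
    mid-sole at the centroid of the active (>= threshold) peak-field region
    and the heel at the caudal-most active point on the foot midline, found
    on a 4x oversampled grid.
    """
    m, offset = _foot_to_plate(model, footfall)
    inv = np.linalg.inv(m)

    # dense peak field over the footprint in foot-frame coordinates
    pad = 3.0 * max(model.pad_sigma_m, model.digit_sigma_m)
    ax = model.outline_semi_x_m + pad
    ay = model.outline_semi_y_m + pad
    d = min(spec.pitch_x_m, spec.pitch_y_m) / _OVERSAMPLE
    fxs = np.arange(-ax, ax + d, d)
    fys = np.arange(-ay, ay + d, d)
    gfx, gfy = np.meshgrid(fxs, fys)
    plate_pts = (m @ np.stack([gfx.ravel(), gfy.ravel()])) + offset[:, None]
    dense = _peak_field_at(
        model, plan, footfall, plate_pts[0], plate_pts[1], n_stance
    ).reshape(gfx.shape)
    active = dense >= threshold
    if not active.any():
        raise GeometryError("footstep never exceeds the activation threshold")

    loci_foot: dict[str, tuple[float, float]] = {
        f"roi{i + 1}": c for i, c in enumerate(model.digit_centres)
    }
    loci_foot["roi6"] = (float(gfx[active].mean()), float(gfy[active].mean()))
    caudal_fy = float(gfy[active].min())
    band = active & (gfy <= caudal_fy + 2 * d)
    # midline point of the caudal-most active band
    mid_idx = np.argmin(np.abs(gfx[band]))
    loci_foot["roi7"] = (float(gfx[band][mid_idx]), float(gfy[band][mid_idx]))

    w3 = _kernel_weights_3x3()
    peaks: dict[str, float] = {}
    plate_xy: dict[str, tuple[float, float]] = {}
    cells: dict[str, tuple[int, int]] = {}
    for name, (fx, fy) in loci_foot.items():
        p = m @ np.array([fx, fy]) + offset
        # snap to the nearest sensor cell centre
        col = int(np.clip(round(p[0] / spec.pitch_x_m - 0.5), 1, spec.n_cols - 2))
        row = int(np.clip(round(p[1] / spec.pitch_y_m - 0.5), 1, spec.n_rows - 2))
        cells[name] = (row, col)
        cx, cy = spec.cell_centre(row, col)
        plate_xy[name] = (cx, cy)
        xs = cx + np.array([-1, 0, 1]) * spec.pitch_x_m
        ys = cy + np.array([-1, 0, 1]) * spec.pitch_y_m
        gx, gy = np.meshgrid(xs, ys)
        vals = _peak_field_at(model, plan, footfall, gx, gy, n_stance)
        vals[vals < threshold] = 0.0  # cells below threshold never enter a step
        peaks[name] = float((vals * w3).sum())
    return peaks, plate_xy, cells


def _truth_for_step(
    model: FootModel,
    plan: GaitPlan,
    footfall: Footfall,
    spec: PlateSpec,
    frames: np.ndarray,
    stance_frames: np.ndarray,
    threshold: float,
) -> StepTruth:
    t, r, c = np.nonzero(frames >= threshold)
    mask = set(zip(t.tolist(), r.tolist(), c.tolist()))
    cop_f, cop_xy = _dense_cop(
        model, plan, footfall, spec, stance_frames, frames.shape[0], threshold
    )
    peaks, plate_xy, cells = _roi_truth(
        model, plan, footfall, spec, stance_frames.size, threshold
    )
    complete_spatial = not any(
        ri in (0, spec.n_rows - 1) or ci in (0, spec.n_cols - 1) for _, ri, ci in mask
    )
    active_t = {ti for ti, _, _ in mask}
    complete_temporal = bool(mask) and 0 not in active_t and (frames.shape[0] - 1) not in active_t
    return StepTruth(
        label=model.label,
        footfall=footfall,
        mask=mask,
        cop_frames=cop_f,
        cop_xy_m=cop_xy,
        roi_peaks_kpa=peaks,
        roi_xy_m=plate_xy,
        roi_cells=cells,
        complete_spatial=complete_spatial,
        complete_temporal=complete_temporal,
    )


def generate_footstep(
    model: FootModel,
    plan: GaitPlan,
    placement: Footfall,
    *,
    spec: PlateSpec | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[PressureRecord, StepTruth]:
    """Generate one footstep as a full-plate record plus its ground truth.

    The record spans from t = 0 to lift-off plus ``plan.margin_frames`` empty
    frames; noise (if any) is added to every cell of every frame and clipped
    at zero.
    """
    spec = spec or PlateSpec()
    _check_placement(model, placement, spec)
    n_stance = int(round(plan.stance_s * spec.freq_hz))
    f0 = int(round(placement.onset_s * spec.freq_hz))
    n_frames = f0 + n_stance + plan.margin_frames
    frames, stance_frames = _step_frames(model, plan, placement, spec, n_frames)
    truth = _truth_for_step(
        model, plan, placement, spec, frames, stance_frames, TRUTH_THRESHOLD_KPA
    )
    if plan.noise_sd_kpa > 0:
        rng = rng if rng is not None else np.random.default_rng(plan.seed)
        frames = np.clip(
            frames + rng.normal(0.0, plan.noise_sd_kpa, size=frames.shape), 0.0, None
        )
    record = PressureRecord(spec=spec, frames=frames, t0=0.0)
    return record, truth


def generate_trial(
    models: Mapping[str, FootModel],
    plan: GaitPlan,
    *,
    spec: PlateSpec | None = None,
    meta: TrialMeta | None = None,
) -> tuple[PressureRecord, GroundTruth]:
    """Generate a whole trial: the frame-wise sum of all planned footsteps.

    Noise is added once, at trial level, after summing the noise-free
    footstep fields; ground truth masks therefore refer to the noise-free
    components.  A step whose mask touches the plate boundary is flagged
    spatially incomplete; a step active in the first or last frame is flagged
    temporally incomplete.
    """
    spec = spec or PlateSpec()
    if not plan.step_sequence:
        raise ValueError("plan has no footfalls")
    n_stance = int(round(plan.stance_s * spec.freq_hz))
    last_off = max(int(round(f.onset_s * spec.freq_hz)) for f in plan.step_sequence)
    n_frames = last_off + n_stance + plan.margin_frames
    total = np.zeros((n_frames, spec.n_rows, spec.n_cols))
    truths: list[StepTruth] = []
    for footfall in plan.step_sequence:
        model = models[footfall.label]
        _check_placement(model, footfall, spec)
        frames, stance_frames = _step_frames(model, plan, footfall, spec, n_frames)
        total += frames
        truths.append(
            _truth_for_step(
                model, plan, footfall, spec, frames, stance_frames, TRUTH_THRESHOLD_KPA
            )
        )
    if plan.noise_sd_kpa > 0:
        rng = np.random.default_rng(plan.seed)
        total = np.clip(
            total + rng.normal(0.0, plan.noise_sd_kpa, size=total.shape), 0.0, None
        )
    meta = meta or TrialMeta(side_hint="+y")
    record = PressureRecord(spec=spec, frames=total, t0=0.0, meta=meta)
    return record, GroundTruth(steps=truths)
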
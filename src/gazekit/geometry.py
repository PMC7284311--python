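"""Gaze geometry: eye-in-orbit, eye-in-head and head-in-space rotations.

The gaze direction of each eye in the ground-fixed frame is obtained by
chaining three rotations::

    R = R_head_in_space @ R_eye_in_head @ R_eye_in_orbit
    v_gaze = R @ e_axis

where ``e_axis`` is the unit vector along the resting eye axis.  The frame
is right-handed with X pointing forward along the naso-occipital axis, Y
pointing left along the interaural axis, and Z pointing up (dorsal).  Sign
conventions for the physiological angles:

* head pitch: nose-up positive,
* head roll: right-side-down positive,
* eye-axis azimuth: left of the midline positive (so the left eye sits at
  +60 degrees, the right eye at -60 degrees),
* eye-axis elevation: above the head plate positive,
* eye-in-orbit horizontal (``eyeh``): counter-clockwise viewed from above
  positive; vertical (``eyev``): upward positive.

Because the angle between a gaze vector and the horizontal ground plane is
invariant under rotations about the vertical axis, head yaw never enters
the elevation computation; only pitch and roll do.

Head orientations with pitch at or beyond 89 degrees approach gimbal lock
of the pitch/roll parameterization; such samples raise
:class:`GimbalLockError` and are flagged and skipped by callers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as _stats
from skimage import measure as _measure

__all__ = [
    "EyeOrbitAngles",
    "EyeAxisPlacement",
    "HeadTilt",
    "VisualFieldMap",
    "GimbalLockError",
    "EYE_AXIS_BASE",
    "GIMBAL_PITCH_LIMIT_DEG",
    "rotation_about_principal_axis",
    "compose_gaze_rotation",
    "gaze_vector",
    "elevation_to_horizontal",
    "eye_axis_angle",
    "gaze_elevation_series",
    "circular_stats",
    "visual_field_coverage",
    "binocular_map_and_contours",
]

#: Unit vector along the resting eye axis in its local frame (forward).
EYE_AXIS_BASE = np.array([1.0, 0.0, 0.0])

#: Head pitch magnitude (degrees) at or beyond which the pitch/roll
#: parameterization is treated as degenerate.
GIMBAL_PITCH_LIMIT_DEG = 89.0

_ORTHO_TOL = 1e-9


class GimbalLockError(ValueError):
    """Raised when head pitch is too close to +/-90 degrees."""


@dataclass(frozen=True)
class EyeOrbitAngles:
    """Eye position within the orbit, degrees.

    ``eyeh`` is the horizontal angular displacement (counter-clockwise
    viewed from above positive), ``eyev`` the vertical displacement
    (upward positive).
    """

    eyeh: float
    eyev: float

    def __post_init__(self) -> None:
        for name, val in (("eyeh", self.eyeh), ("eyev", self.eyev)):
            if not np.isfinite(val):
                raise ValueError(f"{name} must be finite")
            if abs(val) >= 90:
                raise ValueError(f"|{name}| must be < 90 deg, got {val}")


@dataclass(frozen=True)
class EyeAxisPlacement:
    """Resting orientation of one eye axis in the head frame.

    The default geometric model places the eye axes at +/-60 degrees
    azimuth from the midline and 30 degrees elevation above the head
    plate; an alternate model at (+/-64, 22) is available via
    :meth:`alternate`.
    """

    side: Literal["left", "right"]
    azimuth: float
    elevation: float

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if not (np.isfinite(self.azimuth) and np.isfinite(self.elevation)):
            raise ValueError("azimuth and elevation must be finite")

    @classmethod
    def default(cls, side: Literal["left", "right"]) -> "EyeAxisPlacement":
        return cls(side, 60.0 if side == "left" else -60.0, 30.0)

    @classmethod
    def alternate(cls, side: Literal["left", "right"]) -> "EyeAxisPlacement":
        return cls(side, 64.0 if side == "left" else -64.0, 22.0)


@dataclass(frozen=True)
class HeadTilt:
    """Head orientation relative to gravity: pitch (nose-up positive) and
    roll (right-side-down positive), degrees."""

    pitch: float
    roll: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.pitch) and np.isfinite(self.roll)):
            raise ValueError("pitch and roll must be finite")
        if abs(self.pitch) > 90:
            raise ValueError(f"|pitch| must be <= 90 deg, got {self.pitch}")
        if abs(self.roll) > 180:
            raise ValueError(f"|roll| must be <= 180 deg, got {self.roll}")


_AXIS_INDEX = {"roll": 0, "pitch": 1, "dorsal": 2}


def rotation_about_principal_axis(axis: str, angle_deg: float) -> np.ndarray:
    """Proper rotation by ``angle_deg`` about a principal body axis.

    Axes follow the right-hand rule in the X-forward / Y-left / Z-up
    frame: ``roll`` rotates about X, ``pitch`` about Y, ``dorsal`` about
    Z.  Note that a *physiological* nose-up pitch corresponds to a
    negative right-hand rotation about the leftward Y axis; the
    composition helpers below apply that sign mapping.
    """
    if axis not in _AXIS_INDEX:
        raise ValueError(f"axis must be one of {sorted(_AXIS_INDEX)}, got {axis!r}")
    if not np.isfinite(angle_deg):
        raise ValueError("angle must be finite")
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    i = _AXIS_INDEX[axis]
    R = np.eye(3)
    j, k = (i + 1) % 3, (i + 2) % 3
    R[j, j] = c
    R[k, k] = c
    R[k, j] = s
    R[j, k] = -s
    return R


def _check_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("rotation matrix must be 3x3")
    if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
        raise ValueError("matrix is not orthonormal")
    if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
        raise ValueError("matrix is not a proper rotation (det != +1)")
    return R


def head_in_space(tilt: HeadTilt) -> np.ndarray:
    """Head orientation rotation: roll about the forward axis applied
    after pitch about the interaural axis."""
    if abs(tilt.pitch) >= GIMBAL_PITCH_LIMIT_DEG:
        raise GimbalLockError(
            f"head pitch {tilt.pitch:.1f} deg is within "
            f"{90 - GIMBAL_PITCH_LIMIT_DEG:.0f} deg of gimbal lock"
        )
    # nose-up = negative right-hand rotation about +Y (leftward)
    return rotation_about_principal_axis("roll", tilt.roll) @ rotation_about_principal_axis(
        "pitch", -tilt.pitch
    )


def eye_in_head(placement: EyeAxisPlacement) -> np.ndarray:
    """Eye-axis placement rotation: azimuth about the dorsal axis applied
    after elevation about the interaural axis."""
    return rotation_about_principal_axis("dorsal", placement.azimuth) @ rotation_about_principal_axis(
        "pitch", -placement.elevation
    )


def eye_in_orbit(orbit: EyeOrbitAngles) -> np.ndarray:
    """Eye-in-orbit rotation: horizontal displacement applied after
    vertical displacement (left-to-right product order)."""
    return rotation_about_principal_axis("dorsal", orbit.eyeh) @ rotation_about_principal_axis(
        "pitch", -orbit.eyev
    )


def compose_gaze_rotation(
    orbit: EyeOrbitAngles, placement: EyeAxisPlacement, tilt: HeadTilt
) -> np.ndarray:
    """Full gaze rotation: head-in-space x eye-in-head x eye-in-orbit."""
    return head_in_space(tilt) @ eye_in_head(placement) @ eye_in_orbit(orbit)


def gaze_vector(R: np.ndarray) -> np.ndarray:
    """Unit gaze vector in the ground frame: ``R`` applied to the eye-axis
    base vector."""
    R = _check_rotation(R)
    return R @ EYE_AXIS_BASE


def elevation_to_horizontal(v: np.ndarray) -> float:
    """Signed angle (degrees, in [-90, 90]) between a unit gaze vector
    and the horizontal plane; negative means pointing below it."""
    v = np.asarray(v, dtype=float)
    nrm = np.linalg.norm(v)
    if not np.isfinite(nrm) or nrm < 1e-12:
        raise ValueError("gaze vector must be nonzero and finite")
    if abs(nrm - 1.0) > 1e-6:
        raise ValueError(f"gaze vector must be unit norm, got |v| = {nrm}")
    return float(np.rad2deg(np.arcsin(np.clip(v[2] / nrm, -1.0, 1.0))))


def eye_axis_angle(placement: EyeAxisPlacement, tilt: HeadTilt) -> float:
    """Elevation of the resting eye axis (orbit angles zeroed) above the
    horizontal plane, degrees."""
    R = compose_gaze_rotation(EyeOrbitAngles(0.0, 0.0), placement, tilt)
    return elevation_to_horizontal(gaze_vector(R))


def gaze_elevation_series(
    eyeh: np.ndarray,
    eyev: np.ndarray,
    pitch: np.ndarray,
    roll: np.ndarray,
    placement: EyeAxisPlacement,
) -> np.ndarray:
    """Vectorized per-sample gaze elevation over aligned angle series.

    Samples with any missing (NaN) input or a head pitch inside the
    gimbal guard come back NaN.
    """
    eyeh = np.asarray(eyeh, float)
    eyev = np.asarray(eyev, float)
    pitch = np.asarray(pitch, float)
    roll = np.asarray(roll, float)
    out = np.full(eyeh.shape, np.nan)
    ok = (
        np.isfinite(eyeh)
        & np.isfinite(eyev)
        & np.isfinite(pitch)
        & np.isfinite(roll)
        & (np.abs(pitch) < GIMBAL_PITCH_LIMIT_DEG)
    )
    if not np.any(ok):
        return out
    # closed form for the Z component of R @ e_axis; derived by expanding
    # the five elemental rotations acting on the forward base vector
    eh = np.deg2rad(eyeh[ok])
    ev = np.deg2rad(eyev[ok])
    th = np.deg2rad(pitch[ok])
    ph = np.deg2rad(roll[ok])
    az = np.deg2rad(placement.azimuth)
    el = np.deg2rad(placement.elevation)
    # local gaze direction after orbit + placement, in the head frame
    x1 = np.cos(ev) * np.cos(eh)
    y1 = np.cos(ev) * np.sin(eh)
    z1 = np.sin(ev)
    x2 = np.cos(el) * x1 - np.sin(el) * z1
    z2 = np.sin(el) * x1 + np.cos(el) * z1
    xh = np.cos(az) * x2 - np.sin(az) * y1
    yh = np.sin(az) * x2 + np.cos(az) * y1
    zh = z2
    # head-in-space: pitch about Y (nose-up), then roll about X
    z3 = np.sin(th) * xh + np.cos(th) * zh
    zs = np.sin(ph) * yh + np.cos(ph) * z3
    out[ok] = np.rad2deg(np.arcsin(np.clip(zs, -1.0, 1.0)))
    return out


def circular_stats(angles_deg: Sequence[float]) -> tuple[float, float]:
    """Circular mean and circular standard deviation of angles in degrees.

    The mean is the argument of the mean resultant vector; the SD is the
    angular deviation ``sqrt(-2 ln Rbar)`` expressed in degrees.
    """
    a = np.asarray(angles_deg, dtype=float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        raise ValueError("circular_stats requires at least one finite angle")
    rad = np.deg2rad(a)
    z = np.mean(np.exp(1j * rad))
    rbar = np.abs(z)
    if rbar < 1e-12:
        raise ValueError("mean resultant length is zero; circular mean undefined")
    mean = np.rad2deg(np.angle(z))
    sd = np.rad2deg(_stats.circstd(rad, high=np.pi, low=-np.pi))
    return float(mean), float(sd)


@dataclass
class VisualFieldMap:
    """Normalized visual-field coverage of one eye on a spherical grid.

    ``counts[i, j]`` is the fraction of frames on which the grid point at
    elevation ``elevations[i]``, azimuth ``azimuths[j]`` was inside the
    eye's field; 1 means covered on every frame.
    """

    azimuths: np.ndarray  # degrees, ascending, covers [-180, 180)
    elevations: np.ndarray  # degrees, ascending, covers [-90, 90]
    counts: np.ndarray  # (n_elev, n_az), values in [0, 1]
    n_frames: int

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.elevations), len(self.azimuths)):
            raise ValueError("counts shape must be (n_elev, n_az)")

    @property
    def spacing(self) -> float:
        return float(self.azimuths[1] - self.azimuths[0])


def _sphere_grid(spacing: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if spacing <= 0 or abs(360.0 / spacing - round(360.0 / spacing)) > 1e-9:
        raise ValueError("grid spacing must divide 360 evenly")
    az = np.arange(-180.0, 180.0, spacing)
    el = np.arange(-90.0, 90.0 + spacing / 2, spacing)
    azg, elg = np.meshgrid(np.deg2rad(az), np.deg2rad(el))
    pts = np.stack(
        [np.cos(elg) * np.cos(azg), np.cos(elg) * np.sin(azg), np.sin(elg)], axis=-1
    )
    return az, el, pts  # pts shape (n_el, n_az, 3), unit vectors


def visual_field_coverage(
    gaze: np.ndarray,
    grid_spacing: float = 2.0,
    monocular_halffield_deg: float = 180.0,
    point_radius_cm: float = 100.0,
    eye_center_cm: np.ndarray | None = None,
    chunk: int = 2000,
) -> VisualFieldMap:
    """Fraction of frames on which each spherical grid point is visible.

    A grid point at ``point_radius_cm`` from the animal is visible when
    the angle between the vector from the eye center to the point and the
    gaze vector is less than half the monocular field (for the default
    180-degree field this reduces to a positive projection onto the gaze
    direction).  Counts are normalized by the number of frames.

    Parameters
    ----------
    gaze : ndarray, shape (n_frames, 3)
        Per-frame unit gaze vectors in the ground frame.
    eye_center_cm : ndarray, optional
        Eye-center position(s), shape (3,) or (n_frames, 3).  Defaults to
        the origin; at the default 1 m point radius a 0.5 cm offset is
        negligible.
    """
    gaze = np.atleast_2d(np.asarray(gaze, dtype=float))
    if gaze.ndim != 2 or gaze.shape[1] != 3:
        raise ValueError("gaze must have shape (n_frames, 3)")
    valid = np.all(np.isfinite(gaze), axis=1)
    gaze = gaze[valid]
    n = gaze.shape[0]
    if n == 0:
        raise ValueError("visual_field_coverage requires at least one valid frame")
    az, el, pts = _sphere_grid(grid_spacing)
    pts_cm = pts * point_radius_cm
    flat = pts_cm.reshape(-1, 3)  # (P, 3)
    cos_half = np.cos(np.deg2rad(monocular_halffield_deg / 2.0))
    if eye_center_cm is None:
        centers = np.zeros((n, 3))
    else:
        centers = np.broadcast_to(
            np.atleast_2d(np.asarray(eye_center_cm, dtype=float)), (n, 3)
        )
        if eye_center_cm is not None and np.asarray(eye_center_cm).ndim == 2:
            centers = np.asarray(eye_center_cm, dtype=float)[valid]
    counts = np.zeros(flat.shape[0])
    for i0 in range(0, n, chunk):
        g = gaze[i0 : i0 + chunk]
        c = centers[i0 : i0 + chunk]
        # rel[p, f, :] = point p minus eye center on frame f
        rel = flat[:, None, :] - c[None, :, :]
        proj = np.einsum("pfk,fk->pf", rel, g)
        if cos_half <= 0 and abs(cos_half) < 1e-12:
            vis = proj > 0
        else:
            nrm = np.linalg.norm(rel, axis=2)
            vis = proj > cos_half * nrm
        counts += vis.sum(axis=1)
    counts /= n
    return VisualFieldMap(az, el, counts.reshape(pts.shape[:2]), n)


def binocular_map_and_contours(
    left: VisualFieldMap, right: VisualFieldMap, level: float = 0.5
) -> tuple[np.ndarray, dict[str, list[np.ndarray]]]:
    """Summed binocular coverage map and per-eye iso-contours.

    Returns the cellwise sum of the two normalized maps (values in
    [0, 2]; cells above 1 are the binocular zone) and, per eye,
    marching-squares contours at ``level`` as arrays of
    (elevation, azimuth) vertices in degrees.
    """
    if left.counts.shape != right.counts.shape or not np.allclose(
        left.azimuths, right.azimuths
    ):
        raise ValueError("left and right maps must share the same grid")
    summed = left.counts + right.counts
    contours: dict[str, list[np.ndarray]] = {}
    for name, m in (("left", left), ("right", right)):
        polys = []
        for c in _measure.find_contours(m.counts, level):
            el = np.interp(c[:, 0], np.arange(len(m.elevations)), m.elevations)
            az = np.interp(c[:, 1], np.arange(len(m.azimuths)), m.azimuths)
            polys.append(np.column_stack([el, az]))
        contours[name] = polys
    return summed, contours
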
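"""Analytic MEG forward model for a spherically symmetric conductor.

The magnetic field of a current dipole inside a homogeneous conducting
sphere has a closed-form solution (the Sarvas formula).  Two of its
properties carry the whole forward model used here:

* linearity in the dipole moment, so an ``M x 3`` lead-field matrix
  ``L(p)`` fully describes a source location, and
* radial silence — the radial component of the moment produces no field
  outside the sphere, so only tangential moments are observable.

The lead-field *provider* is a contract: anything that maps a grid of
source locations to a dense ``(n, M, 3)`` array can stand behind the
simulator and the scanning localizer (see :class:`PrecomputedLeadField`
for user-supplied matrices).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

MU0_OVER_4PI = 1e-7  # T·m/A

__all__ = [
    "SensorArray",
    "SphereModel",
    "Dipole",
    "HeadPerturbation",
    "helmet_array",
    "dipole_field",
    "lead_field",
    "lead_field_grid",
    "mixing_matrix",
    "perturb_geometry",
    "rotation_matrix",
    "read_sensor_table",
    "SphereLeadField",
    "PrecomputedLeadField",
]


@dataclass(frozen=True)
class SphereModel:
    """Spherical conductor: ``center`` (m) and ``radius`` (m)."""

    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.center.shape != (3,):
            raise ValueError("sphere center must be a 3-vector")
        if not self.radius > 0:
            raise ValueError("sphere radius must be positive")


@dataclass(frozen=True)
class SensorArray:
    """Positions (m), unit sensing orientations and labels of M magnetometers."""

    positions: np.ndarray
    orientations: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        ori = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        if pos.shape != ori.shape or pos.shape[1] != 3 or pos.shape[0] < 1:
            raise ValueError("positions and orientations must both be (M, 3), M >= 1")
        norms = np.linalg.norm(ori, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("sensor orientations must be unit vectors (|n| = 1 ± 1e-9)")
        labels = self.labels or tuple(f"MEG{i:04d}" for i in range(pos.shape[0]))
        if len(labels) != pos.shape[0]:
            raise ValueError("label count must match sensor count")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "orientations", ori)
        object.__setattr__(self, "labels", tuple(labels))

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]

    def validate_against(self, sphere: SphereModel) -> None:
        """All sensors must sit strictly outside the conductor."""
        r = np.linalg.norm(self.positions - sphere.center, axis=1)
        if np.any(r <= sphere.radius):
            bad = np.nonzero(r <= sphere.radius)[0]
            raise ValueError(f"sensors inside the conductor sphere: indices {bad.tolist()}")


@dataclass(frozen=True)
class Dipole:
    """Current dipole: location ``p`` (m) and moment ``q`` (A·m)."""

    location: np.ndarray
    moment: np.ndarray

    def __post_init__(self) -> None:
        loc = np.asarray(self.location, dtype=float)
        mom = np.asarray(self.moment, dtype=float)
        if loc.shape != (3,) or mom.shape != (3,):
            raise ValueError("dipole location and moment must be 3-vectors")
        if not np.all(np.isfinite(mom)):
            raise ValueError("dipole moment must be finite")
        object.__setattr__(self, "location", loc)
        object.__setattr__(self, "moment", mom)


@dataclass(frozen=True)
class HeadPerturbation:
    """Rigid misregistration of the source space: translation (mm) + rotation (deg)."""

    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation_axis: str = "z"
    rotation_angle_deg: float = 0.0
    rotation_origin: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.translation_mm, dtype=float)
        if t.shape != (3,) or not np.all(np.isfinite(t)):
            raise ValueError("translation must be a finite 3-vector in millimeters")
        if self.rotation_axis not in ("x", "y", "z"):
            raise ValueError("rotation_axis must be one of 'x', 'y', 'z'")
        if not np.isfinite(self.rotation_angle_deg):
            raise ValueError("rotation angle must be finite")
        object.__setattr__(self, "translation_mm", t)
        if self.rotation_origin is not None:
            o = np.asarray(self.rotation_origin, dtype=float)
            if o.shape != (3,):
                raise ValueError("rotation_origin must be a 3-vector (meters)")
            object.__setattr__(self, "rotation_origin", o)

    @property
    def is_identity(self) -> bool:
        return not np.any(self.translation_mm) and self.rotation_angle_deg == 0.0


# minimum distance of a source from the sphere center; the closed form
# degenerates exactly at the center
MIN_CENTER_OFFSET = 1e-3


def _fibonacci_cap(n: int, cap_half_angle_deg: float) -> np.ndarray:
    """n quasi-uniform unit vectors on a spherical cap around +z (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    cos_min = np.cos(np.deg2rad(cap_half_angle_deg))
    # uniform in cos(theta) over [cos_min, 1]
    z = 1.0 - (i + 0.5) / n * (1.0 - cos_min)
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def helmet_array(
    m: int = 306,
    sphere: SphereModel | None = None,
    cap_half_angle_deg: float = 110.0,
    shell_radius_factor: float = 1.25,
) -> SensorArray:
    """Synthetic MEG helmet: ``m`` radial magnetometers quasi-uniform on a spherical cap.

    The cap covers 110 degrees of half-angle around +z at 1.25 conductor
    radii, a whole-head-helmet stand-in.  Radial orientations make every
    sensor blind to volume currents, which keeps the primary-current
    Biot-Savart expression exact for the measured component.
    """
    if sphere is None:
        sphere = SphereModel(center=np.zeros(3), radius=0.09)
    radial = _fibonacci_cap(m, cap_half_angle_deg)
    positions = sphere.center + shell_radius_factor * sphere.radius * radial
    return SensorArray(positions=positions, orientations=radial)


def _check_inside(locations: np.ndarray, sphere: SphereModel) -> None:
    loc = np.atleast_2d(locations)
    d = np.linalg.norm(loc - sphere.center, axis=1)
    if np.any(d >= sphere.radius):
        raise ValueError("dipole location(s) outside or on the conductor sphere")
    if np.any(d < MIN_CENTER_OFFSET):
        raise ValueError(
            f"dipole location(s) within {MIN_CENTER_OFFSET * 1e3:.0f} mm of the sphere "
            "center: the spherical-conductor formula degenerates there"
        )


def _sarvas_field(p: np.ndarray, q: np.ndarray, sensors: SensorArray, sphere: SphereModel) -> np.ndarray:
    """Field of dipole (p, q) projected on each sensor orientation (Sarvas closed form)."""
    r = sensors.positions - sphere.center  # (M, 3)
    p0 = p - sphere.center  # (3,)
    a_vec = r - p0  # (M, 3)
    a = np.linalg.norm(a_vec, axis=1)  # (M,)
    rn = np.linalg.norm(r, axis=1)  # (M,)
    ar = np.einsum("ij,ij->i", a_vec, r)  # a_vec · r
    p0r = r @ p0
    F = a * (rn * a + rn**2 - p0r)
    gF = (
        (a**2 / rn + ar / a + 2.0 * a + 2.0 * rn)[:, None] * r
        - (a + 2.0 * rn + ar / a)[:, None] * p0[None, :]
    )
    qxp = np.cross(q, p0)  # (3,)
    B = MU0_OVER_4PI / F[:, None] ** 2 * (F[:, None] * qxp[None, :] - (r @ qxp)[:, None] * gF)
    return np.einsum("ij,ij->i", B, sensors.orientations)


def dipole_field(dipole: Dipole, sensors: SensorArray, sphere: SphereModel) -> np.ndarray:
    """M-vector of the dipole's field projected onto the sensor orientations (tesla)."""
    _check_inside(dipole.location, sphere)
    sensors.validate_against(sphere)
    return _sarvas_field(dipole.location, dipole.moment, sensors, sphere)


def lead_field(p: np.ndarray, sensors: SensorArray, sphere: SphereModel) -> np.ndarray:
    """M x 3 lead-field matrix at location ``p``: column j = field of unit moment e_j."""
    p = np.asarray(p, dtype=float)
    _check_inside(p, sphere)
    sensors.validate_against(sphere)
    cols = [_sarvas_field(p, e, sensors, sphere) for e in np.eye(3)]
    return np.column_stack(cols)


def lead_field_grid(points: np.ndarray, sensors: SensorArray, sphere: SphereModel) -> np.ndarray:
    """Dense ``(n, M, 3)`` lead-field tensor over a grid of source locations.

    Vectorized over grid points; identical to stacking :func:`lead_field`
    per point but orders of magnitude faster for thousand-point grids.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    _check_inside(pts, sphere)
    sensors.validate_against(sphere)
    r = sensors.positions - sphere.center  # (M, 3)
    p0 = pts - sphere.center  # (n, 3)
    a_vec = r[None, :, :] - p0[:, None, :]  # (n, M, 3)
    a = np.linalg.norm(a_vec, axis=2)  # (n, M)
    rn = np.linalg.norm(r, axis=1)[None, :]  # (1, M)
    ar = np.einsum("nmj,mj->nm", a_vec, r)
    p0r = p0 @ r.T  # (n, M)
    F = a * (rn * a + rn**2 - p0r)
    gF = (
        (a**2 / rn + ar / a + 2.0 * a + 2.0 * rn)[..., None] * r[None, :, :]
        - (a + 2.0 * rn + ar / a)[..., None] * p0[:, None, :]
    )
    # q x p0 for unit moments e_k gives rows of the cross-product matrix [e_k x p0]
    # build (n, 3, 3) with row k = e_k x p0
    n = pts.shape[0]
    qxp = np.zeros((n, 3, 3))
    x, y, z = p0[:, 0], p0[:, 1], p0[:, 2]
    qxp[:, 0] = np.stack([np.zeros(n), -z, y], axis=1)  # e_x × p0
    qxp[:, 1] = np.stack([z, np.zeros(n), -x], axis=1)  # e_y × p0
    qxp[:, 2] = np.stack([-y, x, np.zeros(n)], axis=1)  # e_z × p0
    r_dot_qxp = np.einsum("mj,nkj->nmk", r, qxp)  # (n, M, 3)
    B = MU0_OVER_4PI / F[..., None, None] ** 2 * (
        F[..., None, None] * qxp[:, None, :, :] - r_dot_qxp[..., None] * gF[:, :, None, :]
    )  # (n, M, 3moment, 3fieldcomp)
    return np.einsum("nmkj,mj->nmk", B, sensors.orientations)


def mixing_matrix(
    locations: np.ndarray,
    orientations: np.ndarray,
    sensors: SensorArray,
    sphere: SphereModel,
) -> np.ndarray:
    """M x Q mixing matrix: column q is the topography L(p_q) @ q_q."""
    P = np.atleast_2d(np.asarray(locations, dtype=float))
    O = np.atleast_2d(np.asarray(orientations, dtype=float))
    if P.shape != O.shape or P.shape[1] != 3:
        raise ValueError("locations and orientations must both be (Q, 3)")
    L = lead_field_grid(P, sensors, sphere)  # (Q, M, 3)
    return np.einsum("qmk,qk->mq", L, O)


def rotation_matrix(axis: str, angle_deg: float) -> np.ndarray:
    """3x3 rotation about a coordinate axis."""
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
    raise ValueError("axis must be 'x', 'y' or 'z'")


def perturb_geometry(
    points: np.ndarray,
    perturbation: HeadPerturbation,
    sphere: SphereModel | None = None,
) -> np.ndarray:
    """Apply a rigid misregistration to source locations (sensor array fixed).

    Rotation first (about ``rotation_origin``, default the sphere center),
    then translation.  If a sphere is given, every transformed point must
    remain inside the conductor; offenders are reported by index.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    origin = perturbation.rotation_origin
    if origin is None:
        origin = sphere.center if sphere is not None else np.zeros(3)
    R = rotation_matrix(perturbation.rotation_axis, perturbation.rotation_angle_deg)
    out = (pts - origin) @ R.T + origin + perturbation.translation_mm * 1e-3
    if sphere is not None:
        d = np.linalg.norm(out - sphere.center, axis=1)
        bad = np.nonzero(d >= sphere.radius)[0]
        if bad.size:
            raise ValueError(
                f"perturbation moves source points outside the conductor: indices {bad.tolist()}"
            )
    return out


def read_sensor_table(path: str | Path) -> SensorArray:
    """Read a plain-text sensor table: ``label x y z nx ny nz`` per row.

    Whitespace- or comma-delimited; ``#`` starts a comment.  Coordinates in
    meters, orientations unit-norm.
    """
    labels: list[str] = []
    rows: list[list[float]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 7:
            raise ValueError(f"sensor table row needs 7 fields (label x y z nx ny nz): {raw!r}")
        labels.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    if not rows:
        raise ValueError(f"sensor table {path} contains no sensors")
    arr = np.asarray(rows)
    return SensorArray(positions=arr[:, :3], orientations=arr[:, 3:], labels=tuple(labels))


class SphereLeadField:
    """Lead-field provider backed by the analytic spherical-conductor model."""

    def __init__(self, sensors: SensorArray, sphere: SphereModel):
        self.sensors = sensors
        self.sphere = sphere

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return lead_field_grid(points, self.sensors, self.sphere)


class PrecomputedLeadField:
    """Lead-field provider backed by a user-supplied dense matrix.

    The HDF5 container holds ``lead_fields`` (n, M, 3) and ``points``
    (n, 3); queries must match stored grid points exactly (no
    interpolation — the scanning grid is the stored grid).
    """

    def __init__(self, points: np.ndarray, lead_fields: np.ndarray):
        points = np.asarray(points, dtype=float)
        lead_fields = np.asarray(lead_fields, dtype=float)
        if points.ndim != 2 or points.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        if lead_fields.ndim != 3 or lead_fields.shape[0] != points.shape[0] or lead_fields.shape[2] != 3:
            raise ValueError("lead_fields must be (n, M, 3) matching points")
        self.points = points
        self.lead_fields = lead_fields

    @classmethod
    def from_file(cls, path: str | Path) -> "PrecomputedLeadField":
        with h5py.File(path, "r") as f:
            for key in ("points", "lead_fields"):
                if key not in f:
                    raise KeyError(f"lead-field container missing dataset {key!r}")
            return cls(points=f["points"][...], lead_fields=f["lead_fields"][...])

    def to_file(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("points", data=self.points)
            f.create_dataset("lead_fields", data=self.lead_fields)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.empty((pts.shape[0],) + self.lead_fields.shape[1:])
        for i, p in enumerate(pts):
            match = np.nonzero(np.all(np.isclose(self.points, p, atol=1e-12), axis=1))[0]
            if not match.size:
                raise KeyError(f"point {p} not in the precomputed lead-field grid")
            out[i] = self.lead_fields[match[0]]
        return out
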
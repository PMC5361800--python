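"""Synthetic 4D phase-contrast flow phantoms with analytic ground truth.

The generator emulates the statistical structure of a thoracic-aorta
4D-flow acquisition at desk scale: pulsatile laminar flow through a
straight or U-bend tube embedded in static tissue, with a thin air gap
between lumen and tissue.  Three corruption mechanisms mirror the
artifacts the preprocessing stage must undo:

* **velocity aliasing** — stored values wrap into ``[-venc, +venc)``,
* **eddy-current phase offsets** — a first-order spatial polynomial added
  identically to every frame of each component,
* **Gaussian velocity noise** everywhere (air voxels carry pure noise).

Axial velocity profiles: Poiseuille (parabolic), plug, or Womersley
(oscillatory Bessel-function solution for pulsatile pipe flow).  Ground
truth attached to every dataset includes the lumen mask, the wall shear
stress magnitude per frame from the analytic profile, the mean-speed
waveform, and the injected artifact parameters.

Default acquisition parameters follow a typical clinical protocol:
venc 1.5 m/s, 16 cardiac frames at 40 ms, 2 mm isotropic voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy.special import jv

from .datatypes import Centerline, LumenMask, VelocityField4D

__all__ = ["PhantomSpec", "PhantomDataset", "make_phantom", "inject_artifacts",
           "simulate", "wrap_velocity", "womersley_axial_profile",
           "analytic_wall_shear"]


# ---------------------------------------------------------------------------
# specification


@dataclass
class PhantomSpec:
    """Parameters of one synthetic acquisition.

    Lengths mm, speeds m/s, times ms, angular speed rad/s, viscosity Pa·s,
    density kg/m³.  ``harmonics`` are complex axial-velocity amplitudes at
    the wall-free tube center for frequencies ``k / cycle``; ``harmonics[0]``
    is the steady Poiseuille component.  ``eddy_coeffs`` has shape (3, 4):
    per velocity component ``[offset, d/dx, d/dy, d/dz]`` with gradients in
    m/s per mm.
    """

    geometry: str = "straight_tube"         # or "u_bend_tube"
    tube_radius: float = 10.0               # mm
    bend_radius: float = 25.0               # mm, u_bend only
    leg_length: float = 20.0                # mm, u_bend only
    grid_shape: tuple = (40, 40, 40)
    voxel_size: tuple = (2.0, 2.0, 2.0)     # mm
    n_frames: int = 16
    frame_duration: float = 40.0            # ms
    venc: tuple = (1.5, 1.5, 1.5)           # m/s
    v_profile: str = "poiseuille"           # poiseuille | womersley | plug
    v_max: float = 1.0                      # m/s (peak of steady profile)
    harmonics: Optional[tuple] = None       # womersley amplitudes, m/s
    swirl_rate: float = 0.0                 # rad/s about the tube axis
    reversed_flow_patch: Optional[dict] = None
    noise_sd: float = 0.0                   # m/s
    eddy_coeffs: Optional[np.ndarray] = None
    air_gap: Optional[float] = None         # mm; default 3 * max voxel size
    viscosity: float = 3.2e-3               # Pa·s, used for truth WSS
    density: float = 1060.0                 # kg/m³, Womersley number
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if self.harmonics is not None:
            self.harmonics = tuple(complex(h) if isinstance(h, complex)
                                   else float(h) for h in self.harmonics)
        self.voxel_size = tuple(float(v) for v in np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)))
        self.venc = tuple(float(v) for v in np.broadcast_to(
            np.asarray(self.venc, dtype=float), (3,)))
        if self.eddy_coeffs is not None:
            self.eddy_coeffs = np.asarray(self.eddy_coeffs, dtype=float).reshape(3, 4)
        if self.air_gap is None:
            self.air_gap = 3.0 * max(self.voxel_size)
        self.validate()

    def validate(self) -> None:
        if self.geometry not in ("straight_tube", "u_bend_tube"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.v_profile not in ("poiseuille", "womersley", "plug"):
            raise ValueError(f"unknown v_profile {self.v_profile!r}")
        if self.tube_radius < 3.0 * max(self.voxel_size):
            raise ValueError(
                "tube_radius under-resolved: need tube_radius >= 3 * max(voxel_size) "
                f"({self.tube_radius} mm < {3.0 * max(self.voxel_size)} mm)")
        if self.n_frames < 5:
            raise ValueError("n_frames must be >= 5")
        if any(v <= 0 for v in self.venc):
            raise ValueError("venc must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.v_profile == "womersley" and self.harmonics is None:
            raise ValueError("womersley profile requires harmonics")

    @property
    def cycle_duration_s(self) -> float:
        return self.n_frames * self.frame_duration * 1e-3

    @property
    def omega(self) -> float:
        """Fundamental angular frequency of the cardiac cycle, rad/s."""
        return 2.0 * np.pi / self.cycle_duration_s

    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_duration * 1e-3

    def to_json_dict(self) -> dict:
        d = asdict(self)
        if d["eddy_coeffs"] is not None:
            d["eddy_coeffs"] = np.asarray(d["eddy_coeffs"]).tolist()
        return d


@dataclass
class PhantomDataset:
    """One synthetic acquisition plus its ground truth.

    ``velocity`` is what the scanner would store (possibly corrupted);
    ``truth_velocity`` the clean field.  ``truth_wss`` is the analytic wall
    shear stress magnitude per frame (spatially uniform on the straight-tube
    family, hence one value per frame).  ``truth_params`` records the
    injected artifact parameters.
    """

    velocity: VelocityField4D
    magnitude: np.ndarray
    truth_mask: LumenMask
    truth_velocity: np.ndarray
    truth_wss: np.ndarray
    truth_waveform: np.ndarray
    truth_params: dict
    truth_centerline: Centerline
    air_mask: np.ndarray
    tissue_mask: np.ndarray
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# geometry

def _tube_geometry(spec: PhantomSpec):
    """Distance to centerline, unit tangent, and unit radial per voxel.

    Returns (dist, tangent, radial, arc_s) with shapes (nx,ny,nz),
    (nx,ny,nz,3), (nx,ny,nz,3), (nx,ny,nz); radial is zero on the axis.
    Also returns the analytic centerline sampled densely.
    """
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.voxel_size
    x = np.arange(nx) * dx
    y = np.arange(ny) * dy
    z = np.arange(nz) * dz
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")

    if spec.geometry == "straight_tube":
        cx, cy = x.mean(), y.mean()
        dist = np.hypot(X - cx, Y - cy)
        tangent = np.zeros(spec.grid_shape + (3,))
        tangent[..., 2] = 1.0
        radial = np.stack([X - cx, Y - cy, np.zeros_like(X)], axis=-1)
        arc_s = Z.copy()
        s = np.linspace(0.0, z[-1], 200)
        cl_pts = np.stack([np.full_like(s, cx), np.full_like(s, cy), s], axis=1)
        return dist, tangent, radial, arc_s, cl_pts

    # u_bend_tube: leg up (+z), half circle in the x-z plane, leg down (-z)
    Rb, L = spec.bend_radius, spec.leg_length
    cy0 = y.mean()
    total_x = 2.0 * Rb
    x1 = (x[-1] - total_x) / 2.0          # entry-leg x position
    x2 = x1 + 2.0 * Rb                    # exit-leg x position
    z0 = (z[-1] - (L + Rb)) / 2.0         # leg base
    z1 = z0 + L                           # leg top / arc start
    cxc, czc = x1 + Rb, z1                # arc center in x-z

    # candidate 1: entry leg, direction +z
    t1 = np.clip(Z - z0, 0.0, L)
    p1 = np.stack([np.full_like(X, x1), np.full_like(Y, cy0), z0 + t1], axis=-1)
    # candidate 2: arc, phi from pi (entry) to 0 (exit)
    phi = np.arctan2(Z - czc, X - cxc)
    phi = np.clip(phi, 0.0, np.pi)
    p2 = np.stack([cxc + Rb * np.cos(phi),
                   np.full_like(Y, cy0),
                   czc + Rb * np.sin(phi)], axis=-1)
    # candidate 3: exit leg, direction -z
    t3 = np.clip(z1 - Z, 0.0, L)
    p3 = np.stack([np.full_like(X, x2), np.full_like(Y, cy0), z1 - t3], axis=-1)

    P = np.stack([X, Y, Z], axis=-1)
    cands = np.stack([p1, p2, p3], axis=0)                  # (3, nx,ny,nz, 3)
    d2 = np.sum((cands - P[None]) ** 2, axis=-1)
    pick = np.argmin(d2, axis=0)
    nearest = np.choose(pick[..., None].repeat(3, -1), [p1, p2, p3])
    dist = np.linalg.norm(P - nearest, axis=-1)

    tang1 = np.array([0.0, 0.0, 1.0])
    tang3 = np.array([0.0, 0.0, -1.0])
    # arc tangent for decreasing phi: (sin phi, 0, -cos phi)
    tang2 = np.stack([np.sin(phi), np.zeros_like(phi), -np.cos(phi)], axis=-1)
    tangent = np.where((pick == 0)[..., None], tang1,
                       np.where((pick == 2)[..., None], tang3, tang2))

    radial = P - nearest
    s1 = t1
    s2 = L + Rb * (np.pi - phi)
    s3 = L + np.pi * Rb + t3
    arc_s = np.where(pick == 0, s1, np.where(pick == 2, s3, s2))

    # dense analytic centerline
    n_each = 80
    sa = np.linspace(0, L, n_each, endpoint=False)
    leg1 = np.stack([np.full_like(sa, x1), np.full_like(sa, cy0), z0 + sa], 1)
    ph = np.linspace(np.pi, 0, 2 * n_each, endpoint=False)
    arc = np.stack([cxc + Rb * np.cos(ph), np.full_like(ph, cy0),
                    czc + Rb * np.sin(ph)], 1)
    sb = np.linspace(0, L, n_each)
    leg2 = np.stack([np.full_like(sb, x2), np.full_like(sb, cy0), z1 - sb], 1)
    cl_pts = np.vstack([leg1, arc, leg2])
    return dist, tangent, radial, arc_s, cl_pts


def _centerline_from_points(points: np.ndarray) -> Centerline:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    grad = np.gradient(points, s, axis=0)
    tangents = grad / np.linalg.norm(grad, axis=1, keepdims=True)
    d2 = np.gradient(tangents, s, axis=0)  # dT/ds = curvature vector
    curv = d2 - np.sum(d2 * tangents, axis=1, keepdims=True) * tangents
    return Centerline(points=points, arc_length=s, tangents=tangents,
                      curvature=curv)


# ---------------------------------------------------------------------------
# axial velocity profiles

def womersley_axial_profile(r, R_mm, t_s, harmonics, omega, viscosity, density):
    """Axial speed of pulsatile pipe flow (Womersley solution), m/s.

    ``harmonics[k]`` is the complex center amplitude of the k-th harmonic;
    k = 0 is the steady Poiseuille component.  ``r`` and ``R_mm`` in mm,
    ``t_s`` seconds.  Vectorized over ``r``.
    """
    r = np.asarray(r, dtype=float)
    R_m = R_mm * 1e-3
    nu = viscosity / density
    w = np.zeros(np.broadcast_shapes(r.shape, np.shape(t_s)), dtype=complex)
    xi = np.clip(r / R_mm, 0.0, 1.0)
    for k, A in enumerate(harmonics):
        if A == 0:
            continue
        if k == 0:
            w = w + A * (1.0 - xi ** 2)
            continue
        alpha = R_m * np.sqrt(k * omega / nu)
        lam = 1j ** 1.5 * alpha
        shape = 1.0 - jv(0, lam * xi) / jv(0, lam)
        w = w + A * shape * np.exp(1j * k * omega * np.asarray(t_s))
    return w.real


def _axial_speed(spec: PhantomSpec, dist: np.ndarray, t_s: float) -> np.ndarray:
    xi2 = np.clip(dist / spec.tube_radius, 0.0, 1.0) ** 2
    if spec.v_profile == "poiseuille":
        return spec.v_max * (1.0 - xi2)
    if spec.v_profile == "plug":
        return np.full_like(dist, spec.v_max)
    return womersley_axial_profile(dist, spec.tube_radius, t_s, spec.harmonics,
                                   spec.omega, spec.viscosity, spec.density)


def analytic_wall_shear(spec: PhantomSpec, t_s: float,
                        rel_step: float = 1e-4) -> float:
    """|WSS| at the wall from the analytic profile, N/m².

    One-sided numeric derivative of the axial profile at the wall with step
    ``rel_step * R`` (relative error < 1e-4 % on the parabolic profile).
    Undefined (NaN) for the plug profile.
    """
    if spec.v_profile == "plug":
        return float("nan")
    R = spec.tube_radius
    h = rel_step * R
    w_wall = float(np.atleast_1d(_axial_speed(spec, np.array([R]), t_s))[0])
    w_in = float(np.atleast_1d(_axial_speed(spec, np.array([R - h]), t_s))[0])
    dwdr = (w_in - w_wall) / (h * 1e-3)  # (m/s) per m
    return float(spec.viscosity * abs(dwdr))


# ---------------------------------------------------------------------------
# generation

def make_phantom(spec: PhantomSpec) -> PhantomDataset:
    """Build the clean phantom with ground truth (no artifacts).

    Deterministic given ``spec.seed`` (only the magnitude-image noise draws
    from it here).  Raises ``ValueError`` if the tube radius is
    under-resolved relative to the voxel size.
    """
    spec.validate()
    dist, tangent, radial, _arc, cl_pts = _tube_geometry(spec)
    lumen = dist <= spec.tube_radius
    air = (dist > spec.tube_radius) & (dist <= spec.tube_radius + spec.air_gap)
    tissue = dist > spec.tube_radius + spec.air_gap

    times = spec.frame_times_s()
    vals = np.zeros((spec.n_frames,) + spec.grid_shape + (3,))
    with np.errstate(invalid="ignore", divide="ignore"):
        r_hat = np.where(dist[..., None] > 0, radial / dist[..., None], 0.0)
    azim = np.cross(tangent, r_hat)

    for f, t in enumerate(times):
        w = np.where(lumen, _axial_speed(spec, dist, t), 0.0)
        v = w[..., None] * tangent
        if spec.swirl_rate:
            v_theta = spec.swirl_rate * dist * 1e-3  # solid body, m/s
            v = v + np.where(lumen, v_theta, 0.0)[..., None] * azim
        vals[f] = v

    if spec.reversed_flow_patch:
        _apply_patch(vals, spec, cl_pts)

    truth = vals.copy()
    waveform = np.array([np.linalg.norm(vals[f][lumen], axis=-1).mean()
                         for f in range(spec.n_frames)])
    truth_wss = np.array([analytic_wall_shear(spec, t) for t in times])

    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0]))
    mag = np.where(lumen | tissue, 100.0, 5.0)
    mag4 = np.broadcast_to(mag, (spec.n_frames,) + spec.grid_shape).copy()
    mag4 += rng.normal(0.0, 1.0, size=mag4.shape)
    np.clip(mag4, 0.0, None, out=mag4)

    field = VelocityField4D(vals, spec.voxel_size, spec.frame_duration, spec.venc)
    return PhantomDataset(
        velocity=field,
        magnitude=mag4,
        truth_mask=LumenMask(lumen, spec.voxel_size,
                             provenance={"source": "phantom truth"}),
        truth_velocity=truth,
        truth_wss=truth_wss,
        truth_waveform=waveform,
        truth_params={"eddy_coeffs": None, "noise_sd": 0.0,
                      "venc": list(spec.venc)},
        truth_centerline=_centerline_from_points(cl_pts),
        air_mask=air,
        tissue_mask=tissue,
        spec=spec,
    )


def _apply_patch(vals: np.ndarray, spec: PhantomSpec, cl_pts: np.ndarray) -> None:
    """Scale velocity inside a sphere to emulate a recirculation patch.

    Patch dict: ``arc_fraction`` along the centerline, ``side`` in
    {inner, outer, center}, ``radius`` (mm), ``factor`` (default -0.5,
    negative reverses flow locally), ``offset_frac`` of tube radius.
    """
    p = dict(spec.reversed_flow_patch)
    cl = _centerline_from_points(cl_pts)
    frac = float(p.get("arc_fraction", 0.6))
    idx = int(np.argmin(np.abs(cl.arc_fraction() - frac)))
    center = cl.points[idx].copy()
    side = p.get("side", "center")
    if side in ("inner", "outer"):
        kv = cl.curvature[idx]
        if np.linalg.norm(kv) < 1e-8:
            k_idx = int(np.argmax(np.linalg.norm(cl.curvature, axis=1)))
            kv = cl.curvature[k_idx]
        direction = kv / np.linalg.norm(kv)
        if side == "outer":
            direction = -direction
        center = center + p.get("offset_frac", 0.5) * spec.tube_radius * direction
    radius = float(p.get("radius", 0.6 * spec.tube_radius))
    factor = float(p.get("factor", -0.5))

    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.voxel_size
    X, Y, Z = np.meshgrid(np.arange(nx) * dx, np.arange(ny) * dy,
                          np.arange(nz) * dz, indexing="ij")
    inside = ((X - center[0]) ** 2 + (Y - center[1]) ** 2
              + (Z - center[2]) ** 2) <= radius ** 2
    vals[:, inside, :] *= factor


def wrap_velocity(v: np.ndarray, venc) -> np.ndarray:
    """Phase-contrast aliasing: fold values into ``[-venc, +venc)``."""
    venc = np.asarray(venc, dtype=float)
    return np.mod(v + venc, 2.0 * venc) - venc


def inject_artifacts(data: PhantomDataset, spec: PhantomSpec) -> PhantomDataset:
    """Corrupt the clean phantom: add eddy offsets and noise, then wrap.

    Stored value = ``wrap(v_true + eddy(x, y, z) + noise)`` per component;
    the eddy polynomial is identical across frames.  Pure function: with
    ``noise_sd = 0`` and no eddy coefficients, wrap-free voxels are
    bit-identical to the input.
    """
    vals = data.truth_velocity.copy()
    params = {"eddy_coeffs": None, "noise_sd": spec.noise_sd,
              "venc": list(spec.venc)}

    if spec.eddy_coeffs is not None:
        nx, ny, nz = spec.grid_shape
        dx, dy, dz = spec.voxel_size
        X, Y, Z = np.meshgrid(np.arange(nx) * dx, np.arange(ny) * dy,
                              np.arange(nz) * dz, indexing="ij")
        for c in range(3):
            a0, ax, ay, az = spec.eddy_coeffs[c]
            vals[..., c] += a0 + ax * X + ay * Y + az * Z
        params["eddy_coeffs"] = spec.eddy_coeffs.tolist()

    if spec.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1]))
        vals += rng.normal(0.0, spec.noise_sd, size=vals.shape)

    if spec.eddy_coeffs is not None or spec.noise_sd > 0 or \
            np.any(np.abs(vals) >= np.asarray(spec.venc)):
        vals = wrap_velocity(vals, np.asarray(spec.venc))

    field = VelocityField4D(vals, spec.voxel_size, spec.frame_duration, spec.venc)
    return PhantomDataset(
        velocity=field, magnitude=data.magnitude, truth_mask=data.truth_mask,
        truth_velocity=data.truth_velocity, truth_wss=data.truth_wss,
        truth_waveform=data.truth_waveform, truth_params=params,
        truth_centerline=data.truth_centerline, air_mask=data.air_mask,
        tissue_mask=data.tissue_mask, spec=spec,
    )


def simulate(spec: PhantomSpec) -> PhantomDataset:
    """Clean phantom plus injected artifacts in one call."""
    return inject_artifacts(make_phantom(spec), spec)
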
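"""Shared phantom fixtures.

Phantoms are generated once per session; tests must not mutate them.
"""

import numpy as np
import pytest

from aortaflow import PhantomSpec, make_phantom
from aortaflow.phantom import inject_artifacts


@pytest.fixture(scope="session")
def poiseuille20():
    """Steady parabolic flow, R = 10 mm at 20 voxels/diameter, noiseless."""
    spec = PhantomSpec(tube_radius=10.0, grid_shape=(40, 40, 36),
                       voxel_size=1.0, n_frames=6, v_profile="poiseuille",
                       v_max=1.0, seed=11)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def poiseuille_coarse():
    """Steady parabolic flow at clinical-like 10 voxels/diameter."""
    spec = PhantomSpec(tube_radius=10.0, grid_shape=(36, 36, 32),
                       voxel_size=2.0, n_frames=8, v_profile="poiseuille",
                       v_max=1.0, seed=5)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def womersley_pulsatile():
    """Single-harmonic pulsatile flow at a resolvable Womersley number.

    R = 2 mm, 0.15 mm voxels, 20 frames of 50 ms (alpha ~ 2.9): the
    oscillatory Stokes layer spans several voxels, so the wall model's
    assumptions hold and the analytic Bessel oracle is meaningful.
    """
    spec = PhantomSpec(tube_radius=2.0, grid_shape=(52, 52, 12),
                       voxel_size=0.15, n_frames=20, frame_duration=50.0,
                       v_profile="womersley", harmonics=(0.6, 0.3), seed=13)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def ubend():
    """U-bend tube: bend radius 50 mm (apex curvature 0.02 /mm)."""
    spec = PhantomSpec(geometry="u_bend_tube", tube_radius=10.0,
                       bend_radius=50.0, leg_length=20.0,
                       grid_shape=(64, 24, 48), voxel_size=2.5,
                       n_frames=6, v_profile="poiseuille", v_max=1.0, seed=17)
    return make_phantom(spec)


def make_swirl(rotation_deg: float, v_axial: float = 0.5, seed: int = 7,
               **kw) -> tuple:
    """Plug-flow phantom whose transit rotation equals ``rotation_deg``.

    Solid-body swirl is superposed on a plug profile so that every tracer
    transits the tube in the same time T = L / v and accumulates exactly
    omega * T of rotation.
    """
    spec_kw = dict(tube_radius=10.0, grid_shape=(36, 36, 32), voxel_size=2.0,
                   n_frames=8, frame_duration=40.0, v_profile="plug",
                   v_max=v_axial, seed=seed)
    spec_kw.update(kw)
    nz = spec_kw["grid_shape"][2]
    vox = np.broadcast_to(np.asarray(spec_kw["voxel_size"], float), (3,))
    length_m = (nz - 1) * vox[2] * 1e-3
    transit_s = length_m / v_axial
    omega = np.radians(rotation_deg) / transit_s
    spec = PhantomSpec(swirl_rate=omega, **spec_kw)
    return make_phantom(spec), omega


@pytest.fixture(scope="session")
def artifact_phantom():
    """Noiseless pulsatile phantom corrupted with known eddy offsets.

    Pure oscillatory flow (no steady harmonic): the lumen is excluded from
    the static-tissue mask by its temporal variation, and any slow near-wall
    voxel that slips in has exactly zero temporal mean, so the injected
    eddy polynomial is identifiable to machine precision.
    """
    eddy = np.array([[0.05, 0.001, 0.0, 0.0],
                     [0.02, 0.0, 0.0005, 0.0],
                     [-0.01, 0.0, 0.0, 0.0002]])
    spec = PhantomSpec(tube_radius=10.0, grid_shape=(36, 36, 28),
                       voxel_size=2.0, n_frames=8, v_profile="womersley",
                       harmonics=(0.0, 0.6), eddy_coeffs=eddy, noise_sd=0.0,
                       seed=23)
    return inject_artifacts(make_phantom(spec), spec)
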
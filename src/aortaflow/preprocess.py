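"""Phase-contrast preprocessing: noise masking, velocity anti-aliasing,
and eddy-current phase-offset correction.

The three corrections are applied in the order noise mask → unwrap →
static-tissue detection → eddy correction.  Unwrapping before the eddy fit
exactly inverts the corruption model ``stored = wrap(v + eddy + noise)``
whenever ``|v + eddy| < 2·venc``; static-tissue velocities are far below
venc, so their fit is unaffected either way.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .datatypes import VelocityField4D

__all__ = ["StaticTissueMask", "EddyFit", "mask_noise", "detect_static_tissue",
           "correct_eddy", "unwrap_velocity"]


@dataclass
class StaticTissueMask:
    """Voxels with high signal magnitude and temporally stable velocity."""

    mask: np.ndarray
    sd_threshold: float          # m/s, temporal-sd cut per component
    magnitude_threshold: float   # absolute magnitude cut used

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class EddyFit:
    """Spatial polynomial fitted to static-tissue velocity per component.

    ``coeffs[c]`` are the polynomial coefficients of component ``c`` in the
    monomial basis returned by :func:`_monomials` (world mm coordinates);
    offsets in m/s, gradients in m/s per mm.
    """

    coeffs: np.ndarray
    terms: list
    order: int
    residual_rms: np.ndarray
    n_static_voxels: int


def mask_noise(magnitude: np.ndarray, threshold_frac: float = 0.1) -> np.ndarray:
    """Flag background voxels whose signal is noise.

    A voxel is noise when its time-averaged magnitude is below
    ``threshold_frac`` times the robust maximum (99th percentile) of the
    time-averaged magnitude image.  Returns True where noise.
    """
    magnitude = np.asarray(magnitude, dtype=float)
    if np.any(magnitude < 0):
        raise ValueError("magnitude must be non-negative")
    mean_mag = magnitude.mean(axis=0) if magnitude.ndim == 4 else magnitude
    robust_max = np.percentile(mean_mag, 99)
    if robust_max <= 0:
        raise ValueError("no signal: magnitude image is all zero")
    return mean_mag < threshold_frac * robust_max


def detect_static_tissue(field: VelocityField4D, magnitude: np.ndarray,
                         sd_threshold: float = 0.05,
                         magnitude_frac: float = 0.1) -> StaticTissueMask:
    """Select static-tissue voxels as support for the eddy-current fit.

    Keeps voxels that are (a) not noise by :func:`mask_noise` with
    ``magnitude_frac`` and (b) temporally stable: the standard deviation
    over frames of every velocity component is below ``sd_threshold``.
    """
    if field.n_frames < 5:
        raise ValueError("need at least 5 frames to assess temporal stability")
    noise = mask_noise(magnitude, magnitude_frac)
    sd = field.values.std(axis=0)            # (nx, ny, nz, 3)
    stable = np.all(sd < sd_threshold, axis=-1)
    mask = stable & ~noise
    if not mask.any():
        raise ValueError(
            "no static tissue found; raise sd_threshold (currently "
            f"{sd_threshold} m/s) or lower magnitude_frac")
    mean_mag = np.asarray(magnitude, dtype=float)
    mean_mag = mean_mag.mean(axis=0) if mean_mag.ndim == 4 else mean_mag
    return StaticTissueMask(mask=mask, sd_threshold=sd_threshold,
                            magnitude_threshold=float(
                                magnitude_frac * np.percentile(mean_mag, 99)))


def _monomials(order: int) -> list:
    """Monomial exponent triples of total degree <= order, constant first."""
    terms = []
    for deg in range(order + 1):
        for ex in itertools.combinations_with_replacement(range(3), deg):
            powers = [ex.count(a) for a in range(3)]
            terms.append(tuple(powers))
    return terms


def _design_matrix(coords: np.ndarray, terms: list) -> np.ndarray:
    cols = [np.prod([coords[:, a] ** p for a, p in enumerate(t)], axis=0)
            for t in terms]
    return np.stack(cols, axis=1)


def correct_eddy(field: VelocityField4D, static: StaticTissueMask,
                 order: int = 1) -> tuple[VelocityField4D, EddyFit]:
    """Remove eddy-current phase offsets by a static-tissue polynomial fit.

    Per component, a spatial polynomial of total degree ``order`` is fitted
    (least squares) to the temporal-mean velocity over static voxels and
    subtracted from every voxel and frame.  The offset is modeled as
    time-invariant, matching the slowly varying eddy-current phase error.
    """
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    if not static.mask.any():
        raise ValueError("static tissue mask is empty")

    idx = np.argwhere(static.mask)
    coords = idx * field.voxel_size            # mm
    terms = _monomials(order)
    A = _design_matrix(coords, terms)
    rank = np.linalg.matrix_rank(A)
    if rank < len(terms):
        raise ValueError(
            f"rank-deficient eddy fit: static voxels span rank {rank} < "
            f"{len(terms)} terms; static tissue may be coplanar")

    mean_v = field.values.mean(axis=0)         # (nx, ny, nz, 3)
    b = mean_v[static.mask]                    # (n_static, 3)
    coeffs, _, _, _ = np.linalg.lstsq(A, b, rcond=None)
    resid = b - A @ coeffs
    residual_rms = np.sqrt(np.mean(resid ** 2, axis=0))

    xs, ys, zs = field.world_axes()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    grid_coords = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    fit_field = (_design_matrix(grid_coords, terms) @ coeffs).reshape(
        field.grid_shape + (3,))

    corrected = field.copy()
    corrected.values -= fit_field[None]
    fit = EddyFit(coeffs=coeffs.T.copy(), terms=terms, order=order,
                  residual_rms=residual_rms, n_static_voxels=len(b))
    return corrected, fit


_NEIGHBOR_OFFSETS = [(0, 1, 0, 0), (0, -1, 0, 0), (0, 0, 1, 0), (0, 0, -1, 0),
                     (0, 0, 0, 1), (0, 0, 0, -1), (1, 0, 0, 0), (-1, 0, 0, 0)]


def _shift4(vol: np.ndarray, off: tuple, fill: float) -> np.ndarray:
    """Shift a 4D array by ``off`` voxels, filling exposed borders."""
    out = np.full_like(vol, fill)
    src = []
    dst = []
    for o in off:
        if o == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif o > 0:
            src.append(slice(0, -o))
            dst.append(slice(o, None))
        else:
            src.append(slice(-o, None))
            dst.append(slice(0, o))
    out[tuple(dst)] = vol[tuple(src)]
    return out


def unwrap_velocity(field: VelocityField4D, seed_frac: float = 0.5,
                    ) -> tuple[VelocityField4D, int]:
    """Anti-aliasing: undo venc wrapping by seeded region growing.

    Per component, voxels with ``|v| <= seed_frac * venc`` form a trusted
    seed region (wrapping folds values near ±venc, so low-speed voxels are
    reliably unwrapped).  The region grows over spatial 6-neighbors and
    temporal neighbors; each newly reached voxel is compared to the median
    of its already-trusted neighbors and, when the difference exceeds venc,
    shifted by the multiple of 2·venc that minimizes it.  Growing to a
    fixed point makes the operation idempotent, and voxels differing from
    all neighbors by less than venc are never altered.

    Returns the unwrapped field and the number of voxel-component
    corrections.  Raises ``RuntimeError`` if some voxels remain unreachable.
    """
    out = field.copy()
    n_corrected = 0
    for c in range(3):
        venc = float(field.venc[c])
        vols = out.values[..., c]              # (T, nx, ny, nz) view
        visited = np.abs(vols) <= seed_frac * venc
        if not visited.any():
            flat = int(np.argmin(np.abs(vols)))
            visited.flat[flat] = True
        max_layers = sum(vols.shape) + field.n_frames
        for _ in range(max_layers):
            if visited.all():
                break
            nbr_vals = np.stack([_shift4(vols, off, np.nan)
                                 for off in _NEIGHBOR_OFFSETS])
            nbr_ok = np.stack([_shift4(visited.astype(float), off, 0.0)
                               for off in _NEIGHBOR_OFFSETS]) > 0.5
            nbr_vals[~nbr_ok] = np.nan
            frontier = (~visited) & nbr_ok.any(axis=0)
            if not frontier.any():
                break
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                med = np.nanmedian(nbr_vals, axis=0)
            diff = med - vols
            fix = frontier & (np.abs(diff) > venc)
            if fix.any():
                shift = np.round(diff[fix] / (2.0 * venc))
                vols[fix] += 2.0 * venc * shift
                n_corrected += int(np.count_nonzero(shift))
            visited |= frontier
        if not visited.all():
            raise RuntimeError(
                "velocity unwrapping did not reach "
                f"{int((~visited).sum())} voxels of component {c}")
    return out, n_corrected
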
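"""Forward simulator for parallel-beam OPT.

Generates 3-D phantoms and projects them through a configurable forward
model: equiangular parallel-beam line integrals with optional rotation-axis
offset, in-plane / out-of-plane axis tilt, seeded per-angle horizontal
jitter, a smooth multiplicative illumination field, and Poisson or Gaussian
noise.  Every downstream algorithm (flat-fielding, calibration, jitter
correction, FBP) is testable against this model by parameter recovery.

Geometry
--------
Phantoms are ``(z, y, x)`` with the rotation axis along ``z`` (vertical) and
the optical axis along ``y``.  The detector image of a projection is
``(row, column) == (z, x)``.  For angle ``theta`` the projection is the sum
over ``y`` of the phantom rotated by ``-theta`` about the axis, so a point at
radius ``r`` and azimuth ``psi`` traces the detector column

    col(theta) = center + r * cos(theta - psi)

(the classic sinogram sinusoid).  Artifacts compose in this order: column
shift by the axis offset, in-plane rotation by the tilt, jitter shift,
illumination, noise — chosen so that the correction pipeline (rotate by
``-tilt`` then shift by ``-offset``) inverts the clean transform exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage

from .errors import GeometryError
from .stack_io import AcquisitionGeometry, ProjectionStack, detector_center_col

__all__ = [
    "Phantom",
    "ArtifactSpec",
    "make_phantom",
    "forward_project",
    "inject_jitter",
    "shift_columns",
    "default_illumination",
    "attenuation_to_transmission",
]


@dataclass
class Phantom:
    """Voxel grid of attenuation coefficient (tOPT) or fluorophore density (eOPT)."""

    voxels: np.ndarray
    voxel_size_um: float = 1.0

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"phantom must be 3-D (z, y, x), got {self.voxels.ndim}-D")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("phantom voxels must be finite")
        if np.any(self.voxels < 0):
            raise ValueError("phantom voxels must be >= 0")

    @property
    def total_mass(self) -> float:
        return float(self.voxels.sum())


@dataclass
class ArtifactSpec:
    """Acquisition imperfections applied by :func:`forward_project`.

    axis_offset_px
        Horizontal displacement of the rotation-axis image from the detector
        center column (sub-pixel floats allowed).
    tilt_inplane_deg / tilt_outplane_deg
        Rotation of the axis within the detector plane / lean of the axis
        toward the camera.
    jitter_sigma_px, jitter_seed
        Per-angle rigid horizontal Gaussian jitter; reproducible from seed.
    illumination
        ``None``, ``"default"`` (low-order polynomial bump, peak-to-edge 1.5)
        or an explicit strictly positive ``(row, column)`` field that
        multiplies each projection.
    noise
        ``None``, ``("gaussian", sigma)`` or ``("poisson", scale)`` where
        ``scale`` converts projection values to expected photon counts.
    noise_seed
        Seed for the noise generator (independent of the jitter stream).
    """

    axis_offset_px: float = 0.0
    tilt_inplane_deg: float = 0.0
    tilt_outplane_deg: float = 0.0
    jitter_sigma_px: float = 0.0
    jitter_seed: int = 0
    illumination: object = None
    noise: tuple | None = None
    noise_seed: int = 0

    # populated by forward_project for recovery tests
    true_jitter_px: np.ndarray | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------

def _grid(shape):
    nz, ny, nx = shape
    z = np.arange(nz)[:, None, None]
    y = np.arange(ny)[None, :, None]
    x = np.arange(nx)[None, None, :]
    return z, y, x


def _centers(shape):
    nz, ny, nx = shape
    return (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0


def make_phantom(kind: str, size: tuple[int, int, int], params: dict | None = None,
                 voxel_size_um: float = 1.0) -> Phantom:
    """Build a deterministic test phantom.

    Kinds
    -----
    ``disks``
        Uniform-value cylinders (circles repeated over a z-band).  Params:
        ``disks`` = list of ``(cy, cx, radius, value)`` in pixels (defaults
        provided), ``z_band`` = (z0, z1) slab holding the disks.
    ``shepp_logan_3d``
        The classic head phantom resampled to ``(y, x)`` and stacked over z
        with a parabolic intensity profile.
    ``branching_tree``
        A small airway-tree stand-in: Gaussian-profile tubes that fork.
    ``bead``
        A single Gaussian-profile sphere (fiducial-marker stand-in).
        Params: ``center`` = (z, y, x), ``radius`` (Gaussian sigma, px),
        ``value`` peak amplitude.
    """
    params = dict(params or {})
    size = tuple(int(s) for s in size)
    if any(s < 8 for s in size):
        raise ValueError(f"every phantom dimension must be >= 8, got {size}")
    nz, ny, nx = size
    cz, cy, cx = _centers(size)

    if kind == "bead":
        center = params.get("center", (cz, cy, cx))
        radius = float(params.get("radius", 2.0))
        value = float(params.get("value", 1.0))
        z, y, x = _grid(size)
        r2 = ((z - center[0]) ** 2 + (y - center[1]) ** 2 + (x - center[2]) ** 2)
        vox = value * np.exp(-0.5 * r2 / radius ** 2)
        return Phantom(vox, voxel_size_um)

    if kind == "disks":
        rmax = min(ny, nx) / 2.0
        disks = params.get("disks", [
            (cy, cx, 0.55 * rmax, 0.5),
            (cy - 0.35 * rmax, cx - 0.2 * rmax, 0.18 * rmax, 1.0),
            (cy + 0.3 * rmax, cx + 0.25 * rmax, 0.12 * rmax, 0.8),
        ])
        z0, z1 = params.get("z_band", (nz // 4, nz - nz // 4))
        vox = np.zeros(size)
        yy = np.arange(ny)[:, None]
        xx = np.arange(nx)[None, :]
        plane = np.zeros((ny, nx))
        for (dy, dx, r, v) in disks:
            plane += np.where((yy - dy) ** 2 + (xx - dx) ** 2 <= r ** 2, v, 0.0)
        vox[z0:z1] = plane
        return Phantom(vox, voxel_size_um)

    if kind == "shepp_logan_3d":
        from skimage.data import shepp_logan_phantom
        from skimage.transform import resize
        plane = resize(shepp_logan_phantom(), (ny, nx), order=1,
                       anti_aliasing=True, preserve_range=True)
        # keep support inside the inscribed circle so no mass rotates out
        zz = (np.arange(nz) - cz) / (nz / 2.0)
        profile = np.clip(1.0 - zz ** 2, 0.0, None)
        vox = profile[:, None, None] * plane[None]
        return Phantom(vox, voxel_size_um)

    if kind == "branching_tree":
        sigma = float(params.get("tube_sigma", max(1.5, min(ny, nx) / 40)))
        value = float(params.get("value", 1.0))
        vox = np.zeros(size)
        z, y, x = _grid(size)

        def tube(p0, p1, amp):
            p0 = np.asarray(p0, float)
            p1 = np.asarray(p1, float)
            d = p1 - p0
            L2 = float(d @ d)
            t = ((z - p0[0]) * d[0] + (y - p0[1]) * d[1] + (x - p0[2]) * d[2]) / L2
            t = np.clip(t, 0.0, 1.0)
            qz = p0[0] + t * d[0]
            qy = p0[1] + t * d[1]
            qx = p0[2] + t * d[2]
            r2 = (z - qz) ** 2 + (y - qy) ** 2 + (x - qx) ** 2
            np.maximum(vox, amp * np.exp(-0.5 * r2 / sigma ** 2), out=vox)

        r = 0.3 * min(ny, nx)
        trunk_top = (0.15 * nz, cy, cx)
        trunk_bot = (0.55 * nz, cy, cx)
        tube(trunk_top, trunk_bot, value)
        for sgn in (-1.0, 1.0):
            b1 = (0.8 * nz, cy + sgn * 0.5 * r, cx + sgn * 0.4 * r)
            tube(trunk_bot, b1, 0.8 * value)
            tube(b1, (0.92 * nz, cy + sgn * 0.75 * r, cx - sgn * 0.1 * r), 0.6 * value)
        return Phantom(vox, voxel_size_um)

    raise ValueError(f"unknown phantom kind {kind!r}")


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def shift_columns(image: np.ndarray, shift_px: float) -> np.ndarray:
    """Rigidly shift an image (or stack) along its last axis, linear interp,
    zero fill.  A positive shift moves content toward higher column index."""
    if shift_px == 0.0:
        return image.copy()
    shift = [0.0] * (image.ndim - 1) + [float(shift_px)]
    return ndimage.shift(image, shift, order=1, mode="constant", cval=0.0,
                         prefilter=False)


def default_illumination(shape: tuple[int, int]) -> np.ndarray:
    """Smooth multiplicative field, peak-to-edge ratio 1.5, strictly positive.

    Low-order polynomial bump: 1.5 at the center falling to 1.0 on the
    image border.
    """
    nr, nc = shape
    r = (np.arange(nr) - (nr - 1) / 2.0) / ((nr - 1) / 2.0)
    c = (np.arange(nc) - (nc - 1) / 2.0) / ((nc - 1) / 2.0)
    return 1.0 + 0.5 * (1.0 - r[:, None] ** 2) * (1.0 - c[None, :] ** 2)


def _rotation_matrix_zyx(theta_rad: float, outplane_rad: float) -> np.ndarray:
    """Output->input sampling matrix for (z, y, x) offsets.

    With no out-of-plane tilt this reduces to the in-plane map
    ``[y; x] = [[cos, sin], [-sin, cos]] @ [u; s]`` which realizes projection
    angle ``theta``; out-of-plane tilt conjugates that rotation with a lean
    of the axis about the detector-column (x) direction.
    """
    c, s = np.cos(theta_rad), np.sin(theta_rad)
    base = np.array([[1.0, 0.0, 0.0],
                     [0.0, c, s],
                     [0.0, -s, c]])
    if outplane_rad == 0.0:
        return base
    cb, sb = np.cos(outplane_rad), np.sin(outplane_rad)
    tilt = np.array([[cb, -sb, 0.0],
                     [sb, cb, 0.0],
                     [0.0, 0.0, 1.0]])
    return tilt @ base @ tilt.T


def _project_clean(voxels: np.ndarray, angles_deg: np.ndarray,
                   outplane_deg: float) -> np.ndarray:
    """Line integrals (sum over y of the rotated volume) for each angle."""
    nz, ny, nx = voxels.shape
    center = np.array([(nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0])
    out = np.empty((len(angles_deg), nz, nx))
    beta = np.deg2rad(outplane_deg)
    for i, ang in enumerate(angles_deg):
        theta = np.deg2rad(ang)
        m = _rotation_matrix_zyx(theta, beta)
        offset = center - m @ center
        rotated = ndimage.affine_transform(
            voxels, m, offset=offset, order=1, mode="constant", cval=0.0,
            prefilter=False)
        out[i] = rotated.sum(axis=1)
    return out


def forward_project(phantom: Phantom, geometry: AcquisitionGeometry,
                    artifacts: ArtifactSpec | None = None) -> ProjectionStack:
    """Simulate the projection stack of ``phantom`` under ``geometry``.

    Returns a stack of shape ``(n_projections, nz, nx)``.  With all
    artifacts off the values are straight line integrals (value * pixel).
    The true per-angle jitter shifts are stored on the returned stack's
    ``extras["true_jitter_px"]`` and on ``artifacts.true_jitter_px``.
    """
    artifacts = artifacts or ArtifactSpec()
    nz, ny, nx = phantom.voxels.shape
    # the detector is nx columns wide; y-extents beyond that would clip
    if ny > nx:
        raise GeometryError(
            f"phantom y-extent {ny} exceeds detector width {nx}")
    data = _project_clean(phantom.voxels, geometry.angles_deg,
                          artifacts.tilt_outplane_deg)

    if artifacts.axis_offset_px:
        data = shift_columns(data, artifacts.axis_offset_px)
    if artifacts.tilt_inplane_deg:
        data = np.stack([
            ndimage.rotate(p, artifacts.tilt_inplane_deg, reshape=False,
                           order=1, mode="constant", cval=0.0, prefilter=False)
            for p in data])

    extras: dict = {}
    if artifacts.jitter_sigma_px > 0:
        rng = np.random.default_rng(artifacts.jitter_seed)
        shifts = rng.normal(0.0, artifacts.jitter_sigma_px,
                            geometry.n_projections)
        data = np.stack([shift_columns(p, s) for p, s in zip(data, shifts)])
    else:
        shifts = np.zeros(geometry.n_projections)
    artifacts.true_jitter_px = shifts
    extras["true_jitter_px"] = [float(s) for s in shifts]

    illum = artifacts.illumination
    if illum is not None:
        if isinstance(illum, str):
            if illum != "default":
                raise ValueError(f"unknown illumination spec {illum!r}")
            illum = default_illumination((nz, nx))
        illum = np.asarray(illum, dtype=float)
        if illum.shape != (nz, nx):
            raise GeometryError(
                f"illumination field shape {illum.shape} != projection shape {(nz, nx)}")
        if np.any(illum <= 0):
            raise ValueError("illumination field must be strictly positive")
        data = data * illum[None]
        extras["illumination"] = True

    if artifacts.noise is not None:
        kind, param = artifacts.noise
        rng = np.random.default_rng(artifacts.noise_seed)
        if kind == "gaussian":
            data = data + rng.normal(0.0, float(param), data.shape)
        elif kind == "poisson":
            scale = float(param)
            if scale <= 0:
                raise ValueError("poisson scale must be > 0")
            data = rng.poisson(np.clip(data, 0, None) * scale) / scale
        else:
            raise ValueError(f"unknown noise kind {kind!r}")

    return ProjectionStack(data=data, geometry=geometry, stage="raw",
                           extras=extras)


def inject_jitter(stack: ProjectionStack, jitter_sigma_px: float,
                  jitter_seed: int = 0) -> tuple[ProjectionStack, np.ndarray]:
    """Rigidly shift each projection horizontally by a seeded Gaussian draw.

    Returns the jittered stack and the true per-angle shifts so recovery can
    be tested.  ``sigma = 0`` is the identity.
    """
    if jitter_sigma_px < 0:
        raise ValueError("jitter sigma must be >= 0")
    n = stack.geometry.n_projections
    if jitter_sigma_px == 0:
        return stack.with_data(stack.data.copy()), np.zeros(n)
    rng = np.random.default_rng(jitter_seed)
    shifts = rng.normal(0.0, jitter_sigma_px, n)
    data = np.stack([shift_columns(p, s) for p, s in zip(stack.data, shifts)])
    out = stack.with_data(data)
    out.extras["true_jitter_px"] = [float(s) for s in shifts]
    return out, shifts


def attenuation_to_transmission(stack: ProjectionStack, bright: np.ndarray,
                                illumination: np.ndarray | None = None,
                                ) -> ProjectionStack:
    """Convert line-integral attenuation A into measured intensity
    ``I = I0 * exp(-A)`` (Beer-Lambert forward model), optionally modulated
    by an extra illumination field."""
    bright = np.asarray(bright, dtype=float)
    inten = bright[None] * np.exp(-stack.data)
    if illumination is not None:
        inten = inten * np.asarray(illumination, dtype=float)[None]
    return stack.with_data(inten, stage="raw")
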
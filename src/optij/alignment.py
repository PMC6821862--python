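"""Fiducial tracking, sinusoid fitting, and rotation-geometry estimation.

A small high-contrast bead embedded near the sample traces an ideal sinusoid
across the projections.  Tracking the bead and fitting

    v(theta) = A * cos(theta + phi) + c

per coordinate yields (a) the rotation-axis offset from the detector center
(mean of the horizontal fit), (b) the axis tilt from the vertical bead
motion decomposed into components in phase / in quadrature with the
horizontal motion, and (c) per-angle jitter corrections from the horizontal
fit residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import FitError, TrackingError
from .stack_io import ProjectionStack

__all__ = [
    "FiducialTrack",
    "SinusoidFit",
    "GeometryModel",
    "detect_fiducial",
    "track_fiducial",
    "fit_sinusoid",
    "estimate_geometry",
    "dynamic_offset",
]


@dataclass
class FiducialTrack:
    """Per-projection bead centroids in detector coordinates."""

    angles_deg: np.ndarray
    x_px: np.ndarray  # column coordinate
    y_px: np.ndarray  # row coordinate
    ok: np.ndarray    # bool success flag per projection

    def __post_init__(self):
        self.angles_deg = np.asarray(self.angles_deg, float)
        self.x_px = np.asarray(self.x_px, float)
        self.y_px = np.asarray(self.y_px, float)
        self.ok = np.asarray(self.ok, bool)
        n = len(self.angles_deg)
        if not (len(self.x_px) == len(self.y_px) == len(self.ok) == n):
            raise ValueError("track arrays must have equal length")
        if self.ok.any() and not (
                np.all(np.isfinite(self.x_px[self.ok]))
                and np.all(np.isfinite(self.y_px[self.ok]))):
            raise ValueError("entries flagged ok must be finite")

    def to_csv(self, path) -> None:
        rows = np.column_stack([self.angles_deg, self.x_px, self.y_px,
                                self.ok.astype(float)])
        np.savetxt(path, rows, delimiter=",", fmt="%.6f",
                   header="angle_deg,x_px,y_px,ok", comments="")

    @classmethod
    def from_csv(cls, path) -> "FiducialTrack":
        rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(rows[:, 0], rows[:, 1], rows[:, 2], rows[:, 3] > 0.5)


@dataclass
class SinusoidFit:
    """Least-squares fit of ``A*cos(theta + phi) + c`` to one coordinate."""

    amplitude_px: float
    phase_deg: float
    mean_px: float
    residuals_px: np.ndarray = field(repr=False)
    rmse_px: float = 0.0
    # linear-parameterization coefficients (a*cos + b*sin + c), kept for the
    # in-phase / quadrature decomposition used by tilt estimation
    coef_cos: float = 0.0
    coef_sin: float = 0.0

    def predict(self, angles_deg: np.ndarray) -> np.ndarray:
        th = np.deg2rad(np.asarray(angles_deg, float))
        return (self.amplitude_px * np.cos(th + np.deg2rad(self.phase_deg))
                + self.mean_px)


@dataclass
class GeometryModel:
    """Rotation-axis correction values consumed at sinogram creation.

    ``axis_offset_px`` is the axis column minus the detector center column;
    ``tilt_outplane_deg`` is diagnostic only (a per-slice parallel-beam FBP
    cannot correct the row mixing it causes).
    """

    axis_offset_px: float = 0.0
    tilt_inplane_deg: float | None = 0.0
    tilt_outplane_deg: float | None = None
    source: str = "user"

    def __post_init__(self):
        if self.tilt_inplane_deg is not None and abs(self.tilt_inplane_deg) >= 45:
            raise ValueError("in-plane tilt must satisfy |tilt| < 45 degrees")


# ---------------------------------------------------------------------------
# Detection / tracking
# ---------------------------------------------------------------------------

def _window(image: np.ndarray, roi) -> tuple[np.ndarray, int, int]:
    """Clip an (x, y, w, h) rectangle to the image; returns view + origin."""
    nr, nc = image.shape
    x, y, w, h = roi
    if w <= 0 or h <= 0 or x + w <= 0 or y + h <= 0 or x >= nc or y >= nr:
        raise ValueError(f"empty roi {roi} for image of shape {image.shape}")
    c0 = int(np.clip(np.floor(x), 0, nc - 1))
    r0 = int(np.clip(np.floor(y), 0, nr - 1))
    c1 = int(np.clip(np.ceil(x + w), c0 + 1, nc))
    r1 = int(np.clip(np.ceil(y + h), r0 + 1, nr))
    return image[r0:r1, c0:c1], r0, c0


def detect_fiducial(projection: np.ndarray, roi=None, polarity: str = "bright",
                    prev: tuple[float, float] | None = None):
    """Locate the bead in one projection.

    The window (full image if ``roi`` is None) is thresholded at
    ``mean + 3*SD`` of its border pixels; the intensity-weighted centroid of
    the above-threshold blob nearest ``prev`` (or the window center) is
    returned as ``(x_px, y_px)`` with sub-pixel precision, or ``None`` when
    no blob exceeds the threshold.
    """
    img = np.asarray(projection, float)
    if polarity == "dark":
        img = -img
    elif polarity != "bright":
        raise ValueError(f"polarity must be 'bright' or 'dark', got {polarity!r}")
    if roi is not None:
        win, r0, c0 = _window(img, roi)
    else:
        win, r0, c0 = img, 0, 0
    if win.size == 0:
        raise ValueError("empty roi")

    border = np.concatenate([win[0], win[-1], win[1:-1, 0], win[1:-1, -1]]) \
        if min(win.shape) > 1 else win.ravel()
    thr = border.mean() + 3.0 * border.std()
    mask = win > thr
    if not mask.any():
        return None

    labels, n = ndimage.label(mask)
    if prev is not None:
        target = (prev[1] - r0, prev[0] - c0)  # (row, col) in window coords
    else:
        target = ((win.shape[0] - 1) / 2.0, (win.shape[1] - 1) / 2.0)
    coms = ndimage.center_of_mass(mask, labels, index=range(1, n + 1))
    best = 1 + int(np.argmin([(cr - target[0]) ** 2 + (cc - target[1]) ** 2
                              for cr, cc in coms]))
    blob = labels == best

    weights = np.where(blob, win - thr, 0.0)
    total = weights.sum()
    if total <= 0:
        return None
    rr, cc = np.nonzero(blob)
    y = (weights[rr, cc] * rr).sum() / total + r0
    x = (weights[rr, cc] * cc).sum() / total + c0

    # refine on a symmetric patch: the thresholded blob is cut at sub-pixel
    # level, which biases the centroid by up to ~0.3 px; an un-clipped
    # background-subtracted centroid over a centered square is unbiased for
    # a symmetric spot
    radius = max(3, int(np.ceil(2.0 * np.sqrt(blob.sum() / np.pi))))
    pr, pc = int(round(y)), int(round(x))
    nr, nc = img.shape
    if (radius <= pr < nr - radius) and (radius <= pc < nc - radius):
        patch = img[pr - radius:pr + radius + 1, pc - radius:pc + radius + 1]
        pborder = np.concatenate([patch[0], patch[-1],
                                  patch[1:-1, 0], patch[1:-1, -1]])
        pw = np.clip(patch - pborder.mean(), 0.0, None)
        if pw.sum() > 0:
            ir, ic = np.mgrid[0:patch.shape[0], 0:patch.shape[1]]
            y = (pw * ir).sum() / pw.sum() + pr - radius
            x = (pw * ic).sum() / pw.sum() + pc - radius
    return float(x), float(y)


def _blob_diameter(projection, x, y, polarity):
    """Rough bead diameter from the above-threshold extent around (x, y)."""
    det = detect_fiducial(projection, roi=(x - 16, y - 16, 32, 32),
                          polarity=polarity)
    img = np.asarray(projection, float)
    if polarity == "dark":
        img = -img
    win, r0, c0 = _window(img, (x - 16, y - 16, 32, 32))
    border = np.concatenate([win[0], win[-1], win[1:-1, 0], win[1:-1, -1]])
    mask = win > border.mean() + 3.0 * border.std()
    return max(2.0, np.sqrt(mask.sum() / np.pi) * 2.0)


def track_fiducial(stack: ProjectionStack, seed_roi, polarity: str = "bright",
                   window_px: float | None = None) -> FiducialTrack:
    """Track the bead through every projection.

    The search window is re-centered on the previous hit each frame (default
    size: 3x the detected blob diameter).  Failed frames are flagged, not
    interpolated; more than 20% failures raises :class:`TrackingError` with
    per-angle diagnostics.
    """
    n = stack.geometry.n_projections
    angles = stack.angles_deg
    xs = np.full(n, np.nan)
    ys = np.full(n, np.nan)
    ok = np.zeros(n, bool)

    hit = detect_fiducial(stack.data[0], roi=seed_roi, polarity=polarity)
    if hit is None:
        raise TrackingError("bead not found in the seed ROI of projection 0")
    if window_px is None:
        window_px = 3.0 * _blob_diameter(stack.data[0], hit[0], hit[1], polarity)
    window_px = max(window_px, 6.0)

    prev = hit
    for i in range(n):
        # progressively widen the search if the bead jumped out of the
        # window (large jitter); keep the row extent tight so nearby sample
        # structure at other rows does not capture the search
        res = None
        for scale in (1.0, 2.0, 4.0):
            w = window_px * scale
            roi = (prev[0] - w / 2, prev[1] - window_px / 2, w, window_px)
            res = detect_fiducial(stack.data[i], roi=roi, polarity=polarity,
                                  prev=prev)
            if res is not None:
                break
        if res is not None:
            xs[i], ys[i] = res
            ok[i] = True
            prev = res
        # on failure keep searching around the last good position

    if ok.sum() < 0.8 * n:
        diags = [(int(i), float(angles[i]), bool(ok[i])) for i in range(n)]
        raise TrackingError(
            f"bead found in only {int(ok.sum())}/{n} projections (need >= 80%)",
            diagnostics=diags)
    return FiducialTrack(angles, xs, ys, ok)


# ---------------------------------------------------------------------------
# Sinusoid fit and geometry estimation
# ---------------------------------------------------------------------------

def _normalize_phase_deg(phi: float) -> float:
    """Wrap to [-180, 180); +180 resolves to -180."""
    return float((phi + 180.0) % 360.0 - 180.0)


def fit_sinusoid(angles_deg, values_px) -> SinusoidFit:
    """Closed-form least squares of ``v = A*cos(theta + phi) + c``.

    Solved in the linear parameterization ``a*cos(theta) + b*sin(theta) + c``
    (normal equations via ``lstsq``), then ``A = hypot(a, b)`` and
    ``phi = atan2(-b, a)``.  Exact to machine precision on noiseless
    sinusoids sampled at >= 4 distinct angles.
    """
    angles_deg = np.asarray(angles_deg, float)
    values_px = np.asarray(values_px, float)
    if angles_deg.shape != values_px.shape:
        raise FitError("angles and values must have equal length")
    if len(angles_deg) < 4:
        raise FitError(f"need >= 4 samples, got {len(angles_deg)}")
    if np.ptp(angles_deg) <= 180.0:
        raise FitError(
            f"angular span {np.ptp(angles_deg):.1f} deg must exceed 180 deg")

    th = np.deg2rad(angles_deg)
    design = np.column_stack([np.cos(th), np.sin(th), np.ones_like(th)])
    (a, b, c), *_ = np.linalg.lstsq(design, values_px, rcond=None)
    amplitude = float(np.hypot(a, b))
    phase = _normalize_phase_deg(np.rad2deg(np.arctan2(-b, a))) if amplitude else 0.0
    fitted = design @ np.array([a, b, c])
    residuals = values_px - fitted
    return SinusoidFit(amplitude_px=amplitude, phase_deg=phase, mean_px=float(c),
                       residuals_px=residuals,
                       rmse_px=float(np.sqrt(np.mean(residuals ** 2))),
                       coef_cos=float(a), coef_sin=float(b))


def estimate_geometry(track: FiducialTrack,
                      detector_center_col: float) -> GeometryModel:
    """Axis offset and tilt from a single bead track.

    Offset is the mean of the horizontal sinusoid minus the detector center.
    Tilt comes from decomposing the vertical motion against the horizontal
    phase: the in-phase vertical amplitude over the horizontal amplitude is
    ``tan(tilt_inplane)``; the quadrature ratio is ``sin(tilt_outplane)``
    (reported as a diagnostic only).  A horizontal amplitude below 1 px makes
    the tilt indeterminate: the offset is still returned, tilts are None.
    """
    m = track.ok
    fit_x = fit_sinusoid(track.angles_deg[m], track.x_px[m])
    offset = fit_x.mean_px - detector_center_col

    if fit_x.amplitude_px < 1.0:
        return GeometryModel(axis_offset_px=offset, tilt_inplane_deg=None,
                             tilt_outplane_deg=None, source="estimated")

    fit_y = fit_sinusoid(track.angles_deg[m], track.y_px[m])
    ax, bx = fit_x.coef_cos, fit_x.coef_sin
    ay, by = fit_y.coef_cos, fit_y.coef_sin
    amp_x = fit_x.amplitude_px
    # unit vector along the horizontal oscillation in (cos, sin) coefficient
    # space; project the vertical coefficients on it / its quadrature.
    # Signs flipped because the row coordinate increases downward, so that a
    # positive in-plane tilt here is undone by rotating projections by -tilt.
    in_phase = -(ay * ax + by * bx) / amp_x
    quadrature = -(ay * bx - by * ax) / amp_x
    tilt_in = float(np.rad2deg(np.arctan2(in_phase, amp_x)))
    ratio = np.clip(quadrature / amp_x, -1.0, 1.0)
    tilt_out = float(np.rad2deg(np.arcsin(ratio)))
    return GeometryModel(axis_offset_px=offset, tilt_inplane_deg=tilt_in,
                         tilt_outplane_deg=tilt_out, source="estimated")


def dynamic_offset(track: FiducialTrack) -> np.ndarray:
    """Per-angle jitter-correction shifts (pixels).

    ``correction[i] = -(observed_x[i] - fitted_x[i])``: applying these column
    shifts to the projections cancels the per-angle jitter up to the bead
    localization error.  Angles with no valid bead hit get correction 0.
    """
    m = track.ok
    fit_x = fit_sinusoid(track.angles_deg[m], track.x_px[m])
    corrections = np.zeros(len(track.angles_deg))
    corrections[m] = -fit_x.residuals_px
    return corrections
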
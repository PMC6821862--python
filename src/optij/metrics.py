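"""Reconstruction quality metrics.

* Fourier Ring Correlation (FRC) resolution from two independent
  reconstructions, obtained by splitting a full acquisition into its even-
  and odd-indexed projections (each half still spans the full angular range
  at twice the step).
* Profile full-width-at-half-maximum as a classical resolution proxy.
* Region SNR / brightness-ratio statistics for comparing labelling
  strategies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import GeometryError
from .stack_io import AcquisitionGeometry, ProjectionStack

__all__ = [
    "FRCResult",
    "RoiStats",
    "split_projections",
    "frc_curve",
    "frc_resolution_from_halves",
    "profile_fwhm",
    "roi_stats",
]

#: Fixed FRC threshold criterion (recorded in every FRCResult so alternative
#: criteria can be added without changing the output contract).
DEFAULT_FRC_THRESHOLD = 1.0 / 7.0


@dataclass
class FRCResult:
    """FRC curve plus the threshold-crossing resolution estimate.

    ``resolution_px`` is ``1 / frequency`` at the first crossing of the
    threshold (linearly interpolated between rings); ``None`` when the curve
    never crosses ("not reached").
    """

    freq_cyc_per_px: np.ndarray
    frc: np.ndarray
    threshold: float = DEFAULT_FRC_THRESHOLD
    resolution_px: float | None = None
    resolution_um: float | None = None

    @property
    def resolution_reached(self) -> bool:
        return self.resolution_px is not None


@dataclass
class RoiStats:
    """Signal/background region statistics.

    ``snr = (mean_signal - mean_background) / sd_background`` and
    ``br = mean_background / mean_signal`` (so a background contributing
    25-33% of the total signal reads as ``br`` in [0.25, 0.33]).
    """

    mean_signal: float
    mean_background: float
    sd_background: float

    @property
    def snr(self) -> float:
        if self.sd_background <= 0:
            raise ValueError("snr undefined: background SD is zero")
        return (self.mean_signal - self.mean_background) / self.sd_background

    @property
    def br(self) -> float:
        return self.mean_background / self.mean_signal


# ---------------------------------------------------------------------------
# Projection splitting
# ---------------------------------------------------------------------------

def split_projections(stack: ProjectionStack) -> tuple[ProjectionStack, ProjectionStack]:
    """Split into even- and odd-indexed angle halves.

    Each half spans the full angular range with doubled step; together they
    partition the original angle set (512 in -> two stacks of 256).
    """
    g = stack.geometry
    if g.n_projections % 2:
        raise ValueError(
            f"need an even projection count to split, got {g.n_projections}")
    half_n = g.n_projections // 2
    step = g.step_deg
    geom_even = AcquisitionGeometry(
        n_projections=half_n, angular_range_deg=g.angular_range_deg,
        start_angle_deg=g.start_angle_deg, pixel_size_um=g.pixel_size_um,
        min_step_deg=g.min_step_deg, modality=g.modality)
    geom_odd = replace(geom_even, start_angle_deg=g.start_angle_deg + step)
    even = ProjectionStack(stack.data[0::2].copy(), geom_even, stage=stack.stage)
    odd = ProjectionStack(stack.data[1::2].copy(), geom_odd, stage=stack.stage)
    return even, odd


# ---------------------------------------------------------------------------
# Fourier Ring Correlation
# ---------------------------------------------------------------------------

def _apodize(img: np.ndarray, margin_frac: float = 0.1) -> np.ndarray:
    """Mean-subtract and cosine-taper a 10% margin to suppress leakage."""
    img = img - img.mean()

    def taper(n):
        w = np.ones(n)
        m = max(1, int(round(margin_frac * n)))
        ramp = 0.5 * (1.0 - np.cos(np.pi * (np.arange(m) + 0.5) / m))
        w[:m] = ramp
        w[-m:] = ramp[::-1]
        return w

    return img * taper(img.shape[0])[:, None] * taper(img.shape[1])[None, :]


def frc_curve(img1: np.ndarray, img2: np.ndarray, ring_width: float | None = None,
              threshold: float = DEFAULT_FRC_THRESHOLD,
              apodize: bool = True) -> FRCResult:
    """Fourier ring correlation between two equal-shape 2-D images.

    ``FRC(r) = Re(sum_ring F1 conj(F2)) / sqrt(sum_ring |F1|^2 sum_ring |F2|^2)``
    over centered rings of the 2-D DFT.  Ring width defaults to one frequency
    sample of the shorter image axis.  Images are mean-subtracted and
    edge-apodized (cosine taper, 10% margin) first unless ``apodize=False``.
    """
    img1 = np.asarray(img1, float)
    img2 = np.asarray(img2, float)
    if img1.shape != img2.shape:
        raise GeometryError(f"image shapes differ: {img1.shape} vs {img2.shape}")
    if min(img1.shape) < 32:
        raise ValueError("images must be at least 32x32 for a stable FRC")

    if apodize:
        img1 = _apodize(img1)
        img2 = _apodize(img2)

    f1 = np.fft.fftshift(np.fft.fft2(img1))
    f2 = np.fft.fftshift(np.fft.fft2(img2))
    ny, nx = img1.shape
    fy = np.fft.fftshift(np.fft.fftfreq(ny))[:, None]
    fx = np.fft.fftshift(np.fft.fftfreq(nx))[None, :]
    radius = np.hypot(fy, fx)

    if ring_width is None:
        ring_width = 1.0 / min(ny, nx)
    n_rings = int(np.floor(0.5 / ring_width)) + 1
    ring_idx = np.minimum((radius / ring_width).astype(int), n_rings - 1)
    valid = radius <= 0.5 + 1e-12

    cross = np.bincount(ring_idx[valid],
                        weights=(f1 * np.conj(f2)).real[valid],
                        minlength=n_rings)
    p1 = np.bincount(ring_idx[valid], weights=np.abs(f1[valid]) ** 2,
                     minlength=n_rings)
    p2 = np.bincount(ring_idx[valid], weights=np.abs(f2[valid]) ** 2,
                     minlength=n_rings)
    denom = np.sqrt(p1 * p2)
    with np.errstate(invalid="ignore", divide="ignore"):
        frc = np.where(denom > 0, cross / np.where(denom > 0, denom, 1.0), 0.0)
    freqs = (np.arange(n_rings) + 0.5) * ring_width

    res_px = _threshold_crossing(freqs, frc, threshold)
    return FRCResult(freq_cyc_per_px=freqs, frc=frc, threshold=threshold,
                     resolution_px=res_px)


def _threshold_crossing(freqs: np.ndarray, frc: np.ndarray,
                        threshold: float) -> float | None:
    """1/frequency at the first downward threshold crossing (linear interp).

    Returns None when the curve never drops below the threshold.  The
    resolution is floored at 2 px (Nyquist).
    """
    below = np.nonzero(frc < threshold)[0]
    below = below[below > 0]  # ignore the DC ring
    if len(below) == 0:
        return None
    j = below[0]
    f0, f1 = freqs[j - 1], freqs[j]
    v0, v1 = frc[j - 1], frc[j]
    if v0 == v1:
        fc = f1
    else:
        fc = f0 + (v0 - threshold) / (v0 - v1) * (f1 - f0)
    return max(2.0, 1.0 / fc)


def frc_resolution_from_halves(stack: ProjectionStack, geometry_model=None,
                               jitter_corrections=None, filter_spec=None,
                               rows_sample=None,
                               pixel_size_um: float | None = None,
                               threshold: float = DEFAULT_FRC_THRESHOLD,
                               ) -> FRCResult:
    """Split-half FRC resolution of a reconstruction.

    Reconstructs the even- and odd-projection halves on the sampled rows,
    computes per-slice FRC, averages the curves, then thresholds.  Reports
    micrometers via ``pixel_size_um`` (defaults to the stack's geometry).
    """
    from .reconstruct import reconstruct_volume

    even, odd = split_projections(stack)
    if jitter_corrections is not None:
        jitter_corrections = np.asarray(jitter_corrections, float)
        jc_even, jc_odd = jitter_corrections[0::2], jitter_corrections[1::2]
    else:
        jc_even = jc_odd = None
    if rows_sample is None:
        rows_sample = [stack.n_rows // 2]

    vol_a = reconstruct_volume(even, geometry_model, jc_even, filter_spec,
                               rows=rows_sample)
    vol_b = reconstruct_volume(odd, geometry_model, jc_odd, filter_spec,
                               rows=rows_sample)

    curves = []
    freqs = None
    for sa, sb in zip(vol_a.voxels, vol_b.voxels):
        res = frc_curve(sa, sb, threshold=threshold)
        curves.append(res.frc)
        freqs = res.freq_cyc_per_px
    mean_frc = np.mean(curves, axis=0)
    res_px = _threshold_crossing(freqs, mean_frc, threshold)

    px_um = pixel_size_um if pixel_size_um is not None \
        else stack.geometry.pixel_size_um
    return FRCResult(freq_cyc_per_px=freqs, frc=mean_frc, threshold=threshold,
                     resolution_px=res_px,
                     resolution_um=None if res_px is None else res_px * px_um)


# ---------------------------------------------------------------------------
# Profile FWHM and region statistics
# ---------------------------------------------------------------------------

def profile_fwhm(image: np.ndarray, line_endpoints,
                 interpolation_step_px: float = 0.1) -> float:
    """Full width at half maximum along a line, in pixels.

    The intensity profile is sampled with linear interpolation at
    ``interpolation_step_px`` between endpoints given as
    ``((y0, x0), (y1, x1))``; the background (mean of the two profile ends)
    is subtracted and the half-max crossings are located sub-pixel.
    """
    from scipy import ndimage

    image = np.asarray(image, float)
    (y0, x0), (y1, x1) = line_endpoints
    for (yy, xx) in ((y0, x0), (y1, x1)):
        if not (0 <= yy <= image.shape[0] - 1 and 0 <= xx <= image.shape[1] - 1):
            raise ValueError(f"line endpoint ({yy}, {xx}) outside image")
    length = float(np.hypot(y1 - y0, x1 - x0))
    n = max(int(np.ceil(length / interpolation_step_px)) + 1, 2)
    t = np.linspace(0.0, 1.0, n)
    coords = np.vstack([y0 + t * (y1 - y0), x0 + t * (x1 - x0)])
    profile = ndimage.map_coordinates(image, coords, order=1)

    background = 0.5 * (profile[0] + profile[-1])
    profile = profile - background
    peak = profile.max()
    if peak <= 0 or np.ptp(profile) == 0:
        raise ValueError("flat profile: no peak to measure")
    half = 0.5 * peak
    ipk = int(np.argmax(profile))

    def crossing(idx_range):
        prev = None
        for i in idx_range:
            if profile[i] < half:
                # linear interpolation between i and the neighbor toward peak
                j = i + (1 if i < ipk else -1)
                frac = (half - profile[i]) / (profile[j] - profile[i])
                return i + frac * (j - i)
            prev = i
        return idx_range[-1] if hasattr(idx_range, "__getitem__") else prev

    left = crossing(range(ipk, -1, -1))
    right = crossing(range(ipk, n))
    return abs(right - left) * length / (n - 1)


def roi_stats(image_or_volume: np.ndarray, signal_mask: np.ndarray,
              background_mask: np.ndarray) -> RoiStats:
    """Mean/SD statistics over disjoint signal and background regions."""
    data = np.asarray(image_or_volume, float)
    sm = np.asarray(signal_mask, bool)
    bm = np.asarray(background_mask, bool)
    if sm.shape != data.shape or bm.shape != data.shape:
        raise GeometryError("mask shapes must match the data")
    if not sm.any() or not bm.any():
        raise ValueError("signal and background masks must be non-empty")
    if (sm & bm).any():
        raise ValueError("signal and background masks must be disjoint")
    return RoiStats(mean_signal=float(data[sm].mean()),
                    mean_background=float(data[bm].mean()),
                    sd_background=float(data[bm].std()))
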
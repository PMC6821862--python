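"""Projection pre-processing: Beer-Lambert conversion and flat-fielding.

Transmission projections are divided by an average bright-field image and
log-transformed so the stack holds line-integrated linear attenuation, which
is what filtered back-projection of a transmission measurement requires.
Emission projections get a conventional ``(I - dark) / flat`` correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError
from .stack_io import ProjectionStack

__all__ = ["BrightField", "beer_lambert_correct", "flatfield_correct"]


@dataclass
class BrightField:
    """Average bright-field image I0 and the number of frames averaged."""

    image: np.ndarray
    n_averaged: int = 1

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.image.ndim != 2:
            raise GeometryError("bright field must be a 2-D (row, column) image")


def beer_lambert_correct(stack: ProjectionStack, bright: BrightField | np.ndarray,
                         floor: float = 1.0,
                         clamp_negative: bool = True) -> ProjectionStack:
    """Convert raw transmission intensities to linear attenuation.

    Per pixel: ``A = -ln(max(I, floor) / max(I0, floor))``.  Intensities are
    floored at a small positive count before the log so zero pixels cannot
    produce infinities.  Negative attenuation (I > I0, from noise) clamps to
    zero by default; pass ``clamp_negative=False`` to keep signed values.
    """
    if floor <= 0:
        raise ValueError(f"floor must be > 0, got {floor}")
    i0 = bright.image if isinstance(bright, BrightField) else np.asarray(bright, float)
    if i0.shape != stack.data.shape[1:]:
        raise GeometryError(
            f"bright field shape {i0.shape} does not match projection shape "
            f"{stack.data.shape[1:]}")
    i0c = np.maximum(i0, floor)
    ic = np.maximum(stack.data, floor)
    atten = -np.log(ic / i0c[None])
    if clamp_negative:
        atten = np.clip(atten, 0.0, None)
    return stack.with_data(atten, stage="attenuation")


def flatfield_correct(stack: ProjectionStack, dark: np.ndarray | None = None,
                      flat: np.ndarray | None = None,
                      floor: float = 1e-6) -> ProjectionStack:
    """Emission-mode non-uniformity correction: ``(I - dark) / normalized(flat)``.

    The flat field is normalized to unit mean so overall brightness is
    preserved.  With neither dark nor flat given this is the identity.
    """
    data = stack.data.astype(np.float64, copy=True)
    shape = data.shape[1:]
    if dark is not None:
        dark = np.asarray(dark, float)
        if dark.shape != shape:
            raise GeometryError(
                f"dark frame shape {dark.shape} != projection shape {shape}")
        data = data - dark[None]
    if flat is not None:
        flat = np.asarray(flat, float)
        if flat.shape != shape:
            raise GeometryError(
                f"flat field shape {flat.shape} != projection shape {shape}")
        norm = flat / flat.mean()
        if np.any(norm <= floor):
            raise ValueError(
                "flat field has non-positive values after unit-mean normalization")
        data = data / norm[None]
    return stack.with_data(data, stage="flatfield_corrected")
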
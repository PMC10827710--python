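"""Axial (180°-periodic) orientation arithmetic and the DoG bias function.

Orientations of line gratings live on a half-circle: a grating rotated by
180° is indistinguishable from the original.  All circular statistics on
such *axial* data are computed by doubling the angles onto the full circle,
applying ordinary circular statistics, and halving back.  Signed
orientation differences live in (−90°, +90°], with negative values meaning
the first orientation is counter-clockwise of the reference.

The derivative-of-Gaussian (DoG) curve

    f(x) = x · a · w · c · exp(−(w·x)²),   c = √2·e^{1/2}

is the standard tuning function for serial-dependence-style response
biases: it is odd, peaks at x = 1/(w√2), and the constant c is chosen so
that the peak value equals the amplitude ``a`` (in degrees).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DOG_C",
    "DoGParams",
    "DegenerateMeanError",
    "orientation_diff",
    "wrap_orientation",
    "axial_circular_mean",
    "axial_circular_sd",
    "axial_resultant_length",
    "dog_value",
]

#: Normalising constant of the DoG curve, √2/e^{−1/2}; makes max f = a.
DOG_C: float = math.sqrt(2.0) * math.exp(0.5)


class DegenerateMeanError(ValueError):
    """Axial circular mean is undefined: the resultant vector has ~zero length.

    Raised e.g. for two orthogonal orientations, which are antipodal on the
    doubled circle.  Carries the measured resultant length.
    """

    def __init__(self, resultant_length: float):
        self.resultant_length = float(resultant_length)
        super().__init__(
            f"degenerate axial mean: resultant length {resultant_length:.3g}"
        )


@dataclass(frozen=True)
class DoGParams:
    """Amplitude/width parameterisation of the DoG bias curve.

    a : peak bias in degrees (negative = repulsion).
    w : inverse-width in 1/degrees; the peak sits at x = 1/(w√2).
    """

    a: float
    w: float

    @property
    def peak_location(self) -> float:
        """Delta (degrees) at which |f| is maximal: 1/(w√2)."""
        return 1.0 / (self.w * math.sqrt(2.0))


def _check_finite(x: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite")


def wrap_orientation(theta):
    """Wrap angles onto the canonical orientation domain [0, 180)."""
    theta = np.asarray(theta, dtype=float)
    _check_finite(theta, "orientation")
    out = np.mod(theta, 180.0)
    return out if out.ndim else float(out)


def orientation_diff(a, b):
    """Signed axial difference a − b, in (−90, +90].

    Returns the unique d with a ≡ b + d (mod 180).  Negative values mean
    ``a`` lies counter-clockwise of ``b``.  The ±90 tie is resolved to +90.
    Vectorised over array inputs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_finite(a, "a")
    _check_finite(b, "b")
    d = np.mod(a - b, 180.0)
    d = np.where(d > 90.0, d - 180.0, d)
    return d if d.ndim else float(d)


def axial_resultant_length(angles) -> float:
    """Mean resultant length of orientations on the doubled circle, in [0, 1]."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("empty angle list")
    _check_finite(angles, "angles")
    z = np.exp(2j * np.deg2rad(angles))
    return float(abs(z.mean()))


def axial_circular_mean(angles, *, tol: float = 1e-9) -> float:
    """Circular mean of axial data via angle doubling; result in [0, 180).

    Raises :class:`DegenerateMeanError` when the doubled resultant length
    falls below ``tol`` (orientations balanced around the circle, e.g. two
    orthogonal ones).
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("empty angle list")
    _check_finite(angles, "angles")
    z = np.exp(2j * np.deg2rad(angles)).mean()
    r = abs(z)
    if r < tol:
        raise DegenerateMeanError(r)
    mean = float(np.mod(np.rad2deg(np.angle(z)) / 2.0, 180.0))
    # rounding can land a tiny negative angle exactly on 180.0
    return 0.0 if mean >= 180.0 else mean


def axial_circular_sd(errors) -> float:
    """Circular standard deviation of axial deviations, in degrees.

    Doubles the angles, applies sd = √(−2 ln R), and halves back so the
    result is on the orientation scale.
    """
    r = axial_resultant_length(errors)
    if r <= 0.0:
        return float("inf")
    return float(np.rad2deg(math.sqrt(-2.0 * math.log(r))) / 2.0)


def dog_value(x, p: DoGParams):
    """Evaluate the DoG bias curve f(x) = x·a·w·c·exp(−(w·x)²) in degrees.

    Odd in x; maximum value ``p.a`` attained at x = 1/(p.w·√2).
    """
    x = np.asarray(x, dtype=float)
    _check_finite(x, "x")
    out = x * p.a * p.w * DOG_C * np.exp(-((p.w * x) ** 2))
    return out if out.ndim else float(out)
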
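"""Circular statistics shared by all other modules.

All angles live on the half-open interval (-pi, pi].  Features measured in a
180-degree-periodic space (stimulus orientation) are doubled on input so that
internally every feature covers the full circle; see :func:`scale_orientation`.
Degrees never appear past the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "wrap",
    "circ_dist",
    "resultant",
    "ResultantStats",
    "circ_sd",
    "circ_mad",
    "vm_pdf",
    "vm_sample",
    "scale_orientation",
    "fisher_info_vm",
    "bessel_ratio",
    "inv_bessel_ratio",
]

TWO_PI = 2.0 * np.pi


def _check_finite(x: np.ndarray, name: str = "input") -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite")


def wrap(x):
    """Wrap angle(s) to the interval (-pi, pi].

    The boundary maps to +pi (never -pi), so every direction has a unique
    representation.  Accepts scalars or arrays; returns the same shape.
    """
    x = np.asarray(x, dtype=float)
    _check_finite(x, "angle")
    out = np.pi - np.mod(np.pi - x, TWO_PI)
    return out if out.ndim else float(out)


def circ_dist(a, b):
    """Signed circular distance wrap(a - b), in (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_finite(a, "a")
    _check_finite(b, "b")
    return wrap(a - b)


@dataclass(frozen=True)
class ResultantStats:
    """Mean resultant vector of a circular sample.

    ``length`` is in [0, 1] (1 for a point mass, 0 for a balanced/uniform
    sample); ``direction`` is the circular mean, in (-pi, pi].
    """

    length: float
    direction: float


def resultant(angles, weights=None) -> ResultantStats:
    """Weighted mean resultant vector of a set of angles."""
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if angles.size == 0:
        raise ValueError("resultant of an empty set is undefined")
    _check_finite(angles, "angles")
    if weights is None:
        z = np.exp(1j * angles).mean()
    else:
        weights = np.atleast_1d(np.asarray(weights, dtype=float))
        if weights.shape != angles.shape:
            raise ValueError("weights must match angles in shape")
        if np.any(weights < 0):
            raise ValueError("weights must be nonnegative")
        total = weights.sum()
        if total <= 0:
            raise ValueError("weights must not all be zero")
        z = (weights * np.exp(1j * angles)).sum() / total
    length = min(float(np.abs(z)), 1.0)
    return ResultantStats(length=length, direction=float(wrap(np.angle(z))))


def circ_sd(angles) -> float:
    """Circular standard deviation sqrt(-2 ln R).

    R is the mean resultant length.  Returns +inf for R = 0 (the uniform
    limit), which callers are expected to filter.
    """
    r = resultant(angles).length
    if r <= 1e-12:  # numerically zero resultant: uniform limit
        return float("inf")
    return float(np.sqrt(max(-2.0 * np.log(r), 0.0)))


def circ_mad(deviations) -> float:
    """Mean absolute (circular) deviation; lies in [0, pi].

    For deviations uniform on the circle the expectation is pi/2, which is
    the reference value used when screening non-target deviations for swap
    errors.
    """
    deviations = np.atleast_1d(np.asarray(deviations, dtype=float))
    if deviations.size == 0:
        raise ValueError("circ_mad of an empty set is undefined")
    return float(np.mean(np.abs(wrap(deviations))))


def vm_pdf(x, mu, kappa):
    """von Mises density exp(kappa cos(x - mu)) / (2 pi I0(kappa)).

    kappa = 0 gives the circular uniform density 1/(2 pi).  Uses the
    exponentially scaled Bessel function, so large kappa is safe.
    """
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    x = np.asarray(x, dtype=float)
    _check_finite(x, "x")
    out = np.exp(kappa * (np.cos(x - mu) - 1.0)) / (TWO_PI * special.i0e(kappa))
    return out if out.ndim else float(out)


def vm_sample(mu: float, kappa: float, n: int, rng: np.random.Generator):
    """Draw n von Mises samples, wrapped to (-pi, pi]."""
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    if n < 0:
        raise ValueError("n must be nonnegative")
    return wrap(rng.vonmises(mu, kappa, size=n))


def scale_orientation(theta_deg):
    """Map an orientation in degrees (180-degree space) onto the full circle.

    Orientations are doubled so that the 180-degree space of unique
    orientations covers (-pi, pi], making orientation directly comparable
    with angular location: 90 deg -> pi, -45 deg -> -pi/2.
    """
    theta_deg = np.asarray(theta_deg, dtype=float)
    _check_finite(theta_deg, "theta")
    return wrap(2.0 * np.deg2rad(theta_deg))


def bessel_ratio(kappa):
    """A(kappa) = I1(kappa)/I0(kappa), the mean resultant length of vM(kappa)."""
    kappa = np.asarray(kappa, dtype=float)
    out = special.i1e(kappa) / special.i0e(kappa)
    return out if out.ndim else float(out)


def inv_bessel_ratio(r: float) -> float:
    """Invert A(kappa) = r: concentration of a von Mises with resultant r.

    Uses the standard piecewise approximation followed by Newton refinement.
    r = 0 maps to 0, r -> 1 diverges (capped at 1e4).
    """
    r = float(r)
    if r <= 0.0:
        return 0.0
    if r >= 1.0:
        return 1e4
    if r < 0.53:
        k = 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    elif r < 0.85:
        k = -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    else:
        k = 1.0 / (r**3 - 4.0 * r**2 + 3.0 * r)
    # Newton steps on A(k) - r, using A'(k) = 1 - A/k - A^2.
    for _ in range(25):
        a = bessel_ratio(k)
        da = 1.0 - a / k - a * a if k > 0 else 0.5
        if da <= 0:
            break
        step = (a - r) / da
        k -= step
        if k <= 0:
            k = 1e-8
        if abs(step) < 1e-10 * (1.0 + k):
            break
    return min(float(k), 1e4)


def fisher_info_vm(m, kappa):
    """Fisher information for the mean direction of m von Mises samples.

    Equals m * kappa * I1(kappa)/I0(kappa) for known concentration kappa.
    Vectorised over m.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m < 0) or kappa < 0:
        raise ValueError("m and kappa must be nonnegative")
    out = m * kappa * bessel_ratio(kappa)
    return out if out.ndim else float(out)
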
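"""Hyperbolic-plane primitives for the popularity–similarity (PS) network model.

Nodes live in a two-dimensional hyperbolic disk in native polar coordinates:
the radial coordinate ``r`` encodes popularity (hubs sit near the centre),
the angular coordinate ``theta`` encodes similarity.  Edge likelihoods follow
the Fermi–Dirac form used throughout the PS-model literature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PSModelParams",
    "PolarCoordinates",
    "angular_separation",
    "hyperbolic_distance",
    "connection_probability",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class PSModelParams:
    """Parameters of the popularity–similarity growth model.

    Attributes
    ----------
    gamma : float
        Target power-law exponent of the degree distribution; must exceed 2.
    temperature : float
        Clustering temperature ``T`` of the Fermi–Dirac connection rule
        (``T -> 0`` gives deterministic nearest-neighbour attachment).
    angular_span : float
        Width ``w`` of the angular sector new nodes are dropped into,
        in radians; the full circle ``2*pi`` by default.
    m : int
        Number of links each newly arriving node establishes.
    beta : float
        Popularity-fading exponent, derived as ``1/(gamma - 1)``.
    """

    gamma: float = 2.97
    temperature: float = 0.83
    angular_span: float = TWO_PI
    m: int = 2
    beta: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.gamma > 2:
            raise ValueError(f"gamma must be > 2, got {self.gamma}")
        if self.temperature < 0:
            raise ValueError(f"temperature must be >= 0, got {self.temperature}")
        if not 0 < self.angular_span <= TWO_PI:
            raise ValueError(f"angular_span must be in (0, 2*pi], got {self.angular_span}")
        if self.m < 1:
            raise ValueError(f"m must be a positive integer, got {self.m}")
        object.__setattr__(self, "beta", 1.0 / (self.gamma - 1.0))


@dataclass(frozen=True)
class PolarCoordinates:
    """Position of a node in the hyperbolic disk, ``theta`` reduced mod 2*pi."""

    r: float
    theta: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.r) or self.r < 0:
            raise ValueError(f"radial coordinate must be finite and >= 0, got {self.r}")
        if not math.isfinite(self.theta):
            raise ValueError(f"angular coordinate must be finite, got {self.theta}")
        object.__setattr__(self, "theta", self.theta % TWO_PI)


def angular_separation(theta_1, theta_2):
    """Shortest angle between two directions, in ``[0, pi]``.

    Accepts scalars or numpy arrays (broadcast elementwise).
    """
    delta = np.abs(np.asarray(theta_1) - np.asarray(theta_2)) % TWO_PI
    out = np.minimum(delta, TWO_PI - delta)
    return float(out) if out.ndim == 0 else out


def hyperbolic_distance(a, b, *, r_a=None, theta_a=None, r_b=None, theta_b=None):
    """Distance in the native hyperbolic disk via the hyperbolic law of cosines.

    ``d = arccosh(cosh r_a cosh r_b - sinh r_a sinh r_b cos dtheta)``; the
    arccosh argument is clamped at 1 so that rounding near coincident points
    cannot produce NaN.  The exact law is used rather than the common
    ``r_a + r_b + 2 ln(dtheta/2)`` approximation, which breaks down at small
    separations.

    Parameters may be two :class:`PolarCoordinates`, or arrays via
    :func:`hyperbolic_distance_arrays`.
    """
    return hyperbolic_distance_arrays(a.r, a.theta, b.r, b.theta)


def hyperbolic_distance_arrays(r_a, theta_a, r_b, theta_b):
    """Vectorised hyperbolic distance on raw coordinate arrays/scalars."""
    dtheta = angular_separation(theta_a, theta_b)
    arg = np.cosh(r_a) * np.cosh(r_b) - np.sinh(r_a) * np.sinh(r_b) * np.cos(dtheta)
    arg = np.maximum(arg, 1.0)
    out = np.arccosh(arg)
    # the law of cosines loses precision as dtheta -> 0; the exact limit there
    # is the radial difference
    out = np.where(dtheta == 0, np.abs(np.asarray(r_a) - np.asarray(r_b)), out)
    return float(out) if np.ndim(out) == 0 else out


def connection_probability(x, R, T):
    """Fermi–Dirac probability of an edge at hyperbolic distance ``x``.

    ``p(x) = 1 / (1 + exp((x - R) / (2 T)))`` with cutoff radius ``R`` and
    temperature ``T``; decreasing in ``x``, equal to 1/2 at ``x = R``.
    ``T = 0`` is handled as the step-function limit (1 inside, 0 outside,
    1/2 on the boundary).
    """
    x = np.asarray(x, dtype=float)
    if T == 0:
        out = np.where(x < R, 1.0, np.where(x > R, 0.0, 0.5))
    else:
        # exp argument clipped to keep the tails exact 0/1 instead of overflowing
        z = np.clip((x - R) / (2.0 * T), -745.0, 745.0)
        out = 1.0 / (1.0 + np.exp(z))
    return float(out) if out.ndim == 0 else out
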
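"""Two-degree-of-freedom flapping-foil kinematics.

The foil is a rigid symmetric NACA 0012 section actuated in *sway*
(lateral translation) and *yaw* (rotation about a pivot near the leading
edge)::

    y_sway(t)   = a_sway * sin(2 pi f t)
    phi_yaw(t)  = a_yaw  * sin(2 pi f t - pi/2)

The quarter-period phase shift between the two degrees of freedom makes
the yaw angle maximal whenever the foil crosses zero sway, which mimics
the tail-fin motion of a carangiform swimmer.  Positive yaw rotates the
trailing edge towards negative y, so the sway and yaw excursions of the
trailing edge add constructively and the peak-to-peak trailing-edge
amplitude exceeds ``2 * a_sway``.

The module also provides the Strouhal and Reynolds numbers used to
characterise both the foil and the fish, and the posed NACA 0012 outline
used to build solid masks for the pressure reconstruction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FoilParams",
    "TrajectorySeries",
    "foil_pose",
    "trailing_edge_path",
    "peak_to_peak",
    "strouhal",
    "reynolds",
    "foil_outline",
]


@dataclass(frozen=True)
class FoilParams:
    """Motion program and geometry of the flapping foil.

    Parameters
    ----------
    a_sway : float
        Sway amplitude in metres.
    a_yaw : float
        Yaw amplitude in radians (must be below pi/2).
    f : float
        Flapping frequency in Hz.
    r_te : float
        Distance from the rotation centre to the trailing edge (m).
    chord, span : float
        Foil chord and span (m).
    U : float
        Free-stream flow speed (m/s).
    nu : float
        Kinematic viscosity of the fluid (m^2/s).
    """

    a_sway: float = 0.01
    a_yaw: float = math.radians(20.0)
    f: float = 2.0
    r_te: float = 0.048
    chord: float = 0.067
    span: float = 0.190
    U: float = 0.3
    nu: float = 1.0e-6

    def __post_init__(self) -> None:
        # Amplitudes and the pivot offset may be zero (degenerate but
        # well-defined motions); the remaining physical scales may not.
        for name in ("a_sway", "a_yaw", "r_te"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"FoilParams.{name} must be non-negative")
        for name in ("f", "chord", "span", "U", "nu"):
            value = getattr(self, name)
            if not value > 0.0:
                raise ValueError(f"FoilParams.{name} must be strictly positive, got {value!r}")
        if self.a_yaw >= math.pi / 2:
            raise ValueError(f"yaw amplitude must be below pi/2 rad, got {self.a_yaw}")


@dataclass(frozen=True)
class TrajectorySeries:
    """A uniformly sampled scalar time series (positions or angles)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or times.size < 2:
            raise ValueError("times must be a 1-D array with at least two samples")
        if times.shape != values.shape:
            raise ValueError("times and values must have equal length")
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-12):
            raise ValueError("times must be uniformly spaced")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def rate(self) -> float:
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


def foil_pose(t, p: FoilParams):
    """Sway position (m) and yaw angle (rad) of the foil at time ``t``.

    Vectorised over ``t``; periodic with period ``1/f``.
    """
    t = np.asarray(t, dtype=float)
    phase = 2.0 * math.pi * p.f * t
    sway = p.a_sway * np.sin(phase)
    yaw = p.a_yaw * np.sin(phase - math.pi / 2.0)
    if t.ndim == 0:
        return float(sway), float(yaw)
    return sway, yaw


def trailing_edge_lateral(t, p: FoilParams):
    """Lateral trailing-edge position using exact trigonometric kinematics.

    Positive yaw rotates the trailing edge towards negative y, hence
    ``y_te = sway - r_te * sin(yaw)``.  No small-angle linearisation is
    applied; at a 20 degree yaw amplitude that would already err by ~2%.
    """
    sway, yaw = foil_pose(np.asarray(t, dtype=float), p)
    return sway - p.r_te * np.sin(yaw)


def trailing_edge_path(p: FoilParams, duration: float, rate: float) -> TrajectorySeries:
    """Sample the lateral trailing-edge trajectory over ``duration`` seconds.

    ``rate`` must resolve the flapping cycle densely (>= 100 f) and the
    duration must cover at least one full period.
    """
    if duration < 1.0 / p.f:
        raise ValueError(
            f"duration {duration} s does not cover one flapping period ({1.0 / p.f} s)"
        )
    if rate < 100.0 * p.f:
        raise ValueError(f"sampling rate {rate} Hz is below 100 x f = {100.0 * p.f} Hz")
    n = int(math.floor(duration * rate)) + 1
    times = np.arange(n) / rate
    return TrajectorySeries(times, trailing_edge_lateral(times, p))


def peak_to_peak(series: TrajectorySeries) -> float:
    """Max minus min of a trajectory's values."""
    values = np.asarray(series.values, dtype=float)
    if values.size == 0:
        raise ValueError("empty series")
    return float(values.max() - values.min())


def strouhal(A: float, f: float, U: float) -> float:
    """Strouhal number St = A f / U with A the peak-to-peak amplitude."""
    if U <= 0:
        raise ValueError(f"flow speed U must be positive, got {U}")
    return A * f / U


def reynolds(U: float, L: float, nu: float) -> float:
    """Reynolds number Re = U L / nu."""
    if nu <= 0:
        raise ValueError(f"kinematic viscosity must be positive, got {nu}")
    return U * L / nu


# Closed-trailing-edge NACA 4-digit thickness polynomial (last coefficient
# -0.1036 instead of -0.1015 so the outline closes to a point at the TE).
_NACA_COEFFS = (0.2969, -0.1260, -0.3516, 0.2843, -0.1036)


def _naca0012_half_thickness(xc: np.ndarray, chord: float) -> np.ndarray:
    a0, a1, a2, a3, a4 = _NACA_COEFFS
    yt = 5.0 * 0.12 * (a0 * np.sqrt(xc) + a1 * xc + a2 * xc**2 + a3 * xc**3 + a4 * xc**4)
    return yt * chord


def foil_outline(t: float, p: FoilParams, n: int = 100) -> np.ndarray:
    """Closed polygon (x, y) of the posed NACA 0012 outline at time ``t``.

    The section is placed chordwise along +x with the leading edge
    upstream, rotated by the yaw angle about the rotation centre located
    ``r_te`` ahead of the trailing edge, and translated by the sway
    position.  Returns an ``(n, 2)`` array whose last vertex repeats the
    first.
    """
    if n < 20:
        raise ValueError(f"need at least 20 outline points, got {n}")
    n_side = n // 2 + 1
    # Cosine spacing clusters points near both edges.
    beta = np.linspace(0.0, math.pi, n_side)
    xc = 0.5 * (1.0 - np.cos(beta))
    yt = _naca0012_half_thickness(xc, p.chord)
    xs = xc * p.chord
    upper = np.column_stack([xs, yt])
    lower = np.column_stack([xs[::-1][1:-1], -yt[::-1][1:-1]])
    pts = np.vstack([upper, lower])

    sway, yaw = foil_pose(float(t), p)
    pivot = np.array([p.chord - p.r_te, 0.0])
    rel = pts - pivot
    # Positive yaw deflects the trailing edge towards -y.
    c, s = math.cos(-yaw), math.sin(-yaw)
    rot = rel @ np.array([[c, s], [-s, c]])
    posed = rot + pivot + np.array([0.0, sway])
    return np.vstack([posed, posed[:1]])
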
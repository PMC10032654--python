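"""Synthetic swimmers, reverse Karman vortex streets and oracle flows.

This module generates inputs with the structure the analysis chain
assumes, so the whole pipeline can be exercised without video or PIV
recordings:

* traveling-wave midline tracks emulating 9-marker digitisation at
  125 fps, with an amplitude envelope growing towards the tail and
  optional Gaussian marker noise;
* planar velocity-field sequences of a Lamb-Oseen vortex street
  (thrust-type, i.e. reverse Karman with a centreline jet, or the
  sign-flipped drag-type street) advected over a uniform free stream;
* steady analytic flows (uniform, solid-body rotation, Lamb-Oseen)
  whose pressure fields are known in closed form, used as oracles for
  the pressure reconstruction;
* rasterised solid body masks, and in-line followers whose undulation is
  phase-locked to the wake ("vortex phase matching").

The swimmer midline is built so the body is inextensible: the lateral
displacement as a function of arclength ``s`` (in body lengths) is

    y(s, t) = A(s) sin(2 pi f t - 2 pi s / lam + phi0),
    A(s) = a_head + (a_tail - a_head) s**q,

and the axial coordinate follows from ``dx = sqrt(dl^2 - dy^2)`` so that
marker arclengths are time-invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.spatial import cKDTree

from .kinematics import MidlineTrack

__all__ = [
    "SwimmerSpec",
    "WakeSpec",
    "VelocityFieldSequence",
    "simulate_swimmer",
    "simulate_wake",
    "analytic_flow",
    "body_mask",
    "simulate_inline_follower",
    "lamb_oseen_vtheta",
    "default_width_profile",
]

RHO_WATER = 1000.0  # kg/m^3


@dataclass(frozen=True)
class SwimmerSpec:
    """Parameters of a synthetic traveling-wave swimmer.

    Amplitudes are half-ranges in metres; ``lam`` is the body-wave
    wavelength in body lengths; ``q`` is the envelope exponent
    (quadratic growth towards the tail by default, a common carangiform
    emulation).  Defaults emulate the trout trials: BL = 0.19 m bodies
    digitised with 9 midline markers at 125 fps, beating at 2 Hz with a
    tail amplitude of 7% BL and a head amplitude of a quarter of that.
    """

    f: float = 2.0
    lam: float = 1.0
    a_head: float = 0.25 * 0.07 * 0.19
    a_tail: float = 0.07 * 0.19
    q: float = 2.0
    BL: float = 0.19
    n_markers: int = 9
    fps: float = 125.0
    noise_sd: float = 0.0
    heading: float = 0.0
    snout_offset: tuple[float, float] = (0.0, 0.0)
    phi0: float = 0.0
    duration: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.a_tail >= self.a_head >= 0.0):
            raise ValueError("need a_tail >= a_head >= 0")
        if self.lam <= 0:
            raise ValueError("wavelength must be positive")
        if self.n_markers < 2:
            raise ValueError("need at least 2 markers")
        if self.fps <= 2.0 * self.f:
            raise ValueError(
                f"fps={self.fps} does not satisfy the Nyquist bound for f={self.f}"
            )
        if self.BL <= 0 or self.duration <= 0:
            raise ValueError("BL and duration must be positive")


def _envelope(spec: SwimmerSpec, s: np.ndarray) -> np.ndarray:
    return spec.a_head + (spec.a_tail - spec.a_head) * s**spec.q


def _envelope_deriv(spec: SwimmerSpec, s: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        d = spec.q * (spec.a_tail - spec.a_head) * s ** (spec.q - 1.0)
    return np.nan_to_num(d)


def simulate_swimmer(spec: SwimmerSpec) -> MidlineTrack:
    """Generate a midline track of an inextensible traveling-wave swimmer.

    Markers are equally spaced in arclength.  Raises if the amplitude is
    too large for the wavelength (the body tangent would exceed 90
    degrees) or if the frame rate violates the Nyquist bound.
    """
    n_frames = int(math.floor(spec.duration * spec.fps)) + 1
    times = np.arange(n_frames) / spec.fps
    s = np.linspace(0.0, 1.0, 1001)  # arclength fraction, fine grid
    A = _envelope(spec, s)
    dA = _envelope_deriv(spec, s)
    k = 2.0 * math.pi / spec.lam
    omega = 2.0 * math.pi * spec.f

    # Worst-case |dy/dl| over the cycle at each station.
    slope_amp = np.hypot(dA, A * k) / spec.BL
    if slope_amp.max() >= 1.0:
        raise ValueError(
            "amplitude envelope too large for wavelength: body tangent would "
            f"reach 90 degrees (max |dy/dl| = {slope_amp.max():.2f})"
        )

    marker_s = np.linspace(0.0, 1.0, spec.n_markers)
    xy = np.empty((n_frames, spec.n_markers, 2))
    c, sn = math.cos(spec.heading), math.sin(spec.heading)
    rot = np.array([[c, -sn], [sn, c]])
    offset = np.asarray(spec.snout_offset, dtype=float)

    for fi, t in enumerate(times):
        psi = omega * t - k * s + spec.phi0
        y = A * np.sin(psi)
        dyds = dA * np.sin(psi) + A * k * np.cos(psi)  # metres per BL
        dxds = np.sqrt(np.maximum(spec.BL**2 - dyds**2, 0.0))
        x = cumulative_trapezoid(dxds, s, initial=0.0)
        mx = np.interp(marker_s, s, x)
        my = np.interp(marker_s, s, y)
        xy[fi] = np.column_stack([mx, my]) @ rot.T + offset

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        xy = xy + rng.normal(0.0, spec.noise_sd, size=xy.shape)
    return MidlineTrack(times, xy, spec.BL, spec.fps)


# ---------------------------------------------------------------------------
# velocity fields


@dataclass
class VelocityFieldSequence:
    """Planar velocity frames on a shared regular grid.

    ``u`` and ``v`` have shape ``(n_frames, ny, nx)`` with ``x`` along
    the last axis; ``mask`` (optional, same shape, boolean) marks solid
    cells.  ``U_inf`` is the free-stream speed and ``rho`` the fluid
    density used in pressure reconstruction.
    """

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    dt: float
    U_inf: float = 0.0
    rho: float = RHO_WATER
    mask: np.ndarray | None = None
    meta: dict | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.ndim != 3 or self.u.shape != self.v.shape:
            raise ValueError("u and v must both have shape (n_frames, ny, nx)")
        if self.u.shape[1:] != (self.y.size, self.x.size):
            raise ValueError("field shape does not match the grid")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.u.shape:
                raise ValueError("mask shape must match the velocity frames")
        fluid = ~self.mask if self.mask is not None else np.ones_like(self.u, dtype=bool)
        if not np.all(np.isfinite(self.u[fluid])) or not np.all(np.isfinite(self.v[fluid])):
            raise ValueError("velocities must be finite on fluid cells")
        if self.meta is None:
            self.meta = {}

    @property
    def n_frames(self) -> int:
        return self.u.shape[0]

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def dy(self) -> float:
        return float(self.y[1] - self.y[0])

    def frame_mask(self, frame: int) -> np.ndarray | None:
        return None if self.mask is None else self.mask[frame]


@dataclass(frozen=True)
class WakeSpec:
    """Lamb-Oseen vortex street advected over a uniform free stream.

    Consecutive vortices sit ``lam_w`` apart in x, alternate between the
    rows ``y = +/- b/2`` and alternate in circulation sign;
    ``street_sign = +1`` arranges the signs so the induced centreline
    flow exceeds the free stream (thrust wake / reverse Karman street),
    ``-1`` gives the drag-wake arrangement.  Vortices advect downstream
    at ``U_c`` and are recycled upstream with spatial period
    ``n_vortices * lam_w`` so the street is statistically stationary;
    ``n_vortices`` must be even to preserve the alternation across the
    wrap.  Defaults correspond to the flapping-foil operating point:
    U_inf = 0.3 m/s, advection at U_c = 1.1 U_inf, and a street pattern
    advancing one inter-vortex spacing per flap cycle of a 2 Hz flapper
    (lam_w = U_c / f), so the shedding frequency ``U_c / lam_w`` equals
    the flapping frequency.
    """

    gamma: float = 0.02
    r_c: float = 0.008
    lam_w: float = 0.165
    b: float = 0.03
    U_inf: float = 0.3
    U_c: float = 0.33
    street_sign: int = 1
    rho: float = RHO_WATER
    x_range: tuple[float, float] = (0.0, 0.5)
    y_range: tuple[float, float] = (-0.1, 0.1)
    spacing: float = 0.002
    fps: float = 1000.0
    n_vortices: int = 6
    duration: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.r_c < self.b:
            raise ValueError("core radius must be below the lateral row spacing b")
        if self.lam_w <= 0:
            raise ValueError("streamwise spacing lam_w must be positive")
        if self.spacing > self.r_c / 4.0:
            raise ValueError(
                f"grid spacing {self.spacing} too coarse: need >= 4 cells per "
                f"core radius ({self.r_c})"
            )
        if self.street_sign not in (-1, 1):
            raise ValueError("street_sign must be +1 (thrust) or -1 (drag)")
        if self.n_vortices < 2 or self.n_vortices % 2:
            raise ValueError("n_vortices must be an even count >= 2")

    @property
    def shedding_period(self) -> float:
        """Time for the street to advect by one inter-vortex spacing."""
        return self.lam_w / self.U_c

    @property
    def shedding_frequency(self) -> float:
        return self.U_c / self.lam_w


def lamb_oseen_vtheta(r: np.ndarray, gamma: float, r_c: float) -> np.ndarray:
    """Tangential speed of a Lamb-Oseen vortex, regular at the origin."""
    r = np.asarray(r, dtype=float)
    r2 = np.maximum(r**2, 1e-300)
    return gamma / (2.0 * math.pi) * (1.0 - np.exp(-r2 / r_c**2)) / np.sqrt(r2)


def _add_vortex(u, v, X, Y, xv, yv, gamma, r_c):
    dx = X - xv
    dy = Y - yv
    r2 = dx**2 + dy**2
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = gamma / (2.0 * math.pi) * (1.0 - np.exp(-r2 / r_c**2)) / r2
    factor = np.where(r2 > 0, factor, 0.0)
    u += -dy * factor
    v += dx * factor


def _street_grid(spec: WakeSpec):
    x = np.arange(spec.x_range[0], spec.x_range[1] + 0.5 * spec.spacing, spec.spacing)
    y = np.arange(spec.y_range[0], spec.y_range[1] + 0.5 * spec.spacing, spec.spacing)
    return x, y


def street_vortices(spec: WakeSpec, t: float):
    """Vortex centres and circulations ``(x, y, gamma)`` at time ``t``."""
    L = spec.n_vortices * spec.lam_w
    x0 = spec.x_range[0] + 0.5 * (
        (spec.x_range[1] - spec.x_range[0]) - (spec.n_vortices - 1) * spec.lam_w
    )
    out = []
    for k in range(spec.n_vortices):
        xk = x0 + (k * spec.lam_w + spec.U_c * t) % L
        top = k % 2 == 0
        yk = 0.5 * spec.b if top else -0.5 * spec.b
        gk = spec.street_sign * spec.gamma * (1.0 if top else -1.0)
        out.append((xk, yk, gk))
    return out


def simulate_wake(spec: WakeSpec, duration: float | None = None,
                  t0: float = 0.0) -> VelocityFieldSequence:
    """Simulate the advecting vortex street on a regular grid.

    ``duration`` defaults to one shedding period (plus one frame) which,
    on the centreline, covers a full oscillation cycle of the street.
    """
    if duration is None:
        duration = spec.duration if spec.duration is not None else spec.shedding_period
    x, y = _street_grid(spec)
    X, Y = np.meshgrid(x, y)
    n_frames = int(math.floor(duration * spec.fps)) + 1
    u = np.empty((n_frames, y.size, x.size))
    v = np.empty_like(u)
    for fi in range(n_frames):
        t = t0 + fi / spec.fps
        uf = np.full_like(X, spec.U_inf)
        vf = np.zeros_like(X)
        for xv, yv, gv in street_vortices(spec, t):
            _add_vortex(uf, vf, X, Y, xv, yv, gv, spec.r_c)
        u[fi] = uf
        v[fi] = vf
    meta = {"kind": "vortex_street", "street_sign": spec.street_sign,
            "lam_w": spec.lam_w, "b": spec.b, "gamma": spec.gamma,
            "r_c": spec.r_c, "U_c": spec.U_c}
    return VelocityFieldSequence(x, y, u, v, 1.0 / spec.fps,
                                 U_inf=spec.U_inf, rho=spec.rho, meta=meta)


def analytic_flow(kind: Literal["uniform", "solid_rotation", "lamb_oseen"],
                  params: dict, grid) -> VelocityFieldSequence:
    """Steady oracle flows with known pressure structure.

    ``grid`` is ``(x, y)`` arrays of node coordinates.  ``params``:

    * ``uniform``: ``u0``, ``v0`` (m/s); pressure constant.
    * ``solid_rotation``: ``omega`` (rad/s), ``center``;
      ``p(r) - p(0) = rho omega^2 r^2 / 2``.
    * ``lamb_oseen``: ``gamma``, ``r_c``, ``center``;
      ``dp/dr = rho v_theta(r)^2 / r``.

    Optional ``params`` keys: ``n_frames`` (default 3), ``dt`` (default
    1 ms), ``rho``.
    """
    x, y = (np.asarray(g, dtype=float) for g in grid)
    X, Y = np.meshgrid(x, y)
    n_frames = int(params.get("n_frames", 3))
    dt = float(params.get("dt", 1e-3))
    rho = float(params.get("rho", RHO_WATER))
    if kind == "uniform":
        uf = np.full_like(X, float(params.get("u0", 0.0)))
        vf = np.full_like(X, float(params.get("v0", 0.0)))
        U_inf = float(params.get("u0", 0.0))
    elif kind == "solid_rotation":
        cx, cy = params.get("center", (0.0, 0.0))
        omega = float(params["omega"])
        uf = -omega * (Y - cy)
        vf = omega * (X - cx)
        U_inf = 0.0
    elif kind == "lamb_oseen":
        cx, cy = params.get("center", (0.0, 0.0))
        uf = np.zeros_like(X)
        vf = np.zeros_like(X)
        _add_vortex(uf, vf, X, Y, cx, cy, float(params["gamma"]), float(params["r_c"]))
        U_inf = 0.0
    else:
        raise ValueError(f"unknown analytic flow kind {kind!r}")
    u = np.repeat(uf[None], n_frames, axis=0)
    v = np.repeat(vf[None], n_frames, axis=0)
    return VelocityFieldSequence(x, y, u, v, dt, U_inf=U_inf, rho=rho,
                                 meta={"kind": kind, **params})


# ---------------------------------------------------------------------------
# solid masks and followers


def default_width_profile(max_width: float) -> Callable[[np.ndarray], np.ndarray]:
    """Trout-like full-width profile: pointed snout, widest at 25% BL,
    tapering to the tail tip."""

    def width(s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        head = np.sqrt(np.clip(s / 0.25, 0.0, 1.0))
        tail = np.clip((1.0 - s) / 0.75, 0.0, 1.0) ** 0.8
        return max_width * np.minimum(head, tail)

    return width


def body_mask(midline_xy: np.ndarray, width_profile, grid) -> np.ndarray:
    """Rasterise a body outline around a midline onto a grid.

    ``width_profile`` maps arclength fraction ``s`` in [0, 1] to the
    *full* body width in metres (a callable, or an array sampled at the
    midline markers).  A grid node is solid when it lies within half the
    local width of the midline.  Returns a boolean ``(ny, nx)`` array.
    """
    x, y = (np.asarray(g, dtype=float) for g in grid)
    pts = np.asarray(midline_xy, dtype=float)
    if (pts[:, 0].min() < x.min() or pts[:, 0].max() > x.max()
            or pts[:, 1].min() < y.min() or pts[:, 1].max() > y.max()):
        raise ValueError("midline extends outside the grid bounds")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    s_markers = arc / arc[-1]
    n_dense = 800
    s_dense = np.linspace(0.0, 1.0, n_dense)
    dense = np.column_stack([
        np.interp(s_dense, s_markers, pts[:, 0]),
        np.interp(s_dense, s_markers, pts[:, 1]),
    ])
    if callable(width_profile):
        widths = np.asarray(width_profile(s_dense), dtype=float)
    else:
        widths = np.interp(s_dense, s_markers, np.asarray(width_profile, dtype=float))
    if np.all(widths <= 0):
        return np.zeros((y.size, x.size), dtype=bool)
    X, Y = np.meshgrid(x, y)
    nodes = np.column_stack([X.ravel(), Y.ravel()])
    tree = cKDTree(dense)
    dist, idx = tree.query(nodes, k=1)
    solid = dist <= 0.5 * widths[idx]
    return solid.reshape(y.size, x.size)


def add_body_blockage(seq: VelocityFieldSequence, nose, width: float) -> VelocityFieldSequence:
    """Superpose the potential flow of a blunt body nose onto a sequence.

    Real velocity fields measured around a fish contain the body's
    blockage of the oncoming flow — in particular the stagnation region
    ahead of the snout that produces positive head pressure.  A free
    vortex street does not.  This helper emulates the blockage with the
    classical half-body source flow: a point source of strength
    ``Q = U_inf * width`` (matching the asymptotic body width) placed so
    the stagnation point falls at ``nose``.  All frames are modified
    alike (the body is static); the subtraction is recorded in ``meta``.
    """
    if seq.U_inf <= 0:
        raise ValueError("body blockage needs a positive free-stream speed")
    Q = seq.U_inf * width
    a = Q / (2.0 * math.pi * seq.U_inf)  # source-to-stagnation distance
    sx, sy = nose[0] + a, nose[1]
    X, Y = np.meshgrid(seq.x, seq.y)
    dx = X - sx
    dy = Y - sy
    r2 = np.maximum(dx**2 + dy**2, (0.25 * a) ** 2)
    us = Q / (2.0 * math.pi) * dx / r2
    vs = Q / (2.0 * math.pi) * dy / r2
    meta = dict(seq.meta or {})
    meta["body_blockage"] = {"nose": tuple(nose), "width": width, "Q": Q}
    return VelocityFieldSequence(seq.x, seq.y, seq.u + us[None], seq.v + vs[None],
                                 seq.dt, U_inf=seq.U_inf, rho=seq.rho,
                                 mask=None if seq.mask is None else seq.mask.copy(),
                                 meta=meta)


def simulate_inline_follower(wake: WakeSpec, swimmer: SwimmerSpec,
                             distances: Sequence[float], phase_const: float = 0.0):
    """Wake-locked followers at given gap distances behind the foil.

    Each follower swims on the centreline with its snout ``d`` metres
    downstream of the foil trailing edge (taken as the origin), beats at
    the wake shedding frequency ``U_c / lam_w`` and delays its body wave
    by ``2 pi d / lam_w + phase_const`` — the phase relationship of a
    swimmer synchronising to vortices advected at ``U_c``.  Returns a
    list of ``(distance, MidlineTrack)`` pairs.
    """
    distances = list(distances)
    if not distances:
        raise ValueError("need at least one follower distance")
    if any(d < 0 for d in distances):
        raise ValueError("follower distances must be non-negative")
    f_w = wake.shedding_frequency
    out = []
    for i, d in enumerate(distances):
        spec_d = replace(
            swimmer,
            f=f_w,
            heading=0.0,
            snout_offset=(d, 0.0),
            phi0=-(2.0 * math.pi * d / wake.lam_w + phase_const),
            seed=swimmer.seed + i,
        )
        out.append((d, simulate_swimmer(spec_d)))
    return out
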
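"""Pressure reconstruction from sequential planar velocity fields.

The pressure gradient is estimated on the measurement grid from the
Eulerian material acceleration,

    grad p = -rho (du/dt + (u . grad) u) + mu laplacian(u),

with the time derivative taken between consecutive frames and spatial
derivatives by central differences (one-sided next to domain edges and
solid masks).  The gradient is then integrated along eight families of
straight paths marching inward from the domain boundary — east, west,
north, south and the four diagonals — accumulating ``grad p . dl`` by
the trapezoidal rule.  Paths blocked by a solid node contribute no
candidate; each fluid node takes the median of its surviving candidates,
which makes the estimate robust to individual corrupted path families.

Boundary reference
------------------
Paths are initiated on the domain boundary.  With ``boundary="edge"``
(default) the boundary values are first obtained by integrating the
tangential pressure gradient around the domain edge and the gauge is
fixed by a zero *mean* boundary pressure; for a quiescent or uniform
far field this coincides with assuming zero pressure at the boundary,
while remaining exact for conservative gradients whose true boundary
pressure varies (rotational oracle flows).  ``boundary="zero"`` pins
every path origin to exactly zero instead.

All pressures are therefore relative; solid nodes are never assigned a
pressure and surface pressures are read from adjacent fluid nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .synth import VelocityFieldSequence

__all__ = [
    "PressureConfig",
    "PressureField",
    "pressure_gradient",
    "integrate_pressure",
    "head_pressure",
    "head_box_mask",
    "drag_force",
    "subtract_mean_flow",
    "vorticity",
    "vortex_centers",
]


@dataclass(frozen=True)
class PressureConfig:
    """Fluid constants and numerical options for pressure reconstruction."""

    rho: float = 1000.0
    mu: float = 0.0
    time_scheme: str = "forward"  # or "central"
    include_viscous: bool = False
    boundary: str = "edge"  # or "zero"

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise ValueError("density must be positive")
        if self.mu < 0:
            raise ValueError("viscosity must be non-negative")
        if self.time_scheme not in ("forward", "central"):
            raise ValueError("time_scheme must be 'forward' or 'central'")
        if self.boundary not in ("edge", "zero"):
            raise ValueError("boundary must be 'edge' or 'zero'")


@dataclass
class PressureField:
    """Relative pressure on the measurement grid.

    ``defined`` is True where at least one integration path survived;
    undefined fluid nodes carry the value of their nearest defined
    neighbour, solid nodes carry NaN.
    """

    x: np.ndarray
    y: np.ndarray
    p: np.ndarray
    defined: np.ndarray
    spread: np.ndarray | None = None  # max-min over surviving candidates


# ---------------------------------------------------------------------------
# derivatives


def _masked_derivative(f: np.ndarray, h: float, axis: int,
                       valid: np.ndarray) -> np.ndarray:
    """First derivative with central stencils, one-sided at edges/masks.

    ``valid`` marks nodes carrying usable values; the derivative is NaN
    where no valid neighbour exists along ``axis``.
    """
    f = np.where(valid, f, np.nan)
    fp = np.full_like(f, np.nan)
    fm = np.full_like(f, np.nan)
    vp = np.zeros_like(valid)
    vm = np.zeros_like(valid)
    sl_to = [slice(None)] * f.ndim
    sl_from = [slice(None)] * f.ndim
    sl_to[axis], sl_from[axis] = slice(None, -1), slice(1, None)
    fp[tuple(sl_to)] = f[tuple(sl_from)]
    vp[tuple(sl_to)] = valid[tuple(sl_from)]
    sl_to[axis], sl_from[axis] = slice(1, None), slice(None, -1)
    fm[tuple(sl_to)] = f[tuple(sl_from)]
    vm[tuple(sl_to)] = valid[tuple(sl_from)]

    d = np.full_like(f, np.nan)
    both = valid & vp & vm
    d[both] = (fp[both] - fm[both]) / (2.0 * h)
    fwd = valid & vp & ~vm
    d[fwd] = (fp[fwd] - f[fwd]) / h
    bwd = valid & ~vp & vm
    d[bwd] = (f[bwd] - fm[bwd]) / h
    return d


def pressure_gradient(seq: VelocityFieldSequence, frame: int,
                      cfg: PressureConfig | None = None):
    """Pressure-gradient components ``(dp/dx, dp/dy)`` in Pa/m at ``frame``.

    Uses the configured finite-difference scheme in time (``forward``
    needs ``frame + 1``; ``central`` also needs ``frame - 1``) and
    mask-aware central differences in space.  Solid nodes are NaN.
    """
    if cfg is None:
        cfg = PressureConfig(rho=seq.rho)
    if seq.n_frames < 2:
        raise ValueError("pressure gradients need at least two sequential frames")
    if cfg.time_scheme == "central" and (frame < 1 or frame + 1 >= seq.n_frames):
        raise ValueError("central time scheme needs frames on both sides")
    if cfg.time_scheme == "forward" and frame + 1 >= seq.n_frames:
        raise ValueError("forward time scheme needs the next frame")

    mask = seq.frame_mask(frame)
    fluid = np.ones(seq.u.shape[1:], dtype=bool) if mask is None else ~mask
    u = np.where(fluid, seq.u[frame], np.nan)
    v = np.where(fluid, seq.v[frame], np.nan)

    if cfg.time_scheme == "forward":
        dudt = (seq.u[frame + 1] - seq.u[frame]) / seq.dt
        dvdt = (seq.v[frame + 1] - seq.v[frame]) / seq.dt
    else:
        dudt = (seq.u[frame + 1] - seq.u[frame - 1]) / (2.0 * seq.dt)
        dvdt = (seq.v[frame + 1] - seq.v[frame - 1]) / (2.0 * seq.dt)

    dudx = _masked_derivative(u, seq.dx, 1, fluid)
    dudy = _masked_derivative(u, seq.dy, 0, fluid)
    dvdx = _masked_derivative(v, seq.dx, 1, fluid)
    dvdy = _masked_derivative(v, seq.dy, 0, fluid)

    ax = dudt + u * dudx + v * dudy
    ay = dvdt + u * dvdx + v * dvdy
    gx = -cfg.rho * ax
    gy = -cfg.rho * ay
    if cfg.include_viscous and cfg.mu > 0:
        lap_u = (_masked_derivative(_masked_derivative(u, seq.dx, 1, fluid), seq.dx, 1, fluid)
                 + _masked_derivative(_masked_derivative(u, seq.dy, 0, fluid), seq.dy, 0, fluid))
        lap_v = (_masked_derivative(_masked_derivative(v, seq.dx, 1, fluid), seq.dx, 1, fluid)
                 + _masked_derivative(_masked_derivative(v, seq.dy, 0, fluid), seq.dy, 0, fluid))
        gx = gx + cfg.mu * lap_u
        gy = gy + cfg.mu * lap_v
    gx[~fluid] = np.nan
    gy[~fluid] = np.nan
    return gx, gy


# ---------------------------------------------------------------------------
# path integration


def _boundary_loop(ny: int, nx: int):
    """Perimeter node indices in a closed counter-clockwise-ish loop."""
    idx = []
    idx += [(0, j) for j in range(nx)]
    idx += [(i, nx - 1) for i in range(1, ny)]
    idx += [(ny - 1, j) for j in range(nx - 2, -1, -1)]
    idx += [(i, 0) for i in range(ny - 2, 0, -1)]
    return idx


def _edge_boundary_values(gx, gy, fluid, dx, dy):
    """Boundary pressures from tangential integration around the edge.

    The closure error of the loop integral is redistributed linearly
    (for a conservative gradient it vanishes); masked boundary nodes
    break the chain and stay NaN.  Gauge: zero mean over defined nodes.
    """
    ny, nx = fluid.shape
    loop = _boundary_loop(ny, nx)
    n = len(loop)
    vals = np.full(n, np.nan)
    cum = np.zeros(n)
    ok = np.zeros(n, dtype=bool)
    ok[0] = fluid[loop[0]]
    vals[0] = 0.0 if ok[0] else np.nan
    lengths = np.zeros(n)
    blocked = not ok[0]
    for i in range(1, n + 1):
        a = loop[i - 1]
        bnode = loop[i % n]
        di, dj = bnode[0] - a[0], bnode[1] - a[1]
        step = math.hypot(dj * dx, di * dy)
        ex = 0.0 if step == 0 else dj * dx / step
        ey = 0.0 if step == 0 else di * dy / step
        ga = gx[a] * ex + gy[a] * ey
        gb = gx[bnode] * ex + gy[bnode] * ey
        inc = 0.5 * (ga + gb) * step
        if i < n:
            lengths[i] = lengths[i - 1] + step
            if fluid[bnode] and not blocked and np.isfinite(inc) and np.isfinite(vals[i - 1]):
                vals[i] = vals[i - 1] + inc
                ok[i] = True
            elif fluid[bnode]:
                # restart an arc after a blockage with a free gauge
                vals[i] = 0.0
                ok[i] = True
                blocked = False
            else:
                blocked = True
        else:
            closure = inc + (vals[n - 1] - vals[0]) if ok[n - 1] and ok[0] else np.nan
            total = lengths[-1] + step
    if np.isfinite(closure) and ok.all():
        vals = vals - closure * lengths / total
    if ok.any():
        vals = vals - np.nanmean(vals)
    B = np.full((ny, nx), np.nan)
    for val, node in zip(vals, loop):
        B[node] = val
    return B


_DIRECTIONS = [(0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (1, -1), (-1, 1), (-1, -1)]


def _march(gproj: np.ndarray, entry: np.ndarray, fluid: np.ndarray,
           di: int, dj: int, dl: float) -> np.ndarray:
    """Accumulate trapezoidal path integrals along one grid direction.

    ``entry`` holds starting pressures on boundary nodes whose
    predecessor lies outside the grid (NaN elsewhere); NaN gradients or
    solid nodes block the path for all nodes further along it.
    """
    ny, nx = gproj.shape
    p = np.array(entry, dtype=float)
    p[~fluid] = np.nan

    def shifted(arr, fill=np.nan):
        out = np.full_like(arr, fill)
        if dj == 1:
            out[:, 1:] = arr[:, :-1]
        elif dj == -1:
            out[:, :-1] = arr[:, 1:]
        else:
            out[:] = arr
        return out

    if di == 0:
        cols = range(1, nx) if dj == 1 else range(nx - 2, -1, -1)
        for j in cols:
            jp = j - dj
            cand = p[:, jp] + 0.5 * (gproj[:, jp] + gproj[:, j]) * dl
            take = np.isnan(p[:, j]) & fluid[:, j]
            p[take, j] = cand[take]
    else:
        rows = range(1, ny) if di == 1 else range(ny - 2, -1, -1)
        for i in rows:
            ip = i - di
            prev_p = shifted(p[ip][None])[0]
            prev_g = shifted(gproj[ip][None])[0]
            cand = prev_p + 0.5 * (prev_g + gproj[i]) * dl
            take = np.isnan(p[i]) & fluid[i]
            p[i, take] = cand[take]
    return p


def integrate_pressure(gx: np.ndarray, gy: np.ndarray, x: np.ndarray,
                       y: np.ndarray, mask: np.ndarray | None = None,
                       boundary: str = "edge",
                       return_candidates: bool = False) -> PressureField:
    """Integrate a pressure gradient by median polling of eight path families.

    Straight paths march inward from the domain boundary along the
    eight principal grid directions, accumulating ``grad p . dl`` with
    the trapezoidal rule (``dl`` is the cell diagonal on diagonal
    families).  Paths crossing a solid node are discarded for all nodes
    beyond the obstruction; each node's pressure is the median of its
    surviving candidates.  Nodes with no surviving path are marked
    undefined and filled from the nearest defined neighbour.
    """
    gx = np.asarray(gx, dtype=float)
    gy = np.asarray(gy, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ny, nx = gx.shape
    fluid = np.ones((ny, nx), dtype=bool) if mask is None else ~np.asarray(mask, dtype=bool)
    if not fluid.any():
        raise ValueError("all nodes are masked solid; nothing to integrate")
    dx = float(x[1] - x[0])
    dy = float(y[1] - y[0])

    gxw = np.where(fluid, gx, np.nan)
    gyw = np.where(fluid, gy, np.nan)
    if boundary == "edge":
        B = _edge_boundary_values(gxw, gyw, fluid, dx, dy)
    elif boundary == "zero":
        B = np.full((ny, nx), np.nan)
        for node in _boundary_loop(ny, nx):
            B[node] = 0.0 if fluid[node] else np.nan
    else:
        raise ValueError("boundary must be 'edge' or 'zero'")

    candidates = np.full((len(_DIRECTIONS), ny, nx), np.nan)
    for d, (di, dj) in enumerate(_DIRECTIONS):
        dl = math.hypot(dj * dx, di * dy)
        ex = dj * dx / dl
        ey = di * dy / dl
        gproj = gxw * ex + gyw * ey
        entry = np.full((ny, nx), np.nan)
        if di == 1:
            entry[0, :] = B[0, :]
        elif di == -1:
            entry[-1, :] = B[-1, :]
        if dj == 1:
            entry[:, 0] = B[:, 0]
        elif dj == -1:
            entry[:, -1] = B[:, -1]
        candidates[d] = _march(gproj, entry, fluid, di, dj, dl)

    with np.errstate(invalid="ignore"):
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", category=RuntimeWarning)
            p = np.nanmedian(candidates, axis=0)
            spread = np.nanmax(candidates, axis=0) - np.nanmin(candidates, axis=0)
    defined = fluid & np.isfinite(p)

    # fill undefined fluid nodes from the nearest defined neighbour
    undef = fluid & ~defined
    if undef.any():
        if not defined.any():
            raise ValueError("no integration path survived anywhere")
        X, Y = np.meshgrid(x, y)
        tree = cKDTree(np.column_stack([X[defined], Y[defined]]))
        _, idx = tree.query(np.column_stack([X[undef], Y[undef]]), k=1)
        p[undef] = p[defined][idx]
    p[~fluid] = np.nan
    field = PressureField(x, y, p, defined, spread)
    if return_candidates:
        return field, candidates
    return field


# ---------------------------------------------------------------------------
# head pressure and wake visualisation helpers


def head_box_mask(field: PressureField, snout, heading: float, BL: float,
                  width: float) -> np.ndarray:
    """Boolean grid of nodes inside the snout interrogation box.

    The box extends ``0.1 * BL`` from the snout along the heading
    direction (towards the body) and ``+/- width / 2`` laterally.
    """
    X, Y = np.meshgrid(field.x, field.y)
    sx, sy = snout
    hx, hy = math.cos(heading), math.sin(heading)
    ax = (X - sx) * hx + (Y - sy) * hy
    lat = -(X - sx) * hy + (Y - sy) * hx
    return (ax >= 0.0) & (ax <= 0.1 * BL) & (np.abs(lat) <= 0.5 * width)


def head_pressure(field: PressureField, snout, heading: float, BL: float,
                  width: float) -> float:
    """Mean pressure in the snout box, excluding solid/undefined nodes."""
    box = head_box_mask(field, snout, heading, BL, width)
    use = box & np.isfinite(field.p)
    if not use.any():
        raise ValueError("snout box contains no defined fluid nodes")
    return float(field.p[use].mean())


def drag_force(pressure: float, surface_area: float) -> float:
    """Pressure-drag estimate F = p * S for a frontal surface area S."""
    return pressure * surface_area


def subtract_mean_flow(seq: VelocityFieldSequence) -> VelocityFieldSequence:
    """Subtract the spatio-temporal mean axial flow for wake visualisation.

    Only ``u`` is shifted; the vorticity (hence the visible vortex
    structure) is unchanged.  The subtracted value is recorded in the
    metadata.
    """
    if seq.n_frames == 0:
        raise ValueError("empty sequence")
    fluid = ~seq.mask if seq.mask is not None else np.ones_like(seq.u, dtype=bool)
    mean_u = float(seq.u[fluid].mean())
    meta = dict(seq.meta or {})
    meta["subtracted_mean_u"] = mean_u
    return VelocityFieldSequence(seq.x, seq.y, seq.u - mean_u, seq.v.copy(), seq.dt,
                                 U_inf=seq.U_inf, rho=seq.rho,
                                 mask=None if seq.mask is None else seq.mask.copy(),
                                 meta=meta)


def vorticity(u: np.ndarray, v: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Out-of-plane vorticity dv/dx - du/dy on the grid."""
    dvdx = np.gradient(v, x, axis=1)
    dudy = np.gradient(u, y, axis=0)
    return dvdx - dudy


def vortex_centers(u: np.ndarray, v: np.ndarray, x: np.ndarray, y: np.ndarray,
                   threshold: float = 0.25, min_cells: int = 4):
    """Detect vortex centres from thresholded vorticity blobs.

    Nodes where ``|vorticity|`` exceeds ``threshold`` times the frame
    maximum are grouped into connected blobs; each blob yields a centre
    at the vorticity-weighted centroid (sub-cell precision) and a sign.
    Returns a list of ``(x, y, sign)`` sorted downstream; empty for
    irrotational frames.
    """
    w = vorticity(u, v, x, y)
    wmax = np.nanmax(np.abs(w))
    if not np.isfinite(wmax) or wmax <= 0 or wmax < 1e-12:
        return []
    strong = np.abs(w) >= threshold * wmax
    labels, n = ndimage.label(strong)
    X, Y = np.meshgrid(x, y)
    centers = []
    for lab in range(1, n + 1):
        blob = labels == lab
        if blob.sum() < min_cells:
            continue
        wb = np.abs(w[blob])
        cx = float((X[blob] * wb).sum() / wb.sum())
        cy = float((Y[blob] * wb).sum() / wb.sum())
        sign = 1 if w[blob].mean() > 0 else -1
        centers.append((cx, cy, sign))
    centers.sort(key=lambda c: c[0])
    return centers
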
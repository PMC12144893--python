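"""Numba kernels shared by surfaces, restraints and the Langevin integrator.

Surfaces and restraints are encoded as flat float arrays so that a single
compiled integrator can serve every landscape in the package:

surface kinds
    0 ("poly1d")  params = polynomial coefficients c0..cn, E(x) = sum c_k x^k
    1 ("bumps2d") params = [n_basins,
                            c_0, d_0, w_0, ..., c_{n-1}, d_{n-1}, w_{n-1},
                            k_wide, k_narrow, s_f, w_f]
                  E(s, y) = -sum_k d_k * bump((s - c_k)/w_k)
                            + 0.5 * k_lat(s) * y**2
                  with k_lat(s) = k_wide + (k_narrow - k_wide) * sigmoid((s_f - s)/w_f)

restraint rows (n, 5): [kind, anchor_x, anchor_y, spring_constant, flat_radius]
    1 = tether      half-harmonic on distance from anchor beyond flat_radius
    2 = funnel_wall half-harmonic on |y| beyond flat_radius

The bump profile exp(1 - 1/(1 - u^2)) is smooth and compactly supported on
|u| < 1, so basins have strictly local influence: two landscapes that differ
only in one basin depth are *identical* outside that basin's support.
"""

from __future__ import annotations

import numpy as np
from numba import njit

SURF_POLY1D = 0
SURF_BUMPS2D = 1

RESTR_TETHER = 1
RESTR_FUNNEL_WALL = 2


@njit(cache=True)
def bump(u):
    if u <= -1.0 or u >= 1.0:
        return 0.0
    return np.exp(1.0 - 1.0 / (1.0 - u * u))


@njit(cache=True)
def dbump(u):
    if u <= -1.0 or u >= 1.0:
        return 0.0
    t = 1.0 - u * u
    return np.exp(1.0 - 1.0 / t) * (-2.0 * u / (t * t))


@njit(cache=True)
def _lateral_stiffness(s, k_wide, k_narrow, s_f, w_f):
    z = (s_f - s) / w_f
    # guarded logistic
    if z > 40.0:
        sig = 1.0
    elif z < -40.0:
        sig = 0.0
    else:
        sig = 1.0 / (1.0 + np.exp(-z))
    return k_wide + (k_narrow - k_wide) * sig


@njit(cache=True)
def _dlateral_stiffness(s, k_wide, k_narrow, s_f, w_f):
    z = (s_f - s) / w_f
    if z > 40.0 or z < -40.0:
        return 0.0
    sig = 1.0 / (1.0 + np.exp(-z))
    return (k_narrow - k_wide) * sig * (1.0 - sig) * (-1.0 / w_f)


@njit(cache=True)
def surface_energy(kind, params, x, y):
    if kind == SURF_POLY1D:
        e = 0.0
        xp = 1.0
        for k in range(params.shape[0]):
            e += params[k] * xp
            xp *= x
        return e
    # bumps2d
    nb = int(params[0])
    e = 0.0
    for k in range(nb):
        c = params[1 + 3 * k]
        d = params[2 + 3 * k]
        w = params[3 + 3 * k]
        e -= d * bump((x - c) / w)
    off = 1 + 3 * nb
    klat = _lateral_stiffness(x, params[off], params[off + 1], params[off + 2], params[off + 3])
    return e + 0.5 * klat * y * y


@njit(cache=True)
def surface_gradient(kind, params, x, y):
    if kind == SURF_POLY1D:
        g = 0.0
        xp = 1.0
        for k in range(1, params.shape[0]):
            g += k * params[k] * xp
            xp *= x
        return g, 0.0
    nb = int(params[0])
    gx = 0.0
    for k in range(nb):
        c = params[1 + 3 * k]
        d = params[2 + 3 * k]
        w = params[3 + 3 * k]
        gx -= d * dbump((x - c) / w) / w
    off = 1 + 3 * nb
    kw, kn, sf, wf = params[off], params[off + 1], params[off + 2], params[off + 3]
    klat = _lateral_stiffness(x, kw, kn, sf, wf)
    dklat = _dlateral_stiffness(x, kw, kn, sf, wf)
    gx += 0.5 * dklat * y * y
    gy = klat * y
    return gx, gy


@njit(cache=True)
def restraint_energy(restr, x, y):
    e = 0.0
    for i in range(restr.shape[0]):
        kind = int(restr[i, 0])
        ax, ay = restr[i, 1], restr[i, 2]
        k, r0 = restr[i, 3], restr[i, 4]
        if kind == RESTR_TETHER:
            dx = x - ax
            dy = y - ay
            d = np.sqrt(dx * dx + dy * dy)
            if d > r0:
                e += 0.5 * k * (d - r0) * (d - r0)
        elif kind == RESTR_FUNNEL_WALL:
            d = abs(y)
            if d > r0:
                e += 0.5 * k * (d - r0) * (d - r0)
    return e


@njit(cache=True)
def restraint_gradient(restr, x, y):
    gx = 0.0
    gy = 0.0
    for i in range(restr.shape[0]):
        kind = int(restr[i, 0])
        ax, ay = restr[i, 1], restr[i, 2]
        k, r0 = restr[i, 3], restr[i, 4]
        if kind == RESTR_TETHER:
            dx = x - ax
            dy = y - ay
            d = np.sqrt(dx * dx + dy * dy)
            if d > r0 and d > 1e-300:
                f = k * (d - r0) / d
                gx += f * dx
                gy += f * dy
        elif kind == RESTR_FUNNEL_WALL:
            d = abs(y)
            if d > r0:
                s = 1.0 if y > 0.0 else -1.0
                gy += k * (d - r0) * s
    return gx, gy


@njit(cache=True)
def bias_force(x, grid_min, grid_dx, dvdx):
    """Minus is applied by caller; returns dV/ds linearly interpolated."""
    n = dvdx.shape[0]
    t = (x - grid_min) / grid_dx
    if t <= 0.0:
        return dvdx[0]
    if t >= n - 1:
        return dvdx[n - 1]
    j = int(t)
    f = t - j
    return dvdx[j] * (1.0 - f) + dvdx[j + 1] * f


@njit(cache=True)
def bias_value(x, grid_min, grid_dx, v):
    n = v.shape[0]
    t = (x - grid_min) / grid_dx
    if t <= 0.0:
        return v[0]
    if t >= n - 1:
        return v[n - 1]
    j = int(t)
    f = t - j
    return v[j] * (1.0 - f) + v[j + 1] * f


@njit(cache=True)
def total_energy(kind, params, restr, x, y):
    return surface_energy(kind, params, x, y) + restraint_energy(restr, x, y)


@njit(cache=True)
def _reflect(x, lo, hi):
    # mirror back into [lo, hi]; loop handles multiple-width excursions
    while x < lo or x > hi:
        if x < lo:
            x = 2.0 * lo - x
        else:
            x = 2.0 * hi - x
    return x


@njit(cache=True)
def integrate_chunk(
    pos,
    kind,
    params,
    restr,
    ndim,
    use_bias,
    grid_min,
    grid_dx,
    bias_dvdx,
    dt,
    friction,
    kT,
    box,
    noise,
    step0,
    save_stride,
    frames,
):
    """Advance `noise.shape[0]` Euler-Maruyama steps, saving frames in place.

    `frames` has one row per saved frame for the whole run; a step s (1-based
    global index step0 + i + 1) is saved at row s // save_stride when
    s % save_stride == 0.  Returns the global index of the first step at which
    a non-finite energy was encountered, or -1 on success.
    """
    x = pos[0]
    y = pos[1] if ndim == 2 else 0.0
    amp = np.sqrt(2.0 * kT * dt / friction)
    n = noise.shape[0]
    for i in range(n):
        gx, gy = surface_gradient(kind, params, x, y)
        rgx, rgy = restraint_gradient(restr, x, y)
        gx += rgx
        gy += rgy
        if use_bias:
            gx += bias_force(x, grid_min, grid_dx, bias_dvdx)
        x = x - gx * dt / friction + amp * noise[i, 0]
        x = _reflect(x, box[0, 0], box[0, 1])
        if ndim == 2:
            y = y - gy * dt / friction + amp * noise[i, 1]
            y = _reflect(y, box[1, 0], box[1, 1])
        if not (np.isfinite(x) and np.isfinite(y)):
            return step0 + i + 1
        gstep = step0 + i + 1
        if gstep % save_stride == 0:
            row = gstep // save_stride
            if row < frames.shape[0]:
                frames[row, 0] = x
                if ndim == 2:
                    frames[row, 1] = y
    pos[0] = x
    if ndim == 2:
        pos[1] = y
    return -1


@njit(cache=True)
def first_passage_chunk(
    pos,
    kind,
    params,
    restr,
    ndim,
    dt,
    friction,
    kT,
    box,
    noise,
    target_lo,
    target_hi,
):
    """Advance until the CV enters [target_lo, target_hi] or noise is spent.

    Returns the number of steps taken in this chunk; position updated in
    place.  Caller detects arrival by checking the final CV.
    """
    x = pos[0]
    y = pos[1] if ndim == 2 else 0.0
    amp = np.sqrt(2.0 * kT * dt / friction)
    n = noise.shape[0]
    taken = n
    for i in range(n):
        gx, gy = surface_gradient(kind, params, x, y)
        rgx, rgy = restraint_gradient(restr, x, y)
        gx += rgx
        gy += rgy
        x = x - gx * dt / friction + amp * noise[i, 0]
        x = _reflect(x, box[0, 0], box[0, 1])
        if ndim == 2:
            y = y - gy * dt / friction + amp * noise[i, 1]
            y = _reflect(y, box[1, 0], box[1, 1])
        if target_lo <= x <= target_hi:
            taken = i + 1
            break
    pos[0] = x
    if ndim == 2:
        pos[1] = y
    return taken


@njit(cache=True)
def batch_energy(kind, params, restr, X):
    out = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        x = X[i, 0]
        y = X[i, 1] if X.shape[1] == 2 else 0.0
        out[i] = surface_energy(kind, params, x, y) + restraint_energy(restr, x, y)
    return out


@njit(cache=True)
def batch_gradient(kind, params, restr, X):
    out = np.empty_like(X)
    for i in range(X.shape[0]):
        x = X[i, 0]
        y = X[i, 1] if X.shape[1] == 2 else 0.0
        gx, gy = surface_gradient(kind, params, x, y)
        rgx, rgy = restraint_gradient(restr, x, y)
        out[i, 0] = gx + rgx
        if X.shape[1] == 2:
            out[i, 1] = gy + rgy
    return out


@njit(cache=True)
def markov_chain_passage(p_cum, start, target_mask, u):
    """First-passage of a discrete chain; u = uniforms, one per step.

    Returns (steps, final_state); steps = -1 means the target was not reached
    before u was exhausted (continue by calling again from final_state).
    """
    state = start
    if target_mask[state]:
        return 0, state
    n = u.shape[0]
    for t in range(n):
        r = u[t]
        row = p_cum[state]
        # linear scan; state counts are tiny
        nxt = row.shape[0] - 1
        for j in range(row.shape[0]):
            if r <= row[j]:
                nxt = j
                break
        state = nxt
        if target_mask[state]:
            return t + 1, state
    return -1, state
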
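"""Multiple-walker well-tempered metadynamics on the exit coordinate.

Gaussian hills are deposited along the CV every ``deposition_stride`` steps
with well-tempered damping w = w0 · exp(-V(s)/((γ-1) kT)); all walkers feel,
and deposit into, one shared bias.  Walkers advance in lockstep between
deposition events and hills are applied in walker-index order at each event,
so runs are deterministic and invariant to scheduling.  The free energy is
recovered from the final bias as F(s) = -γ/(γ-1) · V(s), and equilibrium
frame weights from the final-bias estimator w_i ∝ exp(+V(s_i)/kT) after an
equilibration fraction is discarded.

The bias lives on a uniform grid with linear interpolation; an exact
analytic Gaussian summation over a hills log is provided as the slow
reference path for tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .dynamics import SimConfig, Trajectory, stream
from .plumed import HillsLog
from .toy_systems import (
    FreeEnergyProfile,
    InvalidParameterError,
    PotentialSurface,
    encode_restraints,
)


class GridOverflowError(RuntimeError):
    """A walker's CV left the bias grid."""


class EmptySelectionError(ValueError):
    """No frames survived the selection (e.g. all discarded as equilibration)."""


@dataclass
class MetaDConfig:
    hill_height_w0: float = 1.2  # kT
    hill_sigma: float = 0.10  # CV units
    bias_factor_gamma: float = 8.0
    deposition_stride: int = 500  # steps
    n_walkers: int = 4
    grid_min: float = 0.0
    grid_max: float = 10.0
    n_grid: int = 512

    def __post_init__(self):
        if self.bias_factor_gamma <= 1:
            raise InvalidParameterError("bias_factor_gamma must exceed 1")
        if self.hill_height_w0 <= 0 or self.hill_sigma <= 0:
            raise InvalidParameterError("hill height and sigma must be positive")
        if self.n_walkers < 1 or self.deposition_stride < 1 or self.n_grid < 2:
            raise InvalidParameterError("n_walkers, deposition_stride, n_grid out of range")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.grid_min, self.grid_max, self.n_grid)


@dataclass
class BiasGrid:
    """Accumulated bias V(s) >= 0 on a uniform CV grid."""

    grid: np.ndarray
    values: np.ndarray
    gamma: float

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("bias values must be finite and >= 0")

    def value_at(self, s) -> np.ndarray:
        return np.interp(s, self.grid, self.values)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# cv bias_kT gamma={self.gamma!r}\n")
            for s, v in zip(self.grid, self.values):
                fh.write(f"{float(s)!r} {float(v)!r}\n")


@dataclass
class WeightedFrames:
    """Equilibrium-reweighted frame references with normalized weights."""

    traj_index: np.ndarray
    frame_index: np.ndarray
    cv: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.size == 0:
            raise EmptySelectionError("no frames selected")
        if np.any(self.weights < 0) or not np.all(np.isfinite(self.weights)):
            raise InvalidParameterError("weights must be finite and >= 0")
        total = self.weights.sum()
        if abs(total - 1.0) > 1e-12:
            self.weights = self.weights / total

    @property
    def n(self) -> int:
        return self.weights.shape[0]


def run_metad(
    surface: PotentialSurface,
    restraints,
    sim_config: SimConfig,
    metad_config: MetaDConfig,
) -> tuple[list[Trajectory], HillsLog, BiasGrid]:
    """Shared-bias multiple-walker well-tempered metadynamics run.

    Every walker runs ``sim_config.n_steps`` steps.  Hills are deposited at
    each walker's current CV every ``deposition_stride`` steps, in
    walker-index order, against the shared bias.
    """
    mc = metad_config
    if mc.grid_min > surface.domain[0, 0] + 1e-12 or mc.grid_max < surface.domain[0, 1] - 1e-12:
        raise InvalidParameterError(
            f"bias grid [{mc.grid_min}, {mc.grid_max}] does not cover the CV domain "
            f"{surface.domain[0].tolist()}"
        )
    ndim = surface.n_dims
    restr = encode_restraints(restraints)
    grid = mc.grid
    grid_dx = float(grid[1] - grid[0])
    V = np.zeros_like(grid)
    dvdx = np.zeros_like(grid)
    kT = sim_config.kT
    dt = sim_config.time_step

    x0 = np.asarray(sim_config.initial_position, dtype=float)[:ndim]
    if not surface.in_domain(x0[None, :])[0]:
        raise InvalidParameterError(f"initial position {x0} outside domain")

    n_frames = sim_config.n_frames
    positions = [np.zeros(2) for _ in range(mc.n_walkers)]
    for p in positions:
        p[:ndim] = x0
    frames = [np.empty((n_frames, ndim)) for _ in range(mc.n_walkers)]
    frame_bias = [np.empty(n_frames) for _ in range(mc.n_walkers)]
    for w in range(mc.n_walkers):
        frames[w][0] = x0
        frame_bias[w][0] = 0.0
    rngs = [stream(sim_config.seed, 101, w) for w in range(mc.n_walkers)]

    hills_t, hills_c, hills_s, hills_h, hills_w = [], [], [], [], []
    done = 0
    last_row = [0] * mc.n_walkers
    while done < sim_config.n_steps:
        stride = min(mc.deposition_stride, sim_config.n_steps - done)
        for w in range(mc.n_walkers):
            noise = rngs[w].standard_normal((stride, ndim))
            status = K.integrate_chunk(
                positions[w], surface.kind_code, surface.params, restr, ndim,
                True, float(grid[0]), grid_dx, dvdx,
                dt, sim_config.friction, kT, surface.domain,
                noise, done, sim_config.save_stride, frames[w],
            )
            if status >= 0:
                raise GridOverflowError(
                    f"walker {w}: non-finite coordinates at step {status}"
                )
        done += stride
        if stride == mc.deposition_stride:  # full cycle -> deposit, walker order
            t_dep = done * dt
            for w in range(mc.n_walkers):
                s_c = positions[w][0]
                if s_c < mc.grid_min or s_c > mc.grid_max:
                    raise GridOverflowError(
                        f"walker {w} CV {s_c} left the bias grid at step {done}"
                    )
                v_here = np.interp(s_c, grid, V)
                h = mc.hill_height_w0 * np.exp(-v_here / ((mc.bias_factor_gamma - 1.0) * kT))
                # mirror images across the reflecting walls avoid boundary
                # underfill of the bias (image-hill correction)
                for c in (s_c, 2.0 * mc.grid_min - s_c, 2.0 * mc.grid_max - s_c):
                    V += h * np.exp(-0.5 * ((grid - c) / mc.hill_sigma) ** 2)
                hills_t.append(t_dep)
                hills_c.append(float(s_c))
                hills_s.append(mc.hill_sigma)
                hills_h.append(float(h))
                hills_w.append(w)
            dvdx = np.gradient(V, grid)
        # bias recorded at end-of-cycle resolution for newly saved frames
        row_hi = done // sim_config.save_stride
        for w in range(mc.n_walkers):
            lo = last_row[w] + 1
            if row_hi >= lo:
                cvs = frames[w][lo : row_hi + 1, 0]
                frame_bias[w][lo : row_hi + 1] = np.interp(cvs, grid, V)
                last_row[w] = row_hi

    bias = BiasGrid(grid=grid, values=V, gamma=mc.bias_factor_gamma)
    times = np.arange(n_frames) * (sim_config.save_stride * dt)
    trajs = []
    for w in range(mc.n_walkers):
        cv = frames[w][:, 0].copy()
        trajs.append(
            Trajectory(
                times=times.copy(),
                positions=frames[w],
                cv_values=cv,
                surface_label=[surface.label] * n_frames,
                walker_id=w,
                bias_at_frame=frame_bias[w],
            )
        )
    log = HillsLog(
        time=np.array(hills_t),
        center=np.array(hills_c),
        sigma=np.array(hills_s),
        height=np.array(hills_h),
        biasf=np.full(len(hills_t), mc.bias_factor_gamma),
        walker_id=np.array(hills_w, dtype=int),
    )
    return trajs, log, bias


def bias_from_hills(
    log: HillsLog, grid: np.ndarray, gamma: float | None = None, mirror: bool = True
) -> BiasGrid:
    """Exact Gaussian summation of a hills log (slow reference path).

    ``mirror`` adds image hills reflected at the grid ends, matching the
    deposition convention used by :func:`run_metad`.
    """
    grid = np.asarray(grid, dtype=float)
    V = np.zeros_like(grid)
    lo, hi = grid[0], grid[-1]
    for i in range(log.n):
        centers = (log.center[i],)
        if mirror:
            centers = (log.center[i], 2 * lo - log.center[i], 2 * hi - log.center[i])
        for c in centers:
            V += log.height[i] * np.exp(-0.5 * ((grid - c) / log.sigma[i]) ** 2)
    if gamma is None:
        gamma = float(log.biasf[0]) if log.n else np.inf
    return BiasGrid(grid=grid, values=V, gamma=gamma)


def averaged_bias(
    log: HillsLog,
    grid: np.ndarray,
    gamma: float | None = None,
    *,
    last_fraction: float = 0.5,
    n_snapshots: int = 100,
    mirror: bool = True,
) -> BiasGrid:
    """Time-averaged bias over the tail of the deposition history.

    Rebuilds V(t) hill by hill (with mirror images at the grid edges, as in
    deposition) and averages mean-aligned snapshots over the last
    ``last_fraction`` of hills.  Averaging suppresses the hill-sized ripples
    of a single late-time bias while leaving the converged shape intact.
    """
    grid = np.asarray(grid, dtype=float)
    if gamma is None:
        gamma = float(log.biasf[0]) if log.n else np.inf
    V = np.zeros_like(grid)
    lo, hi = grid[0], grid[-1]
    start = int(last_fraction * log.n)
    snap_at = np.unique(np.linspace(max(start, 1), log.n, n_snapshots, dtype=int))
    acc = np.zeros_like(grid)
    taken = 0
    for i in range(log.n):
        centers = (log.center[i],)
        if mirror:
            centers = (log.center[i], 2 * lo - log.center[i], 2 * hi - log.center[i])
        for c in centers:
            V += log.height[i] * np.exp(-0.5 * ((grid - c) / log.sigma[i]) ** 2)
        if i + 1 in snap_at:
            acc += V - V.mean()
            taken += 1
    Vbar = acc / max(taken, 1)
    Vbar -= Vbar.min()
    return BiasGrid(grid=grid, values=Vbar, gamma=gamma)


def free_energy_estimate(bias: BiasGrid) -> FreeEnergyProfile:
    """Well-tempered inversion F(s) = -γ/(γ-1) · V(s), shifted to min 0."""
    if bias.gamma <= 1:
        raise InvalidParameterError("well-tempered estimate requires gamma > 1")
    scale = bias.gamma / (bias.gamma - 1.0) if np.isfinite(bias.gamma) else 1.0
    return FreeEnergyProfile(bias.grid, -scale * bias.values, source="metad")


def reweight(
    trajectories: list[Trajectory],
    bias: BiasGrid,
    kT: float = 1.0,
    equilibration_fraction: float = 0.2,
) -> WeightedFrames:
    """Final-bias estimator: frame i gets weight ∝ exp(+V_final(s_i)/kT).

    The first ``equilibration_fraction`` of each walker's frames is
    discarded (the bias is far from its asymptotic shape there).
    """
    if not 0 <= equilibration_fraction < 1:
        raise InvalidParameterError("equilibration_fraction must be in [0, 1)")
    ti, fi, cv = [], [], []
    for k, traj in enumerate(trajectories):
        start = int(equilibration_fraction * traj.n_frames)
        idx = np.arange(start, traj.n_frames)
        ti.append(np.full(idx.size, k))
        fi.append(idx)
        cv.append(traj.cv_values[idx])
    ti = np.concatenate(ti) if ti else np.array([], dtype=int)
    if ti.size == 0:
        raise EmptySelectionError("all frames discarded as equilibration")
    fi = np.concatenate(fi)
    cv = np.concatenate(cv)
    v = bias.value_at(cv) / kT
    w = np.exp(v - v.max())
    return WeightedFrames(traj_index=ti, frame_index=fi, cv=cv, weights=w / w.sum())
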
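"""Overdamped Langevin dynamics on model landscapes.

Euler–Maruyama integration of dx = -(∇E/γ) dt + sqrt(2 kT dt / γ) dW with
reflecting boundaries at the domain box.  The integrator is the package's
molecular-dynamics stand-in: it consumes only configurational statistics and
first-passage times, so no velocities are carried.  Random numbers come from
counter-based Philox streams keyed per (seed, purpose, walker/replica), which
makes multi-walker and multi-replica runs reproducible independently of
scheduling.

Also houses the brute-force kinetics oracles used to validate the Markov
state model estimates: direct first-passage sampling and the 1D
mean-first-passage-time ODE solved by quadrature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

from . import _kernels as K
from .toy_systems import (
    DomainError,
    InvalidParameterError,
    PotentialSurface,
    encode_restraints,
)

_CHUNK = 1 << 16


class NumericalFailureError(RuntimeError):
    """Non-finite coordinates encountered during integration."""


class ConfigurationError(ValueError):
    pass


def stream(seed: int, *ids: int) -> np.random.Generator:
    """Counter-based Philox stream keyed by (seed, *ids)."""
    key = [int(seed)] + [int(i) for i in ids]
    return np.random.Generator(np.random.Philox(np.random.SeedSequence(key)))


@dataclass
class SimConfig:
    n_steps: int
    time_step: float = 0.004
    friction: float = 1.0
    kT: float = 1.0
    save_stride: int = 10
    seed: int = 0
    initial_position: tuple = (0.0, 0.0)
    walker_id: int = 0

    def __post_init__(self):
        if self.time_step <= 0:
            raise InvalidParameterError("time_step must be positive")
        if self.n_steps < 1 or self.save_stride < 1:
            raise InvalidParameterError("n_steps and save_stride must be >= 1")

    @property
    def n_frames(self) -> int:
        return self.n_steps // self.save_stride + 1


@dataclass
class Trajectory:
    """Saved frames of one walker, with per-frame CV and optional bias."""

    times: np.ndarray
    positions: np.ndarray  # (n_frames, n_dims)
    cv_values: np.ndarray
    surface_label: list
    walker_id: int = 0
    bias_at_frame: np.ndarray | None = None
    switch_events: list = field(default_factory=list)  # (frame_index, old, new)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_dims(self) -> int:
        return self.positions.shape[1]

    @property
    def end_position(self) -> np.ndarray:
        return self.positions[-1].copy()


def _prep(surface: PotentialSurface, restraints, config: SimConfig):
    x0 = np.asarray(config.initial_position, dtype=float)[: surface.n_dims]
    if not surface.in_domain(x0[None, :])[0]:
        raise DomainError(f"initial position {x0} outside domain {surface.domain.tolist()}")
    restr = encode_restraints(restraints)
    pos = np.zeros(2)
    pos[: surface.n_dims] = x0
    return pos, restr


def integrate(
    surface: PotentialSurface,
    restraints=None,
    bias=None,
    config: SimConfig = None,
    *,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Run Euler–Maruyama under surface + restraints (+ optional CV bias).

    Identical (config, seed) gives bit-identical trajectories.  A non-finite
    coordinate raises NumericalFailureError naming the step index.
    """
    if config is None:
        raise ConfigurationError("config is required")
    pos, restr = _prep(surface, restraints, config)
    ndim = surface.n_dims
    if rng is None:
        rng = stream(config.seed, 11, config.walker_id)

    use_bias = bias is not None
    if use_bias:
        grid = bias.grid
        grid_min = float(grid[0])
        grid_dx = float(grid[1] - grid[0])
        dvdx = np.gradient(bias.values, grid)
        bias_values = bias.values
    else:
        grid_min, grid_dx = 0.0, 1.0
        dvdx = np.zeros(2)
        bias_values = None

    n_frames = config.n_frames
    frames = np.empty((n_frames, ndim))
    frames[0] = pos[:ndim]

    done = 0
    while done < config.n_steps:
        m = min(_CHUNK, config.n_steps - done)
        noise = rng.standard_normal((m, ndim))
        status = K.integrate_chunk(
            pos,
            surface.kind_code,
            surface.params,
            restr,
            ndim,
            use_bias,
            grid_min,
            grid_dx,
            dvdx,
            config.time_step,
            config.friction,
            config.kT,
            surface.domain,
            noise,
            done,
            config.save_stride,
            frames,
        )
        if status >= 0:
            raise NumericalFailureError(f"non-finite energy/position at step {status}")
        done += m

    times = np.arange(n_frames) * (config.save_stride * config.time_step)
    cv = frames[:, 0].copy()
    bias_at_frame = np.interp(cv, bias.grid, bias_values) if use_bias else None
    return Trajectory(
        times=times,
        positions=frames,
        cv_values=cv,
        surface_label=[surface.label] * n_frames,
        walker_id=config.walker_id,
        bias_at_frame=bias_at_frame,
    )


def switch_surface(
    trajectory: Trajectory,
    new_surface: PotentialSurface,
    config: SimConfig,
    restraints=None,
    bias=None,
    *,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Continue a trajectory on a different governing surface.

    The in-silico analogue of photoisomerizing the bound ligand: position is
    continuous across the switch and the concatenated trajectory records the
    switch event at the junction frame.
    """
    end = trajectory.end_position
    if not new_surface.in_domain(end[None, :])[0]:
        raise DomainError("trajectory end state lies outside the new surface's domain")
    cont = integrate(
        new_surface,
        restraints,
        bias,
        replace(config, initial_position=tuple(end)),
        rng=rng,
    )
    switch_idx = trajectory.n_frames - 1
    old_label = trajectory.surface_label[-1]
    return Trajectory(
        times=np.concatenate([trajectory.times, trajectory.times[-1] + cont.times[1:]]),
        positions=np.vstack([trajectory.positions, cont.positions[1:]]),
        cv_values=np.concatenate([trajectory.cv_values, cont.cv_values[1:]]),
        surface_label=list(trajectory.surface_label) + [new_surface.label] * (cont.n_frames - 1),
        walker_id=trajectory.walker_id,
        bias_at_frame=None,
        switch_events=list(trajectory.switch_events)
        + [(switch_idx, old_label, new_surface.label)],
    )


def brute_force_mfpt(
    surface: PotentialSurface,
    restraints,
    start_region: str,
    target_region: str,
    n_replicas: int,
    max_steps: int,
    seed: int,
    *,
    time_step: float = 0.004,
    friction: float = 1.0,
    kT: float = 1.0,
    burn_in_steps: int = 20000,
) -> dict:
    """Direct first-passage sampling: the model-free kinetics oracle.

    Replicas are equilibrated near the start region's minimum, then run until
    the CV first enters the target region.  Replicas that hit ``max_steps``
    are censored: counted, excluded from the mean, and flagged with a
    warning in the returned record.
    """
    if n_replicas < 1:
        raise InvalidParameterError("n_replicas must be >= 1")
    i_start = surface.region_index(start_region)  # raises KeyError -> config error
    i_target = surface.region_index(target_region)
    if i_start == i_target:
        return {
            "mean": 0.0,
            "sem": 0.0,
            "n_reached": n_replicas,
            "n_censored": 0,
            "times": np.zeros(n_replicas),
        }
    target = surface.regions[i_target]
    x0 = surface.region_minimum(start_region)
    restr = encode_restraints(restraints)
    ndim = surface.n_dims

    times = []
    n_censored = 0
    for rep in range(n_replicas):
        rng = stream(seed, 7001, rep)
        pos = np.zeros(2)
        pos[:ndim] = x0
        # burn-in with an unreachable target
        left = burn_in_steps
        while left > 0:
            m = min(_CHUNK, left)
            noise = rng.standard_normal((m, ndim))
            K.first_passage_chunk(
                pos, surface.kind_code, surface.params, restr, ndim,
                time_step, friction, kT, surface.domain, noise, np.inf, np.inf,
            )
            left -= m
        steps = 0
        reached = False
        while steps < max_steps:
            m = min(_CHUNK, max_steps - steps)
            noise = rng.standard_normal((m, ndim))
            taken = K.first_passage_chunk(
                pos, surface.kind_code, surface.params, restr, ndim,
                time_step, friction, kT, surface.domain, noise,
                target.cv_lo, target.cv_hi,
            )
            steps += taken
            if target.cv_lo <= pos[0] <= target.cv_hi:
                reached = True
                break
        if reached:
            times.append(steps * time_step)
        else:
            n_censored += 1
    times = np.asarray(times)
    if n_censored:
        warnings.warn(
            f"{n_censored}/{n_replicas} first-passage replicas censored at "
            f"max_steps={max_steps}; the mean excludes them and underestimates the MFPT"
        )
    mean = float(times.mean()) if times.size else float("nan")
    sem = float(times.std(ddof=1) / np.sqrt(times.size)) if times.size > 1 else float("nan")
    return {
        "mean": mean,
        "sem": sem,
        "n_reached": int(times.size),
        "n_censored": int(n_censored),
        "times": times,
    }


def mfpt_ode_1d(
    x_grid: np.ndarray,
    potential: np.ndarray,
    x_start: float,
    x_target: float,
    *,
    kT: float = 1.0,
    friction: float = 1.0,
) -> float:
    """Mean first-passage time of 1D overdamped diffusion by quadrature.

    Solves D τ'' - U'/γ τ' = -1 with a reflecting boundary at the grid edge
    opposite the target, via the standard double integral
    τ(x0) = (γ/kT) ∫_{x0}^{b} e^{U(y)/kT} ∫_{a}^{y} e^{-U(z)/kT} dz dy.
    """
    x = np.asarray(x_grid, dtype=float)
    U = np.asarray(potential, dtype=float)
    if x_target < x_start:  # mirror so the target is on the right
        x, U = -x[::-1], U[::-1]
        x_start, x_target = -x_start, -x_target
    U = U - U.min()
    inner = cumulative_trapezoid(np.exp(-U / kT), x, initial=0.0)
    integrand = np.exp(U / kT) * inner
    outer = cumulative_trapezoid(integrand, x, initial=0.0)
    o_start = np.interp(x_start, x, outer)
    o_target = np.interp(x_target, x, outer)
    return float((friction / kT) * (o_target - o_start))
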
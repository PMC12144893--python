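"""Analytic stand-in landscapes for tethered-ligand unbinding.

The atomistic system — a covalently tethered photoswitchable agonist leaving
a receptor's orthosteric pocket through vestibule states — is replaced by
low-dimensional model potentials expressed in reduced units (kT = 1, unit
length, unit friction).  The exit landscape has

* a deep bound basin at small values of the exit coordinate s (the
  orthosteric pocket),
* one or more shallower intermediate basins (vestibule states),
* a flat unbound region at large s whose lateral confinement opens up
  (funnel geometry, realised as s-dependent lateral harmonic stiffness),
* optionally a capped half-harmonic tether emulating the covalent
  disulfide anchor, and
* paired "E"/"Z" isomer variants differing only in bound-basin depth.

All basins use compactly supported bump profiles, so an isomer pair is
bit-identical outside the pocket.  Every surface carries analytic gradients
and declared regions whose boundaries sit at the saddles of the projected
free energy along s.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import _kernels as K


class InvalidParameterError(ValueError):
    """A landscape or restraint parameter violates its preconditions."""


class DomainError(ValueError):
    """A position or grid lies outside a surface's declared domain box."""


_NO_RESTRAINTS = np.zeros((0, 5))


@dataclass(frozen=True)
class Region:
    """Named interval of the collective variable (exit coordinate)."""

    name: str
    cv_lo: float
    cv_hi: float

    def contains(self, cv: np.ndarray) -> np.ndarray:
        cv = np.asarray(cv, dtype=float)
        return (cv >= self.cv_lo) & (cv < self.cv_hi)


@dataclass(frozen=True)
class RestraintTerm:
    """Half-harmonic restraint: zero inside ``flat_radius``, harmonic beyond.

    kind "tether" acts on the distance to ``anchor`` (the covalent-anchor
    stand-in); "funnel_wall" acts on |y|, the lateral coordinate;
    "reflecting_box" and "surface_switch" are declarative markers handled by
    the integrator and the switching protocol respectively.
    """

    kind: str
    anchor: tuple[float, float] = (0.0, 0.0)
    spring_constant: float = 1.0
    flat_radius: float = 0.0
    max_extension: float | None = None

    _CODES = {"tether": K.RESTR_TETHER, "funnel_wall": K.RESTR_FUNNEL_WALL}

    def __post_init__(self):
        if self.kind not in ("tether", "funnel_wall", "reflecting_box", "surface_switch"):
            raise InvalidParameterError(f"unknown restraint kind {self.kind!r}")
        if self.spring_constant < 0 or self.flat_radius < 0:
            raise InvalidParameterError("spring_constant and flat_radius must be >= 0")

    def encode(self) -> np.ndarray:
        code = self._CODES.get(self.kind, 0)
        return np.array(
            [code, self.anchor[0], self.anchor[1], self.spring_constant, self.flat_radius]
        )

    def energy(self, points: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(points, dtype=float))
        row = self.encode()[None, :]
        return np.array(
            [K.restraint_energy(row, p[0], p[1] if len(p) > 1 else 0.0) for p in X]
        )

    def gradient(self, points: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(points, dtype=float))
        row = self.encode()[None, :]
        out = np.empty_like(X)
        for i, p in enumerate(X):
            gx, gy = K.restraint_gradient(row, p[0], p[1] if len(p) > 1 else 0.0)
            out[i, 0] = gx
            if X.shape[1] > 1:
                out[i, 1] = gy
        return out


def encode_restraints(restraints) -> np.ndarray:
    rows = [r.encode() for r in (restraints or []) if r.kind in RestraintTerm._CODES]
    return np.vstack(rows) if rows else _NO_RESTRAINTS


@dataclass
class PotentialSurface:
    """Analytic energy landscape with named regions and exact gradients."""

    n_dims: int
    kind: str  # "poly1d" | "bumps2d"
    params: np.ndarray
    domain: np.ndarray  # (n_dims, 2)
    regions: list[Region]
    label: str = ""
    meta: dict = field(default_factory=dict)

    _KIND_CODES = {"poly1d": K.SURF_POLY1D, "bumps2d": K.SURF_BUMPS2D}

    @property
    def kind_code(self) -> int:
        return self._KIND_CODES[self.kind]

    def _as_points(self, points) -> np.ndarray:
        X = np.asarray(points, dtype=float)
        if X.ndim == 1:
            X = X[:, None] if self.n_dims == 1 else X[None, :]
        if X.shape[1] != self.n_dims:
            raise DomainError(
                f"points have {X.shape[1]} coordinates, surface is {self.n_dims}-dimensional"
            )
        return X

    def energy(self, points) -> np.ndarray:
        X = self._as_points(points)
        return K.batch_energy(self.kind_code, self.params, _NO_RESTRAINTS, X)

    def gradient(self, points) -> np.ndarray:
        X = self._as_points(points)
        return K.batch_gradient(self.kind_code, self.params, _NO_RESTRAINTS, X)

    def in_domain(self, points) -> np.ndarray:
        X = self._as_points(points)
        ok = np.ones(X.shape[0], dtype=bool)
        for d in range(self.n_dims):
            ok &= (X[:, d] >= self.domain[d, 0]) & (X[:, d] <= self.domain[d, 1])
        return ok

    def region_of(self, cv) -> np.ndarray:
        """Index into ``self.regions`` per CV value (-1 if in no region)."""
        cv = np.atleast_1d(np.asarray(cv, dtype=float))
        out = np.full(cv.shape, -1, dtype=int)
        for i, r in enumerate(self.regions):
            out[r.contains(cv)] = i
        if self.regions:  # regions are right-open; the domain edge belongs to the last
            out[(out < 0) & (cv == self.regions[-1].cv_hi)] = len(self.regions) - 1
        return out

    def region_index(self, name: str) -> int:
        for i, r in enumerate(self.regions):
            if r.name == name:
                return i
        raise KeyError(f"surface {self.label!r} declares no region {name!r}")

    def region_minimum(self, name: str) -> np.ndarray:
        """Position of the energy minimum inside a region (lateral coordinate 0)."""
        r = self.regions[self.region_index(name)]
        s = np.linspace(max(r.cv_lo, self.domain[0, 0]), min(r.cv_hi, self.domain[0, 1]), 2001)
        pts = s[:, None] if self.n_dims == 1 else np.column_stack([s, np.zeros_like(s)])
        e = self.energy(pts)
        return pts[int(np.argmin(e))]

    # -- serialization: parameters only, so runs reproduce from config text --

    def to_dict(self) -> dict:
        return {
            "n_dims": self.n_dims,
            "kind": self.kind,
            "params": self.params.tolist(),
            "domain": self.domain.tolist(),
            "regions": [[r.name, r.cv_lo, r.cv_hi] for r in self.regions],
            "label": self.label,
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PotentialSurface":
        return cls(
            n_dims=int(d["n_dims"]),
            kind=d["kind"],
            params=np.asarray(d["params"], dtype=float),
            domain=np.asarray(d["domain"], dtype=float),
            regions=[Region(n, float(lo), float(hi)) for n, lo, hi in d["regions"]],
            label=d.get("label", ""),
            meta=d.get("meta", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PotentialSurface":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class FreeEnergyProfile:
    """F(s) on an ordered CV grid, offset so that min F = 0."""

    grid: np.ndarray
    values: np.ndarray
    kT: float = 1.0
    source: str = "analytic"  # analytic | metad | reweighted

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.values.shape:
            raise InvalidParameterError("grid and values must be equal-length vectors")
        if np.any(np.diff(self.grid) <= 0):
            raise InvalidParameterError("grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("free-energy values must be finite")
        self.values = self.values - self.values.min()

    def write(self, path) -> None:
        """Two-column plain-text export (cv, F)."""
        with open(path, "w") as fh:
            fh.write(f"# cv F_kT source={self.source} kT={self.kT!r}\n")
            for s, f in zip(self.grid, self.values):
                fh.write(f"{float(s)!r} {float(f)!r}\n")

    @classmethod
    def read(cls, path, kT: float = 1.0, source: str = "metad") -> "FreeEnergyProfile":
        data = np.loadtxt(path)
        return cls(grid=data[:, 0], values=data[:, 1], kT=kT, source=source)


# --------------------------------------------------------------------------
# landscape factories
# --------------------------------------------------------------------------


def make_double_well(
    barrier: float, asymmetry: float, well_separation: float, label: str = "double_well"
) -> PotentialSurface:
    """1D quartic double well calibrated to exact barrier and tilt.

    ``barrier`` is the saddle height above the *deeper* minimum and
    ``asymmetry`` the energy difference between the two minima, both in kT.
    Regions "left"/"right" split at the saddle.
    """
    if barrier <= 0 or well_separation <= 0:
        raise InvalidParameterError("barrier and well_separation must be positive")
    if asymmetry < 0 or asymmetry >= barrier:
        raise InvalidParameterError("need 0 <= asymmetry < barrier for two minima to exist")
    a = well_separation / 2.0

    def critical_points(h, c):
        roots = np.roots([4.0 * h / a**4, 0.0, -4.0 * h / a**2, -c])
        real = np.sort(roots[np.abs(roots.imag) < 1e-9].real)
        return real

    def energy(h, c, x):
        return h * ((x / a) ** 2 - 1.0) ** 2 - c * x

    def residual(theta):
        h, c = theta
        pts = critical_points(h, c)
        if len(pts) < 3:
            return [1e3, 1e3]
        x1, xs, x2 = pts[0], pts[1], pts[2]
        e1, es, e2 = energy(h, c, x1), energy(h, c, xs), energy(h, c, x2)
        deep, shallow = min(e1, e2), max(e1, e2)
        return [es - deep - barrier, shallow - deep - asymmetry]

    sol, info, ok, msg = optimize.fsolve(
        residual, x0=[barrier, asymmetry / (2.0 * a)], full_output=True, xtol=1e-14
    )
    h, c = sol
    if not ok or max(abs(r) for r in residual(sol)) > 1e-10:
        raise InvalidParameterError(
            f"double-well calibration failed for barrier={barrier}, asymmetry={asymmetry}: {msg}"
        )
    x1, xs, x2 = critical_points(h, c)
    coeffs = np.array([h, -c, -2.0 * h / a**2, 0.0, h / a**4])
    # reflecting walls at +-1.8 a: high enough (~5x the barrier) to confine,
    # far enough out that the basins and saddle sit clear of wall artifacts
    lo, hi = -1.8 * a, 1.8 * a
    regions = [Region("left", lo, float(xs)), Region("right", float(xs), hi)]
    meta = {
        "barrier": barrier,
        "asymmetry": asymmetry,
        "well_separation": well_separation,
        "minima": [float(x1), float(x2)],
        "saddle": float(xs),
    }
    return PotentialSurface(
        n_dims=1,
        kind="poly1d",
        params=coeffs,
        domain=np.array([[lo, hi]]),
        regions=regions,
        label=label,
        meta=meta,
    )


_EXIT_DEFAULTS = dict(
    lateral_stiffness=20.0,
    open_stiffness=0.1,
    funnel_center=5.5,
    funnel_width=0.8,
    pocket_center=1.2,
    pocket_width=1.5,
    intermediate_width=1.0,
    intermediate_span=(4.5, 6.5),
    domain=((0.0, 10.0), (-4.0, 4.0)),
)


def make_exit_landscape(
    bound_depth: float = 10.0,
    intermediate_depth: float = 4.0,
    n_intermediates: int = 2,
    lateral_stiffness: float = 20.0,
    domain=None,
    *,
    open_stiffness: float = 0.1,
    funnel_center: float = 5.5,
    funnel_width: float = 0.8,
    pocket_center: float = 1.2,
    pocket_width: float = 1.5,
    intermediate_width: float = 1.0,
    intermediate_span: tuple[float, float] = (4.5, 6.5),
    label: str = "Z",
    region_boundaries: list[float] | None = None,
) -> PotentialSurface:
    """2D exit-path landscape: pocket, vestibule intermediates, unbound plateau.

    The exit coordinate s runs from the pocket (small s) to the unbound
    region (large s).  Lateral confinement tightens from ``open_stiffness``
    far out to ``lateral_stiffness`` in the pocket — the funnel geometry that
    keeps unbinding reversible.  Region boundaries are placed at the saddles
    of the laterally integrated free energy along s and stored with the
    surface; ``region_boundaries`` overrides them (used to keep isomer pairs
    on identical state definitions).
    """
    if not (bound_depth > intermediate_depth > 0):
        raise InvalidParameterError("need bound_depth > intermediate_depth > 0")
    if n_intermediates < 1:
        raise InvalidParameterError("n_intermediates must be >= 1")
    if domain is None:
        domain = _EXIT_DEFAULTS["domain"]
    domain = np.asarray(domain, dtype=float)

    if n_intermediates == 1:
        centers = [0.5 * (intermediate_span[0] + intermediate_span[1])]
    else:
        centers = list(np.linspace(intermediate_span[0], intermediate_span[1], n_intermediates))
    basins = [(pocket_center, bound_depth, pocket_width)] + [
        (c, intermediate_depth, intermediate_width) for c in centers
    ]
    params = [float(len(basins))]
    for c, d, w in basins:
        params += [c, d, w]
    params += [open_stiffness, lateral_stiffness, funnel_center, funnel_width]
    params = np.asarray(params)

    # projected free energy along s (lateral integral is exactly Gaussian)
    def f_eff(s):
        u = np.zeros_like(s)
        for c, d, w in basins:
            uu = (s - c) / w
            mask = np.abs(uu) < 1.0
            u[mask] -= d * np.exp(1.0 - 1.0 / (1.0 - uu[mask] ** 2))
        z = (funnel_center - s) / funnel_width
        sig = 1.0 / (1.0 + np.exp(-np.clip(z, -40, 40)))
        klat = open_stiffness + (lateral_stiffness - open_stiffness) * sig
        return u + 0.5 * np.log(klat)

    if region_boundaries is None:
        s_fine = np.linspace(domain[0, 0], domain[0, 1], 8001)
        fe = f_eff(s_fine)
        cuts = []
        anchors = [c for c, _, _ in basins] + [min(centers[-1] + 2.0 * intermediate_width, domain[0, 1])]
        for left, right in zip(anchors[:-1], anchors[1:]):
            mask = (s_fine > left) & (s_fine < right)
            seg = np.where(mask)[0]
            cuts.append(float(s_fine[seg[np.argmax(fe[seg])]]))
        region_boundaries = cuts
    edges = [domain[0, 0]] + list(region_boundaries) + [domain[0, 1]]
    names = ["pocket"] + [f"intermediate_{k + 1}" for k in range(n_intermediates)] + ["outside"]
    regions = [Region(n, lo, hi) for n, lo, hi in zip(names, edges[:-1], edges[1:])]

    meta = {
        "bound_depth": bound_depth,
        "intermediate_depth": intermediate_depth,
        "n_intermediates": n_intermediates,
        "anchor": [pocket_center, 0.0],
        "region_boundaries": [float(b) for b in region_boundaries],
        "pocket_support": [pocket_center - pocket_width, pocket_center + pocket_width],
    }
    return PotentialSurface(
        n_dims=2,
        kind="bumps2d",
        params=params,
        domain=domain,
        regions=regions,
        label=label,
        meta=meta,
    )


def make_isomer_pair(
    shared: dict | None = None,
    bound_depth_E: float = 7.0,
    bound_depth_Z: float = 10.0,
) -> tuple[PotentialSurface, PotentialSurface]:
    """E/Z landscape pair differing only in bound-basin depth.

    Emulates in-pocket photoisomerization: the two isomer surfaces are
    pointwise identical outside the pocket basin's compact support and share
    identical region boundaries, so trajectories can hop between them
    mid-run (the in-silico analogue of inverting the azo-bond dihedral).
    """
    shared = dict(shared or {})
    shared.pop("bound_depth", None)
    label_E = shared.pop("label_E", "E")
    label_Z = shared.pop("label_Z", "Z")
    surf_Z = make_exit_landscape(bound_depth=bound_depth_Z, label=label_Z, **shared)
    surf_E = make_exit_landscape(
        bound_depth=bound_depth_E,
        label=label_E,
        region_boundaries=surf_Z.meta["region_boundaries"],
        **shared,
    )
    return surf_E, surf_Z


# --------------------------------------------------------------------------
# analytic oracles
# --------------------------------------------------------------------------


def analytic_free_energy(
    surface: PotentialSurface, cv_grid: np.ndarray, kT: float = 1.0, n_y: int = 1201
) -> FreeEnergyProfile:
    """Ground-truth F(s) = -kT log ∫ exp(-E(s,y)/kT) dy by quadrature.

    In one dimension the lateral integral is absent and F equals the
    potential shifted to min 0.
    """
    cv_grid = np.asarray(cv_grid, dtype=float)
    if cv_grid.min() < surface.domain[0, 0] - 1e-12 or cv_grid.max() > surface.domain[0, 1] + 1e-12:
        raise DomainError("cv_grid extends beyond the surface domain")
    if surface.n_dims == 1:
        F = surface.energy(cv_grid[:, None])
        return FreeEnergyProfile(cv_grid, F, kT=kT, source="analytic")
    y = np.linspace(surface.domain[1, 0], surface.domain[1, 1], n_y)
    S, Y = np.meshgrid(cv_grid, y, indexing="ij")
    pts = np.column_stack([S.ravel(), Y.ravel()])
    E = K.batch_energy(surface.kind_code, surface.params, _NO_RESTRAINTS, pts).reshape(S.shape)
    E0 = E.min()
    Z = np.trapezoid(np.exp(-(E - E0) / kT), y, axis=1)
    F = -kT * np.log(Z) + E0
    return FreeEnergyProfile(cv_grid, F, kT=kT, source="analytic")


def region_probabilities(
    profile: FreeEnergyProfile, regions: list[Region]
) -> dict[str, float]:
    """Boltzmann weight of each region from a free-energy profile.

    Integrates exp(-F/kT) over each region's CV interval; the result is
    normalized over the full grid.
    """
    w = np.exp(-profile.values / profile.kT)
    # trapezoid segments assigned to the region of their midpoint: the
    # per-region integrals then partition the total exactly
    seg = 0.5 * (w[:-1] + w[1:]) * np.diff(profile.grid)
    mid = 0.5 * (profile.grid[:-1] + profile.grid[1:])
    total = seg.sum()
    out = {}
    for r in regions:
        out[r.name] = float(seg[r.contains(mid)].sum() / total)
    return out


def boltzmann_region_weights_2d(
    surface: PotentialSurface, kT: float = 1.0, n_s: int = 2001, n_y: int = 801
) -> dict[str, float]:
    """Independent 2D quadrature of region weights, bypassing the projection."""
    s = np.linspace(surface.domain[0, 0], surface.domain[0, 1], n_s)
    y = np.linspace(surface.domain[1, 0], surface.domain[1, 1], n_y)
    S, Y = np.meshgrid(s, y, indexing="ij")
    pts = np.column_stack([S.ravel(), Y.ravel()])
    E = K.batch_energy(surface.kind_code, surface.params, _NO_RESTRAINTS, pts).reshape(S.shape)
    E0 = E.min()
    dens = np.trapezoid(np.exp(-(E - E0) / kT), y, axis=1)
    total = np.trapezoid(dens, s)
    out = {}
    for r in surface.regions:
        mask = r.contains(s)
        out[r.name] = float(np.trapezoid(dens[mask], s[mask]) / total)
    return out


def check_gradient(surface: PotentialSurface, points, rel_tol: float = 1e-5) -> None:
    """Raise if the analytic gradient disagrees with central differences."""
    X = np.atleast_2d(np.asarray(points, dtype=float))
    h = 1e-6
    g = surface.gradient(X)
    for d in range(surface.n_dims):
        Xp = X.copy()
        Xm = X.copy()
        Xp[:, d] += h
        Xm[:, d] -= h
        fd = (surface.energy(Xp) - surface.energy(Xm)) / (2 * h)
        scale = np.maximum(np.abs(fd), 1.0)
        err = np.abs(fd - g[:, d]) / scale
        if np.any(err > rel_tol):
            i = int(np.argmax(err))
            raise AssertionError(
                f"gradient mismatch at {X[i]} (dim {d}): analytic {g[i, d]}, fd {fd[i]}"
            )
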
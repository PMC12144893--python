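import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pocketswitch as ps
from pocketswitch.toy_systems import (
    DomainError,
    InvalidParameterError,
    boltzmann_region_weights_2d,
    check_gradient,
)


class TestDoubleWell:
    def test_symmetric_well_has_degenerate_minima(self):
        surf = ps.make_double_well(5.0, 0.0, 2.0)
        e = surf.energy(np.array(surf.meta["minima"]))
        assert abs(e[0] - e[1]) < 1e-9

    @pytest.mark.parametrize("barrier,asym", [(5.0, 2.0), (3.0, 0.5), (7.0, 4.0)])
    def test_barrier_and_tilt_are_exact(self, barrier, asym):
        surf = ps.make_double_well(barrier, asym, 2.0)
        e_min = surf.energy(np.array(surf.meta["minima"]))
        e_saddle = surf.energy([surf.meta["saddle"]])[0]
        assert e_saddle - e_min.min() == pytest.approx(barrier, abs=1e-9)
        assert abs(e_min[0] - e_min[1]) == pytest.approx(asym, abs=1e-9)

    def test_basin_free_energy_difference_matches_quadrature(self):
        # the basin Delta F from the pipeline's projected profile must agree
        # with independent fine-grained quadrature of exp(-E) over each basin
        surf = ps.make_double_well(5.0, 2.0, 2.0)
        grid = np.arange(surf.domain[0, 0], surf.domain[0, 1] + 1e-12, 1e-3)
        prof = ps.analytic_free_energy(surf, grid)
        probs = ps.region_probabilities(prof, surf.regions)
        dF = -np.log(probs["left"] / probs["right"])
        # oracle: direct quadrature, same spacing, no profile machinery
        E = surf.energy(grid[:, None])
        w = np.exp(-(E - E.min()))
        split = surf.meta["saddle"]
        dF_oracle = -np.log(np.trapezoid(w[grid < split], grid[grid < split])
                            / np.trapezoid(w[grid >= split], grid[grid >= split]))
        # boundary-segment treatment differs between the two quadratures at
        # O(dx * w(saddle)); 1e-4 kT comfortably bounds it at dx = 1e-3
        assert dF == pytest.approx(dF_oracle, abs=1e-4)
        # the tilt dominates: quadrature dF is near the 2 kT minima offset
        assert dF == pytest.approx(2.0, abs=0.3)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            ps.make_double_well(-1.0, 0.0, 2.0)
        with pytest.raises(InvalidParameterError):
            ps.make_double_well(5.0, 2.0, 0.0)
        with pytest.raises(InvalidParameterError):
            ps.make_double_well(5.0, 6.0, 2.0)  # tilt would erase a basin


class TestExitLandscape:
    def test_global_minimum_in_pocket(self, exit_surface):
        g = np.linspace(0, 10, 2001)
        prof = ps.analytic_free_energy(exit_surface, g)
        s_min = g[np.argmin(prof.values)]
        assert exit_surface.regions[exit_surface.region_of(s_min)[0]].name == "pocket"

    def test_region_structure(self, exit_surface):
        names = [r.name for r in exit_surface.regions]
        assert names == ["pocket", "intermediate_1", "intermediate_2", "outside"]
        # contiguous cover of the CV domain
        for a, b in zip(exit_surface.regions[:-1], exit_surface.regions[1:]):
            assert a.cv_hi == b.cv_lo
        # mutually exclusive and non-empty on the default grid
        g = np.linspace(0, 10, 1001)
        idx = exit_surface.region_of(g)
        assert (idx >= 0).all()
        assert set(idx) == {0, 1, 2, 3}

    def test_projected_free_energy_matches_2d_quadrature(self, exit_surface):
        g = np.linspace(0, 10, 2001)
        prof = ps.analytic_free_energy(exit_surface, g)
        w1 = ps.region_probabilities(prof, exit_surface.regions)
        w2 = boltzmann_region_weights_2d(exit_surface)
        for name in w2:
            dF1 = -np.log(w1[name] / w1["pocket"])
            dF2 = -np.log(w2[name] / w2["pocket"])
            assert dF1 == pytest.approx(dF2, abs=1e-2)

    def test_depth_ordering_required(self):
        with pytest.raises(InvalidParameterError):
            ps.make_exit_landscape(bound_depth=3.0, intermediate_depth=4.0)

    def test_deeper_pocket_is_more_probable(self):
        # Boltzmann weight of the pocket strictly increases along a depth ladder
        weights = []
        for depth in (8.0, 10.0, 12.0):
            surf = ps.make_exit_landscape(bound_depth=depth)
            g = np.linspace(0, 10, 2001)
            prof = ps.analytic_free_energy(surf, g)
            weights.append(ps.region_probabilities(prof, surf.regions)["pocket"])
        assert weights[0] < weights[1] < weights[2]

    def test_region_probabilities_normalized(self, exit_surface):
        g = np.linspace(0, 10, 2001)
        prof = ps.analytic_free_energy(exit_surface, g)
        probs = ps.region_probabilities(prof, exit_surface.regions)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)


class TestIsomerPair:
    def test_equal_depths_give_identical_surfaces(self):
        E, Z = ps.make_isomer_pair(bound_depth_E=10.0, bound_depth_Z=10.0)
        pts = np.column_stack([np.linspace(0, 10, 500), np.linspace(-3, 3, 500)])
        assert np.max(np.abs(E.energy(pts) - Z.energy(pts))) == 0.0

    def test_surfaces_identical_outside_pocket(self):
        E, Z = ps.make_isomer_pair(bound_depth_E=7.0, bound_depth_Z=10.0)
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(0, 10, 2000), rng.uniform(-4, 4, 2000)])
        diff = np.abs(E.energy(pts) - Z.energy(pts))
        support_hi = Z.meta["pocket_support"][1]
        assert np.max(diff[pts[:, 0] > support_hi]) < 1e-9
        assert np.max(diff[pts[:, 0] < support_hi]) > 1.0  # pocket differs
        assert E.label == "E" and Z.label == "Z"
        # matched region boundaries so state definitions transfer
        assert [r.cv_lo for r in E.regions] == [r.cv_lo for r in Z.regions]

    def test_shallower_isomer_leaves_pocket_sooner(self):
        # brute-force kinetics oracle: first exit from the pocket is faster
        # on the E surface (7 kT) than the Z surface (10 kT)
        E, Z = ps.make_isomer_pair(bound_depth_E=6.0, bound_depth_Z=9.0)
        res_E = ps.brute_force_mfpt(E, [], "pocket", "intermediate_1",
                                    n_replicas=200, max_steps=10_000_000, seed=3)
        res_Z = ps.brute_force_mfpt(Z, [], "pocket", "intermediate_1",
                                    n_replicas=200, max_steps=10_000_000, seed=3)
        assert res_E["n_censored"] == 0 and res_Z["n_censored"] == 0
        assert res_E["mean"] < res_Z["mean"]


class TestAnalyticFreeEnergy:
    def test_1d_profile_equals_shifted_potential(self, dw_surface):
        g = np.linspace(-1.5, 1.5, 301)
        prof = ps.analytic_free_energy(dw_surface, g)
        expected = dw_surface.energy(g[:, None])
        assert np.max(np.abs(prof.values - (expected - expected.min()))) < 1e-12

    def test_constant_surface_gives_zero_profile(self):
        flat = ps.PotentialSurface(
            n_dims=1, kind="poly1d", params=np.array([3.0]),
            domain=np.array([[-1.0, 1.0]]), regions=[ps.Region("all", -1, 1)],
        )
        prof = ps.analytic_free_energy(flat, np.linspace(-1, 1, 101))
        assert np.max(np.abs(prof.values)) == 0.0

    def test_separable_surface_projection(self):
        # E(s,y) = U(s) + W(y): the lateral integral adds only a constant,
        # checked against direct quadrature of the full 2D integrand
        surf = ps.make_exit_landscape(
            lateral_stiffness=2.0, open_stiffness=2.0  # constant k_lat -> separable
        )
        g = np.linspace(0.5, 9.5, 401)
        prof = ps.analytic_free_energy(surf, g)
        U = surf.energy(np.column_stack([g, np.zeros_like(g)]))
        gap = (prof.values - (U - U.min()))
        assert np.max(np.abs(gap - gap[0])) < 1e-9

    def test_grid_outside_domain_rejected(self, exit_surface):
        with pytest.raises(DomainError):
            ps.analytic_free_energy(exit_surface, np.linspace(-1, 5, 50))


class TestRestraints:
    def test_tether_flat_then_increasing(self):
        t = ps.RestraintTerm(kind="tether", anchor=(1.0, 0.0),
                             spring_constant=2.0, flat_radius=0.5)
        d = np.linspace(0, 3, 301)
        e = t.energy(np.column_stack([1.0 + d, np.zeros_like(d)])).ravel()
        assert np.all(e[d <= 0.5] == 0.0)
        beyond = e[d > 0.5 + 1e-9]
        assert np.all(np.diff(beyond) > 0)

    @given(st.floats(0.1, 5.0), st.floats(0.0, 2.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_tether_continuous_at_flat_radius(self, k, r0):
        t = ps.RestraintTerm(kind="tether", anchor=(0.0, 0.0),
                             spring_constant=k, flat_radius=r0)
        eps = 1e-7
        pts = np.array([[r0 - eps, 0.0], [r0 + eps, 0.0]])
        e = t.energy(pts)
        g = t.gradient(pts)
        assert abs(e[1] - e[0]) < 1e-6
        assert abs(g[1, 0] - g[0, 0]) < 1e-5

    def test_funnel_wall_acts_laterally(self):
        wall = ps.RestraintTerm(kind="funnel_wall", spring_constant=5.0, flat_radius=1.0)
        e = wall.energy(np.array([[0.0, 0.5], [0.0, 2.0], [7.0, 2.0]])).ravel()
        assert e[0] == 0.0
        assert e[1] == pytest.approx(0.5 * 5.0 * 1.0**2)
        assert e[1] == e[2]  # independent of the exit coordinate

    def test_unknown_kind_rejected(self):
        with pytest.raises(InvalidParameterError):
            ps.RestraintTerm(kind="rubber_band")


class TestGradients:
    @pytest.mark.parametrize("maker", [
        lambda: ps.make_double_well(5.0, 2.0, 2.0),
        lambda: ps.make_exit_landscape(),
        lambda: ps.make_exit_landscape(bound_depth=12.0, n_intermediates=3),
    ])
    def test_gradient_matches_finite_differences(self, maker):
        surf = maker()
        rng = np.random.default_rng(42)
        pts = np.column_stack([
            rng.uniform(surf.domain[d, 0] + 0.05, surf.domain[d, 1] - 0.05, 300)
            for d in range(surf.n_dims)
        ])
        check_gradient(surf, pts, rel_tol=1e-5)

    def test_energy_finite_on_domain(self, exit_surface):
        g = np.linspace(0, 10, 101)
        y = np.linspace(-4, 4, 41)
        S, Y = np.meshgrid(g, y)
        e = exit_surface.energy(np.column_stack([S.ravel(), Y.ravel()]))
        assert np.all(np.isfinite(e))


class TestSerialization:
    def test_surface_roundtrip(self, tmp_path, exit_surface):
        path = tmp_path / "surf.json"
        exit_surface.save(path)
        back = ps.PotentialSurface.load(path)
        pts = np.column_stack([np.linspace(0, 10, 100), np.linspace(-3, 3, 100)])
        assert np.array_equal(back.energy(pts), exit_surface.energy(pts))
        assert [r.name for r in back.regions] == [r.name for r in exit_surface.regions]
        json.loads(path.read_text())  # plain-text JSON descriptor

    def test_profile_roundtrip(self, tmp_path, dw_surface):
        prof = ps.analytic_free_energy(dw_surface, np.linspace(-1.5, 1.5, 101))
        path = tmp_path / "fes.dat"
        prof.write(path)
        back = ps.FreeEnergyProfile.read(path)
        assert np.array_equal(back.grid, prof.grid)
        assert np.array_equal(back.values, prof.values)
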
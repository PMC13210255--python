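"""Axisymmetric finite-volume solver: geometry, diffusion, reduction to the
batch reactor, and the qualitative release pattern."""

import dataclasses

import numpy as np
import pytest

from neurorelease.batch import _rk4, integrate_batch
from neurorelease.fixtures import make_initial_fields
from neurorelease.params import ConfigError, NETWORK_SPECIES
from neurorelease.spatial import (DEPOT, DomainMap, SpatialScenario,
                                  assign_domains, axisym_laplacian,
                                  build_grid, run_spatial, spatial_rhs,
                                  total_bulk_concentration,
                                  _laplacian_operator)


class TestGrid:
    def test_volumes_sum_to_cylinder(self):
        g = build_grid(4, 4)
        assert g.cell_volumes().size == 16
        assert g.total_volume() == pytest.approx(
            np.pi * g.R ** 2 * g.L, rel=1e-12)

    def test_default_geometry_volume(self):
        g = build_grid(8, 8)
        # pi * (3 mm)^2 * 12 mm
        assert g.total_volume() == pytest.approx(np.pi * 9e-6 * 12e-3, rel=1e-12)

    def test_refinement_splits_volumes_conservatively(self):
        g1, g2 = build_grid(4, 4), build_grid(8, 8)
        v1, v2 = g1.cell_volumes(), g2.cell_volumes()
        for i in range(4):
            for j in range(4):
                children = v2[2 * i:2 * i + 2, 2 * j:2 * j + 2].sum()
                assert children == pytest.approx(v1[i, j], rel=1e-12)

    def test_rejects_degenerate_meshes(self):
        with pytest.raises(ConfigError):
            build_grid(2, 8)
        with pytest.raises(ConfigError):
            build_grid(8, 8, R=0.0)


class TestAssignDomains:
    def test_depot_only_preset(self):
        g = build_grid(4, 8)
        dm = assign_domains("depot-only", g)
        assert np.all(dm.labels == DEPOT)

    def test_default_preset_partitions_grid(self):
        g = build_grid(8, 24)
        dm = assign_domains("default", g)
        assert set(np.unique(dm.labels)) == {1, 2, 3}
        assert dm.depot_mask.any() and dm.cellular_mask.any()

    def test_explicit_extents_classified_by_cell_center(self):
        g = build_grid(4, 4)
        dm = assign_domains({"depot": (0.0, 0.5, 0.0, 0.5)}, g)
        # brute-force center-in-box check
        for i in range(4):
            for j in range(4):
                inside = (g.r[i] / g.R <= 0.5) and (g.z[j] / g.L <= 0.5)
                assert (dm.labels[i, j] == DEPOT) == inside

    def test_empty_depot_rejected(self):
        g = build_grid(4, 4)
        with pytest.raises(ConfigError):
            assign_domains({"depot": (0.9, 0.95, 0.9, 0.95)}, g)
        with pytest.raises(ConfigError):
            DomainMap(labels=np.full((4, 4), 3))


class TestAxisymLaplacian:
    def test_uniform_field_has_zero_divergence(self):
        g = build_grid(8, 16)
        lap = axisym_laplacian(np.full((8, 16), 3.7), 1e-9, g)
        assert np.allclose(lap, 0.0, atol=1e-20)

    def test_discrete_conservation_closed_box(self):
        rng = np.random.default_rng(7)
        g = build_grid(12, 20)
        field = rng.random((12, 20))
        lap = axisym_laplacian(field, 1e-9, g)
        total = float((lap * g.cell_volumes()).sum())
        scale = float((np.abs(lap) * g.cell_volumes()).sum())
        assert abs(total) <= 1e-12 * max(scale, 1e-30)

    def test_radial_gaussian_matches_free_space_solution(self):
        # z-uniform radial Gaussian: axisymmetric radial diffusion equals
        # planar 2D diffusion, for which sigma^2 grows by 2Dt and the peak
        # scales by sigma0^2/sigma_t^2 -- exact closed form while the pulse
        # is far from the outer boundary.
        D, sigma0, t_end = 1e-9, 2e-4, 10.0
        g = build_grid(96, 4)
        c0 = np.exp(-g.r[:, None] ** 2 / (2 * sigma0 ** 2)) * np.ones((1, 4))
        op = _laplacian_operator(g, D)

        def rhs(t, y):
            return op(y.reshape(96, 4)).ravel()

        t_eval = np.linspace(0.0, t_end, 41)
        ys = _rk4(rhs, c0.ravel(), t_eval, dt=0.05)
        c_end = ys[-1].reshape(96, 4)[:, 0]
        s2 = sigma0 ** 2 + 2 * D * t_end
        exact = sigma0 ** 2 / s2 * np.exp(-g.r ** 2 / (2 * s2))
        err = np.max(np.abs(c_end - exact)) / exact.max()
        assert err < 0.02

    def test_second_order_spatial_convergence(self):
        # observed order of accuracy >= 1.8 on the Gaussian problem
        D, sigma0, t_end = 1e-9, 3e-4, 5.0
        errors = []
        for nr in (24, 48, 96):
            g = build_grid(nr, 4)
            c0 = np.exp(-g.r[:, None] ** 2 / (2 * sigma0 ** 2)) * np.ones((1, 4))
            op = _laplacian_operator(g, D)

            def rhs(t, y):
                return op(y.reshape(nr, 4)).ravel()

            ys = _rk4(rhs, c0.ravel(), np.array([0.0, t_end]), dt=0.02)
            c_end = ys[-1].reshape(nr, 4)[:, 0]
            s2 = sigma0 ** 2 + 2 * D * t_end
            exact = sigma0 ** 2 / s2 * np.exp(-g.r ** 2 / (2 * s2))
            errors.append(np.max(np.abs(c_end - exact)))
        order1 = np.log2(errors[0] / errors[1])
        order2 = np.log2(errors[1] / errors[2])
        assert min(order1, order2) >= 1.8


class TestSpatialRhs:
    def test_reduces_to_batch_rate_vector_without_diffusion(self, fixture):
        from neurorelease.batch import rate_vector

        g = build_grid(4, 4)
        dm = assign_domains("depot-only", g)
        state0 = fixture.batch_state0()
        fields = {n: np.full((4, 4), state0.conc[n]) for n in NETWORK_SPECIES}
        bundle = fixture.bundle
        rt = rate_vector(state0, bundle.kinetics)
        # diffusion contributes nothing on a uniform field, so the full RHS
        # equals the batch rates cellwise
        dy = spatial_rhs(fields, bundle, g, dm)
        for name in NETWORK_SPECIES:
            assert np.allclose(dy[name], rt.rates[name], rtol=1e-12, atol=1e-25)

    def test_equilibrium_fields_stationary_without_degradation(self, fixture):
        g = build_grid(4, 8)
        dm = assign_domains("depot-only", g)
        bundle = dataclasses.replace(
            fixture.bundle,
            kinetics=dataclasses.replace(fixture.kinetics, Vmax=0.0))
        fields = make_initial_fields(g, dm, fixture.loading, bundle)
        dy = spatial_rhs(fields, bundle, g, dm)
        scale = max(f.max() for f in fields.values())
        for name in NETWORK_SPECIES:
            assert np.max(np.abs(dy[name])) <= 1e-10 * scale

    def test_no_degradation_outside_depot(self, fixture):
        # uniform pSC everywhere, matrix only in depot: GABA production is
        # restricted to depot cells
        g = build_grid(8, 16)
        dm = assign_domains("default", g)
        fields = make_initial_fields(g, dm, fixture.loading, fixture.bundle)
        dy = spatial_rhs(fields, fixture.bundle, g, dm)
        assert np.all(dy["GABA"][~dm.depot_mask] == 0.0)
        assert dy["GABA"][dm.depot_mask].max() > 0.0


class TestRunSpatial:
    def test_mass_conserved_without_reactions(self, fixture):
        bundle = dataclasses.replace(
            fixture.bundle,
            kinetics=dataclasses.replace(fixture.kinetics, Vmax=0.0,
                                         kf1=1e-30, kr1=1e-30))
        g = build_grid(8, 16)
        dm = assign_domains("default", g)
        fields = make_initial_fields(g, dm, fixture.loading, bundle)
        rec = run_spatial(SpatialScenario(bundle=bundle, grid=g, domain_map=dm,
                                          initial_fields=fields, t_end=20.0))
        for name in ("SC", "p", "pSC", "enzyme"):
            tot = rec.total_amount(name)
            if tot[0] > 0:
                assert np.max(np.abs(tot - tot[0])) / tot[0] < 1e-10

    def test_diffusion_off_matches_batch_oracle_cellwise(self, fixture):
        g = build_grid(4, 4)
        dm = assign_domains("depot-only", g)
        fields = make_initial_fields(g, dm, fixture.loading, fixture.bundle)
        # depot-only layout has no cellular zone; place the enzyme uniformly
        # so the initial condition matches the batch reactor exactly
        fields["enzyme"] = np.full((4, 4), fixture.kinetics.enzyme0)
        rec = run_spatial(SpatialScenario(
            bundle=fixture.bundle, grid=g, domain_map=dm,
            initial_fields=fields, t_end=30.0, diffusion=False,
            output_times=np.linspace(0, 30.0, 16), rtol=1e-10, atol=1e-16))
        traj = integrate_batch(fixture.batch_state0(), fixture.kinetics,
                               30.0, dt_out=2.0)
        for name in NETWORK_SPECIES:
            batch_series = traj.species(name)
            cell_series = rec.fields[name][:, 2, 2]
            assert np.allclose(cell_series, batch_series, rtol=1e-6,
                               atol=1e-12 * max(1.0, batch_series.max()))

    def test_mirror_symmetric_layout_preserves_symmetry(self, fixture):
        # depot symmetric about mid-plane; no cellular zone
        g = build_grid(8, 24)
        dm = assign_domains({"depot": (0.0, 0.5, 1 / 3, 2 / 3)}, g)
        fields = make_initial_fields(g, dm, fixture.loading, fixture.bundle)
        rec = run_spatial(SpatialScenario(bundle=fixture.bundle, grid=g,
                                          domain_map=dm, initial_fields=fields,
                                          t_end=20.0))
        for name in ("SC", "GABA", "pSC"):
            final = rec.fields[name][-1]
            assert np.allclose(final, final[:, ::-1], rtol=1e-6,
                               atol=1e-12 * max(final.max(), 1e-30))

    def test_gaba_appears_first_at_depot(self, fixture):
        rec = run_spatial(fixture.spatial_scenario())
        k_early = np.searchsorted(rec.times, 1.0)
        gab = rec.fields["GABA"][k_early]
        ij = np.unravel_index(np.argmax(gab), gab.shape)
        assert rec.domain_map.labels[ij] == DEPOT

    def test_released_bulk_scaffold_monotone(self, fixture):
        rec = run_spatial(fixture.spatial_scenario())
        series = total_bulk_concentration(rec, "SC")
        assert np.all(np.diff(series) >= -1e-12 * series.max())

    def test_bulk_average_of_uniform_field_is_identity(self, fixture):
        g = build_grid(4, 4)
        dm = assign_domains("depot-only", g)
        fields = {n: np.zeros((4, 4)) for n in NETWORK_SPECIES}
        fields["GABA"] = np.full((4, 4), 0.125)
        bundle = dataclasses.replace(
            fixture.bundle,
            kinetics=dataclasses.replace(fixture.kinetics, Vmax=0.0))
        rec = run_spatial(SpatialScenario(bundle=bundle, grid=g, domain_map=dm,
                                          initial_fields=fields, t_end=5.0))
        assert total_bulk_concentration(rec, "GABA") == pytest.approx(
            np.full(len(rec.times), 0.125), rel=1e-9)
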
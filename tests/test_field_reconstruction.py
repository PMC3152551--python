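"""Initial interpolation, iterative assimilation, land correction, ensembles."""

import numpy as np
import pytest

from larvadrift.field_reconstruction import (
    AssimilationConfig,
    assimilate,
    assimilation_weights,
    build_ensemble,
    field_rms_error,
    initial_field,
    land_correct,
    prediction_error,
    simulate_cycle,
)
from larvadrift.grids import Grid, LandMask, VelocityField
from larvadrift.probe_data import (
    GeoPoint,
    ProbeCycle,
    RawVelocityObs,
    RegionBounds,
    raw_velocities,
)
from larvadrift.synthetic_fixtures import (
    AnalyticFieldSpec,
    make_analytic_field,
    make_synthetic_cycles,
)


def _obs_at(points, values):
    return [
        RawVelocityObs(v=np.asarray(v, dtype=float), X=GeoPoint(*p), cycle_id=str(k))
        for k, (p, v) in enumerate(zip(points, values))
    ]


class TestInitialField:
    def test_constant_observations_reproduced(self, small_grid, rng):
        pts = [
            (160.2 + 2.4 * rng.random(), -11.8 + 2.4 * rng.random())
            for _ in range(25)
        ]
        f = initial_field(_obs_at(pts, [(0.05, 0.0)] * 25), small_grid)
        assert np.allclose(f.u1, 0.05) and np.allclose(f.u2, 0.0)
        assert np.all(np.isfinite(f.u1)) and np.all(np.isfinite(f.u2))

    def test_linear_field_reproduced_inside_hull(self, small_grid, rng):
        a, b, c, d = 0.01, 0.004, -0.02, 0.006
        pts = [
            (160.0 + 3.0 * rng.random(), -12.0 + 3.0 * rng.random())
            for _ in range(60)
        ]
        vals = [(a + b * p[0], c + d * p[1]) for p in pts]
        f = initial_field(_obs_at(pts, vals), small_grid)
        LON, LAT = small_grid.meshgrid()
        # interior nodes well inside the hull
        sel = (
            (LON > 160.6) & (LON < 162.4) & (LAT > -11.4) & (LAT < -9.6)
        )
        assert np.allclose(f.u1[sel], a + b * LON[sel], atol=1e-6)
        assert np.allclose(f.u2[sel], c + d * LAT[sel], atol=1e-6)

    def test_too_few_or_collinear_observations_fatal(self, small_grid):
        with pytest.raises(ValueError):
            initial_field(_obs_at([(161, -10)], [(0, 0)]), small_grid)
        collinear = _obs_at(
            [(160.5, -10.0), (161.0, -10.0), (161.5, -10.0)], [(0, 0)] * 3
        )
        with pytest.raises(ValueError):
            initial_field(collinear, small_grid)


class TestSimulateCycle:
    def test_uniform_field_closed_form(self, small_grid):
        f = VelocityField(
            small_grid,
            np.full(small_grid.shape, 0.1),
            np.zeros(small_grid.shape),
        )
        c = ProbeCycle("c", GeoPoint(160.5, -10.0), GeoPoint(161.5, -10.0), 10.0, 1000)
        pred = simulate_cycle(f, c)
        assert pred.y_pred.lon == pytest.approx(161.5, abs=1e-6)
        assert pred.y_pred.lat == pytest.approx(-10.0, abs=1e-8)
        assert pred.v_model == pytest.approx([0.1, 0.0], abs=1e-7)
        assert pred.X_model.lon == pytest.approx(161.0, abs=1e-6)

    def test_zero_field_fixed_point(self, small_grid):
        f = VelocityField(small_grid, np.zeros(small_grid.shape), np.zeros(small_grid.shape))
        c = ProbeCycle("c", GeoPoint(161.0, -10.5), GeoPoint(161.2, -10.5), 8.0, 1000)
        pred = simulate_cycle(f, c)
        assert pred.y_pred == pytest.approx((161.0, -10.5))
        assert pred.v_model == pytest.approx([0.0, 0.0])

    def test_rotation_conserves_radius(self, small_grid, rotation_spec):
        f, _ = make_analytic_field(rotation_spec, small_grid)
        c = ProbeCycle("c", GeoPoint(162.0, -10.5), GeoPoint(162.0, -10.5), 40.0, 1000)
        pred = simulate_cycle(f, c)
        r0 = np.hypot(162.0 - 161.5, -10.5 + 10.5)
        r1 = np.hypot(pred.y_pred.lon - 161.5, pred.y_pred.lat + 10.5)
        assert r1 == pytest.approx(r0, rel=1e-4)

    def test_exit_is_flagged_and_clamped(self, small_grid):
        f = VelocityField(
            small_grid, np.full(small_grid.shape, 0.5), np.zeros(small_grid.shape)
        )
        c = ProbeCycle("c", GeoPoint(162.8, -10.0), GeoPoint(162.9, -10.0), 10.0, 1000)
        pred = simulate_cycle(f, c)
        assert pred.exited
        assert pred.y_pred.lon == pytest.approx(163.0, abs=1e-6)


class TestWeights:
    def test_peak_at_anchor_node(self, small_grid):
        anchor = GeoPoint(161.0, -10.0)  # exactly on a node
        g1, _, _ = assimilation_weights(small_grid, anchor, anchor, anchor)
        i = np.unravel_index(np.argmax(g1), g1.shape)
        LON, LAT = small_grid.meshgrid()
        assert (LON[i], LAT[i]) == pytest.approx((161.0, -10.0))
        assert np.sum(g1 == g1.max()) == 1

    def test_coincident_anchors_give_equal_weights(self, small_grid):
        p = GeoPoint(161.3, -10.7)
        g1, g2, g3 = assimilation_weights(small_grid, p, p, p)
        assert np.array_equal(g1, g2) and np.array_equal(g2, g3)

    def test_shift_equivariance_by_one_node(self, small_grid):
        # anchors off the node lattice so no node sits exactly on the
        # truncation radius, where float noise could flip support membership
        h = small_grid.spacing_deg
        p = [
            GeoPoint(161.013, -10.541),
            GeoPoint(161.217, -10.438),
            GeoPoint(161.421, -10.327),
        ]
        q = [GeoPoint(x.lon + h, x.lat) for x in p]
        w_p = assimilation_weights(small_grid, *p)
        w_q = assimilation_weights(small_grid, *q)
        for a, b in zip(w_p, w_q):
            # interior columns shift by one node index along lon
            assert np.allclose(a[:, 5:-6], b[:, 6:-5], atol=1e-9)

    def test_compact_support(self, small_grid):
        p = GeoPoint(161.5, -10.5)
        g1, _, _ = assimilation_weights(small_grid, p, p, p)
        LON, LAT = small_grid.meshgrid()
        far = np.hypot(LON - p.lon, LAT - p.lat) > 3 * small_grid.spacing_deg
        assert np.all(g1[far] == 0.0)
        assert np.all(g1 >= 0.0)


class TestAssimilate:
    def test_self_consistent_observations_fixed_point(self, small_grid, rng,
                                                      rotation_spec, small_region):
        f0, _ = make_analytic_field(rotation_spec, small_grid)
        cycles, _ = make_synthetic_cycles(
            rotation_spec, 60, small_region, rng, margin_deg=0.4
        )
        # observations generated by (a field equal to) field0: no change
        obs = raw_velocities(cycles)
        fa = assimilate(f0, obs, cycles)
        assert np.allclose(fa.u1, f0.u1, atol=2e-4)
        assert np.allclose(fa.u2, f0.u2, atol=2e-4)

    def test_recovery_from_zero_field(self, small_grid, rng, small_region):
        """Dense noise-free coverage recovers a uniform field within 10%.

        Assessed at well-covered interior nodes: near an update anchor and
        away from the boundary strip, where cycle coverage thins out and the
        kernel-spread corrections over/undershoot.
        """
        spec = AnalyticFieldSpec("uniform", {"u1": 0.05, "u2": 0.02})
        cycles, _ = make_synthetic_cycles(spec, 500, small_region, rng, margin_deg=0.3)
        obs = raw_velocities(cycles)
        zero = VelocityField(
            small_grid, np.zeros(small_grid.shape), np.zeros(small_grid.shape)
        )
        fa = assimilate(zero, obs, cycles)
        LON, LAT = small_grid.meshgrid()
        anchors = []
        for c, o in zip(cycles, obs):
            anchors.append((c.x_dive.lon, c.x_dive.lat))
            anchors.append((o.X.lon, o.X.lat))
            anchors.append((c.y_surface.lon, c.y_surface.lat))
        a = np.array(anchors)
        dist = np.min(
            np.hypot(LON[..., None] - a[:, 0], LAT[..., None] - a[:, 1]), axis=-1
        )
        b = small_region
        interior = (
            (LON >= b.lon_min + 0.6)
            & (LON <= b.lon_max - 0.6)
            & (LAT >= b.lat_min + 0.6)
            & (LAT <= b.lat_max - 0.6)
        )
        near = interior & (dist <= small_grid.spacing_deg)
        assert near.sum() > 100
        assert np.all(np.abs(fa.u1[near] - 0.05) < 0.1 * 0.05)
        assert np.all(np.abs(fa.u2[near] - 0.02) < 0.1 * 0.02)

    def test_no_trust_limit_keeps_background(self, small_grid, rng, small_region,
                                             uniform_spec):
        cycles, _ = make_synthetic_cycles(uniform_spec, 1, small_region, rng,
                                          margin_deg=0.5)
        obs = raw_velocities(cycles)
        f0 = VelocityField(
            small_grid, np.full(small_grid.shape, 0.01), np.zeros(small_grid.shape)
        )
        fa = assimilate(
            f0, obs, cycles, AssimilationConfig(sigma_ratio=1e6, iterations=3)
        )
        assert np.allclose(fa.u1, f0.u1, atol=1e-9)
        assert np.allclose(fa.u2, f0.u2, atol=1e-9)

    def test_iteration_does_not_worsen_endpoint_error(self, small_grid, rng,
                                                      small_region, gyre_spec):
        cycles, _ = make_synthetic_cycles(
            gyre_spec, 80, small_region, rng, noise_sd_deg=0.003, margin_deg=0.3
        )
        obs = raw_velocities(cycles)
        f = initial_field(obs, small_grid)
        errs = [prediction_error(f, cycles)]
        cfg = AssimilationConfig(iterations=1)
        for _ in range(3):
            f = assimilate(f, obs, cycles, cfg)
            errs.append(prediction_error(f, cycles))
        assert errs[-1] <= errs[0]
        assert errs == sorted(errs, reverse=True)


class TestLandCorrect:
    @staticmethod
    def _island_mask(grid):
        LON, LAT = grid.meshgrid()
        mask = np.hypot(LON - 161.5, LAT + 10.5) < 0.45
        return LandMask(grid, mask)

    def test_magnitude_preserved_and_interior_untouched(self, small_grid, rng):
        mask = self._island_mask(small_grid)
        u1 = rng.normal(0, 0.05, small_grid.shape)
        u2 = rng.normal(0, 0.05, small_grid.shape)
        f = VelocityField(small_grid, u1, u2)
        fc = land_correct(f, mask)
        assert np.allclose(fc.speed(), f.speed(), atol=1e-12)
        # nodes with a fully-uniform 8-neighbourhood are untouched
        m = mask.mask
        changed = (fc.u1 != f.u1) | (fc.u2 != f.u2)
        for i, j in zip(*np.nonzero(changed)):
            window = m[max(i - 1, 0) : i + 2, max(j - 1, 0) : j + 2]
            assert window.any() and not window.all()

    def test_all_boundary_vectors_point_seaward(self, small_grid, rng):
        mask = self._island_mask(small_grid)
        m = mask.mask
        f = VelocityField(
            small_grid,
            rng.normal(0, 0.05, small_grid.shape),
            rng.normal(0, 0.05, small_grid.shape),
        )
        fc = land_correct(f, mask)
        nlat, nlon = small_grid.shape
        for i in range(nlat):
            for j in range(nlon):
                neigh = [
                    (i + di, j + dj)
                    for di in (-1, 0, 1)
                    for dj in (-1, 0, 1)
                    if (di, dj) != (0, 0)
                    and 0 <= i + di < nlat
                    and 0 <= j + dj < nlon
                ]
                coastal = (m[i, j] and any(not m[a] for a in map(tuple, neigh))) or (
                    not m[i, j] and any(m[a] for a in map(tuple, neigh))
                )
                if not coastal:
                    continue
                vx, vy = fc.u1[i, j], fc.u2[i, j]
                if vx == 0 and vy == 0:
                    continue
                best = max(
                    neigh,
                    key=lambda ab: (vx * (ab[1] - j) + vy * (ab[0] - i))
                    / np.hypot(ab[1] - j, ab[0] - i),
                )
                assert not m[best]

    def test_landward_vector_rotated_seaward_at_same_speed(self, small_grid):
        # land strip east of 162.5; an eastward sea vector on the coastal
        # column is rotated (speed kept), far-field vectors are untouched
        LON, _ = small_grid.meshgrid()
        mask = LandMask(small_grid, LON > 162.55)
        u1 = np.full(small_grid.shape, 0.1)
        fc = land_correct(VelocityField(small_grid, u1, np.zeros(small_grid.shape)), mask)
        j_coast = 25  # lon 162.5, last sea column
        i = small_grid.shape[0] // 2
        assert np.hypot(fc.u1[i, j_coast], fc.u2[i, j_coast]) == pytest.approx(0.1)
        assert fc.u1[i, j_coast] <= 1e-12  # no longer pointing east at the land
        # far from the coast: unchanged
        assert fc.u1[i, 2] == pytest.approx(0.1) and fc.u2[i, 2] == 0.0


class TestEnsemble:
    def test_determinism_and_empty(self, small_grid, small_region, rng, gyre_spec):
        cycles, _ = make_synthetic_cycles(gyre_spec, 200, small_region, rng)
        obs = raw_velocities(cycles)
        e1 = build_ensemble(obs, cycles, small_grid, n_fields=2, master_seed=5)
        e2 = build_ensemble(obs, cycles, small_grid, n_fields=2, master_seed=5)
        assert len(e1) == 2
        for a, b in zip(e1.fields, e2.fields):
            assert np.array_equal(a.u1, b.u1) and np.array_equal(a.u2, b.u2)
        e0 = build_ensemble(obs, cycles, small_grid, n_fields=0, master_seed=5)
        assert len(e0) == 0

    def test_ensemble_mean_beats_most_members(self, small_region, rotation_spec):
        rng = np.random.default_rng(7)
        grid = Grid(small_region, spacing_deg=0.15)
        cycles, _ = make_synthetic_cycles(
            rotation_spec, 300, small_region, rng, noise_sd_deg=0.01, margin_deg=0.2
        )
        obs = raw_velocities(cycles)
        ens = build_ensemble(obs, cycles, grid, n_fields=25, master_seed=3)
        errs = [field_rms_error(f, rotation_spec) for f in ens.fields]
        e_mean = field_rms_error(ens.mean_field(), rotation_spec)
        assert np.mean([e_mean < e for e in errs]) >= 0.8


class TestPredictionError:
    def test_self_consistency(self, small_grid, rng, small_region, rotation_spec):
        f, _ = make_analytic_field(rotation_spec, small_grid)
        cycles, _ = make_synthetic_cycles(
            rotation_spec, 30, small_region, rng, margin_deg=0.4
        )
        assert prediction_error(f, cycles) < 5e-4

    def test_linear_error_propagation_under_bias(self, small_grid, small_region):
        rng = np.random.default_rng(11)
        u0, bias = (0.02, 0.0), 0.01
        spec = AnalyticFieldSpec("uniform", {"u1": u0[0], "u2": u0[1]})
        cycles, _ = make_synthetic_cycles(
            spec, 40, small_region, rng, mean_duration_days=10.0,
            duration_jitter=0.0, margin_deg=0.5,
        )
        biased = VelocityField(
            small_grid,
            np.full(small_grid.shape, u0[0] + bias),
            np.zeros(small_grid.shape),
        )
        assert prediction_error(biased, cycles) == pytest.approx(10 * bias, rel=0.02)

    def test_empty_cycles_error(self, small_grid):
        f = VelocityField(small_grid, np.zeros(small_grid.shape), np.zeros(small_grid.shape))
        with pytest.raises(ValueError):
            prediction_error(f, [])
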
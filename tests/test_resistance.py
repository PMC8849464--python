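"""Tests of resistance transforms, commute/current solvers, AICc selection
and the GA optimiser."""

import numpy as np
import pandas as pd
import pytest

from landgen.datatypes import (
    AnalysisError,
    ConfigurationError,
    DistanceMatrix,
    RasterSurface,
)
from landgen.resistance import (
    CategoricalReclass,
    ConductanceGraph,
    GAConfig,
    SurfaceSpec,
    TransformParams,
    aicc,
    bootstrap_rank,
    build_conductance_graph,
    commute_distance,
    current_map,
    effective_resistance,
    fit_surface_model,
    ga_optimise,
    model_selection,
    monomolecular,
    rescale_surface,
    surface_collinearity,
)
from landgen.resistance import SurfaceModel


def _raster(vals, cell=1.0, **kw):
    return RasterSurface(np.asarray(vals, dtype=float), cell_size=cell, **kw)


class TestRescale:
    def test_endpoints(self):
        out = rescale_surface(_raster([[0.0, 500.0, 1000.0]]))
        assert np.allclose(out.values, [[1.0, 50.5, 100.0]])

    def test_idempotent_on_target_range(self):
        r = _raster([[1.0, 40.0, 100.0]])
        out = rescale_surface(r)
        assert np.allclose(out.values, r.values)

    def test_minmax_invariant(self):
        rng = np.random.default_rng(0)
        out = rescale_surface(_raster(rng.uniform(-50, 700, (8, 9))))
        assert out.values.min() == pytest.approx(1.0)
        assert out.values.max() == pytest.approx(100.0)

    def test_constant_raster_error(self):
        with pytest.raises(AnalysisError):
            rescale_surface(_raster(np.full((3, 3), 7.0)))


class TestCollinearity:
    def test_self_and_monotone_transform(self):
        rng = np.random.default_rng(1)
        a = _raster(rng.uniform(0, 1, (40, 40)))
        b = a.copy_with(np.exp(3 * a.values))  # strictly monotone transform
        rho, warns = surface_collinearity({"a": a, "b": b})
        assert rho.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)
        assert warns  # correlated surfaces are reported

    def test_independent_noise(self):
        rng = np.random.default_rng(2)
        a = _raster(rng.normal(size=(100, 100)))
        b = _raster(rng.normal(size=(100, 100)))
        rho, warns = surface_collinearity({"a": a, "b": b})
        assert abs(rho.loc["a", "b"]) < 0.05
        assert not warns

    def test_misaligned_error(self):
        with pytest.raises(ConfigurationError):
            surface_collinearity({"a": _raster(np.zeros((3, 3))),
                                  "b": _raster(np.zeros((4, 4)))})


class TestMonomolecular:
    def test_anchors_increasing(self):
        r = _raster([[1.0, 100.0]])
        out = monomolecular(r, TransformParams(variant=0, shape=0.7, maximum=42.0))
        assert out.values[0, 0] == pytest.approx(1.0)
        assert out.values[0, 1] == pytest.approx(42.0)

    def test_large_shape_is_linear(self):
        """shape -> infinity: the curve converges to the affine map."""
        x = np.linspace(1, 100, 200)[None, :]
        out = monomolecular(_raster(x), TransformParams(variant=0, shape=1e5, maximum=100.0))
        affine = 1.0 + (100.0 - 1.0) * (x - 1.0) / 99.0
        assert np.abs(out.values - affine).max() < 1e-3

    def test_variants_distinct_and_bounded(self):
        x = np.linspace(1, 100, 50)[None, :]
        curves = []
        for v in range(8):
            out = monomolecular(_raster(x), TransformParams(variant=v, shape=0.3, maximum=60.0))
            assert out.values.min() >= 1.0 - 1e-9
            assert out.values.max() <= 60.0 + 1e-9
            curves.append(out.values.ravel())
        for i in range(8):
            for j in range(i + 1, 8):
                assert not np.allclose(curves[i], curves[j])

    def test_parameter_validation(self):
        with pytest.raises(ConfigurationError):
            TransformParams(variant=0, shape=-1.0, maximum=50.0)
        with pytest.raises(ConfigurationError):
            TransformParams(variant=0, shape=1.0, maximum=1.0)
        with pytest.raises(ConfigurationError):
            TransformParams(variant=9, shape=1.0, maximum=50.0)


class TestConductanceGraph:
    def test_edge_averaging_rule(self):
        g = build_conductance_graph(_raster([[2.0, 4.0]]))
        assert 1.0 / g.conductance[0] == pytest.approx(3.0)

    def test_uniform_grid_cardinal_conductance(self):
        g = build_conductance_graph(_raster(np.full((3, 3), 5.0)), connectivity=4)
        assert np.allclose(g.conductance, 1.0 / 5.0)

    def test_diagonal_scaling(self):
        g = build_conductance_graph(_raster([[2.0, 9.0], [9.0, 4.0]]))
        # the (0,0)-(1,1) diagonal edge: resistance sqrt(2) * (2+4)/2
        diag = [
            1.0 / c
            for (u, v), c in zip(g.edges, g.conductance)
            if {tuple(g.cell_of_node[u]), tuple(g.cell_of_node[v])}
            == {(0, 0), (1, 1)}
        ]
        assert diag[0] == pytest.approx(3.0 * np.sqrt(2.0))

    def test_disconnected_focal_error(self):
        vals = np.ones((3, 3))
        mask = np.zeros((3, 3), bool)
        mask[:, 1] = True  # wall splits left and right columns
        r = _raster(vals, nodata_mask=mask)
        with pytest.raises(AnalysisError):
            build_conductance_graph(r, 4, focal_cells=[(0, 0), (0, 2)])


class TestCommute:
    def test_two_node_closed_form(self):
        g = build_conductance_graph(_raster([[2.0, 4.0]]))
        R = effective_resistance(g, [0, 1])
        assert R[0, 1] == pytest.approx(3.0, abs=1e-10)
        assert g.vol * R[0, 1] == pytest.approx(2.0, abs=1e-10)

    def test_three_node_path_hand_laplacian(self):
        g = build_conductance_graph(_raster(np.ones((1, 3))), connectivity=4)
        R = effective_resistance(g, [0, 2])
        assert R[0, 1] == pytest.approx(2.0, abs=1e-10)
        assert g.vol * R[0, 1] == pytest.approx(8.0, abs=1e-10)

    def test_parallel_resistor_law(self):
        one = ConductanceGraph(
            n_nodes=2, edges=np.array([[0, 1]]), conductance=np.array([1.0]),
            vol=2.0, node_of_cell={(0, 0): 0, (0, 1): 1},
            cell_of_node=np.array([[0, 0], [0, 1]]), shape=(1, 2),
        )
        two = ConductanceGraph(
            n_nodes=2, edges=np.array([[0, 1], [0, 1]]),
            conductance=np.array([1.0, 1.0]), vol=4.0,
            node_of_cell={(0, 0): 0, (0, 1): 1},
            cell_of_node=np.array([[0, 0], [0, 1]]), shape=(1, 2),
        )
        r1 = effective_resistance(one, [0, 1])[0, 1]
        r2 = effective_resistance(two, [0, 1])[0, 1]
        assert r1 == pytest.approx(1.0, abs=1e-12)
        assert r2 == pytest.approx(0.5, abs=1e-12)

    def test_metric_properties_and_scale_invariance(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(1, 50, (8, 8))
        sites = pd.DataFrame(
            {"site_id": ["a", "b", "c", "d"],
             "x": [0.5, 7.5, 0.5, 7.5], "y": [0.5, 0.5, 7.5, 7.5]}
        )
        r = _raster(vals)
        g = build_conductance_graph(r)
        dm = commute_distance(g, sites, r)
        v = dm.values
        assert np.allclose(v, v.T, atol=1e-10)
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    assert v[i, j] <= v[i, k] + v[k, j] + 1e-9
        # doubling all resistances doubles effective resistances but leaves
        # commute times (random-walk steps) unchanged: the walk's transition
        # probabilities do not see a common conductance factor
        g2 = build_conductance_graph(r.copy_with(2 * vals))
        nodes = [g.node_of_cell[r.nearest_cell(row.x, row.y)] for row in sites.itertuples()]
        R1 = effective_resistance(g, nodes)
        R2 = effective_resistance(g2, nodes)
        assert np.allclose(R2, 2 * R1, rtol=1e-9)
        dm2 = commute_distance(g2, sites, r)
        assert np.allclose(dm2.values, v, rtol=1e-9)


class TestCurrentMap:
    def _sites(self, coords):
        return pd.DataFrame(
            {"site_id": [f"s{i}" for i in range(len(coords))],
             "x": [c[0] for c in coords], "y": [c[1] for c in coords]}
        )

    def test_symmetry_and_kirchhoff(self):
        r = _raster(np.ones((9, 9)))
        cm = current_map(r, self._sites([(0.5, 4.5), (8.5, 4.5)]))
        assert cm.max_kirchhoff_residual < 1e-8
        v = cm.raster.values
        assert np.abs(v - v[:, ::-1]).max() < 1e-8  # swap the two focal cells
        assert np.abs(v - v[::-1, :]).max() < 1e-8  # mirror across the axis

    def test_cross_method_consistency(self):
        """Effective resistance from the current solver equals
        commute / vol from the commute solver."""
        rng = np.random.default_rng(6)
        r = _raster(rng.uniform(1, 30, (7, 7)))
        sites = self._sites([(0.5, 0.5), (6.5, 6.5), (0.5, 6.5)])
        cm = current_map(r, sites)
        g = build_conductance_graph(r)
        dm = commute_distance(g, sites, r)
        expected = dm.values / g.vol
        assert np.allclose(cm.pair_resistance.values, expected, rtol=1e-8)

    def test_currents_nonnegative(self):
        r = _raster(np.ones((5, 5)))
        cm = current_map(r, self._sites([(0.5, 0.5), (4.5, 4.5)]))
        assert (cm.raster.values[cm.raster.valid()] >= 0).all()


class TestAICc:
    def test_hand_formula(self):
        assert aicc(-100.0, 2, 25) == pytest.approx(204.0 + 12.0 / 22.0, abs=1e-12)

    def test_k_zero_reduces_to_minus_2ll(self):
        assert aicc(-50.0, 0, 10) == pytest.approx(100.0)

    def test_large_n_approaches_aic(self):
        assert abs(aicc(-100.0, 3, 10**9) - (200.0 + 6.0)) < 1e-6

    def test_overparameterised_error(self):
        with pytest.raises(ConfigurationError):
            aicc(-10.0, 10, 11)


class TestModelSelection:
    def test_printed_table_arithmetic(self):
        """The nine published AICc values: runner-up delta = 2.26 and
        top-model weight = 0.76 at two decimals."""
        vals = {
            "Elevation": (-749.51, 4), "Distance": (-747.25, 2),
            "Roads": (-736.25, 6), "Elevation + Roads": (-729.55, 9),
            "Land": (-720.26, 12), "Elevation + Land cover": (-687.82, 15),
            "Land cover + Roads": (-648.63, 17), "Null model": (-565.08, 1),
            "Elevation + Land cover + Roads": (-520.44, 20),
        }
        tab = model_selection(vals)
        assert tab["model"].iloc[0] == "Elevation"
        assert tab["delta_AICc"].iloc[1] == pytest.approx(2.26, abs=1e-9)
        assert round(tab["weight"].iloc[0], 2) == 0.76
        assert tab["weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_equal_models_split_weight(self):
        tab = model_selection({"a": (10.0, 2), "b": (10.0, 2)})
        assert np.allclose(tab["weight"], 0.5)

    def test_single_model(self):
        tab = model_selection({"only": (3.0, 1)})
        assert tab["delta_AICc"].iloc[0] == 0.0
        assert tab["weight"].iloc[0] == pytest.approx(1.0)


def _toy_models(rng, n=8):
    labels = [f"S{i}" for i in range(n)]
    base = rng.uniform(1, 10, (n, n))
    base = (base + base.T) / 2
    np.fill_diagonal(base, 0)
    eff = DistanceMatrix(labels, base)
    gen_vals = 0.1 + 0.01 * base + (lambda m: (m + m.T) / 2)(rng.normal(0, 0.005, (n, n)))
    np.fill_diagonal(gen_vals, 0)
    gen = DistanceMatrix(labels, gen_vals)
    noise = rng.uniform(1, 10, (n, n))
    noise = (noise + noise.T) / 2
    np.fill_diagonal(noise, 0)
    bad_eff = DistanceMatrix(labels, noise)
    good = SurfaceModel("good", "surface", k=2, fit=fit_surface_model(eff, gen),
                        effective_dm=eff)
    bad = SurfaceModel("bad", "surface", k=2, fit=fit_surface_model(bad_eff, gen),
                       effective_dm=bad_eff)
    sites = pd.DataFrame({"site_id": labels, "x": np.arange(n) * 1.0, "y": 0.0})
    return good, bad, gen, sites


class TestBootstrapRank:
    def test_dominant_model_top_every_iteration(self):
        rng = np.random.default_rng(3)
        good, bad, gen, sites = _toy_models(rng)
        df = bootstrap_rank([good, bad], gen, sites, frac=0.85, n_boot=50, seed=1)
        row = df.set_index("model").loc["good"]
        assert row["top_pct"] == pytest.approx(100.0)
        assert row["avg_rank"] == pytest.approx(1.0)

    def test_ranks_are_permutations(self):
        rng = np.random.default_rng(5)
        good, bad, gen, sites = _toy_models(rng)
        df = bootstrap_rank([good, bad], gen, sites, frac=0.85, n_boot=30, seed=2)
        assert df["avg_rank"].sum() == pytest.approx(3.0)  # 1 + 2 every iteration


class TestGA:
    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(8)
        elev = _raster(rng.uniform(0, 1000, (15, 15)))
        spec = SurfaceSpec("elev", rescale_surface(elev), "continuous")
        sites = pd.DataFrame(
            {"site_id": [f"S{i}" for i in range(6)],
             "x": rng.uniform(0, 15, 6), "y": rng.uniform(0, 15, 6)}
        )
        true_res = monomolecular(rescale_surface(elev),
                                 TransformParams(variant=0, shape=0.5, maximum=40.0))
        g = build_conductance_graph(true_res)
        eff = commute_distance(g, sites, true_res)
        gen_vals = 0.05 + 1e-6 * eff.values
        gen = DistanceMatrix(eff.labels, gen_vals)
        cfg = GAConfig(pop_mult=4, generations=3, patience=2, seed=13)
        m1 = ga_optimise([spec], gen, sites, cfg)
        m2 = ga_optimise([spec], gen, sites, cfg)
        p1, p2 = m1.components[0][1], m2.components[0][1]
        assert (p1.variant, p1.shape, p1.maximum) == (p2.variant, p2.shape, p2.maximum)
        assert m1.fit.loglik == pytest.approx(m2.fit.loglik, abs=1e-12)
        assert m1.k == 4  # intercept + slope + shape + maximum

    def test_categorical_anchor_fixed(self):
        rng = np.random.default_rng(9)
        classes = rng.integers(1, 4, size=(12, 12)).astype(float)
        cat = RasterSurface(classes, cell_size=1.0, kind="categorical")
        spec = SurfaceSpec("land", cat, "categorical", anchor=1)
        sites = pd.DataFrame(
            {"site_id": [f"S{i}" for i in range(5)],
             "x": rng.uniform(0, 12, 5), "y": rng.uniform(0, 12, 5)}
        )
        gen_vals = rng.uniform(0.01, 0.2, (5, 5))
        gen_vals = (gen_vals + gen_vals.T) / 2
        np.fill_diagonal(gen_vals, 0)
        gen = DistanceMatrix([f"S{i}" for i in range(5)], gen_vals)
        m = ga_optimise([spec], gen, sites, GAConfig(pop_mult=3, generations=2, seed=1))
        reclass = m.components[0][1]
        assert isinstance(reclass, CategoricalReclass)
        assert reclass.values[1] == 1.0
        assert m.k == 2 + 2  # intercept + slope + two free class values
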
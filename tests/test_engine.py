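import numpy as np
import pytest
from scipy.stats import spearmanr
from sklearn.decomposition import PCA as SkPCA

from irsei import engine, pipeline, synth
from irsei.engine import LAYER_ORDER, IndicatorStack
from irsei.errors import ConfigurationError, DataError, DegenerateRangeError
from irsei.raster import IndicatorRaster


def _layer(values, polarity="benefit", name="", mask=None):
    values = np.asarray(values, dtype=float)
    mask = np.ones(values.shape, dtype=bool) if mask is None else mask
    return IndicatorRaster(np.where(mask, values, np.nan), polarity, mask, name=name)


def _stack_from_grids(grids: dict[str, np.ndarray], mask=None) -> IndicatorStack:
    """Build a stack directly from already-[0,1] grids (no renormalization)."""
    some = next(iter(grids.values()))
    mask = np.ones(some.shape, dtype=bool) if mask is None else mask
    layers = {n: _layer(g, name=n, mask=mask) for n, g in grids.items()}
    return IndicatorStack(layers=layers, analysis_mask=mask)


class TestMinmaxNormalize:
    def test_affine(self):
        out = engine.minmax_normalize(_layer([[2.0, 4.0, 6.0]]))
        np.testing.assert_allclose(out.values, [[0.0, 0.5, 1.0]])

    def test_idempotent_on_attained_unit_range(self):
        out = engine.minmax_normalize(_layer([[0.0, 0.25, 1.0]]))
        np.testing.assert_allclose(out.values, [[0.0, 0.25, 1.0]])

    def test_masked_outlier_ignored(self):
        values = np.array([[0.0, 10.0], [100.0, 5.0]])
        mask = np.array([[True, True], [False, True]])
        out = engine.minmax_normalize(_layer(values), mask)
        np.testing.assert_allclose(out.values[0], [0.0, 1.0])
        assert not out.valid_mask[1, 0]

    def test_constant_raises(self):
        with pytest.raises(DegenerateRangeError):
            engine.minmax_normalize(_layer([[3.0, 3.0, 3.0]]))


class TestBuildStack:
    def _inputs(self, rng, shape=(12, 12)):
        mk = lambda pol: _layer(rng.uniform(size=shape), pol)
        return dict(
            gndvi=mk("benefit"), wet=mk("benefit"), m_ndbsi=mk("cost"),
            tir=mk("cost"), lui=mk("cost"),
        )

    def test_all_land_mask_is_valid_mask(self, rng):
        stack = engine.build_stack(**self._inputs(rng), water=None)
        assert stack.analysis_mask.all()
        for name in LAYER_ORDER:
            vals = stack.layers[name].masked()
            assert vals.min() == 0.0 and vals.max() == 1.0

    def test_water_pixels_excluded(self, rng):
        from irsei.shoreline import WaterMask

        inputs = self._inputs(rng)
        water = np.zeros((12, 12), dtype=bool)
        water[:6] = True
        stack = engine.build_stack(**inputs, water=WaterMask(water, 0.0))
        assert stack.analysis_mask.sum() == 72

    def test_constant_layer_named_in_error(self, rng):
        inputs = self._inputs(rng)
        inputs["lui"] = _layer(np.full((12, 12), 0.5), "cost")
        with pytest.raises(DegenerateRangeError, match="LUI"):
            engine.build_stack(**inputs, water=None)


class TestPca:
    def test_matches_sklearn_oracle(self, rng):
        grids = {n: rng.uniform(size=(10, 10)) for n in LAYER_ORDER}
        stack = _stack_from_grids(grids)
        result = engine.pca(stack)
        X = stack.matrix()
        sk = SkPCA(n_components=5).fit(X)
        np.testing.assert_allclose(result.eigenvalues, sk.explained_variance_, atol=1e-8)
        for mine, ref in zip(result.loadings, sk.components_):
            sign = np.sign(np.dot(mine, ref)) or 1.0
            np.testing.assert_allclose(mine, sign * ref, atol=1e-8)

    def test_eigenvalues_nonincreasing_nonnegative(self, rng):
        stack = _stack_from_grids({n: rng.uniform(size=(8, 8)) for n in LAYER_ORDER})
        ev = engine.pca(stack).eigenvalues
        assert (np.diff(ev) <= 1e-12).all() and (ev >= 0).all()

    def test_orthonormal_loadings(self, rng):
        stack = _stack_from_grids({n: rng.uniform(size=(8, 8)) for n in LAYER_ORDER})
        L = engine.pca(stack).loadings
        np.testing.assert_allclose(L @ L.T, np.eye(L.shape[0]), atol=1e-8)

    def test_informative_pair_dominates(self, rng):
        base = rng.uniform(size=(20, 20))
        grids = {
            "GNDVI": base,
            "WET": 1.0 - base,  # perfectly anti-correlated with greenness
            "M-NDBSI": np.full((20, 20), 0.5) + rng.normal(0, 1e-4, (20, 20)),
            "TIR": np.full((20, 20), 0.5) + rng.normal(0, 1e-4, (20, 20)),
            "LUI": np.full((20, 20), 0.5) + rng.normal(0, 1e-4, (20, 20)),
        }
        stack = _stack_from_grids(grids)
        result = engine.pca(stack)
        informative = 2 * np.var(base, ddof=1)
        assert result.eigenvalues[0] == pytest.approx(informative, rel=1e-3)
        assert result.eigenvalues[0] / result.eigenvalues.sum() > 0.99

    def test_eigenvalue_sum_is_total_variance(self, rng):
        stack = _stack_from_grids({n: rng.uniform(size=(9, 9)) for n in LAYER_ORDER})
        result = engine.pca(stack)
        total = np.var(stack.matrix(), axis=0, ddof=1).sum()
        assert result.eigenvalues.sum() == pytest.approx(total, abs=1e-6)


class TestIrseiFromPca:
    def test_single_varying_factor_monotone_in_gndvi(self, rng):
        g = rng.uniform(size=(15, 15))
        grids = {
            "GNDVI": g,
            "WET": np.full(g.shape, 0.5) + rng.normal(0, 1e-5, g.shape),
            "M-NDBSI": np.full(g.shape, 0.5) + rng.normal(0, 1e-5, g.shape),
            "TIR": np.full(g.shape, 0.5) + rng.normal(0, 1e-5, g.shape),
            "LUI": np.full(g.shape, 0.5) + rng.normal(0, 1e-5, g.shape),
        }
        stack = _stack_from_grids(grids)
        res = engine.irsei_from_pca(engine.pca(stack), stack)
        order = np.argsort(g.ravel())
        irsei_sorted = res.irsei.ravel()[order]
        assert (np.diff(irsei_sorted) >= -1e-9).all()

    def test_range_and_orientation(self, degradation_series):
        for prod in degradation_series:
            res = prod.irsei
            vals = res.irsei[res.mask]
            assert vals.min() == pytest.approx(0.0, abs=1e-12)
            assert vals.max() == pytest.approx(1.0, abs=1e-12)
            g = prod.stack.layers["GNDVI"].values[res.mask]
            assert np.corrcoef(vals, g)[0, 1] >= 0.0

    def test_loading_sign_flip_invariance(self, rng):
        stack = _stack_from_grids({n: rng.uniform(size=(10, 10)) for n in LAYER_ORDER})
        p = engine.pca(stack)
        flipped = engine.PcaResult(loadings=-p.loadings, eigenvalues=p.eigenvalues, pc1=-p.pc1)
        a = engine.irsei_from_pca(p, stack)
        b = engine.irsei_from_pca(flipped, stack)
        np.testing.assert_allclose(a.irsei[a.mask], b.irsei[b.mask], atol=1e-12)

    def test_affine_rescale_of_input_layer_absorbed(self, thermal_constants):
        script = synth.degradation_script(epochs=("a", "b"))
        scene, lcm = synth.make_timeseries(script, seed=13)[0]
        base = pipeline.run_epoch(scene, lcm, thermal_constants)
        # rescale the scene's thermal response: LST in celsius-like units
        from irsei import indices

        L = indices.radiance(scene.thermal_dn, thermal_constants)
        T = indices.brightness_temperature(L, thermal_constants)
        lst_grid = indices.lst(T, thermal_constants)
        shifted = pipeline.run_epoch(
            scene, lcm, lst_raster=3.0 * (lst_grid - 273.15) + 7.0
        )
        np.testing.assert_allclose(
            base.irsei.irsei[base.irsei.mask],
            shifted.irsei.irsei[shifted.irsei.mask],
            atol=1e-6,
        )

    def test_degradation_series_monotone_mean(self, degradation_series):
        means = [p.irsei.mean for p in degradation_series]
        assert all(m2 <= m1 + 1e-9 for m1, m2 in zip(means, means[1:]))


class TestEqualWeight:
    def test_hand_arithmetic(self):
        grids = {
            "GNDVI": np.array([[0.0, 0.8, 1.0]]),
            "WET": np.array([[0.0, 0.5, 1.0]]),
            "M-NDBSI": np.array([[0.0, 0.3, 1.0]]),
            "TIR": np.array([[0.0, 0.2, 1.0]]),
            "LUI": np.array([[0.0, 0.5, 1.0]]),
        }
        stack = _stack_from_grids(grids)
        ndwi = _layer([[0.0, 0.6, 1.0]], "benefit", "NDWI")
        res = engine.irsei_equal_weight(stack, ndwi)
        assert res.irsei[0, 1] == pytest.approx((0.8 + 0.6 + 0.7 + 0.8 + 0.5) / 5)
        assert res.irsei[0, 0] == pytest.approx((0 + 0 + 1 + 1 + 1) / 5)

    def test_best_case_is_one(self):
        grids = {
            "GNDVI": np.array([[1.0, 0.0]]),
            "WET": np.array([[1.0, 0.0]]),
            "M-NDBSI": np.array([[0.0, 1.0]]),
            "TIR": np.array([[0.0, 1.0]]),
            "LUI": np.array([[0.0, 1.0]]),
        }
        res = engine.irsei_equal_weight(
            _stack_from_grids(grids), _layer([[1.0, 0.0]], "benefit")
        )
        assert res.irsei[0, 0] == 1.0
        assert res.irsei[0, 1] == 0.0

    def test_rank_agreement_with_pca_on_one_factor_scene(self, rng):
        f = rng.uniform(size=(25, 25))  # one latent quality factor
        noise = lambda: rng.normal(0, 0.02, f.shape)
        grids = {
            "GNDVI": np.clip(f + noise(), 0, 1),
            "WET": np.clip(f + noise(), 0, 1),
            "M-NDBSI": np.clip(1 - f + noise(), 0, 1),
            "TIR": np.clip(1 - f + noise(), 0, 1),
            "LUI": np.clip(1 - f + noise(), 0, 1),
        }
        stack = _stack_from_grids(grids)
        pca_res = engine.irsei_from_pca(engine.pca(stack), stack)
        eq_res = engine.irsei_equal_weight(stack, _layer(np.clip(f + noise(), 0, 1), "benefit"))
        rho = spearmanr(pca_res.irsei.ravel(), eq_res.irsei.ravel()).statistic
        assert rho >= 0.9

    def test_missing_ndwi(self, rng):
        stack = _stack_from_grids({n: rng.uniform(size=(5, 5)) for n in LAYER_ORDER})
        with pytest.raises(ConfigurationError):
            engine.irsei_equal_weight(stack, None)


class TestGrade:
    def test_uniform_values_split_evenly(self, rng):
        vals = rng.uniform(size=(200, 200))
        mask = np.ones(vals.shape, dtype=bool)
        _, _, props = engine.grade(vals, mask)
        for level in range(1, 6):
            assert props[level] == pytest.approx(20.0, abs=1.5)

    def test_endpoint_inclusion(self):
        vals = np.ones((4, 4))
        grades, areas, props = engine.grade(vals, np.ones((4, 4), bool), pixel_area_km2=1.0)
        assert (grades == 5).all()
        assert props[5] == 100.0
        assert areas[5] == 16.0

    def test_proportions_partition(self, rng):
        vals = rng.uniform(size=(50, 50))
        mask = rng.uniform(size=(50, 50)) > 0.2
        _, _, props = engine.grade(vals, mask)
        assert sum(props.values()) == pytest.approx(100.0, abs=0.05)

    def test_break_validation(self):
        with pytest.raises(ConfigurationError):
            engine.grade(np.zeros((2, 2)), np.ones((2, 2), bool), breaks=(0.4, 0.2, 0.6, 0.8))


class TestSummarizeEpochs:
    def test_printed_interval_difference(self):
        df = engine.summarize_epochs([0.5185, 0.4338], ["2007", "2013"])
        assert df["delta"].iloc[1] == pytest.approx(-0.0847)

    def test_printed_cumulative_difference(self):
        df = engine.summarize_epochs(
            [0.4470, 0.5185, 0.4338, 0.45, 0.4768],
            ["2002", "2007", "2013", "2017", "2022"],
        )
        assert df["cumulative"].iloc[-1] == pytest.approx(0.0298)

    def test_constant_series(self):
        df = engine.summarize_epochs([0.4, 0.4, 0.4])
        assert (df["delta"].iloc[1:] == 0).all()
        assert (df["cumulative"] == 0).all()

    def test_single_epoch_rejected(self):
        with pytest.raises(DataError):
            engine.summarize_epochs([0.5])
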
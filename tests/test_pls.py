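import numpy as np
import pytest
import xarray as xr

from phenodrivers import (
    Coupling,
    DesignMatrix,
    InsufficientDataError,
    SimulationConfig,
    build_design,
    driver_map,
    fit_pls,
    generate_climate_cube,
    month_window,
    typical_date,
    vip_scores,
)


def nipals_pls1(X, y, A):
    """Hand-coded PLS1/NIPALS oracle: weights, scores, loadings, coefficients, VIP."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    n, p = Xc.shape
    W = np.zeros((p, A))
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    for a in range(A):
        w = Xc.T @ yc
        w = w / np.linalg.norm(w)
        t = Xc @ w
        pl = Xc.T @ t / (t @ t)
        qa = (yc @ t) / (t @ t)
        Xc = Xc - np.outer(t, pl)
        yc = yc - qa * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, pl, qa
    coef = W @ np.linalg.solve(P.T @ W, q)
    ssy = q**2 * np.einsum("na,na->a", T, T)
    vip = np.sqrt(p * ((W / np.linalg.norm(W, axis=0)) ** 2 @ ssy) / ssy.sum())
    return coef, vip


def standardized(rng, n=25, p=24):
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    y = (y - y.mean()) / y.std(ddof=1)
    return X, y


def make_dm(X, y):
    p = X.shape[1]
    return DesignMatrix(
        X=X, y=y, labels=tuple(f"v{i}" for i in range(p)),
        kept=np.ones(p, dtype=bool), year_index=np.arange(X.shape[0]),
    )


class TestTypicalDate:
    def test_percentile_interpolation(self):
        assert typical_date([150, 152, 154, 160]) == pytest.approx(155.5)

    def test_constant_and_single(self):
        assert typical_date([140.0] * 5) == 140.0
        assert typical_date([212.0]) == 212.0

    def test_nan_ignored_empty_rejected(self):
        assert typical_date([np.nan, 150.0]) == 150.0
        with pytest.raises(ValueError):
            typical_date([np.nan])


class TestMonthWindow:
    def test_after_the_15th_includes_month(self):
        # June 20 (doy 171): window runs July of the previous year to June
        window = month_window(171)
        assert window[0] == (7, -1)
        assert window[-1] == (6, 0)

    def test_before_the_15th_excludes_month(self):
        # June 10 (doy 161): last month is May
        window = month_window(161)
        assert window[0] == (6, -1)
        assert window[-1] == (5, 0)

    def test_january_wraps_to_previous_year(self):
        # Jan 20: window Feb(prev) .. Jan(same)
        window = month_window(20)
        assert window[0] == (2, -1)
        assert window[-1] == (1, 0)
        assert sum(off == -1 for _, off in window) == 11

    def test_always_twelve_distinct_months(self):
        for doy in (1, 46, 170, 200, 365):
            window = month_window(doy)
            assert len(window) == 12
            assert sorted(m for m, _ in window) == list(range(1, 13))


class TestBuildDesign:
    def _inputs(self, ny=25, seed=0):
        rng = np.random.default_rng(seed)
        return (
            rng.normal(size=ny),
            rng.normal(size=(ny, 12)),
            rng.normal(10, 2, size=(ny, 12)),
        )

    def test_scaling_contract(self):
        resp, temp, prec = self._inputs()
        dm = build_design(resp, temp, prec, month_window(200))
        assert dm.X.shape == (24, 24)  # offsets cost the first year
        np.testing.assert_allclose(dm.X.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(dm.X.std(axis=0, ddof=1), 1, atol=1e-12)
        assert dm.y.mean() == pytest.approx(0, abs=1e-12)
        assert dm.y.std(ddof=1) == pytest.approx(1)

    def test_missing_month_drops_year(self):
        resp, temp, prec = self._inputs()
        prec[10, 2] = np.nan  # March precipitation of year 10
        dm = build_design(resp, temp, prec, month_window(200))
        assert 10 not in dm.year_index
        assert dm.X.shape[0] == 23

    def test_year_offsets_shift_columns(self):
        resp, temp, prec = self._inputs()
        window = month_window(171)  # July(prev) .. June(same)
        dm = build_design(resp, temp, prec, window, min_years=5)
        # first analyzable year is year 1: year 0 lacks previous-year months
        assert dm.year_index[0] == 1
        # the first temperature column is July of the previous year
        col = temp[dm.year_index - 1, 6]
        col = (col - col.mean()) / col.std(ddof=1)
        np.testing.assert_allclose(dm.X[:, 0], col, atol=1e-12)

    def test_insufficient_years(self):
        resp, temp, prec = self._inputs(ny=10)
        with pytest.raises(InsufficientDataError):
            build_design(resp, temp, prec, month_window(200), min_years=15)

    def test_zero_variance_response(self):
        resp, temp, prec = self._inputs()
        with pytest.raises(InsufficientDataError):
            build_design(np.full_like(resp, 3.0), temp, prec, month_window(200))

    def test_zero_variance_predictor_dropped(self):
        resp, temp, prec = self._inputs()
        prec[:, :] = 0.0  # all-zero precipitation
        dm = build_design(resp, temp, prec, month_window(200))
        assert dm.kept.sum() == 12
        assert not dm.kept[12:].any()


class TestVIP:
    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(0)
        for A in (1, 3, 5, 10):
            X, y = standardized(rng)
            res = fit_pls(make_dm(X, y), max_components=A, cv_target=2.0)  # force A comps
            _, vip_want = nipals_pls1(X, y, res.n_components)
            np.testing.assert_allclose(res.vip, vip_want, atol=1e-8)

    def test_coefficients_match_oracle(self):
        rng = np.random.default_rng(3)
        X, y = standardized(rng)
        res = fit_pls(make_dm(X, y), max_components=5, cv_target=2.0)
        coef_want, _ = nipals_pls1(X, y, res.n_components)
        np.testing.assert_allclose(res.coefficients, coef_want, atol=1e-8)

    def test_mean_squared_vip_is_one(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            X, y = standardized(rng, n=20, p=10)
            res = fit_pls(make_dm(X, y))
            assert np.mean(res.vip**2) == pytest.approx(1.0, abs=1e-8)

    def test_single_component_reduction(self):
        # orthonormal predictors with weight all on column 0: VIP = (sqrt(p), 0, ...)
        n, p = 32, 8
        X = np.zeros((n, p))
        rng = np.random.default_rng(2)
        for j in range(p):
            X[:, j] = np.sin(np.arange(n) * (j + 1))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = X[:, 0]
        W = np.zeros((p, 1)); W[0, 0] = 1.0
        T = (X @ W)
        vip = vip_scores(W, T, np.array([1.0]))
        assert vip[0] == pytest.approx(np.sqrt(p))
        np.testing.assert_allclose(vip[1:], 0, atol=1e-12)

    def test_response_equal_to_one_predictor(self):
        rng = np.random.default_rng(4)
        X, _ = standardized(rng)
        y = X[:, 7].copy()
        res = fit_pls(make_dm(X, y))
        assert res.coefficients[7] > 0
        assert res.vip[7] >= 0.8 and res.important[7]
        assert res.vip[7] == res.vip.max()
        assert res.explained_variance > 0.99


class TestFitPLS:
    def test_full_rank_limit_equals_ols(self):
        rng = np.random.default_rng(5)
        n, p = 40, 8
        X = rng.normal(size=(n, p))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = X @ rng.normal(size=p) + rng.normal(size=n)
        y = (y - y.mean()) / y.std(ddof=1)
        res = fit_pls(make_dm(X, y), max_components=p, cv_target=2.0)
        assert res.n_components == p
        beta = np.linalg.lstsq(X - X.mean(0), y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(res.coefficients, beta, atol=1e-6)

    def test_component_count_selection(self):
        # a 2-component structure should not need the full cap in fitted mode
        rng = np.random.default_rng(6)
        n = 60
        t1, t2 = rng.normal(size=n), rng.normal(size=n)
        X = np.column_stack([t1 + 0.01 * rng.normal(size=n) for _ in range(5)]
                            + [t2 + 0.01 * rng.normal(size=n) for _ in range(5)])
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = t1 + t2
        y = (y - y.mean()) / y.std(ddof=1)
        res = fit_pls(make_dm(X, y), selection="fitted")
        assert res.n_components <= 3
        assert res.explained_variance >= 0.90

    def test_cap_when_criterion_unreachable(self):
        rng = np.random.default_rng(7)
        X, y = standardized(rng)  # pure noise: Q2 never reaches 0.9
        res = fit_pls(make_dm(X, y), max_components=10)
        assert res.n_components == 10

    def test_unknown_selection_mode(self):
        rng = np.random.default_rng(8)
        X, y = standardized(rng)
        with pytest.raises(ValueError):
            fit_pls(make_dm(X, y), selection="bootstrap")


@pytest.fixture(scope="module")
def coupled_scene():
    cfg = SimulationConfig(
        fine_shape=(10, 10), seed=11,
        couplings=(Coupling(month=4, variable="T", target="bgs", coefficient=-3.0),),
    )
    climate = generate_climate_cube(cfg)
    from phenodrivers import generate_ndvi_cube, phenology_grids, regrid_cube

    cube, _ = generate_ndvi_cube(cfg)
    grids = phenology_grids(cube)
    coarse = regrid_cube(grids, cfg.agg_factor, variables=["bgs_doy"])
    return cfg, coarse, climate, grids


class TestDriverMap:

    def test_injected_driver_recovered(self, coupled_scene):
        cfg, coarse, climate, grids = coupled_scene
        window = month_window(typical_date(grids["bgs_doy"].values))
        dm = driver_map(coarse["bgs_doy"], climate, window)
        labels = list(dm["predictor"].values)
        i = labels.index("T_apr")
        klass = dm["driver_class"].values[i]
        fitted = dm["n_components"].values >= 0
        assert fitted.all()
        # important with negative coefficient in >= 80% of pixels
        assert (klass == 3).mean() >= 0.8

    def test_pure_noise_response_mostly_unimportant(self):
        cfg = SimulationConfig(fine_shape=(20, 20), seed=12, couplings=())
        climate = generate_climate_cube(cfg)  # 4x4 coarse grid
        rng = np.random.default_rng(0)
        noise = xr.DataArray(
            rng.normal(size=(cfg.n_years, *cfg.coarse_shape)),
            dims=("year", "y", "x"),
            coords={"year": climate["year"], "y": climate["y"], "x": climate["x"]},
        )
        dm = driver_map(noise, climate, month_window(200))
        klass = dm["driver_class"].values.reshape(24, -1)
        # no predictor shows a spatially coherent important+signed pattern:
        # neither class reaches the 80% recovery level any true driver shows
        pos_frac = (klass == 2).mean(axis=1)
        neg_frac = (klass == 3).mean(axis=1)
        assert pos_frac.max() < 0.8
        assert neg_frac.max() < 0.8

    def test_insufficient_years_white(self, coupled_scene):
        cfg, coarse, climate, grids = coupled_scene
        short = coarse["bgs_doy"].where(coarse["year"] < coarse["year"].values[6])
        dm = driver_map(short, climate, month_window(200))
        assert (dm["driver_class"].values == 0).all()
        assert (dm["n_components"].values == -1).all()
        assert np.isnan(dm["coefficient"].values).all()
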
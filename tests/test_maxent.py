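"""Maxent core: features, penalized fit vs convex oracle, outputs, evaluation."""

import warnings

import numpy as np
import pytest
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp
from scipy.stats import mannwhitneyu

from alpshift import maxent as mx


def lbfgs_oracle(Fp, Fb, betas):
    """Maximize the penalized objective with a split-variable L-BFGS-B solver."""
    k = Fp.shape[1]
    mean_p = Fp.mean(axis=0)

    def negobj(ab):
        lam = ab[:k] - ab[k:]
        return -(mean_p @ lam) + logsumexp(Fb @ lam) + betas @ (ab[:k] + ab[k:])

    res = minimize(
        negobj, np.zeros(2 * k), method="L-BFGS-B", bounds=[(0, None)] * 2 * k,
        options={"maxiter": 20000, "ftol": 1e-15, "gtol": 1e-12},
    )
    return -res.fun


class TestFeatures:
    def test_combinatorial_count(self):
        rng = np.random.default_rng(0)
        fm = mx.build_features(rng.normal(size=(30, 3)))
        kinds = [k for k, _, _ in fm.features]
        assert kinds.count("linear") == 3
        assert kinds.count("quadratic") == 3
        assert kinds.count("product") == 3

    def test_background_scaling_spans_unit_interval(self):
        rng = np.random.default_rng(1)
        bg = rng.normal(size=(40, 2))
        fm = mx.build_features(bg)
        F = fm.transform(bg)
        np.testing.assert_allclose(F.min(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(F.max(axis=0), 1.0, atol=1e-12)

    def test_constant_axis_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        bg = np.column_stack([rng.normal(size=20), np.full(20, 1.0)])
        with pytest.warns(UserWarning, match="constant"):
            fm = mx.build_features(bg)
        assert all(i == 0 for _, i, _ in fm.features)


class TestFit:
    def test_no_signal_gives_uniform_raw(self):
        rng = np.random.default_rng(3)
        bg = rng.normal(size=(30, 1))
        with pytest.warns(UserWarning, match="constant"):
            fm = mx.build_features(np.full((30, 1), 2.0))
        model = mx.fit_maxent(bg[:5], bg, fm, beta=1.0)
        np.testing.assert_allclose(model.lambdas, 0.0)
        np.testing.assert_allclose(model.raw(bg), 1.0 / 30, atol=1e-12)

    def test_one_dimensional_oracle(self):
        """Worked 1-D problem: fit matches a bounded scalar optimizer."""
        bg = np.array([[0.0], [1 / 3], [2 / 3], [1.0]])
        pres = np.array([[1.0], [1.0]])
        fm = mx.build_features(bg, classes=("linear",))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = mx.fit_maxent(pres, bg, fm, beta=0.05)
        Fp, Fb = fm.transform(pres), fm.transform(bg)
        betas = mx.feature_betas(Fp, 0.05)
        res = minimize_scalar(
            lambda lam: -mx.penalized_objective(np.array([lam]), Fp, Fb, betas),
            bounds=(-100, 100), method="bounded", options={"xatol": 1e-12},
        )
        fitted = mx.penalized_objective(model.lambdas, Fp, Fb, betas)
        assert fitted == pytest.approx(-res.fun, abs=1e-4)

    def test_raw_normalizes_over_background(self):
        rng = np.random.default_rng(4)
        bg = rng.normal(size=(50, 2))
        pres = bg[:12] + 0.1
        fm = mx.build_features(bg)
        model = mx.fit_maxent(pres, bg, fm)
        assert model.raw(bg).sum() == pytest.approx(1.0, abs=1e-6)
        assert 0.0 <= model.entropy <= np.log(50) + 1e-9

    def test_oracle_equivalence_random_instances(self):
        """Fitted objective within 1e-3 of a generic convex-optimizer maximum."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            d = int(rng.integers(1, 4))
            nb = int(rng.integers(20, 51))
            m = int(rng.integers(5, 16))
            bg = rng.normal(size=(nb, d))
            pres = bg[rng.choice(nb, m)] + rng.normal(0, 0.1, (m, d))
            fm = mx.build_features(bg)
            model = mx.fit_maxent(pres, bg, fm, beta=1.0)
            Fp, Fb = fm.transform(pres), fm.transform(bg)
            betas = mx.feature_betas(Fp, 1.0)
            fitted = mx.penalized_objective(model.lambdas, Fp, Fb, betas)
            assert fitted == pytest.approx(lbfgs_oracle(Fp, Fb, betas), abs=1e-3)

    def test_objective_non_increasing_in_beta(self):
        rng = np.random.default_rng(6)
        bg = rng.normal(size=(40, 2))
        pres = bg[:10] + 0.05
        fm = mx.build_features(bg)
        objs = []
        for beta in (0.01, 0.1, 1.0, 10.0):
            model = mx.fit_maxent(pres, bg, fm, beta=beta)
            Fp, Fb = fm.transform(pres), fm.transform(bg)
            objs.append(
                mx.penalized_objective(model.lambdas, Fp, Fb, mx.feature_betas(Fp, beta))
            )
        assert all(a >= b - 1e-9 for a, b in zip(objs, objs[1:]))

    def test_json_round_trip(self):
        rng = np.random.default_rng(7)
        bg = rng.normal(size=(30, 2))
        fm = mx.build_features(bg)
        model = mx.fit_maxent(bg[:8] + 0.2, bg, fm)
        back = mx.MaxentModel.from_json(model.to_json())
        np.testing.assert_allclose(back.raw(bg), model.raw(bg), atol=1e-12)


class TestCloglog:
    def test_uniform_model_gives_1_minus_inv_e(self):
        rng = np.random.default_rng(8)
        bg = rng.normal(size=(25, 1))
        fm = mx.build_features(bg)
        model = mx.MaxentModel(
            feature_map=fm, lambdas=np.zeros(len(fm.features)),
            log_z=np.log(25), entropy=np.log(25), beta=1.0, n_background=25,
        )
        np.testing.assert_allclose(
            mx.predict_cloglog(model, bg), 1.0 - np.exp(-1.0), atol=1e-12
        )

    def test_monotone_in_raw(self):
        rng = np.random.default_rng(9)
        bg = rng.normal(size=(40, 1))
        fm = mx.build_features(bg)
        model = mx.fit_maxent(bg[:10] + 0.5, bg, fm)
        raw = model.raw(bg)
        clog = mx.predict_cloglog(model, bg)
        order = np.argsort(raw)
        assert np.all(np.diff(clog[order]) >= -1e-15)


class TestAUC:
    def test_worked_examples(self):
        assert mx.auc([0.9, 0.8], [0.1, 0.2]) == 1.0
        assert mx.auc([0.5, 0.5], [0.5, 0.5]) == 0.5
        assert mx.auc([0.8, 0.3], [0.5, 0.1]) == 0.75

    def test_equals_mann_whitney_u(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            p = rng.normal(0.5, 1, rng.integers(5, 30))
            b = rng.normal(0, 1, rng.integers(5, 30))
            if rng.random() < 0.3:            # inject ties
                b[: min(3, b.size)] = p[: min(3, b.size)]
            u = mannwhitneyu(p, b).statistic
            assert mx.auc(p, b) == pytest.approx(u / (p.size * b.size), abs=1e-12)


class TestThresholdAndRescale:
    def test_omission_threshold_examples(self):
        scores = np.arange(0.1, 1.01, 0.1)
        assert mx.omission_threshold(scores, 0.10) == pytest.approx(0.2)
        assert mx.omission_threshold(scores, 0.0) == pytest.approx(0.1)
        assert mx.omission_threshold([0.42], 0.10) == pytest.approx(0.42)
        # exactly the scores strictly below the threshold are omitted
        thr = mx.omission_threshold(scores, 0.10)
        assert (scores < thr).sum() == 1

    def test_rescale_rule(self):
        surf = mx.rescale_projection(np.array([[0.1, 0.4, 0.8]]), 0.4)
        np.testing.assert_allclose(surf.values, [[np.nan, 0.0, 1.0]])
        all_below = mx.rescale_projection(np.array([[0.1, 0.2]]), 0.5)
        assert np.isnan(all_below.values).all()
        tie = mx.rescale_projection(np.array([[0.5, 0.2]]), 0.5)
        np.testing.assert_allclose(tie.values, [[1.0, np.nan]])

    def test_rescaled_values_in_unit_interval(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(size=(20, 20))
        surf = mx.rescale_projection(vals, 0.3)
        finite = surf.values[np.isfinite(surf.values)]
        assert finite.min() >= 0.0 and finite.max() == pytest.approx(1.0)

    def test_mask_landcover(self):
        surf = mx.rescale_projection(np.full((4, 4), 0.9), 0.1)
        checker = np.indices((4, 4)).sum(axis=0) % 2
        masked = mx.mask_landcover(surf, checker)
        assert np.isfinite(masked.values).sum() == 8
        identity = mx.mask_landcover(surf, np.ones((4, 4)))
        np.testing.assert_allclose(identity.values, surf.values)
        empty = mx.mask_landcover(surf, np.zeros((4, 4)))
        assert np.isnan(empty.values).all()


@pytest.fixture(scope="module")
def separable_problem():
    rng = np.random.default_rng(12)
    bg = rng.uniform(-3, 3, size=(400, 2))
    pres = rng.normal(1.5, 0.25, size=(40, 2))   # niche s.d. << env range
    return pres, bg, mx.build_features(bg)


class TestBootstrapAndProjection:
    def test_reproducible_and_bounded(self, separable_problem):
        pres, bg, fm = separable_problem
        a = mx.bootstrap_evaluate(pres, bg, fm, n_rep=3, seed=5)
        b = mx.bootstrap_evaluate(pres, bg, fm, n_rep=3, seed=5)
        np.testing.assert_array_equal(a.auc_test, b.auc_test)
        assert np.all((a.auc_test >= 0) & (a.auc_test <= 1))

    def test_separable_species_has_high_test_auc(self, separable_problem):
        pres, bg, fm = separable_problem
        ev = mx.bootstrap_evaluate(pres, bg, fm, n_rep=10, seed=6)
        assert ev.auc_test.mean() > 0.9

    def test_annual_projection_shapes_and_shift(self, separable_problem):
        """A warmer year moves a cold-adapted species' surface upslope."""
        pres, bg, fm = separable_problem
        model = mx.fit_maxent(pres, bg, fm)
        # env axis 0 falls with elevation; year 2 is 'warmer' (axis shifted down)
        elev = np.linspace(400, 3400, 900).reshape(30, 30)
        env1 = np.stack([2.5 - 1e-3 * elev, np.full((30, 30), 1.5)])
        env2 = np.stack([2.9 - 1e-3 * elev, np.full((30, 30), 1.5)])
        surfaces = mx.annual_projection(model, {2000: env1, 2001: env2}, 0.2)
        assert [s.year for s in surfaces] == [2000, 2001]
        same = mx.annual_projection(model, {2000: env1, 2001: env1}, 0.2)
        np.testing.assert_allclose(same[0].values, same[1].values, equal_nan=True)

        def centroid(surface):
            ok = np.isfinite(surface.values)
            return (elev[ok] * surface.values[ok]).sum() / surface.values[ok].sum()

        assert centroid(surfaces[1]) > centroid(surfaces[0])
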
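import numpy as np
import pandas as pd
import pytest

from conftest import small_sim_config
from methdmr.lipidomics import filter_lipids, fit_oplsda, preprocess, vip_scores
from methdmr.simulate import simulate_lipidome
from oracles import nipals_pls1


def _toy(seed=0, n=20, p=30, shift=2.0):
    """Two-class data: half the features shifted between classes."""
    rng = np.random.default_rng(seed)
    y = np.array([-1.0] * (n // 2) + [1.0] * (n // 2))
    X = rng.normal(0, 1, (n, p))
    X[:, : p // 2] += shift * y[:, None] / 2
    return X - X.mean(axis=0), y


class TestPreprocess:
    def _mat(self, seed=1):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.lognormal(10, 1, (15, 8)),
                            index=[f"f{i}" for i in range(15)],
                            columns=[f"s{i}" for i in range(8)])

    def test_centering(self):
        X = preprocess(self._mat(), scaling="none")
        assert np.allclose(X.mean(axis=0), 0, atol=1e-9)

    def test_constant_feature_under_pareto_is_zero(self):
        mat = self._mat()
        mat.loc["f0"] = 5.0
        X = preprocess(mat, scaling="pareto")
        assert np.allclose(X["f0"], 0)

    def test_pareto_variance_equals_raw_sd(self):
        mat = self._mat()
        X = preprocess(mat, scaling="pareto")
        raw_sd = mat.T.std(ddof=1)
        assert np.allclose(X.var(ddof=1), raw_sd, rtol=1e-10)

    def test_unit_variance_drops_constant_features(self):
        mat = self._mat()
        mat.loc["f0"] = 5.0
        X = preprocess(mat, scaling="unit-variance")
        assert "f0" not in X.columns
        assert np.allclose(X.var(ddof=1), 1.0)


class TestOplsda:
    def test_separable_classes_have_positive_margin(self):
        X, y = _toy(shift=4.0)
        model = fit_oplsda(X, y, n_orthogonal=1)
        assert model.t_pred[y > 0].min() > model.t_pred[y < 0].max()

    def test_zero_orthogonal_equals_nipals_pls1(self):
        X, y = _toy(seed=3)
        model = fit_oplsda(X, y, n_orthogonal=0)
        w, t, p, q = nipals_pls1(X, y - y.mean())
        sign = np.sign(w @ model.w_pred)
        assert np.allclose(model.w_pred, sign * w, atol=1e-10)
        assert np.allclose(model.t_pred, sign * t, atol=1e-8)

    def test_zero_orthogonal_matches_sklearn_pls1(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = _toy(seed=5)
        model = fit_oplsda(X, y, n_orthogonal=0)
        pls = sklearn.PLSRegression(n_components=1, scale=False).fit(X, y)
        t_sk = pls.x_scores_[:, 0]
        r = np.corrcoef(model.t_pred, t_sk)[0, 1]
        assert abs(abs(r) - 1) < 1e-8

    def test_orthogonal_scores_uncorrelated_with_y(self):
        X, y = _toy(seed=7, shift=1.0)
        model = fit_oplsda(X, y, n_orthogonal=2)
        yc = y - y.mean()
        for j in range(model.n_orthogonal):
            t_o = model.t_orth[:, j]
            r = (t_o - t_o.mean()) @ yc / (np.linalg.norm(t_o - t_o.mean()) * np.linalg.norm(yc))
            assert abs(r) < 1e-8

    def test_label_swap_negates_scores_keeps_vip(self):
        X, y = _toy(seed=9)
        m1 = fit_oplsda(X, y, n_orthogonal=1)
        m2 = fit_oplsda(X, -y, n_orthogonal=1)
        assert np.allclose(m1.t_pred, -m2.t_pred, atol=1e-9)
        assert np.allclose(m1.vip, m2.vip, atol=1e-12)

    def test_permuted_labels_degrade_q2(self):
        X, y = _toy(seed=11, shift=3.0)
        good = fit_oplsda(X, y, n_orthogonal=1)
        rng = np.random.default_rng(13)
        perm = fit_oplsda(X, rng.permutation(y), n_orthogonal=1)
        assert good.q2 > 0.5
        assert perm.q2 < 0.2  # near or below zero for uninformative labels

    def test_too_many_components_rejected(self):
        X, y = _toy(n=6)
        with pytest.raises(ValueError):
            fit_oplsda(X, y, n_orthogonal=10)


class TestVip:
    def test_single_feature_vip_is_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (10, 1))
        y = np.array([-1.0] * 5 + [1.0] * 5)
        model = fit_oplsda(X - X.mean(0), y, n_orthogonal=0)
        assert model.vip[0] == pytest.approx(1.0)

    def test_informative_feature_scores_above_one(self):
        rng = np.random.default_rng(2)
        y = np.array([-1.0] * 10 + [1.0] * 10)
        X = np.column_stack([y + rng.normal(0, 0.1, 20), rng.normal(0, 1, 20)])
        model = fit_oplsda(X - X.mean(0), y, n_orthogonal=0)
        assert model.vip[0] > 1 > model.vip[1]

    def test_mean_squared_vip_is_one(self):
        X, y = _toy(seed=17)
        for k in (0, 1, 2):
            model = fit_oplsda(X, y, n_orthogonal=k)
            assert abs(np.mean(vip_scores(model) ** 2) - 1) < 1e-10


class TestFilterLipids:
    def test_planted_recovery(self):
        cfg = small_sim_config(seed=6)
        mat, meta, truth = simulate_lipidome(cfg)
        groups = {s: ("A" if s.startswith("CON") else "B") for s in mat.columns}
        y = np.array([1.0 if g == "B" else -1.0 for g in groups.values()])
        scaled = preprocess(mat, scaling="pareto", log_transform=True)
        model = fit_oplsda(scaled.to_numpy(), y, n_orthogonal=1)
        out = filter_lipids(mat, groups, model.vip, group_order=["A", "B"])
        called = set(out.loc[out["significant"], "feature_id"])
        planted = set(truth.lipids["feature_id"])
        assert len(called & planted) >= len(planted) - 2
        assert len(called - planted) <= 2

    def test_vip_exactly_one_excluded(self):
        samples = [f"s{i}" for i in range(8)]
        groups = {s: ("A" if i < 4 else "B") for i, s in enumerate(samples)}
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(rng.lognormal(8, 0.1, (3, 8)), index=["f0", "f1", "f2"], columns=samples)
        mat.loc["f0", samples[4:]] *= 10  # strongly significant
        out = filter_lipids(mat, groups, vip=np.array([1.0, 1.0, 1.0]), group_order=["A", "B"])
        assert not out["significant"].any()  # strict VIP > 1

    def test_no_adjust_variant_uses_raw_p(self):
        samples = [f"s{i}" for i in range(12)]
        groups = {s: ("A" if i < 6 else "B") for i, s in enumerate(samples)}
        rng = np.random.default_rng(8)
        mat = pd.DataFrame(rng.lognormal(8, 0.3, (40, 12)),
                           index=[f"f{i}" for i in range(40)], columns=samples)
        mat.iloc[0, 6:] *= 1.6  # borderline shift: raw p < 0.05 but q above
        vip = np.full(40, 1.2)
        raw = filter_lipids(mat, groups, vip, adjust="none", group_order=["A", "B"])
        fdr = filter_lipids(mat, groups, vip, adjust="fdr", group_order=["A", "B"])
        assert raw["significant"].sum() >= fdr["significant"].sum()
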
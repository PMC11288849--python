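"""Level-1 metadata construction, best-learner rule, meta-learners."""

import numpy as np
import pandas as pd
import pytest

import selstack as ss
from selstack.stacking import (
    LevelOneData,
    _GBLUPGroup,
    build_metadata,
    fit_meta,
    generate_level_one,
    method_name,
    predict_stack,
    select_best,
)


class _OracleGroup:
    """Pass-through learner: predicts the linear signal y = X[:, 0] exactly."""

    names = ("oracle",)

    def fit(self, X, y, seed):
        return self

    def predict_columns(self, X):
        return {"oracle": X[:, 0].astype(float)}


class _NoisyGroup:
    names = ("noisy",)

    def __init__(self):
        self._rng = None

    def fit(self, X, y, seed):
        self._rng = np.random.default_rng(seed)
        self._mean = float(np.mean(y))
        return self

    def predict_columns(self, X):
        return {"noisy": self._mean + self._rng.standard_normal(X.shape[0])}


def _oracle_spec():
    return ss.BaseLearnerSpec(("oracle",), _OracleGroup)


def _noisy_spec():
    return ss.BaseLearnerSpec(("noisy",), _NoisyGroup)


@pytest.fixture()
def linear_data(rng):
    X = rng.integers(0, 3, size=(30, 8)).astype(float)
    y = X[:, 0].astype(float)
    return X, y


def test_oracle_learner_column_equals_target(linear_data):
    X, y = linear_data
    L, groups = generate_level_one([_oracle_spec()], X, y, k_inner=5, seed=1)
    np.testing.assert_allclose(L.predictions["oracle"], y)
    assert L.inner_pa["oracle"] == pytest.approx(1.0)


def test_leave_one_out_bookkeeping(linear_data):
    X, y = linear_data
    n = len(y)
    L, _ = generate_level_one([_oracle_spec()], X[:10], y[:10], k_inner=10, seed=1)
    assert len(L.predictions) == 10
    assert np.isfinite(L.predictions.to_numpy()).all()


def test_level_one_deterministic(linear_data):
    X, y = linear_data
    L1, _ = generate_level_one([_oracle_spec(), _noisy_spec()], X, y, seed=42)
    L2, _ = generate_level_one([_oracle_spec(), _noisy_spec()], X, y, seed=42)
    pd.testing.assert_frame_equal(L1.predictions, L2.predictions)


def test_select_best_rules():
    assert select_best({"A": 0.10, "B": 0.20, "C": 0.30}) == ["C"]
    assert select_best({"A": 0.0, "B": 0.4}) == ["B"]
    with pytest.warns(RuntimeWarning, match="mean"):
        assert set(select_best({"A": 0.15, "B": 0.15, "C": 0.15})) == {"A", "B", "C"}
    with pytest.raises(ValueError):
        select_best({"A": float("nan")})


def _toy_level_one(rng, n=20, k=3):
    cols = {f"L{i}": rng.standard_normal(n) for i in range(k)}
    pa = {f"L{i}": 0.1 * (i + 1) for i in range(k)}
    return LevelOneData(predictions=pd.DataFrame(cols), inner_pa=pa)


def test_build_metadata_variants(rng):
    L = _toy_level_one(rng)
    snp = rng.standard_normal((20, 7))
    assert build_metadata(L, "GEBV-BL").learner_names == ["L0", "L1", "L2"]
    best = build_metadata(L, "GEBV-BL-Best")
    assert best.learner_names == ["L2"]  # PA 0.3 > mean 0.2
    plus = build_metadata(L, "GEBV-BL+SNP", snp_block=snp)
    assert plus.matrix().shape == (20, 3 + 7)
    both = build_metadata(L, "GEBV-BL-Best+SNP", snp_block=snp)
    assert both.matrix().shape == (20, 1 + 7)
    with pytest.raises(ValueError, match="SNP"):
        build_metadata(L, "GEBV-BL+SNP")
    with pytest.raises(ValueError, match="variant"):
        build_metadata(L, "nope")


def test_ssm_mean_of_duplicated_learner(rng):
    col = rng.standard_normal(15)
    L = LevelOneData(predictions=pd.DataFrame({"a": col, "b": col}),
                     inner_pa={"a": 0.5, "b": 0.5})
    meta = fit_meta("SSM", L, rng.standard_normal(15))
    np.testing.assert_allclose(meta.predict(L), col)


def test_ssm_permutation_invariant(rng):
    cols = {c: rng.standard_normal(12) for c in "abc"}
    y = rng.standard_normal(12)
    L1 = LevelOneData(pd.DataFrame(cols), {c: 0.1 for c in "abc"})
    m1 = fit_meta("SSM", L1, y)
    order = ["c", "a", "b"]
    L2 = LevelOneData(pd.DataFrame(cols)[order], {c: 0.1 for c in "abc"})
    m2 = fit_meta("SSM", L2, y)
    np.testing.assert_allclose(m1.predict(L1), m2.predict(L2))


def test_sr_recovers_single_perfect_learner(rng):
    y = rng.standard_normal(25)
    L = LevelOneData(pd.DataFrame({"perfect": y}), {"perfect": 1.0})
    meta = fit_meta("SR", L, y)
    assert meta.params["intercept"] == pytest.approx(0.0, abs=1e-8)
    assert meta.params["coef"][0] == pytest.approx(1.0, abs=1e-8)
    np.testing.assert_allclose(meta.predict(L), y, atol=1e-8)


def test_sr_collinear_warns(rng):
    col = rng.standard_normal(15)
    L = LevelOneData(pd.DataFrame({"a": col, "b": col}), {"a": 0.1, "b": 0.1})
    with pytest.warns(RuntimeWarning, match="collinear"):
        fit_meta("SR", L, rng.standard_normal(15))


def test_swr_weights_nonnegative_sum_to_one(rng):
    n = 40
    signal = rng.standard_normal(n)
    L = LevelOneData(pd.DataFrame({
        "good": signal + 0.1 * rng.standard_normal(n),
        "bad": -signal,
        "meh": rng.standard_normal(n),
    }), {"good": 0.9, "bad": -0.9, "meh": 0.0})
    meta = fit_meta("SWR", L, signal)
    w = meta.params["weights"]
    assert (w >= 0).all()
    assert w.sum() == pytest.approx(1.0)
    assert w[0] > 0.5  # the aligned learner dominates


def test_srr_infinite_penalty_predicts_training_mean(rng):
    y = rng.standard_normal(20) + 3.0
    L = _toy_level_one(rng)
    meta = fit_meta("SRR", L, y, ridge_alpha=np.inf)
    np.testing.assert_allclose(meta.predict(L), y.mean(), atol=1e-8)


def test_srr_selects_penalty_and_predicts(rng):
    n = 60
    signal = rng.standard_normal(n)
    L = LevelOneData(pd.DataFrame({
        "s1": signal + 0.2 * rng.standard_normal(n),
        "s2": signal + 0.2 * rng.standard_normal(n),
    }), {"s1": 0.9, "s2": 0.9})
    meta = fit_meta("SRR", L, signal, seed=0)
    assert meta.params["alpha"] in ss.stacking.RIDGE_GRID
    assert np.corrcoef(meta.predict(L), signal)[0, 1] > 0.9


def test_s2kgblup_requires_snp_block(rng):
    L = _toy_level_one(rng)
    with pytest.raises(ValueError, match="SNP"):
        fit_meta("S2KGBLUP", L, rng.standard_normal(20))


def test_meta_variant_mismatch_errors(rng):
    L = _toy_level_one(rng)
    meta = fit_meta("SSM", L, rng.standard_normal(20))
    snp = rng.standard_normal((20, 4))
    L_snp = build_metadata(L, "GEBV-BL+SNP", snp_block=snp)
    with pytest.raises(ValueError, match="variant"):
        meta.predict(L_snp)


def test_predict_stack_constant_learners_conserved(rng):
    class _ConstGroup:
        names = ("c1", "c2")

        def fit(self, X, y, seed):
            return self

        def predict_columns(self, X):
            return {"c1": np.full(X.shape[0], 7.0),
                    "c2": np.full(X.shape[0], 7.0)}

    X = rng.integers(0, 3, size=(20, 5)).astype(float)
    y = rng.standard_normal(20)
    spec = ss.BaseLearnerSpec(("c1", "c2"), _ConstGroup)
    L, groups = generate_level_one([spec], X, y, k_inner=4, seed=0)
    meta = fit_meta("SSM", L, y)
    out = predict_stack(meta, groups, rng.integers(0, 3, size=(6, 5)).astype(float))
    np.testing.assert_allclose(out, 7.0)


def test_singleton_best_reduces_to_that_learner(linear_data):
    X, y = linear_data
    L, groups = generate_level_one([_oracle_spec(), _noisy_spec()], X, y, seed=5)
    best = build_metadata(L, "GEBV-BL-Best")
    assert best.learner_names == ["oracle"]
    meta = fit_meta("SSM", best, y)
    Xq = np.random.default_rng(0).integers(0, 3, size=(8, 8)).astype(float)
    out = predict_stack(meta, groups, Xq)
    np.testing.assert_allclose(out, Xq[:, 0])


def test_noise_column_shifts_ssm_by_its_share(rng):
    y = rng.standard_normal(18)
    base = {"a": y + 0.1, "b": y - 0.1}
    L2 = LevelOneData(pd.DataFrame(base), {"a": 0.9, "b": 0.9})
    noise = rng.standard_normal(18)
    L3 = LevelOneData(pd.DataFrame({**base, "n": noise}),
                      {"a": 0.9, "b": 0.9, "n": 0.0})
    p2 = fit_meta("SSM", L2, y).predict(L2)
    p3 = fit_meta("SSM", L3, y).predict(L3)
    np.testing.assert_allclose(p3, (2 * p2 + noise) / 3, atol=1e-12)


def test_stacking_model_end_to_end_contract(rng):
    X = rng.integers(0, 3, size=(40, 20)).astype(float)
    y = X[:, 0] + 0.5 * rng.standard_normal(40)
    res = ss.StackingModel(X, y, n_trees=10, seed=1).fit()
    Xq = rng.integers(0, 3, size=(9, 20)).astype(float)
    out = res.predict(Xq)
    assert len(out) == 9
    assert np.isfinite(out.to_numpy()).all()
    # 14 base learners + 5 meta x 4 variants + S2KGBLUP x 2 variants
    assert out.shape[1] == 14 + 22
    assert method_name("SSM", "GEBV-BL-Best") == "SSMBest"


def test_gblup_group_duplicate_row_consistency(rng):
    X = rng.integers(0, 3, size=(25, 40)).astype(float)
    y = rng.standard_normal(25)
    g = _GBLUPGroup().fit(X, y, 0)
    pred_tr = g.predict_columns(X)["GBLUP"]
    pred_q = g.predict_columns(X[3:4])["GBLUP"]
    assert pred_q[0] == pytest.approx(pred_tr[3], abs=1e-8)


def test_sr_is_affine_recalibration_of_single_learner(rng):
    col = rng.standard_normal(25)
    y = 2.0 + 3.0 * col + 0.01 * rng.standard_normal(25)
    L = LevelOneData(pd.DataFrame({"only": col}), {"only": 0.9})
    meta = fit_meta("SR", L, y)
    pred = meta.predict(L)
    # prediction is an affine map of the learner column
    a, b = np.polyfit(col, pred, 1)
    np.testing.assert_allclose(pred, b + a * col, atol=1e-10)
    assert a == pytest.approx(3.0, abs=0.05)
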
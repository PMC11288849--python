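"""Marker centering, VanRaden G, and single/two-kernel GBLUP."""

import numpy as np
import pytest

import selstack as ss
from selstack.data import GenotypeMatrix
from selstack.kernels import KinshipMatrix


def _geno(dosage, prefix="s"):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    return GenotypeMatrix(samples=[f"{prefix}{i}" for i in range(n)],
                          markers=[f"m{j}" for j in range(m)],
                          dosage=np.asarray(dosage, dtype=float))


def _grm_oracle(dosage, p=None):
    """Element-wise double-loop VanRaden G (independent of the fast path)."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    if p is None:
        p = dosage.mean(axis=0) / 2.0
    denom = sum(2.0 * p[j] * (1.0 - p[j]) for j in range(m))
    K = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            K[i, k] = sum((dosage[i, j] - 2 * p[j]) * (dosage[k, j] - 2 * p[j])
                          for j in range(m)) / denom
    return K


def test_center_markers_examples():
    g = _geno([[2.0], [0.0], [1.0]])
    mc = ss.center_markers(g)
    assert mc.p[0] == pytest.approx(0.5)
    np.testing.assert_allclose(mc.W[:, 0], [1.0, -1.0, 0.0])
    # training frequencies applied to other genotypes
    mc2 = ss.center_markers(_geno([[2.0]]), freqs=np.array([0.25]))
    assert mc2.W[0, 0] == pytest.approx(1.5)


def test_center_markers_requires_complete_data():
    g = GenotypeMatrix(samples=["a"], markers=["m"], dosage=np.array([[np.nan]]))
    with pytest.raises(ValueError, match="impute"):
        ss.center_markers(g)


def test_center_all_monomorphic_errors():
    g = _geno([[2.0, 0.0], [2.0, 0.0]])
    with pytest.raises(ValueError, match="monomorphic"):
        ss.center_markers(g)


def test_grm_hand_example():
    g = _geno([[0, 2], [1, 1], [2, 0]])
    K = ss.grm_vanraden(ss.center_markers(g))
    np.testing.assert_allclose(K.values,
                               [[2, 0, -2], [0, 0, 0], [-2, 0, 2]], atol=1e-12)


def test_grm_duplicate_individuals_identical_rows(rng):
    d = rng.integers(0, 3, size=(5, 20)).astype(float)
    d[4] = d[0]
    K = ss.grm_vanraden(ss.center_markers(_geno(d)))
    np.testing.assert_allclose(K.values[0], K.values[4], atol=1e-12)
    np.testing.assert_allclose(K.values[:, 0], K.values[:, 4], atol=1e-12)


def test_grm_matches_double_loop_oracle(rng):
    for _ in range(5):
        d = rng.integers(0, 3, size=(10, 50)).astype(float)
        K = ss.grm_vanraden(ss.center_markers(_geno(d)))
        np.testing.assert_allclose(K.values, _grm_oracle(d), atol=1e-10)


def test_grm_row_sums_vanish(rng):
    d = rng.integers(0, 3, size=(12, 60)).astype(float)
    K = ss.grm_vanraden(ss.center_markers(_geno(d)))
    np.testing.assert_allclose(K.values.sum(axis=1), 0.0, atol=1e-8 * 60)


def test_grm_from_predictions_cases(rng):
    v = rng.standard_normal(8)
    vs = (v - v.mean()) / v.std()
    K1 = ss.grm_from_predictions(vs[:, None])
    np.testing.assert_allclose(K1.values, np.outer(vs, vs), atol=1e-10)
    # duplicated columns leave the kernel unchanged
    K2 = ss.grm_from_predictions(np.column_stack([v, v]))
    np.testing.assert_allclose(K2.values, K1.values, atol=1e-10)
    # orthonormal columns * sqrt(n) give diagonal mean 1
    n = 8
    q, _ = np.linalg.qr(rng.standard_normal((n, 2)))
    cols = q * np.sqrt(n)
    cols = (cols - cols.mean(axis=0)) / cols.std(axis=0)  # standardized inputs
    K3 = ss.grm_from_predictions(cols)
    assert np.diag(K3.values).mean() == pytest.approx(1.0, abs=1e-10)
    with pytest.raises(ValueError, match="constant"):
        ss.grm_from_predictions(np.ones((5, 2)))


def test_gblup_identity_kernel_closed_form():
    K = KinshipMatrix(np.eye(2), ["a", "b"])
    res = ss.fit_gblup(np.array([1.0, -1.0]), K, var_components=(1.0, 1.0))
    np.testing.assert_allclose(res.gebv, [0.5, -0.5], atol=1e-6)
    assert res.beta == pytest.approx(0.0, abs=1e-8)


def test_gblup_zero_genetic_variance():
    K = KinshipMatrix(np.eye(3), list("abc"))
    res = ss.fit_gblup(np.array([1.0, 2.0, 3.0]), K, var_components=(0.0, 1.0))
    np.testing.assert_allclose(res.gebv, 0.0, atol=1e-12)


def test_gblup_equals_marker_ridge(rng):
    # GBLUP GEBVs coincide with W @ alpha-hat from the ridge marker model
    # with penalty sigma_e^2 * denom / sigma_g^2 (same fixed variances)
    n, m = 50, 200
    d = rng.integers(0, 3, size=(n, m)).astype(float)
    mc = ss.center_markers(_geno(d))
    K = ss.grm_vanraden(mc)
    y = rng.standard_normal(n) + mc.W[:, 0]
    sg2, se2 = 0.8, 0.5
    res = ss.fit_gblup(y, K, var_components=(sg2, se2))
    W = mc.W
    lam = se2 * mc.denom / sg2
    alpha = np.linalg.solve(W.T @ W + lam * np.eye(m), W.T @ (y - res.beta))
    np.testing.assert_allclose(res.gebv, W @ alpha, atol=1e-6)


def test_gblup_reml_estimates_reasonable(rng):
    # y dominated by genetic signal through K should give high h2-hat
    n, m = 60, 300
    d = rng.integers(0, 3, size=(n, m)).astype(float)
    mc = ss.center_markers(_geno(d))
    K = ss.grm_vanraden(mc)
    L = np.linalg.cholesky(K.values + 1e-6 * np.eye(n))
    u = L @ rng.standard_normal(n)
    y = u + 0.1 * rng.standard_normal(n)
    res = ss.GBLUP(y, K).fit()
    assert res.heritability > 0.7
    assert np.corrcoef(res.gebv, u)[0, 1] > 0.9


def test_gblup_reorder_invariance(rng):
    n, m = 30, 80
    d = rng.integers(0, 3, size=(n, m)).astype(float)
    mc = ss.center_markers(_geno(d))
    K = ss.grm_vanraden(mc)
    y = rng.standard_normal(n)
    res = ss.GBLUP(y, K).fit()
    perm = rng.permutation(n)
    ids = [K.samples[i] for i in perm]
    res_p = ss.GBLUP(y[perm], K, ids=ids).fit()
    assert res_p.sigma_g2 == pytest.approx(res.sigma_g2, rel=1e-6, abs=1e-10)
    np.testing.assert_allclose(res_p.gebv, res.gebv[perm], atol=1e-8)


def test_predict_duplicate_test_individual(rng):
    n, m = 20, 60
    d = rng.integers(0, 3, size=(n, m)).astype(float)
    d_full = np.vstack([d, d[3]])  # test row duplicates training row 3
    ids = [f"s{i}" for i in range(n)] + ["query"]
    mc = ss.center_markers(_geno(d))
    p = mc.p
    W_full = d_full - 2 * p[None, :]
    K_full = KinshipMatrix(W_full @ W_full.T / mc.denom, ids)
    y = rng.standard_normal(n)
    res = ss.GBLUP(y, K_full, ids=ids[:n]).fit(var_components=(1.0, 0.5))
    pred = ss.predict_gblup(res, K_full, ["query"])
    assert pred[0] == pytest.approx(res.gebv[3], abs=1e-5)


def test_predict_unrelated_test_is_zero():
    K = KinshipMatrix(np.eye(4), list("abcd"))
    res = ss.GBLUP(np.array([1.0, -1.0, 2.0]), K, ids=list("abc")).fit(
        var_components=(1.0, 1.0))
    pred = ss.predict_gblup(res, K, ["d"])
    assert pred[0] == pytest.approx(0.0, abs=1e-10)


def test_predict_matches_full_mme_oracle(rng):
    # treating test phenotypes as missing in the all-individual MME gives the
    # same GEBVs as the explicit BLUP extension
    n, m = 30, 120
    d = rng.integers(0, 3, size=(n, m)).astype(float)
    mc = ss.center_markers(_geno(d))
    K_full = ss.grm_vanraden(mc)
    tr = list(range(22))
    te = list(range(22, 30))
    y = rng.standard_normal(22)
    sg2, se2 = 1.0, 0.7
    ids = K_full.samples
    res = ss.GBLUP(y, K_full, ids=[ids[i] for i in tr]).fit(var_components=(sg2, se2))
    pred = ss.predict_gblup(res, K_full, [ids[i] for i in te])
    # oracle: u = sg2 * K[:, tr] @ V_tr^-1 (y - Xb) from the joint model
    Ktt = K_full.values[np.ix_(tr, tr)]
    V = sg2 * Ktt + se2 * np.eye(len(tr))
    X = np.ones((len(tr), 1))
    Vi = np.linalg.inv(V)
    b = float((X.T @ Vi @ y)[0] / (X.T @ Vi @ X)[0, 0])
    u_all = sg2 * K_full.values[:, tr] @ Vi @ (y - b)
    np.testing.assert_allclose(pred, u_all[te], atol=1e-6)


def test_two_kernel_collinear_matches_single(rng):
    n, m = 25, 80
    d = rng.integers(0, 3, size=(n, m)).astype(float)
    K = ss.grm_vanraden(ss.center_markers(_geno(d)))
    y = rng.standard_normal(n)
    single = ss.GBLUP(y, K).fit()
    two = ss.fit_two_kernel_gblup(y, K, K, var_components=(
        single.sigma_g2 / 2, single.sigma_g2 / 2, single.sigma_e2))
    np.testing.assert_allclose(two.gebv, single.gebv, atol=1e-6)


def test_two_kernel_nested_reduction(rng):
    n, m = 25, 80
    d = rng.integers(0, 3, size=(n, m)).astype(float)
    K1 = ss.grm_vanraden(ss.center_markers(_geno(d)))
    K2 = KinshipMatrix(np.eye(n), K1.samples)
    y = rng.standard_normal(n)
    two = ss.fit_two_kernel_gblup(y, K1, K2, var_components=(0.9, 0.0, 0.4))
    one = ss.GBLUP(y, K1).fit(var_components=(0.9, 0.4))
    np.testing.assert_allclose(two.gebv, one.gebv, atol=1e-6)


def test_two_kernel_variance_recovery():
    # simulate independent effects through two random kernels
    n = 80
    recovered = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        d1 = rng.integers(0, 3, size=(n, 60)).astype(float)
        d2 = rng.integers(0, 3, size=(n, 60)).astype(float)
        K1 = ss.grm_vanraden(ss.center_markers(_geno(d1)))
        K2 = ss.grm_vanraden(ss.center_markers(_geno(d2)))
        L1 = np.linalg.cholesky(K1.values + 1e-8 * np.eye(n))
        L2 = np.linalg.cholesky(K2.values + 1e-8 * np.eye(n))
        y = (np.sqrt(1.0) * L1 @ rng.standard_normal(n)
             + np.sqrt(0.5) * L2 @ rng.standard_normal(n)
             + np.sqrt(0.3) * rng.standard_normal(n))
        fit = ss.fit_two_kernel_gblup(y, K1, K2)
        recovered.append((fit.sigma1_2, fit.sigma2_2))
    m1, m2 = np.mean(recovered, axis=0)
    assert m1 == pytest.approx(1.0, abs=0.3)
    assert m2 == pytest.approx(0.5, abs=0.3)


def test_two_kernel_loglik_nondecreasing(rng):
    n = 30
    d1 = rng.integers(0, 3, size=(n, 40)).astype(float)
    d2 = rng.integers(0, 3, size=(n, 40)).astype(float)
    K1 = ss.grm_vanraden(ss.center_markers(_geno(d1)))
    K2 = ss.grm_vanraden(ss.center_markers(_geno(d2)))
    y = rng.standard_normal(n)
    fit = ss.TwoKernelGBLUP(y, K1, K2).fit(track_loglik=True, max_iter=60)
    ll = np.asarray(fit.loglik_path)
    assert np.all(np.diff(ll) >= -1e-7)


def test_kinship_validation():
    with pytest.raises(ValueError, match="symmetric"):
        KinshipMatrix(np.array([[1.0, 0.5], [0.2, 1.0]]), ["a", "b"])
    with pytest.raises(ValueError, match="square"):
        KinshipMatrix(np.ones((2, 3)), ["a", "b"])
    bad = -np.eye(3)
    with pytest.raises(ValueError, match="positive semi-definite"):
        ss.GBLUP(np.zeros(3), KinshipMatrix(bad, list("abc")))
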
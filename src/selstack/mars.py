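"""Multivariate adaptive regression splines (forward pass + GCV pruning).

The model is f(X) = b0 + sum_m b_m h_m(X) where each basis term h_m is a
product of at most ``degree`` hinge functions (x_j - t)+ or (t - x_j)+ with
knots t at observed values of feature j, and no term multiplies two hinges
on the same feature. The forward pass greedily adds the reflected hinge pair
(parent term x feature/knot) that maximally reduces the training RSS, up to
``max_terms`` terms; the backward pass deletes terms one at a time, keeping
the submodel with the lowest generalized cross-validation score

    GCV = (RSS / N) / (1 - C(M)/N)^2,   C(M) = M + d (M - 1) / 2

with penalty d = 3 per knot-bearing term. Degree 1 is additive; degrees 2
and 3 admit second- and third-order marker interactions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

__all__ = [
    "BasisTerm",
    "MARS",
    "MARSResults",
    "hinge",
    "forward_pass",
    "gcv",
    "backward_pass",
    "fit_mars",
    "predict_mars",
    "default_max_terms",
]

_COLLINEAR_TOL = 1e-10
_RSS_IMPROVE_TOL = 1e-10
_MAX_KNOTS = 32  # thin very fine-grained features to this many candidate knots


def hinge(x, t: float, side: int):
    """Hinge basis value: max(x - t, 0) for side +1, max(t - x, 0) for -1."""
    x = np.asarray(x, dtype=float)
    v = np.maximum(x - t, 0.0) if side > 0 else np.maximum(t - x, 0.0)
    return float(v) if v.ndim == 0 else v


@dataclass(frozen=True)
class BasisTerm:
    """Product of hinge factors (feature, knot, side); empty = intercept."""

    factors: tuple[tuple[int, float, int], ...] = ()

    @property
    def degree(self) -> int:
        return len(self.factors)

    @property
    def features(self) -> frozenset[int]:
        return frozenset(f for f, _, _ in self.factors)

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        out = np.ones(X.shape[0])
        for j, t, side in self.factors:
            out = out * hinge(X[:, j], t, side)
        return out

    def extended(self, j: int, t: float, side: int) -> "BasisTerm":
        return BasisTerm(self.factors + ((j, float(t), int(side)),))

    def __repr__(self) -> str:
        if not self.factors:
            return "1"
        parts = [f"(x{j}-{t:g})+" if s > 0 else f"({t:g}-x{j})+"
                 for j, t, s in self.factors]
        return "*".join(parts)


def design_matrix(terms: Sequence[BasisTerm], X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.column_stack([t.evaluate(X) for t in terms])


def _pruned_lstsq(B: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least squares via pivoted QR, dropping numerically collinear columns.

    Returns coefficients (zeros for dropped columns) and the residual SS.
    """
    n, m = B.shape
    Q, R, piv = scipy.linalg.qr(B, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    scale = diag[0] if diag.size and diag[0] > 0 else 1.0
    rank = int(np.sum(diag > _COLLINEAR_TOL * scale))
    rank = max(rank, 1)
    coef = np.zeros(m)
    rhs = Q.T @ y
    coef_k = scipy.linalg.solve_triangular(R[:rank, :rank], rhs[:rank])
    coef[piv[:rank]] = coef_k
    resid = y - B @ coef
    return coef, float(resid @ resid)


def _orthonormal_basis(B: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing, SVD-based)."""
    U, s, _ = np.linalg.svd(B, full_matrices=False)
    if s.size == 0:
        return U[:, :0]
    keep = s > _COLLINEAR_TOL * s[0] * max(B.shape)
    return U[:, keep]


def default_max_terms(n_features: int) -> int:
    """Forward-pass term budget: min(21, 2*ceil(m/10)+1), at least 3."""
    return max(3, min(21, 2 * int(np.ceil(n_features / 10.0)) + 1))


def _knot_candidates(X: np.ndarray) -> list[np.ndarray]:
    knots = []
    for j in range(X.shape[1]):
        vals = np.unique(X[:, j])
        if len(vals) > _MAX_KNOTS:
            qs = np.linspace(0, 1, _MAX_KNOTS)
            vals = np.unique(np.quantile(vals, qs))
        knots.append(vals)
    return knots


def forward_pass(
    X: np.ndarray,
    y: np.ndarray,
    degree: int = 1,
    max_terms: Optional[int] = None,
) -> list[BasisTerm]:
    """Greedy hinge-pair addition; returns the (overfit) forward basis."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    if max_terms is None:
        max_terms = default_max_terms(m)
    if max_terms < 3:
        raise ValueError("max_terms must be >= 3")
    if n < 2 * max_terms:
        warnings.warn("fewer than 2*max_terms rows; forward pass may overfit",
                      RuntimeWarning)
    knots = _knot_candidates(X)
    feat_idx = np.repeat(np.arange(m), [len(k) for k in knots])
    knot_vals = np.concatenate(knots) if knots else np.empty(0)
    Xrep = X[:, feat_idx]
    plus_all = np.maximum(Xrep - knot_vals[None, :], 0.0)
    minus_all = np.maximum(knot_vals[None, :] - Xrep, 0.0)

    terms: list[BasisTerm] = [BasisTerm()]
    B = np.ones((n, 1))
    Q = B / np.sqrt(n)
    r = y - Q @ (Q.T @ y)

    while len(terms) < max_terms:
        best = None  # (reduction, parent_idx, cand_col, use_plus, use_minus)
        for pi, parent in enumerate(terms):
            if parent.degree >= degree:
                continue
            pv = parent.evaluate(X)
            if not np.any(pv != 0.0):
                continue
            allowed = ~np.isin(feat_idx, list(parent.features))
            if not allowed.any():
                continue
            cols = np.flatnonzero(allowed)
            Cp = pv[:, None] * plus_all[:, cols]
            Cm = pv[:, None] * minus_all[:, cols]
            Ap = Cp - Q @ (Q.T @ Cp)
            Am = Cm - Q @ (Q.T @ Cm)
            g11 = np.einsum("ij,ij->j", Ap, Ap)
            g22 = np.einsum("ij,ij->j", Am, Am)
            g12 = np.einsum("ij,ij->j", Ap, Am)
            b1 = Ap.T @ r
            b2 = Am.T @ r
            scale = float(r @ r) + 1.0
            eps = _COLLINEAR_TOL * n
            red1 = np.where(g11 > eps, b1 ** 2 / np.where(g11 > eps, g11, 1.0), 0.0)
            red2 = np.where(g22 > eps, b2 ** 2 / np.where(g22 > eps, g22, 1.0), 0.0)
            det = g11 * g22 - g12 ** 2
            ok = det > 1e-12 * np.maximum(g11 * g22, eps)
            safe_det = np.where(ok, det, 1.0)
            c1 = (g22 * b1 - g12 * b2) / safe_det
            c2 = (g11 * b2 - g12 * b1) / safe_det
            red_pair = np.where(ok, b1 * c1 + b2 * c2, np.maximum(red1, red2))
            ci = int(np.argmax(red_pair))
            reduction = float(red_pair[ci])
            if best is None or reduction > best[0]:
                best = (reduction, pi, cols[ci],
                        g11[ci] > eps, g22[ci] > eps)
        if best is None or best[0] < _RSS_IMPROVE_TOL:
            break
        _, pi, col, use_plus, use_minus = best
        if not (use_plus or use_minus):
            break
        parent = terms[pi]
        j = int(feat_idx[col])
        t = float(knot_vals[col])
        budget = max_terms - len(terms)
        if use_plus and budget >= 1:
            terms.append(parent.extended(j, t, +1))
            B = np.column_stack([B, parent.evaluate(X) * hinge(X[:, j], t, +1)])
            budget -= 1
        if use_minus and budget >= 1:
            terms.append(parent.extended(j, t, -1))
            B = np.column_stack([B, parent.evaluate(X) * hinge(X[:, j], t, -1)])
        Q = _orthonormal_basis(B)
        r = y - Q @ (Q.T @ y)
    return terms


def gcv(rss: float, N: int, M: int, d: float = 3.0) -> float:
    """Generalized cross-validation score of an M-term submodel.

    Effective parameters C(M) = M + d (M - 1) / 2; returns +inf when
    C(M) >= N (inadmissible submodel).
    """
    if N <= 0:
        raise ValueError("N must be positive")
    c = M + d * (M - 1) / 2.0
    if c >= N:
        return float("inf")
    return (rss / N) / (1.0 - c / N) ** 2


def backward_pass(
    terms: Sequence[BasisTerm],
    X: np.ndarray,
    y: np.ndarray,
    penalty: float = 3.0,
) -> "MARSResults":
    """Prune by iterative deletion, keeping the global GCV minimum submodel."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    terms = list(terms)

    def fit_subset(subset: list[int]):
        B = design_matrix([terms[i] for i in subset], X)
        coef, rss = _pruned_lstsq(B, y)
        return coef, rss

    current = list(range(len(terms)))
    coef, rss = fit_subset(current)
    best = (gcv(rss, n, len(current), penalty), list(current), coef, rss)
    while len(current) > 1:
        best_step = None
        for drop in current[1:]:  # never delete the intercept
            trial = [i for i in current if i != drop]
            coef_t, rss_t = fit_subset(trial)
            g = gcv(rss_t, n, len(trial), penalty)
            if best_step is None or g < best_step[0]:
                best_step = (g, trial, coef_t, rss_t)
        current = best_step[1]
        if best_step[0] < best[0]:
            best = best_step
    g_best, subset, coef, rss = best
    kept = [terms[i] for i in subset]
    return MARSResults(terms=kept, coef=coef, gcv_=g_best, rss=rss,
                       n_forward_terms=len(terms), n_obs=n, penalty=penalty)


@dataclass
class MARSResults:
    """Selected MARS submodel: retained terms and their coefficients."""

    terms: list[BasisTerm]
    coef: np.ndarray
    gcv_: float
    rss: float
    n_forward_terms: int
    n_obs: int
    penalty: float = 3.0

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return design_matrix(self.terms, X) @ self.coef

    def summary(self):
        import pandas as pd

        return pd.DataFrame({
            "term": [repr(t) for t in self.terms],
            "coef": self.coef,
        })


class MARS:
    """Adaptive regression splines model (statsmodels-style fit interface)."""

    def __init__(self, degree: int = 1, max_terms: Optional[int] = None,
                 penalty: float = 3.0):
        if degree not in (1, 2, 3):
            raise ValueError("degree must be 1, 2 or 3")
        self.degree = degree
        self.max_terms = max_terms
        self.penalty = penalty

    def fit(self, X: np.ndarray, y: np.ndarray) -> MARSResults:
        terms = forward_pass(X, y, degree=self.degree, max_terms=self.max_terms)
        return backward_pass(terms, X, y, penalty=self.penalty)


def fit_mars(X: np.ndarray, y: np.ndarray, degree: int = 1,
             max_terms: Optional[int] = None, penalty: float = 3.0) -> MARSResults:
    """Forward + backward MARS fit (functional wrapper)."""
    return MARS(degree=degree, max_terms=max_terms, penalty=penalty).fit(X, y)


def predict_mars(model: MARSResults, X: np.ndarray) -> np.ndarray:
    return model.predict(X)
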
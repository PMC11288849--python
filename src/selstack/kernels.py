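"""Marker coding, VanRaden genomic relationship matrix, and GBLUP.

The additive relationship between individuals is estimated from
column-centered marker dosages: W_ij = dosage_ij - 2 p_j, and

    G = W W' / sum_j 2 p_j (1 - p_j)

(an individual-by-individual kernel, VanRaden's method 1). Single-kernel
GBLUP, y* = X b + Z u + e with u ~ N(0, G sigma_g^2), is fitted by REML via
the spectral decomposition of G, profiling the restricted likelihood over the
variance ratio. The two-kernel variant adds a second independent random
effect with its own kernel (here built from level-1 learner predictions) and
is fitted by EM-REML.

When predicting unphenotyped individuals, their markers are centered with
the *training-set* allele frequencies so that no test information leaks into
the coding.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .data import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerCoding",
    "KinshipMatrix",
    "GBLUP",
    "GBLUPResults",
    "TwoKernelGBLUP",
    "TwoKernelResults",
    "center_markers",
    "grm_vanraden",
    "grm_from_predictions",
    "fit_gblup",
    "predict_gblup",
    "fit_two_kernel_gblup",
]

KERNEL_RIDGE = 1e-8  # numerical floor added to kernel diagonals before inversion


@dataclass
class MarkerCoding:
    """Column-centered marker matrix with its allele frequencies."""

    W: np.ndarray              # n x m centered dosages
    p: np.ndarray              # per-marker alt-allele frequency used to center
    samples: list[str]

    @property
    def denom(self) -> float:
        """VanRaden scaling constant sum_j 2 p_j (1 - p_j)."""
        return float(np.sum(2.0 * self.p * (1.0 - self.p)))


@dataclass
class KinshipMatrix:
    """Symmetric n x n relationship matrix with sample ids."""

    values: np.ndarray
    samples: list[str]
    source: str = "markers"  # "markers" | "predictions"

    def __post_init__(self) -> None:
        K = np.asarray(self.values, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("kinship matrix must be square")
        if K.shape[0] != len(self.samples):
            raise ValueError("kinship dimension does not match sample ids")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric to 1e-10")
        self.values = 0.5 * (K + K.T)

    @property
    def n(self) -> int:
        return len(self.samples)

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        pos = {s: k for k, s in enumerate(self.samples)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise KeyError(f"sample id(s) not in kinship matrix: {missing[:5]}")
        return np.array([pos[i] for i in ids], dtype=int)

    def submatrix(self, rows: Sequence[str], cols: Sequence[str]) -> np.ndarray:
        ri, ci = self.index_of(rows), self.index_of(cols)
        return self.values[np.ix_(ri, ci)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.samples)


def center_markers(
    g: GenotypeMatrix,
    freqs: Optional[np.ndarray] = None,
) -> MarkerCoding:
    """Center dosages by column: W_ij = dosage_ij - 2 p_j.

    ``freqs`` supplies externally computed allele frequencies (typically the
    training set's, applied to test genotypes); otherwise p is computed from
    the data itself.
    """
    dosage = np.asarray(g.dosage, dtype=float)
    if not np.isfinite(dosage).all():
        raise ValueError("missing dosages present; impute before centering")
    if freqs is None:
        p = dosage.mean(axis=0) / 2.0
    else:
        p = np.asarray(freqs, dtype=float)
        if p.shape != (g.n_markers,):
            raise ValueError("freqs length must equal the number of markers")
    if np.all((p <= 0.0) | (p >= 1.0)):
        raise ValueError("all markers are monomorphic; VanRaden denominator is zero")
    W = dosage - 2.0 * p[None, :]
    return MarkerCoding(W=W, p=p, samples=list(g.samples))


def grm_vanraden(mc: MarkerCoding) -> KinshipMatrix:
    """VanRaden genomic relationship matrix G = W W' / sum 2 p (1 - p)."""
    if len(mc.samples) < 2:
        raise ValueError("kinship needs at least 2 individuals")
    denom = mc.denom
    if denom <= 0:
        raise ValueError("VanRaden denominator is zero")
    K = (mc.W @ mc.W.T) / denom
    return KinshipMatrix(values=K, samples=list(mc.samples), source="markers")


def grm_from_predictions(
    L: np.ndarray | pd.DataFrame,
    samples: Optional[list[str]] = None,
    stats: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> KinshipMatrix:
    """Similarity kernel from level-1 prediction columns.

    Columns are standardized to mean 0, variance 1 (constant columns are
    dropped with a warning) and K = P P' / q with q the number of retained
    columns. ``stats`` supplies (mean, sd) computed on training rows so test
    rows can be standardized consistently.
    """
    if isinstance(L, pd.DataFrame):
        if samples is None:
            samples = [str(i) for i in L.index]
        L = L.to_numpy(dtype=float)
    L = np.asarray(L, dtype=float)
    if L.ndim != 2 or L.shape[1] < 1:
        raise ValueError("need at least one prediction column")
    if samples is None:
        samples = [f"S{i}" for i in range(L.shape[0])]
    if stats is None:
        mu, sd = L.mean(axis=0), L.std(axis=0)
    else:
        mu, sd = (np.asarray(a, dtype=float) for a in stats)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all prediction columns are constant")
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} constant prediction column(s)",
                      RuntimeWarning)
    P = (L[:, keep] - mu[keep]) / sd[keep]
    K = P @ P.T / P.shape[1]
    return KinshipMatrix(values=K, samples=list(samples), source="predictions")


# ---------------------------------------------------------------------------
# single-kernel GBLUP
# ---------------------------------------------------------------------------


class GBLUP:
    """y* = X b + Z u + e with u ~ N(0, K sigma_g^2), intercept-only X.

    REML via the spectral decomposition of the projected kernel: with
    P = I - X (X'X)^-1 X', the nonzero eigenpairs of P K P give independent
    contrasts whose restricted likelihood is profiled over the variance
    ratio delta = sigma_e^2 / sigma_g^2 by 1-d optimization.
    """

    def __init__(self, y: np.ndarray, K: KinshipMatrix,
                 ids: Optional[list[str]] = None):
        y = np.asarray(y, dtype=float)
        if ids is None:
            if len(y) != K.n:
                raise ValueError("y length must match kinship dimension")
            ids = list(K.samples)
        idx = K.index_of(ids)
        self.ids = list(ids)
        self.y = y
        self.K = K.values[np.ix_(idx, idx)]
        self.kinship = K
        w = np.linalg.eigvalsh(self.K)
        if w.min() < -1e-8 * max(1.0, abs(w.max())):
            raise ValueError("kinship matrix is not positive semi-definite")

    def fit(self, var_components: Optional[tuple[float, float]] = None) -> "GBLUPResults":
        n = len(self.y)
        X = np.ones((n, 1))
        if var_components is not None:
            sg2, se2 = (float(v) for v in var_components)
            if sg2 < 0 or se2 < 0:
                raise ValueError("variances must be >= 0")
            return self._solve(sg2, se2)
        # REML profile over delta on rotated contrasts
        Px = np.eye(n) - X @ X.T / n
        A = Px @ self.K @ Px
        w, U = np.linalg.eigh(0.5 * (A + A.T))
        order = np.argsort(w)[::-1]
        w, U = w[order[: n - 1]], U[:, order[: n - 1]]
        w = np.clip(w, 0.0, None)
        eta = U.T @ self.y
        eta2 = eta ** 2

        def neg_restricted(log_delta: float) -> float:
            delta = np.exp(log_delta)
            denom = w + delta
            sg2 = float(np.mean(eta2 / denom))
            if sg2 <= 0:
                return np.inf
            return 0.5 * (np.sum(np.log(denom)) + (n - 1) * np.log(sg2))

        grid = np.linspace(-12.0, 12.0, 49)
        vals = [neg_restricted(g) for g in grid]
        k = int(np.argmin(vals))
        lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
        res = minimize_scalar(neg_restricted, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-8})
        delta = float(np.exp(res.x))
        sg2 = float(np.mean(eta2 / (w + delta)))
        se2 = sg2 * delta
        # delta at the grid edges means one component is effectively zero
        if delta >= np.exp(11.5):
            sg2, se2 = 0.0, float(np.var(self.y, ddof=1))
        return self._solve(sg2, se2)

    def _solve(self, sg2: float, se2: float) -> "GBLUPResults":
        n = len(self.y)
        V = sg2 * self.K + (se2 + KERNEL_RIDGE) * np.eye(n)
        Vi = np.linalg.inv(V)
        X = np.ones((n, 1))
        b = float((X.T @ Vi @ self.y)[0] / (X.T @ Vi @ X)[0, 0])
        resid = self.y - b
        u = sg2 * self.K @ (Vi @ resid)
        return GBLUPResults(model=self, beta=b, sigma_g2=sg2, sigma_e2=se2,
                            gebv=u, Vinv_resid=Vi @ resid)


@dataclass
class GBLUPResults:
    model: GBLUP
    beta: float
    sigma_g2: float
    sigma_e2: float
    gebv: np.ndarray            # u-hat for the training individuals
    Vinv_resid: np.ndarray

    @property
    def heritability(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else np.nan

    def predict(self, K_full: KinshipMatrix, test_ids: Sequence[str]) -> np.ndarray:
        """BLUP extension u_test = K_test,train K_train,train^-1 u_train."""
        K_ct = K_full.submatrix(list(test_ids), self.model.ids)
        K_tt = K_full.submatrix(self.model.ids, self.model.ids)
        K_tt = K_tt + KERNEL_RIDGE * np.eye(K_tt.shape[0])
        return K_ct @ np.linalg.solve(K_tt, self.gebv)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": [self.beta, self.sigma_g2, self.sigma_e2, self.heritability]},
            index=["intercept", "sigma_g2", "sigma_e2", "h2_kernel"],
        )


def fit_gblup(y: np.ndarray, K: KinshipMatrix, ids: Optional[list[str]] = None,
              var_components: Optional[tuple[float, float]] = None) -> GBLUPResults:
    """Fit single-kernel GBLUP (functional wrapper)."""
    return GBLUP(y, K, ids=ids).fit(var_components=var_components)


def predict_gblup(result: GBLUPResults, K_full: KinshipMatrix,
                  test_ids: Sequence[str]) -> np.ndarray:
    return result.predict(K_full, test_ids)


# ---------------------------------------------------------------------------
# two-kernel GBLUP
# ---------------------------------------------------------------------------


class TwoKernelGBLUP:
    """y* = X b + u1 + u2 + e with u_k ~ N(0, K_k sigma_k^2), EM-REML fit."""

    def __init__(self, y: np.ndarray, K1: KinshipMatrix, K2: KinshipMatrix,
                 ids: Optional[list[str]] = None):
        y = np.asarray(y, dtype=float)
        if ids is None:
            if list(K1.samples) != list(K2.samples):
                raise ValueError("kernels have different sample ids; pass ids=")
            ids = list(K1.samples)
        self.ids = list(ids)
        self.y = y
        i1, i2 = K1.index_of(ids), K2.index_of(ids)
        self.K1 = K1.values[np.ix_(i1, i1)]
        self.K2 = K2.values[np.ix_(i2, i2)]
        for K in (self.K1, self.K2):
            w = np.linalg.eigvalsh(K)
            if w.min() < -1e-8 * max(1.0, abs(w.max())):
                raise ValueError("kinship matrix is not positive semi-definite")

    def _reml_loglik(self, s1: float, s2: float, se: float) -> float:
        n = len(self.y)
        V = s1 * self.K1 + s2 * self.K2 + se * np.eye(n)
        sign, logdet_v = np.linalg.slogdet(V)
        Vi = np.linalg.inv(V)
        X = np.ones((n, 1))
        XtViX = float((X.T @ Vi @ X)[0, 0])
        P = Vi - (Vi @ X @ X.T @ Vi) / XtViX
        return float(-0.5 * (logdet_v + np.log(XtViX) + self.y @ P @ self.y))

    def fit(self, max_iter: int = 500, tol: float = 1e-8,
            var_components: Optional[tuple[float, float, float]] = None,
            track_loglik: bool = False,
            accelerate: Optional[bool] = None) -> "TwoKernelResults":
        n = len(self.y)
        X = np.ones((n, 1))
        I = np.eye(n)
        if var_components is not None:
            s1, s2, se = (float(v) for v in var_components)
            converged, it, path = True, 0, ()
        else:
            v0 = float(np.var(self.y)) or 1.0
            s1 = s2 = se = v0 / 3.0
            # Aitken jumps counter EM's geometric crawl near boundary
            # components; plain EM is kept when the (monotone) restricted
            # likelihood path is requested
            if accelerate is None:
                accelerate = not track_loglik
            history: list[tuple[float, float, float]] = []
            clamp = 1e-6 * v0
            path_list: list[float] = []
            converged = False
            for it in range(1, max_iter + 1):
                V = s1 * self.K1 + s2 * self.K2 + (se + KERNEL_RIDGE) * I
                Vi = np.linalg.inv(V)
                XtViX = float((X.T @ Vi @ X)[0, 0])
                P = Vi - (Vi @ X @ X.T @ Vi) / XtViX
                Py = P @ self.y
                # EM updates: s_new = s + s^2 (y'P K P y - tr(P K)) / n
                n1 = s1 + (s1 ** 2) * (float(Py @ self.K1 @ Py) - float(np.sum(P * self.K1))) / n
                n2 = s2 + (s2 ** 2) * (float(Py @ self.K2 @ Py) - float(np.sum(P * self.K2))) / n
                ne = se + (se ** 2) * (float(Py @ Py) - float(np.trace(P))) / n
                n1, n2, ne = (max(v, 1e-10) for v in (n1, n2, ne))
                rel = max(abs(n1 - s1) / max(s1, 1e-10), abs(n2 - s2) / max(s2, 1e-10),
                          abs(ne - se) / max(se, 1e-10))
                s1, s2, se = n1, n2, ne
                if track_loglik:
                    path_list.append(self._reml_loglik(s1, s2, se))
                if rel < tol:
                    converged = True
                    break
                if accelerate:
                    history.append((s1, s2, se))
                    if len(history) >= 3 and it % 8 == 0:
                        jumped = []
                        for x1, x2, x3 in zip(*history[-3:]):
                            d1, d2 = x2 - x1, x3 - x2
                            if d1 - d2 != 0 and abs(d2) < abs(d1) and d1 * d2 > 0:
                                lim = max(x3 + d2 * d2 / (d1 - d2), 1e-10)
                                jumped.append(1e-10 if lim < clamp else lim)
                            else:
                                jumped.append(x3)
                        s1, s2, se = jumped
                        history.clear()
            if not converged:
                warnings.warn("two-kernel EM-REML did not converge", RuntimeWarning)
            path = tuple(path_list)
        V = s1 * self.K1 + s2 * self.K2 + (se + KERNEL_RIDGE) * I
        Vi = np.linalg.inv(V)
        b = float((X.T @ Vi @ self.y)[0] / (X.T @ Vi @ X)[0, 0])
        resid = self.y - b
        Vr = Vi @ resid
        u1 = s1 * self.K1 @ Vr
        u2 = s2 * self.K2 @ Vr
        return TwoKernelResults(model=self, beta=b, sigma1_2=s1, sigma2_2=s2,
                                sigma_e2=se, u1=u1, u2=u2, Vinv_resid=Vr,
                                converged=converged, n_iter=it, loglik_path=path)


@dataclass
class TwoKernelResults:
    model: TwoKernelGBLUP
    beta: float
    sigma1_2: float
    sigma2_2: float
    sigma_e2: float
    u1: np.ndarray
    u2: np.ndarray
    Vinv_resid: np.ndarray
    converged: bool = True
    n_iter: int = 0
    loglik_path: tuple[float, ...] = ()

    @property
    def gebv(self) -> np.ndarray:
        """Total genetic prediction: sum of both kernel components."""
        return self.u1 + self.u2

    def predict(self, K1_cross: np.ndarray, K2_cross: np.ndarray) -> np.ndarray:
        """Predictions for new rows given test-by-train kernel blocks."""
        return (self.sigma1_2 * K1_cross + self.sigma2_2 * K2_cross) @ self.Vinv_resid

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": [self.beta, self.sigma1_2, self.sigma2_2, self.sigma_e2]},
            index=["intercept", "sigma1_2", "sigma2_2", "sigma_e2"],
        )


def fit_two_kernel_gblup(y: np.ndarray, K1: KinshipMatrix, K2: KinshipMatrix,
                         ids: Optional[list[str]] = None,
                         **fit_kwargs) -> TwoKernelResults:
    """Fit the two-kernel GBLUP (functional wrapper)."""
    return TwoKernelGBLUP(y, K1, K2, ids=ids).fit(**fit_kwargs)
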
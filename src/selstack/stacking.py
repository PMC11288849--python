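"""Stacked generalization for genomic prediction.

Level 0 fits fourteen base learners on marker dosages with the adjusted
phenotype as target: GBLUP, MARS of degree 1-3, quantile random forests at
tau = 0.1 ... 0.9 (one shared forest: the observation weights do not depend
on tau) and a random forest. Their out-of-fold predictions from an inner
k-fold split form the level-1 metadata, in four variants:

* ``GEBV-BL``          all fourteen prediction columns;
* ``GEBV-BL+SNP``      predictions plus the centered SNP dosage block;
* ``GEBV-BL-Best``     only learners whose inner-fold predictive ability
                       strictly exceeds the across-learner mean;
* ``GEBV-BL-Best+SNP`` the Best subset plus the SNP block.

Level 1 combines the metadata with one of six meta-learners: simple mean
(SSM), non-negative sum-to-one weighted regression (SWR), ordinary least
squares (SR), ridge regression with inner-CV penalty choice (SRR), random
forest (SRF) and, for the +SNP variants, a two-kernel GBLUP (S2KGBLUP) whose
first kernel is the VanRaden matrix of the SNP block and whose second kernel
is the standardized cross-product of the prediction columns.

Out-of-fold level-1 features are the default; ``naive_level1=True`` uses the
in-sample predictions of the refit learners instead (the literal stacking
recipe, which leaks training information).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from ._rng import stage_seed_sequence
from .forests import QuantileRandomForest, RandomForest
from .kernels import (
    KinshipMatrix,
    MarkerCoding,
    TwoKernelGBLUP,
    grm_from_predictions,
    grm_vanraden,
    GBLUP,
)
from .mars import MARS

logger = logging.getLogger(__name__)

__all__ = [
    "VARIANTS",
    "META_KINDS",
    "QRF_TAUS",
    "LevelOneData",
    "MetaLearnerModel",
    "BaseLearnerSpec",
    "default_base_learners",
    "generate_level_one",
    "select_best",
    "build_metadata",
    "fit_meta",
    "predict_stack",
    "StackingModel",
    "StackingResults",
]

VARIANTS = ("GEBV-BL", "GEBV-BL+SNP", "GEBV-BL-Best", "GEBV-BL-Best+SNP")
META_KINDS = ("SSM", "SWR", "SR", "SRR", "SRF", "S2KGBLUP")
QRF_TAUS = tuple(round(0.1 * k, 1) for k in range(1, 10))
RIDGE_GRID = np.logspace(-4, 4, 50)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# base learners
# ---------------------------------------------------------------------------


class _GBLUPGroup:
    """GBLUP base learner on the VanRaden kernel of the training markers."""

    names = ("GBLUP",)

    def __init__(self) -> None:
        self._fit = None

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int) -> "_GBLUPGroup":
        p = X.mean(axis=0) / 2.0
        W = X - 2.0 * p[None, :]
        denom = float(np.sum(2.0 * p * (1.0 - p)))
        if denom <= 0:
            raise ValueError("all training markers monomorphic")
        K = KinshipMatrix(W @ W.T / denom, [f"T{i}" for i in range(len(y))])
        res = GBLUP(y, K).fit()
        self._fit = (p, W, denom, res)
        return self

    def predict_columns(self, X: np.ndarray) -> dict[str, np.ndarray]:
        p, W_tr, denom, res = self._fit
        W_te = X - 2.0 * p[None, :]
        K_cross = W_te @ W_tr.T / denom
        # BLUP extension to unphenotyped rows
        pred = res.sigma_g2 * K_cross @ res.Vinv_resid
        return {"GBLUP": pred}


class _MARSGroup:
    def __init__(self, degree: int, max_terms: Optional[int] = None) -> None:
        self.degree = degree
        self.max_terms = max_terms
        self.names = (f"MARS{degree}",)
        self._fit = None

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int) -> "_MARSGroup":
        self._fit = MARS(degree=self.degree, max_terms=self.max_terms).fit(X, y)
        return self

    def predict_columns(self, X: np.ndarray) -> dict[str, np.ndarray]:
        return {self.names[0]: self._fit.predict(X)}


class _QRFGroup:
    """Nine quantile learners sharing one trained forest."""

    names = tuple(f"QRF{t}" for t in QRF_TAUS)

    def __init__(self, n_trees: int = 500, min_node: int = 5) -> None:
        self.n_trees = n_trees
        self.min_node = min_node
        self._fit = None

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int) -> "_QRFGroup":
        self._fit = QuantileRandomForest(
            n_trees=self.n_trees, min_node=self.min_node, seed=seed
        ).fit(X, y)
        return self

    def predict_columns(self, X: np.ndarray) -> dict[str, np.ndarray]:
        Q = self._fit.predict_quantiles(X, QRF_TAUS)
        return {name: Q[:, k] for k, name in enumerate(self.names)}


class _RFGroup:
    names = ("RF",)

    def __init__(self, n_trees: int = 500, min_node: int = 5) -> None:
        self.n_trees = n_trees
        self.min_node = min_node
        self._fit = None

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int) -> "_RFGroup":
        self._fit = RandomForest(
            n_trees=self.n_trees, min_node=self.min_node, seed=seed
        ).fit(X, y)
        return self

    def predict_columns(self, X: np.ndarray) -> dict[str, np.ndarray]:
        return {"RF": self._fit.predict(X)}


@dataclass
class BaseLearnerSpec:
    """Factory for one group of base learners (a group shares one fit)."""

    names: tuple[str, ...]
    make: Callable[[], object]


def default_base_learners(n_trees: int = 500, min_node: int = 5,
                          mars_max_terms: Optional[int] = None) -> list[BaseLearnerSpec]:
    """The fourteen standard base learners as four fit groups."""
    specs = [BaseLearnerSpec(("GBLUP",), _GBLUPGroup)]
    for d in (1, 2, 3):
        specs.append(BaseLearnerSpec(
            (f"MARS{d}",), lambda d=d: _MARSGroup(d, mars_max_terms)))
    specs.append(BaseLearnerSpec(
        _QRFGroup.names, lambda: _QRFGroup(n_trees=n_trees, min_node=min_node)))
    specs.append(BaseLearnerSpec(
        ("RF",), lambda: _RFGroup(n_trees=n_trees, min_node=min_node)))
    return specs


# ---------------------------------------------------------------------------
# level-1 metadata
# ---------------------------------------------------------------------------


@dataclass
class LevelOneData:
    """Base-learner GEBV columns (plus optional SNP block) for stacking."""

    predictions: pd.DataFrame          # rows = individuals, cols = learners
    inner_pa: dict[str, float]
    variant: str = "GEBV-BL"
    snp: Optional[np.ndarray] = None   # centered dosages aligned with rows
    snp_names: Optional[list[str]] = None
    #: allele frequencies used to center the SNP block (training-set values)
    snp_freq: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        cols = list(self.predictions.columns)
        if len(set(cols)) != len(cols):
            raise ValueError("duplicate learner column names")
        has_snp = self.snp is not None
        if has_snp != self.variant.endswith("+SNP"):
            raise ValueError("SNP block must be present iff the variant has +SNP")
        if has_snp and self.snp.shape[0] != len(self.predictions):
            raise ValueError("SNP block row count mismatch")

    @property
    def learner_names(self) -> list[str]:
        return list(self.predictions.columns)

    def matrix(self) -> np.ndarray:
        """Full feature matrix: learner columns, then the SNP block if any."""
        M = self.predictions.to_numpy(dtype=float)
        if self.snp is not None:
            M = np.hstack([M, self.snp])
        return M


def _kfold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    k = min(max(int(k), 2), n)
    perm = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(perm, k)]


def generate_level_one(
    learners: Sequence[BaseLearnerSpec],
    X_train: np.ndarray,
    y_train: np.ndarray,
    k_inner: int = 5,
    seed: int = 0,
    naive: bool = False,
) -> tuple[LevelOneData, dict[str, object]]:
    """Out-of-fold level-1 metadata plus refit base learners.

    Each learner group is fitted on every inner-fold complement to produce
    leak-free out-of-fold prediction columns, then refitted on all training
    rows for test-time use. A group failing on a fold has all its columns
    dropped with a logged warning. Returns the metadata and the dict of
    refit groups keyed by learner name.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    n = len(y_train)
    cols: dict[str, np.ndarray] = {}
    failed: set[str] = set()
    if not naive:
        rng = np.random.default_rng(stage_seed_sequence(seed, "inner-folds"))
        folds = _kfold_indices(n, k_inner, rng)
        oof: dict[str, np.ndarray] = {
            name: np.full(n, np.nan) for spec in learners for name in spec.names
        }
        for fi, fold in enumerate(folds):
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            for gi, spec in enumerate(learners):
                if set(spec.names) <= failed:
                    continue
                child = int(stage_seed_sequence(seed, f"fold{fi}-group{gi}")
                            .generate_state(1)[0] % (2 ** 31))
                try:
                    fitted = spec.make().fit(X_train[mask], y_train[mask], child)
                    preds = fitted.predict_columns(X_train[fold])
                except Exception as exc:  # pragma: no cover - defensive
                    logger.warning("learner group %s failed on fold %d: %s",
                                   spec.names, fi, exc)
                    failed.update(spec.names)
                    continue
                for name in spec.names:
                    oof[name][fold] = preds[name]
        cols = {k: v for k, v in oof.items() if k not in failed and np.isfinite(v).all()}
    refit: dict[str, object] = {}
    for gi, spec in enumerate(learners):
        if set(spec.names) <= failed:
            continue
        child = int(stage_seed_sequence(seed, f"refit-group{gi}")
                    .generate_state(1)[0] % (2 ** 31))
        try:
            fitted = spec.make().fit(X_train, y_train, child)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("learner group %s failed on refit: %s", spec.names, exc)
            failed.update(spec.names)
            continue
        for name in spec.names:
            refit[name] = fitted
        if naive:
            preds = fitted.predict_columns(X_train)
            for name in spec.names:
                cols[name] = preds[name]
    if not cols:
        raise RuntimeError("every base learner failed; no level-1 metadata")
    frame = pd.DataFrame(cols)
    pa = {name: _pearson(frame[name].to_numpy(), y_train) for name in frame.columns}
    return LevelOneData(predictions=frame, inner_pa=pa, variant="GEBV-BL"), refit


def select_best(inner_pa: dict[str, float]) -> list[str]:
    """Learners whose predictive ability strictly exceeds the mean PA.

    Falls back to all learners (with a warning) when the strict rule selects
    nobody, which happens when every PA is identical.
    """
    finite = {k: v for k, v in inner_pa.items() if np.isfinite(v)}
    if not finite:
        raise ValueError("no learner has a finite predictive ability")
    mean_pa = float(np.mean(list(finite.values())))
    best = [k for k, v in finite.items() if v > mean_pa]
    if not best:
        warnings.warn("no learner exceeds the mean PA; keeping all", RuntimeWarning)
        return list(finite)
    return best


def build_metadata(
    L: LevelOneData,
    variant: str,
    snp_block: Optional[np.ndarray] = None,
    snp_names: Optional[list[str]] = None,
) -> LevelOneData:
    """Assemble one of the four metadata variants from the raw level-1 data."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    preds = L.predictions
    if "Best" in variant:
        if not L.inner_pa:
            raise ValueError("Best variant requires inner predictive abilities")
        keep = select_best(L.inner_pa)
        preds = preds[[c for c in preds.columns if c in keep]]
    snp = None
    names = None
    if variant.endswith("+SNP"):
        if snp_block is None:
            raise ValueError("+SNP variant requires a SNP block")
        snp = np.asarray(snp_block, dtype=float)
        names = snp_names
    pa = {k: v for k, v in L.inner_pa.items() if k in preds.columns}
    return LevelOneData(predictions=preds.copy(), inner_pa=pa, variant=variant,
                        snp=snp, snp_names=names)


# ---------------------------------------------------------------------------
# meta-learners
# ---------------------------------------------------------------------------


@dataclass
class MetaLearnerModel:
    """A fitted level-1 combiner."""

    kind: str
    variant: str
    learner_names: list[str]
    params: dict = field(default_factory=dict)

    def predict(self, L_test: LevelOneData) -> np.ndarray:
        if L_test.variant != self.variant:
            raise ValueError(
                f"metadata variant {L_test.variant!r} does not match the "
                f"fitted variant {self.variant!r}"
            )
        if list(L_test.predictions.columns) != self.learner_names:
            raise ValueError("learner columns differ between fit and predict")
        kind = self.kind
        P = self.params
        cols = L_test.predictions.to_numpy(dtype=float)
        if kind == "SSM":
            return cols.mean(axis=1)
        if kind == "SWR":
            return cols @ P["weights"]
        if kind == "SR":
            return P["intercept"] + L_test.matrix() @ P["coef"]
        if kind == "SRR":
            Z = (L_test.matrix() - P["mu"]) / P["sd"]
            return P["intercept"] + Z @ P["coef"]
        if kind == "SRF":
            return P["forest"].predict(L_test.matrix())
        if kind == "S2KGBLUP":
            # test SNP rows arrive centered with the training frequencies
            K1c = L_test.snp @ P["W_tr"].T / P["denom"]
            keep = P["col_keep"]
            Pte = (cols[:, keep] - P["col_mu"][keep]) / P["col_sd"][keep]
            K2c = Pte @ P["P_tr"].T / P["P_tr"].shape[1]
            return P["beta"] + P["fit"].predict(K1c, K2c)
        raise ValueError(f"unknown meta-learner kind {kind!r}")


def fit_meta(
    kind: str,
    L: LevelOneData,
    y: np.ndarray,
    seed: int = 0,
    ridge_alpha: Optional[float] = None,
    n_trees: int = 500,
    min_node: int = 5,
) -> MetaLearnerModel:
    """Fit one meta-learner on level-1 metadata.

    ``ridge_alpha`` overrides the inner-CV penalty search for SRR (``np.inf``
    shrinks the prediction to the training mean).
    """
    if kind not in META_KINDS:
        raise ValueError(f"unknown meta-learner kind {kind!r}")
    y = np.asarray(y, dtype=float)
    cols = L.predictions.to_numpy(dtype=float)
    names = L.learner_names
    if kind == "SSM":
        return MetaLearnerModel(kind, L.variant, names)
    if kind == "SWR":
        # non-negative least squares, weights normalized to sum to one
        w, _ = scipy.optimize.nnls(cols, y)
        total = w.sum()
        if total <= 0:
            warnings.warn("all SWR weights zero; using equal weights", RuntimeWarning)
            w = np.full(cols.shape[1], 1.0 / cols.shape[1])
        else:
            w = w / total
        return MetaLearnerModel(kind, L.variant, names, {"weights": w})
    M = L.matrix()
    if kind == "SR":
        D = np.column_stack([np.ones(len(y)), M])
        rank = np.linalg.matrix_rank(D)
        if rank < D.shape[1]:
            warnings.warn("collinear level-1 columns; SR solved by pseudo-inverse",
                          RuntimeWarning)
        sol, *_ = np.linalg.lstsq(D, y, rcond=None)
        return MetaLearnerModel(kind, L.variant, names,
                                {"intercept": float(sol[0]), "coef": sol[1:]})
    if kind == "SRR":
        mu, sd = M.mean(axis=0), M.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Z = (M - mu) / sd
        if ridge_alpha is None:
            alpha = _ridge_cv_alpha(Z, y, seed)
        else:
            alpha = float(ridge_alpha)
        if np.isinf(alpha):
            coef = np.zeros(Z.shape[1])
        else:
            coef = _ridge_solve(Z, y - y.mean(), alpha)
        return MetaLearnerModel(kind, L.variant, names,
                                {"mu": mu, "sd": sd, "coef": coef,
                                 "intercept": float(y.mean()), "alpha": alpha})
    if kind == "SRF":
        forest = RandomForest(n_trees=n_trees, min_node=min_node, seed=seed).fit(M, y)
        return MetaLearnerModel(kind, L.variant, names, {"forest": forest})
    if kind == "S2KGBLUP":
        if L.snp is None:
            raise ValueError("S2KGBLUP requires a +SNP metadata variant")
        # kernel 1: VanRaden G of the SNP block (the block holds dosages
        # centered with the training allele frequencies)
        W_tr = np.asarray(L.snp, dtype=float)
        if L.snp_freq is not None:
            denom = float(np.sum(2.0 * L.snp_freq * (1.0 - L.snp_freq)))
        else:
            denom = float(np.trace(W_tr @ W_tr.T) / W_tr.shape[0])
        if denom <= 0:
            raise ValueError("degenerate SNP block: VanRaden denominator is zero")
        ids = [f"T{i}" for i in range(len(y))]
        K1 = KinshipMatrix(W_tr @ W_tr.T / denom, ids, source="markers")
        # kernel 2: standardized cross-product of the prediction columns
        col_mu, col_sd = cols.mean(axis=0), cols.std(axis=0)
        keep = col_sd > 0
        if not keep.any():
            raise ValueError("all prediction columns constant")
        if not keep.all():
            warnings.warn("dropped constant prediction column(s) from the "
                          "S2KGBLUP kernel", RuntimeWarning)
        P_tr = (cols[:, keep] - col_mu[keep]) / col_sd[keep]
        K2 = KinshipMatrix(P_tr @ P_tr.T / P_tr.shape[1], ids, source="predictions")
        fit = TwoKernelGBLUP(y, K1, K2).fit()
        return MetaLearnerModel(kind, L.variant, names,
                                {"W_tr": W_tr, "denom": denom, "P_tr": P_tr,
                                 "col_mu": col_mu, "col_sd": np.where(col_sd > 0, col_sd, 1.0),
                                 "col_keep": keep, "beta": fit.beta, "fit": fit})
    raise AssertionError


def _ridge_solve(Z: np.ndarray, yc: np.ndarray, alpha: float) -> np.ndarray:
    n, p = Z.shape
    if p <= n:
        A = Z.T @ Z + alpha * np.eye(p)
        return np.linalg.solve(A, Z.T @ yc)
    A = Z @ Z.T + alpha * np.eye(n)
    return Z.T @ np.linalg.solve(A, yc)


_VARIANT_SUFFIX = {"GEBV-BL": "", "GEBV-BL-Best": "Best",
                   "GEBV-BL+SNP": "+SNP", "GEBV-BL-Best+SNP": "Best+SNP"}


def method_name(kind: str, variant: str) -> str:
    """Report label of a meta-learner/variant combination (e.g. 'SSMBest')."""
    return kind + _VARIANT_SUFFIX[variant]


def _base_prediction_frame(groups: dict[str, object], names: Sequence[str],
                           X: np.ndarray) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    done: set[int] = set()
    for name in names:
        g = groups[name]
        if id(g) in done:
            continue
        done.add(id(g))
        cols.update(g.predict_columns(X))
    return pd.DataFrame({n: cols[n] for n in names})


def predict_stack(
    meta: MetaLearnerModel,
    refit_groups: dict[str, object],
    X_test: np.ndarray,
    snp_freq: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Apply refit base learners to test rows, rebuild the metadata variant
    the meta-learner was trained on, and return its final GEBVs."""
    X_test = np.asarray(X_test, dtype=float)
    preds = _base_prediction_frame(refit_groups, meta.learner_names, X_test)
    snp = None
    if meta.variant.endswith("+SNP"):
        if snp_freq is None:
            raise ValueError("+SNP prediction needs the training allele frequencies")
        snp = X_test - 2.0 * np.asarray(snp_freq, dtype=float)[None, :]
    L_test = LevelOneData(predictions=preds, inner_pa={}, variant=meta.variant,
                          snp=snp, snp_freq=snp_freq)
    return meta.predict(L_test)


class StackingModel:
    """Two-level stacking ensemble over marker dosages (fit/predict shape).

    Parameters mirror the defaults of the component learners: 500 trees and
    min_node 5 for the forests, mtry = ceil(v/3), inner 5-fold out-of-fold
    metadata. ``naive_level1=True`` switches to in-sample level-1 features.
    """

    def __init__(
        self,
        X_train: np.ndarray,
        y_train: np.ndarray,
        learners: Optional[Sequence[BaseLearnerSpec]] = None,
        k_inner: int = 5,
        seed: int = 0,
        n_trees: int = 500,
        min_node: int = 5,
        mars_max_terms: Optional[int] = None,
        naive_level1: bool = False,
    ) -> None:
        self.X_train = np.asarray(X_train, dtype=float)
        self.y_train = np.asarray(y_train, dtype=float)
        if self.X_train.shape[0] != len(self.y_train):
            raise ValueError("X_train and y_train row counts differ")
        self.learners = list(learners) if learners is not None else \
            default_base_learners(n_trees=n_trees, min_node=min_node,
                                  mars_max_terms=mars_max_terms)
        self.k_inner = k_inner
        self.seed = seed
        self.n_trees = n_trees
        self.min_node = min_node
        self.naive_level1 = naive_level1

    def fit(
        self,
        variants: Sequence[str] = VARIANTS,
        meta_kinds: Sequence[str] = META_KINDS,
    ) -> "StackingResults":
        for v in variants:
            if v not in VARIANTS:
                raise ValueError(f"unknown variant {v!r}")
        freq = self.X_train.mean(axis=0) / 2.0
        snp_block = self.X_train - 2.0 * freq[None, :]
        level_one, groups = generate_level_one(
            self.learners, self.X_train, self.y_train,
            k_inner=self.k_inner, seed=self.seed, naive=self.naive_level1,
        )
        metas: dict[str, MetaLearnerModel] = {}
        for variant in variants:
            L_v = build_metadata(level_one, variant,
                                 snp_block=snp_block if variant.endswith("+SNP") else None)
            if variant.endswith("+SNP"):
                L_v = replace(L_v, snp_freq=freq)
            for kind in meta_kinds:
                if kind == "S2KGBLUP" and not variant.endswith("+SNP"):
                    continue  # needs the SNP kernel by construction
                child = int(stage_seed_sequence(self.seed, f"meta-{kind}-{variant}")
                            .generate_state(1)[0] % (2 ** 31))
                metas[method_name(kind, variant)] = fit_meta(
                    kind, L_v, self.y_train, seed=child,
                    n_trees=self.n_trees, min_node=self.min_node,
                )
        return StackingResults(model=self, level_one=level_one, groups=groups,
                               metas=metas, train_freq=freq)


@dataclass
class StackingResults:
    """Fitted stacking ensemble: level-1 metadata, refit learners, metas."""

    model: StackingModel
    level_one: LevelOneData
    groups: dict[str, object]
    metas: dict[str, MetaLearnerModel]
    train_freq: np.ndarray

    def base_predictions(self, X: np.ndarray) -> pd.DataFrame:
        return _base_prediction_frame(self.groups, self.level_one.learner_names,
                                      np.asarray(X, dtype=float))

    def predict(self, X_test: np.ndarray, include_base: bool = True) -> pd.DataFrame:
        """GEBV columns per method (base learners first, then meta-learners)."""
        X_test = np.asarray(X_test, dtype=float)
        out = {}
        base = self.base_predictions(X_test)
        if include_base:
            out.update({c: base[c].to_numpy() for c in base.columns})
        for name, meta in self.metas.items():
            preds = base[meta.learner_names]
            snp = None
            if meta.variant.endswith("+SNP"):
                snp = X_test - 2.0 * self.train_freq[None, :]
            L_test = LevelOneData(predictions=preds, inner_pa={},
                                  variant=meta.variant, snp=snp,
                                  snp_freq=self.train_freq if snp is not None else None)
            out[name] = meta.predict(L_test)
        return pd.DataFrame(out)

    def summary(self) -> pd.DataFrame:
        pa = self.level_one.inner_pa
        return pd.DataFrame({
            "learner": list(pa),
            "inner_pa": [pa[k] for k in pa],
            "selected_best": [k in select_best(pa) for k in pa],
        })


def _ridge_cv_alpha(Z: np.ndarray, y: np.ndarray, seed: int,
                    k: int = 5, grid: np.ndarray = RIDGE_GRID) -> float:
    """Penalty chosen by inner k-fold CV over a log grid (one SVD per fold)."""
    n = Z.shape[0]
    rng = np.random.default_rng(stage_seed_sequence(seed, "ridge-cv"))
    folds = _kfold_indices(n, k, rng)
    err = np.zeros(len(grid))
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        Ztr, ytr = Z[mask], y[mask]
        Zte, yte = Z[fold], y[fold]
        ybar = ytr.mean()
        U, s, Vt = np.linalg.svd(Ztr, full_matrices=False)
        Uty = U.T @ (ytr - ybar)
        for gi, alpha in enumerate(grid):
            shrink = s / (s ** 2 + alpha)
            coef = Vt.T @ (shrink * Uty)
            pred = ybar + Zte @ coef
            err[gi] += float(np.sum((yte - pred) ** 2))
    return float(grid[int(np.argmin(err))])
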
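"""EM-REML variance components, heritability, and adjusted phenotypes.

The repeated-records analysis model is

    y = X u + Z g + W p + V r + T b + R i + e

with fixed year means ``u`` and independent centered-normal random terms:
progeny genetic effects ``g``, permanent-environment (individual) effects
``p``, population effects ``r``, plot effects ``b``, year-by-progeny
interaction ``i`` and residual ``e``. Variance components are estimated by
EM-REML on Henderson's mixed-model equations; the adjusted phenotype y* of an
individual is the mean of its records after subtracting the estimated year
mean, plot effect and year-by-progeny effect, leaving genetic, permanent-
environment and population signal in y*.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import PhenotypeRecords

logger = logging.getLogger(__name__)

__all__ = [
    "VarianceComponents",
    "AdjustedPhenotypes",
    "VarianceComponentModel",
    "VarianceComponentResults",
    "fit_vc_reml",
    "heritability",
    "adjust_phenotypes",
]

RANDOM_TERMS = ("g", "p", "r", "b", "i")
_TERM_COLUMNS = {"g": "progeny", "p": "id", "r": "population", "b": "plot"}
VARIANCE_FLOOR = 1e-10


@dataclass
class VarianceComponents:
    """Estimated variance components (squared trait units) plus fit metadata."""

    sigma_g2: float
    sigma_p2: float
    sigma_r2: float
    sigma_b2: float
    sigma_i2: float
    sigma_e2: float
    n_iter: int = 0
    converged: bool = True
    loglik: float = np.nan
    dropped_terms: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {"g": self.sigma_g2, "p": self.sigma_p2, "r": self.sigma_r2,
                "b": self.sigma_b2, "i": self.sigma_i2, "e": self.sigma_e2}


@dataclass
class AdjustedPhenotypes:
    """Per-individual adjusted phenotypes y* for one trait."""

    table: pd.DataFrame  # columns: id, trait, ystar
    provenance: str

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    def values_for(self, ids: list[str]) -> np.ndarray:
        s = self.table.set_index("id")["ystar"]
        missing = [i for i in ids if i not in s.index]
        if missing:
            raise KeyError(f"no adjusted phenotype for: {missing[:5]}")
        return s.loc[ids].to_numpy(dtype=float)


def _level_matrix(labels: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = sorted(labels.unique())
    idx = {lv: k for k, lv in enumerate(levels)}
    Z = np.zeros((len(labels), len(levels)))
    Z[np.arange(len(labels)), [idx[v] for v in labels]] = 1.0
    return Z, levels


class VarianceComponentModel:
    """Mixed model for repeated multi-year phenotype records of one trait."""

    def __init__(self, records: PhenotypeRecords, trait: Optional[str] = None,
                 terms: Optional[Sequence[str]] = None):
        if terms is None:
            terms = RANDOM_TERMS
        else:
            unknown = set(terms) - set(RANDOM_TERMS)
            if unknown:
                raise ValueError(f"unknown random term(s): {sorted(unknown)}")
        traits = records.traits
        if trait is None:
            if len(traits) != 1:
                raise ValueError(f"records hold several traits {traits}; pass trait=")
            trait = traits[0]
        self.trait = trait
        self.records = records.for_trait(trait)
        tab = self.records.table
        self.y = tab["value"].to_numpy(dtype=float)
        self.X, self.year_levels = _level_matrix(tab["year"])
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("singular fixed-effect (year) design")
        self.Z: dict[str, np.ndarray] = {}
        self.levels: dict[str, list[str]] = {}
        self.dropped: list[str] = []
        for term in ("g", "p", "r", "b"):
            if term not in terms:
                continue
            col = tab[_TERM_COLUMNS[term]]
            Z, lv = _level_matrix(col)
            if len(lv) < 2:
                self.dropped.append(term)
                logger.warning("random term %r has a single level; dropped", term)
                continue
            self.Z[term] = Z
            self.levels[term] = lv
        if "i" in terms:
            inter = tab["year"].astype(str) + ":" + tab["progeny"].astype(str)
            Zi, lvi = _level_matrix(inter)
            if len(lvi) < 2 or ("g" in terms and "g" in self.dropped):
                self.dropped.append("i")
                logger.warning("year-by-progeny term has a single level; dropped")
            else:
                self.Z["i"] = Zi
                self.levels["i"] = lvi
        self.terms = [t for t in RANDOM_TERMS if t in self.Z]

    # -- restricted log-likelihood (direct V-based evaluation) -------------
    def reml_loglik(self, sigmas: dict[str, float]) -> float:
        n = len(self.y)
        V = sigmas["e"] * np.eye(n)
        for t in self.terms:
            V += sigmas[t] * (self.Z[t] @ self.Z[t].T)
        sign, logdet_v = np.linalg.slogdet(V)
        Vi = np.linalg.inv(V)
        XtViX = self.X.T @ Vi @ self.X
        sign2, logdet_x = np.linalg.slogdet(XtViX)
        P = Vi - Vi @ self.X @ np.linalg.solve(XtViX, self.X.T @ Vi)
        return float(-0.5 * (logdet_v + logdet_x + self.y @ P @ self.y))

    def fit(
        self,
        max_iter: int = 500,
        tol: float = 1e-8,
        start: Optional[dict[str, float]] = None,
        track_loglik: bool = False,
        accelerate: Optional[bool] = None,
    ) -> "VarianceComponentResults":
        y, X = self.y, self.X
        n, p = X.shape
        terms = self.terms
        W = np.hstack([X] + [self.Z[t] for t in terms])
        q = [self.Z[t].shape[1] for t in terms]
        offs = np.cumsum([p] + q)
        WtW = W.T @ W
        Wty = W.T @ y
        yty = float(y @ y)
        v0 = float(np.var(y)) or 1.0
        sig = {t: (start or {}).get(t, v0 / (len(terms) + 1)) for t in terms}
        sig_e = (start or {}).get("e", v0 / (len(terms) + 1))
        # Aitken extrapolation every few sweeps speeds up EM's geometric
        # crawl toward boundary components; plain EM (guaranteed monotone
        # restricted likelihood) is used when the path is being tracked
        if accelerate is None:
            accelerate = not track_loglik
        history: list[dict[str, float]] = []
        loglik_path: list[float] = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            C = WtW.copy()
            for k, t in enumerate(terms):
                lam = sig_e / max(sig[t], VARIANCE_FLOOR)
                sl = slice(offs[k], offs[k + 1])
                C[sl, sl] += lam * np.eye(q[k])
            Cinv = np.linalg.inv(C)
            sol = Cinv @ Wty
            new_e = max((yty - float(sol @ Wty)) / (n - p), VARIANCE_FLOOR)
            # EM shrinks a null component geometrically but never reaches 0;
            # clamp negligible components to the floor so they cannot stall
            # the relative-change convergence test
            clamp = 1e-6 * max(v0, VARIANCE_FLOOR)
            new = {}
            for k, t in enumerate(terms):
                sl = slice(offs[k], offs[k + 1])
                u = sol[sl]
                est = (float(u @ u) + sig_e * float(np.trace(Cinv[sl, sl]))) / q[k]
                new[t] = max(est, VARIANCE_FLOOR) if est >= clamp else VARIANCE_FLOOR
            rel = max(
                [abs(new[t] - sig[t]) / max(sig[t], VARIANCE_FLOOR) for t in terms]
                + [abs(new_e - sig_e) / max(sig_e, VARIANCE_FLOOR)]
            )
            sig, sig_e = new, new_e
            if track_loglik:
                loglik_path.append(self.reml_loglik({**sig, "e": sig_e}))
            if rel < tol:
                converged = True
                break
            if accelerate:
                history.append({**sig, "e": sig_e})
                if len(history) >= 3 and it % 8 == 0:
                    x1, x2, x3 = history[-3], history[-2], history[-1]
                    jumped = dict(sig)
                    jumped_e = sig_e
                    for name in list(sig) + ["e"]:
                        d1 = x2[name] - x1[name]
                        d2 = x3[name] - x2[name]
                        denom = d1 - d2
                        if denom != 0 and abs(d2) < abs(d1) and d1 * d2 > 0:
                            lim = x3[name] + d2 * d2 / denom
                            lim = max(lim, VARIANCE_FLOOR)
                            if lim < clamp:
                                lim = VARIANCE_FLOOR
                            if name == "e":
                                jumped_e = max(lim, VARIANCE_FLOOR)
                            else:
                                jumped[name] = lim
                    sig, sig_e = jumped, jumped_e
                    history.clear()
        if not converged:
            warnings.warn("EM-REML did not converge within max_iter", RuntimeWarning)
        # final solutions at the converged components
        C = WtW.copy()
        for k, t in enumerate(terms):
            lam = sig_e / max(sig[t], VARIANCE_FLOOR)
            sl = slice(offs[k], offs[k + 1])
            C[sl, sl] += lam * np.eye(q[k])
        sol = np.linalg.solve(C, Wty)
        blue = sol[:p]
        blups = {t: sol[offs[k]:offs[k + 1]] for k, t in enumerate(terms)}
        full = {t: sig.get(t, 0.0) for t in RANDOM_TERMS}
        vc = VarianceComponents(
            sigma_g2=full["g"], sigma_p2=full["p"], sigma_r2=full["r"],
            sigma_b2=full["b"], sigma_i2=full["i"], sigma_e2=sig_e,
            n_iter=it, converged=converged,
            loglik=loglik_path[-1] if track_loglik else self.reml_loglik({**sig, "e": sig_e}),
            dropped_terms=tuple(self.dropped),
        )
        return VarianceComponentResults(self, vc, blue, blups,
                                        tuple(loglik_path) if track_loglik else ())


@dataclass
class VarianceComponentResults:
    model: VarianceComponentModel
    components: VarianceComponents
    year_means: np.ndarray
    blups: dict[str, np.ndarray]
    loglik_path: tuple[float, ...] = ()

    def heritability(self, include_plot: bool = False) -> float:
        return heritability(self.components, include_plot=include_plot)

    def blup_for(self, term: str, label: str) -> float:
        if term not in self.blups:
            return 0.0
        return float(self.blups[term][self.model.levels[term].index(label)])

    def adjust_phenotypes(self, mode: str = "corrected_mean") -> AdjustedPhenotypes:
        """Adjusted phenotypes y* per genotyped individual.

        ``corrected_mean`` (default): mean over the individual's records of
        (y - year mean - plot BLUP - year-by-progeny BLUP). ``genetic_blup``:
        progeny BLUP + permanent-environment BLUP instead.
        """
        tab = self.model.records.table
        if mode == "genetic_blup":
            out = []
            for ind, sub in tab.groupby("id", sort=False):
                g = self.blup_for("g", sub["progeny"].iloc[0])
                p = self.blup_for("p", ind)
                out.append((ind, self.model.trait, g + p))
            return AdjustedPhenotypes(
                pd.DataFrame(out, columns=["id", "trait", "ystar"]),
                provenance="genetic+permanent-environment BLUP",
            )
        if mode != "corrected_mean":
            raise ValueError(f"unknown adjustment mode {mode!r}")
        year_of = {lv: self.year_means[k] for k, lv in enumerate(self.model.year_levels)}
        corrected = tab["value"].to_numpy(dtype=float).copy()
        corrected -= np.array([year_of[v] for v in tab["year"]])
        if "b" in self.blups:
            lv = {l: k for k, l in enumerate(self.model.levels["b"])}
            corrected -= self.blups["b"][[lv[v] for v in tab["plot"]]]
        if "i" in self.blups:
            lv = {l: k for k, l in enumerate(self.model.levels["i"])}
            inter = tab["year"].astype(str) + ":" + tab["progeny"].astype(str)
            corrected -= self.blups["i"][[lv[v] for v in inter]]
        df = pd.DataFrame({"id": tab["id"], "ystar": corrected})
        ystar = df.groupby("id", sort=False)["ystar"].mean().reset_index()
        ystar.insert(1, "trait", self.model.trait)
        return AdjustedPhenotypes(ystar, provenance="records minus year, plot, year:progeny")

    def summary(self) -> pd.DataFrame:
        c = self.components
        rows = [("progeny (g)", c.sigma_g2), ("permanent env (p)", c.sigma_p2),
                ("population (r)", c.sigma_r2), ("plot (b)", c.sigma_b2),
                ("year x progeny (i)", c.sigma_i2), ("residual (e)", c.sigma_e2)]
        df = pd.DataFrame(rows, columns=["component", "variance"])
        df["h2"] = ""
        df.loc[len(df)] = ("heritability", self.heritability(), "")
        return df


def fit_vc_reml(records: PhenotypeRecords, trait: Optional[str] = None,
                terms: Optional[Sequence[str]] = None,
                **fit_kwargs) -> VarianceComponentResults:
    """Fit the variance-component model by EM-REML (functional wrapper)."""
    return VarianceComponentModel(records, trait=trait, terms=terms).fit(**fit_kwargs)


def heritability(vc: VarianceComponents, include_plot: bool = False) -> float:
    """Individual heritability sigma_g^2 over the phenotypic variance.

    The plot variance is excluded from the denominator by default (the
    convention adopted here); pass ``include_plot=True`` to add it.
    """
    denom = (vc.sigma_g2 + vc.sigma_p2 + vc.sigma_r2 + vc.sigma_i2 + vc.sigma_e2)
    if include_plot:
        denom += vc.sigma_b2
    # treat floored components as zero for the degenerate check
    if denom <= 10 * VARIANCE_FLOOR:
        raise ValueError("all variance components are zero; heritability undefined")
    return vc.sigma_g2 / denom


def adjust_phenotypes(records: PhenotypeRecords, fit: VarianceComponentResults,
                      mode: str = "corrected_mean") -> AdjustedPhenotypes:
    """Adjusted phenotypes from a fitted variance-component model."""
    return fit.adjust_phenotypes(mode=mode)
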
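"""Repeated-holdout evaluation of base and stacked genomic predictors.

The protocol: split the individuals uniformly at random into 70% training
and 30% testing, fit every base learner and meta-learner on the training
side, predict GEBVs for the test side, and repeat 10 times. Reported per
method: mean predictive ability (Pearson correlation between predicted GEBV
and adjusted phenotype on test individuals), its standard error across
replicates (SD/sqrt(reps)), and mean squared error. Pairwise method
agreement is summarized by the Spearman correlation of pooled test GEBVs
and by the top-decile coincidence (fraction of shared individuals among the
top 10% ranked by each method).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from ._rng import stage_seed_sequence
from .data import GenotypeMatrix
from .pheno import AdjustedPhenotypes
from .stacking import META_KINDS, VARIANTS, StackingModel

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "EvalReport",
    "ExperimentConfig",
    "make_splits",
    "predictive_ability",
    "mse",
    "top_decile_agreement",
    "run_experiment",
]


@dataclass
class SplitPlan:
    """Replicated train/test partitions of n individuals."""

    n: int
    frac: float
    n_reps: int
    seed: int
    replicates: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for tr, te in self.replicates:
            if len(tr) + len(te) != self.n or np.intersect1d(tr, te).size:
                raise ValueError("replicate partitions must be disjoint and exhaustive")


def make_splits(n: int, frac: float = 0.7, n_reps: int = 10, seed: int = 0) -> SplitPlan:
    """Uniform random 70/30 partitions; train size = floor(frac * n)."""
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must lie strictly between 0 and 1")
    if n < 10:
        raise ValueError("need at least 10 individuals to split")
    rng = np.random.default_rng(stage_seed_sequence(seed, "splits"))
    n_train = int(math.floor(frac * n))
    reps = []
    for _ in range(n_reps):
        perm = rng.permutation(n)
        reps.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return SplitPlan(n=n, frac=frac, n_reps=n_reps, seed=seed, replicates=reps)


def predictive_ability(pred: np.ndarray, ystar: np.ndarray) -> float:
    """Pearson correlation between predicted GEBVs and adjusted phenotypes."""
    pred = np.asarray(pred, dtype=float)
    ystar = np.asarray(ystar, dtype=float)
    if len(pred) != len(ystar) or len(pred) < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if pred.std() == 0 or ystar.std() == 0:
        warnings.warn("constant vector: predictive ability undefined", RuntimeWarning)
        return np.nan
    return float(np.corrcoef(pred, ystar)[0, 1])


def mse(pred: np.ndarray, ystar: np.ndarray) -> float:
    pred = np.asarray(pred, dtype=float)
    ystar = np.asarray(ystar, dtype=float)
    if len(pred) != len(ystar):
        raise ValueError("length mismatch")
    return float(np.mean((pred - ystar) ** 2))


def top_decile_agreement(a: np.ndarray, b: np.ndarray, frac: float = 0.1) -> float:
    """Fraction of shared individuals among the top-k of both rankings.

    k = ceil(frac * n); ties at the k-th rank are broken by stable index
    order, so the measure is deterministic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("length mismatch")
    n = len(a)
    k = int(math.ceil(frac * n))
    if k < 1:
        raise ValueError("frac * n must be at least 1")
    top_a = set(np.argsort(-a, kind="stable")[:k].tolist())
    top_b = set(np.argsort(-b, kind="stable")[:k].tolist())
    return len(top_a & top_b) / k


@dataclass
class ExperimentConfig:
    """Settings of one repeated-holdout stacking experiment."""

    n_reps: int = 10
    train_frac: float = 0.7
    k_inner: int = 5
    n_trees: int = 500
    min_node: int = 5
    mars_max_terms: Optional[int] = None
    variants: Sequence[str] = VARIANTS
    meta_kinds: Sequence[str] = META_KINDS
    naive_level1: bool = False
    seed: int = 0
    trait: Optional[str] = None


@dataclass
class EvalReport:
    """Aggregated results of a repeated-holdout experiment."""

    trait: str
    summary: pd.DataFrame          # method, mean_pa, se_pa, mean_mse, gain_vs_gblup_pct
    per_replicate: pd.DataFrame    # method, replicate, pa, mse
    spearman: pd.DataFrame         # pooled-GEBV Spearman matrix
    agreement: pd.DataFrame        # pooled-GEBV top-decile agreement matrix
    pooled: pd.DataFrame           # replicate, index, ystar, one column per method
    n_failed: int = 0

    def spearman_mean_per_replicate(self) -> pd.DataFrame:
        """Within-replicate Spearman matrices averaged over replicates.

        The ``spearman`` attribute (and the CSV export) shows the *pooled*
        presentation; this is the alternative aggregation.
        """
        methods = [c for c in self.pooled.columns
                   if c not in ("replicate", "index", "ystar")]
        mats = []
        for _, block in self.pooled.groupby("replicate"):
            B = block[methods].to_numpy()
            if len(methods) > 2:
                rho = np.atleast_2d(spearmanr(B).statistic)
            elif len(methods) == 2:
                s = float(spearmanr(B[:, 0], B[:, 1]).statistic)
                rho = np.array([[1.0, s], [s, 1.0]])
            else:
                rho = np.ones((1, 1))
            mats.append(rho)
        return pd.DataFrame(np.mean(mats, axis=0), index=methods, columns=methods)

    def to_csv(self, out_dir) -> None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        self.summary.to_csv(f"{out_dir}/summary.csv", index=False)
        self.per_replicate.to_csv(f"{out_dir}/per_replicate.csv", index=False)
        self.spearman.to_csv(f"{out_dir}/spearman.csv")
        self.agreement.to_csv(f"{out_dir}/agreement.csv")

    def plot_heatmaps(self, out_dir) -> None:
        """Spearman / top-decile agreement heatmaps (matplotlib, optional)."""
        import os

        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        os.makedirs(out_dir, exist_ok=True)
        for name, mat in (("spearman", self.spearman), ("agreement", self.agreement)):
            fig, ax = plt.subplots(figsize=(8, 7))
            im = ax.imshow(mat.to_numpy(), vmin=-1 if name == "spearman" else 0,
                           vmax=1, cmap="RdBu_r")
            ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=90, fontsize=6)
            ax.set_yticks(range(len(mat.index)), mat.index, fontsize=6)
            fig.colorbar(im, ax=ax, label=name)
            fig.tight_layout()
            fig.savefig(f"{out_dir}/{name}.png", dpi=150)
            plt.close(fig)


def run_experiment(
    genotypes: GenotypeMatrix,
    adjusted: AdjustedPhenotypes,
    config: ExperimentConfig = ExperimentConfig(),
    split_plan: Optional[SplitPlan] = None,
) -> EvalReport:
    """Repeated 70/30 holdout over all base learners and meta-learners.

    Per replicate: fit the stacking model on the training individuals,
    predict test GEBVs for every method, and record PA and MSE. A failed
    replicate is logged and excluded; at least one must succeed. The
    Spearman and agreement matrices are computed on test GEBVs pooled over
    replicates (each individual contributes once per replicate in which it
    was held out).
    """
    ids = [i for i in genotypes.samples if i in set(adjusted.ids)]
    if len(ids) < 10:
        raise ValueError("fewer than 10 individuals with genotype and phenotype")
    idx = [genotypes.samples.index(i) for i in ids]
    X = np.asarray(genotypes.dosage, dtype=float)[idx]
    if not np.isfinite(X).all():
        raise ValueError("missing dosages present; impute before evaluation")
    y = adjusted.values_for(ids)
    n = len(ids)
    plan = split_plan or make_splits(n, config.train_frac, config.n_reps, config.seed)
    per_rows = []
    pooled_rows = []
    n_failed = 0
    for r, (tr, te) in enumerate(plan.replicates):
        child = int(stage_seed_sequence(config.seed, f"replicate-{r}")
                    .generate_state(1)[0] % (2 ** 31))
        try:
            res = StackingModel(
                X[tr], y[tr], k_inner=config.k_inner, seed=child,
                n_trees=config.n_trees, min_node=config.min_node,
                mars_max_terms=config.mars_max_terms,
                naive_level1=config.naive_level1,
            ).fit(variants=config.variants, meta_kinds=config.meta_kinds)
            preds = res.predict(X[te])
        except Exception as exc:
            logger.warning("replicate %d failed: %s", r, exc)
            n_failed += 1
            continue
        for method in preds.columns:
            p = preds[method].to_numpy()
            per_rows.append((method, r, predictive_ability(p, y[te]), mse(p, y[te])))
        block = preds.copy()
        block.insert(0, "ystar", y[te])
        block.insert(0, "index", te)
        block.insert(0, "replicate", r)
        pooled_rows.append(block)
    if not pooled_rows:
        raise RuntimeError("every replicate failed")
    per = pd.DataFrame(per_rows, columns=["method", "replicate", "pa", "mse"])
    pooled = pd.concat(pooled_rows, ignore_index=True)
    methods = [c for c in pooled.columns if c not in ("replicate", "index", "ystar")]
    agg = per.groupby("method", sort=False).agg(
        mean_pa=("pa", "mean"),
        sd_pa=("pa", lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0),
        mean_mse=("mse", "mean"),
        n_reps=("pa", "size"),
    ).reset_index()
    agg["se_pa"] = agg["sd_pa"] / np.sqrt(agg["n_reps"])
    gblup_pa = agg.loc[agg["method"] == "GBLUP", "mean_pa"]
    ref = float(gblup_pa.iloc[0]) if len(gblup_pa) else np.nan
    agg["gain_vs_gblup_pct"] = 100.0 * agg["mean_pa"] / ref if ref else np.nan
    summary = agg[["method", "mean_pa", "se_pa", "mean_mse", "gain_vs_gblup_pct"]]
    G = pooled[methods].to_numpy(dtype=float)
    if len(methods) > 2:
        rho = np.atleast_2d(spearmanr(G).statistic)
    elif len(methods) == 2:
        s = float(spearmanr(G[:, 0], G[:, 1]).statistic)
        rho = np.array([[1.0, s], [s, 1.0]])
    else:
        rho = np.ones((1, 1))
    spear = pd.DataFrame(rho, index=methods, columns=methods)
    agree = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
    for i, a in enumerate(methods):
        for j in range(i + 1, len(methods)):
            v = top_decile_agreement(G[:, i], G[:, j])
            agree.iloc[i, j] = agree.iloc[j, i] = v
    return EvalReport(trait=adjusted.table["trait"].iloc[0] if len(adjusted.table) else "trait",
                      summary=summary, per_replicate=per, spearman=spear,
                      agreement=agree, pooled=pooled, n_failed=n_failed)
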
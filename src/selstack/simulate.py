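"""Synthetic family-structured population and multi-year trial generator.

Emulates a perennial-crop progeny trial: two small founder pools are crossed
into full-sib families, offspring are genotyped at biallelic SNPs laid out on
a genetic map (Haldane crossovers, no interference), and repeated yearly
records are generated from a variance-component model with year means,
progeny, permanent-environment, population, plot, year-by-progeny and
residual terms. Genetic values can mix additive, dominance and pairwise
(additive-by-additive) epistatic QTL effects so that non-linear learners have
signal to exploit.

The default design mirrors a 13-family x 15-offspring coffee progeny trial
(195 individuals) scored over three years.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .data import GenotypeMatrix, PhenotypeRecords

__all__ = [
    "SimConfig",
    "TrueValues",
    "EffectTable",
    "simulate_population",
    "simulate_architecture",
    "simulate_trials",
    "simulate_dataset",
    "simulate_component_records",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic breeding-trial generator."""

    n_progenies: int = 13
    fam_size: int = 15
    n_markers: int = 1000
    n_chromosomes: int = 11
    chrom_length_cM: float = 100.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int = 100
    #: (additive, dominance, pairwise-epistasis) shares of genetic variance
    variance_shares: tuple[float, float, float] = (1.0, 0.0, 0.0)
    #: target narrow/broad-sense ratio sigma_g^2 / (sigma_g^2+sigma_p^2+
    #: sigma_r^2+sigma_i^2+sigma_e^2); ignored if ``components`` given
    target_h2: float = 0.40
    #: explicit variance components {"p","r","b","i","e"} in squared trait
    #: units; overrides target_h2 when provided
    components: Optional[dict[str, float]] = None
    n_years: int = 3
    n_plots: int = 15
    n_populations: int = 2
    grand_mean: float = 10.0
    year_effect_sd: float = 1.0
    trait: str = "trait"
    seed: int = 2024

    def __post_init__(self) -> None:
        shares = np.asarray(self.variance_shares, dtype=float)
        if (shares < 0).any() or not np.isclose(shares.sum(), 1.0):
            raise ValueError("variance shares must be >= 0 and sum to 1")
        if self.components is not None:
            if any(v < 0 for v in self.components.values()):
                raise ValueError("variance components must be >= 0")
        if self.n_progenies * self.fam_size < 10:
            raise ValueError("population too small: n_progenies*fam_size must be >= 10")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")

    @property
    def n_individuals(self) -> int:
        return self.n_progenies * self.fam_size


@dataclass
class TrueValues:
    """Oracle genetic values of the simulated individuals (trait units)."""

    samples: list[str]
    total: np.ndarray     # total genetic value (additive + dominance + epistasis)
    additive: np.ndarray  # true breeding value

    def __post_init__(self) -> None:
        if not (np.isfinite(self.total).all() and np.isfinite(self.additive).all()):
            raise ValueError("true genetic values must be finite")


@dataclass
class EffectTable:
    """QTL positions and effects, with the centering used to realize them."""

    qtl_idx: np.ndarray         # indices into the marker list
    additive: np.ndarray        # per-QTL additive effect
    dominance: np.ndarray       # per-QTL dominance deviation
    epi_pairs: np.ndarray       # (k, 2) indices into qtl_idx
    epi_effects: np.ndarray     # per-pair additive-by-additive effect
    qtl_freq: np.ndarray        # alt-allele frequency used for centering

    def _codes(self, dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = dosage[:, self.qtl_idx]
        add = x - 2.0 * self.qtl_freq[None, :]          # centered additive coding
        het = (x == 1.0).astype(float)
        dom = het - het.mean(axis=0)                    # centered heterozygosity
        return add, dom

    def component_values(self, dosage: np.ndarray) -> dict[str, np.ndarray]:
        add, dom = self._codes(dosage)
        va = add @ self.additive
        vd = dom @ self.dominance
        if len(self.epi_effects):
            prod = add[:, self.epi_pairs[:, 0]] * add[:, self.epi_pairs[:, 1]]
            prod = prod - prod.mean(axis=0)
            ve = prod @ self.epi_effects
        else:
            ve = np.zeros(dosage.shape[0])
        return {"additive": va, "dominance": vd, "epistasis": ve}

    def genetic_values(self, dosage: np.ndarray) -> np.ndarray:
        comp = self.component_values(dosage)
        return comp["additive"] + comp["dominance"] + comp["epistasis"]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "qtl_idx": self.qtl_idx,
            "additive": self.additive,
            "dominance": self.dominance,
            "freq": self.qtl_freq,
        })
        return df


def _marker_map(cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Assign markers to chromosomes and sorted cM positions."""
    chrom = np.sort(rng.integers(0, cfg.n_chromosomes, size=cfg.n_markers))
    pos = np.empty(cfg.n_markers)
    for c in range(cfg.n_chromosomes):
        m = chrom == c
        pos[m] = np.sort(rng.uniform(0.0, cfg.chrom_length_cM, size=m.sum()))
    return chrom, pos


def _gamete(hap: np.ndarray, chrom: np.ndarray, pos: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """One meiosis of a diploid (2, m) haplotype pair under Haldane's model."""
    m = hap.shape[1]
    out = np.empty(m, dtype=hap.dtype)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        d = np.diff(pos[idx])
        r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))  # Haldane map function
        cross = (rng.random(len(d)) < r).astype(int)
        start = int(rng.integers(0, 2))
        strand = (start + np.concatenate([[0], np.cumsum(cross)])) % 2
        out[idx] = hap[strand, idx]
    return out


def simulate_population(cfg: SimConfig) -> GenotypeMatrix:
    """Cross two founder pools into full-sib families of genotyped offspring.

    Founder haplotype alleles are drawn per marker with alt-allele frequency
    uniform in ``cfg.maf_range``; gametes recombine per chromosome with
    Haldane crossovers. Family (progeny) labels are recorded, and progenies
    are assigned round-robin to ``n_populations`` population labels.
    """
    if cfg.n_markers < cfg.n_chromosomes:
        raise ValueError("n_markers must be >= n_chromosomes")
    rng = stage_rng(cfg.seed, "population")
    chrom, pos = _marker_map(cfg, rng)
    freqs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_markers)
    # founder pools: 3 + 3 diploid parents
    n_pool = 3
    founders = (rng.random((2 * n_pool, 2, cfg.n_markers)) < freqs).astype(np.int8)
    pool_a, pool_b = founders[:n_pool], founders[n_pool:]
    crosses = [(i % n_pool, (i // n_pool) % n_pool) for i in range(cfg.n_progenies)]
    dosage = np.empty((cfg.n_individuals, cfg.n_markers))
    samples, family, population = [], [], []
    row = 0
    for f, (ia, ib) in enumerate(crosses):
        fam = f"F{f + 1:02d}"
        pop = f"P{(f % cfg.n_populations) + 1}"
        for k in range(cfg.fam_size):
            g1 = _gamete(pool_a[ia], chrom, pos, rng)
            g2 = _gamete(pool_b[ib], chrom, pos, rng)
            dosage[row] = g1 + g2
            samples.append(f"{fam}_I{k + 1:02d}")
            family.append(fam)
            population.append(pop)
            row += 1
    return GenotypeMatrix(samples=samples, markers=[f"M{j + 1:04d}" for j in range(cfg.n_markers)],
                          dosage=dosage, family=family, population=population)


def _rescale(component: np.ndarray, target_var: float) -> float:
    """Return the factor scaling effects so var(component) == target_var."""
    v = component.var()
    if target_var == 0.0:
        return 0.0
    if v <= 0:
        raise ValueError("component has zero realized variance; cannot match share")
    return float(np.sqrt(target_var / v))


def simulate_architecture(g: GenotypeMatrix, cfg: SimConfig) -> EffectTable:
    """Sample QTL effects and rescale so realized variance shares match cfg.

    Additive effects, dominance deviations and pairwise additive-by-additive
    epistatic effects are drawn from standard normals, then each component is
    rescaled so its realized variance share (over the simulated individuals)
    matches ``cfg.variance_shares`` exactly; total genetic variance is 1.
    """
    if cfg.n_qtl > g.n_markers:
        raise ValueError("n_qtl cannot exceed the number of markers")
    sa, sd, se = cfg.variance_shares
    if se > 0 and cfg.n_qtl < 2:
        raise ValueError("pairwise epistasis requires n_qtl >= 2")
    rng = stage_rng(cfg.seed, "effects")
    qtl = np.sort(rng.choice(g.n_markers, size=cfg.n_qtl, replace=False))
    p = g.dosage[:, qtl].mean(axis=0) / 2.0
    a = rng.standard_normal(cfg.n_qtl)
    d = rng.standard_normal(cfg.n_qtl)
    n_pairs = min(cfg.n_qtl, cfg.n_qtl * (cfg.n_qtl - 1) // 2)
    if se > 0:
        pair_ids = rng.choice(cfg.n_qtl * (cfg.n_qtl - 1) // 2, size=n_pairs, replace=False)
        # map linear index to (i < j) pair
        ii, jj = np.triu_indices(cfg.n_qtl, k=1)
        pairs = np.column_stack([ii[pair_ids], jj[pair_ids]])
        w = rng.standard_normal(n_pairs)
    else:
        pairs = np.empty((0, 2), dtype=int)
        w = np.empty(0)
    table = EffectTable(qtl_idx=qtl, additive=a, dominance=d if sd > 0 else np.zeros_like(d),
                        epi_pairs=pairs, epi_effects=w, qtl_freq=p)
    comp = table.component_values(g.dosage)
    table.additive = a * _rescale(comp["additive"], sa)
    if sd > 0:
        table.dominance = d * _rescale(comp["dominance"], sd)
    else:
        table.dominance = np.zeros_like(d)
    if se > 0:
        table.epi_effects = w * _rescale(comp["epistasis"], se)
    return table


def _nuisance_components(vg: float, cfg: SimConfig) -> dict[str, float]:
    if cfg.components is not None:
        comps = {k: float(cfg.components.get(k, 0.0)) for k in ("p", "r", "b", "i", "e")}
        if any(v < 0 for v in comps.values()):
            raise ValueError("negative variance component")
        return comps
    h2 = cfg.target_h2
    if not 0 < h2 <= 1:
        raise ValueError("target_h2 must lie in (0, 1]")
    total = vg / h2
    budget = total - vg
    # split of the non-genetic denominator variance: mostly residual, with
    # moderate year-by-progeny and permanent-environment terms
    comps = {"p": 0.15 * budget, "r": 0.05 * budget, "i": 0.20 * budget,
             "e": 0.60 * budget, "b": 0.05 * total}
    return comps


def simulate_trials(
    g: GenotypeMatrix,
    effects: EffectTable,
    cfg: SimConfig,
) -> tuple[PhenotypeRecords, TrueValues]:
    """Generate repeated yearly records from the variance-component model.

    Each record is year mean + genetic value + permanent-environment +
    population + plot + year-by-progeny + residual, every random term drawn
    from a centered normal with its variance. Plot membership is assigned
    once at 'planting' and kept across years.
    """
    rng = stage_rng(cfg.seed, "trials")
    n = g.n_samples
    gv = effects.genetic_values(g.dosage)
    comp = effects.component_values(g.dosage)
    true = TrueValues(samples=list(g.samples), total=gv, additive=comp["additive"])
    vg = float(gv.var())
    comps = _nuisance_components(vg, cfg)
    years = [f"Y{k + 1}" for k in range(cfg.n_years)]
    year_mean = cfg.grand_mean + rng.normal(0.0, cfg.year_effect_sd, size=cfg.n_years)
    fam = g.family if g.family is not None else ["F01"] * n
    pops = g.population if g.population is not None else ["P1"] * n
    fam_levels = sorted(set(fam))
    pop_levels = sorted(set(pops))
    plot_of = rng.integers(0, cfg.n_plots, size=n)
    p_eff = rng.normal(0.0, np.sqrt(comps["p"]), size=n)
    r_eff = rng.normal(0.0, np.sqrt(comps["r"]), size=len(pop_levels))
    b_eff = rng.normal(0.0, np.sqrt(comps["b"]), size=cfg.n_plots)
    i_eff = rng.normal(0.0, np.sqrt(comps["i"]), size=(cfg.n_years, len(fam_levels)))
    fam_idx = np.array([fam_levels.index(f) for f in fam])
    pop_idx = np.array([pop_levels.index(p) for p in pops])
    rows = []
    for yk, year in enumerate(years):
        e = rng.normal(0.0, np.sqrt(comps["e"]), size=n)
        value = (year_mean[yk] + gv + p_eff + r_eff[pop_idx] + b_eff[plot_of]
                 + i_eff[yk, fam_idx] + e)
        for i in range(n):
            rows.append((g.samples[i], fam[i], pops[i], year,
                         f"PL{plot_of[i] + 1:02d}", cfg.trait, value[i]))
    table = pd.DataFrame(rows, columns=["id", "progeny", "population", "year",
                                        "plot", "trait", "value"])
    return PhenotypeRecords(table), true


def simulate_dataset(cfg: SimConfig) -> tuple[GenotypeMatrix, PhenotypeRecords, TrueValues, EffectTable]:
    """Convenience wrapper: population -> architecture -> trials."""
    g = simulate_population(cfg)
    eff = simulate_architecture(g, cfg)
    records, true = simulate_trials(g, eff, cfg)
    return g, records, true, eff


def simulate_component_records(
    vc: dict[str, float],
    n_progenies: int = 13,
    fam_size: int = 15,
    n_years: int = 3,
    n_plots: int = 15,
    n_populations: int = 2,
    grand_mean: float = 10.0,
    year_effect_sd: float = 1.0,
    trait: str = "trait",
    seed: int = 0,
) -> PhenotypeRecords:
    """Draw records directly from the variance-component analysis model.

    Every random term (progeny ``g``, permanent environment ``p``, population
    ``r``, plot ``b``, year-by-progeny ``i``, residual ``e``) is sampled from
    a centered normal with the variance given in ``vc``. This is the oracle
    generator for variance-component and heritability recovery checks.
    """
    comps = {k: float(vc.get(k, 0.0)) for k in ("g", "p", "r", "b", "i", "e")}
    if any(v < 0 for v in comps.values()):
        raise ValueError("negative variance component")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), *b"components"]))
    n = n_progenies * fam_size
    fam_idx = np.repeat(np.arange(n_progenies), fam_size)
    pop_idx = fam_idx % n_populations
    plot_of = rng.integers(0, n_plots, size=n)
    year_mean = grand_mean + rng.normal(0.0, year_effect_sd, size=n_years)
    g_eff = rng.normal(0.0, np.sqrt(comps["g"]), size=n_progenies)
    p_eff = rng.normal(0.0, np.sqrt(comps["p"]), size=n)
    r_eff = rng.normal(0.0, np.sqrt(comps["r"]), size=n_populations)
    b_eff = rng.normal(0.0, np.sqrt(comps["b"]), size=n_plots)
    i_eff = rng.normal(0.0, np.sqrt(comps["i"]), size=(n_years, n_progenies))
    rows = []
    for yk in range(n_years):
        e = rng.normal(0.0, np.sqrt(comps["e"]), size=n)
        value = (year_mean[yk] + g_eff[fam_idx] + p_eff + r_eff[pop_idx]
                 + b_eff[plot_of] + i_eff[yk, fam_idx] + e)
        for i in range(n):
            rows.append((f"F{fam_idx[i] + 1:02d}_I{i % fam_size + 1:02d}",
                         f"F{fam_idx[i] + 1:02d}", f"P{pop_idx[i] + 1}",
                         f"Y{yk + 1}", f"PL{plot_of[i] + 1:02d}", trait, value[i]))
    table = pd.DataFrame(rows, columns=["id", "progeny", "population", "year",
                                        "plot", "trait", "value"])
    return PhenotypeRecords(table)
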
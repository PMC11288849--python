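"""Core containers for genotype and phenotype data.

Dosage orientation is fixed throughout the package: a cell holds the count of
the alternate (second) allele, so 2 = homozygous alt ("AA" in the usual
genomic-selection coding), 1 = heterozygous, 0 = homozygous reference.
Missing calls are stored as ``numpy.nan``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeRecords",
    "QCReport",
    "qc_filter",
    "impute_missing",
]

PHENOTYPE_COLUMNS = ["id", "progeny", "population", "year", "plot", "trait", "value"]


def _check_unique(ids: Sequence[str], kind: str) -> None:
    dupes = [k for k, c in Counter(ids).items() if c > 1]
    if dupes:
        raise ValueError(f"duplicate {kind} id(s): {', '.join(map(str, sorted(dupes)))}")


@dataclass
class GenotypeMatrix:
    """n samples x m biallelic markers as alt-allele dosages {0, 1, 2, nan}."""

    samples: list[str]
    markers: list[str]
    dosage: np.ndarray  # float array, nan = missing
    family: Optional[list[str]] = None
    population: Optional[list[str]] = None
    #: imputed matrices carry fractional dosages in [0, 2]; raw calls are {0,1,2}
    continuous: bool = False

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        _check_unique(self.samples, "sample")
        _check_unique(self.markers, "marker")
        finite = self.dosage[np.isfinite(self.dosage)]
        if self.continuous:
            if finite.size and ((finite < 0) | (finite > 2)).any():
                raise ValueError("continuous dosages must lie in [0, 2]")
        elif finite.size and not np.isin(finite, [0.0, 1.0, 2.0]).all():
            bad = finite[~np.isin(finite, [0.0, 1.0, 2.0])]
            raise ValueError(f"non-missing dosages must be in {{0,1,2}}; found {bad[:5]}")
        for label, values in (("family", self.family), ("population", self.population)):
            if values is not None and len(values) != len(self.samples):
                raise ValueError(f"{label} labels must match the number of samples")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def is_missing(self) -> np.ndarray:
        return ~np.isfinite(self.dosage)

    def call_rate(self) -> np.ndarray:
        """Per-marker fraction of non-missing calls."""
        return np.isfinite(self.dosage).mean(axis=0)

    def allele_frequency(self) -> np.ndarray:
        """Per-marker alt-allele frequency over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def minor_allele_frequency(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        markers = [m for m, k in zip(self.markers, keep) if k]
        return GenotypeMatrix(
            samples=list(self.samples),
            markers=markers,
            dosage=self.dosage[:, keep].copy(),
            family=None if self.family is None else list(self.family),
            population=None if self.population is None else list(self.population),
            continuous=self.continuous,
        )

    def subset_samples(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            markers=list(self.markers),
            dosage=self.dosage[idx, :].copy(),
            family=None if self.family is None else [self.family[i] for i in idx],
            population=None if self.population is None else [self.population[i] for i in idx],
            continuous=self.continuous,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dosage, index=pd.Index(self.samples, name="id"),
                          columns=self.markers)
        if self.population is not None:
            df.insert(0, "population", self.population)
        if self.family is not None:
            df.insert(0, "family", self.family)
        return df


@dataclass
class PhenotypeRecords:
    """Long-format repeated phenotype records.

    Columns: id, progeny, population, year, plot, trait, value.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PHENOTYPE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"phenotype table missing column(s): {missing}")
        self.table = self.table[PHENOTYPE_COLUMNS].reset_index(drop=True)
        values = self.table["value"].to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("phenotype values must be finite")

    @property
    def individuals(self) -> list[str]:
        return list(pd.unique(self.table["id"]))

    @property
    def traits(self) -> list[str]:
        return list(pd.unique(self.table["trait"]))

    def for_trait(self, trait: str) -> "PhenotypeRecords":
        sub = self.table[self.table["trait"] == trait]
        if sub.empty:
            raise KeyError(f"no records for trait {trait!r}")
        return PhenotypeRecords(sub.copy())

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class QCReport:
    markers_in: int
    markers_kept: int
    removed_call_rate: int
    removed_maf: int
    min_call_rate: float
    min_maf: float

    def __post_init__(self) -> None:
        if self.markers_kept + self.removed_call_rate + self.removed_maf != self.markers_in:
            raise ValueError("QC bookkeeping mismatch: kept + removals != markers in")


def qc_filter(
    g: GenotypeMatrix,
    min_call_rate: float = 0.90,
    min_maf: float = 0.05,
) -> tuple[GenotypeMatrix, QCReport]:
    """Marker quality control: call rate and minor-allele-frequency filters.

    Keeps markers with call rate >= ``min_call_rate`` and MAF >= ``min_maf``
    (MAF on non-missing calls). The sample set is unchanged. Markers failing
    the call-rate filter are counted there even if they also fail on MAF.
    """
    for name, thr in (("min_call_rate", min_call_rate), ("min_maf", min_maf)):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {thr}")
    cr = g.call_rate()
    maf = g.minor_allele_frequency()
    cr_ok = cr >= min_call_rate
    maf_ok = np.where(np.isfinite(maf), maf >= min_maf, False)
    keep = cr_ok & maf_ok
    if not keep.any():
        raise ValueError(
            "QC removed every marker; relax min_call_rate/min_maf thresholds"
        )
    report = QCReport(
        markers_in=g.n_markers,
        markers_kept=int(keep.sum()),
        removed_call_rate=int((~cr_ok).sum()),
        removed_maf=int((cr_ok & ~maf_ok).sum()),
        min_call_rate=min_call_rate,
        min_maf=min_maf,
    )
    return g.subset_markers(keep), report


def impute_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages at marker j with twice its alt-allele frequency.

    Mean imputation keeps the marker mean (hence allele frequency) unchanged
    and gives every learner the complete matrix it requires.
    """
    miss = g.is_missing()
    if not miss.any():
        dosage = g.dosage.copy()
    else:
        fully_missing = miss.all(axis=0)
        if fully_missing.any():
            bad = [g.markers[j] for j in np.flatnonzero(fully_missing)[:5]]
            raise ValueError(f"marker(s) with no calls cannot be imputed (QC first): {bad}")
        fill = 2.0 * g.allele_frequency()
        dosage = np.where(miss, fill[None, :], g.dosage)
    return GenotypeMatrix(
        samples=list(g.samples), markers=list(g.markers), dosage=dosage,
        family=None if g.family is None else list(g.family),
        population=None if g.population is None else list(g.population),
        continuous=True,
    )
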
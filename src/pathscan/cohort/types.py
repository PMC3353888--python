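"""Core domain containers shared by every pipeline stage.

Genotypes are held as a dense ``float64`` samples x variants matrix of
minor-allele dosages with ``NaN`` marking missing calls.  Autosomal entries
are 0/1/2; X-chromosome male entries are 0/1 (hemizygous).  Variant and
sample metadata live in pandas DataFrames with fixed column schemas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VARIANT_COLUMNS = [
    "id", "chrom", "pos", "minor_allele", "major_allele",
    "maf", "missing_rate", "hwe_p",
]

SAMPLE_COLUMNS = [
    "id", "sex", "age", "weight_kg", "height_m", "bmi",
    "sbp_raw", "dbp_raw", "on_med", "sbp_adj", "dbp_adj",
    "hypertensive", "phenotyped",
]


class CohortError(ValueError):
    """Raised for malformed cohort inputs (duplicate ids, bad codes...)."""


def make_variant_table(records: Iterable[dict]) -> pd.DataFrame:
    """Build a variant table, filling computed columns with NaN."""
    df = pd.DataFrame(list(records))
    for col in VARIANT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[VARIANT_COLUMNS].reset_index(drop=True)
    df["chrom"] = df["chrom"].astype(str)
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise CohortError(f"duplicated variant id: {dup!r}")
    return df


@dataclass
class GenotypeMatrix:
    """Samples x variants minor-allele dosage matrix.

    Parameters
    ----------
    dosages : ndarray of shape (n_samples, n_variants)
        Minor-allele dosages; NaN encodes a missing call.
    sample_ids : ndarray of str
    variants : DataFrame
        One row per variant with the :data:`VARIANT_COLUMNS` schema, in
        matrix column order.
    male : ndarray of bool, optional
        Per-sample male indicator, needed for X-chromosome allele counting.
    """

    dosages: np.ndarray
    sample_ids: np.ndarray
    variants: pd.DataFrame
    male: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.dosages.ndim != 2:
            raise CohortError("dosages must be 2-D (samples x variants)")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise CohortError("sample_ids length does not match dosage rows")
        if len(self.variants) != m:
            raise CohortError("variant table length does not match columns")
        if len(set(self.sample_ids)) != n:
            raise CohortError("sample ids are not unique")
        if self.male is not None:
            self.male = np.asarray(self.male, dtype=bool)
            if len(self.male) != n:
                raise CohortError("male mask length does not match samples")
        self.validate_codes()

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variants["id"].to_numpy()

    def validate_codes(self) -> None:
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise CohortError("dosages must be 0, 1, 2 or NaN")
        is_x = (self.variants["chrom"].astype(str) == "X").to_numpy()
        if is_x.any() and self.male is not None and self.male.any():
            male_x = self.dosages[np.ix_(self.male, is_x)]
            bad = male_x == 2.0
            if bad.any():
                raise CohortError("male X genotypes must be hemizygous (0/1)")

    def column(self, snp_id: str) -> np.ndarray:
        """Dosage vector for one variant id."""
        idx = self.index_of([snp_id])[0]
        return self.dosages[:, idx]

    def index_of(self, snp_ids: Sequence[str]) -> np.ndarray:
        lookup = pd.Index(self.variants["id"])
        idx = lookup.get_indexer(list(snp_ids))
        if (idx < 0).any():
            missing = [s for s, i in zip(snp_ids, idx) if i < 0]
            raise KeyError(f"variants not in matrix: {missing[:5]}")
        return idx

    def subset(self, sample_mask: np.ndarray | None = None,
               variant_mask: np.ndarray | None = None) -> "GenotypeMatrix":
        """Return a copy restricted to the given boolean masks."""
        smask = np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask, bool)
        vmask = np.ones(self.n_variants, bool) if variant_mask is None else np.asarray(variant_mask, bool)
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(smask, vmask)].copy(),
            sample_ids=self.sample_ids[smask].copy(),
            variants=self.variants.loc[vmask].reset_index(drop=True).copy(),
            male=None if self.male is None else self.male[smask].copy(),
        )


@dataclass(frozen=True)
class GeneInterval:
    """1-based inclusive gene bounds, extended by ``flank_bp`` on each side."""

    name: str
    chrom: str
    start: int
    end: int
    flank_bp: int = 20_000

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise CohortError(f"{self.name}: start > end")
        if self.flank_bp < 0:
            raise CohortError(f"{self.name}: negative flank")

    @property
    def flanked_start(self) -> int:
        return self.start - self.flank_bp

    @property
    def flanked_end(self) -> int:
        return self.end + self.flank_bp

    def contains(self, chrom: str, pos: int) -> bool:
        return str(chrom) == str(self.chrom) and self.flanked_start <= pos <= self.flanked_end


@dataclass
class PathwayDef:
    """A named gene set resolved to a de-duplicated SNP id list."""

    name: str
    genes: list[str]
    snp_ids: list[str] = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass(frozen=True)
class AssocResult:
    """Single-SNP additive association fit."""

    snp_id: str
    model: str              # "logistic" | "linear"
    outcome: str            # "HTN" | "SBP" | "DBP"
    effect: float           # log-odds or mmHg per minor allele
    se: float
    statistic: float        # 1-df Wald chi-square
    p: float
    n_used: int
    monomorphic: bool = False
    converged: bool = True

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.effect)) if self.model == "logistic" else float("nan")


@dataclass(frozen=True)
class SetTestResult:
    """Outcome of the LD-aware set-based permutation test for one SNP set."""

    set_name: str
    level: str              # "pathway" | "gene"
    outcome: str
    n_snps: int
    selected: tuple[str, ...]
    set_stat: float
    n_perm: int
    emp_p: float

    @property
    def n_sig(self) -> int:
        return len(self.selected)


def new_sample_table(ids: Sequence[str]) -> pd.DataFrame:
    """Empty sample table scaffold with the canonical schema."""
    df = pd.DataFrame({"id": list(ids)})
    for col in SAMPLE_COLUMNS[1:]:
        df[col] = np.nan
    df["phenotyped"] = False
    return df[SAMPLE_COLUMNS]


def orient_to_minor(dosages: np.ndarray, male: np.ndarray | None,
                    is_x: np.ndarray) -> np.ndarray:
    """Flip dosage coding per variant so the coded allele has frequency <= 0.5.

    Returns a boolean array marking which columns were flipped.  Ties at 0.5
    keep the existing coding.  Allele counting is chromosome-aware: males
    contribute one allele on X.
    """
    n, m = dosages.shape
    flipped = np.zeros(m, dtype=bool)
    for j in range(m):
        col = dosages[:, j]
        obs = ~np.isnan(col)
        if not obs.any():
            continue
        if is_x[j] and male is not None:
            w = np.where(male, 1.0, 2.0)
        else:
            w = np.full(n, 2.0)
        alleles = float(w[obs].sum())
        coded_count = float(np.nansum(col[obs]))
        if alleles > 0 and coded_count / alleles > 0.5:
            flipped[j] = True
            dosages[:, j] = w - col   # per-sample cap: 1 for male X, else 2
    return flipped


__all__ = [
    "GenotypeMatrix", "GeneInterval", "PathwayDef", "AssocResult",
    "SetTestResult", "CohortError", "make_variant_table", "new_sample_table",
    "orient_to_minor", "VARIANT_COLUMNS", "SAMPLE_COLUMNS",
]
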
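"""SNP- and sample-level quality control.

Filters applied by :func:`apply_qc`, in order: SNP missingness > 0.05,
MAF < 1%, HWE exact-test p < 1e-6; then a sample filter on the
homozygosity-based inbreeding coefficient (outside 4 SD of the cohort mean),
computed on the surviving SNPs only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .cohort.types import GenotypeMatrix


@dataclass(frozen=True)
class QcThresholds:
    max_snp_missing: float = 0.05
    min_maf: float = 0.01
    hwe_alpha: float = 1.0e-6
    inbreeding_sd: float = 4.0

    def __post_init__(self) -> None:
        if not (0 <= self.max_snp_missing <= 1 and 0 <= self.min_maf <= 0.5
                and 0 < self.hwe_alpha <= 1 and self.inbreeding_sd > 0):
            raise ValueError("QC thresholds out of range")


@dataclass
class QcReport:
    n_snps_in: int = 0
    removed_missingness: int = 0
    removed_maf: int = 0
    removed_hwe: int = 0
    n_snps_out: int = 0
    n_samples_in: int = 0
    removed_inbreeding: int = 0
    n_samples_out: int = 0
    removed_snp_ids: dict = field(default_factory=dict)
    removed_sample_ids: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("snps_in", self.n_snps_in),
            ("snps_removed_missingness", self.removed_missingness),
            ("snps_removed_maf", self.removed_maf),
            ("snps_removed_hwe", self.removed_hwe),
            ("snps_out", self.n_snps_out),
            ("samples_in", self.n_samples_in),
            ("samples_removed_inbreeding", self.removed_inbreeding),
            ("samples_out", self.n_samples_out),
        ]
        return pd.DataFrame(rows, columns=["criterion", "count"])


def snp_missingness(g: GenotypeMatrix, snp: str | int | None = None) -> float | np.ndarray:
    """Proportion of missing genotype calls, per SNP or for one SNP."""
    if snp is None:
        return np.isnan(g.dosages).mean(axis=0)
    j = snp if isinstance(snp, (int, np.integer)) else g.index_of([snp])[0]
    return float(np.isnan(g.dosages[:, j]).mean())


def _allele_counts(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(coded-allele count, total allele count) per variant, X-aware."""
    obs = ~np.isnan(g.dosages)
    is_x = (g.variants["chrom"].astype(str) == "X").to_numpy()
    coded = np.nansum(g.dosages, axis=0)
    totals = obs.sum(axis=0) * 2.0
    if is_x.any() and g.male is not None:
        wx = np.where(g.male, 1.0, 2.0)   # males carry one X allele
        totals[is_x] = (obs[:, is_x] * wx[:, None]).sum(axis=0)
    return coded, totals


def minor_allele_freq(g: GenotypeMatrix, snp: str | int | None = None) -> float | np.ndarray:
    """Minor-allele frequency per SNP (folded to <= 0.5).

    Autosomes: (het + 2 * hom_coded) / (2 * n_nonmissing).  X SNPs: males
    contribute a single allele each.
    """
    coded, totals = _allele_counts(g)
    if np.any(totals == 0):
        bad = g.variants.loc[totals == 0, "id"].tolist()
        raise ValueError(f"all-missing SNP(s): {bad[:5]}")
    freq = coded / totals
    maf = np.minimum(freq, 1.0 - freq)
    if snp is None:
        return maf
    j = snp if isinstance(snp, (int, np.integer)) else g.index_of([snp])[0]
    return float(maf[j])


def hwe_exact_p(hom_major: int, het: int, hom_minor: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote configurations no more probable than the observed one
    (probability-ordering convention).  Monomorphic tables return 1.0.
    """
    if min(hom_major, het, hom_minor) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = hom_major + het + hom_minor
    if n < 1:
        raise ValueError("need at least one genotype")
    rare = 2 * min(hom_major, hom_minor) + het
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    if hets[-1] > 2 * n - rare:
        hets = hets[hets <= 2 * n - rare]
    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    # log P(het | n, rare) up to a constant: multinomial weight * 2^het
    logw = (hets * np.log(2.0) - gammaln(hom_r + 1) - gammaln(hets + 1)
            - gammaln(hom_c + 1))
    logw -= logw.max()
    probs = np.exp(logw)
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-10)].sum()))


def hwe_scan(g: GenotypeMatrix) -> np.ndarray:
    """HWE exact p per variant.  X-chromosome SNPs use females only (males
    are hemizygous); if the sex of samples is unknown, X SNPs get p = 1."""
    is_x = (g.variants["chrom"].astype(str) == "X").to_numpy()
    out = np.ones(g.n_variants)
    for j in range(g.n_variants):
        col = g.dosages[:, j]
        if is_x[j]:
            if g.male is None:
                continue
            col = col[~g.male]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        het = int((col == 1).sum())
        hom_coded = int((col == 2).sum())
        hom_other = int((col == 0).sum())
        out[j] = hwe_exact_p(hom_other, het, hom_coded)
    return out


def inbreeding_coefficient(g: GenotypeMatrix, sample: str | int | None = None):
    """Homozygosity-based inbreeding coefficient F per sample.

    F = (O_hom - E_hom) / (L - E_hom) over the sample's non-missing
    autosomal polymorphic SNPs, with the expected homozygosity per SNP
    1 - 2 p (1 - p) * n/(n - 1) using cohort allele frequency p and
    non-missing allele count n.
    """
    is_auto = (g.variants["chrom"].astype(str) != "X").to_numpy()
    coded, totals = _allele_counts(g)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(totals > 0, coded / np.maximum(totals, 1), np.nan)
    usable = is_auto & (totals > 2) & (p > 0) & (p < 1)
    if not usable.any():
        raise ValueError("no usable autosomal polymorphic SNPs for F")
    pj = p[usable]
    nj = totals[usable]
    e_hom_per_snp = 1.0 - 2.0 * pj * (1.0 - pj) * nj / (nj - 1.0)
    D = g.dosages[:, usable]
    obs = ~np.isnan(D)
    o_hom = ((D == 0) | (D == 2)).sum(axis=1).astype(float)
    e_hom = obs @ e_hom_per_snp
    L = obs.sum(axis=1).astype(float)
    denom = L - e_hom
    if np.any(L == 0):
        raise ValueError("sample with no usable genotypes")
    if np.any(denom == 0):
        raise ValueError("degenerate expected homozygosity (L == E_hom)")
    F = (o_hom - e_hom) / denom
    if sample is None:
        return F
    i = sample if isinstance(sample, (int, np.integer)) else list(g.sample_ids).index(sample)
    return float(F[i])


def duplicate_concordance(g1: np.ndarray, g2: np.ndarray) -> float:
    """Fraction of matching calls over entries non-missing in both vectors."""
    a = np.asarray(g1, float)
    b = np.asarray(g2, float)
    if a.shape != b.shape:
        raise ValueError("vectors must share variant order and length")
    both = ~np.isnan(a) & ~np.isnan(b)
    if not both.any():
        raise ValueError("no comparable entries")
    return float((a[both] == b[both]).mean())


def apply_qc(g: GenotypeMatrix, samples: pd.DataFrame,
             thresholds: QcThresholds = QcThresholds()):
    """Run SNP filters then the sample inbreeding filter.

    Returns (filtered GenotypeMatrix, filtered sample table, QcReport).
    SNPs failing several criteria are counted once, under the first failed
    criterion in the order missingness -> MAF -> HWE.  The variant table of
    the returned matrix carries recomputed maf / missing_rate / hwe_p.
    """
    report = QcReport(n_snps_in=g.n_variants, n_samples_in=g.n_samples)

    miss = snp_missingness(g)
    maf = minor_allele_freq(g) if g.n_variants else np.empty(0)
    hwe = hwe_scan(g)

    fail_miss = miss > thresholds.max_snp_missing
    fail_maf = ~fail_miss & (maf < thresholds.min_maf)
    fail_hwe = ~fail_miss & ~fail_maf & (hwe < thresholds.hwe_alpha)
    report.removed_missingness = int(fail_miss.sum())
    report.removed_maf = int(fail_maf.sum())
    report.removed_hwe = int(fail_hwe.sum())
    keep_snps = ~(fail_miss | fail_maf | fail_hwe)
    report.removed_snp_ids = {
        "missingness": g.variants.loc[fail_miss, "id"].tolist(),
        "maf": g.variants.loc[fail_maf, "id"].tolist(),
        "hwe": g.variants.loc[fail_hwe, "id"].tolist(),
    }
    if not keep_snps.any():
        raise ValueError("QC removed every SNP")

    g2 = g.subset(variant_mask=keep_snps)
    F = inbreeding_coefficient(g2)
    mean_f, sd_f = float(F.mean()), float(F.std(ddof=1)) if len(F) > 1 else 0.0
    if sd_f > 0:
        keep_samples = np.abs(F - mean_f) <= thresholds.inbreeding_sd * sd_f
    else:
        keep_samples = np.ones(g2.n_samples, bool)
    report.removed_inbreeding = int((~keep_samples).sum())
    report.removed_sample_ids = list(g2.sample_ids[~keep_samples])
    if not keep_samples.any():
        raise ValueError("QC removed every sample")

    g3 = g2.subset(sample_mask=keep_samples)
    g3.variants["missing_rate"] = snp_missingness(g3)
    g3.variants["maf"] = minor_allele_freq(g3)
    g3.variants["hwe_p"] = hwe_scan(g3)
    samples_out = samples[samples["id"].isin(g3.sample_ids)].reset_index(drop=True)
    report.n_snps_out = g3.n_variants
    report.n_samples_out = g3.n_samples
    return g3, samples_out, report


__all__ = [
    "QcThresholds", "QcReport", "snp_missingness", "minor_allele_freq",
    "hwe_exact_p", "hwe_scan", "inbreeding_coefficient",
    "duplicate_concordance", "apply_qc",
]
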
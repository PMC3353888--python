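"""Seeded synthetic-cohort generator.

Genotypes come from a threshold latent-Gaussian model: within each LD block
one shared and one private standard-normal draw per haplotype are mixed
with weight sqrt(rho) and thresholded at each SNP's allele-frequency
quantile, so genotypes are HWE-consistent and within-block dosage r^2 is
approximately ``ld_r2_target`` (realized LD is approximate by design).
Blocks are independent; genes tile consecutive blocks; pathways tile genes.

Phenotypes: covariates are drawn to match the study cohort's marginals
(58% female; age ~ N(49, 14.5) truncated at 18; BMI ~ N(24.1, 5.4)
truncated above 14), hypertension is a Bernoulli draw from a logistic
liability with per-SNP log odds ratios concentrated in the causal pathway,
and SBP/DBP are Gaussian with per-SNP mmHg effects sharing each SNP's
direction.  Blood pressure is drawn consistent with the case label, treated
cases are sampled among cases and their stored raw BP is lowered by
15/10 mmHg so the pipeline's medication adjustment is exercised.

All randomness flows from one root seed through named substreams
(genotypes, covariates, phenotypes, missingness).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from functools import lru_cache

from scipy.optimize import brentq
from scipy.special import expit, ndtri
from scipy.stats import multivariate_normal, norm

from .cohort.types import GeneInterval, GenotypeMatrix, PathwayDef, make_variant_table, new_sample_table
from .phenotypes import adjust_bp_for_medication

_SUBSTREAMS = ("genotypes", "covariates", "phenotypes", "missingness")


@dataclass
class SimulationSpec:
    n_samples: int = 400
    pathways: Sequence[tuple[str, int, int]] = (("PW1", 2, 10), ("PW2", 2, 10))
    ld_block_size: int = 5
    ld_r2_target: float = 0.4
    maf_range: tuple[float, float] = (0.05, 0.45)
    causal_pathway: str | None = None
    causal_snp_fraction: float = 0.5
    effect_or_range: tuple[float, float] = (1.15, 1.35)
    effect_beta_range: tuple[float, float] = (1.0, 3.0)
    covariate_effects: dict = field(default_factory=lambda: {
        "sex": 0.0, "age": 0.0, "age2": 0.0, "bmi": 0.0})
    baseline_prevalence: float = 0.494
    missing_rate: float = 0.0
    medication_rate_in_cases: float = 0.5
    seed: int | None = None
    random_effect_sign: bool = True
    bp_covariate_scale: float = 15.0
    snp_spacing_bp: int = 5_000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.ld_r2_target < 1.0):
            raise ValueError("ld_r2_target must be in [0, 1)")
        for rate in (self.causal_snp_fraction, self.baseline_prevalence,
                     self.missing_rate, self.medication_rate_in_cases):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must be in [0, 1]")

    def substreams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_SUBSTREAMS))
        return {name: np.random.default_rng(child)
                for name, child in zip(_SUBSTREAMS, children)}


@lru_cache(maxsize=4096)
def _latent_rho(tau: float, r_allele: float) -> float:
    """Latent equicorrelation giving allele-indicator correlation ~r_allele
    at threshold tau, by inverting the bivariate-normal orthant probability
    (thresholding attenuates correlation, so sqrt(r2) alone undershoots)."""
    if r_allele <= 0.0:
        return 0.0
    p = float(norm.cdf(tau))
    pq = p * (1.0 - p)

    def realized(rho: float) -> float:
        joint = multivariate_normal(mean=[0.0, 0.0],
                                    cov=[[1.0, rho], [rho, 1.0]]).cdf([tau, tau])
        return (joint - p * p) / pq

    hi = 0.9999
    if realized(hi) <= r_allele:
        return hi
    return float(brentq(lambda rho: realized(rho) - r_allele, 0.0, hi, xtol=1e-6))


def simulate_genotypes(spec: SimulationSpec):
    """Generate (GenotypeMatrix, VariantTable, genes, pathways).

    Missing calls are injected completely at random at ``missing_rate``.
    """
    rngs = spec.substreams()
    rng = rngs["genotypes"]
    n = spec.n_samples
    r_allele = float(np.sqrt(spec.ld_r2_target))  # desired dosage correlation

    records, genes, pathway_defs = [], [], []
    columns: list[np.ndarray] = []
    chrom_cursor: dict[str, int] = {}
    snp_counter = 0
    for p_idx, (pname, n_genes, snps_per_gene) in enumerate(spec.pathways):
        chrom = str(p_idx % 22 + 1)
        gene_names = []
        for g_idx in range(n_genes):
            gname = f"{pname}_G{g_idx + 1}"
            gene_names.append(gname)
            start_pos = chrom_cursor.get(chrom, 1_000_000)
            positions = start_pos + spec.snp_spacing_bp * np.arange(snps_per_gene)
            chrom_cursor[chrom] = int(positions[-1]) + 1_000_000

            mafs = rng.uniform(*spec.maf_range, size=snps_per_gene)
            thresholds = ndtri(mafs)
            dos = np.zeros((n, snps_per_gene))
            for block_start in range(0, snps_per_gene, spec.ld_block_size):
                b = min(spec.ld_block_size, snps_per_gene - block_start)
                sl = slice(block_start, block_start + b)
                tau = float(thresholds[sl].mean())
                rho = _latent_rho(round(tau, 3), round(r_allele, 3)) if b > 1 else 0.0
                for _hap in range(2):
                    shared = rng.standard_normal((n, 1))
                    private = rng.standard_normal((n, b))
                    latent = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * private
                    dos[:, sl] += (latent < thresholds[sl]).astype(float)
            columns.append(dos)

            span = int(positions[-1] - positions[0])
            # shrink the annotated interval so edge SNPs enter via the flank
            if span > 44_000:
                g_start, g_end = int(positions[0]) + 20_000, int(positions[-1]) - 20_000
            else:
                g_start, g_end = int(positions[0]), int(positions[-1])
            genes.append(GeneInterval(name=gname, chrom=chrom,
                                      start=g_start, end=g_end))
            for k in range(snps_per_gene):
                snp_counter += 1
                records.append({"id": f"snp{snp_counter:05d}", "chrom": chrom,
                                "pos": int(positions[k]), "minor_allele": "A",
                                "major_allele": "G"})
        pathway_defs.append((pname, gene_names))

    dosages = np.concatenate(columns, axis=1) if columns else np.empty((n, 0))
    if spec.missing_rate > 0:
        rng_miss = rngs["missingness"]
        mask = rng_miss.random(dosages.shape) < spec.missing_rate
        dosages[mask] = np.nan

    variants = make_variant_table(records)
    ids = variants["id"].to_numpy()
    offset = 0
    gene_snps: dict[str, list[str]] = {}
    for gene in genes:
        k = next(sp for (pn, ng, sp) in spec.pathways if gene.name.startswith(pn + "_"))
        gene_snps[gene.name] = [str(s) for s in ids[offset:offset + k]]
        offset += k
    pathways = [PathwayDef(name=pn, genes=gnames,
                           snp_ids=[s for gn in gnames for s in gene_snps[gn]])
                for pn, gnames in pathway_defs]

    g = GenotypeMatrix(dosages=dosages, sample_ids=np.array(
        [f"S{i + 1:05d}" for i in range(n)], dtype=object), variants=variants)
    return g, g.variants, genes, pathways


def _truncated_normal(rng, mean, sd, size, low=None, high=None):
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = np.zeros(size, bool)
        if low is not None:
            bad |= out < low
        if high is not None:
            bad |= out > high
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    if low is not None:
        out = np.maximum(out, low)
    if high is not None:
        out = np.minimum(out, high)
    return out


def _pick_causal(pathways: Sequence[PathwayDef], spec: SimulationSpec,
                 rng: np.random.Generator) -> list[str]:
    target = next((p for p in pathways if p.name == spec.causal_pathway), None)
    if target is None:
        raise ValueError(f"causal pathway {spec.causal_pathway!r} not simulated")
    k = max(1, int(round(spec.causal_snp_fraction * target.n_snps)))
    # spread picks across the set to avoid stacking one LD block
    idx = np.linspace(0, target.n_snps - 1, num=k).round().astype(int)
    idx = np.unique(idx)
    return [target.snp_ids[i] for i in idx]


def simulate_phenotypes(g: GenotypeMatrix, spec: SimulationSpec,
                        pathways: Sequence[PathwayDef] | None = None,
                        return_truth: bool = False):
    """Generate a SampleTable for a simulated genotype matrix.

    ``return_truth`` additionally returns the planted ground truth
    (causal SNP ids, per-SNP log-OR and mmHg effects, intercept).
    """
    rngs = spec.substreams()
    rng_cov = rngs["covariates"]
    rng_phe = rngs["phenotypes"]
    n = g.n_samples

    female = rng_cov.random(n) < 0.582
    age = _truncated_normal(rng_cov, 48.99, 14.5, n, low=18.0)
    bmi = _truncated_normal(rng_cov, 24.07, 5.4, n, low=14.0 + 1e-9)
    height = np.where(female, rng_cov.normal(1.59, 0.07, n), rng_cov.normal(1.70, 0.07, n))
    height = np.clip(height, 1.2, 2.2)
    weight = bmi * height**2

    causal_ids: list[str] = []
    log_ors = np.empty(0)
    betas_sbp = np.empty(0)
    betas_dbp = np.empty(0)
    eta_gen = np.zeros(n)
    sbp_gen = np.zeros(n)
    dbp_gen = np.zeros(n)
    if spec.causal_pathway is not None:
        if pathways is None:
            raise ValueError("pathways required when causal_pathway is set")
        causal_ids = _pick_causal(pathways, spec, rng_phe)
        m = len(causal_ids)
        log_ors = np.log(rng_phe.uniform(*spec.effect_or_range, size=m))
        betas_sbp = rng_phe.uniform(*spec.effect_beta_range, size=m)
        betas_dbp = 0.6 * betas_sbp
        if spec.random_effect_sign:
            sign = np.where(rng_phe.random(m) < 0.5, 1.0, -1.0)
            log_ors *= sign
            betas_sbp *= sign
            betas_dbp *= sign
        D = g.dosages[:, g.index_of(causal_ids)]
        mu = np.nanmean(D, axis=0)
        D = np.where(np.isnan(D), mu, D)
        eta_gen = (D - mu) @ log_ors
        sbp_gen = (D - mu) @ betas_sbp
        dbp_gen = (D - mu) @ betas_dbp

    ce = spec.covariate_effects
    male = ~female
    cov_eta = (ce.get("sex", 0.0) * male
               + ce.get("age", 0.0) * (age - 49.0)
               + ce.get("age2", 0.0) * (age - 49.0)**2
               + ce.get("bmi", 0.0) * (bmi - 24.0))
    eta = eta_gen + cov_eta
    prev = spec.baseline_prevalence
    if prev <= 0.0 or prev >= 1.0:
        raise ValueError("baseline_prevalence must be inside (0, 1)")
    b0 = brentq(lambda b: expit(b + eta).mean() - prev, -30.0, 30.0)
    hypertensive = rng_phe.random(n) < expit(b0 + eta)

    on_med = hypertensive & (rng_phe.random(n) < spec.medication_rate_in_cases)
    cov_bp = cov_eta * spec.bp_covariate_scale
    sbp_mu = 124.0 + 16.0 * hypertensive + sbp_gen + cov_bp
    dbp_mu = 77.0 + 9.0 * hypertensive + dbp_gen + 0.6 * cov_bp
    sbp = rng_phe.normal(sbp_mu, 12.0)
    dbp = rng_phe.normal(dbp_mu, 8.0)

    # force BP consistent with the drawn label for untreated individuals
    untreated_case = hypertensive & ~on_med
    for _ in range(200):
        bad = untreated_case & (sbp < 140.0) & (dbp < 90.0)
        if not bad.any():
            break
        k = int(bad.sum())
        sbp[bad] = rng_phe.normal(sbp_mu[bad] + 6.0, 12.0, k)
        dbp[bad] = rng_phe.normal(dbp_mu[bad] + 4.0, 8.0, k)
    still = untreated_case & (sbp < 140.0) & (dbp < 90.0)
    sbp[still] = 140.0 + rng_phe.exponential(5.0, int(still.sum()))
    control = ~hypertensive
    for _ in range(200):
        bad = control & ((sbp >= 140.0) | (dbp >= 90.0))
        if not bad.any():
            break
        k = int(bad.sum())
        sbp[bad] = rng_phe.normal(np.minimum(sbp_mu[bad], 125.0), 8.0, k)
        dbp[bad] = rng_phe.normal(np.minimum(dbp_mu[bad], 78.0), 6.0, k)
    still = control & ((sbp >= 140.0) | (dbp >= 90.0))
    sbp[still] = np.minimum(sbp[still], 139.0 - rng_phe.exponential(3.0, int(still.sum())))
    dbp[still] = np.minimum(dbp[still], 89.0 - rng_phe.exponential(2.0, int(still.sum())))

    # stored raw BP of treated cases reflects treatment (-15 / -10 mmHg)
    sbp = np.where(on_med, sbp - 15.0, sbp)
    dbp = np.where(on_med, dbp - 10.0, dbp)

    samples = new_sample_table(g.sample_ids)
    samples["sex"] = np.where(female, "female", "male")
    samples["age"] = age
    samples["weight_kg"] = weight
    samples["height_m"] = height
    samples["bmi"] = bmi
    samples["sbp_raw"] = sbp
    samples["dbp_raw"] = dbp
    samples["on_med"] = on_med
    sbp_adj, dbp_adj = adjust_bp_for_medication(sbp, dbp, on_med)
    samples["sbp_adj"] = sbp_adj
    samples["dbp_adj"] = dbp_adj
    samples["hypertensive"] = hypertensive
    samples["phenotyped"] = True
    g.male = male.to_numpy() if hasattr(male, "to_numpy") else np.asarray(male)

    if not return_truth:
        return samples
    truth = {
        "causal_snp_ids": list(causal_ids),
        "log_or": [float(v) for v in log_ors],
        "beta_sbp": [float(v) for v in betas_sbp],
        "beta_dbp": [float(v) for v in betas_dbp],
        "intercept": float(b0),
        "seed": spec.seed,
    }
    return samples, truth


def simulate_cohort(spec: SimulationSpec):
    """Convenience wrapper: genotypes + phenotypes + planted truth."""
    g, variants, genes, pathways = simulate_genotypes(spec)
    samples, truth = simulate_phenotypes(g, spec, pathways, return_truth=True)
    return g, variants, genes, pathways, samples, truth


def study_like_pathways(n_pathways: int = 28, n_genes_total: int = 101,
                        snps_per_gene: int = 43) -> list[tuple[str, int, int]]:
    """Pathway shape roughly matching the study's scale (28 pathways,
    101 genes, ~4.3k SNPs)."""
    base = n_genes_total // n_pathways
    extra = n_genes_total - base * n_pathways
    return [(f"PW{i + 1:02d}", base + (1 if i < extra else 0), snps_per_gene)
            for i in range(n_pathways)]


__all__ = ["SimulationSpec", "simulate_genotypes", "simulate_phenotypes",
           "simulate_cohort", "study_like_pathways"]
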
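"""Per-SNP additive association models.

Logistic regression for hypertension status and ordinary least squares for
medication-adjusted SBP/DBP, each adjusted for sex, age, age^2 and BMI.
Reported tests are 1-df Wald chi-squares on the dosage coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort.types import AssocResult, GenotypeMatrix
from .phenotypes import (  # re-exported: shared phenotype operations
    adjust_bp_for_medication,
    classify_hypertension,
    code_x_genotype,
    compute_bmi,
)

OUTCOMES = ("HTN", "SBP", "DBP")


@dataclass(frozen=True)
class ModelSpec:
    """Outcome + covariate specification for the additive model."""

    outcome: str = "HTN"
    covariates: tuple[str, ...] = ("sex", "age", "age2", "bmi")
    center_age: bool = False
    med_adjust_sbp: float = 15.0
    med_adjust_dbp: float = 10.0

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}")

    @property
    def model(self) -> str:
        return "logistic" if self.outcome == "HTN" else "linear"


def outcome_vector(samples: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    """Phenotype vector for the model: 0/1 status or adjusted BP (mmHg)."""
    if spec.outcome == "HTN":
        return samples["hypertensive"].astype(float).to_numpy()
    col = "sbp_adj" if spec.outcome == "SBP" else "dbp_adj"
    return samples[col].astype(float).to_numpy()


def covariate_matrix(samples: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    """Design columns (no intercept) in the order of ``spec.covariates``."""
    cols = []
    age = samples["age"].astype(float).to_numpy()
    if spec.center_age:
        age = age - np.nanmean(age)
    for name in spec.covariates:
        if name == "sex":
            cols.append((samples["sex"] == "male").astype(float).to_numpy())
        elif name == "age":
            cols.append(age)
        elif name == "age2":
            cols.append(age**2)
        elif name == "bmi":
            cols.append(samples["bmi"].astype(float).to_numpy())
        else:
            raise ValueError(f"unknown covariate {name!r}")
    return np.column_stack(cols) if cols else np.empty((len(samples), 0))


def _wald_from_fit(params, bse, j=1):
    effect = float(params[j])
    se = float(bse[j])
    statistic = (effect / se) ** 2 if se > 0 else float("nan")
    p = float(stats.chi2.sf(statistic, df=1)) if np.isfinite(statistic) else 1.0
    return effect, se, statistic, p


def snp_association(dosages: np.ndarray, samples: pd.DataFrame, spec: ModelSpec,
                    snp_id: str = "snp") -> AssocResult:
    """Fit one SNP: outcome ~ dosage + covariates, complete-case.

    Monomorphic-in-sample SNPs are flagged and assigned p = 1 so set sizes
    stay stable downstream; non-converged logistic fits (separation) are
    flagged with ``converged = False``.
    """
    y = outcome_vector(samples, spec)
    X_cov = covariate_matrix(samples, spec)
    d = np.asarray(dosages, float)
    keep = ~np.isnan(d) & ~np.isnan(y)
    if X_cov.shape[1]:
        keep &= ~np.isnan(X_cov).any(axis=1)
    n_used = int(keep.sum())
    d_k = d[keep]
    if n_used == 0 or np.unique(d_k).size < 2:
        return AssocResult(snp_id=snp_id, model=spec.model, outcome=spec.outcome,
                           effect=0.0, se=float("inf"), statistic=0.0, p=1.0,
                           n_used=n_used, monomorphic=True)
    X = np.column_stack([np.ones(n_used), d_k, X_cov[keep]])
    y_k = y[keep]
    converged = True
    try:
        if spec.model == "logistic":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y_k, X).fit(disp=0, maxiter=100)
            converged = bool(res.mle_retvals.get("converged", True))
        else:
            res = sm.OLS(y_k, X).fit()
    except Exception:
        return AssocResult(snp_id=snp_id, model=spec.model, outcome=spec.outcome,
                           effect=0.0, se=float("inf"), statistic=0.0, p=1.0,
                           n_used=n_used, converged=False)
    effect, se, statistic, p = _wald_from_fit(res.params, res.bse)
    if not np.isfinite(statistic):
        return AssocResult(snp_id=snp_id, model=spec.model, outcome=spec.outcome,
                           effect=effect, se=se, statistic=0.0, p=1.0,
                           n_used=n_used, converged=False)
    return AssocResult(snp_id=snp_id, model=spec.model, outcome=spec.outcome,
                       effect=effect, se=se, statistic=statistic, p=p,
                       n_used=n_used, converged=converged)


def assoc_scan(g: GenotypeMatrix, samples: pd.DataFrame, spec: ModelSpec) -> list[AssocResult]:
    """One Wald fit per SNP, in (chrom, pos) order."""
    order = _sort_order(g.variants)
    ids = g.variant_ids
    return [snp_association(g.dosages[:, j], samples, spec, snp_id=str(ids[j]))
            for j in order]


def _sort_order(variants: pd.DataFrame) -> np.ndarray:
    chrom = variants["chrom"].astype(str)
    chrom_key = chrom.map(lambda c: 23 if c == "X" else int(c) if c.isdigit() else 99)
    return np.lexsort((variants["pos"].to_numpy(), chrom_key.to_numpy()))


def results_frame(results: list[AssocResult], variants: pd.DataFrame) -> pd.DataFrame:
    """Tabulate AssocResults with chrom/pos merged in (TSV-ready)."""
    df = pd.DataFrame([{
        "snp": r.snp_id, "n": r.n_used, "effect": r.effect, "se": r.se,
        "or": r.odds_ratio, "stat": r.statistic, "p": r.p,
        "monomorphic": r.monomorphic, "converged": r.converged,
    } for r in results])
    meta = variants[["id", "chrom", "pos"]].rename(columns={"id": "snp"})
    df = meta.merge(df, on="snp", how="right")
    return df[["snp", "chrom", "pos", "n", "effect", "se", "or", "stat", "p",
               "monomorphic", "converged"]]


__all__ = [
    "ModelSpec", "snp_association", "assoc_scan", "results_frame",
    "outcome_vector", "covariate_matrix", "compute_bmi",
    "classify_hypertension", "adjust_bp_for_medication", "code_x_genotype",
    "OUTCOMES",
]
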
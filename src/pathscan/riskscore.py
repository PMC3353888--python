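"""Unfavorable-allele ratio genetic risk score and quintile regression.

For a panel of significant SNPs, each SNP contributes its minor allele when
the association is risk-increasing (OR > 1 / beta > 0) and its major allele
when protective (OR < 1 / beta < 0).  A sample's score is
r_i / n_i: unfavorable alleles carried over total alleles counted, with
missing genotypes excluded from both numerator and denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .association import ModelSpec, covariate_matrix, outcome_vector
from .cohort.types import AssocResult, GenotypeMatrix


@dataclass
class RiskModel:
    """SNP panel with per-SNP direction: True = minor allele unfavorable."""

    snp_ids: list[str]
    minor_is_unfavorable: list[bool]
    source_effects: list[float]
    outcome: str = "HTN"

    def __post_init__(self) -> None:
        if len(self.snp_ids) != len(self.minor_is_unfavorable):
            raise ValueError("snp/direction length mismatch")

    def flipped(self) -> "RiskModel":
        return RiskModel(snp_ids=list(self.snp_ids),
                         minor_is_unfavorable=[not d for d in self.minor_is_unfavorable],
                         source_effects=list(self.source_effects),
                         outcome=self.outcome)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp": self.snp_ids,
            "direction": ["risk" if d else "protective" for d in self.minor_is_unfavorable],
            "source_effect": self.source_effects,
        })


def build_risk_model(assoc: dict[str, AssocResult] | list[AssocResult],
                     selected: list[str]) -> RiskModel:
    """Assign per-SNP unfavorable alleles from the sign of the effect.

    Risk SNPs (OR > 1 / beta > 0) contribute the minor allele; protective
    SNPs (OR < 1 / beta < 0) contribute the major allele.  A SNP with a
    null effect (OR exactly 1 / beta exactly 0) is dropped with a warning.
    """
    if not selected:
        raise ValueError("empty SNP selection for the risk model")
    if not isinstance(assoc, dict):
        assoc = {r.snp_id: r for r in assoc}
    ids, dirs, effs = [], [], []
    outcome = None
    for snp in selected:
        if snp not in assoc:
            raise KeyError(f"no association result for {snp!r}")
        r = assoc[snp]
        outcome = outcome or r.outcome
        if r.effect == 0.0:
            warnings.warn(f"{snp}: effect exactly null; dropped from risk model")
            continue
        ids.append(snp)
        dirs.append(r.effect > 0)   # log-OR > 0 <=> OR > 1
        effs.append(r.effect)
    if not ids:
        raise ValueError("all selected SNPs had null effects")
    return RiskModel(snp_ids=ids, minor_is_unfavorable=dirs,
                     source_effects=effs, outcome=outcome or "HTN")


def score_samples(g: GenotypeMatrix, model: RiskModel) -> pd.DataFrame:
    """Per-sample (r_i, n_i, score).

    Autosomal SNPs contribute two alleles, male X SNPs one.  Missing
    genotypes drop out of both counts; a sample missing every model SNP has
    an undefined (NaN) score.
    """
    idx = g.index_of(model.snp_ids)
    D = g.dosages[:, idx]
    obs = ~np.isnan(D)
    is_x = (g.variants["chrom"].astype(str).to_numpy()[idx] == "X")
    if is_x.any() and g.male is not None:
        alleles = np.where(g.male[:, None] & is_x[None, :], 1.0, 2.0)
    else:
        alleles = np.full(D.shape, 2.0)
    direction = np.asarray(model.minor_is_unfavorable)
    unfav = np.where(direction[None, :], D, alleles - D)
    r_i = np.nansum(np.where(obs, unfav, 0.0), axis=1)
    n_i = (alleles * obs).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(n_i > 0, r_i / np.maximum(n_i, 1e-300), np.nan)
    return pd.DataFrame({"id": g.sample_ids, "r": r_i, "n": n_i, "score": score})


def assign_quintiles(scores: np.ndarray) -> np.ndarray:
    """Quintile label (1..5) per score; boundaries at the 20/40/60/80th
    percentiles, boundary values assigned to the lower quintile.  Errors if
    ties collapse a quintile to emptiness."""
    s = np.asarray(scores, float)
    valid = np.isfinite(s)
    if np.unique(s[valid]).size < 5:
        raise ValueError("need at least 5 distinct score values for quintiles")
    cuts = np.percentile(s[valid], [20, 40, 60, 80])
    q = np.full(len(s), np.nan)
    q[valid] = 1 + np.searchsorted(cuts, s[valid], side="left")
    counts = [(q[valid] == k).sum() for k in range(1, 6)]
    if min(counts) == 0:
        empty = counts.index(0) + 1
        raise ValueError(f"degenerate quintiles: quintile {empty} is empty "
                         f"(mass of tied scores at a boundary)")
    return q


def quintile_model(scores: pd.DataFrame | np.ndarray, samples: pd.DataFrame,
                   spec: ModelSpec) -> pd.DataFrame:
    """Adjusted regression of the outcome on quintile indicators (Q2-Q5
    versus the lowest quintile).

    Returns one row per quintile with the estimate, 95% CI (OR scale for
    the binary outcome, mmHg for BP) and Wald p-value; Q1 is the reference
    row.
    """
    s = scores["score"].to_numpy() if isinstance(scores, pd.DataFrame) else np.asarray(scores, float)
    if len(s) != len(samples):
        raise ValueError("scores and samples must align")
    y = outcome_vector(samples, spec)
    X_cov = covariate_matrix(samples, spec)
    q = assign_quintiles(s)
    keep = np.isfinite(q) & np.isfinite(y)
    if X_cov.shape[1]:
        keep &= np.isfinite(X_cov).all(axis=1)
    qk, yk = q[keep], y[keep]
    ind = np.column_stack([(qk == k).astype(float) for k in range(2, 6)])
    X = np.column_stack([np.ones(keep.sum()), ind, X_cov[keep]])
    if spec.model == "logistic":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(yk, X).fit(disp=0, maxiter=100)
    else:
        res = sm.OLS(yk, X).fit()
    rows = [{"quintile": 1, "n": int((qk == 1).sum()), "estimate": 1.0 if spec.model == "logistic" else 0.0,
             "se": 0.0, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan}]
    for j, k in enumerate(range(2, 6), start=1):
        b, se = float(res.params[j]), float(res.bse[j])
        z = sps.norm.ppf(0.975)
        p = float(sps.chi2.sf((b / se) ** 2, df=1)) if se > 0 else np.nan
        if spec.model == "logistic":
            rows.append({"quintile": k, "n": int((qk == k).sum()),
                         "estimate": float(np.exp(b)), "se": se,
                         "ci_low": float(np.exp(b - z * se)),
                         "ci_high": float(np.exp(b + z * se)), "p": p})
        else:
            rows.append({"quintile": k, "n": int((qk == k).sum()),
                         "estimate": b, "se": se,
                         "ci_low": b - z * se, "ci_high": b + z * se, "p": p})
    return pd.DataFrame(rows)


__all__ = ["RiskModel", "build_risk_model", "score_samples",
           "assign_quintiles", "quintile_model"]
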
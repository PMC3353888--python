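"""LD-aware set-based permutation test at pathway and gene level.

Algorithm, per SNP set: fit every SNP, greedily pick the most significant
SNP meeting the per-SNP p cutoff, drop remaining SNPs in LD with it
(r^2 above threshold), repeat; the set statistic is the mean 1-df chi-square
of the picks.  Phenotype labels are then permuted (covariates stay with
individuals), the whole selection is re-run per permutation, and the
empirical p is the fraction of permuted set statistics reaching the
observed one, with the (r+1)/(n+1) correction.

Two statistic engines are provided.  ``wald_refit`` refits the full GLM per
SNP per permutation (reference).  ``score_fast`` residualizes genotypes and
phenotype on the covariates once and computes the partial-correlation
t-square in one matrix product per permutation block; for linear outcomes
it equals the OLS Wald statistic, for the binary outcome it is a trend-test
approximation.  LD is computed once on the observed genotypes and cached;
permutation never alters it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .association import ModelSpec, covariate_matrix, outcome_vector
from .cohort.types import GenotypeMatrix, PathwayDef, SetTestResult

DEFAULT_GRID = (("Default", 0.5, 0.05), ("Strict", 0.1, 0.01), ("Loose", 0.8, 0.05))

# above this many SNP-fits per set test, "auto" switches to the fast engine
AUTO_FAST_FITS = 100_000


@dataclass(frozen=True)
class SetTestParams:
    r2_threshold: float = 0.5
    p_cutoff: float = 0.05
    n_perm: int = 10_000
    seed: int | None = None
    stat_mode: str = "auto"       # auto | wald_refit | score_fast
    perm_scheme: str = "label"    # label | freedman_lane

    def __post_init__(self) -> None:
        if not (0 <= self.r2_threshold <= 1):
            raise ValueError("r2_threshold must be in [0, 1]")
        if not (0 < self.p_cutoff <= 1):
            raise ValueError("p_cutoff must be in (0, 1]")
        if self.stat_mode not in ("auto", "wald_refit", "score_fast"):
            raise ValueError(f"unknown stat_mode {self.stat_mode!r}")
        if self.perm_scheme not in ("label", "freedman_lane"):
            raise ValueError(f"unknown perm_scheme {self.perm_scheme!r}")

    def resolve_mode(self, n_fits: int) -> str:
        if self.stat_mode != "auto":
            return self.stat_mode
        return "score_fast" if n_fits > AUTO_FAST_FITS else "wald_refit"


def bonferroni_cutoff(alpha: float, m: int) -> float:
    """Family-wise threshold alpha / m."""
    if m < 1:
        raise ValueError("need at least one test")
    return alpha / m


def format_cutoff(value: float, sig_figs: int = 1) -> str:
    """Round a cutoff for display at the given significant figures."""
    if value <= 0:
        return "0"
    from math import floor, log10
    exponent = floor(log10(abs(value)))
    rounded = round(value, -exponent + sig_figs - 1)
    return f"{rounded:.10g}"


# ---------------------------------------------------------------------------
# LD

def pairwise_r2(d1: np.ndarray, d2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over
    pairwise-complete samples.  Undefined (constant vector) -> 0.0, which
    never justifies pruning."""
    a = np.asarray(d1, float)
    b = np.asarray(d2, float)
    both = ~np.isnan(a) & ~np.isnan(b)
    if both.sum() < 2:
        raise ValueError("need at least two pairwise-complete samples")
    a, b = a[both], b[both]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def r2_matrix(D: np.ndarray) -> np.ndarray:
    """Pairwise-complete r^2 matrix for a samples x SNPs dosage block."""
    D = np.asarray(D, float)
    M = (~np.isnan(D)).astype(float)
    X = np.where(np.isnan(D), 0.0, D)
    n = M.T @ M
    sx = X.T @ M
    sy = sx.T
    sxx = (X * X).T @ M
    syy = sxx.T
    sxy = X.T @ X
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        var_x = n * sxx - sx * sx
        var_y = n * syy - sy * sy
        r2 = cov * cov / (var_x * var_y)
    r2[~np.isfinite(r2)] = 0.0
    np.fill_diagonal(r2, 1.0)
    return r2


# ---------------------------------------------------------------------------
# greedy selection

def greedy_select_idx(stats_vec: np.ndarray, r2: np.ndarray, stat_min: float,
                      r2_threshold: float) -> list[int]:
    """Greedy LD-pruned pick of column indices, most significant first.

    Picks the max statistic among remaining SNPs while it reaches
    ``stat_min`` (the statistic equivalent of the p cutoff), then eliminates
    remaining SNPs with r^2 strictly above the threshold against the pick.
    Ties broken by input (chrom, pos) order.
    """
    selected: list[int] = []
    remaining = np.ones(len(stats_vec), bool)
    masked = np.where(remaining, stats_vec, -np.inf)
    while True:
        j = int(np.argmax(masked))
        if masked[j] < stat_min or not np.isfinite(masked[j]):
            break
        selected.append(j)
        kill = remaining & (r2[j] > r2_threshold)
        kill[j] = True
        remaining &= ~kill
        masked[kill] = -np.inf
        if not remaining.any():
            break
    return selected


def greedy_select(snp_ids: Sequence[str], pvals: np.ndarray, stats_vec: np.ndarray,
                  g: GenotypeMatrix, params: SetTestParams) -> list[str]:
    """Public wrapper returning selected SNP ids in selection order."""
    idx = g.index_of(snp_ids)
    r2 = r2_matrix(g.dosages[:, idx])
    stat_min = float(sps.chi2.isf(params.p_cutoff, df=1))
    picked = greedy_select_idx(np.asarray(stats_vec, float), r2, stat_min,
                               params.r2_threshold)
    # guard: respect the p cutoff exactly even if stats/p disagree slightly
    return [str(snp_ids[j]) for j in picked if pvals[j] <= params.p_cutoff]


# ---------------------------------------------------------------------------
# statistic engines

class ScoreEngine:
    """Partial-correlation t-square statistics, vectorized over SNPs and
    permutations.  Missing dosages are mean-imputed once."""

    def __init__(self, D: np.ndarray, y: np.ndarray, X_cov: np.ndarray):
        n = len(y)
        G = np.array(D, float)
        mu = np.nanmean(G, axis=0)
        nanmask = np.isnan(G)
        G[nanmask] = np.take(mu, np.nonzero(nanmask)[1])
        X = np.column_stack([np.ones(n), X_cov])
        Q, _ = np.linalg.qr(X)
        self.Q = Q
        self.df = n - X.shape[1] - 1
        self.Gr = G - Q @ (Q.T @ G)
        self.gg = (self.Gr**2).sum(axis=0)
        self.y = y

    def stats_for(self, Y: np.ndarray) -> np.ndarray:
        """Y: samples x P outcome matrix -> SNPs x P chi-square statistics."""
        Yr = Y - self.Q @ (self.Q.T @ Y)
        yy = (Yr**2).sum(axis=0)
        u = self.Gr.T @ Yr
        with np.errstate(invalid="ignore", divide="ignore"):
            rho2 = u**2 / (self.gg[:, None] * yy[None, :])
        rho2 = np.clip(rho2, 0.0, 1.0 - 1e-12)
        out = self.df * rho2 / (1.0 - rho2)
        out[~np.isfinite(out)] = 0.0
        out[self.gg == 0, :] = 0.0
        return out

    def observed(self) -> tuple[np.ndarray, np.ndarray]:
        s = self.stats_for(self.y[:, None])[:, 0]
        return s, sps.chi2.sf(s, df=1)


def _wald_stat_logistic(X: np.ndarray, y: np.ndarray) -> float:
    """1-df Wald chi-square for X[:, 1] from a Newton-fitted logistic model.
    Returns 0.0 on separation / non-convergence (flagged-result convention)."""
    beta = np.zeros(X.shape[1])
    for _ in range(50):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        if w.max() < 1e-10:
            return 0.0
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return 0.0
        beta += step
        if np.abs(step).max() < 1e-10:
            break
    else:
        return 0.0
    if np.abs(beta).max() > 50:   # separation drift
        return 0.0
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return 0.0
    se2 = cov[1, 1]
    return float(beta[1] ** 2 / se2) if se2 > 0 else 0.0


def _wald_stat_linear(X: np.ndarray, y: np.ndarray) -> float:
    """1-df Wald chi-square for X[:, 1] from an OLS fit."""
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        return 0.0
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    if dof <= 0:
        return 0.0
    sigma2 = float(resid @ resid) / dof
    se2 = sigma2 * XtX_inv[1, 1]
    return float(beta[1] ** 2 / se2) if se2 > 0 else 0.0


class WaldRefitEngine:
    """Reference engine: refits the full GLM per SNP (and per permutation)
    with complete-case handling per SNP, exactly as :func:`snp_association`
    does for the observed data."""

    def __init__(self, D: np.ndarray, samples: pd.DataFrame, spec: ModelSpec,
                 snp_ids: Sequence[str]):
        self.D = D
        self.spec = spec
        self.snp_ids = list(snp_ids)
        self.y = outcome_vector(samples, spec)
        self.X_cov = covariate_matrix(samples, spec)
        self._fit = _wald_stat_logistic if spec.model == "logistic" else _wald_stat_linear
        n, m = D.shape
        self._designs = []
        for j in range(m):
            keep = ~np.isnan(D[:, j])
            if self.X_cov.shape[1]:
                keep &= np.isfinite(self.X_cov).all(axis=1)
            X = np.column_stack([np.ones(int(keep.sum())), D[keep, j],
                                 self.X_cov[keep]])
            mono = np.unique(D[keep, j]).size < 2
            self._designs.append((keep, X, mono))

    def _stats_for_y(self, y: np.ndarray) -> np.ndarray:
        out = np.empty(self.D.shape[1])
        for j, (keep, X, mono) in enumerate(self._designs):
            out[j] = 0.0 if mono else self._fit(X, y[keep])
        return out

    def stats_for(self, Y: np.ndarray) -> np.ndarray:
        return np.column_stack([self._stats_for_y(Y[:, k]) for k in range(Y.shape[1])])

    def observed(self) -> tuple[np.ndarray, np.ndarray]:
        s = self._stats_for_y(self.y)
        return s, sps.chi2.sf(s, df=1)


def _analysis_mask(samples: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    y = outcome_vector(samples, spec)
    X = covariate_matrix(samples, spec)
    mask = samples["phenotyped"].astype(bool).to_numpy() & np.isfinite(y)
    if X.shape[1]:
        mask &= np.isfinite(X).all(axis=1)
    return mask


def _distinct_permutations(y: np.ndarray) -> np.ndarray:
    from sympy.utilities.iterables import multiset_permutations
    perms = np.array(list(multiset_permutations(list(y))), dtype=float)
    return perms.T  # samples x n_perm


def _perm_outcome_fn(y: np.ndarray, X_cov: np.ndarray, scheme: str):
    """Map a permutation index vector to a permuted outcome vector.

    ``label`` shuffles the phenotype itself (case/control label swapping and
    its quantitative analogue).  ``freedman_lane`` keeps the covariate fit
    in place and permutes only its residuals; with no covariates the two
    schemes coincide exactly.
    """
    if scheme == "label":
        return lambda perm: y[perm]
    X = np.column_stack([np.ones(len(y)), X_cov])
    Q, _ = np.linalg.qr(X)
    fitted = Q @ (Q.T @ y)
    resid = y - fitted
    return lambda perm: fitted + resid[perm]


def _make_engine(mode: str, D: np.ndarray, y: np.ndarray, X_cov: np.ndarray,
                 samples: pd.DataFrame, spec: ModelSpec, snp_ids: Sequence[str]):
    if mode == "score_fast":
        return ScoreEngine(D, y, X_cov)
    return WaldRefitEngine(D, samples, spec, snp_ids)


def set_based_test(set_def: PathwayDef | Sequence[str], g: GenotypeMatrix,
                   samples: pd.DataFrame, spec: ModelSpec,
                   params: SetTestParams, *, level: str = "pathway",
                   exhaustive: bool = False,
                   rng: np.random.Generator | None = None) -> SetTestResult:
    """Run the set-based permutation test for one SNP set.

    ``exhaustive=True`` enumerates every distinct permutation of the
    phenotype vector instead of sampling (tiny cohorts only) and reports the
    exact permutation p (count / total, identity included, no +1).
    """
    if isinstance(set_def, PathwayDef):
        name, snp_ids = set_def.name, list(set_def.snp_ids)
    else:
        name, snp_ids = "set", [str(s) for s in set_def]
    n_snps = len(snp_ids)
    if n_snps == 0:
        return SetTestResult(set_name=name, level=level, outcome=spec.outcome,
                             n_snps=0, selected=(), set_stat=0.0, n_perm=0, emp_p=1.0)

    mask = _analysis_mask(samples, spec)
    sub = samples.loc[mask].reset_index(drop=True)
    idx = g.index_of(snp_ids)
    D = g.dosages[np.ix_(mask, idx)]
    y = outcome_vector(sub, spec)
    X_cov = covariate_matrix(sub, spec)

    mode = params.resolve_mode(n_fits=n_snps * (params.n_perm + 1))
    engine = _make_engine(mode, D, y, X_cov, sub, spec, snp_ids)
    obs_stats, obs_p = engine.observed()
    r2 = r2_matrix(D)
    stat_min = float(sps.chi2.isf(params.p_cutoff, df=1))
    picked = greedy_select_idx(obs_stats, r2, stat_min, params.r2_threshold)
    selected = tuple(snp_ids[j] for j in picked)
    if not picked:
        return SetTestResult(set_name=name, level=level, outcome=spec.outcome,
                             n_snps=n_snps, selected=(), set_stat=0.0,
                             n_perm=0, emp_p=1.0)
    set_stat = float(np.mean(obs_stats[picked]))

    if exhaustive:
        Y = _distinct_permutations(y)
        n_perm = Y.shape[1]
        perm_stats = engine.stats_for(Y)
        count = _count_exceeding(perm_stats, r2, stat_min, params.r2_threshold, set_stat)
        emp_p = count / n_perm
        return SetTestResult(set_name=name, level=level, outcome=spec.outcome,
                             n_snps=n_snps, selected=selected, set_stat=set_stat,
                             n_perm=n_perm, emp_p=float(emp_p))

    if rng is None:
        rng = np.random.default_rng(params.seed)
    perm_y = _perm_outcome_fn(y, X_cov, params.perm_scheme)
    count = 0
    done = 0
    block = 256
    n = len(y)
    while done < params.n_perm:
        b = min(block, params.n_perm - done)
        Y = np.empty((n, b))
        for k in range(b):
            Y[:, k] = perm_y(rng.permutation(n))
        perm_stats = engine.stats_for(Y)
        count += _count_exceeding(perm_stats, r2, stat_min, params.r2_threshold, set_stat)
        done += b
    emp_p = (1 + count) / (params.n_perm + 1)
    return SetTestResult(set_name=name, level=level, outcome=spec.outcome,
                         n_snps=n_snps, selected=selected, set_stat=set_stat,
                         n_perm=params.n_perm, emp_p=float(emp_p))


def _count_exceeding(perm_stats: np.ndarray, r2: np.ndarray, stat_min: float,
                     r2_threshold: float, observed: float) -> int:
    """Count permutations whose greedily-selected mean statistic >= observed.

    Ties count as exceeding; the comparison carries a small relative
    tolerance so exact ties survive floating-point noise between the
    observed and permuted computation paths.
    """
    cut = observed - max(1e-12, 1e-9 * abs(observed))
    count = 0
    for k in range(perm_stats.shape[1]):
        picked = greedy_select_idx(perm_stats[:, k], r2, stat_min, r2_threshold)
        stat = float(np.mean(perm_stats[picked, k])) if picked else 0.0
        if stat >= cut:
            count += 1
    return count


def run_level(sets: Sequence[PathwayDef], g: GenotypeMatrix, samples: pd.DataFrame,
              specs: Sequence[ModelSpec], params: SetTestParams, *,
              level: str = "pathway") -> list[SetTestResult]:
    """Set-based test for every set x outcome, sharing one permutation
    stream per outcome so the per-SNP statistics are computed once."""
    results: list[SetTestResult] = []
    for spec in specs:
        results.extend(_run_level_one_outcome(sets, g, samples, spec, params, level))
    return results


def _run_level_one_outcome(sets: Sequence[PathwayDef], g: GenotypeMatrix,
                           samples: pd.DataFrame, spec: ModelSpec,
                           params: SetTestParams, level: str,
                           grid: Sequence[tuple[str, float, float]] | None = None):
    """Shared-permutation engine over the union of set SNPs.

    When ``grid`` is given, every (r2, p_cutoff) cell is evaluated against
    the identical permutation statistics (same seed by construction).
    Returns a list of SetTestResult, or a list of (condition, SetTestResult)
    when ``grid`` is set.
    """
    union_ids: list[str] = []
    seen: set[str] = set()
    for s in sets:
        for snp in s.snp_ids:
            if snp not in seen:
                seen.add(snp)
                union_ids.append(snp)
    cells = [(None, params)] if grid is None else [
        (cond, replace(params, r2_threshold=r2, p_cutoff=pc)) for cond, r2, pc in grid
    ]

    if not union_ids:
        out = []
        for cond, cell in cells:
            for s in sets:
                r = SetTestResult(set_name=s.name, level=level, outcome=spec.outcome,
                                  n_snps=0, selected=(), set_stat=0.0, n_perm=0, emp_p=1.0)
                out.append(r if grid is None else (cond, r))
        return out

    mask = _analysis_mask(samples, spec)
    sub = samples.loc[mask].reset_index(drop=True)
    union_idx = g.index_of(union_ids)
    D_union = g.dosages[np.ix_(mask, union_idx)]
    y = outcome_vector(sub, spec)
    X_cov = covariate_matrix(sub, spec)
    col_of = {snp: j for j, snp in enumerate(union_ids)}

    mode = params.resolve_mode(n_fits=len(union_ids) * (params.n_perm + 1))
    engine = _make_engine(mode, D_union, y, X_cov, sub, spec, union_ids)
    obs_stats, _ = engine.observed()

    set_cols = [np.array([col_of[snp] for snp in s.snp_ids], dtype=int) for s in sets]
    set_r2 = [r2_matrix(D_union[:, cols]) if len(cols) else np.empty((0, 0))
              for cols in set_cols]

    observed: dict[tuple[int, int], tuple[tuple[str, ...], float]] = {}
    counts = np.zeros((len(cells), len(sets)), dtype=int)
    stat_mins = [float(sps.chi2.isf(cell.p_cutoff, df=1)) for _, cell in cells]
    for ci, (_, cell) in enumerate(cells):
        for si, s in enumerate(sets):
            cols = set_cols[si]
            picked = greedy_select_idx(obs_stats[cols], set_r2[si], stat_mins[ci],
                                       cell.r2_threshold) if len(cols) else []
            sel = tuple(s.snp_ids[j] for j in picked)
            stat = float(np.mean(obs_stats[cols][picked])) if picked else 0.0
            observed[(ci, si)] = (sel, stat)

    active = [(ci, si) for ci in range(len(cells)) for si in range(len(sets))
              if observed[(ci, si)][0]]
    n_perm = params.n_perm
    if active and n_perm > 0:
        rng = np.random.default_rng(params.seed)
        perm_y = _perm_outcome_fn(y, X_cov, params.perm_scheme)
        n = len(y)
        done = 0
        block = 256
        while done < n_perm:
            b = min(block, n_perm - done)
            Y = np.empty((n, b))
            for k in range(b):
                Y[:, k] = perm_y(rng.permutation(n))
            perm_stats = engine.stats_for(Y)
            for ci, si in active:
                cols = set_cols[si]
                sub_stats = perm_stats[cols, :]
                obs_set_stat = observed[(ci, si)][1]
                cut = obs_set_stat - max(1e-12, 1e-9 * abs(obs_set_stat))
                for k in range(b):
                    picked = greedy_select_idx(sub_stats[:, k], set_r2[si],
                                               stat_mins[ci], cells[ci][1].r2_threshold)
                    stat = float(np.mean(sub_stats[picked, k])) if picked else 0.0
                    if stat >= cut:
                        counts[ci, si] += 1
            done += b

    out = []
    for ci, (cond, cell) in enumerate(cells):
        for si, s in enumerate(sets):
            sel, stat = observed[(ci, si)]
            if sel:
                emp_p = (1 + int(counts[ci, si])) / (n_perm + 1)
                r = SetTestResult(set_name=s.name, level=level, outcome=spec.outcome,
                                  n_snps=len(s.snp_ids), selected=sel,
                                  set_stat=stat, n_perm=n_perm, emp_p=float(emp_p))
            else:
                r = SetTestResult(set_name=s.name, level=level, outcome=spec.outcome,
                                  n_snps=len(s.snp_ids), selected=(), set_stat=0.0,
                                  n_perm=0, emp_p=1.0)
            out.append(r if grid is None else (cond, r))
    return out


def sensitivity_grid(set_def: PathwayDef, g: GenotypeMatrix, samples: pd.DataFrame,
                     specs: Sequence[ModelSpec], params: SetTestParams,
                     grid: Sequence[tuple[str, float, float]] = DEFAULT_GRID
                     ) -> pd.DataFrame:
    """Empirical p for one set under a grid of (r^2, p_cutoff) conditions,
    every cell scored against the same permutation stream."""
    rows = []
    for spec in specs:
        cells = _run_level_one_outcome([set_def], g, samples, spec, params,
                                       level="pathway", grid=list(grid))
        for cond, res in cells:
            cell = dict(zip([c[0] for c in grid], grid))[cond]
            rows.append({"outcome": spec.outcome, "condition": cond,
                         "r2": cell[1], "p_cutoff": cell[2],
                         "n_sig": res.n_sig, "emp_p": res.emp_p})
    return pd.DataFrame(rows, columns=["outcome", "condition", "r2", "p_cutoff",
                                       "n_sig", "emp_p"])


__all__ = [
    "SetTestParams", "DEFAULT_GRID", "bonferroni_cutoff", "format_cutoff",
    "pairwise_r2", "r2_matrix", "greedy_select", "greedy_select_idx",
    "set_based_test", "run_level", "sensitivity_grid",
    "ScoreEngine", "WaldRefitEngine",
]
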
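"""End-to-end orchestration and publication-style outputs.

``run_all`` drives simulate/read -> QC -> per-SNP association for the three
outcomes -> pathway-level set tests -> gene-level set tests inside the top
pathway -> sensitivity grid -> risk-score quintile models, and writes every
stage artifact (TSV + markdown + JSON manifest) under the output directory.
A run is reproducible from config + seed alone.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import ModelSpec, assoc_scan, results_frame
from .cohort import (
    PathwayDef,
    assign_snps_to_genes,
    build_pathways,
    read_cohort,
    read_gene_intervals,
    read_pathway_memberships,
)
from .qc import QcThresholds, apply_qc
from .riskscore import build_risk_model, quintile_model, score_samples
from .settest import (
    DEFAULT_GRID,
    SetTestParams,
    bonferroni_cutoff,
    run_level,
    sensitivity_grid,
)
from .simulate import SimulationSpec, simulate_cohort

OUTCOME_SPECS = (ModelSpec("HTN"), ModelSpec("DBP"), ModelSpec("SBP"))


@dataclass
class RunConfig:
    out_dir: str = "pathscan_out"
    seed: int | None = None
    # either a simulation block ...
    simulate: dict | None = None
    # ... or paths to cohort files
    genotype_path: str | None = None
    genotype_format: str = "plink_text"
    phenotype_path: str | None = None
    gene_path: str | None = None
    pathway_path: str | None = None
    gene_flank_bp: int = 20_000
    qc: dict = field(default_factory=dict)
    set_test: dict = field(default_factory=dict)
    grid: list = field(default_factory=lambda: [list(row) for row in DEFAULT_GRID])
    outcomes: list = field(default_factory=lambda: ["HTN", "DBP", "SBP"])

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is required and never defaulted")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def format_p(p: float, n_perm: int | None = None) -> str:
    """Two-significant-figure p-value string, floored at 1/(n_perm+1)."""
    if n_perm:
        p = max(p, 1.0 / (n_perm + 1))
    if p >= 0.995:
        return "1.00"
    return f"{p:.2g}"


def pathway_table(results, n_perm_floor: bool = True, alpha: float = 0.05) -> pd.DataFrame:
    """Table-2 style pathway report: one row per set, N Sig + P per outcome,
    sorted by the HTN empirical p, starred at the Bonferroni cutoff."""
    by_set: dict[str, dict] = {}
    outcomes = []
    for r in results:
        if r.outcome not in outcomes:
            outcomes.append(r.outcome)
        row = by_set.setdefault(r.set_name, {"Pathway": r.set_name, "SNPs": r.n_snps})
        row[f"N_Sig_{r.outcome}"] = r.n_sig
        row[f"P_{r.outcome}"] = r.emp_p
        row[f"Pstr_{r.outcome}"] = format_p(r.emp_p, r.n_perm if n_perm_floor else None)
    cutoff = bonferroni_cutoff(alpha, len(by_set)) if by_set else alpha
    rows = list(by_set.values())
    for row in rows:
        for out in outcomes:
            p = row.get(f"P_{out}", 1.0)
            if p < cutoff:
                row[f"Pstr_{out}"] = row[f"Pstr_{out}"] + "*"
    sort_key = f"P_{outcomes[0]}" if outcomes else None
    df = pd.DataFrame(rows)
    if sort_key and sort_key in df.columns:
        df = df.sort_values([sort_key, "Pathway"], kind="mergesort").reset_index(drop=True)
    return df


def gene_table(results, assoc_by_outcome: dict[str, pd.DataFrame],
               alpha: float = 0.05, n_genes_total: int | None = None) -> pd.DataFrame:
    """Table-3 style gene report: adds the most significant SNP's OR (binary)
    or beta (continuous); genes with no selected SNP render 'NA'."""
    by_gene: dict[str, dict] = {}
    outcomes = []
    for r in results:
        if r.outcome not in outcomes:
            outcomes.append(r.outcome)
        row = by_gene.setdefault(r.set_name, {"Gene": r.set_name, "SNPs": r.n_snps})
        row[f"N_Sig_{r.outcome}"] = r.n_sig
        row[f"P_{r.outcome}"] = format_p(r.emp_p, r.n_perm or None)
        if r.n_sig == 0:
            row[f"Effect_{r.outcome}"] = "NA"
        else:
            top = r.selected[0]
            tab = assoc_by_outcome[r.outcome]
            rec = tab.loc[tab["snp"] == top]
            if rec.empty:
                row[f"Effect_{r.outcome}"] = "NA"
            elif r.outcome == "HTN":
                row[f"Effect_{r.outcome}"] = f"{float(rec['or'].iloc[0]):.2f}"
            else:
                row[f"Effect_{r.outcome}"] = f"{float(rec['effect'].iloc[0]):.2f}"
    return pd.DataFrame(list(by_gene.values()))


def sensitivity_table(df: pd.DataFrame) -> pd.DataFrame:
    """Table-4 layout: Outcome / Conditions / R2 / P_SNP cutoff / P_path."""
    out = df.rename(columns={"outcome": "Outcome", "condition": "Conditions",
                             "r2": "R2", "p_cutoff": "P_SNP_cutoff",
                             "emp_p": "P_path"})
    return out[["Outcome", "Conditions", "R2", "P_SNP_cutoff", "P_path"]]


def _df_to_markdown(df: pd.DataFrame) -> str:
    header = "| " + " | ".join(map(str, df.columns)) + " |"
    sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
    lines = [header, sep]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines) + "\n"


def _load_inputs(config: RunConfig):
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        if "pathways" in sim_kwargs:
            sim_kwargs["pathways"] = [tuple(p) for p in sim_kwargs["pathways"]]
        spec = SimulationSpec(**sim_kwargs)
        g, variants, genes, pathways, samples, truth = simulate_cohort(spec)
        return g, samples, genes, pathways, truth
    if not (config.genotype_path and config.phenotype_path
            and config.gene_path and config.pathway_path):
        raise ValueError("either 'simulate' or all four cohort file paths are required")
    g, _, samples = read_cohort(config.genotype_path, config.phenotype_path,
                                format=config.genotype_format)
    genes = read_gene_intervals(config.gene_path, flank_bp=config.gene_flank_bp)
    memberships = read_pathway_memberships(config.pathway_path)
    gene_map = assign_snps_to_genes(g.variants, genes)
    pathways = build_pathways(memberships, gene_map)
    return g, samples, genes, pathways, None


def _restrict_sets(pathways, surviving_ids: set[str]):
    return [PathwayDef(name=p.name, genes=list(p.genes),
                       snp_ids=[s for s in p.snp_ids if s in surviving_ids])
            for p in pathways]


def run_all(config: RunConfig) -> Path:
    """Execute every stage; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        g, samples, genes, pathways, truth = _load_inputs(config)

        stage = "qc"
        thresholds = QcThresholds(**config.qc)
        keep = samples["phenotyped"].astype(bool).to_numpy()
        if not keep.all():   # single analysis population: drop unphenotyped
            g = g.subset(sample_mask=keep)
            samples = samples.loc[keep].reset_index(drop=True)
        g, samples, qc_report = apply_qc(g, samples, thresholds)
        qc_report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
        surviving = set(map(str, g.variant_ids))
        pathways = _restrict_sets(pathways, surviving)

        stage = "association"
        specs = [ModelSpec(o) for o in config.outcomes]
        assoc_by_outcome = {}
        for spec in specs:
            res = assoc_scan(g, samples, spec)
            tab = results_frame(res, g.variants)
            tab.to_csv(out / f"assoc_{spec.outcome.lower()}.tsv", sep="\t", index=False)
            assoc_by_outcome[spec.outcome] = tab

        stage = "pathway set test"
        params = SetTestParams(seed=config.seed, **config.set_test)
        path_results = run_level(pathways, g, samples, specs, params, level="pathway")
        ptab = pathway_table(path_results)
        ptab.to_csv(out / "pathway_table.tsv", sep="\t", index=False)
        (out / "pathway_table.md").write_text(_df_to_markdown(ptab))

        stage = "gene set test"
        htn_results = [r for r in path_results if r.outcome == specs[0].outcome]
        top = min(htn_results, key=lambda r: (r.emp_p, r.set_name))
        top_def = next(p for p in pathways if p.name == top.set_name)
        gene_map = assign_snps_to_genes(g.variants, genes)
        gene_sets = [PathwayDef(name=gn, genes=[gn],
                                snp_ids=[s for s in gene_map.get(gn, []) if s in surviving])
                     for gn in top_def.genes]
        gene_results = run_level(gene_sets, g, samples, specs, params, level="gene")
        gtab = gene_table(gene_results, assoc_by_outcome)
        gtab.to_csv(out / "gene_table.tsv", sep="\t", index=False)
        (out / "gene_table.md").write_text(_df_to_markdown(gtab))

        stage = "sensitivity grid"
        grid = [tuple(row) for row in config.grid]
        sens = sensitivity_grid(top_def, g, samples, specs, params, grid=grid)
        sensitivity_table(sens).to_csv(out / "sensitivity_table.tsv", sep="\t", index=False)

        stage = "risk score"
        quintiles = {}
        for spec in specs:
            sel = [r for r in path_results
                   if r.outcome == spec.outcome and r.set_name == top.set_name]
            selected = list(sel[0].selected) if sel else []
            if not selected:
                continue
            tab = assoc_by_outcome[spec.outcome]
            assoc_map = {
                row.snp: _assoc_from_row(row, spec)
                for row in tab.itertuples() if row.snp in set(selected)
            }
            model = build_risk_model(assoc_map, selected)
            model.to_frame().to_csv(out / f"risk_model_{spec.outcome.lower()}.tsv",
                                    sep="\t", index=False)
            scores = score_samples(g, model)
            scores.to_csv(out / f"risk_scores_{spec.outcome.lower()}.tsv",
                          sep="\t", index=False)
            try:
                qm = quintile_model(scores, samples, spec)
            except ValueError:
                continue
            qm.to_csv(out / f"quintile_{spec.outcome.lower()}.tsv", sep="\t", index=False)
            quintiles[spec.outcome] = qm

        stage = "manifest"
        manifest = {
            "pathscan_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "seed": config.seed,
            "config": asdict(config),
            "n_samples": int(g.n_samples),
            "n_snps": int(g.n_variants),
            "n_pathways": len(pathways),
            "top_pathway": top.set_name,
            "bonferroni_pathway_cutoff": bonferroni_cutoff(0.05, len(pathways)),
        }
        if truth is not None:
            manifest["planted_truth"] = truth
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out


def _assoc_from_row(row, spec: ModelSpec):
    from .cohort.types import AssocResult
    return AssocResult(snp_id=row.snp, model=spec.model, outcome=spec.outcome,
                       effect=float(row.effect), se=float(row.se),
                       statistic=float(row.stat), p=float(row.p),
                       n_used=int(row.n), monomorphic=bool(row.monomorphic),
                       converged=bool(row.converged))


__all__ = ["RunConfig", "run_all", "pathway_table", "gene_table",
           "sensitivity_table", "format_p", "OUTCOME_SPECS"]
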
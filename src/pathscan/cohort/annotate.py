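"""SNP-to-gene assignment and pathway construction."""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import pandas as pd

from .types import CohortError, GeneInterval, PathwayDef


def assign_snps_to_genes(variants: pd.DataFrame,
                         genes: Sequence[GeneInterval]) -> dict[str, list[str]]:
    """Map each gene to the SNP ids inside its flanked interval.

    A SNP belongs to a gene iff the chromosome matches and
    ``start - flank <= pos <= end + flank`` (bounds inclusive).  A SNP may
    land in several overlapping genes; empty assignments are kept.
    """
    chroms = variants["chrom"].astype(str).to_numpy()
    pos = variants["pos"].to_numpy()
    ids = variants["id"].to_numpy()
    out: dict[str, list[str]] = {}
    for gene in genes:
        mask = (chroms == str(gene.chrom)) & (pos >= gene.flanked_start) & (pos <= gene.flanked_end)
        out[gene.name] = [str(s) for s in ids[mask]]
    return out


def build_pathways(memberships: Sequence[tuple[str, str]] | Mapping[str, Sequence[str]],
                   gene_map: Mapping[str, Sequence[str]]) -> list[PathwayDef]:
    """Resolve pathway -> gene memberships into de-duplicated SNP id sets.

    ``memberships`` is either a list of (pathway, gene) rows or a mapping
    pathway -> genes.  Genes absent from ``gene_map`` trigger a warning and
    are skipped; a pathway left with zero SNPs is retained.
    """
    if isinstance(memberships, Mapping):
        rows = [(p, g) for p, gs in memberships.items() for g in gs]
    else:
        rows = list(memberships)
    if not rows:
        raise CohortError("empty pathway definition")

    ordered: dict[str, list[str]] = {}
    for pathway, gene in rows:
        ordered.setdefault(str(pathway), []).append(str(gene))

    defs = []
    for name, genes in ordered.items():
        snp_ids: list[str] = []
        seen: set[str] = set()
        for gene in genes:
            if gene not in gene_map:
                warnings.warn(f"pathway {name!r}: gene {gene!r} not in gene list; skipped")
                continue
            for snp in gene_map[gene]:
                if snp not in seen:
                    seen.add(snp)
                    snp_ids.append(snp)
        defs.append(PathwayDef(name=name, genes=genes, snp_ids=snp_ids))
    return defs


__all__ = ["assign_snps_to_genes", "build_pathways"]
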
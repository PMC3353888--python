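"""Readers and writers for cohort files.

Supported genotype formats: PLINK text (.ped/.map), PLINK 1 binary
(.bed/.bim/.fam, SNP-major) and plain-text VCF (biallelic SNPs only).
Phenotypes, gene intervals and pathway memberships are tab-separated text.

After reading, every variant is re-oriented so that the coded allele is the
minor allele as observed in the data (ties at frequency 0.5 keep the file's
coding).  Genotyped samples without a phenotype row are retained and flagged
``phenotyped = False``.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ..phenotypes import adjust_bp_for_medication, classify_hypertension, compute_bmi
from .types import (
    CohortError,
    GeneInterval,
    GenotypeMatrix,
    make_variant_table,
    new_sample_table,
    orient_to_minor,
)

_SEX_CODES = {"male": "male", "m": "male", "1": "male",
              "female": "female", "f": "female", "2": "female"}

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# PLINK 1 2-bit codes -> dosage of allele A1: 00=2, 01=missing, 10=1, 11=0
_BED_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSAGE_TO_BED_CODE = {2.0: 0, 1.0: 2, 0.0: 3}


# ---------------------------------------------------------------------------
# phenotype / gene / pathway tables

def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read the phenotype TSV (id, sex, age, weight_kg, height_m, sbp, dbp,
    on_med) and derive BMI, medication-adjusted BP and hypertension status."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    required = ["id", "sex", "age", "weight_kg", "height_m", "sbp", "dbp", "on_med"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortError(f"phenotype file missing columns: {missing}")
    if df["id"].duplicated().any():
        raise CohortError("duplicated sample id in phenotype file")
    sex = df["sex"].astype(str).str.lower().map(_SEX_CODES)
    if sex.isna().any():
        bad = df.loc[sex.isna(), "sex"].iloc[0]
        raise CohortError(f"unrecognized sex code: {bad!r}")
    on_med = df["on_med"].astype(str).str.lower().isin(["1", "true", "yes"])
    out = new_sample_table(df["id"])
    out["sex"] = sex.to_numpy()
    out["age"] = df["age"].astype(float).to_numpy()
    out["weight_kg"] = df["weight_kg"].astype(float).to_numpy()
    out["height_m"] = df["height_m"].astype(float).to_numpy()
    out["bmi"] = compute_bmi(out["weight_kg"], out["height_m"])
    out["sbp_raw"] = df["sbp"].astype(float).to_numpy()
    out["dbp_raw"] = df["dbp"].astype(float).to_numpy()
    out["on_med"] = on_med.to_numpy()
    sbp_adj, dbp_adj = adjust_bp_for_medication(out["sbp_raw"], out["dbp_raw"], out["on_med"])
    out["sbp_adj"], out["dbp_adj"] = sbp_adj, dbp_adj
    out["hypertensive"] = classify_hypertension(out["sbp_raw"], out["dbp_raw"], out["on_med"])
    out["phenotyped"] = True
    return out


def write_phenotypes(samples: pd.DataFrame, path: str | Path) -> None:
    df = pd.DataFrame({
        "id": samples["id"],
        "sex": samples["sex"],
        "age": samples["age"],
        "weight_kg": samples["weight_kg"],
        "height_m": samples["height_m"],
        "sbp": samples["sbp_raw"],
        "dbp": samples["dbp_raw"],
        "on_med": samples["on_med"].astype(bool).astype(int),
    })
    df.to_csv(path, sep="\t", index=False)


def read_gene_intervals(path: str | Path, flank_bp: int = 20_000) -> list[GeneInterval]:
    """Read a 4+ column TSV (gene, chrom, start, end)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    required = ["gene", "chrom", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortError(f"gene file missing columns: {missing}")
    return [GeneInterval(name=r.gene, chrom=str(r.chrom), start=int(r.start),
                         end=int(r.end), flank_bp=flank_bp)
            for r in df.itertuples()]


def write_gene_intervals(genes: Sequence[GeneInterval], path: str | Path) -> None:
    pd.DataFrame([{"gene": g.name, "chrom": g.chrom, "start": g.start, "end": g.end}
                  for g in genes]).to_csv(path, sep="\t", index=False)


def read_pathway_memberships(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column TSV (pathway, gene), one row per membership."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"pathway", "gene"}.issubset(df.columns):
        raise CohortError("pathway file needs columns: pathway, gene")
    if df.empty:
        raise CohortError("empty pathway file")
    return list(df[["pathway", "gene"]].itertuples(index=False, name=None))


def write_pathway_memberships(rows: Sequence[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(rows, columns=["pathway", "gene"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotype formats

def _decode_ped_genotypes(tokens: list[str], n_variants: int,
                          sample_id: str) -> tuple[list[tuple[str, str]], None]:
    pairs = tokens[6:]
    if len(pairs) != 2 * n_variants:
        raise CohortError(f"sample {sample_id}: expected {2 * n_variants} alleles, "
                          f"got {len(pairs)}")
    return [(pairs[2 * k], pairs[2 * k + 1]) for k in range(n_variants)], None


def _read_plink_text(prefix: Path):
    map_df = pd.read_csv(prefix.with_suffix(".map"), sep=r"\s+", header=None,
                         names=["chrom", "id", "cm", "pos"], dtype={"chrom": str, "id": str})
    n_variants = len(map_df)
    sample_ids, sexes, allele_rows = [], [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            tokens = line.split()
            if not tokens:
                continue
            sample_ids.append(tokens[1])
            sexes.append(tokens[4])
            allele_rows.append(_decode_ped_genotypes(tokens, n_variants, tokens[1])[0])
    male = np.array([s == "1" for s in sexes])

    # per variant: determine the two observed alleles, code dosage of allele1
    dosages = np.full((len(sample_ids), n_variants), np.nan)
    a_minor, a_major = [], []
    for j in range(n_variants):
        counts: dict[str, int] = {}
        for row in allele_rows:
            for a in row[j]:
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        alleles = sorted(counts, key=lambda a: (counts[a], a))
        if len(alleles) > 2:
            raise CohortError(f"non-biallelic variant {map_df['id'][j]!r}")
        if not alleles:
            a1, a2 = "N", "N"
        elif len(alleles) == 1:
            a1, a2 = alleles[0], "N"      # monomorphic: no alternate seen
        else:
            a1, a2 = alleles[0], alleles[1]   # least frequent first
        a_minor.append(a1)
        a_major.append(a2)
        for i, row in enumerate(allele_rows):
            x, y = row[j]
            if x == "0" or y == "0":
                continue
            dosages[i, j] = (x == a1) + (y == a1)
    variants = make_variant_table([
        {"id": v.id, "chrom": str(v.chrom), "pos": int(v.pos),
         "minor_allele": a_minor[j], "major_allele": a_major[j]}
        for j, v in enumerate(map_df.itertuples())
    ])
    return dosages, np.array(sample_ids, dtype=object), variants, male


def _write_plink_text(g: GenotypeMatrix, samples: pd.DataFrame, prefix: Path) -> None:
    v = g.variants
    with open(prefix.with_suffix(".map"), "w") as fh:
        for row in v.itertuples():
            fh.write(f"{row.chrom}\t{row.id}\t0\t{int(row.pos)}\n")
    sex_code = samples.set_index("id")["sex"].map({"male": "1", "female": "2"}).to_dict()
    minor = v["minor_allele"].fillna("A").to_numpy()
    major = v["major_allele"].fillna("B").to_numpy()
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, sid in enumerate(g.sample_ids):
            fields = [str(sid), str(sid), "0", "0", sex_code.get(sid, "0"), "-9"]
            for j in range(g.n_variants):
                d = g.dosages[i, j]
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 2:
                    fields += [minor[j], minor[j]]
                elif d == 1:
                    # male X hemizygote written as homozygous minor
                    if g.male is not None and g.male[i] and str(v["chrom"][j]) == "X":
                        fields += [minor[j], minor[j]]
                    else:
                        fields += [minor[j], major[j]]
                else:
                    fields += [major[j], major[j]]
            fh.write(" ".join(fields) + "\n")


def _read_plink_binary(prefix: Path):
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"],
                      dtype={"iid": str, "sex": str})
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "id": str, "a1": str, "a2": str})
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise CohortError("not a SNP-major PLINK 1 .bed file")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * m:
        raise CohortError(".bed size does not match .fam/.bim dimensions")
    body = body.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.stack([(body >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2)
    codes = codes.reshape(m, -1)[:, :n]
    dosages = _BED_CODE_TO_DOSAGE[codes].T.copy()
    male = (fam["sex"] == "1").to_numpy()
    variants = make_variant_table([
        {"id": r.id, "chrom": str(r.chrom), "pos": int(r.pos),
         "minor_allele": r.a1, "major_allele": r.a2}
        for r in bim.itertuples()
    ])
    return dosages, fam["iid"].to_numpy(dtype=object), variants, male


def _write_plink_binary(g: GenotypeMatrix, samples: pd.DataFrame, prefix: Path) -> None:
    v = g.variants
    sex_code = samples.set_index("id")["sex"].map({"male": "1", "female": "2"}).to_dict()
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in g.sample_ids:
            fh.write(f"{sid} {sid} 0 0 {sex_code.get(sid, '0')} -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for row in v.itertuples():
            a1 = row.minor_allele if isinstance(row.minor_allele, str) else "A"
            a2 = row.major_allele if isinstance(row.major_allele, str) else "B"
            fh.write(f"{row.chrom}\t{row.id}\t0\t{int(row.pos)}\t{a1}\t{a2}\n")
    n, m = g.n_samples, g.n_variants
    is_x = (v["chrom"].astype(str) == "X").to_numpy()
    bytes_per_snp = (n + 3) // 4
    out = np.empty((m, bytes_per_snp), dtype=np.uint8)
    codes = np.empty(n, dtype=np.uint8)
    for j in range(m):
        col = g.dosages[:, j]
        if is_x[j] and g.male is not None:
            col = col.copy()
            col[g.male & (col == 1)] = 2.0   # hemizygote stored as hom A1
        codes.fill(1)  # missing
        for dose, code in _DOSAGE_TO_BED_CODE.items():
            codes[col == dose] = code
        padded = np.zeros(bytes_per_snp * 4, dtype=np.uint8)
        padded[:n] = codes
        padded[n:] = 1
        quads = padded.reshape(-1, 4)
        out[j] = quads[:, 0] | (quads[:, 1] << 2) | (quads[:, 2] << 4) | (quads[:, 3] << 6)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        out.tofile(fh)


def _read_vcf(path: Path):
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise CohortError("VCF support requires cyvcf2") from exc
    vcf = VCF(str(path))
    sample_ids = np.array(vcf.samples, dtype=object)
    records, cols = [], []
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            raise CohortError(f"non-biallelic variant {var.ID or var.POS!r}")
        chrom = var.CHROM.removeprefix("chr")
        gts = np.asarray(var.genotype.array())[:, :2].astype(float)
        gts[gts < 0] = np.nan
        records.append({"id": var.ID or f"{chrom}:{var.POS}", "chrom": chrom,
                        "pos": var.POS, "minor_allele": var.ALT[0],
                        "major_allele": var.REF})
        cols.append(np.nansum(gts, axis=1) + np.where(np.isnan(gts).all(axis=1), np.nan, 0))
    dosages = np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))
    return dosages, sample_ids, make_variant_table(records), None


def _write_vcf(g: GenotypeMatrix, samples: pd.DataFrame, path: Path) -> None:
    v = g.variants
    order = np.lexsort((v["pos"].to_numpy(), v["chrom"].to_numpy()))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, g.sample_ids)) + "\n")
        for j in order:
            row = v.iloc[j]
            gts = []
            for i in range(g.n_samples):
                d = g.dosages[i, j]
                if np.isnan(d):
                    gts.append("./.")
                elif d == 2:
                    gts.append("1/1")
                elif d == 1:
                    gts.append("0/1")
                else:
                    gts.append("0/0")
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{row['id']}\t"
                     f"{row['major_allele']}\t{row['minor_allele']}\t.\t.\t.\tGT\t"
                     + "\t".join(gts) + "\n")


_READERS = {"plink_text": _read_plink_text, "plink_binary": _read_plink_binary,
            "vcf": _read_vcf}


def read_cohort(genotype_path: str | Path, phenotype_path: str | Path | None,
                format: str = "plink_text"):
    """Load genotypes plus phenotypes into (GenotypeMatrix, VariantTable,
    SampleTable).

    Dosages are re-oriented to the observed minor allele.  Genotyped samples
    missing from the phenotype file are flagged (``phenotyped = False``),
    never dropped.
    """
    if format not in _READERS:
        raise CohortError(f"unknown genotype format: {format!r}")
    genotype_path = Path(genotype_path)
    dosages, sample_ids, variants, male = _READERS[format](genotype_path)

    if phenotype_path is not None:
        pheno = read_phenotypes(phenotype_path)
        if male is None:
            male = pd.Series(pheno.set_index("id")["sex"]).reindex(sample_ids).eq("male").to_numpy()
        unknown = [sid for sid in sample_ids if sid not in set(pheno["id"])]
        if unknown:
            warnings.warn(f"{len(unknown)} genotyped sample(s) without phenotypes "
                          f"(flagged, retained): {unknown[:5]}")
        samples = pd.DataFrame({"id": sample_ids}).merge(pheno, on="id", how="left")
        samples["phenotyped"] = samples["id"].isin(set(pheno["id"])).astype(bool)
    else:
        samples = new_sample_table(sample_ids)
        if male is not None:
            samples["sex"] = np.where(male, "male", "female")

    is_x = (variants["chrom"].astype(str) == "X").to_numpy()
    # male X hemizygotes: diploid-coded hom -> 1 copy; het -> invalid, missing
    if is_x.any() and male is not None and male.any():
        mx = np.ix_(male, is_x)
        block = dosages[mx]
        block[block == 2] = 1.0
        dosages[mx] = block
    flipped = orient_to_minor(dosages, male, is_x)
    if flipped.any():
        mi = variants.loc[flipped, "minor_allele"].copy()
        variants.loc[flipped, "minor_allele"] = variants.loc[flipped, "major_allele"]
        variants.loc[flipped, "major_allele"] = mi

    g = GenotypeMatrix(dosages=dosages, sample_ids=sample_ids,
                       variants=variants, male=male)
    return g, g.variants, samples


def write_cohort(g: GenotypeMatrix, samples: pd.DataFrame, out_prefix: str | Path,
                 format: str = "plink_text") -> None:
    """Write genotypes (plus a phenotype TSV at ``<prefix>.pheno.tsv``)."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if format == "plink_text":
        _write_plink_text(g, samples, prefix)
    elif format == "plink_binary":
        _write_plink_binary(g, samples, prefix)
    elif format == "vcf":
        _write_vcf(g, samples, prefix.with_suffix(".vcf"))
    else:
        raise CohortError(f"unknown genotype format: {format!r}")
    mask = samples["phenotyped"].astype(bool)
    write_phenotypes(samples.loc[mask], str(prefix) + ".pheno.tsv")


__all__ = [
    "read_cohort", "write_cohort", "read_phenotypes", "write_phenotypes",
    "read_gene_intervals", "write_gene_intervals",
    "read_pathway_memberships", "write_pathway_memberships",
]
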
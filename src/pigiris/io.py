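"""Readers and writers for the pipeline's on-disk formats.

Plain-text formats throughout: pedigree/phenotype CSV, phased VCF
(written directly, read through cyvcf2), a simple samples x variants
dosage TSV, BED-style coverage TSV (half-open windows), truth YAML,
gene annotation from GFF3 (via gffutils) or BED, and lower-triangle
relationship-matrix TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import MISSING, GenotypeMatrix, Pedigree, SimTruth

__all__ = [
    "write_pedigree_csv",
    "read_pedigree_csv",
    "write_phased_vcf",
    "read_vcf",
    "write_genotype_tsv",
    "read_genotype_tsv",
    "write_coverage_tsv",
    "read_coverage_tsv",
    "write_truth_yaml",
    "read_truth_yaml",
    "read_gene_annotation",
    "write_relationship_tsv",
]


def write_pedigree_csv(ped: Pedigree, path) -> None:
    ped.table.to_csv(path, index=False)


def read_pedigree_csv(path) -> Pedigree:
    df = pd.read_csv(path, dtype={"id": str, "sire": str, "dam": str})
    return Pedigree(df)


def write_phased_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal phased VCF 4.2 ('|' separator, './.' for missing)."""
    if not g.phased:
        raise ValueError("phased VCF writing requires haplotypes")
    lines = ["##fileformat=VCFv4.2"]
    for chrom in pd.unique(g.variants["chrom"]):
        sub = g.variants[g.variants["chrom"] == chrom]
        lines.append(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1000}>")
    if "r2" in g.variants.columns:
        lines.append(
            '##INFO=<ID=DR2,Number=1,Type=Float,Description="Imputation accuracy">'
        )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(g.sample_ids)
    )
    has_r2 = "r2" in g.variants.columns
    for j, var in enumerate(g.variants.itertuples(index=False)):
        info = f"DR2={var.r2:.4f}" if has_r2 else "."
        gts = []
        for i in range(g.n_samples):
            if g.dosages[i, j] == MISSING:
                gts.append("./.")
            else:
                gts.append(f"{g.haplotypes[i, 0, j]}|{g.haplotypes[i, 1, j]}")
        lines.append(
            f"{var.chrom}\t{var.pos}\t{var.chrom}_{var.pos}\t{var.ref}\t{var.alt}"
            f"\t.\tPASS\t{info}\tGT\t" + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF (GT field) into a GenotypeMatrix via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    chroms, poss, refs, alts, r2s = [], [], [], [], []
    dosage_rows, hap_rows = [], []
    all_phased = True
    for var in vcf:
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
        r2s.append(var.INFO.get("DR2"))
        row_d, row_h = [], []
        for gt in var.genotypes:  # [allele1, allele2, phased]
            a1, a2 = gt[0], gt[1]
            if a1 < 0 or a2 < 0:
                row_d.append(MISSING)
                row_h.append((0, 0))
            else:
                row_d.append(a1 + a2)
                row_h.append((a1, a2))
                if not gt[2]:
                    all_phased = False
        dosage_rows.append(row_d)
        hap_rows.append(row_h)
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts}
    )
    if any(r is not None for r in r2s):
        variants["r2"] = [np.nan if r is None else float(r) for r in r2s]
    dosages = np.array(dosage_rows, dtype=np.int8).T
    haps = None
    if all_phased and len(hap_rows):
        haps = np.array(hap_rows, dtype=np.int8).transpose(1, 2, 0)
    samples = pd.DataFrame({"id": sample_ids})
    return GenotypeMatrix(samples, variants, dosages, haps)


def write_genotype_tsv(g: GenotypeMatrix, path) -> None:
    """Samples x variants dosage TSV with NA for missing."""
    cols = g.variants["chrom"].astype(str) + "_" + g.variants["pos"].astype(str)
    df = pd.DataFrame(g.dosages.astype(float), index=g.sample_ids, columns=cols)
    df[g.dosages == MISSING] = np.nan
    df.index.name = "sample"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    chrom_pos = [c.rsplit("_", 1) for c in df.columns]
    variants = pd.DataFrame(
        {
            "chrom": [c for c, _ in chrom_pos],
            "pos": [int(p) for _, p in chrom_pos],
            "ref": "A",
            "alt": "C",
        }
    )
    d = df.to_numpy(dtype=float)
    dosages = np.where(np.isnan(d), MISSING, d).astype(np.int8)
    return GenotypeMatrix(pd.DataFrame({"id": df.index.astype(str)}), variants, dosages)


def write_coverage_tsv(coverage: pd.DataFrame, path) -> None:
    coverage[["chrom", "start", "end", "sample", "depth"]].to_csv(
        path, sep="\t", index=False
    )


def read_coverage_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})


def write_truth_yaml(truth: SimTruth, path) -> None:
    data = {
        "h2": float(truth.h2),
        "h2_trait2": float(truth.h2_trait2),
        "r_g": float(truth.r_g),
        "thresholds": [float(t) for t in truth.thresholds],
        "farm_date_effects": [float(x) for x in truth.farm_date_effects],
        "sex_effects": [float(x) for x in truth.sex_effects],
        "causal_variant": truth.causal_variant,
        "causal_effect": float(truth.causal_effect),
        "deletion_intervals": [
            [c, int(s), int(e)] for c, s, e in truth.deletion_intervals
        ],
    }
    Path(path).write_text(yaml.safe_dump(data))


def read_truth_yaml(path) -> SimTruth:
    data = yaml.safe_load(Path(path).read_text())
    return SimTruth(
        h2=data["h2"],
        h2_trait2=data.get("h2_trait2", 0.4),
        r_g=data["r_g"],
        thresholds=tuple(data["thresholds"]),
        farm_date_effects=tuple(data["farm_date_effects"]),
        sex_effects=tuple(data["sex_effects"]),
        causal_variant=data.get("causal_variant"),
        causal_effect=data.get("causal_effect", 0.0),
        deletion_intervals=tuple(tuple(x) for x in data.get("deletion_intervals", [])),
    )


def read_gene_annotation(path) -> pd.DataFrame:
    """Gene spans from GFF3 (gene features) or BED, half-open coordinates.

    Returns a frame with chrom, start, end, gene. GFF3's 1-based
    inclusive spans become 0-based half-open; BED is half-open already.
    """
    path = Path(path)
    if path.suffix.lower() in (".bed",):
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "gene"], usecols=range(4),
        )
        return df
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type("gene"):
        name = feat.attributes.get("Name", feat.attributes.get("ID", [feat.id]))[0]
        rows.append((feat.seqid, feat.start - 1, feat.end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def write_relationship_tsv(rel, path) -> None:
    """Lower-triangle (id_i, id_j, value) export of a relationship matrix."""
    ids, vals = rel.ids, rel.values
    with open(path, "w") as fh:
        fh.write("id1\tid2\tvalue\n")
        for i in range(len(ids)):
            for j in range(i + 1):
                fh.write(f"{ids[i]}\t{ids[j]}\t{vals[i, j]:.8g}\n")
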
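"""Readers and writers for the pipeline's table formats.

All on-disk formats are plain text: BED-like gene annotation TSV,
ortholog TSV, COJO-style GWAS summary TSV (``SNP A1 A2 freq b se p N``),
dosage TSV and VCF for genotypes, phenotype TSV (id, debv, edc), LD-score
and clump TSVs, and a text GRM triplet format.  Every writer round-trips
through the corresponding reader.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data import GenotypeMatrix, _snp_metadata

_GENE_COLS = ["gene_id", "species", "chrom", "start_bp", "end_bp"]
_ORTHO_COLS = ["human_id", "cattle_id", "identity_pct", "goc_score",
               "confidence", "orthology_type", "n_tissues_smr"]


def write_gene_annotation(genes: pd.DataFrame, path) -> None:
    genes[_GENE_COLS].to_csv(path, sep="\t", index=False)


def read_gene_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(_GENE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"gene annotation missing columns: {sorted(missing)}")
    return df


def write_orthologs(orthologs: pd.DataFrame, path) -> None:
    cols = [c for c in _ORTHO_COLS if c in orthologs.columns]
    orthologs[cols].to_csv(path, sep="\t", index=False)


def read_orthologs(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_summary_cojo(summary: pd.DataFrame, path) -> None:
    """COJO-style summary file with header ``SNP A1 A2 freq b se p N``.

    Positions survive the round trip because snp ids are ``chrom:pos``.
    """
    out = pd.DataFrame({
        "SNP": summary["snp_id"], "A1": summary["a1"], "A2": summary["a2"],
        "freq": summary["freq"], "b": summary["b"], "se": summary["se"],
        "p": summary["p"], "N": summary["n"],
    })
    out.to_csv(path, sep="\t", index=False)


def read_summary_cojo(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    out = pd.DataFrame({
        "snp_id": df["SNP"], "a1": df["A1"], "a2": df["A2"],
        "freq": df["freq"], "b": df["b"], "se": df["se"],
        "p": df["p"], "n": df["N"],
    })
    parts = out["snp_id"].str.split(":", n=1, expand=True)
    if parts.shape[1] == 2 and parts[1].str.isnumeric().all():
        out.insert(1, "chrom", parts[0])
        out.insert(2, "pos_bp", parts[1].astype(np.int64))
    return out


def write_phenotypes(phen: pd.DataFrame, path) -> None:
    phen[["individual_id", "debv", "edc"]].to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if (df["edc"] <= 0).any():
        raise ValueError("edc must be positive")
    return df


# ---------------------------------------------------------------------------
# genotypes


def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    """SNPs as rows (snp_id chrom pos_bp ref alt + one column per individual)."""
    head = genotypes.snp_meta[["snp_id", "chrom", "pos_bp", "ref", "alt"]].copy()
    dos = pd.DataFrame(genotypes.dosages.T, columns=genotypes.individual_ids)
    pd.concat([head.reset_index(drop=True), dos], axis=1).to_csv(
        path, sep="\t", index=False, na_rep="NA")


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values="NA")
    ind = [c for c in df.columns if c not in ("snp_id", "chrom", "pos_bp", "ref", "alt")]
    dosages = df[ind].to_numpy(dtype=np.float32).T
    meta = _snp_metadata(df["chrom"].tolist(), df["pos_bp"].to_numpy(), dosages)
    return GenotypeMatrix(ind, meta, dosages)


_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    meta = genotypes.snp_meta
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(meta["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.individual_ids) + "\n")
        for j in range(genotypes.n_snps):
            row = meta.iloc[j]
            gts = "\t".join(_GT.get(float(d), "./.") if not np.isnan(d) else "./."
                            for d in genotypes.dosages[:, j])
            fh.write(f"{row.chrom}\t{row.pos_bp}\t{row.snp_id}\t{row.ref}\t"
                     f"{row.alt}\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF
    vcf = VCF(str(path), gts012=True)
    individuals = list(vcf.samples)
    chroms, positions, rows = [], [], []
    for var in vcf:
        chroms.append(var.CHROM)
        positions.append(var.POS)
        d = var.gt_types.astype(np.float32)
        d[d == 3] = np.nan
        rows.append(d)
    dosages = np.vstack(rows).T if rows else np.empty((len(individuals), 0), np.float32)
    meta = _snp_metadata(chroms, np.asarray(positions, dtype=np.int64), dosages)
    return GenotypeMatrix(individuals, meta, dosages)


# ---------------------------------------------------------------------------
# analysis outputs


def write_ld_scores(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_ld_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_clumps(clump_result, path) -> None:
    rows = []
    for snp in clump_result.index_snps:
        members = clump_result.clump_members[snp]
        info = clump_result.index_info[snp]
        rows.append({
            "index_snp": snp, "chrom": info["chrom"], "pos_bp": info["pos_bp"],
            "p": info["p"], "n_members": len(members),
            "member_ids": ",".join(members) if members else ".",
        })
    pd.DataFrame(rows, columns=["index_snp", "chrom", "pos_bp", "p",
                                "n_members", "member_ids"]).to_csv(
        path, sep="\t", index=False)


def write_snp_list(snp_ids, path, maf=None) -> None:
    if maf is None:
        Path(path).write_text("".join(f"{s}\n" for s in snp_ids))
    else:
        pd.DataFrame({"snp_id": list(snp_ids), "maf": list(maf)}).to_csv(
            path, sep="\t", index=False)


def read_gene_set(path) -> set[str]:
    """One gene id per line."""
    return {ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()}


def write_gene_set(gene_ids, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(gene_ids)))


def write_grm_tsv(grm, path) -> None:
    """Lower triangle (incl. diagonal) as id_i, id_j, value, n_snps."""
    ids = grm.individual_ids
    with open(path, "w") as fh:
        fh.write("id_i\tid_j\tvalue\tn_snps\n")
        for i in range(len(ids)):
            for j in range(i + 1):
                fh.write(f"{ids[i]}\t{ids[j]}\t{grm.matrix[i, j]:.10g}\t{grm.n_snps_used}\n")


def read_grm_tsv(path):
    from .varcomp import Grm
    df = pd.read_csv(path, sep="\t")
    ids = list(dict.fromkeys(df["id_i"]))
    index = {v: k for k, v in enumerate(ids)}
    n = len(ids)
    mat = np.zeros((n, n))
    for row in df.itertuples(index=False):
        i, j = index[row.id_i], index[row.id_j]
        mat[i, j] = mat[j, i] = row.value
    return Grm(ids, mat, int(df["n_snps"].iloc[0]), snp_ids=None)


def read_grm_gcta_bin(prefix):
    """Reader for the common lower-triangle binary GRM layout
    (``<prefix>.grm.id`` text + ``<prefix>.grm.bin`` float32 stream +
    optional ``<prefix>.grm.N.bin``), for interoperability."""
    from .varcomp import Grm
    ids = pd.read_csv(f"{prefix}.grm.id", sep="\t", header=None)[1].astype(str).tolist()
    n = len(ids)
    vals = np.fromfile(f"{prefix}.grm.bin", dtype=np.float32)
    if len(vals) != n * (n + 1) // 2:
        raise ValueError("GRM binary length does not match id count")
    mat = np.zeros((n, n))
    k = 0
    for i in range(n):
        mat[i, : i + 1] = vals[k: k + i + 1]
        mat[: i + 1, i] = vals[k: k + i + 1]
        k += i + 1
    n_path = Path(f"{prefix}.grm.N.bin")
    n_snps = int(np.fromfile(n_path, dtype=np.float32)[0]) if n_path.exists() else 0
    return Grm(ids, mat, n_snps, snp_ids=None)
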
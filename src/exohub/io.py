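"""Readers and writers for the pipeline's plain-text artifacts.

Long-format call tables and all matrices travel as TSV; the optional VCF 4.2
export (FORMAT ``GT:AD:DP:GQ``, annotations in INFO) exists for round-trip
testing of the VCF ingestion path, which is backed by cyvcf2.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .features import GeneCountMatrix
from .filtering import CALL_COLUMNS, GenotypeMatrix
from .stratify import AdjustedMatrix

logger = logging.getLogger(__name__)

_CALL_DTYPES = {
    "sample_id": str,
    "variant_id": str,
    "rsid": str,
    "gene": str,
    "coding_type": str,
    "functional_type": str,
    "maf": float,
    "genotype": np.int64,
    "alt_reads": np.int64,
    "depth": np.int64,
    "gq": np.int64,
}


def write_calls_tsv(calls: pd.DataFrame, path: str | Path) -> None:
    calls[CALL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    calls = pd.read_csv(path, sep="\t", dtype=_CALL_DTYPES)
    missing = set(CALL_COLUMNS) - set(calls.columns)
    if missing:
        raise ValueError(f"call table missing columns: {sorted(missing)}")
    return calls[CALL_COLUMNS]


def write_genotype_matrix(G: GenotypeMatrix, path: str | Path, map_path: str | Path | None = None) -> None:
    """Samples in rows, first column the class label; optional variant->gene map TSV."""
    G.to_frame().to_csv(path, sep="\t")
    if map_path is not None:
        pd.DataFrame(
            {
                "variant_id": list(G.variant_to_gene),
                "gene": [G.variant_to_gene[v] for v in G.variant_to_gene],
                "rsid": [G.rsids.get(v, ".") for v in G.variant_to_gene],
            }
        ).sort_values("variant_id").to_csv(map_path, sep="\t", index=False)


def read_genotype_matrix(path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    labels = df.pop("label").to_numpy()
    vmap = pd.read_csv(map_path, sep="\t", dtype=str)
    return GenotypeMatrix(
        sample_ids=list(df.index),
        variant_ids=list(df.columns),
        values=df.to_numpy(dtype=np.int64),
        labels=labels,
        variant_to_gene=dict(zip(vmap["variant_id"], vmap["gene"])),
        rsids=dict(zip(vmap["variant_id"], vmap["rsid"])),
    )


def write_adjusted_matrix(A: AdjustedMatrix, path: str | Path) -> None:
    """Integer cells; first column adjusted phenotype, second the original label."""
    df = pd.DataFrame(A.values, index=A.sample_ids, columns=A.feature_ids)
    df.insert(0, "label", A.labels)
    df.insert(0, "adjusted_phenotype", A.adjusted_phenotype)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_adjusted_matrix(A_path: str | Path, variant_to_gene: dict[str, str]) -> AdjustedMatrix:
    df = pd.read_csv(A_path, sep="\t", index_col="sample_id")
    ph = df.pop("adjusted_phenotype").to_numpy(dtype=np.int64)
    labels = df.pop("label").to_numpy()
    return AdjustedMatrix(
        sample_ids=list(df.index),
        feature_ids=list(df.columns),
        values=df.to_numpy(dtype=np.int64),
        adjusted_phenotype=ph,
        labels=labels,
        variant_to_gene=variant_to_gene,
    )


def write_gene_counts(C: GeneCountMatrix, path: str | Path) -> None:
    C.to_frame().to_csv(path, sep="\t")


def read_gene_counts(path: str | Path) -> GeneCountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    ph = df.pop("adjusted_phenotype").to_numpy(dtype=np.int64)
    labels = df.pop("label").to_numpy()
    return GeneCountMatrix(
        sample_ids=list(df.index),
        gene_ids=list(df.columns),
        values=df.to_numpy(dtype=np.int64),
        adjusted_phenotype=ph,
        labels=labels,
    )


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CTYPE,Number=1,Type=String,Description="Coding consequence">
##INFO=<ID=FTYPE,Number=1,Type=String,Description="Functional region">
##INFO=<ID=MAF,Number=1,Type=Float,Description="Reference-population minor allele frequency">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""

#: nominal evidence written for homozygous-reference cells in the VCF export
_REF_FIELDS = "0/0:30,0:30:99"


def write_vcf(calls: pd.DataFrame, all_samples: list[str], path: str | Path) -> None:
    """Minimal single-file VCF 4.2 export of a call table.

    Per-variant annotations go to INFO; per-sample evidence to GT:AD:DP:GQ.
    Samples without a call at a site are written as homozygous reference with
    nominal evidence (the reader drops them again).
    """
    samples = sorted(all_samples)
    sample_pos = {s: i for i, s in enumerate(samples)}

    def sort_key(vid: str):
        chrom, pos, ref, alt = vid.split(":")
        return (int(chrom), int(pos), ref, alt)

    by_variant = dict(tuple(calls.groupby("variant_id", sort=False)))
    chroms = sorted({vid.split(":")[0] for vid in by_variant}, key=lambda c: (len(c), c))
    contigs = "".join(f"##contig=<ID={c}>\n" for c in chroms)
    lines = [
        _VCF_HEADER
        + contigs
        + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
    ]
    for vid in sorted(by_variant, key=sort_key):
        grp = by_variant[vid]
        chrom, pos, ref, alt = vid.split(":")
        first = grp.iloc[0]
        info = (
            f"GENE={first['gene']};CTYPE={first['coding_type']};"
            f"FTYPE={first['functional_type']};MAF={first['maf']:.6g}"
        )
        cells = [_REF_FIELDS] * len(samples)
        for _, row in grp.iterrows():
            gt = "0/1" if row["genotype"] == 1 else "1/1"
            ref_reads = int(row["depth"]) - int(row["alt_reads"])
            cells[sample_pos[row["sample_id"]]] = (
                f"{gt}:{ref_reads},{int(row['alt_reads'])}:{int(row['depth'])}:{int(row['gq'])}"
            )
        lines.append(
            f"{chrom}\t{pos}\t{first['rsid']}\t{ref}\t{alt}\t.\tPASS\t{info}\tGT:AD:DP:GQ\t"
            + "\t".join(cells)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf_calls(path: str | Path) -> pd.DataFrame:
    """Ingest a VCF produced by :func:`write_vcf` (or any single-allelic VCF
    with the same INFO/FORMAT fields) back into the long call-table format.

    Homozygous-reference and missing genotypes are skipped; missing genotypes
    are counted in a log line (the matrix treats them as 0).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    n_missing = 0
    for var in vcf:
        vid = f"{var.CHROM}:{var.POS}:{var.REF}:{var.ALT[0]}"
        ad = var.format("AD")
        dp = var.format("DP")
        gq = var.format("GQ")
        for i, g in enumerate(var.genotypes):
            alleles = g[:-1]
            if any(a < 0 for a in alleles):
                n_missing += 1
                continue
            genotype = int(sum(1 for a in alleles if a > 0))
            if genotype == 0:
                continue
            rows.append(
                {
                    "sample_id": samples[i],
                    "variant_id": vid,
                    "rsid": var.ID or ".",
                    "gene": var.INFO.get("GENE"),
                    "coding_type": var.INFO.get("CTYPE"),
                    "functional_type": var.INFO.get("FTYPE"),
                    "maf": float(var.INFO.get("MAF")),
                    "genotype": genotype,
                    "alt_reads": int(ad[i][1]),
                    "depth": int(dp[i][0]) if np.ndim(dp) > 1 else int(dp[i]),
                    "gq": int(gq[i][0]) if np.ndim(gq) > 1 else int(gq[i]),
                }
            )
    if n_missing:
        logger.info("skipped %d no-call genotypes (treated as 0 downstream)", n_missing)
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return calls.sort_values(["sample_id", "variant_id"], kind="mergesort").reset_index(drop=True)
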
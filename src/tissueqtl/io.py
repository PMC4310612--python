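"""Readers and writers for the standard formats the pipeline touches.

VCF genotypes go through pysam; tab-delimited BED-like phenotype matrices,
BED12 gene models, BED feature sets, read-pair and allelic-count tables go
through pandas. All coordinates are converted to 0-based half-open on read.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .types import (
    ASSOCIATION_COLUMNS,
    FEATURE_COLUMNS,
    FeatureSet,
    GeneModel,
    GenotypeMatrix,
    PhenotypeMatrix,
)

log = logging.getLogger(__name__)


def read_genotypes(path: str | Path, maf_threshold: float = 0.05) -> GenotypeMatrix:
    """Read a VCF of biallelic SNPs into a dosage matrix.

    Dosage = number of ALT alleles in the GT field; ``./.`` becomes missing
    and is excluded from the MAF denominator. Multiallelic records are
    rejected. VCF POS is 1-based and stored internally as 0-based.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    rows, dosage_rows = [], []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            raise ValueError(
                f"non-biallelic record at {rec.chrom}:{rec.pos} ({rec.id})"
            )
        dos = np.full(len(samples), np.nan)
        for i, sample in enumerate(samples):
            gt = rec.samples[sample].get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            dos[i] = float(sum(1 for a in gt if a != 0))
        rows.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos - 1,
                "ref": rec.ref,
                "alt": rec.alts[0],
                "id": rec.id or f"{rec.chrom}:{rec.pos}",
            }
        )
        dosage_rows.append(dos)
    vf.close()
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "id"])
    variants = variants.sort_values(["chrom", "pos"], kind="stable")
    order = variants.index.to_numpy()
    variants = variants.reset_index(drop=True)
    dosages = (
        np.asarray(dosage_rows, dtype=float).T[:, order]
        if dosage_rows
        else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(
        samples=samples,
        variants=variants,
        dosages=dosages,
        maf_threshold=maf_threshold,
    )


def write_genotypes_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF (GT only) from a dosage matrix."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = gm.variants["chrom"].unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, var in gm.variants.iterrows():
            calls = [
                gt_map.get(d, "./.") if not np.isnan(d) else "./."
                for d in gm.dosages[:, j]
            ]
            fh.write(
                f"{var.chrom}\t{var.pos + 1}\t{var.id}\t{var.ref}\t{var.alt}"
                f"\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_phenotypes(
    path: str | Path,
    kind: str,
    samples: list[str] | None = None,
) -> PhenotypeMatrix:
    """Read a BED-like tab file (chrom,start,end,id,gene_id,strand + samples).

    If ``samples`` is given the matrix is re-ordered to that sample list.
    Methylation values are validated against [0,1] by the container.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    cols = list(df.columns)
    if cols[0].startswith("#"):
        df = df.rename(columns={cols[0]: cols[0].lstrip("#")})
        cols = list(df.columns)
    if cols[:6] != FEATURE_COLUMNS:
        raise ValueError(
            f"expected leading columns {FEATURE_COLUMNS}, found {cols[:6]}"
        )
    file_samples = cols[6:]
    features = df[FEATURE_COLUMNS].copy()
    if "anchor" in df.columns:
        features["anchor"] = df["anchor"]
        file_samples = [s for s in file_samples if s != "anchor"]
    values = df[file_samples].to_numpy(dtype=float).T
    if samples is not None:
        idx = [file_samples.index(s) for s in samples]
        values = values[idx]
        file_samples = list(samples)
    if len(features) == 0:
        log.warning("phenotype file %s has an empty data section", path)
    return PhenotypeMatrix(
        samples=file_samples, features=features, values=values, kind=kind
    )


def write_phenotypes(pm: PhenotypeMatrix, path: str | Path) -> None:
    meta = pm.features[
        FEATURE_COLUMNS + (["anchor"] if "anchor" in pm.features else [])
    ]
    data = pd.DataFrame(pm.values.T, columns=pm.samples, index=meta.index)
    df = pd.concat([meta, data], axis=1)
    # %.17g keeps the round-trip exact for doubles
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_associations(
    records: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config: dict | None = None,
) -> None:
    """Write association records as TSV with a commented provenance header.

    Rows are ordered by (gene_id, nominal_p) for byte-stable output.
    """
    df = records.copy()
    for col in ASSOCIATION_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[ASSOCIATION_COLUMNS]
    df = df.sort_values(
        ["gene_id", "nominal_p", "feature_id", "regressor_id"], kind="stable"
    )
    buf = _io.StringIO()
    if seed is not None:
        buf.write(f"# seed={seed}\n")
    for key, val in (config or {}).items():
        buf.write(f"# {key}={val}\n")
    df.to_csv(buf, sep="\t", index=False, float_format="%.6g")
    Path(path).write_text(buf.getvalue())


def read_associations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")


def read_gene_models_bed12(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED12 (one transcript per gene)."""
    names = [
        "chrom", "start", "end", "name", "score", "strand",
        "thick_start", "thick_end", "rgb", "block_count",
        "block_sizes", "block_starts",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=names, comment="#")
    models = []
    for row in df.itertuples():
        sizes = [int(x) for x in str(row.block_sizes).rstrip(",").split(",")]
        starts = [int(x) for x in str(row.block_starts).rstrip(",").split(",")]
        if len(sizes) != int(row.block_count) or len(sizes) != len(starts):
            raise ValueError(f"malformed BED12 blocks for {row.name}")
        exons = [
            (row.start + s, row.start + s + size) for s, size in zip(starts, sizes)
        ]
        models.append(
            GeneModel(
                gene_id=str(row.name), chrom=str(row.chrom),
                strand=str(row.strand), exons=exons,
            )
        )
    return models


def write_gene_models_bed12(models: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in models:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, e in g.exons)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n"
            )


def read_feature_bed(path: str | Path, name: str | None = None) -> FeatureSet:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
    )
    return FeatureSet(
        name or Path(path).stem,
        list(df.itertuples(index=False, name=None)),
    )


def write_feature_bed(fs: FeatureSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in fs.intervals():
            fh.write(f"{chrom}\t{start}\t{end}\n")


READ_PAIR_COLUMNS = ["sample", "chrom", "r1_start", "r1_end", "r2_start", "r2_end"]


def read_read_pairs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in READ_PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"read-pair table missing columns {missing}")
    return df


ALLELIC_COLUMNS = [
    "individual", "cell_type", "chrom", "pos", "ref", "alt",
    "ref_count", "total_count",
]


def read_allelic_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ALLELIC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"allelic-count table missing columns {missing}")
    if (df["ref_count"] > df["total_count"]).any():
        raise ValueError("ref_count exceeds total_count")
    return df
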
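"""Readers and writers for the standard formats the pipeline touches.

GTF and VCF inputs are converted to the internal 0-based half-open
convention on read; writers convert back. All TSV writers emit a
commented header line recording the package version.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    SV_CLASSES,
    AnalysisConfig,
    CovariateTable,
    ExpressionMatrix,
    FragmentAlignmentTable,
    GeneModel,
    GenomicInterval,
    SVCallset,
    SVRecord,
)

PKG_VERSION = "0.1.0"

PRIMARY_CHROMS = {f"chr{i}" for i in range(1, 23)} | {"chrX", "chrY", "chrM"}


def _header_comment(extra: str = "") -> str:
    tag = f"# misexpression v{PKG_VERSION}"
    return tag + (f" {extra}" if extra else "")


def config_hash(config: AnalysisConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Gene annotation


def _biotype_label(raw: str | None) -> str:
    if raw == "protein_coding":
        return "protein_coding"
    if raw in ("lncRNA", "lincRNA"):
        return "lncRNA"
    return "other"


def read_gene_annotation(path: str | Path, fmt: str = "gtf") -> list[GeneModel]:
    """Read a gene annotation into GeneModel records.

    GTF (GENCODE dialect) via pyranges; exon rows are collapsed per gene
    into a merged-exon length. BED12 uses block fields as exons. Genes on
    contigs outside the primary assembly are retained but flagged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "gtf":
        return _read_gtf(path)
    if fmt == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unsupported annotation format {fmt!r}")


def _read_gtf(path: Path) -> list[GeneModel]:
    _validate_gtf_lines(path)
    import pyranges as pr

    df = pr.read_gtf(str(path)).df  # already 0-based half-open
    if df.empty:
        return []
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: GTF has no gene_id attribute")
    genes: list[GeneModel] = []
    gene_rows = df[df["Feature"] == "gene"]
    exon_rows = df[df["Feature"] == "exon"]
    seen: set[str] = set()
    for _, row in gene_rows.iterrows():
        gid = row["gene_id"]
        if gid in seen:
            raise ValueError(f"{path}: duplicate gene_id {gid!r}")
        seen.add(gid)
        chrom = str(row["Chromosome"])
        interval = GenomicInterval(chrom, int(row["Start"]), int(row["End"]), str(row["Strand"]))
        exons = [
            GenomicInterval(chrom, int(e.Start), int(e.End), str(e.Strand))
            for e in exon_rows[exon_rows["gene_id"] == gid].itertuples()
        ]
        biotype = _biotype_label(row.get("gene_type") or row.get("gene_biotype"))
        genes.append(
            GeneModel(
                gene_id=gid,
                interval=interval,
                biotype=biotype,
                exons=exons,
                flagged_contig=chrom not in PRIMARY_CHROMS,
            )
        )
    return genes


def _validate_gtf_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start")


def write_gene_annotation(genes: list[GeneModel], path: str | Path) -> None:
    """Write GeneModels as GENCODE-style GTF (converting back to 1-based)."""
    with open(Path(path), "w") as fh:
        fh.write(f"#!{_header_comment()[2:]}\n")
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_type "{g.biotype}";'
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tmisexpression\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{ex.chrom}\tmisexpression\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{ex.strand}\t.\t{attrs}\n"
                )


def _read_bed12(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED columns")
            chrom, start, end, name, _, strand = parts[0], int(parts[1]), int(parts[2]), parts[3], parts[4], parts[5]
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {name!r}")
            seen.add(name)
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            exons = [
                GenomicInterval(chrom, start + off, start + off + size, strand)
                for off, size in zip(offsets, sizes)
            ]
            genes.append(
                GeneModel(
                    gene_id=name,
                    interval=GenomicInterval(chrom, start, end, strand),
                    exons=exons,
                    flagged_contig=chrom not in PRIMARY_CHROMS,
                )
            )
    return genes


# ---------------------------------------------------------------------------
# SV callsets


def read_sv_callset(path: str | Path, fmt: str = "vcf") -> SVCallset:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "vcf":
        return _read_sv_vcf(path)
    if fmt == "tsv":
        return _read_sv_tsv(path)
    raise ValueError(f"unsupported SV format {fmt!r}")


def _read_sv_vcf(path: Path) -> SVCallset:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[SVRecord] = []
    skipped = 0
    for i, var in enumerate(vcf):
        svtype = var.INFO.get("SVTYPE")
        if svtype is None and var.ALT and var.ALT[0].startswith("<"):
            svtype = var.ALT[0].strip("<>")
        if svtype == "MEI" or (svtype == "INS" and "MEI" in str(var.ALT)):
            svclass = "MEI"
        else:
            svclass = svtype
        if svclass not in SV_CLASSES:
            warnings.warn(f"skipping record {var.ID or i}: unknown SVTYPE {svtype!r}")
            skipped += 1
            continue
        start = var.start  # cyvcf2: 0-based
        end = var.INFO.get("END")
        end = int(end) if end is not None else var.end
        carriers: set[str] = set()
        n_alt = 0
        n_called = 0
        if samples:
            gts = var.genotype.array()
            for sidx, gt in enumerate(gts):
                alleles = [a for a in gt[:-1] if a >= 0]
                if not alleles:
                    continue
                n_called += len(alleles)
                alt = sum(1 for a in alleles if a > 0)
                n_alt += alt
                if alt:
                    carriers.add(samples[sidx])
        maf = var.INFO.get("MAF")
        if maf is None:
            af = var.INFO.get("AF")
            if af is not None:
                af = float(af[0] if isinstance(af, tuple) else af)
                maf = min(af, 1.0 - af)
            elif n_called:
                af = n_alt / n_called
                maf = min(af, 1.0 - af)
            else:
                raise ValueError(
                    f"{path}: record {var.ID or i} has neither MAF/AF nor genotypes"
                )
        records.append(
            SVRecord(
                sv_id=var.ID or f"sv_{i}",
                interval=GenomicInterval(var.CHROM, start, end),
                svclass=svclass,
                maf=float(maf),
                carriers=frozenset(carriers),
            )
        )
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} records with unknown SVTYPE")
    return SVCallset(records, sample_universe=frozenset(samples))


def _read_sv_tsv(path: Path) -> SVCallset:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "start", "end", "svclass", "maf"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    universe: set[str] = set()
    skipped = 0
    for i, row in df.iterrows():
        if row["svclass"] not in SV_CLASSES:
            warnings.warn(f"skipping row {i}: unknown svclass {row['svclass']!r}")
            skipped += 1
            continue
        carriers: frozenset[str] = frozenset()
        if "carriers" in df.columns and pd.notna(row["carriers"]) and row["carriers"]:
            carriers = frozenset(str(row["carriers"]).split(","))
            universe |= carriers
        records.append(
            SVRecord(
                sv_id=str(row["sv_id"]) if "sv_id" in df.columns else f"sv_{i}",
                interval=GenomicInterval(str(row["chrom"]), int(row["start"]), int(row["end"])),
                svclass=str(row["svclass"]),
                maf=float(row["maf"]),
                carriers=carriers,
            )
        )
    return SVCallset(records)


def write_sv_callset(callset: SVCallset, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        fh.write(_header_comment() + "\n")
        fh.write("sv_id\tchrom\tstart\tend\tsvclass\tmaf\tcarriers\n")
        for r in callset:
            fh.write(
                f"{r.sv_id}\t{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"{r.svclass}\t{r.maf:.6g}\t{','.join(sorted(r.carriers))}\n"
            )


# ---------------------------------------------------------------------------
# Expression / covariates / fragments


def read_expression_matrix(path: str | Path, unit: str, subset: bool = False) -> ExpressionMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    nonnum = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if nonnum:
        col = nonnum[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        raise ValueError(
            f"{path}: non-numeric value at gene {bad.index[0]!r}, sample {col!r}"
        )
    df.index = df.index.astype(str)
    return ExpressionMatrix(df, unit=unit, subset=subset)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        fh.write(_header_comment(f"unit={matrix.unit}") + "\n")
        matrix.values.to_csv(fh, sep="\t", index_label="gene_id")


def read_covariate_table(path: str | Path) -> CovariateTable:
    df = pd.read_csv(Path(path), sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    return CovariateTable(df)


def write_covariate_table(table: CovariateTable, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        fh.write(_header_comment() + "\n")
        table.values.to_csv(fh, sep="\t", index_label="sample_id")


def read_fragments(bed_path: str | Path, depths_path: str | Path) -> FragmentAlignmentTable:
    """Fragments as BED6 (name column = sample id) plus a depth TSV."""
    frag = pd.read_csv(
        Path(bed_path),
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "sample_id", "score", "strand"],
    )
    frag = frag[["sample_id", "chrom", "start", "end", "strand"]]
    dep = pd.read_csv(Path(depths_path), sep="\t", comment="#")
    depths = dict(zip(dep["sample_id"].astype(str), dep["depth"].astype(int)))
    frag["sample_id"] = frag["sample_id"].astype(str)
    return FragmentAlignmentTable(frag, depths)


def write_fragments(table: FragmentAlignmentTable, bed_path: str | Path, depths_path: str | Path) -> None:
    frag = table.fragments
    with open(Path(bed_path), "w") as fh:
        for row in frag.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.sample_id}\t0\t{row.strand}\n")
    with open(Path(depths_path), "w") as fh:
        fh.write(_header_comment() + "\nsample_id\tdepth\n")
        for s, d in table.depths.items():
            fh.write(f"{s}\t{d}\n")


def read_bed_track(path: str | Path, value_col: bool = False) -> pd.DataFrame:
    """Generic BED3(+score) track as a DataFrame (chrom, start, end[, value])."""
    names = ["chrom", "start", "end"] + (["value"] if value_col else [])
    df = pd.read_csv(
        Path(path), sep="\t", comment="#", header=None, usecols=range(len(names)), names=names
    )
    return df


def write_bed_track(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("chrom", "start", "end", "value") if c in df.columns]
    df[cols].to_csv(Path(path), sep="\t", header=False, index=False)
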
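"""Core domain types shared by every pipeline stage.

All genomic coordinates are 0-based half-open throughout the package.
Inputs in 1-based conventions (GTF, VCF) are converted on read and
converted back on write.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")
SV_CLASSES = ("DEL", "DUP", "INV", "MEI")
BIOTYPES = ("protein_coding", "lncRNA", "other")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True if this interval fully covers ``other``."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def distance(self, other: "GenomicInterval") -> int:
        """Gap in bp between two intervals; 0 iff they overlap or abut.

        Intervals on different chromosomes have no defined distance.
        """
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        return max(0, other.start - self.end, self.start - other.end)


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of possibly-overlapping intervals on one chromosome/strand."""
    if not intervals:
        return []
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise ValueError("cannot merge intervals across chromosomes")
    ordered = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged = [ordered[0]]
    for iv in ordered[1:]:
        last = merged[-1]
        if iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = replace(last, end=iv.end)
        else:
            merged.append(iv)
    return merged


@dataclass
class GeneModel:
    """A gene body with its collapsed exon structure.

    ``collapsed_exon_length`` is the total length of merged exons, the
    length used for TPM normalisation. ``median_tpm`` is filled in by the
    expression pipeline once a cohort has been quantified.
    """

    gene_id: str
    interval: GenomicInterval
    biotype: str = "other"
    exons: list[GenomicInterval] = field(default_factory=list)
    collapsed_exon_length: int | None = None
    median_tpm: float | None = None
    flagged_contig: bool = False

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValueError(f"biotype must be one of {BIOTYPES}")
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(f"exon off-chromosome for gene {self.gene_id}")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"exon outside gene body for {self.gene_id}")
        if self.collapsed_exon_length is None:
            self.collapsed_exon_length = (
                sum(iv.length for iv in merge_intervals(self.exons))
                if self.exons
                else self.interval.length
            )
        if self.collapsed_exon_length <= 0:
            raise ValueError(f"non-positive exon length for {self.gene_id}")
        if self.collapsed_exon_length > self.interval.length:
            raise ValueError(f"exon length exceeds gene body for {self.gene_id}")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """Transcription start site position (strand-aware)."""
        return self.interval.start if self.strand != "-" else self.interval.end - 1

    @property
    def tts(self) -> int:
        """Transcription termination site position (strand-aware)."""
        return self.interval.end - 1 if self.strand != "-" else self.interval.start


@dataclass
class ExpressionMatrix:
    """Gene x sample expression table in counts or TPM.

    Backed by a pandas DataFrame with gene ids as the index and sample
    ids as columns.
    """

    values: pd.DataFrame
    unit: str  # "counts" or "TPM"
    subset: bool = False  # True when the matrix does not cover the full gene set

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "TPM"):
            raise ValueError("unit must be 'counts' or 'TPM'")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative expression value at gene {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )
        if self.unit == "TPM" and not self.subset:
            sums = arr.sum(axis=0)
            ok = np.isclose(sums, 1e6, rtol=1e-3) | (sums == 0)
            if not ok.all():
                bad = self.values.columns[~ok].tolist()
                raise ValueError(
                    f"TPM columns do not sum to 1e6 (set subset=True for gene "
                    f"subsets): {bad[:5]}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    def restrict_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[genes], self.unit, subset=True)

    def restrict_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = [s for s in samples if s in self.values.columns]
        return ExpressionMatrix(self.values[samples], self.unit, subset=self.subset)


@dataclass
class CovariateTable:
    """Sample x covariate table; categorical columns are rank-encoded on use."""

    values: pd.DataFrame  # index = sample ids, columns = covariates

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate sample ids in covariate table")

    @property
    def sample_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def covariate_names(self) -> list[str]:
        return self.values.columns.tolist()

    def numeric(self) -> pd.DataFrame:
        """Rank-encode non-numeric covariates so Spearman tests apply uniformly."""
        out = {}
        for name in self.values.columns:
            col = self.values[name]
            if pd.api.types.is_numeric_dtype(col):
                out[name] = col.astype(float)
            else:
                out[name] = col.astype("category").cat.codes.astype(float)
        return pd.DataFrame(out, index=self.values.index)


@dataclass
class SVRecord:
    """A structural variant call with frequency, carriers and consequences."""

    sv_id: str
    interval: GenomicInterval
    svclass: str
    maf: float
    carriers: frozenset[str] = frozenset()
    consequences: Mapping[str, list[str]] | None = None

    def __post_init__(self) -> None:
        if self.svclass not in SV_CLASSES:
            raise ValueError(f"svclass must be one of {SV_CLASSES}, got {self.svclass!r}")
        if not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"MAF must be in [0, 0.5], got {self.maf}")
        object.__setattr__(self, "carriers", frozenset(self.carriers))

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class SVCallset:
    records: list[SVRecord]
    sample_universe: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        ids = [r.sv_id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise ValueError(f"duplicate sv_id in callset: {dup!r}")
        universe = frozenset(self.sample_universe)
        if universe:
            for r in self.records:
                extra = r.carriers - universe
                if extra:
                    raise ValueError(
                        f"SV {r.sv_id} carriers outside sample universe: {sorted(extra)[:3]}"
                    )
        self.sample_universe = universe

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, predicate) -> "SVCallset":
        return SVCallset([r for r in self.records if predicate(r)], self.sample_universe)

    def rare(self, maf_threshold: float = 0.01) -> "SVCallset":
        return self.subset(lambda r: r.maf < maf_threshold)


@dataclass
class FragmentAlignmentTable:
    """Strand-aware fragment alignments plus per-sample library depths.

    ``fragments`` columns: sample_id, chrom, start, end, strand.
    ``depths`` maps sample_id -> total assigned fragments (library size).
    """

    fragments: pd.DataFrame
    depths: Mapping[str, int]

    def __post_init__(self) -> None:
        required = {"sample_id", "chrom", "start", "end", "strand"}
        missing = required - set(self.fragments.columns)
        if missing:
            raise ValueError(f"fragment table missing columns: {sorted(missing)}")
        for s, d in self.depths.items():
            if d <= 0:
                raise ValueError(f"non-positive depth for sample {s!r}")
        unknown = set(self.fragments["sample_id"]) - set(self.depths)
        if unknown:
            raise ValueError(f"fragments for samples without depth: {sorted(unknown)[:3]}")


@dataclass
class AnalysisConfig:
    """Every tunable threshold of the pipeline, with cohort-analysis defaults."""

    inactive_tpm: float = 0.1      # TPM above which a sample counts as expressing
    inactive_frac: float = 0.05    # inactive iff expressed in < this fraction of samples
    misexp_z: float = 2.0          # misexpression Z-score gate (strict >)
    misexp_tpm: float = 0.5        # misexpression TPM gate (strict >)
    outlier_fold: float = 5.0      # global outlier: >= fold x expected top events
    cov_rho: float = 0.2           # |Spearman rho| gate for covariate filtering
    cov_alpha: float = 0.05        # BH-FDR alpha for covariate filtering
    gene_flank_bp: int = 10_000    # gene +/- flank for variant enrichment
    sv_window_bp: int = 200_000    # window for SV association and SV enrichment
    max_window_bp: int = 1_000_000  # distance-scan reach either side of a gene
    rare_maf: float = 0.01         # rare variant MAF cutoff (strict <)
    expressed_median_tpm: float = 0.5  # "expressed gene" gate for mechanism calling
    control_scope: str = "carriers"    # control-SV zero-TPM scope: carriers | all
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "inactive_tpm misexp_z misexp_tpm outlier_fold cov_rho cov_alpha "
            "gene_flank_bp sv_window_bp max_window_bp expressed_median_tpm"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config threshold {name} must be positive")
        if not 0 < self.inactive_frac < 1:
            raise ValueError("inactive_frac must be in (0, 1)")
        if not 0 < self.rare_maf <= 0.5:
            raise ValueError("rare_maf must be in (0, 0.5]")
        if self.control_scope not in ("carriers", "all"):
            raise ValueError("control_scope must be 'carriers' or 'all'")
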
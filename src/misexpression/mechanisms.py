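"""Putative misexpression mechanisms for associated SVs.

Transcriptional readthrough candidates are deletions that remove an
expressed gene's termination site (and a polyA site) upstream of the
misexpressed gene, or tandem duplications that place an entire inactive
gene downstream of an expressed gene's promoter. Readthrough is then
tested directly from strand-aware fragment coverage over the predicted
readthrough region (FPKM for depth, FBNC for breadth; both Z-scored
across the cohort). Remaining associated SVs may qualify as candidates
for altering 3D chromatin architecture via TAD-boundary and CTCF cCRE
overlap rules.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    FragmentAlignmentTable,
    GeneModel,
    GenomicInterval,
    SVRecord,
)
from .svassoc import SVAssociation


@dataclass
class ReadthroughCandidate:
    sv_id: str
    misexpressed_gene_id: str
    donor_gene_id: str
    region: GenomicInterval
    kind: str  # DEL | DUP


@dataclass
class ReadthroughMetrics:
    """Per-sample coverage metrics over one readthrough region."""

    region: GenomicInterval
    table: pd.DataFrame  # index sample_id; columns count, fpkm, fbnc, fpkm_z, fbnc_z


# ---------------------------------------------------------------------------
# Geometry helpers (all strand-aware relative to the misexpressed gene)


def _is_upstream(sv: SVRecord, gene: GeneModel) -> bool:
    """SV entirely on the 5' side of the gene, not overlapping it."""
    siv, giv = sv.interval, gene.interval
    if siv.chrom != giv.chrom or siv.overlaps(giv):
        return False
    left = siv.end <= giv.start
    return left if gene.strand != "-" else not left


def _covers_tts_not_tss(sv: SVRecord, gene: GeneModel) -> bool:
    return sv.interval.contains_point(gene.tts) and not sv.interval.contains_point(gene.tss)


def _covers_tss_not_tts(sv: SVRecord, gene: GeneModel) -> bool:
    return sv.interval.contains_point(gene.tss) and not sv.interval.contains_point(gene.tts)


def _is_downstream_gene(candidate: GeneModel, gene: GeneModel) -> bool:
    """candidate positioned 3' of ``gene`` (no overlap requirement on ends)."""
    if gene.strand != "-":
        return candidate.interval.start >= gene.interval.end
    return candidate.interval.end <= gene.interval.start


def readthrough_region(gene: GeneModel, sv: SVRecord, kind: str = "DEL") -> GenomicInterval:
    """Region from the misexpressed gene's 5' boundary upstream to the
    gene-proximal SV breakpoint; strand follows the misexpressed gene.

    The same rule serves both deletion and duplication candidates: the
    breakpoint is the SV edge nearest the gene on its 5' side.
    """
    giv = gene.interval
    edges = (sv.interval.start, sv.interval.end)
    if gene.strand != "-":
        below = [b for b in edges if b < giv.start]
        if not below:
            raise ValueError("no SV breakpoint on the gene's 5' side")
        return GenomicInterval(giv.chrom, max(below), giv.start, gene.strand)
    above = [b for b in edges if b > giv.end]
    if not above:
        raise ValueError("no SV breakpoint on the gene's 5' side")
    return GenomicInterval(giv.chrom, giv.end, min(above), gene.strand)


def _intervening_region_clear(
    gene: GeneModel,
    breakpoint_region: GenomicInterval,
    genes_by_id: dict[str, GeneModel],
    median_tpm: dict[str, float],
    expressed_thr: float,
    exclude: set[str],
) -> bool:
    """No expressed same-strand gene inside the predicted readthrough region."""
    for gid, other in genes_by_id.items():
        if gid in exclude:
            continue
        if other.interval.chrom != breakpoint_region.chrom:
            continue
        if other.strand != gene.strand:
            continue
        if median_tpm.get(gid, 0.0) <= expressed_thr:
            continue
        if other.interval.overlaps(breakpoint_region):
            return False
    return True


# ---------------------------------------------------------------------------
# Candidate selection


def select_readthrough_deletions(
    associations: list[SVAssociation],
    svs_by_id: dict[str, SVRecord],
    genes_by_id: dict[str, GeneModel],
    polya_sites: pd.DataFrame,
    median_tpm: dict[str, float],
    expressed_thr: float = 0.5,
) -> list[ReadthroughCandidate]:
    """Deletions satisfying the three readthrough criteria.

    (1) deletion upstream of (not overlapping) the misexpressed gene;
    (2) deletion covers the 3' terminus but not the 5' terminus of a
        same-strand donor gene expressed above ``expressed_thr`` median
        TPM, and overlaps at least one terminal-exon polyA site;
    (3) the region between the misexpressed gene's 5' boundary and the
        gene-proximal breakpoint holds no expressed same-strand gene.
    A deletion associated with several genes keeps only the closest.
    """
    if polya_sites is None:
        raise ValueError("polyA site track is required for deletion readthrough calls")
    by_sv: dict[str, list[SVAssociation]] = {}
    for assoc in associations:
        if assoc.svclass == "DEL":
            by_sv.setdefault(assoc.sv_id, []).append(assoc)
    out: list[ReadthroughCandidate] = []
    for sv_id, assocs in by_sv.items():
        sv = svs_by_id[sv_id]
        assocs = [a for a in assocs if _is_upstream(sv, genes_by_id[a.gene_id])]
        if not assocs:
            continue
        assocs.sort(key=lambda a: genes_by_id[a.gene_id].interval.distance(sv.interval))
        assoc = assocs[0]  # closest gene
        gene = genes_by_id[assoc.gene_id]
        donor = _find_del_donor(sv, gene, genes_by_id, polya_sites, median_tpm, expressed_thr)
        if donor is None:
            continue
        region = readthrough_region(gene, sv, "DEL")
        if not _intervening_region_clear(
            gene, region, genes_by_id, median_tpm, expressed_thr,
            exclude={gene.gene_id, donor.gene_id},
        ):
            continue
        out.append(
            ReadthroughCandidate(sv_id, gene.gene_id, donor.gene_id, region, "DEL")
        )
    return out


def _find_del_donor(
    sv: SVRecord,
    gene: GeneModel,
    genes_by_id: dict[str, GeneModel],
    polya_sites: pd.DataFrame,
    median_tpm: dict[str, float],
    expressed_thr: float,
) -> GeneModel | None:
    pa = polya_sites[
        (polya_sites["chrom"] == sv.interval.chrom)
        & (polya_sites["start"] < sv.interval.end)
        & (polya_sites["end"] > sv.interval.start)
    ]
    if pa.empty:
        return None
    for gid, donor in genes_by_id.items():
        if gid == gene.gene_id or donor.strand != gene.strand:
            continue
        if median_tpm.get(gid, 0.0) <= expressed_thr:
            continue
        if _covers_tts_not_tss(sv, donor):
            return donor
    return None


def select_readthrough_duplications(
    associations: list[SVAssociation],
    svs_by_id: dict[str, SVRecord],
    genes_by_id: dict[str, GeneModel],
    median_tpm: dict[str, float],
    expressed_thr: float = 0.5,
) -> list[ReadthroughCandidate]:
    """Tandem duplications satisfying the three readthrough criteria.

    (1) duplication covers the entire misexpressed gene; (2) it covers
    the 5' but not the 3' terminus of a downstream, same-strand donor
    gene expressed above threshold; (3) intervening-region rule as for
    deletions. With several qualifying genes, the one giving the
    shortest expected readthrough region is kept.
    """
    by_sv: dict[str, list[SVAssociation]] = {}
    for assoc in associations:
        if assoc.svclass == "DUP":
            by_sv.setdefault(assoc.sv_id, []).append(assoc)
    out: list[ReadthroughCandidate] = []
    for sv_id, assocs in by_sv.items():
        sv = svs_by_id[sv_id]
        candidates: list[ReadthroughCandidate] = []
        for assoc in assocs:
            gene = genes_by_id[assoc.gene_id]
            if not sv.interval.contains(gene.interval):
                continue
            donor = _find_dup_donor(sv, gene, genes_by_id, median_tpm, expressed_thr)
            if donor is None:
                continue
            region = readthrough_region(gene, sv, "DUP")
            if not _intervening_region_clear(
                gene, region, genes_by_id, median_tpm, expressed_thr,
                exclude={gene.gene_id, donor.gene_id},
            ):
                continue
            candidates.append(
                ReadthroughCandidate(sv_id, gene.gene_id, donor.gene_id, region, "DUP")
            )
        if candidates:
            candidates.sort(key=lambda c: c.region.length)
            out.append(candidates[0])  # shortest expected readthrough region
    return out


def _find_dup_donor(
    sv: SVRecord,
    gene: GeneModel,
    genes_by_id: dict[str, GeneModel],
    median_tpm: dict[str, float],
    expressed_thr: float,
) -> GeneModel | None:
    for gid, donor in genes_by_id.items():
        if gid == gene.gene_id or donor.strand != gene.strand:
            continue
        if median_tpm.get(gid, 0.0) <= expressed_thr:
            continue
        if not _is_downstream_gene(donor, gene):
            continue
        if _covers_tss_not_tts(sv, donor):
            return donor
    return None


# ---------------------------------------------------------------------------
# Readthrough metrics


def compute_fpkm_fbnc(
    region: GenomicInterval, fragments: FragmentAlignmentTable
) -> ReadthroughMetrics:
    """Strand-aware FPKM and FBNC per sample over a readthrough region.

    FPKM = count / (region_length_kb * depth/1e6); FBNC = covered bases /
    region length, counting only fragments on the region's strand.
    Z-scores are computed across all samples with a depth (ddof=1).
    """
    if region.length <= 0:
        raise ValueError("zero-length region")
    frag = fragments.fragments
    sel = frag[
        (frag["chrom"] == region.chrom)
        & (frag["strand"] == region.strand)
        & (frag["start"] < region.end)
        & (frag["end"] > region.start)
    ]
    samples = list(fragments.depths)
    counts = {s: 0 for s in samples}
    cover: dict[str, np.ndarray] = {}
    for row in sel.itertuples(index=False):
        s = row.sample_id
        counts[s] += 1
        lo = max(int(row.start), region.start) - region.start
        hi = min(int(row.end), region.end) - region.start
        arr = cover.setdefault(s, np.zeros(region.length, dtype=bool))
        arr[lo:hi] = True
    rows = []
    for s in samples:
        depth = fragments.depths[s]
        count = counts[s]
        fpkm = count / ((region.length / 1e3) * (depth / 1e6))
        fbnc = float(cover[s].sum() / region.length) if s in cover else 0.0
        rows.append({"sample_id": s, "count": count, "fpkm": fpkm, "fbnc": fbnc})
    table = pd.DataFrame(rows).set_index("sample_id")
    for col in ("fpkm", "fbnc"):
        x = table[col].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            sd = x.std(ddof=1) if len(x) > 1 else 0.0
        table[col + "_z"] = (x - x.mean()) / sd if sd > 0 else np.nan
    return ReadthroughMetrics(region, table)


def classify_readthrough(
    metrics: ReadthroughMetrics, z_thr: float = 2.0
) -> pd.Series:
    """Per-sample readthrough call: FPKM Z > 2 AND FBNC Z > 2 (strict)."""
    if len(metrics.table) < 10:
        raise ValueError("readthrough classification needs >= 10 samples")
    t = metrics.table
    return ((t["fpkm_z"] > z_thr) & (t["fbnc_z"] > z_thr)).rename("readthrough")


# ---------------------------------------------------------------------------
# 3D-architecture candidates


def _overlaps_track(iv: GenomicInterval, track: pd.DataFrame) -> bool:
    sel = track[
        (track["chrom"] == iv.chrom) & (track["start"] < iv.end) & (track["end"] > iv.start)
    ]
    return bool(len(sel))


def select_3d_candidates(
    associations: list[SVAssociation],
    svs_by_id: dict[str, SVRecord],
    genes_by_id: dict[str, GeneModel],
    tad_boundaries: pd.DataFrame | None,
    ctcf_ccres: pd.DataFrame | None,
    chromhmm_states: pd.DataFrame | None,
) -> list[tuple[str, str]]:
    """Associated SVs with potential to rewire 3D chromatin architecture.

    All candidates must overlap a shared TAD boundary and a CTCF-only
    cCRE. Duplications must additionally contain the misexpressed gene
    and overlap an Enh/EnhG chromatin state; deletions must not overlap
    the misexpressed gene. Returns (sv_id, gene_id) pairs.
    """
    missing = [
        name
        for name, track in (
            ("tad_boundaries", tad_boundaries),
            ("ctcf_ccres", ctcf_ccres),
            ("chromhmm_states", chromhmm_states),
        )
        if track is None
    ]
    if missing:
        raise ValueError(f"missing required tracks: {missing}")
    enh = chromhmm_states
    if "value" in chromhmm_states.columns:
        enh = chromhmm_states[chromhmm_states["value"].isin(["Enh", "EnhG"])]
    out: list[tuple[str, str]] = []
    for assoc in associations:
        sv = svs_by_id[assoc.sv_id]
        gene = genes_by_id[assoc.gene_id]
        if not _overlaps_track(sv.interval, tad_boundaries):
            continue
        if not _overlaps_track(sv.interval, ctcf_ccres):
            continue
        if sv.svclass == "DUP":
            if not sv.interval.contains(gene.interval):
                continue
            if not _overlaps_track(sv.interval, enh):
                continue
        elif sv.svclass == "DEL":
            if sv.interval.overlaps(gene.interval):
                continue
        out.append((assoc.sv_id, assoc.gene_id))
    return out


# ---------------------------------------------------------------------------
# Transcript fractions and mechanism summary


def transcript_fractions(transcript_tpms: dict[str, float]) -> dict[str, float] | None:
    """Per-transcript fraction of a gene's total TPM; None when total is 0."""
    total = sum(transcript_tpms.values())
    if total <= 0:
        return None
    return {t: v / total for t, v in transcript_tpms.items()}


MECHANISM_PRECEDENCE = ("readthrough", "fusion", "inversion", "3d_candidate", "unknown")


def summarize_mechanisms(
    associations: list[SVAssociation],
    readthrough_candidates: list[ReadthroughCandidate] | None = None,
    threed_candidates: list[tuple[str, str]] | None = None,
    fusion_table: pd.DataFrame | None = None,
    inversion_flags: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Assign one primary mechanism per (gene, SV) association.

    Precedence: readthrough > fusion > inversion > 3d_candidate > unknown.
    The optional fusion table is input-supplied (columns sv_id, gene_id).
    Returns the association table with a ``mechanism`` column; counts
    partition the association set.
    """
    rt = {(c.sv_id, c.misexpressed_gene_id) for c in (readthrough_candidates or [])}
    td = set(threed_candidates or [])
    inv = set(inversion_flags or [])
    fus: set[tuple[str, str]] = set()
    if fusion_table is not None and len(fusion_table):
        fus = set(zip(fusion_table["sv_id"], fusion_table["gene_id"]))
    rows = []
    for assoc in associations:
        key = (assoc.sv_id, assoc.gene_id)
        if key in rt:
            mech = "readthrough"
        elif key in fus:
            mech = "fusion"
        elif key in inv:
            mech = "inversion"
        elif key in td:
            mech = "3d_candidate"
        else:
            mech = "unknown"
        rows.append(
            {
                "sv_id": assoc.sv_id,
                "gene_id": assoc.gene_id,
                "svclass": assoc.svclass,
                "median_z": assoc.median_z,
                "mechanism": mech,
            }
        )
    return pd.DataFrame(rows)
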
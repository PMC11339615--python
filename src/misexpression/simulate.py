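"""Synthetic cohort generator with known ground truth.

Emulates the data a cohort misexpression analysis consumes: a genome
annotation, a TPM matrix with a bimodal active/inactive structure, rare
misexpression events (some caused by rare SVs carried by 1-3 samples,
some non-genetic background), covariate-tracking genes, global-outlier
samples, a rare SV callset of four classes, and readthrough loci with
carrier-specific strand-aware intergenic coverage. Every injected signal
is recorded in a truth table so downstream stages can be scored.

Background (non-genetic) misexpression is generated as gene-level
bursts: a background gene receives 1 + Poisson-distributed carrier
samples while the per-pair marginal rate is held at the configured
value. Real non-genetic misexpression recurs across samples of a gene;
with exact-zero baselines an isolated outlier always attains the maximal
Z-score sqrt(n), so burst structure is what gives lower Z thresholds
more non-genetic events than higher ones, as seen in real cohorts.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CovariateTable,
    ExpressionMatrix,
    FragmentAlignmentTable,
    GeneModel,
    GenomicInterval,
    SVCallset,
    SVRecord,
)
from . import io as mio


@dataclass
class SimulationConfig:
    """Cohort-generator knobs; defaults define the standard study conditions."""

    n_samples: int = 300
    n_genes: int = 2000
    fraction_inactive: float = 0.6
    n_chromosomes: int = 4
    chrom_length_bp: int = 10_000_000
    active_log_mean: float = 2.0    # log-TPM mean of active genes
    active_log_sd: float = 1.0      # log-TPM sd of active genes
    sample_log_sd: float = 0.3      # within-gene sample-to-sample log variation
    leak_rate: float = 0.02         # P(inactive gene-sample pair leaks TPM U(0, 0.1))
    background_rate: float = 5e-4   # marginal misexpression rate per inactive pair
    background_burst_mean: float = 2.0  # burst size = 1 + Poisson(this)
    background_tpm: tuple[float, float] = (0.6, 50.0)
    n_sv_driven_events: int = 30
    sv_carriers: tuple[int, int] = (1, 3)
    sv_carrier_tpm: tuple[float, float] = (1.0, 100.0)
    sv_length: tuple[int, int] = (5_000, 50_000)
    sv_max_gap: int = 150_000       # causal SV gap to its target gene
    n_null_rare_svs: int = 500
    n_covariate_driven_genes: int = 5
    n_covariates: int = 10
    covariate_rho: float = 0.5
    n_global_outlier_samples: int = 3
    n_readthrough_loci: int = 4     # split evenly DEL/DUP
    min_gene_gap_bp: int = 15_000
    gene_length: tuple[int, int] = (300, 2_000)
    depth: tuple[int, int] = (8_000_000, 12_000_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fraction_inactive < 1:
            raise ValueError("fraction_inactive must be in (0, 1)")
        for name in ("n_samples", "n_genes", "n_chromosomes", "chrom_length_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "n_sv_driven_events",
            "n_null_rare_svs",
            "n_covariate_driven_genes",
            "n_global_outlier_samples",
            "n_readthrough_loci",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


RESERVE_BP = 400_000  # chromosome tail reserved for readthrough loci


@dataclass
class ReadthroughLocusTruth:
    sv_id: str
    kind: str
    donor_gene_id: str
    misexpressed_gene_id: str
    region: GenomicInterval
    carriers: frozenset[str]


@dataclass
class SimulationTruth:
    """Ground truth for every injected signal."""

    events: pd.DataFrame  # gene_id, sample_id, cause
    svs: pd.DataFrame     # sv_id, causal, target_gene
    readthrough_loci: list[ReadthroughLocusTruth] = field(default_factory=list)
    covariate_genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    global_outlier_samples: list[str] = field(default_factory=list)
    inactive_genes: list[str] = field(default_factory=list)


@dataclass
class LocusBundle:
    """A constructed readthrough locus with everything needed to test it."""

    donor: GeneModel
    misexpressed: GeneModel
    sv: SVRecord
    region: GenomicInterval
    fragments: pd.DataFrame
    polya_sites: pd.DataFrame
    carriers: frozenset[str]
    kind: str


@dataclass
class CohortBundle:
    genes: list[GeneModel]
    tpm: ExpressionMatrix
    covariates: CovariateTable
    svs: SVCallset
    fragments: FragmentAlignmentTable
    polya_sites: pd.DataFrame
    truth: SimulationTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Genome layout


def _place_genes(rng: np.random.Generator, cfg: SimulationConfig) -> list[GeneModel]:
    per_chrom = math.ceil(cfg.n_genes / cfg.n_chromosomes)
    span = cfg.chrom_length_bp - RESERVE_BP
    lo, hi = cfg.gene_length
    needed = per_chrom * hi + (per_chrom + 1) * cfg.min_gene_gap_bp
    if needed > span:
        raise ValueError(
            f"infeasible layout: {per_chrom} genes of up to {hi} bp with "
            f"{cfg.min_gene_gap_bp} bp gaps need {needed} bp but only {span} available"
        )
    genes: list[GeneModel] = []
    gid = 0
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        n = min(per_chrom, cfg.n_genes - gid)
        lengths = rng.integers(lo, hi + 1, size=n)
        slack = span - int(lengths.sum()) - (n + 1) * cfg.min_gene_gap_bp
        extra = rng.random(n + 1)
        extra = np.floor(extra / extra.sum() * slack).astype(int)
        strands = rng.choice(["+", "-"], size=n)
        biotypes = rng.choice(
            ["protein_coding", "lncRNA", "other"], size=n, p=[0.45, 0.45, 0.10]
        )
        pos = cfg.min_gene_gap_bp + int(extra[0])
        for i in range(n):
            start = pos
            end = start + int(lengths[i])
            iv = GenomicInterval(chrom, start, end, str(strands[i]))
            genes.append(
                GeneModel(
                    gene_id=f"G{gid:05d}",
                    interval=iv,
                    biotype=str(biotypes[i]),
                    exons=[iv],
                )
            )
            gid += 1
            pos = end + cfg.min_gene_gap_bp + int(extra[i + 1])
    return genes


# ---------------------------------------------------------------------------
# Readthrough loci


def _build_locus(
    rng: np.random.Generator,
    chrom: str,
    offset: int,
    strand: str,
    kind: str,
    locus_idx: int,
    sample_ids: list[str],
    carriers: list[str],
    depths: dict[str, int],
    carrier_tpm: tuple[float, float] = (5.0, 50.0),
) -> tuple[LocusBundle, dict[str, float]]:
    """Construct one readthrough locus in reference coordinates.

    Geometry is built on the forward strand and mirrored for '-' loci.
    Returns the bundle plus carrier TPM values for the misexpressed gene.
    """
    tag = f"RT{locus_idx}"
    donor_len, mis_len = 6_000, 2_000
    inter_gap = 8_000

    if kind == "DEL":
        # donor ... [deletion over donor 3' end + polyA] ... mis gene
        if strand == "+":
            donor_iv = GenomicInterval(chrom, offset, offset + donor_len, "+")
            sv_iv = GenomicInterval(chrom, donor_iv.end - 1_000, donor_iv.end + 3_000)
            mis_iv = GenomicInterval(
                chrom, donor_iv.end + inter_gap, donor_iv.end + inter_gap + mis_len, "+"
            )
            polya = (donor_iv.end - 120, donor_iv.end - 100)
            region = GenomicInterval(chrom, sv_iv.end, mis_iv.start, "+")
        else:
            mis_iv = GenomicInterval(chrom, offset, offset + mis_len, "-")
            donor_start = mis_iv.end + inter_gap
            donor_iv = GenomicInterval(chrom, donor_start, donor_start + donor_len, "-")
            sv_iv = GenomicInterval(chrom, donor_iv.start - 3_000, donor_iv.start + 1_000)
            polya = (donor_iv.start + 100, donor_iv.start + 120)
            region = GenomicInterval(chrom, mis_iv.end, sv_iv.start, "-")
        svclass = "DEL"
    elif kind == "DUP":
        # dup covers the whole mis gene and the donor 5' end downstream
        if strand == "+":
            mis_iv = GenomicInterval(chrom, offset + 3_000, offset + 3_000 + mis_len, "+")
            donor_start = mis_iv.end + inter_gap
            donor_iv = GenomicInterval(chrom, donor_start, donor_start + donor_len, "+")
            sv_iv = GenomicInterval(chrom, offset, donor_iv.start + 1_000)
            polya = (donor_iv.end - 120, donor_iv.end - 100)
            region = GenomicInterval(chrom, sv_iv.start, mis_iv.start, "+")
        else:
            donor_iv = GenomicInterval(chrom, offset, offset + donor_len, "-")
            mis_start = donor_iv.end + inter_gap
            mis_iv = GenomicInterval(chrom, mis_start, mis_start + mis_len, "-")
            sv_iv = GenomicInterval(chrom, donor_iv.end - 1_000, mis_iv.end + 3_000)
            polya = (donor_iv.start + 100, donor_iv.start + 120)
            region = GenomicInterval(chrom, mis_iv.end, sv_iv.end, "-")
        svclass = "DUP"
    else:
        raise ValueError("kind must be DEL or DUP")

    donor = GeneModel(f"{tag}_DONOR", donor_iv, biotype="protein_coding", exons=[donor_iv])
    mis = GeneModel(f"{tag}_MIS", mis_iv, biotype="protein_coding", exons=[mis_iv])
    sv = SVRecord(
        sv_id=f"sv_{tag}",
        interval=sv_iv,
        svclass=svclass,
        maf=len(carriers) / (2 * len(sample_ids)),
        carriers=frozenset(carriers),
    )
    polya_sites = pd.DataFrame([{"chrom": chrom, "start": polya[0], "end": polya[1]}])

    # fragments: carriers tile the readthrough region and the inactive gene
    # on its strand; all samples carry sparse background
    frag_rows: list[dict] = []
    frag_len = 100
    for s in carriers:
        for span_start, span_end in ((region.start, region.end), (mis_iv.start, mis_iv.end)):
            pos = span_start
            while pos < span_end:
                frag_rows.append(
                    {
                        "sample_id": s,
                        "chrom": chrom,
                        "start": pos,
                        "end": min(pos + frag_len, span_end),
                        "strand": region.strand,
                    }
                )
                pos += 80
    carrier_set = set(carriers)
    for s in sample_ids:
        n_bg = rng.poisson(0.8 if s not in carrier_set else 0.3)
        for _ in range(n_bg):
            start = int(rng.integers(region.start, max(region.start + 1, region.end - frag_len)))
            frag_rows.append(
                {
                    "sample_id": s,
                    "chrom": chrom,
                    "start": start,
                    "end": min(start + frag_len, region.end),
                    "strand": str(rng.choice(["+", "-"])),
                }
            )
    fragments = pd.DataFrame(
        frag_rows, columns=["sample_id", "chrom", "start", "end", "strand"]
    )
    tpms = {
        s: float(rng.uniform(carrier_tpm[0], carrier_tpm[1])) for s in carriers
    }
    bundle = LocusBundle(
        donor=donor,
        misexpressed=mis,
        sv=sv,
        region=region,
        fragments=fragments,
        polya_sites=polya_sites,
        carriers=frozenset(carriers),
        kind=kind,
    )
    return bundle, tpms


def simulate_readthrough_locus(
    config: SimulationConfig, kind: str, strand: str = "+"
) -> LocusBundle:
    """Standalone readthrough locus for unit testing mechanism calls."""
    rng = np.random.default_rng(config.seed)
    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]
    n_carriers = int(rng.integers(1, 3))
    carriers = sorted(rng.choice(sample_ids, size=n_carriers, replace=False))
    depths = {s: int(rng.integers(*config.depth)) for s in sample_ids}
    bundle, _ = _build_locus(
        rng, "chr1", 1_000_000, strand, kind, 0, sample_ids, carriers, depths
    )
    return bundle


# ---------------------------------------------------------------------------
# Cohort simulation


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Generate a full synthetic cohort; deterministic given the seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    sample_ids = [f"S{i:04d}" for i in range(cfg.n_samples)]

    genes = _place_genes(rng, cfg)
    n_inactive = int(round(cfg.n_genes * cfg.fraction_inactive))
    order = rng.permutation(cfg.n_genes)
    inactive_ids = [genes[i].gene_id for i in sorted(order[:n_inactive])]
    active_ids = [genes[i].gene_id for i in sorted(order[n_inactive:])]
    inactive_set = set(inactive_ids)

    needed = cfg.n_sv_driven_events + cfg.n_covariate_driven_genes
    if needed > n_inactive:
        raise ValueError(
            f"infeasible config: {needed} causal/covariate genes exceed "
            f"{n_inactive} inactive genes"
        )

    # --- global outlier samples (never used as carriers)
    outliers = sorted(rng.choice(sample_ids, size=cfg.n_global_outlier_samples, replace=False))
    usable_samples = [s for s in sample_ids if s not in set(outliers)]

    # --- expression scaffold
    expr = pd.DataFrame(0.0, index=[g.gene_id for g in genes], columns=sample_ids)
    for gid_ in active_ids:
        base = math.exp(rng.normal(cfg.active_log_mean, cfg.active_log_sd))
        expr.loc[gid_] = base * np.exp(rng.normal(0.0, cfg.sample_log_sd, cfg.n_samples))

    # --- covariates and covariate-driven genes
    cov = pd.DataFrame(
        rng.normal(size=(cfg.n_samples, cfg.n_covariates)),
        index=sample_ids,
        columns=[f"cov{j}" for j in range(cfg.n_covariates)],
    )
    pool = [g for g in inactive_ids]
    cov_genes = [pool.pop(int(rng.integers(len(pool)))) for _ in range(cfg.n_covariate_driven_genes)]
    cov_rows = []
    # monotone link: rank-scaled covariate + uniform noise, mixed to hit the
    # target Spearman rho, then mapped below the 0.1 TPM activity threshold
    b = math.sqrt(max(1e-9, 1.0 / cfg.covariate_rho**2 - 1.0))
    for g in cov_genes:
        j = int(rng.integers(cfg.n_covariates))
        u = cov.iloc[:, j].rank().to_numpy() / cfg.n_samples
        noise = rng.random(cfg.n_samples)
        mix = u + b * noise
        expr.loc[g] = 0.1 * (mix - mix.min()) / (mix.max() - mix.min())
        cov_rows.append({"gene_id": g, "covariate": cov.columns[j]})

    # --- SV-driven misexpression events
    sv_records: list[SVRecord] = []
    sv_truth_rows: list[dict] = []
    event_rows: list[dict] = []
    sv_genes = [pool.pop(int(rng.integers(len(pool)))) for _ in range(cfg.n_sv_driven_events)]
    genes_by_id = {g.gene_id: g for g in genes}
    truth_pairs: set[tuple[str, str]] = set()
    # carriers per gene must stay below the 5% inactivity boundary
    max_carr = max(1, math.ceil(0.05 * cfg.n_samples) - 1)
    for k, gid_ in enumerate(sv_genes):
        gene = genes_by_id[gid_]
        n_carr = min(
            int(rng.integers(cfg.sv_carriers[0], cfg.sv_carriers[1] + 1)), max_carr
        )
        carriers = sorted(rng.choice(usable_samples, size=n_carr, replace=False))
        length = int(rng.integers(*cfg.sv_length))
        gap = int(rng.integers(0, cfg.sv_max_gap))
        side_left = bool(rng.random() < 0.5)
        span_end = cfg.chrom_length_bp - RESERVE_BP
        if side_left and gene.interval.start - gap - length > 0:
            end = gene.interval.start - gap
            start = end - length
        else:
            start = min(gene.interval.end + gap, span_end - length - 1)
            end = start + length
        svclass = str(rng.choice(["DEL", "DUP", "INV", "MEI"], p=[0.5, 0.3, 0.1, 0.1]))
        sv_id = f"sv_causal_{k:03d}"
        sv_records.append(
            SVRecord(
                sv_id=sv_id,
                interval=GenomicInterval(gene.interval.chrom, start, end),
                svclass=svclass,
                maf=n_carr / (2 * cfg.n_samples),
                carriers=frozenset(carriers),
            )
        )
        sv_truth_rows.append({"sv_id": sv_id, "causal": True, "target_gene": gid_})
        for s in carriers:
            expr.loc[gid_, s] = rng.uniform(*cfg.sv_carrier_tpm)
            event_rows.append({"gene_id": gid_, "sample_id": s, "cause": "sv_driven"})
            truth_pairs.add((gid_, s))

    # --- null rare SVs; their carriers stay silent at in-window inactive genes
    inactive_by_chrom: dict[str, list[GeneModel]] = {}
    for gid_ in inactive_ids:
        g = genes_by_id[gid_]
        inactive_by_chrom.setdefault(g.interval.chrom, []).append(g)
    blocked: set[tuple[str, str]] = set()
    for k in range(cfg.n_null_rare_svs):
        length = int(rng.integers(*cfg.sv_length))
        chrom = f"chr{int(rng.integers(cfg.n_chromosomes)) + 1}"
        start = int(rng.integers(0, cfg.chrom_length_bp - RESERVE_BP - length - 1))
        iv = GenomicInterval(chrom, start, start + length)
        near = [
            g.gene_id
            for g in inactive_by_chrom.get(chrom, [])
            if g.interval.distance(iv) <= 200_000
        ]
        carriers: list[str] = []
        for _ in range(40):
            n_carr = int(rng.integers(cfg.sv_carriers[0], cfg.sv_carriers[1] + 1))
            cand = sorted(rng.choice(usable_samples, size=n_carr, replace=False))
            if not any((g, s) in truth_pairs for g in near for s in cand):
                carriers = cand
                break
        if not carriers:
            continue
        svclass = str(rng.choice(["DEL", "DUP", "INV", "MEI"], p=[0.5, 0.3, 0.1, 0.1]))
        sv_id = f"sv_null_{k:03d}"
        sv_records.append(
            SVRecord(
                sv_id=sv_id,
                interval=iv,
                svclass=svclass,
                maf=len(carriers) / (2 * cfg.n_samples),
                carriers=frozenset(carriers),
            )
        )
        sv_truth_rows.append({"sv_id": sv_id, "causal": False, "target_gene": ""})
        for g in near:
            for s in carriers:
                blocked.add((g, s))

    # --- inactive leak and background bursts (skipping blocked cells)
    sample_pos = {s: i for i, s in enumerate(sample_ids)}
    special = set(cov_genes) | set(sv_genes)
    burst_cap = max(1, int(0.04 * cfg.n_samples))
    p_gene = min(
        1.0,
        cfg.background_rate * cfg.n_samples / (1.0 + cfg.background_burst_mean),
    )
    for gid_ in inactive_ids:
        row = expr.loc[gid_].to_numpy(copy=True)
        leak_mask = rng.random(cfg.n_samples) < cfg.leak_rate
        leak_vals = rng.uniform(0.0, 0.1, size=cfg.n_samples)
        if gid_ not in special:
            row = np.where(leak_mask, leak_vals, row)
        if gid_ not in special and rng.random() < p_gene:
            k = min(1 + int(rng.poisson(cfg.background_burst_mean)), burst_cap)
            open_samples = [
                s for s in usable_samples if (gid_, s) not in blocked
            ]
            if open_samples:
                chosen = rng.choice(open_samples, size=min(k, len(open_samples)), replace=False)
                for s in chosen:
                    row[sample_pos[s]] = rng.uniform(*cfg.background_tpm)
                    event_rows.append(
                        {"gene_id": gid_, "sample_id": s, "cause": "background"}
                    )
        for g_s in ((gid_, s) for s in sample_ids):
            if g_s in blocked:
                row[sample_pos[g_s[1]]] = 0.0
        expr.loc[gid_] = row

    # --- readthrough loci in the reserved chromosome tails
    rt_truth: list[ReadthroughLocusTruth] = []
    polya_frames: list[pd.DataFrame] = []
    frag_frames: list[pd.DataFrame] = []
    depths = {s: int(rng.integers(*cfg.depth)) for s in sample_ids}
    for li in range(cfg.n_readthrough_loci):
        kind = "DEL" if li % 2 == 0 else "DUP"
        chrom = f"chr{(li % cfg.n_chromosomes) + 1}"
        offset = cfg.chrom_length_bp - RESERVE_BP + 50_000 + 120_000 * (li // cfg.n_chromosomes)
        strand = "+" if (li // 2) % 2 == 0 else "-"
        n_carr = min(int(rng.integers(1, 3)), max_carr)
        carriers = sorted(rng.choice(usable_samples, size=n_carr, replace=False))
        locus, mis_tpms = _build_locus(
            rng, chrom, offset, strand, kind, li, sample_ids, carriers, depths
        )
        genes.append(locus.donor)
        genes.append(locus.misexpressed)
        donor_base = math.exp(rng.normal(3.0, 0.2))
        expr.loc[locus.donor.gene_id] = donor_base * np.exp(
            rng.normal(0.0, cfg.sample_log_sd, cfg.n_samples)
        )
        mis_row = np.zeros(cfg.n_samples)
        for s, v in mis_tpms.items():
            mis_row[sample_pos[s]] = v
            event_rows.append(
                {"gene_id": locus.misexpressed.gene_id, "sample_id": s, "cause": "readthrough"}
            )
        expr.loc[locus.misexpressed.gene_id] = mis_row
        inactive_ids.append(locus.misexpressed.gene_id)
        sv_records.append(locus.sv)
        sv_truth_rows.append(
            {
                "sv_id": locus.sv.sv_id,
                "causal": True,
                "target_gene": locus.misexpressed.gene_id,
            }
        )
        rt_truth.append(
            ReadthroughLocusTruth(
                sv_id=locus.sv.sv_id,
                kind=kind,
                donor_gene_id=locus.donor.gene_id,
                misexpressed_gene_id=locus.misexpressed.gene_id,
                region=locus.region,
                carriers=locus.carriers,
            )
        )
        polya_frames.append(locus.polya_sites)
        frag_frames.append(locus.fragments)

    # --- global outlier samples: top-expressed in far more genes than expected
    n_nonzero = int((expr.sum(axis=1) > 0).sum())
    cutoff = int(math.ceil(5.0 * n_nonzero / cfg.n_samples))
    n_inflate = cutoff * 2
    if cfg.n_global_outlier_samples:
        cap = len(active_ids) // cfg.n_global_outlier_samples
        if cap <= cutoff:
            raise ValueError(
                "infeasible config: too few active genes to construct "
                f"{cfg.n_global_outlier_samples} global-outlier samples"
            )
        n_inflate = min(n_inflate, cap)
    pool_active = [g for g in active_ids]
    for s in outliers:
        chosen = [pool_active.pop(int(rng.integers(len(pool_active)))) for _ in range(n_inflate)]
        for gid_ in chosen:
            expr.loc[gid_, s] = expr.loc[gid_].max() * rng.uniform(1.5, 3.0)

    # verify inactive genes stay inactive by construction
    sub = expr.loc[inactive_ids]
    frac = (sub > 0.1).mean(axis=1)
    bad = frac[frac >= 0.05]
    if len(bad):
        raise RuntimeError(f"construction violated inactivity for {bad.index.tolist()[:5]}")

    tpm = ExpressionMatrix(expr, unit="TPM", subset=True)
    truth = SimulationTruth(
        events=pd.DataFrame(event_rows, columns=["gene_id", "sample_id", "cause"]),
        svs=pd.DataFrame(sv_truth_rows, columns=["sv_id", "causal", "target_gene"]),
        readthrough_loci=rt_truth,
        covariate_genes=pd.DataFrame(cov_rows, columns=["gene_id", "covariate"]),
        global_outlier_samples=outliers,
        inactive_genes=list(inactive_ids),
    )
    polya = (
        pd.concat(polya_frames, ignore_index=True)
        if polya_frames
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )
    fragments = FragmentAlignmentTable(
        pd.concat(frag_frames, ignore_index=True)
        if frag_frames
        else pd.DataFrame(columns=["sample_id", "chrom", "start", "end", "strand"]),
        depths,
    )
    return CohortBundle(
        genes=genes,
        tpm=tpm,
        covariates=CovariateTable(cov),
        svs=SVCallset(sv_records, sample_universe=frozenset(sample_ids)),
        fragments=fragments,
        polya_sites=polya,
        truth=truth,
        config=cfg,
    )


def permute_carriers(callset: SVCallset, rng: np.random.Generator) -> SVCallset:
    """Reassign every SV's carriers to random samples (carrier-label permutation)."""
    universe = sorted(callset.sample_universe)
    records = []
    for r in callset:
        k = min(len(r.carriers), len(universe))
        new = frozenset(rng.choice(universe, size=k, replace=False)) if k else frozenset()
        records.append(
            SVRecord(r.sv_id, r.interval, r.svclass, r.maf, new, r.consequences)
        )
    return SVCallset(records, callset.sample_universe)


# ---------------------------------------------------------------------------
# Bundle writer


def write_bundle(bundle: CohortBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the whole bundle in standard formats; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": outdir / "annotation.gtf",
        "tpm": outdir / "tpm.tsv",
        "covariates": outdir / "covariates.tsv",
        "svs": outdir / "svs.tsv",
        "fragments": outdir / "fragments.bed",
        "depths": outdir / "depths.tsv",
        "polya": outdir / "polya_sites.bed",
        "truth_events": outdir / "truth_events.tsv",
        "truth_svs": outdir / "truth_svs.tsv",
    }
    mio.write_gene_annotation(bundle.genes, paths["annotation"])
    mio.write_expression_matrix(bundle.tpm, paths["tpm"])
    mio.write_covariate_table(bundle.covariates, paths["covariates"])
    mio.write_sv_callset(bundle.svs, paths["svs"])
    mio.write_fragments(bundle.fragments, paths["fragments"], paths["depths"])
    mio.write_bed_track(bundle.polya_sites, paths["polya"])
    bundle.truth.events.to_csv(paths["truth_events"], sep="\t", index=False)
    bundle.truth.svs.to_csv(paths["truth_svs"], sep="\t", index=False)
    return paths
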
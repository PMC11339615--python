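"""Misexpression-associated and control rare SVs, and their properties.

A rare SV within the association window of an ever-misexpressed inactive
gene is misexpression-associated when the carriers' median TPM > 0.5,
median Z > 2 and no carrier has TPM < 0.1. Control SVs are rare SVs for
which every inactive gene in the window shows zero carrier TPM. The two
sets are compared by length (one-sided Mann-Whitney) and by genomic
score / regulatory-overlap enrichment in length-adjusted logistic
regressions, deletions and duplications separately.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, GeneModel, SVCallset, SVRecord
from .enrichment import (
    LogisticEnrichmentResult,
    annotate_most_severe_consequence,
    gene_feature_enrichment,
)

POSITION_CLASSES = (
    "contains_gene",
    "partial_5prime",
    "partial_3prime",
    "internal",
    "upstream",
    "downstream",
)


@dataclass
class SVAssociation:
    sv_id: str
    gene_id: str
    svclass: str
    carriers: frozenset[str]
    median_tpm: float
    median_z: float
    min_carrier_tpm: float
    position: str
    consequence: str | None = None


def classify_sv_position(sv: SVRecord, gene: GeneModel) -> str:
    """Position of an SV relative to a gene, strand-aware for ends/sides."""
    siv, giv = sv.interval, gene.interval
    if siv.chrom != giv.chrom:
        raise ValueError("SV and gene on different chromosomes")
    if siv.contains(giv):
        return "contains_gene"
    if giv.contains(siv):
        return "internal"
    if siv.overlaps(giv):
        covers_left = siv.start <= giv.start
        if gene.strand != "-":
            return "partial_5prime" if covers_left else "partial_3prime"
        return "partial_3prime" if covers_left else "partial_5prime"
    left = siv.end <= giv.start
    upstream = left if gene.strand != "-" else not left
    return "upstream" if upstream else "downstream"


def identify_associated_svs(
    rare_svs: SVCallset,
    misexpressed_inactive_genes: list[str],
    genes_by_id: dict[str, GeneModel],
    tpm: ExpressionMatrix,
    z: pd.DataFrame,
    window_bp: int = 200_000,
    median_tpm_thr: float = 0.5,
    median_z_thr: float = 2.0,
    carrier_tpm_floor: float = 0.1,
) -> list[SVAssociation]:
    """Associate rare SVs with nearby ever-misexpressed inactive genes.

    One association row is emitted per qualifying (gene, SV) pair; pairs
    are dropped when any carrier has TPM < 0.1 at the gene (carriers of a
    causal SV should all express it at least weakly).
    """
    out: list[SVAssociation] = []
    samples = set(tpm.sample_ids)
    for sv in rare_svs:
        carriers = sorted(sv.carriers & samples)
        if not carriers:
            warnings.warn(f"SV {sv.sv_id} has no carriers in the cohort; skipped")
            continue
        for gid in misexpressed_inactive_genes:
            gene = genes_by_id[gid]
            if gene.interval.chrom != sv.interval.chrom:
                continue
            if gene.interval.distance(sv.interval) > window_bp:
                continue
            ctpm = tpm.values.loc[gid, carriers].to_numpy(dtype=float)
            cz = z.loc[gid, carriers].to_numpy(dtype=float)
            med_tpm = float(np.median(ctpm))
            med_z = float(np.median(cz))
            if med_tpm <= median_tpm_thr or not med_z > median_z_thr:
                continue
            if (ctpm < carrier_tpm_floor).any():
                continue
            consequence = None
            if sv.consequences is not None:
                consequence = annotate_most_severe_consequence(sv, gid)
            out.append(
                SVAssociation(
                    sv_id=sv.sv_id,
                    gene_id=gid,
                    svclass=sv.svclass,
                    carriers=frozenset(carriers),
                    median_tpm=med_tpm,
                    median_z=med_z,
                    min_carrier_tpm=float(ctpm.min()),
                    position=classify_sv_position(sv, gene),
                    consequence=consequence,
                )
            )
    return out


def identify_control_svs(
    rare_svs: SVCallset,
    inactive_genes: list[str],
    genes_by_id: dict[str, GeneModel],
    tpm: ExpressionMatrix,
    window_bp: int = 200_000,
    scope: str = "carriers",
) -> list[str]:
    """Control SVs: zero TPM at every inactive gene within the window.

    ``scope`` selects the samples over which "maximum TPM equal to 0" is
    evaluated: the SV's carriers (default; the samples the SV could act
    in) or the whole cohort. SVs with no inactive gene in the window are
    neither associated nor control and are excluded.
    """
    if scope not in ("carriers", "all"):
        raise ValueError("scope must be 'carriers' or 'all'")
    samples = set(tpm.sample_ids)
    controls: list[str] = []
    for sv in rare_svs:
        near = [
            g
            for g in inactive_genes
            if genes_by_id[g].interval.chrom == sv.interval.chrom
            and genes_by_id[g].interval.distance(sv.interval) <= window_bp
        ]
        if not near:
            continue
        if scope == "carriers":
            cols = sorted(sv.carriers & samples)
            if not cols:
                continue
        else:
            cols = list(tpm.sample_ids)
        sub = tpm.values.loc[near, cols].to_numpy(dtype=float)
        if sub.max() == 0:
            controls.append(sv.sv_id)
    return controls


@dataclass
class ScoreTrack:
    """A genomic score or binary-overlap track with its aggregation rule."""

    name: str
    intervals: pd.DataFrame  # columns chrom, start, end[, value]
    rule: str  # max | min | any

    def __post_init__(self) -> None:
        if self.rule not in ("max", "min", "any"):
            raise ValueError("rule must be max, min or any")
        has_value = "value" in self.intervals.columns
        if self.rule == "any" and has_value:
            raise ValueError("'any' rule applies to categorical (valueless) tracks")
        if self.rule in ("max", "min") and not has_value:
            raise ValueError(f"'{self.rule}' rule needs a value column")


def aggregate_score_over_sv(sv: SVRecord, track: ScoreTrack):
    """Aggregate a track over the SV interval: max/min of overlapped values,
    or any-overlap boolean. No overlap under max/min yields NaN (missing)."""
    df = track.intervals
    sel = df[
        (df["chrom"] == sv.interval.chrom)
        & (df["start"] < sv.interval.end)
        & (df["end"] > sv.interval.start)
    ]
    if track.rule == "any":
        return bool(len(sel))
    if sel.empty:
        return float("nan")
    vals = sel["value"].to_numpy(dtype=float)
    return float(vals.max() if track.rule == "max" else vals.min())


def sv_length_test(
    associated_lengths: np.ndarray, control_lengths: np.ndarray
) -> tuple[float, float]:
    """Mean-length fold difference and one-sided Mann-Whitney p
    (alternative: associated SVs are longer)."""
    a = np.asarray(associated_lengths, dtype=float)
    c = np.asarray(control_lengths, dtype=float)
    if len(a) == 0 or len(c) == 0:
        raise ValueError("both groups must be non-empty")
    if min(len(a), len(c)) < 3:
        warnings.warn("group of size < 3: Mann-Whitney p unreliable")
    fold = float(a.mean() / c.mean())
    _, p = stats.mannwhitneyu(a, c, alternative="greater", method="asymptotic")
    return fold, float(p)


def sv_feature_enrichment(
    features: pd.DataFrame,
    associated: pd.Series,
    lengths: pd.Series,
) -> list[LogisticEnrichmentResult]:
    """Length-adjusted logistic enrichment of per-SV features.

    Features (scores or binary overlaps, already aggregated per SV) are
    Z-transformed over the pooled associated+control set and modelled one
    at a time with log10 SV length as a covariate. Call separately per SV
    class.
    """
    covar = pd.DataFrame({"log10_length": np.log10(lengths.astype(float))})
    feats = features.copy()
    for c in feats.columns:
        if feats[c].dtype == bool:
            feats[c] = feats[c].astype(float)
    return gene_feature_enrichment(feats, associated, extra_covariates=covar)
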
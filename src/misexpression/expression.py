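"""Expression quantification, QC, inactive-gene calling and misexpression.

The pipeline mirrors the cohort analysis it implements: raw counts are
length-normalised to TPM, samples with inflated numbers of top-expression
events are dropped as global outliers, inactive genes (TPM > 0.1 in fewer
than 5% of samples) are identified, genes tracking measured covariates
are removed, and per-gene Z-scores define misexpression events
(TPM > 0.5 and Z > 2, both strict).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import AnalysisConfig, CovariateTable, ExpressionMatrix


@dataclass
class QCReport:
    """Record of what sample/gene QC removed and why."""

    removed_samples: pd.DataFrame = field(default_factory=pd.DataFrame)  # sample_id, top_events
    removed_genes: pd.DataFrame = field(default_factory=pd.DataFrame)    # gene_id, covariate, rho, p_adj
    inactive_fraction: pd.Series = field(default_factory=pd.Series)      # per-gene expressed fraction


def counts_to_tpm(counts: ExpressionMatrix, lengths: dict[str, int]) -> ExpressionMatrix:
    """Convert gene-level counts to TPM using merged-exon lengths.

    Per sample: rate_g = count_g / length_g(kb); TPM_g = rate_g / sum(rate) * 1e6.
    """
    if counts.unit != "counts":
        raise ValueError("input matrix must be in counts")
    missing = [g for g in counts.gene_ids if g not in lengths]
    if missing:
        raise ValueError(f"genes without length: {missing[:5]}")
    lens = np.array([lengths[g] for g in counts.gene_ids], dtype=float)
    if (lens <= 0).any():
        bad = [g for g, l in zip(counts.gene_ids, lens) if l <= 0]
        raise ValueError(f"non-positive exon length for genes: {bad[:5]}")
    rate = counts.values.to_numpy(dtype=float) / (lens[:, None] / 1e3)
    colsum = rate.sum(axis=0)
    zero_cols = colsum == 0
    if zero_cols.any():
        warnings.warn(
            f"all-zero sample columns left as zero TPM: "
            f"{[c for c, z in zip(counts.sample_ids, zero_cols) if z][:5]}"
        )
        colsum[zero_cols] = 1.0
    tpm = rate / colsum * 1e6
    return ExpressionMatrix(
        pd.DataFrame(tpm, index=counts.values.index, columns=counts.values.columns),
        unit="TPM",
        subset=counts.subset,
    )


def count_top_expression_events(tpm: ExpressionMatrix) -> pd.Series:
    """Per-sample count of genes where that sample attains the gene maximum.

    Genes that are zero across all samples must already be excluded by the
    caller. Ties: every sample attaining a gene's maximum counts one event.
    """
    arr = tpm.values.to_numpy(dtype=float)
    colmax = arr.max(axis=1, keepdims=True)
    is_top = arr == colmax
    counts = is_top.sum(axis=0)
    return pd.Series(counts, index=tpm.values.columns, name="top_events")


def remove_global_outliers(
    tpm: ExpressionMatrix, fold: float = 5.0
) -> tuple[ExpressionMatrix, QCReport]:
    """Drop samples with >= fold x the expected number of top-expression events.

    Expected events per sample = (number of genes with any nonzero TPM) /
    (number of samples); genes zero everywhere do not contribute.
    """
    if len(tpm.sample_ids) < 2:
        raise ValueError("global-outlier removal needs at least 2 samples")
    nonzero = tpm.values.loc[tpm.values.sum(axis=1) > 0]
    nonzero_mat = ExpressionMatrix(nonzero, tpm.unit, subset=True)
    counts = count_top_expression_events(nonzero_mat)
    expected = len(nonzero) / len(tpm.sample_ids)
    cutoff = fold * expected
    removed = counts[counts >= cutoff].sort_values(ascending=False)
    if len(removed) == len(tpm.sample_ids):
        raise ValueError("all samples flagged as global outliers; degenerate data")
    kept = [s for s in tpm.sample_ids if s not in set(removed.index)]
    report = QCReport(
        removed_samples=removed.rename_axis("sample_id").reset_index()
    )
    return tpm.restrict_samples(kept), report


def outlier_cutoff(n_genes_nonzero: int, n_samples: int, fold: float = 5.0) -> float:
    """Removal cutoff in events: samples with count >= this are dropped."""
    return fold * n_genes_nonzero / n_samples


def identify_inactive_genes(
    tpm: ExpressionMatrix, tpm_thr: float = 0.1, frac: float = 0.05
) -> tuple[list[str], pd.Series]:
    """Genes with TPM > tpm_thr in (strictly) less than ``frac`` of samples."""
    expressed = (tpm.values > tpm_thr).mean(axis=1)
    inactive = expressed.index[expressed < frac].tolist()
    return inactive, expressed.rename("expressed_fraction")


def filter_covariate_correlated(
    tpm: ExpressionMatrix,
    covariates: CovariateTable,
    rho_thr: float = 0.2,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Remove genes whose expression tracks any covariate.

    Spearman correlation per (gene, covariate) pair (average ranks for
    ties, large-sample t approximation for p); Benjamini-Hochberg FDR is
    applied jointly across all gene x covariate tests. A gene is removed
    iff some pair has |rho| > rho_thr AND adjusted p < alpha.

    Returns (removal table with attribution, retained gene list).
    """
    samples = [s for s in tpm.sample_ids if s in set(covariates.sample_ids)]
    if len(samples) < 10:
        raise ValueError("covariate filtering needs >= 10 overlapping samples")
    expr = tpm.values[samples]
    cov = covariates.numeric().loc[samples]
    usable = []
    for name in cov.columns:
        if cov[name].nunique(dropna=True) < 2:
            warnings.warn(f"constant covariate {name!r} skipped")
        else:
            usable.append(name)
    n = len(samples)
    expr_ranks = expr.rank(axis=1).to_numpy()
    cov_ranks = cov[usable].rank(axis=0).to_numpy()
    er = expr_ranks - expr_ranks.mean(axis=1, keepdims=True)
    cr = cov_ranks - cov_ranks.mean(axis=0, keepdims=True)
    er_norm = np.sqrt((er**2).sum(axis=1))
    cr_norm = np.sqrt((cr**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (er @ cr) / np.outer(er_norm, cr_norm)  # genes x covariates
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    rho = np.nan_to_num(rho, nan=0.0)
    tstat = np.nan_to_num(tstat, nan=0.0)
    tstat[np.abs(rho) >= 1.0] = np.inf  # perfect monotone association
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    _, p_adj_flat, _, _ = multipletests(pvals.ravel(), method="fdr_bh")
    p_adj = p_adj_flat.reshape(pvals.shape)
    hit = (np.abs(rho) > rho_thr) & (p_adj < alpha)
    rows = []
    for gi, gene in enumerate(expr.index):
        js = np.flatnonzero(hit[gi])
        if js.size:
            j = js[np.argmax(np.abs(rho[gi, js]))]
            rows.append(
                {
                    "gene_id": gene,
                    "covariate": usable[j],
                    "rho": float(rho[gi, j]),
                    "p_adj": float(p_adj[gi, j]),
                }
            )
    removed = pd.DataFrame(rows, columns=["gene_id", "covariate", "rho", "p_adj"])
    retained = [g for g in expr.index if g not in set(removed["gene_id"])]
    return removed, retained


def gene_zscores(tpm: ExpressionMatrix) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene standardised TPM across samples (sample sd, ddof=1).

    Returns (Z matrix, boolean Series flagging zero-variance genes whose
    Z-scores are undefined and set to NaN).
    """
    if len(tpm.sample_ids) < 2:
        raise ValueError("Z-scoring needs at least 2 samples")
    arr = tpm.values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    undefined = sd[:, 0] == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (arr - mean) / sd
    z[undefined, :] = np.nan
    zdf = pd.DataFrame(z, index=tpm.values.index, columns=tpm.values.columns)
    return zdf, pd.Series(undefined, index=tpm.values.index, name="zero_variance")


def call_misexpression(
    tpm: ExpressionMatrix,
    z: pd.DataFrame,
    z_thr: float = 2.0,
    tpm_thr: float = 0.5,
) -> pd.DataFrame:
    """Misexpression events: (gene, sample) with TPM > tpm_thr AND Z > z_thr.

    Both inequalities are strict; NaN Z-scores (zero-variance genes) never
    qualify. Returns a table with columns gene_id, sample_id, tpm, z.
    """
    expr = tpm.values.loc[z.index, z.columns]
    mask = (expr.to_numpy() > tpm_thr) & (z.to_numpy() > z_thr)
    gi, si = np.nonzero(mask)
    events = pd.DataFrame(
        {
            "gene_id": z.index.to_numpy()[gi],
            "sample_id": z.columns.to_numpy()[si],
            "tpm": expr.to_numpy()[gi, si],
            "z": z.to_numpy()[gi, si],
        }
    )
    events.attrs["z_thr"] = z_thr
    events.attrs["tpm_thr"] = tpm_thr
    return events


def summarize_prevalence(
    events: pd.DataFrame,
    inactive_genes: list[str],
    samples: list[str],
    biotypes: dict[str, str] | None = None,
    z_grid: tuple[float, ...] = (2, 5, 10, 20, 30, 40),
) -> dict:
    """Cohort-level misexpression prevalence summary.

    Percentages are reported on the 0-100 scale; the gene-sample pair
    denominator is n_inactive_genes x n_samples.
    """
    n_genes = len(inactive_genes)
    n_samples = len(samples)
    n_pairs = n_genes * n_samples
    n_events = len(events)
    genes_hit = events["gene_id"].nunique() if n_events else 0
    samples_hit = events["sample_id"].nunique() if n_events else 0
    per_sample = (
        events.groupby("sample_id").size().reindex(samples, fill_value=0)
        if n_events
        else pd.Series(0, index=samples)
    )
    summary = {
        "n_events": int(n_events),
        "n_pairs": int(n_pairs),
        "pct_pairs_misexpressed": 100.0 * n_events / n_pairs if n_pairs else 0.0,
        "pct_genes_misexpressed": 100.0 * genes_hit / n_genes if n_genes else 0.0,
        "pct_samples_misexpressed": 100.0 * samples_hit / n_samples if n_samples else 0.0,
        "median_events_per_sample": float(per_sample.median()) if n_samples else 0.0,
        "events_at_z": {},
        "biotype_pct_genes_misexpressed": {},
    }
    for zt in z_grid:
        summary["events_at_z"][zt] = int((events["z"] > zt).sum()) if n_events else 0
    if biotypes:
        hit_genes = set(events["gene_id"]) if n_events else set()
        by_type: dict[str, list[int]] = {}
        for g in inactive_genes:
            bt = biotypes.get(g, "other")
            tot_hit = by_type.setdefault(bt, [0, 0])
            tot_hit[0] += 1
            tot_hit[1] += int(g in hit_genes)
        summary["biotype_pct_genes_misexpressed"] = {
            bt: 100.0 * hit / tot for bt, (tot, hit) in by_type.items()
        }
    return summary
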
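"""Model/Results facade over the misexpression pipeline.

``MisexpressionModel`` holds the cohort inputs (TPM matrix, covariates,
annotation, thresholds); ``fit()`` runs global-outlier removal,
inactive-gene identification, covariate filtering and Z-scoring, calls
misexpression events, and returns a ``MisexpressionResults`` carrying
the event table, QC report, prevalence summary and hooks for the
variant-enrichment and SV-association stages.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    AnalysisConfig,
    CovariateTable,
    ExpressionMatrix,
    GeneModel,
    SVCallset,
)
from . import expression as xp
from . import enrichment as en
from . import svassoc as sa
from . import io as mio


class MisexpressionModel:
    """Cohort misexpression model built from a TPM matrix.

    Parameters
    ----------
    tpm : ExpressionMatrix
        Gene x sample TPM matrix (``unit="TPM"``).
    covariates : CovariateTable, optional
        Sample covariates used to drop genes tracking non-genetic factors.
    genes : list of GeneModel, optional
        Annotation; required for variant enrichment and SV association.
    config : AnalysisConfig
        Thresholds; defaults follow the cohort analysis conventions.
    gene_whitelist : list of str, optional
        Restriction of the analysis universe (e.g. genes with evidence of
        expression in some tissue); applied before inactive-gene calling.
    """

    def __init__(
        self,
        tpm: ExpressionMatrix,
        covariates: CovariateTable | None = None,
        genes: list[GeneModel] | None = None,
        config: AnalysisConfig | None = None,
        gene_whitelist: list[str] | None = None,
    ) -> None:
        if tpm.unit != "TPM":
            raise ValueError("model requires a TPM matrix; run counts_to_tpm first")
        self.tpm = tpm
        self.covariates = covariates
        self.genes = genes
        self.genes_by_id = {g.gene_id: g for g in genes} if genes else {}
        self.config = config or AnalysisConfig()
        self.gene_whitelist = gene_whitelist

    @classmethod
    def from_files(
        cls,
        tpm_path: str | Path,
        covariates_path: str | Path | None = None,
        annotation_path: str | Path | None = None,
        config: AnalysisConfig | None = None,
    ) -> "MisexpressionModel":
        tpm = mio.read_expression_matrix(tpm_path, unit="TPM", subset=True)
        cov = mio.read_covariate_table(covariates_path) if covariates_path else None
        genes = mio.read_gene_annotation(annotation_path) if annotation_path else None
        return cls(tpm, cov, genes, config)

    def fit(self) -> "MisexpressionResults":
        cfg = self.config
        tpm, qc = xp.remove_global_outliers(self.tpm, fold=cfg.outlier_fold)
        universe = tpm
        if self.gene_whitelist is not None:
            universe = tpm.restrict_genes(self.gene_whitelist)
        inactive, expressed_frac = xp.identify_inactive_genes(
            universe, cfg.inactive_tpm, cfg.inactive_frac
        )
        qc.inactive_fraction = expressed_frac
        inactive_tpm = tpm.restrict_genes(inactive)
        if self.covariates is not None and len(inactive):
            removed, retained = xp.filter_covariate_correlated(
                inactive_tpm, self.covariates, cfg.cov_rho, cfg.cov_alpha
            )
            qc.removed_genes = removed
            inactive = retained
            inactive_tpm = tpm.restrict_genes(inactive)
        z, zero_var = xp.gene_zscores(inactive_tpm)
        events = xp.call_misexpression(inactive_tpm, z, cfg.misexp_z, cfg.misexp_tpm)
        biotypes = {g.gene_id: g.biotype for g in (self.genes or [])}
        prevalence = xp.summarize_prevalence(
            events, inactive, tpm.sample_ids, biotypes or None
        )
        median_tpm = tpm.values.median(axis=1)
        return MisexpressionResults(
            model=self,
            tpm=tpm,
            inactive_genes=inactive,
            z=z,
            zero_variance=zero_var,
            events=events,
            qc=qc,
            prevalence=prevalence,
            median_tpm=median_tpm,
        )


@dataclass
class MisexpressionResults:
    """Fit results: events, QC, prevalence, and downstream stage entry points."""

    model: MisexpressionModel
    tpm: ExpressionMatrix          # post-QC TPM (all genes)
    inactive_genes: list[str]
    z: pd.DataFrame                # inactive genes x samples
    zero_variance: pd.Series
    events: pd.DataFrame           # gene_id, sample_id, tpm, z
    qc: xp.QCReport
    prevalence: dict
    median_tpm: pd.Series
    _associations: list[sa.SVAssociation] | None = field(default=None, repr=False)

    def summary(self) -> str:
        p = self.prevalence
        lines = [
            "Misexpression cohort summary",
            "============================",
            f"samples (post-QC):          {len(self.tpm.sample_ids)}"
            f"  (removed {len(self.qc.removed_samples)} global outliers)",
            f"inactive genes:             {len(self.inactive_genes)}"
            f"  (removed {len(self.qc.removed_genes)} covariate-correlated)",
            f"misexpression events:       {p['n_events']}"
            f"  (Z > {self.events.attrs.get('z_thr', 2)},"
            f" TPM > {self.events.attrs.get('tpm_thr', 0.5)})",
            f"gene-sample pairs:          {p['n_pairs']}",
            f"% pairs misexpressed:       {p['pct_pairs_misexpressed']:.4f}",
            f"% genes misexpressed:       {p['pct_genes_misexpressed']:.1f}",
            f"% samples with an event:    {p['pct_samples_misexpressed']:.1f}",
            f"median events per sample:   {p['median_events_per_sample']:.1f}",
        ]
        return "\n".join(lines)

    # -- downstream stages -------------------------------------------------

    def enrichment_scan(
        self,
        callsets: dict[str, SVCallset],
        z_grid: tuple[float, ...] = (2, 10, 15),
        flank_bp: int | None = None,
        maf_bins: tuple[str, ...] = ("rare",),
        by_window: bool = False,
    ) -> pd.DataFrame:
        if not self.model.genes_by_id:
            raise ValueError("annotation required for enrichment")
        cfg = self.model.config
        return en.run_enrichment_scan(
            self.tpm,
            self.z,
            self.inactive_genes,
            callsets,
            z_grid=z_grid,
            tpm_thr=cfg.misexp_tpm,
            flank_bp=flank_bp if flank_bp is not None else cfg.gene_flank_bp,
            maf_bins=maf_bins,
            by_window=by_window,
            window_bp=cfg.sv_window_bp,
            max_bp=cfg.max_window_bp,
            genes_by_id=self.model.genes_by_id,
        )

    def associate_svs(self, svs: SVCallset) -> list[sa.SVAssociation]:
        """Misexpression-associated rare SVs around ever-misexpressed genes."""
        cfg = self.model.config
        rare = svs.rare(cfg.rare_maf)
        hit_genes = sorted(set(self.events["gene_id"]))
        self._associations = sa.identify_associated_svs(
            rare,
            hit_genes,
            self.model.genes_by_id,
            self.tpm,
            self.z,
            window_bp=cfg.sv_window_bp,
            median_tpm_thr=cfg.misexp_tpm,
            median_z_thr=cfg.misexp_z,
            carrier_tpm_floor=cfg.inactive_tpm,
        )
        return self._associations

    def control_svs(self, svs: SVCallset) -> list[str]:
        cfg = self.model.config
        return sa.identify_control_svs(
            svs.rare(cfg.rare_maf),
            self.inactive_genes,
            self.model.genes_by_id,
            self.tpm,
            window_bp=cfg.sv_window_bp,
            scope=cfg.control_scope,
        )

    def median_tpm_map(self) -> dict[str, float]:
        return self.median_tpm.to_dict()
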
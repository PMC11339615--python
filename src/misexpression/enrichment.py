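"""Rare-variant enrichment around misexpression events.

Misexpression and control groups are built over an identical gene set so
risk ratios reflect genetic differences rather than gene composition:
for a threshold pair (z_thr, tpm_thr) the misexpression group holds all
qualifying (gene, sample) expression events and the control group all
remaining (gene, sample) pairs of the same genes. Enrichment is the risk
ratio of carrying a qualifying variant near the gene, with a two-sided
Fisher exact p-value and a Wald confidence interval on the log scale.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, GeneModel, SVCallset, SVRecord

# Ensembl VEP consequence terms ordered from most to least severe.
VEP_SEVERITY_ORDER: tuple[str, ...] = (
    "transcript_ablation",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "frameshift_variant",
    "stop_lost",
    "start_lost",
    "transcript_amplification",
    "feature_elongation",
    "feature_truncation",
    "inframe_insertion",
    "inframe_deletion",
    "missense_variant",
    "protein_altering_variant",
    "splice_donor_5th_base_variant",
    "splice_region_variant",
    "splice_donor_region_variant",
    "splice_polypyrimidine_tract_variant",
    "incomplete_terminal_codon_variant",
    "start_retained_variant",
    "stop_retained_variant",
    "synonymous_variant",
    "coding_sequence_variant",
    "mature_miRNA_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "non_coding_transcript_exon_variant",
    "intron_variant",
    "NMD_transcript_variant",
    "non_coding_transcript_variant",
    "coding_transcript_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "TFBS_ablation",
    "TFBS_amplification",
    "TF_binding_site_variant",
    "regulatory_region_ablation",
    "regulatory_region_amplification",
    "regulatory_region_variant",
    "intergenic_variant",
    "sequence_variant",
)
_SEVERITY_RANK = {term: i for i, term in enumerate(VEP_SEVERITY_ORDER)}

# Fallback labels usable when a variant has no predicted consequence on
# the tested gene but its overall most severe consequence is regulatory
# or intergenic.
REGULATORY_FALLBACK: frozenset[str] = frozenset(
    {
        "TFBS_ablation",
        "TF_binding_site_variant",
        "regulatory_region_variant",
        "TFBS_amplification",
        "intergenic_variant",
        "regulatory_region_ablation",
        "regulatory_region_amplification",
    }
)

NO_PREDICTED_EFFECT = "no predicted effect"

MAF_BINS = ("rare", "low", "common5", "common10")


def maf_bin(maf: float) -> str:
    """Half-open MAF bins: rare [0,1%), low [1%,5%), common5 [5%,10%), common10 [10%,50%]."""
    if not 0.0 <= maf <= 0.5:
        raise ValueError(f"MAF must be in [0, 0.5], got {maf}")
    if maf < 0.01:
        return "rare"
    if maf < 0.05:
        return "low"
    if maf < 0.10:
        return "common5"
    return "common10"


@dataclass
class EnrichmentGroups:
    """Misexpression and control (gene, sample) pairs over a shared gene set."""

    misexp: set[tuple[str, str]]
    control: set[tuple[str, str]]
    genes: list[str]
    samples: list[str]
    z_thr: float
    tpm_thr: float

    @property
    def n1(self) -> int:
        return len(self.misexp)

    @property
    def n2(self) -> int:
        return len(self.control)


def build_groups(
    tpm: ExpressionMatrix,
    z: pd.DataFrame,
    inactive_genes: list[str],
    z_thr: float,
    tpm_thr: float = 0.5,
) -> EnrichmentGroups:
    """Construct event groups at a threshold; genes with no event are excluded."""
    genes = [g for g in inactive_genes if g in z.index]
    expr = tpm.values.loc[genes, z.columns]
    zz = z.loc[genes]
    mask = (expr.to_numpy() > tpm_thr) & (zz.to_numpy() > z_thr)
    hit_genes = np.asarray(genes)[mask.any(axis=1)]
    if hit_genes.size == 0:
        raise ValueError("no misexpression events at this threshold; no test possible")
    samples = list(z.columns)
    misexp: set[tuple[str, str]] = set()
    control: set[tuple[str, str]] = set()
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in hit_genes:
        row = mask[gene_pos[g]]
        for j, s in enumerate(samples):
            (misexp if row[j] else control).add((g, s))
    return EnrichmentGroups(misexp, control, list(hit_genes), samples, z_thr, tpm_thr)


@dataclass
class RiskRatioResult:
    a: int
    n1: int
    c: int
    n2: int
    rr: float
    ci_low: float
    ci_high: float
    p: float
    p_adj: float | None = None
    label: dict = field(default_factory=dict)


def risk_ratio_test(a: int, n1: int, c: int, n2: int) -> RiskRatioResult:
    """Risk ratio (a/n1)/(c/n2) with Wald CI and two-sided Fisher p.

    The Wald CI uses exp(ln rr +/- 1.96 * sqrt(1/a - 1/n1 + 1/c - 1/n2));
    when a or c is zero a 0.5 continuity term is added to all four cells
    for the point-free CI only (the Fisher p is unchanged).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= a <= n1 and 0 <= c <= n2):
        raise ValueError("cell counts outside margins")
    rr = (a / n1) / (c / n2) if c > 0 else math.inf if a > 0 else math.nan
    if a == 0 or c == 0:
        # 0.5 added to all four table cells, so margins grow by 1
        aa, cc = a + 0.5, c + 0.5
        nn1, nn2 = n1 + 1.0, n2 + 1.0
    else:
        aa, cc, nn1, nn2 = a, c, n1, n2
    se = math.sqrt(1 / aa - 1 / nn1 + 1 / cc - 1 / nn2)
    center = math.log((aa / nn1) / (cc / nn2))
    ci_low = math.exp(center - 1.96 * se)
    ci_high = math.exp(center + 1.96 * se)
    _, p = stats.fisher_exact([[a, n1 - a], [c, n2 - c]], alternative="two-sided")
    return RiskRatioResult(a, n1, c, n2, rr, ci_low, ci_high, float(p))


def fisher_exact_oracle(a: int, n1: int, c: int, n2: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration over fixed margins.

    Sums the probabilities of all tables (with row totals n1, n2 and the
    observed variant-carrier total) whose probability does not exceed the
    observed table's. Independent of scipy's implementation; used as the
    enumeration oracle in tests.
    """
    k = a + c  # carrier-column margin
    lo, hi = max(0, k - n2), min(n1, k)
    logpmf = {x: _log_hypergeom_pmf(x, n1, n2, k) for x in range(lo, hi + 1)}
    obs = logpmf[a]
    eps = 1e-9
    total = sum(math.exp(lp) for lp in logpmf.values() if lp <= obs + eps)
    return min(1.0, total)


def _log_hypergeom_pmf(x: int, n1: int, n2: int, k: int) -> float:
    return (
        math.lgamma(n1 + 1)
        - math.lgamma(x + 1)
        - math.lgamma(n1 - x + 1)
        + math.lgamma(n2 + 1)
        - math.lgamma(k - x + 1)
        - math.lgamma(n2 - k + x + 1)
        - (
            math.lgamma(n1 + n2 + 1)
            - math.lgamma(k + 1)
            - math.lgamma(n1 + n2 - k + 1)
        )
    )


# ---------------------------------------------------------------------------
# Window assignment

WINDOW_LABELS = (
    ["gene_body"]
    + [f"up_{k}" for k in range(1, 6)]
    + [f"down_{k}" for k in range(1, 6)]
)


def assign_window(
    gene: GeneModel,
    variant: SVRecord,
    window_bp: int = 200_000,
    max_bp: int = 1_000_000,
) -> str | None:
    """Assign a variant to the gene-body or a strand-aware distance window.

    Overlapping variants go to ``gene_body``. Otherwise the variant's
    gene-nearest edge defines its gap d, and it falls in window
    k = ceil(d / window_bp) (k=1 when the gap is zero but there is no
    overlap) on the upstream (5' of the TSS) or downstream side. Variants
    wholly beyond ``max_bp`` get None.
    """
    giv, viv = gene.interval, variant.interval
    if giv.chrom != viv.chrom:
        return None
    if giv.overlaps(viv):
        return "gene_body"
    d = giv.distance(viv)
    if d > max_bp:
        return None
    k = max(1, math.ceil(d / window_bp))
    left = viv.end <= giv.start
    upstream = left if gene.strand != "-" else not left
    return f"up_{k}" if upstream else f"down_{k}"


# ---------------------------------------------------------------------------
# Enrichment scan


def _variants_near_gene(
    gene: GeneModel, callset: SVCallset, flank: int
) -> list[SVRecord]:
    giv = gene.interval
    out = []
    for r in callset:
        if r.interval.chrom != giv.chrom:
            continue
        if r.interval.distance(giv) <= flank:
            out.append(r)
    return out


def run_enrichment_scan(
    tpm: ExpressionMatrix,
    z: pd.DataFrame,
    inactive_genes: list[str],
    callsets: dict[str, SVCallset],
    z_grid: tuple[float, ...] = (2, 10, 15),
    tpm_thr: float = 0.5,
    flank_bp: int = 10_000,
    maf_bins: tuple[str, ...] = ("rare",),
    by_window: bool = False,
    window_bp: int = 200_000,
    max_bp: int = 1_000_000,
    genes_by_id: dict[str, GeneModel] | None = None,
) -> pd.DataFrame:
    """Risk-ratio scan over variant classes, MAF bins and Z thresholds.

    An event (gene, sample) "has a variant" iff the sample carries at
    least one variant of the tested class and MAF bin within the tested
    region of that gene (gene +/- flank, or a specific distance window
    when ``by_window``). Bonferroni correction spans every test executed
    in the scan.
    """
    if genes_by_id is None:
        raise ValueError("genes_by_id annotation map is required")
    if flank_bp <= 0:
        raise ValueError("flank must be positive")
    import warnings

    rows = []
    regions = WINDOW_LABELS if by_window else ["flank"]
    for z_thr in z_grid:
        try:
            groups = build_groups(tpm, z, inactive_genes, z_thr, tpm_thr)
        except ValueError:
            warnings.warn(f"no events at Z > {z_thr}; threshold skipped in scan")
            continue
        for cls_name, callset in callsets.items():
            for bin_name in maf_bins:
                sub = callset.subset(lambda r: maf_bin(r.maf) == bin_name)
                # per gene, map region -> set of samples carrying a qualifying variant
                carrier_map: dict[str, dict[str, set[str]]] = {}
                for g in groups.genes:
                    gene = genes_by_id[g]
                    per_region: dict[str, set[str]] = {}
                    if by_window:
                        for r in sub:
                            if r.interval.chrom != gene.interval.chrom:
                                continue
                            label = assign_window(gene, r, window_bp, max_bp)
                            if label is not None:
                                per_region.setdefault(label, set()).update(r.carriers)
                    else:
                        near = _variants_near_gene(gene, sub, flank_bp)
                        carriers: set[str] = set()
                        for r in near:
                            carriers |= r.carriers
                        per_region["flank"] = carriers
                    carrier_map[g] = per_region
                for region in regions:
                    a = sum(
                        1
                        for (g, s) in groups.misexp
                        if s in carrier_map[g].get(region, ())
                    )
                    c = sum(
                        1
                        for (g, s) in groups.control
                        if s in carrier_map[g].get(region, ())
                    )
                    res = risk_ratio_test(a, groups.n1, c, groups.n2)
                    rows.append(
                        {
                            "class": cls_name,
                            "maf_bin": bin_name,
                            "region": region,
                            "z_thr": z_thr,
                            "a": res.a,
                            "n1": res.n1,
                            "c": res.c,
                            "n2": res.n2,
                            "rr": res.rr,
                            "ci_low": res.ci_low,
                            "ci_high": res.ci_high,
                            "p": res.p,
                        }
                    )
    scan = pd.DataFrame(rows)
    scan["p_adj"] = np.minimum(scan["p"] * len(scan), 1.0)
    scan.attrs["n_tests"] = len(scan)
    return scan


# ---------------------------------------------------------------------------
# Consequence annotation


def most_severe(terms: list[str]) -> str:
    for t in terms:
        if t not in _SEVERITY_RANK:
            raise ValueError(f"unknown VEP consequence term {t!r}")
    return min(terms, key=_SEVERITY_RANK.__getitem__)


def annotate_most_severe_consequence(sv: SVRecord, gene_id: str) -> str:
    """Most severe consequence on the gene, with regulatory/intergenic fallback.

    When a variant has no predicted consequence on the tested gene, its
    overall most severe consequence is used only if regulatory or
    intergenic; otherwise the variant is labelled "no predicted effect".
    """
    if sv.consequences is None:
        raise ValueError(f"SV {sv.sv_id} carries no consequence annotations")
    gene_terms = sv.consequences.get(gene_id)
    if gene_terms:
        return most_severe(list(gene_terms))
    all_terms = [t for terms in sv.consequences.values() for t in terms]
    if all_terms:
        overall = most_severe(all_terms)
        if overall in REGULATORY_FALLBACK:
            return overall
    return NO_PREDICTED_EFFECT


# ---------------------------------------------------------------------------
# Logistic feature enrichment


@dataclass
class LogisticEnrichmentResult:
    feature: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    p_adj: float | None = None
    converged: bool = True
    n_excluded_missing: int = 0
    covariates: tuple[str, ...] = ()


def _fit_single_logit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Logit fit returning (params, bse, converged); separation flagged."""
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    try:
        with warnings_catcher() as caught:
            model = sm.Logit(y, X)
            fit = model.fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", False)) and not caught["separation"]
        if np.abs(fit.params).max() > 50 or not np.isfinite(fit.bse).all():
            converged = False
        return np.asarray(fit.params), np.asarray(fit.bse), converged
    except (PerfectSeparationError, np.linalg.LinAlgError):
        k = X.shape[1]
        return np.full(k, np.nan), np.full(k, np.nan), False


class warnings_catcher:
    """Context manager flagging separation/convergence warnings from statsmodels."""

    def __enter__(self):
        import warnings as _w

        self._cm = _w.catch_warnings(record=True)
        self._records = self._cm.__enter__()
        import warnings as _w2

        _w2.simplefilter("always")
        self.flags = {"separation": False}
        return self.flags

    def __exit__(self, *exc):
        for rec in self._records:
            msg = str(rec.message).lower()
            if "separation" in msg or "convergence" in msg or "converge" in msg:
                self.flags["separation"] = True
        return self._cm.__exit__(*exc)


def zscore_transform(x: np.ndarray) -> np.ndarray:
    """Standardise a feature to mean 0 / sd 1 over its non-missing values."""
    x = np.asarray(x, dtype=float)
    m = np.nanmean(x)
    s = np.nanstd(x, ddof=1)
    if s == 0 or not np.isfinite(s):
        return np.zeros_like(x)
    return (x - m) / s


def gene_feature_enrichment(
    features: pd.DataFrame,
    misexpressed: pd.Series,
    extra_covariates: pd.DataFrame | None = None,
) -> list[LogisticEnrichmentResult]:
    """Single-feature logistic enrichment of gene (or SV) level features.

    Each feature is Z-transformed over the analysis set and modelled
    independently: logit(P(misexpressed)) = b0 + b1 * feature (+ extra
    covariates, themselves Z-transformed). 95% CIs use beta +/- 1.96*se;
    Bonferroni correction spans the features tested. Rows with missing
    feature values are excluded listwise with the count reported.
    """
    import statsmodels.api as sm

    y_all = misexpressed.astype(int)
    if y_all.nunique() < 2 or min((y_all == 0).sum(), (y_all == 1).sum()) < 2:
        raise ValueError("need >= 2 observations per outcome class")
    results: list[LogisticEnrichmentResult] = []
    for feat in features.columns:
        x = features[feat].to_numpy(dtype=float)
        keep = np.isfinite(x)
        cov_arrs = []
        cov_names: tuple[str, ...] = ()
        if extra_covariates is not None:
            cov_names = tuple(extra_covariates.columns)
            for c in extra_covariates.columns:
                cv = extra_covariates[c].to_numpy(dtype=float)
                keep &= np.isfinite(cv)
                cov_arrs.append(cv)
        n_excl = int((~keep).sum())
        xs = zscore_transform(x[keep])
        cols = [xs] + [zscore_transform(cv[keep]) for cv in cov_arrs]
        X = sm.add_constant(np.column_stack(cols))
        y = y_all.to_numpy()[keep]
        params, bse, converged = _fit_single_logit(y, X)
        beta, se = float(params[1]), float(bse[1])
        results.append(
            LogisticEnrichmentResult(
                feature=feat,
                beta=beta,
                se=se,
                ci_low=beta - 1.96 * se,
                ci_high=beta + 1.96 * se,
                p=float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else float("nan"),
                converged=converged,
                n_excluded_missing=n_excl,
                covariates=cov_names,
            )
        )
    m = len(results)
    for r in results:
        r.p_adj = min(1.0, r.p * m) if np.isfinite(r.p) else float("nan")
    return results


def enrichment_results_frame(results: list[LogisticEnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "beta": r.beta,
                "se": r.se,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "p_adj": r.p_adj,
                "converged": r.converged,
                "n_excluded_missing": r.n_excluded_missing,
            }
            for r in results
        ]
    )
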
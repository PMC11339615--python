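"""Quantification, QC gates, Z-scoring and misexpression calling."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from misexpression.core import CovariateTable, ExpressionMatrix
from misexpression import expression as xp


def _mat(values, genes=None, samples=None, unit="counts", subset=True):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), unit=unit, subset=subset
    )


# ---------------------------------------------------------------------------
# counts -> TPM


def test_single_gene_tpm_is_one_million():
    tpm = xp.counts_to_tpm(_mat([[7.0]]), {"g0": 500})
    assert tpm.values.iloc[0, 0] == pytest.approx(1e6)


def test_tpm_closed_form_two_genes():
    tpm = xp.counts_to_tpm(_mat([[10.0], [10.0]]), {"g0": 1000, "g1": 2000})
    assert tpm.values["s0"].tolist() == pytest.approx([666666.6667, 333333.3333], rel=1e-6)


def test_tpm_zero_length_gene_errors():
    with pytest.raises(ValueError, match="length"):
        xp.counts_to_tpm(_mat([[1.0]]), {"g0": 0})


def test_tpm_all_zero_column_warns():
    with pytest.warns(UserWarning, match="all-zero"):
        tpm = xp.counts_to_tpm(_mat([[0.0, 5.0]]), {"g0": 100})
    assert tpm.values["s0"].sum() == 0


@settings(max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_tpm_columns_sum_to_one_million(seed):
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 500, size=(50, 20)).astype(float)
    counts[:, 0] += 1  # ensure at least one nonzero column
    lengths = {f"g{i}": int(rng.integers(200, 5000)) for i in range(50)}
    tpm = xp.counts_to_tpm(_mat(counts), lengths)
    sums = tpm.values.sum(axis=0).to_numpy()
    nonzero = counts.sum(axis=0) > 0
    assert np.allclose(sums[nonzero], 1e6, rtol=1e-9)


# ---------------------------------------------------------------------------
# top expression events and global outliers


def test_top_events_single_sample_dominates():
    m = _mat([[1, 5], [2, 6], [0, 3]])
    counts = xp.count_top_expression_events(m)
    assert counts.tolist() == [0, 3]


def test_top_events_tie_counts_both_samples():
    m = _mat([[4, 4, 1]])
    counts = xp.count_top_expression_events(m)
    assert counts.tolist() == [1, 1, 0]


def test_cohort_scale_outlier_cutoff():
    """At 57,555 nonzero genes and 4,731 samples the removal cutoff is
    60.83 events, so retained samples can have at most 60 top events."""
    cutoff = xp.outlier_cutoff(57_555, 4_731, fold=5.0)
    assert 60 < cutoff < 61
    max_retained = int(np.ceil(cutoff)) - 1
    assert max_retained == 60


def test_remove_global_outliers_constructed():
    rng = np.random.default_rng(0)
    values = rng.uniform(0.5, 2.0, size=(2000, 100))
    values[:1000, 7] = 10.0  # sample 7 is max in 50% of genes; cutoff is 100
    m = _mat(values, unit="TPM")
    kept, report = xp.remove_global_outliers(m, fold=5.0)
    assert report.removed_samples["sample_id"].tolist() == ["s7"]
    assert "s7" not in kept.sample_ids


def test_remove_global_outliers_null_keeps_everyone():
    for seed in range(20):
        rng = np.random.default_rng(seed)
        m = _mat(rng.uniform(0.1, 1.0, size=(400, 50)), unit="TPM")
        _, report = xp.remove_global_outliers(m, fold=5.0)
        assert len(report.removed_samples) == 0


def test_remove_global_outliers_infinite_fold_is_identity():
    m = _mat(np.random.default_rng(1).uniform(size=(30, 10)), unit="TPM")
    kept, report = xp.remove_global_outliers(m, fold=np.inf)
    assert kept.sample_ids == m.sample_ids
    assert len(report.removed_samples) == 0


# ---------------------------------------------------------------------------
# inactive genes


def test_inactive_gene_boundaries():
    n = 100
    values = np.zeros((3, n))
    values[1, :5] = 0.2     # exactly 5.0% of samples above 0.1 -> NOT inactive
    values[2, :] = 0.100    # never strictly above 0.1 -> inactive
    m = _mat(values, unit="TPM")
    inactive, frac = xp.identify_inactive_genes(m, tpm_thr=0.1, frac=0.05)
    assert "g0" in inactive          # all-zero gene
    assert "g1" not in inactive      # strict "< 5%"
    assert "g2" in inactive          # strict "> 0.1"
    assert frac["g1"] == pytest.approx(0.05)


def test_inactive_call_invariant_to_sample_order():
    rng = np.random.default_rng(3)
    values = rng.uniform(0, 0.3, size=(50, 40))
    m = _mat(values, unit="TPM")
    inactive, _ = xp.identify_inactive_genes(m)
    perm = rng.permutation(m.sample_ids).tolist()
    m2 = ExpressionMatrix(m.values[perm], "TPM", subset=True)
    inactive2, _ = xp.identify_inactive_genes(m2)
    assert inactive == inactive2


# ---------------------------------------------------------------------------
# covariate filtering


def test_covariate_identical_gene_removed():
    rng = np.random.default_rng(0)
    n = 50
    cov = rng.normal(size=n)
    expr = np.vstack([cov - cov.min() + 0.01, rng.uniform(0, 0.1, size=n)])
    m = _mat(expr, unit="TPM")
    covs = CovariateTable(pd.DataFrame({"c0": cov}, index=m.sample_ids))
    removed, retained = xp.filter_covariate_correlated(m, covs)
    assert removed["gene_id"].tolist() == ["g0"]
    assert removed["rho"].iloc[0] == pytest.approx(1.0)
    assert retained == ["g1"]


def test_covariate_null_removal_rate_low():
    """Independent genes and covariates: BH-FDR keeps removals rare."""
    rates = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        m = _mat(rng.uniform(0, 0.5, size=(200, 300)), unit="TPM")
        covs = CovariateTable(
            pd.DataFrame(rng.normal(size=(300, 20)), index=m.sample_ids)
        )
        removed, _ = xp.filter_covariate_correlated(m, covs)
        rates.append(len(removed) / 200)
    assert np.mean(rates) <= 0.02


def test_covariate_weak_correlation_not_significant_retained():
    """|rho| above threshold alone is insufficient without significance."""
    rng = np.random.default_rng(7)
    n = 12
    cov = np.arange(n, dtype=float)
    noise = rng.normal(size=n) * 10
    gene = cov * 0.3 + noise  # weak monotone association at tiny n
    m = _mat([np.abs(gene) / 100], unit="TPM")
    covs = CovariateTable(pd.DataFrame({"c0": cov}, index=m.sample_ids))
    removed, retained = xp.filter_covariate_correlated(m, covs)
    assert retained == ["g0"]


def test_constant_covariate_skipped_with_warning():
    rng = np.random.default_rng(1)
    m = _mat(rng.uniform(0, 0.1, size=(5, 20)), unit="TPM")
    covs = CovariateTable(
        pd.DataFrame({"flat": np.ones(20), "ok": rng.normal(size=20)}, index=m.sample_ids)
    )
    with pytest.warns(UserWarning, match="constant covariate"):
        xp.filter_covariate_correlated(m, covs)


# ---------------------------------------------------------------------------
# Z-scores


def test_zscore_closed_form():
    m = _mat([[0, 0, 0, 10]], unit="TPM")
    z, undefined = xp.gene_zscores(m)
    # mean 2.5, sample sd (ddof=1) = 5 -> z of the outlier = 1.5
    assert z.iloc[0, 3] == pytest.approx(1.5)
    assert not undefined.any()


def test_zscore_constant_gene_undefined():
    m = _mat([[3, 3, 3, 3]], unit="TPM")
    z, undefined = xp.gene_zscores(m)
    assert undefined["g0"]
    assert z.loc["g0"].isna().all()
    events = xp.call_misexpression(m, z)
    assert len(events) == 0  # undefined Z never callable


@settings(max_examples=20, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_zscore_mean_zero_sd_one(seed):
    rng = np.random.default_rng(seed)
    m = _mat(rng.uniform(0, 5, size=(30, 25)), unit="TPM")
    z, undefined = xp.gene_zscores(m)
    ok = z[~undefined]
    assert np.allclose(ok.mean(axis=1), 0, atol=1e-9)
    assert np.allclose(ok.std(axis=1, ddof=1), 1, atol=1e-9)


# ---------------------------------------------------------------------------
# misexpression calling


@pytest.mark.parametrize(
    "tpm_val, z_val, is_event",
    [(0.6, 2.5, True), (0.6, 1.9, False), (0.4, 50.0, False), (0.5, 3.0, False)],
)
def test_misexpression_gate_semantics(tpm_val, z_val, is_event):
    m = _mat([[0.0] * 9 + [tpm_val]], unit="TPM")
    z = pd.DataFrame([[0.0] * 9 + [z_val]], index=m.gene_ids, columns=m.sample_ids)
    events = xp.call_misexpression(m, z, z_thr=2.0, tpm_thr=0.5)
    assert (len(events) == 1) == is_event


def test_event_sets_nested_over_thresholds(fitted):
    tpm = fitted.tpm.restrict_genes(fitted.inactive_genes)
    sets = []
    for z_thr in (2, 10, 40):
        ev = xp.call_misexpression(tpm, fitted.z, z_thr=z_thr)
        sets.append(set(zip(ev.gene_id, ev.sample_id)))
    assert sets[2] <= sets[1] <= sets[0]


# ---------------------------------------------------------------------------
# prevalence summaries


def _paper_scale_events():
    """A deterministic event table with the cohort-scale margins:
    28,956 events over 4,437 genes and 4,386 samples."""
    n_ev, n_g, n_s = 28_956, 4_437, 4_386
    genes = [f"g{i % n_g}" for i in range(n_ev)]
    samples = [f"s{i % n_s}" for i in range(n_ev)]
    return pd.DataFrame(
        {"gene_id": genes, "sample_id": samples, "tpm": 1.0, "z": 3.0}
    )


def test_prevalence_cohort_scale_percentages():
    events = _paper_scale_events()
    inactive = [f"g{i}" for i in range(8_650)]
    samples = [f"s{i}" for i in range(4_568)]
    biotypes = {}
    for i in range(8_650):
        if i < 1_070 or 4_437 <= i < 4_437 + 2_022:
            biotypes[f"g{i}"] = "protein_coding"
        else:
            biotypes[f"g{i}"] = "lncRNA"
    s = xp.summarize_prevalence(events, inactive, samples, biotypes)
    assert s["n_pairs"] == 39_513_200
    assert round(s["pct_pairs_misexpressed"], 2) == 0.07
    assert round(s["pct_genes_misexpressed"]) == 51
    assert round(s["pct_samples_misexpressed"]) == 96
    # 1,070 of 3,092 inactive protein-coding genes misexpressed
    assert round(s["biotype_pct_genes_misexpressed"]["protein_coding"], 1) == 34.6


def test_prevalence_zero_events():
    empty = pd.DataFrame(columns=["gene_id", "sample_id", "tpm", "z"])
    s = xp.summarize_prevalence(empty, ["g0", "g1"], ["s0", "s1"])
    assert s["pct_pairs_misexpressed"] == 0
    assert s["median_events_per_sample"] == 0
    assert all(v == 0 for v in s["events_at_z"].values())
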
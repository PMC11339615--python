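"""Readthrough candidate selection, coverage metrics, 3D candidates."""
import numpy as np
import pandas as pd
import pytest

from misexpression.core import (
    FragmentAlignmentTable,
    GeneModel,
    GenomicInterval,
    SVRecord,
)
from misexpression.model import MisexpressionModel
from misexpression.simulate import SimulationConfig, simulate_readthrough_locus
from misexpression import mechanisms as mech
from misexpression.svassoc import SVAssociation


def _assoc(sv, gene_id):
    return SVAssociation(
        sv_id=sv.sv_id, gene_id=gene_id, svclass=sv.svclass,
        carriers=sv.carriers, median_tpm=5.0, median_z=10.0,
        min_carrier_tpm=5.0, position="upstream",
    )


def _locus_inputs(kind, strand="+", seed=0):
    loc = simulate_readthrough_locus(SimulationConfig(seed=seed, n_samples=50), kind, strand)
    genes_by_id = {loc.donor.gene_id: loc.donor, loc.misexpressed.gene_id: loc.misexpressed}
    med = {loc.donor.gene_id: 20.0, loc.misexpressed.gene_id: 0.0}
    assoc = [_assoc(loc.sv, loc.misexpressed.gene_id)]
    svs = {loc.sv.sv_id: loc.sv}
    return loc, assoc, svs, genes_by_id, med


# ---------------------------------------------------------------------------
# deletion selection criteria


@pytest.mark.parametrize("strand", ["+", "-"])
def test_del_locus_selected(strand):
    loc, assoc, svs, genes, med = _locus_inputs("DEL", strand)
    out = mech.select_readthrough_deletions(assoc, svs, genes, loc.polya_sites, med)
    assert [c.sv_id for c in out] == [loc.sv.sv_id]
    assert out[0].donor_gene_id == loc.donor.gene_id
    assert out[0].region == loc.region


def test_del_rejected_without_polya_overlap():
    loc, assoc, svs, genes, med = _locus_inputs("DEL")
    moved = loc.polya_sites.copy()
    moved["start"] += 1_000_000
    moved["end"] += 1_000_000
    out = mech.select_readthrough_deletions(assoc, svs, genes, moved, med)
    assert out == []


def test_del_rejected_with_expressed_gene_in_intervening_region():
    loc, assoc, svs, genes, med = _locus_inputs("DEL")
    mid = (loc.region.start + loc.region.end) // 2
    blocker = GeneModel(
        "BLK", GenomicInterval(loc.region.chrom, mid - 200, mid + 200, loc.misexpressed.strand)
    )
    genes["BLK"] = blocker
    med["BLK"] = 10.0
    out = mech.select_readthrough_deletions(assoc, svs, genes, loc.polya_sites, med)
    assert out == []
    # same gene on the opposite strand does not block
    genes["BLK"] = GeneModel(
        "BLK", GenomicInterval(loc.region.chrom, mid - 200, mid + 200,
                               "-" if loc.misexpressed.strand == "+" else "+")
    )
    out = mech.select_readthrough_deletions(assoc, svs, genes, loc.polya_sites, med)
    assert len(out) == 1


def test_del_rejected_when_donor_not_expressed():
    loc, assoc, svs, genes, med = _locus_inputs("DEL")
    med[loc.donor.gene_id] = 0.1
    out = mech.select_readthrough_deletions(assoc, svs, genes, loc.polya_sites, med)
    assert out == []


def test_del_rejected_when_overlapping_misexpressed_gene():
    loc, assoc, svs, genes, med = _locus_inputs("DEL")
    giv = loc.misexpressed.interval
    overlapping = SVRecord(
        loc.sv.sv_id, GenomicInterval(giv.chrom, giv.start - 500, giv.start + 100),
        "DEL", loc.sv.maf, loc.sv.carriers,
    )
    svs[loc.sv.sv_id] = overlapping
    out = mech.select_readthrough_deletions(assoc, svs, genes, loc.polya_sites, med)
    assert out == []


def test_del_multiple_genes_keeps_closest():
    loc, assoc, svs, genes, med = _locus_inputs("DEL")
    far_iv = (
        GenomicInterval(loc.region.chrom, loc.misexpressed.interval.end + 50_000,
                        loc.misexpressed.interval.end + 52_000, loc.misexpressed.strand)
    )
    genes["FAR"] = GeneModel("FAR", far_iv)
    assoc.append(_assoc(loc.sv, "FAR"))
    out = mech.select_readthrough_deletions(assoc, svs, genes, loc.polya_sites, med)
    assert [c.misexpressed_gene_id for c in out] == [loc.misexpressed.gene_id]


# ---------------------------------------------------------------------------
# duplication selection criteria


@pytest.mark.parametrize("strand", ["+", "-"])
def test_dup_locus_selected(strand):
    loc, assoc, svs, genes, med = _locus_inputs("DUP", strand)
    out = mech.select_readthrough_duplications(assoc, svs, genes, med)
    assert [c.sv_id for c in out] == [loc.sv.sv_id]
    assert out[0].region == loc.region


def test_dup_rejected_when_gene_only_half_covered():
    loc, assoc, svs, genes, med = _locus_inputs("DUP")
    giv = loc.misexpressed.interval
    mid = (giv.start + giv.end) // 2
    if loc.sv.interval.start < giv.start:
        partial_iv = GenomicInterval(giv.chrom, max(0, loc.sv.interval.start), mid)
    else:
        partial_iv = GenomicInterval(giv.chrom, mid, loc.sv.interval.end)
    svs[loc.sv.sv_id] = SVRecord(loc.sv.sv_id, partial_iv, "DUP", loc.sv.maf, loc.sv.carriers)
    out = mech.select_readthrough_duplications(assoc, svs, genes, med)
    assert out == []


def test_dup_rejected_when_donor_fully_covered():
    """Covering both donor termini is not a partial 5' overlap."""
    loc, assoc, svs, genes, med = _locus_inputs("DUP")
    span = GenomicInterval(
        loc.sv.interval.chrom,
        min(loc.sv.interval.start, loc.donor.interval.start - 100),
        max(loc.sv.interval.end, loc.donor.interval.end + 100),
    )
    svs[loc.sv.sv_id] = SVRecord(loc.sv.sv_id, span, "DUP", loc.sv.maf, loc.sv.carriers)
    out = mech.select_readthrough_duplications(assoc, svs, genes, med)
    assert out == []


def test_dup_multiple_genes_keeps_shortest_region():
    loc, assoc, svs, genes, med = _locus_inputs("DUP")
    # a second misexpressed gene inside the duplication, further from the
    # 5' breakpoint -> longer expected readthrough region
    giv = loc.misexpressed.interval
    if loc.misexpressed.strand == "+":
        other_iv = GenomicInterval(giv.chrom, giv.start + 700, giv.end, "+")
    else:
        other_iv = GenomicInterval(giv.chrom, giv.start, giv.end - 700, "-")
    genes["OTH"] = GeneModel("OTH", other_iv)
    assoc.append(_assoc(loc.sv, "OTH"))
    out = mech.select_readthrough_duplications(assoc, svs, genes, med)
    assert [c.misexpressed_gene_id for c in out] == [loc.misexpressed.gene_id]


# ---------------------------------------------------------------------------
# readthrough region geometry


def test_region_construction_plus_strand():
    gene = GeneModel("g", GenomicInterval("chr1", 1_000_000, 1_002_000, "+"))
    sv = SVRecord("v", GenomicInterval("chr1", 980_000, 985_000), "DEL", 0.001)
    region = mech.readthrough_region(gene, sv)
    assert (region.start, region.end) == (985_000, 1_000_000)
    assert region.length == 15_000


def test_region_construction_minus_strand_mirror():
    gene = GeneModel("g", GenomicInterval("chr1", 1_000_000, 1_002_000, "-"))
    sv = SVRecord("v", GenomicInterval("chr1", 1_017_000, 1_022_000), "DEL", 0.001)
    region = mech.readthrough_region(gene, sv)
    assert (region.start, region.end) == (1_002_000, 1_017_000)
    assert region.length == 15_000


def test_region_errors_when_breakpoint_wrong_side():
    gene = GeneModel("g", GenomicInterval("chr1", 1_000, 2_000, "+"))
    sv = SVRecord("v", GenomicInterval("chr1", 3_000, 4_000), "DEL", 0.001)
    with pytest.raises(ValueError, match="5'"):
        mech.readthrough_region(gene, sv)


# ---------------------------------------------------------------------------
# FPKM / FBNC


def _fragments(rows, depths):
    return FragmentAlignmentTable(
        pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "strand"]),
        depths,
    )


def test_fpkm_formula():
    region = GenomicInterval("chr1", 0, 2_000, "+")
    rows = [("s0", "chr1", i * 100, i * 100 + 50, "+") for i in range(4)]
    frags = _fragments(rows, {"s0": 10_000_000, "s1": 10_000_000})
    m = mech.compute_fpkm_fbnc(region, frags)
    assert m.table.loc["s0", "fpkm"] == pytest.approx(4 / (2 * 10))
    assert m.table.loc["s1", "fpkm"] == 0.0


def test_fbnc_formula():
    region = GenomicInterval("chr1", 0, 2_000, "+")
    rows = [("s0", "chr1", 0, 500, "+")]
    frags = _fragments(rows, {"s0": 1_000_000, "s1": 1_000_000})
    m = mech.compute_fpkm_fbnc(region, frags)
    assert m.table.loc["s0", "fbnc"] == pytest.approx(0.25)


def test_opposite_strand_fragments_ignored():
    region = GenomicInterval("chr1", 0, 2_000, "+")
    rows = [("s0", "chr1", 0, 2_000, "-")]
    m = mech.compute_fpkm_fbnc(region, _fragments(rows, {"s0": 1_000_000}))
    assert m.table.loc["s0", "count"] == 0
    assert m.table.loc["s0", "fbnc"] == 0.0


def test_fbnc_monotone_fpkm_increasing_as_fragments_added():
    region = GenomicInterval("chr1", 0, 1_000, "+")
    rows = []
    prev_fbnc, prev_fpkm = -1.0, -1.0
    for i in range(5):
        rows.append(("s0", "chr1", i * 150, i * 150 + 100, "+"))
        m = mech.compute_fpkm_fbnc(region, _fragments(list(rows), {"s0": 1_000_000}))
        fbnc = m.table.loc["s0", "fbnc"]
        fpkm = m.table.loc["s0", "fpkm"]
        assert fbnc >= prev_fbnc
        assert fpkm > prev_fpkm
        prev_fbnc, prev_fpkm = fbnc, fpkm


def test_classify_readthrough_gate():
    region = GenomicInterval("chr1", 0, 1_000, "+")
    table = pd.DataFrame(
        {"count": 0, "fpkm": 0.0, "fbnc": 0.0,
         "fpkm_z": [3.0, 3.0] + [0.0] * 10, "fbnc_z": [3.0, 1.0] + [0.0] * 10},
        index=[f"s{i}" for i in range(12)],
    )
    calls = mech.classify_readthrough(mech.ReadthroughMetrics(region, table))
    assert calls.tolist() == [True, False] + [False] * 10


def test_classify_requires_min_samples():
    region = GenomicInterval("chr1", 0, 1_000, "+")
    table = pd.DataFrame(
        {"count": 0, "fpkm": 0.0, "fbnc": 0.0, "fpkm_z": [3.0], "fbnc_z": [3.0]},
        index=["s0"],
    )
    with pytest.raises(ValueError, match=">= 10"):
        mech.classify_readthrough(mech.ReadthroughMetrics(region, table))


def test_readthrough_invariant_to_noncarrier_relabeling():
    loc = simulate_readthrough_locus(SimulationConfig(seed=2, n_samples=40), "DEL")
    depths = {f"S{i:04d}": 10_000_000 for i in range(40)}
    frags = FragmentAlignmentTable(loc.fragments, depths)
    m = mech.compute_fpkm_fbnc(loc.region, frags)
    calls = mech.classify_readthrough(m)
    # permute non-carrier labels in the fragment table: carrier calls unchanged
    noncarriers = [s for s in depths if s not in loc.carriers]
    perm = dict(zip(noncarriers, np.random.default_rng(0).permutation(noncarriers)))
    perm.update({s: s for s in loc.carriers})
    frag2 = loc.fragments.assign(sample_id=loc.fragments["sample_id"].map(perm))
    m2 = mech.compute_fpkm_fbnc(loc.region, FragmentAlignmentTable(frag2, depths))
    calls2 = mech.classify_readthrough(m2)
    assert calls.loc[sorted(loc.carriers)].equals(calls2.loc[sorted(loc.carriers)])
    assert calls.sum() == calls2.sum()


# ---------------------------------------------------------------------------
# 3D candidates


def _track(chrom, start, end, value=None):
    d = {"chrom": [chrom], "start": [start], "end": [end]}
    if value is not None:
        d["value"] = [value]
    return pd.DataFrame(d)


def test_3d_deletion_rules():
    gene = GeneModel("g", GenomicInterval("chr1", 100_000, 102_000, "+"))
    sv = SVRecord("v", GenomicInterval("chr1", 50_000, 60_000), "DEL", 0.001)
    assoc = [_assoc(sv, "g")]
    tad = _track("chr1", 55_000, 56_000)
    ctcf = _track("chr1", 52_000, 52_500)
    hmm = _track("chr1", 58_000, 59_000, "Enh")
    out = mech.select_3d_candidates(assoc, {"v": sv}, {"g": gene}, tad, ctcf, hmm)
    assert out == [("v", "g")]
    # deletion overlapping the gene is rejected
    sv2 = SVRecord("v", GenomicInterval("chr1", 99_000, 101_000), "DEL", 0.001)
    out = mech.select_3d_candidates(
        [_assoc(sv2, "g")], {"v": sv2}, {"g": gene},
        _track("chr1", 99_500, 99_600), _track("chr1", 99_700, 99_800), hmm,
    )
    assert out == []


def test_3d_duplication_rules():
    gene = GeneModel("g", GenomicInterval("chr1", 100_000, 102_000, "+"))
    tad = _track("chr1", 95_000, 96_000)
    ctcf = _track("chr1", 97_000, 97_500)
    hmm = _track("chr1", 99_000, 99_500, "Enh")
    full = SVRecord("v", GenomicInterval("chr1", 90_000, 110_000), "DUP", 0.001)
    out = mech.select_3d_candidates([_assoc(full, "g")], {"v": full}, {"g": gene}, tad, ctcf, hmm)
    assert out == [("v", "g")]
    half = SVRecord("v", GenomicInterval("chr1", 90_000, 101_000), "DUP", 0.001)
    out = mech.select_3d_candidates([_assoc(half, "g")], {"v": half}, {"g": gene}, tad, ctcf, hmm)
    assert out == []


def test_3d_missing_track_errors():
    with pytest.raises(ValueError, match="tad_boundaries"):
        mech.select_3d_candidates([], {}, {}, None, _track("chr1", 0, 1), _track("chr1", 0, 1))


# ---------------------------------------------------------------------------
# transcript fractions and mechanism summary


def test_transcript_fractions():
    assert mech.transcript_fractions({"t1": 3.0, "t2": 1.0}) == {"t1": 0.75, "t2": 0.25}
    assert mech.transcript_fractions({"t1": 7.0}) == {"t1": 1.0}
    assert mech.transcript_fractions({"t1": 0.0}) is None
    # invariant to global rescaling
    a = mech.transcript_fractions({"t1": 3.0, "t2": 1.0})
    b = mech.transcript_fractions({"t1": 300.0, "t2": 100.0})
    assert a == pytest.approx(b)


def test_summarize_mechanisms_partition_and_precedence():
    sv = SVRecord("v", GenomicInterval("chr1", 0, 100), "DEL", 0.001)
    assocs = [_assoc(sv, f"g{i}") for i in range(4)]
    rt = [mech.ReadthroughCandidate("v", "g0", "d", GenomicInterval("chr1", 0, 10), "DEL")]
    fus = pd.DataFrame({"sv_id": ["v", "v"], "gene_id": ["g0", "g1"]})
    table = mech.summarize_mechanisms(
        assocs, readthrough_candidates=rt, fusion_table=fus,
        threed_candidates=[("v", "g2")],
    )
    by_gene = dict(zip(table["gene_id"], table["mechanism"]))
    assert by_gene == {
        "g0": "readthrough",   # readthrough beats fusion
        "g1": "fusion",
        "g2": "3d_candidate",
        "g3": "unknown",
    }
    assert len(table) == len(assocs)  # counts partition the association set


def test_summarize_mechanisms_no_inputs_all_unknown():
    sv = SVRecord("v", GenomicInterval("chr1", 0, 100), "DEL", 0.001)
    table = mech.summarize_mechanisms([_assoc(sv, "g0")])
    assert table["mechanism"].tolist() == ["unknown"]
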
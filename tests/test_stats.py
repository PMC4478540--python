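"""Downstream statistics: SNP-type classification, Ts/Tv tables, call
statistics, homozygous-difference matrix, diversity, spacing, overlap."""

import math

import numpy as np
import pytest

from _oracles import pi_pairwise
from bessnp import datasets
from bessnp.collate import MasterRecord, MasterSnpTable
from bessnp.stats import (
    adjacent_spacing,
    callstats_percent,
    classify_snp_type,
    nucleotide_diversity,
    pairwise_hom_diff,
    sample_callstats,
    site_pi,
    species_overlap,
    tstv_summary,
    tstv_table,
)
from bessnp.vcfio import FinalVcf


def _final(samples, codes, het=None):
    codes = np.array(codes, dtype=np.int8)
    het = (
        np.array(het, dtype=bool)
        if het is not None
        else np.zeros(codes.shape, dtype=bool)
    )
    records = [("f", j, "A", ["G"]) for j in range(codes.shape[1])]
    return FinalVcf(samples=samples, records=records, codes=codes, het=het)


@pytest.mark.parametrize(
    "ref,alt,cls,kind",
    [
        ("A", "G", "R", "transition"),
        ("G", "A", "R", "transition"),
        ("C", "T", "Y", "transition"),
        ("C", "G", "S", "transversion"),
        ("A", "C", "M", "transversion"),
        ("A", "T", "W", "transversion"),
        ("G", "T", "K", "transversion"),
    ],
)
def test_classify_snp_type(ref, alt, cls, kind):
    assert classify_snp_type(ref, alt) == (cls, kind)


def test_classify_rejects_bad_alleles():
    with pytest.raises(ValueError):
        classify_snp_type("A", "A")
    with pytest.raises(ValueError):
        classify_snp_type("A", "N")


def test_published_counts_reproduce_ratios_and_percentages():
    """Recomputing from the published per-class counts reproduces the
    printed Ts/Tv ratios and percentages exactly."""
    table = tstv_summary(datasets.snp_type_counts())
    assert table.loc["hirsutum", "tstv_ratio"] == 2.19
    assert table.loc["barbadense", "tstv_ratio"] == 2.21
    assert table.loc["longicalyx", "tstv_ratio"] == 1.63
    assert table.loc["hirsutum", "transition_pct"] == 68.7
    assert table.loc["longicalyx", "transition_pct"] == 61.9
    assert table.loc["overall", "transversion_pct"] == 35.2
    assert int(table.loc["overall", "total"]) == 770_194
    # conservation: class counts sum to transitions + transversions
    for tier in table.index:
        row = table.loc[tier]
        assert row[["M", "R", "W", "S", "Y", "K"]].sum() == row["total"]
        assert row["transitions"] + row["transversions"] == row["total"]


def test_tstv_from_toy_master_hand_counted():
    records = [
        MasterRecord("f", 1, "A", ["G"], "hirsutum"),  # R, ts
        MasterRecord("f", 5, "C", ["T"], "hirsutum"),  # Y, ts
        MasterRecord("f", 9, "C", ["G"], "hirsutum"),  # S, tv
        MasterRecord("f", 12, "A", ["C", "T"], "barbadense"),  # M + W, 2 tv
    ]
    table = tstv_table(MasterSnpTable(records=records))
    assert table.loc["hirsutum", "transitions"] == 2
    assert table.loc["hirsutum", "transversions"] == 1
    assert table.loc["hirsutum", "tstv_ratio"] == 2.0
    assert table.loc["barbadense", "total"] == 2  # decomposed pairs
    first_alt = tstv_table(MasterSnpTable(records=records), decompose_multiallelic=False)
    assert first_alt.loc["barbadense", "total"] == 1


def test_all_transition_ratio_is_nan():
    records = [MasterRecord("f", 1, "A", ["G"], "hirsutum")]
    table = tstv_table(MasterSnpTable(records=records))
    assert math.isnan(table.loc["hirsutum", "tstv_ratio"])


def test_published_missingness_percentage():
    df = datasets.final_callstats()
    tm1 = df[df["sample"] == "TM-1"].iloc[0]
    assert callstats_percent(int(tm1.missing_n), 770_194) == 0.28


def test_sample_callstats_recount():
    final = _final(
        ["s1", "s2"],
        [[0, 1, -1, 2], [-1, -1, -1, -1]],
        het=[[False, True, False, False], [False] * 4],
    )
    table = sample_callstats(final)
    assert table.loc["s1", "missing_n"] == 1
    assert table.loc["s1", "het_n"] == 1
    assert table.loc["s1", "missing_pct"] == 25.0
    assert table.loc["s2", "missing_pct"] == 100.0
    assert table.loc["s2", "het_n"] == 0


def test_pairwise_hom_diff_hand_counted():
    # sites: s1 vs s2 differ hom at site0 (0 vs 2); site1 het excluded;
    # site2 missing excluded; site3 equal hom
    final = _final(
        ["s1", "s2", "s3"],
        [[0, 1, -1, 2], [2, 0, 0, 2], [2, 0, 0, 0]],
        het=[[False, True, False, False], [False] * 4, [False] * 4],
    )
    m = pairwise_hom_diff(final)
    assert m.loc["s1", "s2"] == 1
    assert m.loc["s1", "s3"] == 2
    assert m.loc["s2", "s3"] == 1
    assert (m.values == m.values.T).all()
    assert (np.diag(m.values) == 0).all()


def test_hom_diff_bounded_by_callable_hom_sites():
    rng = np.random.default_rng(40)
    codes = rng.choice([-1, 0, 1, 2], size=(4, 60))
    het = codes == 1
    final = _final([f"s{i}" for i in range(4)], codes, het=het)
    m = pairwise_hom_diff(final)
    hom_counts = ((codes >= 0) & ~het).sum(axis=1)
    for i in range(4):
        for j in range(4):
            assert m.iloc[i, j] <= min(hom_counts[i], hom_counts[j])


def test_site_pi_closed_form():
    # two alleles at p = 0.5 from n = 10 alleles: (10/9) * 0.5
    col = np.array([2, 2, 0, 0, 1])  # 5 genotypes -> 10 alleles, 5 alt
    assert site_pi(col) == pytest.approx(10 / 9 * 0.5)
    assert site_pi(np.array([0, 0, 0])) == 0.0
    assert math.isnan(site_pi(np.array([-1, -1])))


def test_site_pi_equals_pairwise_oracle():
    rng = np.random.default_rng(41)
    for _ in range(25):
        col = rng.choice([-1, 0, 1, 2], size=rng.integers(2, 12))
        ours = site_pi(col)
        oracle = pi_pairwise(col)
        if math.isnan(ours):
            assert math.isnan(oracle)
        else:
            assert ours == pytest.approx(oracle)


def test_nucleotide_diversity_mean_over_polymorphic():
    final = _final(["a", "b", "c"], [[0, 0, 2], [0, 2, 2], [0, 1, 2]])
    mean, per_site = nucleotide_diversity(final)
    assert per_site[0] == 0.0  # monomorphic
    assert math.isnan(mean) is False
    poly = [p for p in per_site if p > 0]
    assert mean == pytest.approx(np.mean(poly))
    # site 2 is monomorphic alt: pi 0
    assert per_site[2] == 0.0


def test_nucleotide_diversity_no_polymorphism_is_nan():
    final = _final(["a", "b"], [[0, 0], [0, 0]])
    mean, _ = nucleotide_diversity(final)
    assert math.isnan(mean)


def test_adjacent_spacing_hand_computed():
    records = [
        MasterRecord("f1", 100, "A", ["G"], "hirsutum"),
        MasterRecord("f1", 176, "A", ["G"], "hirsutum"),
        MasterRecord("f1", 200, "A", ["G"], "barbadense"),
        MasterRecord("f2", 10, "A", ["G"], "hirsutum"),  # single SNP: no distance
    ]
    master = MasterSnpTable(records=records)
    out = adjacent_spacing(master, tier="hirsutum")
    assert out["distances"].tolist() == [76]
    assert out["mean"] == 76.0
    all_tiers = adjacent_spacing(master)
    assert sorted(all_tiers["distances"].tolist()) == [24, 76]
    assert all_tiers["mean"] == pytest.approx(50.0)


def test_species_overlap_partition():
    a = {("f", 1), ("f", 2), ("f", 3)}
    b = {("f", 2), ("f", 3), ("f", 4)}
    c = {("f", 3), ("f", 5)}
    out = species_overlap({"h": a, "b": b, "l": c})
    assert out["100"] == 1  # only in a
    assert out["110"] == 1  # a and b
    assert out["111"] == 1
    assert out["001"] == 1
    assert out["010"] == 1
    assert sum(out.values()) == len(a | b | c)
    disjoint = species_overlap({"h": {("f", 1)}, "b": {("f", 2)}, "l": {("f", 3)}})
    assert disjoint["110"] == disjoint["111"] == 0
    identical = species_overlap({"h": a, "b": set(a), "l": set(a)})
    assert identical["111"] == len(a)
    assert sum(v for k, v in identical.items() if k != "111") == 0
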
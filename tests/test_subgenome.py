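"""Flank export, subgenome classification, and genic interval overlap."""

import numpy as np
import pytest

from bessnp.collate import MasterRecord, MasterSnpTable
from bessnp.simdata import SimConfig, generate_reference, revcomp, spike_variants
from bessnp.subgenome import (
    FlankParams,
    classify_subgenome,
    export_flanks,
    genic_overlap,
    read_bed,
)
from bessnp.simdata import BesReference


def _rand(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _master_single(pos, ref, alt, frag="f"):
    return MasterSnpTable(records=[MasterRecord(frag, pos, ref, [alt], "hirsutum")])


def test_flank_centered_101mer_with_iupac_code():
    rng = np.random.default_rng(50)
    seq = list(_rand(rng, 300))
    seq[150] = "A"
    seq = "".join(seq)
    ref = BesReference(fragments={"f": seq})
    flanks = export_flanks(_master_single(150, "A", "G"), ref)
    (f,) = flanks
    assert len(f.sequence) == 101 and f.offset == 50
    assert f.sequence[50] == "R"  # A/G ambiguity
    assert f.sequence[:50] == seq[100:150]
    assert f.sequence[51:] == seq[151:201]


def test_flank_truncated_near_fragment_start():
    rng = np.random.default_rng(51)
    seq = list(_rand(rng, 300))
    seq[20] = "C"
    seq = "".join(seq)
    ref = BesReference(fragments={"f": seq})
    (f,) = export_flanks(_master_single(20, "C", "T"), ref)
    assert len(f.sequence) == 71 and f.offset == 20
    assert f.sequence[20] == "Y"


def test_flank_position_off_fragment_rejected():
    ref = BesReference(fragments={"f": "ACGT" * 30})
    with pytest.raises(ValueError):
        export_flanks(_master_single(500, "A", "G"), ref)


def test_classification_basic_cases():
    rng = np.random.default_rng(52)
    a_chunk = _rand(rng, 101)
    shared = _rand(rng, 101)
    frag = a_chunk + shared
    ref = BesReference(fragments={"f": frag})
    # SNP in the A-only region and one in the shared region
    master = MasterSnpTable(
        records=[
            MasterRecord("f", 50, a_chunk[50], _other(a_chunk[50]), "hirsutum"),
            MasterRecord("f", 151, shared[50], _other(shared[50]), "hirsutum"),
        ]
    )
    flanks = export_flanks(master, ref)
    a_genome = {"A2": _rand(rng, 200) + a_chunk + shared + _rand(rng, 200)}
    d_genome = {"D5": _rand(rng, 200) + shared + _rand(rng, 200)}
    table, summary = classify_subgenome(flanks, a_genome, d_genome)
    assert table["class"].tolist() == ["A_specific", "both"]
    assert summary["A_specific"] == 0.5 and summary["both"] == 0.5


def _other(base):
    return [{"A": "G", "G": "A", "C": "T", "T": "C"}[base]]


def test_iupac_centre_matches_either_allele():
    """A flank whose centre is ref in one genome and alt in the other must
    place in both (the ambiguity base is not a mismatch in either)."""
    rng = np.random.default_rng(53)
    left, right = _rand(rng, 50), _rand(rng, 50)
    ref_seq = left + "A" + right
    alt_seq = left + "G" + right
    ref = BesReference(fragments={"f": ref_seq})
    flanks = export_flanks(_master_single(50, "A", "G"), ref)
    table, _ = classify_subgenome(
        flanks, {"A2": _rand(rng, 60) + ref_seq}, {"D5": alt_seq + _rand(rng, 60)}
    )
    assert table["class"].tolist() == ["both"]


def test_multiple_placements_within_one_genome_unplaced():
    rng = np.random.default_rng(54)
    left, right = _rand(rng, 50), _rand(rng, 50)
    seq = left + "A" + right
    ref = BesReference(fragments={"f": seq})
    flanks = export_flanks(_master_single(50, "A", "G"), ref)
    a_genome = {"A2": seq + _rand(rng, 30) + seq}  # duplicated locus
    table, _ = classify_subgenome(flanks, a_genome, {"D5": _rand(rng, 300)})
    assert table["class"].tolist() == ["unplaced"]


def test_reverse_strand_placement_found():
    rng = np.random.default_rng(55)
    seq = _rand(rng, 101)
    ref = BesReference(fragments={"f": seq})
    flanks = export_flanks(
        MasterSnpTable(
            records=[MasterRecord("f", 50, seq[50], _other(seq[50]), "hirsutum")]
        ),
        ref,
    )
    a_genome = {"A2": _rand(rng, 40) + revcomp(seq) + _rand(rng, 40)}
    table, _ = classify_subgenome(flanks, a_genome, {"D5": _rand(rng, 300)})
    assert table["class"].tolist() == ["A_specific"]


def test_raising_similarity_never_places_more():
    rng = np.random.default_rng(56)
    master_records = []
    seq = _rand(rng, 600)
    ref = BesReference(fragments={"f": seq})
    for pos in range(60, 540, 60):
        master_records.append(
            MasterRecord("f", pos, seq[pos], _other(seq[pos]), "hirsutum")
        )
    flanks = export_flanks(MasterSnpTable(records=master_records), ref)
    # diverged copies of the fragment as the two genomes
    def mutate(s, rate, rng):
        out = list(s)
        for i in range(len(out)):
            if rng.random() < rate:
                out[i] = _other(out[i])[0]
        return "".join(out)

    a_genome = {"A2": mutate(seq, 0.02, np.random.default_rng(1))}
    d_genome = {"D5": mutate(seq, 0.05, np.random.default_rng(2))}
    placed = {}
    for sim in (0.90, 0.96, 0.99):
        table, _ = classify_subgenome(
            flanks, a_genome, d_genome, FlankParams(similarity_fraction=sim)
        )
        placed[sim] = set(table[table["class"] != "unplaced"]["snp_id"])
    assert placed[0.99] <= placed[0.96] <= placed[0.90]


def test_simulated_d_origin_snps_classify_d_specific():
    """With strongly diverged subgenomes, SNPs on D-origin fragments place
    on the D diploid relative."""
    cfg = SimConfig(
        seed=57,
        ancestral_length=12_000,
        n_fragments=16,
        fragment_length_range=(300, 600),
        homeolog_divergence=0.15,
        n_lines=2,
        barbadense_rate=0.01,
    )
    bundle = generate_reference(cfg)
    spike_variants(bundle, cfg)
    records = {}
    for v in bundle.truth.variants:
        if bundle.truth.origin[v.fragment] == "D" and v.sample == "barb01":
            records[(v.fragment, v.pos)] = MasterRecord(
                v.fragment, v.pos, v.ref, [v.alt], "barbadense"
            )
    master = MasterSnpTable(records=list(records.values()))
    assert len(master) >= 10
    flanks = export_flanks(master, bundle.reference)
    table, _ = classify_subgenome(
        flanks, {"A2": bundle.a_genome}, {"D5": bundle.d_genome}
    )
    frac_d = (table["class"] == "D_specific").mean()
    assert frac_d >= 0.95


def test_genic_overlap_boundaries_and_counts(tmp_path):
    records = [
        MasterRecord("f", 10, "A", ["G"], "hirsutum"),  # inside
        MasterRecord("f", 20, "A", ["G"], "hirsutum"),  # at interval end: out
        MasterRecord("f", 5, "A", ["G"], "barbadense"),  # at start: in
        MasterRecord("f", 30, "A", ["G"], "longicalyx"),  # outside
    ]
    master = MasterSnpTable(records=records)
    intervals = {"f": [(5, 20)]}
    table = genic_overlap(master, intervals)
    assert table.loc["hirsutum", "genic_n"] == 1
    assert table.loc["hirsutum", "nongenic_n"] == 1
    assert table.loc["barbadense", "genic_n"] == 1
    assert table.loc["longicalyx", "genic_n"] == 0
    assert table.loc["total", "total"] == 4
    bed = tmp_path / "g.bed"
    bed.write_text("f\t5\t20\n")
    assert read_bed(bed) == intervals
    with pytest.raises(ValueError):
        genic_overlap(master, {"f": [(20, 5)]})
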
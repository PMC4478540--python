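"""Strict fraction-thresholded mapper: indexing, acceptance thresholds,
equivalence with the exhaustive DP oracle, and origin accuracy."""

import numpy as np
import pysam
import pytest

from _oracles import exhaustive_best_placement, rc
from bessnp.mapper import (
    MappingParams,
    align_read,
    align_sample,
    build_index,
)
from bessnp.simdata import (
    BesReference,
    SimConfig,
    generate_reference,
    simulate_reads,
    spike_variants,
)


def _ref(frags):
    return BesReference(fragments=frags)


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def test_index_seed_positions():
    index = build_index(_ref({"f": "A" * 100}), seed_size=20)
    total = sum(len(v) for v in index.kmers.values())
    assert total == 100 - 20 + 1


def test_index_duplicate_fragments_list_both():
    rng = np.random.default_rng(0)
    seq = _random_seq(rng, 60)
    index = build_index(_ref({"f1": seq, "f2": seq}), seed_size=15)
    hits = index.lookup(seq[:15])
    assert {frag for frag, _ in hits} == {"f1", "f2"}


def test_index_absent_kmer_empty():
    index = build_index(_ref({"f": "A" * 100}), seed_size=15)
    assert index.lookup("C" * 15) == []


def test_empty_reference_rejected():
    with pytest.raises(ValueError):
        build_index(_ref({}))


def test_exact_substring_is_perfect_alignment():
    rng = np.random.default_rng(1)
    seq = _random_seq(rng, 400)
    index = build_index(_ref({"f": seq}))
    aln = align_read("r", seq[120:207], index)
    assert aln is not None
    assert aln.start == 120 and aln.strand == "+"
    assert aln.length_fraction_obs == 1.0 and aln.similarity_obs == 1.0


def test_reverse_strand_read_found():
    rng = np.random.default_rng(2)
    seq = _random_seq(rng, 400)
    index = build_index(_ref({"f": seq}))
    aln = align_read("r", rc(seq[50:140]), index)
    assert aln is not None and aln.strand == "-" and aln.start == 50


def test_similarity_threshold_boundary():
    """A full-length 100-base alignment with 3 mismatches has similarity
    0.97: rejected at the tetraploid threshold 0.98, accepted at the
    diverged-diploid threshold 0.96."""
    rng = np.random.default_rng(3)
    seq = _random_seq(rng, 400)
    read = list(seq[100:200])
    for pos in (20, 50, 80):  # interior mismatches
        read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
    read = "".join(read)
    index = build_index(_ref({"f": seq}))
    strict = align_read("r", read, index, MappingParams(similarity_fraction=0.98))
    relaxed = align_read("r", read, index, MappingParams(similarity_fraction=0.96))
    assert strict is None
    assert relaxed is not None
    assert relaxed.similarity_obs == pytest.approx(0.97)
    assert relaxed.length_fraction_obs == 1.0


def test_read_shorter_than_seed_unmapped():
    index = build_index(_ref({"f": "ACGT" * 50}), seed_size=15)
    assert align_read("r", "ACGTACGTAC", index) is None


def test_agrees_with_exhaustive_dp_oracle():
    """Accepted placement and score equal a full-matrix DP evaluated at
    every offset of every fragment on both strands (50 reads x 10 small
    fragments, with substitutions and occasional indels)."""
    rng = np.random.default_rng(17)
    frags = {f"f{i}": _random_seq(rng, 120) for i in range(10)}
    index = build_index(_ref(frags))
    params = MappingParams(length_fraction=0.9, similarity_fraction=0.9)
    checked = 0
    for i in range(50):
        src = f"f{int(rng.integers(10))}"
        start = int(rng.integers(0, 60))
        read = list(frags[src][start : start + 60])
        for _ in range(int(rng.integers(0, 3))):  # up to 2 substitutions
            p = int(rng.integers(len(read)))
            read[p] = "ACGT"[int(rng.integers(4))]
        if rng.random() < 0.2:  # occasional 1-base deletion
            del read[int(rng.integers(len(read)))]
        read = "".join(read)
        if rng.random() < 0.5:
            read = rc(read)
        got = align_read(f"r{i}", read, index, params)
        best, loci = exhaustive_best_placement(
            read, frags, params.length_fraction, params.similarity_fraction
        )
        if got is None:
            assert not loci
            continue
        checked += 1
        assert got.score == best
        assert (got.score, got.fragment, got.strand, got.start) in loci
    assert checked >= 40  # the oracle comparison actually exercised mapping


def test_lowering_similarity_never_unmaps():
    rng = np.random.default_rng(5)
    frags = {f"f{i}": _random_seq(rng, 200) for i in range(4)}
    index = build_index(_ref(frags))
    for i in range(30):
        src = f"f{int(rng.integers(4))}"
        start = int(rng.integers(0, 120))
        read = list(frags[src][start : start + 70])
        for _ in range(int(rng.integers(0, 3))):
            p = int(rng.integers(len(read)))
            read[p] = "ACGT"[int(rng.integers(4))]
        read = "".join(read)
        strict = align_read("r", read, index, MappingParams(similarity_fraction=0.98))
        relaxed = align_read("r", read, index, MappingParams(similarity_fraction=0.90))
        if strict is not None:
            assert relaxed is not None


def test_multiread_policy_on_duplicate_fragments():
    rng = np.random.default_rng(6)
    seq = _random_seq(rng, 200)
    index = build_index(_ref({"f1": seq, "f2": seq}))
    read = seq[40:120]
    discarded = align_read("r", read, index, MappingParams(multiread_policy="discard"))
    assert discarded is None
    kept = align_read("r", read, index, MappingParams(multiread_policy="random"))
    assert kept is not None and kept.unique is False


def test_error_free_reads_map_to_source_fragment(tmp_path):
    """>=99% of error-free prepared reads drawn from fragment interiors
    map back to the fragment covering their source interval."""
    cfg = SimConfig(
        seed=31,
        ancestral_length=8000,
        n_fragments=12,
        fragment_length_range=(400, 600),
        coverage=8.0,
        base_error_rate=0.0,
        n_lines=2,
        homeolog_divergence=0.05,  # well-separated subgenomes
    )
    bundle = generate_reference(cfg)
    samples = spike_variants(bundle, cfg)
    r1, _r2 = simulate_reads(samples["hir01"], cfg, tmp_path / "s")
    index = build_index(bundle.reference)
    bam_path = tmp_path / "s.bam"
    # fragment interval lookup per subgenome
    by_origin = {
        "A": [], "D": [],
    }
    for name, (origin, start, end) in bundle.reference.intervals.items():
        by_origin[origin].append((start, end, name))
    n = correct = 0
    from Bio import SeqIO

    for rec in SeqIO.parse(str(r1), "fastq"):
        _s, hap, _i, start, _ins, _mate = rec.id.split(":")
        sub = hap[0]
        start = int(start)
        homes = [
            nm
            for s0, e0, nm in by_origin[sub]
            if s0 <= start and start + cfg.read_length <= e0
        ]
        if not homes:
            continue  # read not fully inside a same-subgenome fragment
        aln = align_read(rec.id, str(rec.seq), index)
        n += 1
        correct += aln is not None and aln.fragment == homes[0]
    assert n > 100
    assert correct / n >= 0.99


def test_align_sample_deterministic_and_sorted(tmp_path):
    rng = np.random.default_rng(8)
    frags = {f"f{i}": _random_seq(rng, 300) for i in range(3)}
    reference = _ref(frags)
    index = build_index(reference)
    fastq = tmp_path / "reads.fastq"
    with open(fastq, "w") as fh:
        for i in range(40):
            src = f"f{int(rng.integers(3))}"
            start = int(rng.integers(0, 200))
            seq = frags[src][start : start + 80]
            fh.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")
    t1 = align_sample(fastq, index, out_bam=tmp_path / "a.bam")
    t2 = align_sample(fastq, index, out_bam=tmp_path / "b.bam")
    assert t1 == t2 and t1["mapped"] == t1["input"]
    rows1 = [str(r) for r in pysam.AlignmentFile(str(tmp_path / "a.bam"))]
    rows2 = [str(r) for r in pysam.AlignmentFile(str(tmp_path / "b.bam"))]
    assert rows1 == rows2
    starts = [
        (r.reference_id, r.reference_start)
        for r in pysam.AlignmentFile(str(tmp_path / "a.bam"))
    ]
    assert starts == sorted(starts)


def test_align_sample_empty_fastq(tmp_path):
    reference = _ref({"f": "ACGT" * 60})
    index = build_index(reference)
    fastq = tmp_path / "empty.fastq"
    fastq.write_text("")
    tallies = align_sample(fastq, index, out_bam=tmp_path / "e.bam")
    assert tallies == {"input": 0, "mapped": 0}
    assert pysam.AlignmentFile(str(tmp_path / "e.bam")).count(until_eof=True) == 0
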
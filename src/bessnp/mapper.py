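"""Strict fraction-thresholded read alignment against the BES reference.

A placement is accepted only when BOTH the fraction of the read that aligns
(length fraction) and the identity within the aligned part (similarity
fraction) meet their thresholds. This is the stringency that makes
short-read mapping to an allotetraploid reference workable at all: at the
default 0.99/0.98 settings an ~87-bp prepared read tolerates roughly one
mismatch, so reads from the sister subgenome cross-map only where the
homeologs are nearly identical — the exact mechanism that creates
homeo-SNPs, which the caller later masks out.

Alignment is seed-and-extend: exact k-mer seeds locate candidate diagonals,
each candidate is scored with a banded local (free end-clipping) alignment,
and ties across distinct loci are resolved by the multiread policy. The
policy default keeps ambiguous homeologous reads (random placement) rather
than discarding them, because the downstream homeo-SNP correction exists to
handle exactly those reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam
from Bio import SeqIO

from .simdata import BesReference, revcomp, _open_text


@dataclass(frozen=True)
class MappingParams:
    length_fraction: float = 0.99
    similarity_fraction: float = 0.98
    seed_size: int = 15
    multiread_policy: str = "random"  # or "discard"
    rng_seed: int = 0
    match: int = 1
    mismatch: int = -2
    gap: int = -4  # linear per-base gap cost
    band: int = 10

    def validate(self) -> None:
        for name in ("length_fraction", "similarity_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} outside (0, 1]")
        if self.seed_size < 8:
            raise ValueError("seed_size must be >= 8")
        if self.multiread_policy not in ("random", "discard"):
            raise ValueError(f"unknown multiread_policy {self.multiread_policy!r}")


@dataclass
class Alignment:
    read_id: str
    fragment: str
    start: int  # 0-based reference start
    strand: str  # "+" or "-"
    score: int
    cigar: list[tuple[str, int]]  # ops over the *aligned-strand* read
    aligned_read_bases: int
    aligned_columns: int
    identities: int
    read_length: int
    unique: bool = True

    @property
    def length_fraction_obs(self) -> float:
        return self.aligned_read_bases / self.read_length

    @property
    def similarity_obs(self) -> float:
        return self.identities / self.aligned_columns if self.aligned_columns else 0.0


class ReferenceIndex:
    """Exact k-mer lookup over the forward strand of every fragment; the
    reverse strand is covered by querying the reverse complement of the
    read, which is equivalent and keeps the table half the size."""

    def __init__(self, reference: BesReference, seed_size: int = 15):
        if len(reference) == 0:
            raise ValueError("empty reference")
        self.reference = reference
        self.seed_size = seed_size
        self.names: list[str] = list(reference.fragments)
        self.seqs: dict[str, str] = dict(reference.fragments)
        self.kmers: dict[str, list[tuple[str, int]]] = {}
        k = seed_size
        for name, seq in self.seqs.items():
            for i in range(len(seq) - k + 1):
                self.kmers.setdefault(seq[i : i + k], []).append((name, i))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.kmers.get(kmer, [])


def build_index(reference: BesReference, seed_size: int = 15) -> ReferenceIndex:
    return ReferenceIndex(reference, seed_size)


# ---------------------------------------------------------------------------
# banded local alignment

def _banded_local(
    query: str, ref: str, d_lo: int, d_hi: int, params: MappingParams
) -> tuple[int, int, int, int, int, int, list[tuple[str, int]]] | None:
    """Banded Smith–Waterman of query against ref, restricted to diagonals
    (j - i) in [d_lo - band, d_hi + band]. Returns
    (score, qstart, qend, rstart, identities, aligned_columns, cigar-core)."""
    n, m = len(query), len(ref)
    band = params.band
    lo, hi = d_lo - band, d_hi + band
    H: list[dict[int, int]] = [dict() for _ in range(n + 1)]
    best = (0, 0, 0)
    match, mismatch, gap = params.match, params.mismatch, params.gap
    for i in range(1, n + 1):
        qc = query[i - 1]
        row = H[i]
        prev = H[i - 1]
        j_min = max(1, i + lo)
        j_max = min(m, i + hi)
        for j in range(j_min, j_max + 1):
            s = match if qc == ref[j - 1] else mismatch
            h = prev.get(j - 1, 0) + s
            up = prev.get(j, 0) + gap
            left = row.get(j - 1, 0) + gap
            v = max(0, h, up, left)
            if v:
                row[j] = v
                if v > best[0]:
                    best = (v, i, j)
    if best[0] == 0:
        return None
    score, i, j = best
    qend, rend = i, j
    identities = 0
    cigar_rev: list[str] = []
    while i > 0 and j > 0:
        v = H[i].get(j, 0)
        if v == 0:
            break
        qc = query[i - 1]
        s = match if qc == ref[j - 1] else mismatch
        if v == H[i - 1].get(j - 1, 0) + s:
            if qc == ref[j - 1]:
                identities += 1
            cigar_rev.append("M")
            i -= 1
            j -= 1
        elif v == H[i - 1].get(j, 0) + gap:
            cigar_rev.append("I")
            i -= 1
        else:
            cigar_rev.append("D")
            j -= 1
    qstart, rstart = i, j
    cigar: list[tuple[str, int]] = []
    for op in reversed(cigar_rev):
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    return score, qstart, qend, rstart, identities, len(cigar_rev), cigar


def _candidates(query: str, index: ReferenceIndex) -> dict[str, list[int]]:
    """Seed the query: fragment -> sorted distinct diagonals with hits."""
    k = index.seed_size
    diags: dict[str, set[int]] = {}
    for i in range(len(query) - k + 1):
        for frag, off in index.lookup(query[i : i + k]):
            diags.setdefault(frag, set()).add(off - i)
    return {frag: sorted(ds) for frag, ds in diags.items()}


def _cluster_diags(diags: list[int], band: int) -> list[tuple[int, int]]:
    clusters: list[tuple[int, int]] = []
    lo = hi = diags[0]
    for d in diags[1:]:
        if d - hi <= band:
            hi = d
        else:
            clusters.append((lo, hi))
            lo = hi = d
    clusters.append((lo, hi))
    return clusters


def _align_candidate(
    query: str, ref: str, d_lo: int, d_hi: int, params: MappingParams
) -> Alignment | None:
    n = len(query)
    # exact-placement fast path: provably optimal (score n*match is maximal)
    for d in range(d_lo, d_hi + 1):
        if 0 <= d and d + n <= len(ref) and ref[d : d + n] == query:
            return Alignment(
                read_id="",
                fragment="",
                start=d,
                strand="+",
                score=n * params.match,
                cigar=[("M", n)],
                aligned_read_bases=n,
                aligned_columns=n,
                identities=n,
                read_length=n,
            )
    result = _banded_local(query, ref, d_lo, d_hi, params)
    if result is None:
        return None
    score, qstart, qend, rstart, identities, columns, cigar_core = result
    cigar = []
    if qstart:
        cigar.append(("S", qstart))
    cigar.extend(cigar_core)
    if n - qend:
        cigar.append(("S", n - qend))
    return Alignment(
        read_id="",
        fragment="",
        start=rstart,
        strand="+",
        score=score,
        cigar=cigar,
        aligned_read_bases=qend - qstart,
        aligned_columns=columns,
        identities=identities,
        read_length=n,
    )


def align_read(
    read_id: str,
    seq: str,
    index: ReferenceIndex,
    params: MappingParams | None = None,
    rng: np.random.Generator | None = None,
) -> Alignment | None:
    """Best accepted placement of one read, or None if unmapped.

    Every seeded candidate locus (fragment, strand, diagonal cluster) is
    aligned; candidates failing the length or similarity fraction are
    rejected; the best surviving score wins, with ties across distinct loci
    resolved by the multiread policy.
    """
    params = params or MappingParams()
    params.validate()
    if len(seq) < index.seed_size:
        return None
    survivors: list[Alignment] = []
    for strand, query in (("+", seq), ("-", revcomp(seq))):
        for frag, diags in _candidates(query, index).items():
            ref = index.seqs[frag]
            for d_lo, d_hi in _cluster_diags(diags, params.band):
                aln = _align_candidate(query, ref, d_lo, d_hi, params)
                if aln is None:
                    continue
                aln.read_id = read_id
                aln.fragment = frag
                aln.strand = strand
                if (
                    aln.length_fraction_obs >= params.length_fraction
                    and aln.similarity_obs >= params.similarity_fraction
                ):
                    survivors.append(aln)
    if not survivors:
        return None
    best_score = max(a.score for a in survivors)
    best = [a for a in survivors if a.score == best_score]
    # distinct loci only: identical (fragment, strand, start) duplicates collapse
    seen: dict[tuple[str, str, int], Alignment] = {}
    for a in best:
        seen.setdefault((a.fragment, a.strand, a.start), a)
    loci = list(seen.values())
    if len(loci) == 1:
        return loci[0]
    if params.multiread_policy == "discard":
        return None
    rng = rng if rng is not None else np.random.default_rng(params.rng_seed)
    chosen = loci[int(rng.integers(len(loci)))]
    chosen.unique = False
    return chosen


# ---------------------------------------------------------------------------
# sample-level alignment to sorted, indexed BAM

def _sam_header(reference: BesReference) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": name, "LN": len(seq)}
                for name, seq in reference.fragments.items()
            ],
        }
    )


def align_sample(
    fastq_path: str | Path,
    index: ReferenceIndex,
    params: MappingParams | None = None,
    out_bam: str | Path = "sample.bam",
    keep_unmapped: bool = False,
) -> dict[str, int]:
    """Align every prepared read and write a coordinate-sorted, indexed BAM.

    Deterministic given params.rng_seed and the input read order.
    """
    params = params or MappingParams()
    params.validate()
    out_bam = Path(out_bam)
    rng = np.random.default_rng(params.rng_seed)
    tids = {name: i for i, name in enumerate(index.reference.fragments)}
    header = _sam_header(index.reference)
    tmp = out_bam.with_suffix(".unsorted.bam")
    n_in = n_mapped = 0
    with pysam.AlignmentFile(str(tmp), "wb", header=header) as bam:
        with _open_text(fastq_path, "r") as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                n_in += 1
                seq = str(rec.seq)
                quals = rec.letter_annotations["phred_quality"]
                aln = align_read(rec.id, seq, index, params, rng)
                a = pysam.AlignedSegment(header)
                a.query_name = rec.id
                if aln is None:
                    if not keep_unmapped:
                        continue
                    a.is_unmapped = True
                    a.query_sequence = seq
                    a.query_qualities = pysam.qualitystring_to_array(
                        "".join(chr(q + 33) for q in quals)
                    )
                    bam.write(a)
                    continue
                n_mapped += 1
                if aln.strand == "-":
                    seq = revcomp(seq)
                    quals = quals[::-1]
                    a.is_reverse = True
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in quals)
                )
                a.reference_id = tids[aln.fragment]
                a.reference_start = aln.start
                a.mapping_quality = 60 if aln.unique else 0
                a.cigarstring = "".join(f"{n}{op}" for op, n in aln.cigar)
                a.set_tag("AS", aln.score)
                bam.write(a)
    pysam.sort("-o", str(out_bam), str(tmp))
    tmp.unlink()
    pysam.index(str(out_bam))
    return {"input": n_in, "mapped": n_mapped}
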
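"""Subgenome assignment of markers and genic classification.

Each master SNP is exported as a 101-mer (50 bp of reference flank each
side, truncated at fragment ends) whose centre base is the IUPAC ambiguity
code of ref/alt. Flanks are aligned against the two diploid-relative
genomes (A-like and D-like); a marker placed uniquely in exactly one
genome is assigned to that subgenome. During identity computation the
ambiguity base counts as a match to either of its two alleles — otherwise
every flank would carry one guaranteed mismatch against both genomes.

Placement is gapless and full-length (length fraction 1.0), seeded by
exact k-mers, at a similarity threshold of 0.96 by default; ties across
the two genomes give class 'both', multiple placements within one genome
give 'unplaced'.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .collate import MasterSnpTable, TIERS
from .simdata import BesReference, revcomp, write_fasta
from .stats import IUPAC_CLASS

# IUPAC code -> allowed bases, for the centre column
_IUPAC_BASES = {code: pair for pair, code in IUPAC_CLASS.items()}

CLASSES = ("A_specific", "D_specific", "both", "unplaced")


@dataclass
class FlankRecord:
    snp_id: str
    sequence: str  # <=101 bases; centre base is the IUPAC code
    offset: int  # SNP position within the record
    tier: str = ""


@dataclass(frozen=True)
class FlankParams:
    similarity_fraction: float = 0.96
    seed_size: int = 15


def export_flanks(
    master: MasterSnpTable,
    reference: BesReference,
    flank: int = 50,
    fasta_path: str | Path | None = None,
) -> list[FlankRecord]:
    """Centre each SNP in a (2*flank + 1)-mer of reference sequence with
    the ref/alt ambiguity code at the SNP; truncate near fragment ends."""
    records: list[FlankRecord] = []
    for r in master.records:
        seq = reference.fragments[r.fragment]
        if not 0 <= r.pos < len(seq):
            raise ValueError(f"SNP position {r.key} outside fragment")
        start = max(0, r.pos - flank)
        end = min(len(seq), r.pos + flank + 1)
        code = IUPAC_CLASS[frozenset((r.ref, r.alts[0]))]
        offset = r.pos - start
        flank_seq = seq[start : r.pos] + code + seq[r.pos + 1 : end]
        records.append(
            FlankRecord(
                snp_id=f"{r.fragment}_{r.pos + 1}",
                sequence=flank_seq,
                offset=offset,
                tier=r.tier,
            )
        )
    if fasta_path is not None:
        write_fasta(fasta_path, ((f.snp_id, f.sequence) for f in records))
    return records


# ---------------------------------------------------------------------------
# gapless IUPAC-aware placement

class _GenomeIndex:
    def __init__(self, sequences: Mapping[str, str], seed_size: int):
        if not sequences or all(len(s) == 0 for s in sequences.values()):
            raise ValueError("empty reference genome")
        self.seqs = dict(sequences)
        self.k = seed_size
        self.kmers: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.seqs.items():
            for i in range(len(seq) - self.k + 1):
                self.kmers.setdefault(seq[i : i + self.k], []).append((name, i))


def _iupac_variants(flank: FlankRecord) -> tuple[str, str]:
    code = flank.sequence[flank.offset]
    a, b = sorted(_IUPAC_BASES.get(code, frozenset(code)))
    base = flank.sequence
    return (
        base[: flank.offset] + a + base[flank.offset + 1 :],
        base[: flank.offset] + b + base[flank.offset + 1 :],
    )


def _placements(
    flank: FlankRecord, index: _GenomeIndex, params: FlankParams
) -> set[tuple[str, str, int]]:
    """Accepted (chrom, strand, start) placements of a flank in one genome:
    full-length, gapless, centre counts as a match to either allele."""
    n = len(flank.sequence)
    max_mm = n - math.ceil(params.similarity_fraction * n)
    variants_fwd = _iupac_variants(flank)
    accepted: set[tuple[str, str, int]] = set()
    for strand in ("+", "-"):
        queries = (
            variants_fwd
            if strand == "+"
            else tuple(revcomp(q) for q in variants_fwd)
        )
        offsets: set[tuple[str, int]] = set()
        for q in queries:
            for i in range(0, n - index.k + 1):
                for chrom, off in index.kmers.get(q[i : i + index.k], []):
                    offsets.add((chrom, off - i))
        for chrom, start in offsets:
            seq = index.seqs[chrom]
            if start < 0 or start + n > len(seq):
                continue  # length fraction 1.0: must fit entirely
            window = seq[start : start + n]
            mm = min(
                sum(a != b for a, b in zip(window, q)) for q in queries
            )
            if mm <= max_mm:
                accepted.add((chrom, strand, start))
    return accepted


def classify_subgenome(
    flanks: Sequence[FlankRecord],
    a_genome: Mapping[str, str],
    d_genome: Mapping[str, str],
    params: FlankParams | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Classify each flank as A_specific / D_specific / both / unplaced.

    Returns the per-SNP table and the class-fraction summary."""
    params = params or FlankParams()
    a_index = _GenomeIndex(a_genome, params.seed_size)
    d_index = _GenomeIndex(d_genome, params.seed_size)
    rows = []
    for f in flanks:
        in_a = _placements(f, a_index, params)
        in_d = _placements(f, d_index, params)
        if len(in_a) > 1 or len(in_d) > 1:
            cls = "unplaced"
        elif in_a and in_d:
            cls = "both"
        elif in_a:
            cls = "A_specific"
        elif in_d:
            cls = "D_specific"
        else:
            cls = "unplaced"
        rows.append({"snp_id": f.snp_id, "tier": f.tier, "class": cls})
    table = pd.DataFrame(rows)
    n = len(table)
    summary = {
        cls: (float((table["class"] == cls).sum()) / n if n else float("nan"))
        for cls in CLASSES
    }
    return table, summary


# ---------------------------------------------------------------------------
# genic classification by interval overlap

def genic_overlap(
    master: MasterSnpTable,
    intervals: Mapping[str, Sequence[tuple[int, int]]],
) -> pd.DataFrame:
    """Per-tier genic/nongenic counts; a SNP is genic iff its 0-based
    position falls in a half-open feature interval on its fragment."""
    for frag, ivs in intervals.items():
        for start, end in ivs:
            if end <= start or start < 0:
                raise ValueError(f"malformed interval {frag}:{start}-{end}")
    rows = []
    counts = {t: [0, 0] for t in TIERS}  # [genic, nongenic]
    for r in master.records:
        ivs = intervals.get(r.fragment, [])
        genic = any(start <= r.pos < end for start, end in ivs)
        counts[r.tier][0 if genic else 1] += 1
    for tier in TIERS:
        genic_n, nongenic_n = counts[tier]
        total = genic_n + nongenic_n
        rows.append(
            {
                "tier": tier,
                "genic_n": genic_n,
                "nongenic_n": nongenic_n,
                "total": total,
                "genic_pct": genic_percent(genic_n, total) if total else float("nan"),
                "nongenic_pct": genic_percent(nongenic_n, total) if total else float("nan"),
            }
        )
    genic_n = sum(counts[t][0] for t in TIERS)
    nongenic_n = sum(counts[t][1] for t in TIERS)
    total = genic_n + nongenic_n
    rows.append(
        {
            "tier": "total",
            "genic_n": genic_n,
            "nongenic_n": nongenic_n,
            "total": total,
            "genic_pct": genic_percent(genic_n, total) if total else float("nan"),
            "nongenic_pct": genic_percent(nongenic_n, total) if total else float("nan"),
        }
    )
    return pd.DataFrame(rows).set_index("tier")


def genic_percent(count: int, total: int) -> float:
    """Percentage to 2 decimals, annotation-table style."""
    return round(100.0 * count / total, 2)


def read_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            frag, start, end = line.split()[:3]
            out.setdefault(frag, []).append((int(start), int(end)))
    return out
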
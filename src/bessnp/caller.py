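"""Pileup-based probabilistic diploid variant calling and homeo-SNP masking.

The genotype model is a binomial mixture: for diploid genotype G = (a1, a2)
the likelihood of an observed base b with error rate eps (from its quality)
is 0.5*P(b|a1,eps) + 0.5*P(b|a2,eps), with P(b|a,eps) = 1-eps if b == a and
eps/3 otherwise. A flat prior over genotypes on {ref} + observed alleles
gives the posterior. A variant is emitted only at depth >= min_depth, when
the best non-reference genotype reaches min_posterior, and when every
reported alternate allele is seen on both strands.

Homeo-SNPs — artifact variants created by homeologous reads cross-mapping
between subgenomes — are identified by calling the reference-genotype
sample against its own reference with identical parameters: any "variant"
it shows cannot be a real polymorphism, so its positions become a mask
subtracted from every other sample's calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam

from .simdata import BesReference, _BASE_TO_IDX

_IDX_TO_BASE = "ACGT"


@dataclass(frozen=True)
class CallerParams:
    min_depth: int = 6
    min_posterior: float = 0.5
    require_both_strands: bool = True
    max_variants: int = 4
    base_quality_floor: int = 0  # discovery phase: no floor

    def validate(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0.0 < self.min_posterior <= 1.0:
            raise ValueError("min_posterior must be in (0, 1]")
        if self.max_variants < 1:
            raise ValueError("max_variants must be >= 1")


@dataclass
class PileupColumn:
    fragment: str
    pos: int  # 0-based
    # observations as (base index, quality, strand 0=fwd/1=rev) -> count
    obs: dict[tuple[int, int, int], int]

    def counts(self, floor: int = 0) -> np.ndarray:
        """(4, 2) base-by-strand counts at quality >= floor."""
        out = np.zeros((4, 2), dtype=np.int64)
        for (b, q, s), c in self.obs.items():
            if q >= floor:
                out[b, s] += c
        return out

    def depth(self, floor: int = 0) -> int:
        return int(self.counts(floor).sum())


@dataclass
class VariantCall:
    fragment: str
    pos: int  # 0-based internally; +1 when written to VCF
    ref: str
    alts: list[str]
    genotype: tuple[str, str]
    posterior: float
    depth: int
    strand_support: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int]:
        return (self.fragment, self.pos)

    @property
    def is_homozygous_alt(self) -> bool:
        a1, a2 = self.genotype
        return a1 == a2 != self.ref


HomeoMask = set  # set of (fragment, pos) pairs


# ---------------------------------------------------------------------------
# pileup construction

def pileup_counts(
    bam_path: str | Path, reference: BesReference
) -> dict[str, dict[int, np.ndarray]]:
    """Per-fragment, per-quality (L, 4, 2) observation count arrays.

    Parsed straight from CIGAR M-runs; insertions and clips contribute
    nothing, deletion columns are uncovered.
    """
    by_frag: dict[str, dict[int, np.ndarray]] = {
        name: {} for name in reference.fragments
    }
    lengths = {name: len(seq) for name, seq in reference.fragments.items()}
    with pysam.AlignmentFile(str(bam_path)) as bam:
        names = set(bam.references)
        if not names <= set(lengths):
            raise ValueError("BAM reference names do not match the FASTA")
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            frag = read.reference_name
            seq_idx = _BASE_TO_IDX[
                np.frombuffer(read.query_sequence.encode(), dtype=np.uint8)
            ]
            quals = np.asarray(read.query_qualities, dtype=np.int64)
            strand = 1 if read.is_reverse else 0
            qoff, roff = 0, read.reference_start
            store = by_frag[frag]
            for op, ln in read.cigartuples:
                if op == 0:  # M
                    b = seq_idx[qoff : qoff + ln]
                    qq = quals[qoff : qoff + ln]
                    r = np.arange(roff, roff + ln)
                    valid = b < 4
                    for u in np.unique(qq[valid]):
                        sel = valid & (qq == u)
                        arr = store.get(int(u))
                        if arr is None:
                            arr = np.zeros((lengths[frag], 4, 2), dtype=np.int32)
                            store[int(u)] = arr
                        np.add.at(arr, (r[sel], b[sel], strand), 1)
                    qoff += ln
                    roff += ln
                elif op == 1 or op == 4:  # I, S
                    qoff += ln
                elif op == 2:  # D
                    roff += ln
    return by_frag


def depth_array(counts: dict[str, dict[int, np.ndarray]], fragment: str) -> np.ndarray:
    store = counts[fragment]
    if not store:
        return np.zeros(0, dtype=np.int64)
    return sum(arr.sum(axis=(1, 2)) for arr in store.values())


def pileup(
    bam_path: str | Path, reference: BesReference
) -> Iterator[PileupColumn]:
    """Stream one PileupColumn per covered reference position."""
    counts = pileup_counts(bam_path, reference)
    yield from columns_from_counts(counts)


def columns_from_counts(
    counts: dict[str, dict[int, np.ndarray]]
) -> Iterator[PileupColumn]:
    for frag in counts:
        store = counts[frag]
        if not store:
            continue
        total = sum(arr.sum(axis=(1, 2)) for arr in store.values())
        for pos in np.flatnonzero(total):
            obs: dict[tuple[int, int, int], int] = {}
            for q, arr in store.items():
                for b in range(4):
                    for s in range(2):
                        c = int(arr[pos, b, s])
                        if c:
                            obs[(b, q, s)] = obs.get((b, q, s), 0) + c
            yield PileupColumn(fragment=frag, pos=int(pos), obs=obs)


# ---------------------------------------------------------------------------
# genotype posterior

def _p_base_given_allele(b: int, a: int, eps: float) -> float:
    return 1.0 - eps if b == a else eps / 3.0


def site_posterior(
    column: PileupColumn,
    ref_base: str,
    params: CallerParams | None = None,
) -> dict[tuple[str, str], float]:
    """Posterior over diploid genotypes on {ref} + observed alleles."""
    params = params or CallerParams()
    floor = params.base_quality_floor
    obs = [(b, q, c) for (b, q, _s), c in column.obs.items() if q >= floor]
    if not obs:
        raise ValueError("column has no usable observations")
    # merge strands for the likelihood; strand is a filter, not evidence
    merged: dict[tuple[int, int], int] = {}
    for b, q, c in obs:
        merged[(b, q)] = merged.get((b, q), 0) + c
    ref_idx = _BASE_TO_IDX[ord(ref_base)]
    alleles = sorted({int(ref_idx)} | {b for (b, _q) in merged})
    return _posterior_from_obs(merged, alleles)


def _posterior_from_obs(
    merged: dict[tuple[int, int], int], alleles: list[int]
) -> dict[tuple[str, str], float]:
    genotypes = list(combinations_with_replacement(alleles, 2))
    logliks = []
    for a1, a2 in genotypes:
        ll = 0.0
        for (b, q), c in merged.items():
            eps = min(0.75, 10.0 ** (-q / 10.0))
            p = 0.5 * _p_base_given_allele(b, a1, eps) + 0.5 * _p_base_given_allele(
                b, a2, eps
            )
            ll += c * math.log(p)
        logliks.append(ll)
    m = max(logliks)
    weights = [math.exp(ll - m) for ll in logliks]
    z = sum(weights)
    return {
        (_IDX_TO_BASE[a1], _IDX_TO_BASE[a2]): w / z
        for (a1, a2), w in zip(genotypes, weights)
    }


# ---------------------------------------------------------------------------
# per-sample calling

def call_sample(
    columns: Iterable[PileupColumn],
    reference: BesReference,
    params: CallerParams | None = None,
) -> list[VariantCall]:
    """Apply the discovery filters to every covered column."""
    params = params or CallerParams()
    params.validate()
    calls: list[VariantCall] = []
    floor = params.base_quality_floor
    for col in columns:
        counts = col.counts(floor)
        depth = int(counts.sum())
        if depth < params.min_depth:
            continue
        ref_base = reference.fragments[col.fragment][col.pos]
        ref_idx = int(_BASE_TO_IDX[ord(ref_base)])
        if ref_idx > 3:
            continue
        base_totals = counts.sum(axis=1)
        observed_alt = [b for b in range(4) if b != ref_idx and base_totals[b] > 0]
        if len(observed_alt) > params.max_variants:
            continue  # too many alleles: likely artifact, site suppressed
        post = site_posterior(col, ref_base, params)
        nonref = {
            g: p for g, p in post.items() if g != (ref_base, ref_base)
        }
        if not nonref:
            continue
        genotype, posterior = max(nonref.items(), key=lambda kv: kv[1])
        if posterior < params.min_posterior:
            continue
        gt_alts = sorted({a for a in genotype if a != ref_base})
        if params.require_both_strands:
            ok = all(
                counts[_BASE_TO_IDX[ord(a)], 0] >= 1
                and counts[_BASE_TO_IDX[ord(a)], 1] >= 1
                for a in gt_alts
            )
            if not ok:
                continue
        alts = sorted(
            (_IDX_TO_BASE[b] for b in observed_alt),
            key=lambda a: (-base_totals[_BASE_TO_IDX[ord(a)]], a),
        )[: params.max_variants]
        for a in gt_alts:
            if a not in alts:
                alts.append(a)
        calls.append(
            VariantCall(
                fragment=col.fragment,
                pos=col.pos,
                ref=ref_base,
                alts=alts,
                genotype=genotype,
                posterior=posterior,
                depth=depth,
                strand_support={
                    a: (
                        int(counts[_BASE_TO_IDX[ord(a)], 0]),
                        int(counts[_BASE_TO_IDX[ord(a)], 1]),
                    )
                    for a in alts
                },
            )
        )
    calls.sort(key=lambda c: (c.fragment, c.pos))
    return calls


# ---------------------------------------------------------------------------
# homeo-SNP mask

def identify_homeo_mask(self_sample_calls: Iterable[VariantCall]) -> HomeoMask:
    """Every position the reference-genotype sample calls against its own
    reference is a homeologous-mapping artifact."""
    return {c.key for c in self_sample_calls}


def apply_homeo_mask(
    calls: Iterable[VariantCall], mask: HomeoMask
) -> list[VariantCall]:
    """Exact set subtraction by (fragment, position); idempotent."""
    return [c for c in calls if c.key not in mask]


def write_mask(mask: HomeoMask, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("fragment\tpos\n")
        for frag, pos in sorted(mask):
            fh.write(f"{frag}\t{pos}\n")


def read_mask(path: str | Path) -> HomeoMask:
    mask: HomeoMask = set()
    with open(path) as fh:
        next(fh)
        for line in fh:
            frag, pos = line.split()
            mask.add((frag, int(pos)))
    return mask
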
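"""Independent brute-force oracles, implemented before (and apart from)
the production code paths they check."""

from __future__ import annotations

import itertools
import math

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# exhaustive local alignment (full-matrix, no seeds, no band)

def full_local_alignment(query: str, ref: str, match=1, mismatch=-2, gap=-4):
    """Best local alignment by the complete DP matrix.

    Returns (score, qstart, qend, rstart, identities, columns) or None."""
    n, m = len(query), len(ref)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if query[i - 1] == ref[j - 1] else mismatch
            v = max(0, H[i - 1, j - 1] + s, H[i - 1, j] + gap, H[i, j - 1] + gap)
            H[i, j] = v
            if v > best:
                best, bi, bj = v, i, j
    if best == 0:
        return None
    i, j = bi, bj
    identities = columns = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        s = match if query[i - 1] == ref[j - 1] else mismatch
        if H[i, j] == H[i - 1, j - 1] + s:
            identities += query[i - 1] == ref[j - 1]
            columns += 1
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] + gap:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    return best, i, bi, j, identities, columns


def exhaustive_best_placement(
    seq: str,
    fragments: dict[str, str],
    length_fraction: float,
    similarity_fraction: float,
):
    """Evaluate every fragment on both strands with the full DP; apply the
    two acceptance fractions; return (best score, list of surviving loci)."""
    surviving = []
    for frag, ref in fragments.items():
        for strand, query in (("+", seq), ("-", rc(seq))):
            res = full_local_alignment(query, ref)
            if res is None:
                continue
            score, qstart, qend, rstart, identities, columns = res
            if (qend - qstart) / len(seq) < length_fraction:
                continue
            if identities / columns < similarity_fraction:
                continue
            surviving.append((score, frag, strand, rstart))
    if not surviving:
        return None, []
    best = max(s for s, *_ in surviving)
    return best, [t for t in surviving if t[0] == best]


# ---------------------------------------------------------------------------
# genotype posterior by direct enumeration

def genotype_posterior_enum(obs, ref_base: str):
    """obs: list of (base, qual) observations. Direct summation over all
    diploid genotypes on {ref} + observed bases, flat prior."""
    alleles = sorted({ref_base} | {b for b, _ in obs})
    genotypes = list(itertools.combinations_with_replacement(alleles, 2))
    liks = []
    for a1, a2 in genotypes:
        lik = 0.0
        for b, q in obs:
            eps = min(0.75, 10.0 ** (-q / 10.0))
            p1 = (1 - eps) if b == a1 else eps / 3
            p2 = (1 - eps) if b == a2 else eps / 3
            lik += math.log(0.5 * p1 + 0.5 * p2)
        liks.append(lik)
    mx = max(liks)
    w = [math.exp(l - mx) for l in liks]
    z = sum(w)
    return {g: wi / z for g, wi in zip(genotypes, w)}


# ---------------------------------------------------------------------------
# pi by mean pairwise difference

def pi_pairwise(codes_col) -> float:
    """Average pairwise-difference proportion over all called allele pairs."""
    alleles = []
    for c in codes_col:
        if c < 0:
            continue
        alleles.extend([1] * int(c) + [0] * (2 - int(c)))
    n = len(alleles)
    if n < 2:
        return float("nan")
    diff = pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            pairs += 1
            diff += alleles[i] != alleles[j]
    return diff / pairs


# ---------------------------------------------------------------------------
# naive UPGMA

def naive_upgma(dist: np.ndarray):
    """Average-linkage agglomeration from first principles: repeatedly
    join the closest pair of clusters (ties by smallest member index),
    with cluster distance = mean of all original leaf-pair distances.

    Returns the merge list [(frozenset_a, frozenset_b, height), ...]."""
    n = dist.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            ca, cb = clusters[a], clusters[b]
            d = np.mean([dist[i, j] for i in ca for j in cb])
            key = (d, min(min(ca), min(cb)))
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _), a, b = best
        ca, cb = clusters[a], clusters[b]
        merges.append((ca, cb, d))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(ca | cb)
    return merges
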
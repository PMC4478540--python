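"""Downstream summaries of the final multi-sample VCF and master table.

Covers the standard SNP-quality and diversity reporting for a mining
study: SNP-type (IUPAC class) and transition/transversion tables,
per-sample missingness and heterozygosity, the pairwise
homozygous-difference matrix, per-site and mean nucleotide diversity
(Nei's pi with the n/(n-1) small-sample correction), adjacent-SNP spacing
along fragments, and the three-species overlap partition.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .collate import MasterSnpTable, TIERS
from .vcfio import FinalVcf

IUPAC_CLASS = {
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
}
SNP_CLASSES = ("M", "R", "W", "S", "Y", "K")
TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def classify_snp_type(ref: str, alt: str) -> tuple[str, str]:
    """Unordered-pair IUPAC class and transition/transversion label."""
    if ref == alt:
        raise ValueError("ref and alt must differ")
    pair = frozenset((ref, alt))
    if not pair <= set("ACGT"):
        raise ValueError(f"non-ACGT allele in {ref}/{alt}")
    kind = "transition" if pair in TRANSITIONS else "transversion"
    return IUPAC_CLASS[pair], kind


def _class_counts_from_master(
    master: MasterSnpTable, decompose_multiallelic: bool = True
) -> dict[str, dict[str, int]]:
    counts: dict[str, dict[str, int]] = {
        t: {c: 0 for c in SNP_CLASSES} for t in TIERS
    }
    for r in master.records:
        alts = r.alts if decompose_multiallelic else r.alts[:1]
        for alt in alts:
            cls, _ = classify_snp_type(r.ref, alt)
            counts[r.tier][cls] += 1
    return counts


def tstv_summary(class_counts: Mapping[str, Mapping[str, int]]) -> pd.DataFrame:
    """Ts/Tv table from per-tier class counts (tiers may be any labels;
    an 'overall' row summing all tiers is appended).

    Columns: per-class counts and percentages (1 decimal), transition and
    transversion totals and percentages, and the Ts/Tv ratio (2 decimals,
    NA when there are no transversions).
    """
    tiers = list(class_counts)
    data = {t: dict(class_counts[t]) for t in tiers}
    overall = {c: sum(data[t].get(c, 0) for t in tiers) for c in SNP_CLASSES}
    data["overall"] = overall
    rows = []
    for tier, counts in data.items():
        ts = sum(counts.get(c, 0) for c in ("R", "Y"))
        tv = sum(counts.get(c, 0) for c in ("M", "W", "S", "K"))
        total = ts + tv
        row: dict[str, object] = {"tier": tier, "total": total}
        for c in SNP_CLASSES:
            row[c] = counts.get(c, 0)
            row[f"{c}_pct"] = round(100.0 * counts.get(c, 0) / total, 1) if total else float("nan")
        row["transitions"] = ts
        row["transversions"] = tv
        row["transition_pct"] = round(100.0 * ts / total, 1) if total else float("nan")
        row["transversion_pct"] = round(100.0 * tv / total, 1) if total else float("nan")
        row["tstv_ratio"] = round(ts / tv, 2) if tv else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("tier")


def tstv_table(
    master: MasterSnpTable, decompose_multiallelic: bool = True
) -> pd.DataFrame:
    """Ts/Tv table of the master table, per tier plus overall.

    Multi-allelic sites decompose into one ref/alt pair per alternate
    allele by default; first-alt-only counting is available."""
    return tstv_summary(_class_counts_from_master(master, decompose_multiallelic))


# ---------------------------------------------------------------------------
# per-sample call statistics (final VCF)

def sample_callstats(final: FinalVcf) -> pd.DataFrame:
    """Missing and heterozygous counts per sample; denominators are the
    total master positions, percentages to 2 decimals."""
    total = final.n_sites
    rows = []
    for i, s in enumerate(final.samples):
        missing = int((final.codes[i] == -1).sum())
        het = int(final.het[i].sum())
        rows.append(
            {
                "sample": s,
                "total": total,
                "missing_n": missing,
                "missing_pct": round(100.0 * missing / total, 2) if total else float("nan"),
                "het_n": het,
                "het_pct": round(100.0 * het / total, 2) if total else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def callstats_percent(count: int, total: int) -> float:
    """Percentage to 2 decimals, as printed in per-sample call tables."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, 2)


def pairwise_hom_diff(final: FinalVcf) -> pd.DataFrame:
    """Sites where two samples are homozygous for different alleles.

    Heterozygous and missing sites are excluded; the matrix is symmetric
    with a zero diagonal."""
    if len(final.samples) < 2:
        raise ValueError("need at least two samples")
    codes = final.codes.astype(np.int16)
    hom = (codes >= 0) & ~final.het
    n = len(final.samples)
    out = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            both = hom[i] & hom[j]
            diff = int(np.sum(both & (codes[i] != codes[j])))
            out[i, j] = out[j, i] = diff
    return pd.DataFrame(out, index=final.samples, columns=final.samples)


# ---------------------------------------------------------------------------
# nucleotide diversity

def site_pi(codes_col: np.ndarray) -> float:
    """Nei's per-site diversity from one site's dosage column.

    pi_site = (n/(n-1)) * (1 - sum_a p_a^2) over called *alleles*
    (2 per called diploid genotype); undefined (nan) below 2 alleles."""
    called = codes_col[codes_col >= 0]
    n_alleles = 2 * called.size
    if n_alleles < 2:
        return float("nan")
    alt = int(called.sum())
    p_alt = alt / n_alleles
    p = np.array([1.0 - p_alt, p_alt])
    return float(n_alleles / (n_alleles - 1) * (1.0 - np.sum(p**2)))


def nucleotide_diversity(final: FinalVcf) -> tuple[float, np.ndarray]:
    """Mean pi over polymorphic sites (>= 2 observed alleles among called
    genotypes) plus the per-site values (nan where undefined)."""
    m = final.n_sites
    per_site = np.full(m, np.nan)
    for j in range(m):
        per_site[j] = site_pi(final.codes[:, j])
    polymorphic = per_site > 0
    if not polymorphic.any():
        return float("nan"), per_site
    return float(np.nanmean(per_site[polymorphic])), per_site


# ---------------------------------------------------------------------------
# spacing and overlap

def adjacent_spacing(
    master: MasterSnpTable, tier: str | None = None, bins: int = 20
) -> dict[str, object]:
    """Distances between adjacent master SNPs on the same fragment.

    Fragments with fewer than two SNPs contribute nothing; returns the
    distances, their mean, and a histogram."""
    by_frag: dict[str, list[int]] = {}
    for r in master.records:
        if tier is not None and r.tier != tier:
            continue
        by_frag.setdefault(r.fragment, []).append(r.pos)
    distances: list[int] = []
    for positions in by_frag.values():
        positions.sort()
        distances.extend(b - a for a, b in zip(positions, positions[1:]))
    arr = np.array(distances, dtype=np.int64)
    hist, edges = (
        np.histogram(arr, bins=bins) if arr.size else (np.zeros(bins, int), np.zeros(bins + 1))
    )
    return {
        "distances": arr,
        "mean": float(arr.mean()) if arr.size else float("nan"),
        "hist": hist,
        "bin_edges": edges,
    }


def species_overlap(
    sets: Mapping[str, Iterable[tuple[str, int]]]
) -> dict[str, int]:
    """The 7 disjoint region counts of the 3-set Venn partition.

    Keys are '100', '010', ..., '111' in the order of the three given set
    labels (conventionally hirsutum, barbadense, longicalyx)."""
    labels = list(sets)
    if len(labels) != 3:
        raise ValueError("species_overlap expects exactly three sets")
    s = [set(sets[l]) for l in labels]
    union = s[0] | s[1] | s[2]
    out = {f"{a}{b}{c}": 0 for a in "01" for b in "01" for c in "01" if a + b + c != "000"}
    for item in union:
        key = "".join("1" if item in si else "0" for si in s)
        out[key] += 1
    return out
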
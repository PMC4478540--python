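"""Genotype-given-alleles recall over the master SNP table.

Discovery (the caller) and recall are deliberately separate phases: after
the master table is fixed, every sample is re-genotyped at every master
position with a base-quality floor but no depth filter, so the final
multi-sample VCF has a genotype (or an explicit missing call) at all
positions for all samples — the emit-all-sites contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .caller import _posterior_from_obs
from .collate import MasterSnpTable
from .simdata import BesReference, _BASE_TO_IDX
from .vcfio import write_final_vcf

_IDX_TO_BASE = "ACGT"


@dataclass(frozen=True)
class GenotypeParams:
    min_base_quality: int = 20

    def validate(self) -> None:
        if self.min_base_quality < 0:
            raise ValueError("min_base_quality must be >= 0")


@dataclass
class GenotypeColumn:
    """One sample's genotypes across the whole master table."""

    sample: str
    genotypes: list[str]  # GT strings in master order; './.' missing
    depths: list[int]  # usable (quality-passing) depth per site

    def n_missing(self) -> int:
        return sum(g == "./." for g in self.genotypes)


def genotype_given_alleles(
    pileup_counts: Mapping[str, Mapping[int, np.ndarray]],
    master: MasterSnpTable,
    reference: BesReference,
    params: GenotypeParams | None = None,
    sample: str = "sample",
) -> GenotypeColumn:
    """Posterior-max genotype restricted to {ref} + master alts at every
    master position; zero usable bases -> missing. Exactly |master| rows."""
    params = params or GenotypeParams()
    params.validate()
    genotypes: list[str] = []
    depths: list[int] = []
    for rec in master.records:
        frag_len = len(reference.fragments[rec.fragment])
        if not 0 <= rec.pos < frag_len:
            raise ValueError(f"master position {rec.key} outside fragment bounds")
        allele_order = [rec.ref] + rec.alts
        allowed = sorted(int(_BASE_TO_IDX[ord(a)]) for a in allele_order)
        merged: dict[tuple[int, int], int] = {}
        store = pileup_counts.get(rec.fragment, {})
        for q, arr in store.items():
            if q < params.min_base_quality:
                continue
            col = arr[rec.pos]  # (4, 2)
            for b in range(4):
                c = int(col[b].sum())
                if c:
                    merged[(b, q)] = merged.get((b, q), 0) + c
        depth = sum(merged.values())
        depths.append(depth)
        if depth == 0:
            genotypes.append("./.")
            continue
        post = _posterior_from_obs(merged, allowed)
        (a1, a2), _p = max(post.items(), key=lambda kv: kv[1])
        i1, i2 = sorted(
            (allele_order.index(a1), allele_order.index(a2))
        )
        genotypes.append(f"{i1}/{i2}")
    return GenotypeColumn(sample=sample, genotypes=genotypes, depths=depths)


def merge_final_vcf(
    columns: Sequence[GenotypeColumn],
    master: MasterSnpTable,
    path: str | Path,
    reference: BesReference | None = None,
) -> Path:
    """One record per master position, one genotype per sample."""
    n = len(master)
    for col in columns:
        if len(col.genotypes) != n:
            raise ValueError(
                f"column for {col.sample} has {len(col.genotypes)} rows, master has {n}"
            )
    records = [(r.fragment, r.pos, r.ref, r.alts) for r in master.records]
    samples = [c.sample for c in columns]
    write_final_vcf(
        records,
        {c.sample: c.genotypes for c in columns},
        samples,
        path,
        depths={c.sample: c.depths for c in columns},
        reference=reference,
    )
    return Path(path)
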
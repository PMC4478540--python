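"""VCFv4.2 reading and writing for per-sample calls and the final matrix.

Files are written as plain VCF text (small, deterministic headers) and read
back through cyvcf2, which doubles as a format check in the test suite.
Positions are 1-based on disk, 0-based in memory.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from cyvcf2 import VCF

from .caller import VariantCall
from .simdata import BesReference

_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=PP,Number=1,Type=Float,Description="Genotype posterior">',
    '##FORMAT=<ID=ADF,Number=A,Type=Integer,Description="Forward alt depth">',
    '##FORMAT=<ID=ADR,Number=A,Type=Integer,Description="Reverse alt depth">',
]


def _contig_lines(reference: BesReference | None) -> list[str]:
    if reference is None:
        return []
    return [
        f"##contig=<ID={name},length={len(seq)}>"
        for name, seq in reference.fragments.items()
    ]


def _gt_string(call: VariantCall) -> str:
    order = [call.ref] + call.alts
    return "/".join(str(order.index(a)) for a in sorted(call.genotype, key=order.index))


def write_sample_vcf(
    calls: Iterable[VariantCall],
    sample: str,
    path: str | Path,
    reference: BesReference | None = None,
) -> None:
    with open(path, "w") as fh:
        for line in _HEADER_LINES + _contig_lines(reference):
            fh.write(line + "\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample}\n"
        )
        for c in sorted(calls, key=lambda c: (c.fragment, c.pos)):
            adf = ",".join(str(c.strand_support.get(a, (0, 0))[0]) for a in c.alts)
            adr = ",".join(str(c.strand_support.get(a, (0, 0))[1]) for a in c.alts)
            fh.write(
                f"{c.fragment}\t{c.pos + 1}\t.\t{c.ref}\t{','.join(c.alts)}\t.\tPASS\t.\t"
                f"GT:DP:PP:ADF:ADR\t{_gt_string(c)}:{c.depth}:{c.posterior:.4f}:{adf}:{adr}\n"
            )


def read_sample_vcf(path: str | Path) -> list[VariantCall]:
    vcf = VCF(str(path))
    calls: list[VariantCall] = []
    for v in vcf:
        alts = list(v.ALT)
        order = [v.REF] + alts
        a1, a2 = v.genotypes[0][:2]
        genotype = tuple(sorted((order[a1], order[a2])))
        depth = int(v.format("DP")[0][0]) if v.format("DP") is not None else 0
        pp = float(v.format("PP")[0][0]) if v.format("PP") is not None else 1.0
        support = {}
        adf = v.format("ADF")
        adr = v.format("ADR")
        if adf is not None and adr is not None:
            for i, a in enumerate(alts):
                support[a] = (int(adf[0][i]), int(adr[0][i]))
        calls.append(
            VariantCall(
                fragment=v.CHROM,
                pos=v.POS - 1,
                ref=v.REF,
                alts=alts,
                genotype=genotype,  # type: ignore[arg-type]
                posterior=pp,
                depth=depth,
                strand_support=support,
            )
        )
    vcf.close()
    return calls


# ---------------------------------------------------------------------------
# final multi-sample VCF

def write_final_vcf(
    records: Sequence[tuple[str, int, str, list[str]]],
    genotypes: dict[str, list[str]],
    samples: Sequence[str],
    path: str | Path,
    depths: dict[str, list[int]] | None = None,
    reference: BesReference | None = None,
) -> None:
    """records: (fragment, pos0, ref, alts) per master site, sorted;
    genotypes[sample][i]: GT string ('./.' for missing) per site."""
    for s in samples:
        if len(genotypes[s]) != len(records):
            raise ValueError(f"genotype column of {s} does not cover the master")
    with open(path, "w") as fh:
        for line in _HEADER_LINES[:3] + _contig_lines(reference):
            fh.write(line + "\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        fmt = "GT:DP" if depths is not None else "GT"
        for i, (frag, pos, ref, alts) in enumerate(records):
            cells = []
            for s in samples:
                gt = genotypes[s][i]
                if depths is not None:
                    cells.append(f"{gt}:{depths[s][i]}")
                else:
                    cells.append(gt)
            fh.write(
                f"{frag}\t{pos + 1}\t.\t{ref}\t{','.join(alts)}\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(cells)
                + "\n"
            )


class FinalVcf:
    """In-memory view of the final multi-sample VCF."""

    def __init__(
        self,
        samples: list[str],
        records: list[tuple[str, int, str, list[str]]],
        codes: np.ndarray,  # samples x sites, alt dosage, -1 missing
        het: np.ndarray,  # samples x sites bool
    ):
        self.samples = samples
        self.records = records
        self.codes = codes
        self.het = het

    @property
    def n_sites(self) -> int:
        return len(self.records)


def read_final_vcf(path: str | Path) -> FinalVcf:
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[tuple[str, int, str, list[str]]] = []
    codes_rows: list[list[int]] = []
    het_rows: list[list[bool]] = []
    for v in vcf:
        records.append((v.CHROM, v.POS - 1, v.REF, list(v.ALT)))
        row: list[int] = []
        hrow: list[bool] = []
        for g in v.genotypes:
            a1, a2 = g[0], g[1]
            if a1 < 0 or a2 < 0:
                row.append(-1)
                hrow.append(False)
            else:
                row.append(int(a1 > 0) + int(a2 > 0))
                hrow.append(a1 != a2)
        codes_rows.append(row)
        het_rows.append(hrow)
    vcf.close()
    codes = (
        np.array(codes_rows, dtype=np.int8).T
        if codes_rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    het = (
        np.array(het_rows, dtype=bool).T
        if het_rows
        else np.zeros((len(samples), 0), dtype=bool)
    )
    return FinalVcf(samples=samples, records=records, codes=codes, het=het)
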
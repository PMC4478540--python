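"""Nonredundant, tiered master SNP table.

Intraspecific candidates must be 100% homozygous non-reference in at least
one intraspecific line; positions whose coverage in a supporting line sits
more than k standard deviations above that line's mean are discarded as
likely repeats; interspecific positions (homozygous, posterior above the
interspecific threshold) are then added hierarchically — a position keeps
the label of the first species tier that contained it — and the result is
exported as three per-tier VCFs plus a TSV master table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .caller import VariantCall
from .simdata import BesReference

TIERS = ("hirsutum", "barbadense", "longicalyx")


@dataclass(frozen=True)
class CollationParams:
    sd_multiplier: float = 1.0  # the stricter reading of "1 to 2 SDs"
    min_interspecific_posterior: float = 0.98

    def validate(self) -> None:
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be > 0")
        if not 0.0 < self.min_interspecific_posterior <= 1.0:
            raise ValueError("min_interspecific_posterior must be in (0, 1]")


@dataclass
class MasterRecord:
    fragment: str
    pos: int  # 0-based
    ref: str
    alts: list[str]
    tier: str
    samples: list[str] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int]:
        return (self.fragment, self.pos)


@dataclass
class MasterSnpTable:
    records: list[MasterRecord]

    def __post_init__(self) -> None:
        self.records.sort(key=lambda r: (r.fragment, r.pos))
        keys = [r.key for r in self.records]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (fragment, position) in master table")

    def __len__(self) -> int:
        return len(self.records)

    def keys(self) -> set[tuple[str, int]]:
        return {r.key for r in self.records}

    def tier_counts(self) -> dict[str, int]:
        out = {t: 0 for t in TIERS}
        for r in self.records:
            out[r.tier] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fragment": [r.fragment for r in self.records],
                "pos": [r.pos for r in self.records],
                "ref": [r.ref for r in self.records],
                "alts": [",".join(r.alts) for r in self.records],
                "tier": [r.tier for r in self.records],
                "samples": [",".join(r.samples) for r in self.records],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "MasterSnpTable":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        records = [
            MasterRecord(
                fragment=row.fragment,
                pos=int(row.pos),
                ref=row.ref,
                alts=row.alts.split(","),
                tier=row.tier,
                samples=row.samples.split(",") if row.samples else [],
            )
            for row in df.itertuples()
        ]
        return cls(records=records)


# ---------------------------------------------------------------------------

def hirsutum_master(
    per_line_calls: Mapping[str, Sequence[VariantCall]]
) -> dict[tuple[str, int], MasterRecord]:
    """Candidate intraspecific positions: homozygous non-reference in at
    least one line (homeo mask assumed already applied per line)."""
    out: dict[tuple[str, int], MasterRecord] = {}
    for line, calls in per_line_calls.items():
        for c in calls:
            if not c.is_homozygous_alt:
                continue
            rec = out.get(c.key)
            if rec is None:
                rec = MasterRecord(
                    fragment=c.fragment,
                    pos=c.pos,
                    ref=c.ref,
                    alts=list(c.alts),
                    tier="hirsutum",
                )
                out[c.key] = rec
            elif rec.ref != c.ref:
                raise ValueError(f"reference inconsistency at {c.key}")
            for a in c.alts:
                if a not in rec.alts:
                    rec.alts.append(a)
            rec.samples.append(line)
    return out


def coverage_filter(
    candidates: dict[tuple[str, int], MasterRecord],
    depth_lookup: Callable[[str, str, int], int],
    coverage_stats: Mapping[str, tuple[float, float]],
    params: CollationParams | None = None,
) -> dict[tuple[str, int], MasterRecord]:
    """Drop candidates whose coverage in any supporting line exceeds that
    line's mean + k*SD (computed over its covered positions). A supporting
    line with no coverage statistics cannot veto."""
    params = params or CollationParams()
    params.validate()
    kept: dict[tuple[str, int], MasterRecord] = {}
    for key, rec in candidates.items():
        veto = False
        for line in rec.samples:
            stats = coverage_stats.get(line)
            if stats is None:
                continue
            mean, sd = stats
            depth = depth_lookup(line, rec.fragment, rec.pos)
            if depth > mean + params.sd_multiplier * sd:
                veto = True
                break
        if not veto:
            kept[key] = rec
    return kept


def coverage_stats_from_depths(depths: Iterable[np.ndarray]) -> tuple[float, float]:
    """Mean and SD of depth over covered positions (depth >= 1) only."""
    covered = np.concatenate([d[d > 0] for d in depths]) if depths else np.array([])
    if covered.size == 0:
        return (0.0, 0.0)
    return (float(covered.mean()), float(covered.std()))


def add_tiered(
    hirsutum_candidates: dict[tuple[str, int], MasterRecord],
    barbadense_calls: Sequence[VariantCall],
    longicalyx_calls: Sequence[VariantCall],
    params: CollationParams | None = None,
    barbadense_sample: str = "barbadense",
    longicalyx_sample: str = "longicalyx",
) -> MasterSnpTable:
    """Hierarchical retention: hirsutum first, then barbadense, then
    longicalyx; interspecific positions require a homozygous call with
    posterior above min_interspecific_posterior."""
    params = params or CollationParams()
    params.validate()
    table: dict[tuple[str, int], MasterRecord] = dict(hirsutum_candidates)
    for tier, calls, sample in (
        ("barbadense", barbadense_calls, barbadense_sample),
        ("longicalyx", longicalyx_calls, longicalyx_sample),
    ):
        for c in calls:
            if not c.is_homozygous_alt:
                continue
            if c.posterior <= params.min_interspecific_posterior:
                continue
            existing = table.get(c.key)
            if existing is not None:
                if existing.ref != c.ref:
                    raise ValueError(f"reference inconsistency at {c.key}")
                continue  # retained at the higher tier
            table[c.key] = MasterRecord(
                fragment=c.fragment,
                pos=c.pos,
                ref=c.ref,
                alts=list(c.alts),
                tier=tier,
                samples=[sample],
            )
    return MasterSnpTable(records=list(table.values()))


def write_species_vcfs(
    master: MasterSnpTable,
    outdir: str | Path,
    reference: BesReference | None = None,
) -> dict[str, Path]:
    """One VCF per tier; the tiers partition the master table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    contigs = (
        [
            f"##contig=<ID={n},length={len(s)}>"
            for n, s in reference.fragments.items()
        ]
        if reference
        else []
    )
    for tier in TIERS:
        path = outdir / f"{tier}.vcf"
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##source=bessnp collate tier={tier}\n")
            for line in contigs:
                fh.write(line + "\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for r in master.records:
                if r.tier != tier:
                    continue
                fh.write(
                    f"{r.fragment}\t{r.pos + 1}\t.\t{r.ref}\t{','.join(r.alts)}\t.\tPASS\t.\n"
                )
        paths[tier] = path
    return paths


def read_species_vcfs(paths: Mapping[str, str | Path]) -> MasterSnpTable:
    records: list[MasterRecord] = []
    for tier, path in paths.items():
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                frag, pos, _id, ref, alt = line.split("\t")[:5]
                records.append(
                    MasterRecord(
                        fragment=frag,
                        pos=int(pos) - 1,
                        ref=ref,
                        alts=alt.split(","),
                        tier=tier,
                    )
                )
    return MasterSnpTable(records=records)
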
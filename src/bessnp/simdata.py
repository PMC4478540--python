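"""Synthetic allotetraploid resequencing data.

Emulates the structure of the real study system: a Sanger-quality
BAC-end-sequence (BES) reference drawn from two highly similar homeologous
subgenomes (A and D) of an allotetraploid, a panel of closely related
intraspecific tetraploid lines, one moderately diverged tetraploid line,
and one strongly diverged diploid line that carries only A-like loci.
Paired 2x100 bp error-bearing reads are simulated from each sample so the
whole mining pipeline — strict mapping, probabilistic calling, homeo-SNP
masking, collation, re-genotyping — can be verified against known truth.

Coordinates are 0-based half-open internally and 1-based only in VCF output.
"""

from __future__ import annotations

import dataclasses
import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_TO_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_IDX[_b] = _i
# transition partner (A<->G, C<->T) and the two transversion partners, by index
_TRANSITION = np.array([2, 3, 0, 1], dtype=np.uint8)
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.uint8)

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic allotetraploid study panel.

    Rates are substitutions per site; coverage is fold coverage per
    subgenome locus (the two haplotypes of one subgenome copy sum to it).
    """

    seed: int = 17
    ancestral_length: int = 50_000
    n_fragments: int = 60
    fragment_length_range: tuple[int, int] = (400, 800)
    homeolog_divergence: float = 0.02
    line_snp_rate: float = 0.001
    barbadense_rate: float = 0.005
    longicalyx_rate: float = 0.02
    het_fraction: float = 0.1
    read_length: int = 100
    coverage: float = 20.0
    base_error_rate: float = 0.001
    n_lines: int = 12
    ts_tv_ratio: float = 2.0  # odds of a transition vs. all transversions
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    genic_prob: float = 0.35  # chance a fragment carries one genic interval

    def validate(self) -> None:
        rates = {
            "homeolog_divergence": self.homeolog_divergence,
            "line_snp_rate": self.line_snp_rate,
            "barbadense_rate": self.barbadense_rate,
            "longicalyx_rate": self.longicalyx_rate,
            "het_fraction": self.het_fraction,
            "base_error_rate": self.base_error_rate,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name}={value} outside [0, 1]")
        if not (self.longicalyx_rate > self.barbadense_rate > self.line_snp_rate):
            raise ConfigError(
                "species rates must satisfy longicalyx > barbadense > line"
            )
        lo, hi = self.fragment_length_range
        if not (0 < lo <= hi):
            raise ConfigError("fragment_length_range must be positive and ordered")
        if hi > self.ancestral_length:
            raise ConfigError("fragment length exceeds ancestral length")
        if self.coverage <= 0 and self.coverage != 0:
            raise ConfigError("coverage must be >= 0")
        if self.n_fragments < 1 or self.n_lines < 1:
            raise ConfigError("need at least one fragment and one line")
        if self.ancestral_length // self.n_fragments < hi:
            raise ConfigError(
                "n_fragments * max fragment length exceeds ancestral length"
            )


@dataclass
class TruthVariant:
    sample: str
    fragment: str
    pos: int  # 0-based on the fragment
    ref: str
    alt: str
    genotype: str  # "0/1" or "1/1"


@dataclass
class SimTruth:
    """Ground truth backing every verification downstream."""

    variants: list[TruthVariant] = field(default_factory=list)
    homeo_sites: set[tuple[str, int]] = field(default_factory=set)
    genic: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    origin: dict[str, str] = field(default_factory=dict)  # fragment -> "A"/"D"

    def variants_by_sample(self) -> dict[str, list[TruthVariant]]:
        out: dict[str, list[TruthVariant]] = {}
        for v in self.variants:
            out.setdefault(v.sample, []).append(v)
        return out


@dataclass
class BesReference:
    """The BES fragment set: the mapping and calling coordinate system."""

    fragments: dict[str, str]
    # genomic provenance of each fragment: (subgenome, start, end)
    intervals: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.fragments)

    def total_length(self) -> int:
        return sum(len(s) for s in self.fragments.values())

    def write_fasta(self, path: str | Path) -> None:
        write_fasta(path, self.fragments.items())

    @classmethod
    def from_fasta(cls, path: str | Path) -> "BesReference":
        return cls(fragments=dict(read_fasta(path)))


@dataclass
class SampleGenome:
    """One simulated accession: a haplotype pair per subgenome copy."""

    name: str
    species: str  # hirsutum | barbadense | longicalyx
    # subgenome label -> (haplotype1, haplotype2) as uint8 base-index arrays
    haplotypes: dict[str, tuple[np.ndarray, np.ndarray]]


@dataclass
class ReferenceBundle:
    reference: BesReference
    a_genome: str
    d_genome: str
    truth: SimTruth


# ---------------------------------------------------------------------------
# FASTA / FASTQ plumbing (tiny, text-level; gzip-aware by file suffix)

def _open_text(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_fasta(path: str | Path, records, width: int = 70) -> None:
    with _open_text(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path):
    name, chunks = None, []
    with _open_text(path, "r") as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    yield name, "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        yield name, "".join(chunks)


def _arr_to_seq(arr: np.ndarray) -> str:
    return BASES[arr].tobytes().decode()


def _seq_to_arr(seq: str) -> np.ndarray:
    return _BASE_TO_IDX[np.frombuffer(seq.encode(), dtype=np.uint8)].copy()


# ---------------------------------------------------------------------------
# Mutation model: uniform substitution positions, transition-biased alleles

def _draw_alts(
    ref_idx: np.ndarray, rng: np.random.Generator, ts_tv_ratio: float
) -> np.ndarray:
    p_ts = ts_tv_ratio / (ts_tv_ratio + 1.0)
    is_ts = rng.random(ref_idx.size) < p_ts
    alts = np.empty_like(ref_idx)
    alts[is_ts] = _TRANSITION[ref_idx[is_ts]]
    tv_choice = rng.integers(0, 2, size=(~is_ts).sum())
    alts[~is_ts] = _TRANSVERSIONS[ref_idx[~is_ts], tv_choice]
    return alts


def _mutate(
    seq: np.ndarray, rate: float, rng: np.random.Generator, ts_tv_ratio: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (mutated copy, positions, alt indices); every hit changes the base."""
    out = seq.copy()
    if rate <= 0:
        return out, np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint8)
    pos = np.flatnonzero(rng.random(seq.size) < rate)
    alts = _draw_alts(seq[pos], rng, ts_tv_ratio)
    out[pos] = alts
    return out, pos, alts


# ---------------------------------------------------------------------------
# Reference generation

def generate_reference(cfg: SimConfig) -> ReferenceBundle:
    """Build the homeologous A/D genome pair, the BES fragment reference,
    the two diploid-relative genomes, and the truth scaffolding.

    The ancestral sequence is mutated independently into the A and D
    subgenome copies at homeolog_divergence/2 each, so the realised A-D
    mismatch density matches homeolog_divergence. Fragments are placed in
    non-overlapping slots, each drawn from one subgenome copy, in roughly
    equal numbers from A and D.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 0])
    L = cfg.ancestral_length
    ancestral = rng.integers(0, 4, size=L, dtype=np.uint8)
    half = cfg.homeolog_divergence / 2.0
    a_copy, _, _ = _mutate(ancestral, half, rng, cfg.ts_tv_ratio)
    d_copy, _, _ = _mutate(ancestral, half, rng, cfg.ts_tv_ratio)

    truth = SimTruth()
    fragments: dict[str, str] = {}
    intervals: dict[str, tuple[str, int, int]] = {}
    slot = L // cfg.n_fragments
    lo, hi = cfg.fragment_length_range
    origins = np.array(["A", "D"])[
        rng.permutation(np.arange(cfg.n_fragments) % 2)
    ]
    diff_positions = np.flatnonzero(a_copy != d_copy)
    for i in range(cfg.n_fragments):
        flen = int(rng.integers(lo, hi + 1))
        offset = int(rng.integers(0, slot - flen + 1)) if slot > flen else 0
        start = i * slot + offset
        end = start + flen
        origin = str(origins[i])
        name = f"BES{i:05d}"
        src = a_copy if origin == "A" else d_copy
        fragments[name] = _arr_to_seq(src[start:end])
        intervals[name] = (origin, start, end)
        truth.origin[name] = origin
        within = diff_positions[(diff_positions >= start) & (diff_positions < end)]
        truth.homeo_sites.update((name, int(p - start)) for p in within)
        if rng.random() < cfg.genic_prob:
            glen = max(1, int(flen * rng.uniform(0.15, 0.35)))
            gstart = int(rng.integers(0, flen - glen + 1))
            truth.genic[name] = [(gstart, gstart + glen)]
        else:
            truth.genic[name] = []

    reference = BesReference(fragments=fragments, intervals=intervals)
    return ReferenceBundle(
        reference=reference,
        a_genome=_arr_to_seq(a_copy),
        d_genome=_arr_to_seq(d_copy),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Per-sample variant spiking

def _sample_names(cfg: SimConfig) -> list[tuple[str, str]]:
    names = [(f"hir{i + 1:02d}", "hirsutum") for i in range(cfg.n_lines)]
    names.append(("barb01", "barbadense"))
    names.append(("long01", "longicalyx"))
    return names


def spike_variants(
    bundle: ReferenceBundle, cfg: SimConfig
) -> dict[str, SampleGenome]:
    """Create every accession's genome and record its true variants.

    Line 1 of the intraspecific panel is the reference genotype itself
    (zero spiked variants) — the sample later used to learn the homeo-SNP
    mask, exactly as the reference-line resequencing run is used in the
    real workflow. The diploid accession is built from the A-like copy
    only, so D-origin fragments receive none of its reads.
    """
    cfg.validate()
    a_arr = _seq_to_arr(bundle.a_genome)
    d_arr = _seq_to_arr(bundle.d_genome)
    rate_of = {
        "hirsutum": cfg.line_snp_rate,
        "barbadense": cfg.barbadense_rate,
        "longicalyx": cfg.longicalyx_rate,
    }
    samples: dict[str, SampleGenome] = {}
    truth = bundle.truth
    # drop any stale per-sample truth from a previous spike of this bundle
    truth.variants = []
    for s_idx, (name, species) in enumerate(_sample_names(cfg)):
        rng = np.random.default_rng([cfg.seed, 1, s_idx])
        rate = 0.0 if (species == "hirsutum" and s_idx == 0) else rate_of[species]
        copies = {"A": a_arr} if species == "longicalyx" else {"A": a_arr, "D": d_arr}
        haplotypes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for sub, src in copies.items():
            mutated, pos, alts = _mutate(src, rate, rng, cfg.ts_tv_ratio)
            hap1, hap2 = src.copy(), src.copy()
            is_het = rng.random(pos.size) < cfg.het_fraction
            which = rng.integers(0, 2, size=pos.size)
            for p, a, het, w in zip(pos, alts, is_het, which):
                if het:
                    (hap1 if w == 0 else hap2)[p] = a
                else:
                    hap1[p] = a
                    hap2[p] = a
            haplotypes[sub] = (hap1, hap2)
            _record_truth(truth, bundle.reference, name, sub, pos, src, alts, is_het)
        samples[name] = SampleGenome(name=name, species=species, haplotypes=haplotypes)
    return samples


def _record_truth(truth, reference, sample, sub, pos, src, alts, is_het) -> None:
    if pos.size == 0:
        return
    order = np.argsort(pos)
    pos, alts, is_het = pos[order], alts[order], is_het[order]
    for frag, (origin, start, end) in reference.intervals.items():
        if origin != sub:
            continue
        lo = np.searchsorted(pos, start)
        hi = np.searchsorted(pos, end)
        for p, a, het in zip(pos[lo:hi], alts[lo:hi], is_het[lo:hi]):
            truth.variants.append(
                TruthVariant(
                    sample=sample,
                    fragment=frag,
                    pos=int(p - start),
                    ref=chr(BASES[src[p]]),
                    alt=chr(BASES[a]),
                    genotype="0/1" if het else "1/1",
                )
            )


# ---------------------------------------------------------------------------
# Read simulation

def _error_quality(base_error_rate: float) -> int:
    if base_error_rate <= 0:
        return 40
    return int(min(41, round(-10.0 * math.log10(base_error_rate))))


def simulate_reads(
    sample: SampleGenome,
    cfg: SimConfig,
    out_prefix: str | Path,
) -> tuple[Path, Path]:
    """Write paired FASTQ (`_R1`/`_R2`) for one accession.

    Fragments (inserts) are drawn uniformly along each haplotype with
    normal(insert_mean, insert_sd) lengths, FR orientation, per-base
    substitution errors at base_error_rate, and constant quality strings
    consistent with that error rate. Each haplotype of a subgenome copy is
    sequenced at coverage/2, so depth at a reference locus is ~coverage.
    """
    cfg.validate()
    sample_index = hash_name(sample.name)
    rng = np.random.default_rng([cfg.seed, 2, sample_index])
    rl = cfg.read_length
    q = _error_quality(cfg.base_error_rate)
    qual_str = chr(q + 33) * rl
    r1_path = Path(f"{out_prefix}_R1.fastq")
    r2_path = Path(f"{out_prefix}_R2.fastq")
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for sub in sorted(sample.haplotypes):
            for h_idx, hap in enumerate(sample.haplotypes[sub]):
                L = hap.size
                if L < rl:
                    continue
                n_pairs = int(round(cfg.coverage / 2.0 * L / (2.0 * rl)))
                if n_pairs == 0:
                    continue
                inserts = np.clip(
                    rng.normal(cfg.insert_mean, cfg.insert_sd, n_pairs).round(),
                    rl,
                    L,
                ).astype(np.int64)
                starts = (rng.random(n_pairs) * (L - inserts + 1)).astype(np.int64)
                for i in range(n_pairs):
                    s, ins = int(starts[i]), int(inserts[i])
                    fwd = _read_with_errors(hap[s : s + rl], cfg, rng)
                    rev = _read_with_errors(hap[s + ins - rl : s + ins], cfg, rng)
                    name = f"{sample.name}:{sub}{h_idx}:{i}:{s}:{ins}"
                    f1.write(f"@{name}:R1\n{fwd}\n+\n{qual_str}\n")
                    f2.write(f"@{name}:R2\n{revcomp(rev)}\n+\n{qual_str}\n")
    return r1_path, r2_path


def _read_with_errors(arr: np.ndarray, cfg: SimConfig, rng) -> str:
    out = arr.copy()
    if cfg.base_error_rate > 0:
        err = np.flatnonzero(rng.random(out.size) < cfg.base_error_rate)
        if err.size:
            out[err] = (out[err] + rng.integers(1, 4, size=err.size)) % 4
    return _arr_to_seq(out)


def hash_name(name: str) -> int:
    """Stable small-integer hash for seeding per-sample RNG streams."""
    h = 0
    for ch in name:
        h = (h * 131 + ord(ch)) % 2_000_000_011
    return h


# ---------------------------------------------------------------------------
# Truth serialization (VCF + TSV), round-trippable

def write_truth(truth: SimTruth, outdir: str | Path) -> dict[str, Path]:
    """Write the truth VCF (1-based), homeolog-site TSV, genic BED, and
    fragment-origin TSV. Round-trips losslessly through read_truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_sample = truth.variants_by_sample()
    samples = sorted(by_sample)
    vcf_path = outdir / "truth.vcf"
    rows: dict[tuple[str, int, str, str], dict[str, str]] = {}
    for v in truth.variants:
        rows.setdefault((v.fragment, v.pos, v.ref, v.alt), {})[v.sample] = v.genotype
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for (frag, pos, ref, alt), geno in sorted(rows.items()):
            gts = [geno.get(s, "0/0") for s in samples]
            fh.write(
                f"{frag}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
    homeo_path = outdir / "homeo_sites.tsv"
    with open(homeo_path, "w") as fh:
        fh.write("fragment\tpos\n")
        for frag, pos in sorted(truth.homeo_sites):
            fh.write(f"{frag}\t{pos}\n")
    genic_path = outdir / "genic.bed"
    with open(genic_path, "w") as fh:
        for frag in sorted(truth.genic):
            for start, end in truth.genic[frag]:
                fh.write(f"{frag}\t{start}\t{end}\n")
    origin_path = outdir / "origins.tsv"
    with open(origin_path, "w") as fh:
        fh.write("fragment\torigin\n")
        for frag in sorted(truth.origin):
            fh.write(f"{frag}\t{truth.origin[frag]}\n")
    return {
        "vcf": vcf_path,
        "homeo": homeo_path,
        "genic": genic_path,
        "origins": origin_path,
    }


def read_truth(outdir: str | Path) -> SimTruth:
    outdir = Path(outdir)
    truth = SimTruth()
    with open(outdir / "truth.vcf") as fh:
        samples: list[str] = []
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            frag, pos, _, ref, alt = fields[0], int(fields[1]) - 1, *fields[2:5]
            for s, gt in zip(samples, fields[9:]):
                if gt != "0/0":
                    truth.variants.append(
                        TruthVariant(s, frag, pos, ref, alt, gt)
                    )
    with open(outdir / "homeo_sites.tsv") as fh:
        next(fh)
        for line in fh:
            frag, pos = line.split()
            truth.homeo_sites.add((frag, int(pos)))
    with open(outdir / "genic.bed") as fh:
        for line in fh:
            frag, start, end = line.split()
            truth.genic.setdefault(frag, []).append((int(start), int(end)))
    with open(outdir / "origins.tsv") as fh:
        next(fh)
        for line in fh:
            frag, origin = line.split()
            truth.origin[frag] = origin
            truth.genic.setdefault(frag, [])
    return truth
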
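"""End-to-end orchestration: simulate -> prep -> map -> call -> mask ->
collate -> genotype -> reports, with deterministic seeding and a manifest.

Each stage is an ordinary library call and individually re-runnable; the
pipeline simply wires the synthetic study panel through them with the
per-species mapping stringencies (tetraploid samples at similarity 0.98,
the diverged diploid at 0.96) and writes every artifact under one output
directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import caller as caller_mod
from . import collate as collate_mod
from . import readprep, simdata, stats, structure, subgenome
from .genotype import GenotypeParams, genotype_given_alleles, merge_final_vcf
from .mapper import MappingParams, align_sample, build_index
from .vcfio import read_final_vcf, write_sample_vcf

log = logging.getLogger("bessnp")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: Path
    sim: simdata.SimConfig = field(default_factory=simdata.SimConfig)
    prep: readprep.PrepParams = field(default_factory=readprep.PrepParams)
    mapping: MappingParams = field(default_factory=MappingParams)
    diploid_similarity: float = 0.96  # override for the diverged diploid
    caller: caller_mod.CallerParams = field(default_factory=caller_mod.CallerParams)
    collation: collate_mod.CollationParams = field(
        default_factory=collate_mod.CollationParams
    )
    genotyping: GenotypeParams = field(default_factory=GenotypeParams)

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        sim_raw = raw.get("sim", {})
        if "fragment_length_range" in sim_raw:
            sim_raw["fragment_length_range"] = tuple(sim_raw["fragment_length_range"])
        cfg = cls(
            outdir=Path(raw["outdir"]),
            sim=simdata.SimConfig(**sim_raw),
            prep=readprep.PrepParams(**raw.get("prep", {})),
            mapping=MappingParams(**raw.get("mapping", {})),
            caller=caller_mod.CallerParams(**raw.get("caller", {})),
            collation=collate_mod.CollationParams(**raw.get("collation", {})),
            genotyping=GenotypeParams(**raw.get("genotyping", {})),
        )
        if "diploid_similarity" in raw:
            cfg.diploid_similarity = float(raw["diploid_similarity"])
        return cfg


@dataclass
class PipelineResult:
    outdir: Path
    reference: simdata.BesReference
    bundle: simdata.ReferenceBundle
    samples: dict[str, simdata.SampleGenome]
    masked_calls: dict[str, list]
    homeo_mask: set
    raw_calls: dict[str, list]
    master: collate_mod.MasterSnpTable
    hirsutum_candidates: dict
    final_vcf: Path
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.sim
    manifest: dict = {"stages": {}, "files": {}}

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"][name] = "ok"

    try:
        stage("simulate")
        bundle = simdata.generate_reference(cfg)
        reference = bundle.reference
        reference.write_fasta(out / "bes.fa")
        simdata.write_fasta(out / "A_diploid.fa", [("A_genome", bundle.a_genome)])
        simdata.write_fasta(out / "D_diploid.fa", [("D_genome", bundle.d_genome)])
        samples = simdata.spike_variants(bundle, cfg)
        simdata.write_truth(bundle.truth, out / "truth")
        fastqs = {
            name: simdata.simulate_reads(genome, cfg, out / f"{name}")
            for name, genome in samples.items()
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulate", exc) from exc

    try:
        stage("prep")
        prepared = {}
        for name, (r1, r2) in fastqs.items():
            target = out / f"{name}.prepared.fastq"
            readprep.prep_fastq([r1, r2], target, config.prep)
            prepared[name] = target
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("prep", exc) from exc

    try:
        stage("map")
        index = build_index(reference, config.mapping.seed_size)
        bams = {}
        for name, fastq in prepared.items():
            params = config.mapping
            if samples[name].species == "longicalyx":
                params = dataclasses.replace(
                    params, similarity_fraction=config.diploid_similarity
                )
            bam = out / f"{name}.bam"
            align_sample(fastq, index, params, bam)
            bams[name] = bam
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("map", exc) from exc

    try:
        stage("call")
        pileups = {}
        raw_calls = {}
        for name, bam in bams.items():
            counts = caller_mod.pileup_counts(bam, reference)
            pileups[name] = counts
            columns = caller_mod.columns_from_counts(counts)
            raw_calls[name] = caller_mod.call_sample(columns, reference, config.caller)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("call", exc) from exc

    try:
        stage("homeomask")
        self_sample = next(
            n for n, g in samples.items() if g.species == "hirsutum"
        )  # first line is the reference genotype
        mask = caller_mod.identify_homeo_mask(raw_calls[self_sample])
        caller_mod.write_mask(mask, out / "homeo_mask.tsv")
        masked = {
            name: caller_mod.apply_homeo_mask(calls, mask)
            for name, calls in raw_calls.items()
        }
        for name, calls in masked.items():
            write_sample_vcf(calls, name, out / f"{name}.masked.vcf", reference)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("homeomask", exc) from exc

    try:
        stage("collate")
        line_calls = {
            n: masked[n] for n, g in samples.items() if g.species == "hirsutum"
        }
        candidates = collate_mod.hirsutum_master(line_calls)
        depth_cache = {
            n: {
                f: caller_mod.depth_array(pileups[n], f)
                for f in reference.fragments
            }
            for n in line_calls
        }
        cov_stats = {
            n: collate_mod.coverage_stats_from_depths(list(depth_cache[n].values()))
            for n in line_calls
        }

        def depth_lookup(sample: str, fragment: str, pos: int) -> int:
            arr = depth_cache[sample][fragment]
            return int(arr[pos]) if arr.size else 0

        candidates = collate_mod.coverage_filter(
            candidates, depth_lookup, cov_stats, config.collation
        )
        barb = next(n for n, g in samples.items() if g.species == "barbadense")
        long_ = next(n for n, g in samples.items() if g.species == "longicalyx")
        master = collate_mod.add_tiered(
            candidates,
            masked[barb],
            masked[long_],
            config.collation,
            barbadense_sample=barb,
            longicalyx_sample=long_,
        )
        master.write_tsv(out / "master.tsv")
        collate_mod.write_species_vcfs(master, out / "species_vcfs", reference)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("collate", exc) from exc

    try:
        stage("genotype")
        columns = [
            genotype_given_alleles(
                pileups[name], master, reference, config.genotyping, sample=name
            )
            for name in samples
        ]
        final_vcf = merge_final_vcf(columns, master, out / "final.vcf", reference)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("genotype", exc) from exc

    try:
        stage("reports")
        final = read_final_vcf(final_vcf)
        report: dict = {}
        report["tier_counts"] = master.tier_counts()
        report["tstv"] = (
            stats.tstv_table(master).reset_index().to_dict(orient="records")
        )
        report["callstats"] = (
            stats.sample_callstats(final).reset_index().to_dict(orient="records")
        )
        pi_mean, _ = stats.nucleotide_diversity(final)
        report["nei_pi"] = pi_mean
        spacing = {
            tier: stats.adjacent_spacing(master, tier)["mean"]
            for tier in collate_mod.TIERS
        }
        report["adjacent_spacing_mean"] = spacing
        overlap_sets = {
            "hirsutum": set(candidates),
            "barbadense": {
                c.key
                for c in masked[barb]
                if c.is_homozygous_alt
                and c.posterior > config.collation.min_interspecific_posterior
            },
            "longicalyx": {
                c.key
                for c in masked[long_]
                if c.is_homozygous_alt
                and c.posterior > config.collation.min_interspecific_posterior
            },
        }
        report["species_overlap"] = stats.species_overlap(overlap_sets)
        flanks = subgenome.export_flanks(master, reference, fasta_path=out / "flanks.fa")
        _table, subg_summary = subgenome.classify_subgenome(
            flanks, {"A_genome": bundle.a_genome}, {"D_genome": bundle.d_genome}
        )
        report["subgenome_fractions"] = subg_summary
        report["genic"] = (
            subgenome.genic_overlap(master, bundle.truth.genic)
            .reset_index()
            .to_dict(orient="records")
        )
        gm = structure.genotype_numeric(final)
        try:
            pca_res = structure.pca(gm)
            np.savetxt(out / "pca_eigenvalues.tsv", pca_res.eigenvalues)
            report["pca_top_eigenvalues"] = pca_res.eigenvalues[:2].tolist()
        except ValueError:
            report["pca_top_eigenvalues"] = None
        diss = structure.ibs_dissimilarity(gm)
        newick = structure.upgma_newick(diss, gm.samples)
        (out / "tree.nwk").write_text(newick + "\n")
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("reports", exc) from exc

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.suffix not in (".bam", ".bai"):
            manifest["files"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return PipelineResult(
        outdir=out,
        reference=reference,
        bundle=bundle,
        samples=samples,
        masked_calls=masked,
        homeo_mask=mask,
        raw_calls=raw_calls,
        master=master,
        hirsutum_candidates=candidates,
        final_vcf=final_vcf,
        manifest=manifest,
    )
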
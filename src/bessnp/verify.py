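"""Truth-based verification measurements on a synthetic pipeline run.

These quantify how well each stage recovers the generator's ground truth:
how much of the homeo-SNP artifact load the self-sample mask removes (and
how much real signal it spares), how sensitively the discovery caller
finds spiked homozygous variants where strict mapping provides full
coverage, and how concordant the genotype-given-alleles recall is with
truth at master positions.
"""

from __future__ import annotations

from collections import defaultdict

from .pipeline import PipelineResult
from .vcfio import read_final_vcf


def homeo_mask_efficacy(result: PipelineResult) -> dict[str, float | int]:
    """Removal rate of false calls at homeolog-difference sites (pooled
    over all non-self tetraploid samples) and retention of true spiked
    positions.

    A raw call at a homeolog-difference truth site in a sample other than
    the reference-genotype line is an artifact of cross-subgenome mapping;
    the mask should cover it. A spiked truth position, conversely, should
    never be masked.
    """
    truth = result.bundle.truth
    mask = result.homeo_mask
    homeo = truth.homeo_sites
    self_sample = next(
        n for n, g in result.samples.items() if g.species == "hirsutum"
    )
    n_false = n_removed = 0
    for name, genome in result.samples.items():
        if name == self_sample or genome.species == "longicalyx":
            continue
        raw = {c.key for c in result.raw_calls[name]}
        false_calls = raw & homeo
        n_false += len(false_calls)
        n_removed += len(false_calls & mask)
    true_keys = {(v.fragment, v.pos) for v in truth.variants}
    retained = len(true_keys - mask)
    return {
        "removal_pct": 100.0 * n_removed / n_false if n_false else float("nan"),
        "retention_pct": 100.0 * retained / len(true_keys) if true_keys else float("nan"),
        "n_false": n_false,
        "n_true": len(true_keys),
    }


def caller_sensitivity(
    result: PipelineResult, read_span: int = 87
) -> dict[str, float | int]:
    """Discovery recall of spiked homozygous variants at uniquely mappable,
    fully covered sites in the tetraploid samples.

    Eligible sites are >= read_span from both fragment ends (strict
    full-length mapping gives them full depth) and have no other truth
    variant of the same sample within read_span (so no read covering the
    site is lost to the similarity threshold).
    """
    truth = result.bundle.truth
    frag_len = {f: len(s) for f, s in result.reference.fragments.items()}
    by_sample = truth.variants_by_sample()
    total = hit = 0
    for name, genome in result.samples.items():
        if genome.species == "longicalyx":
            continue
        variants = by_sample.get(name, [])
        pos_by_frag = defaultdict(list)
        for v in variants:
            pos_by_frag[v.fragment].append(v.pos)
        called = {c.key for c in result.raw_calls[name]}
        for v in variants:
            if v.genotype != "1/1":
                continue
            L = frag_len[v.fragment]
            if min(v.pos, L - 1 - v.pos) < read_span:
                continue
            if any(
                q != v.pos and abs(q - v.pos) < read_span
                for q in pos_by_frag[v.fragment]
            ):
                continue
            total += 1
            hit += (v.fragment, v.pos) in called
    return {
        "sensitivity_pct": 100.0 * hit / total if total else float("nan"),
        "n_eligible": total,
    }


def genotype_concordance(result: PipelineResult) -> dict[str, float | int]:
    """Agreement of recalled genotypes with truth at master positions.

    Cells compared: every (sample, master position) where the sample has a
    truth variant whose alternate allele the master record carries, plus
    nothing else — the recall step cannot represent alleles outside the
    site's allele list, and positions without a truth record have no
    defined truth genotype restricted to them. Missing calls are excluded.
    """
    truth = result.bundle.truth
    final = read_final_vcf(result.final_vcf)
    rec_idx = {(r[0], r[1]): j for j, r in enumerate(final.records)}
    samp_idx = {s: i for i, s in enumerate(final.samples)}
    total = agree = 0
    by_sample = truth.variants_by_sample()
    for name, variants in by_sample.items():
        i = samp_idx[name]
        for v in variants:
            j = rec_idx.get((v.fragment, v.pos))
            if j is None:
                continue
            if v.alt not in final.records[j][3]:
                continue  # allele not representable at this site
            got = int(final.codes[i, j])
            if got == -1:
                continue
            total += 1
            agree += got == (1 if v.genotype == "0/1" else 2)
    return {
        "concordance_pct": 100.0 * agree / total if total else float("nan"),
        "n_compared": total,
    }
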
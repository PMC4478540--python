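"""Simulate a synthetic allotetraploid resequencing panel.

Builds two homeologous subgenome copies (A and D) from one ancestral
sequence, samples BES-like reference fragments from both, spikes variants
into 6 intraspecific lines plus one diverged tetraploid and one diploid,
and writes paired 2x100 bp reads plus a complete truth set.
"""

from pathlib import Path

from bessnp.simdata import SimConfig, generate_reference, simulate_reads, spike_variants, write_truth

cfg = SimConfig(
    seed=7,
    ancestral_length=20_000,
    n_fragments=32,
    fragment_length_range=(300, 600),
    n_lines=6,
)
out = Path("scratch/example_panel")
out.mkdir(parents=True, exist_ok=True)

bundle = generate_reference(cfg)
samples = spike_variants(bundle, cfg)
for name, genome in samples.items():
    simulate_reads(genome, cfg, out / name)
write_truth(bundle.truth, out / "truth")
bundle.reference.write_fasta(out / "bes.fa")

print(f"reference fragments : {len(bundle.reference)} "
      f"({bundle.reference.total_length()} bp)")
print(f"homeolog-difference sites in fragments: {len(bundle.truth.homeo_sites)}")
print(f"samples             : {', '.join(samples)}")
print(f"spiked truth variants: {len(bundle.truth.variants)}")
print(f"outputs under {out}/")
# The homeolog-difference count is the artifact load the pipeline must
# filter out; the spiked variants are the signal it must recover.
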
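# Methods

This note documents the models, parameter choices, and numerical
conventions behind `bessnp`, and what the synthetic verification does and
does not demonstrate about real data.

## The problem setting

The pipeline targets variant discovery in a recent allotetraploid whose
two subgenomes (A and D) are diverged by only a few percent. Against any
reference, short reads from the sister subgenome can mis-map wherever the
homeologs are locally near-identical; at such positions the mixed pileup
looks like a heterozygous variant shared by every sample. These
homeo-SNPs are artifacts of the reference/mapping combination, not
polymorphisms, and removing them is the pipeline's central correction.
The reference is a set of high-quality BAC-end-sequence (BES) fragments
from the same accession as one of the resequenced lines, which makes a
direct empirical correction possible: calling that line against its own
reference can only yield artifacts.

## Synthetic data generator

The generator emulates the structure of the real study panel rather than
any particular genome:

* One ancestral sequence of `ancestral_length` (default 50 kb) is mutated
  independently into A and D copies at `homeolog_divergence`/2 each, so
  the realised A–D mismatch density matches `homeolog_divergence`
  (default 0.02 per site — chosen so that an ~87-bp prepared read sits at
  the 0.98-similarity cross-mapping boundary, the regime in which
  homeo-SNPs actually arise; coincident double hits depress the realised
  divergence by ~d²/3, far inside binomial noise at ≥50 kb).
* `n_fragments` BES fragments (default 60, lengths 400–800 bp — the
  length range is a documented guess at Sanger-read scale, not a claim
  about any real library) are placed in non-overlapping slots, each drawn
  from one subgenome copy, roughly half from each. One fragment per
  region means homeolog cross-mapping is the only route by which a read
  can land on the "wrong" fragment.
* Samples: `n_lines` intraspecific tetraploid lines (default 12, matching
  the real panel; line 1 carries zero variants and plays the
  reference-genotype role), one tetraploid at `barbadense_rate` (0.005)
  and one diploid built from the A copy only at `longicalyx_rate` (0.02).
  Intraspecific lines use `line_snp_rate` (0.001). Spiked variants are
  heterozygous with probability `het_fraction` (0.1). Substitutions are
  transition-biased 2:1 (`ts_tv_ratio`), so synthetic type tables show
  the transition excess genuine SNP sets do.
* Reads: 2×100 bp, FR orientation, insert ~ Normal(300, 30) clipped to
  the read length, each haplotype of a subgenome copy sequenced at
  `coverage`/2 (default 20× per subgenome locus), uniform per-base
  substitution errors at `base_error_rate` (default 0.001) with constant
  quality strings matching that rate. No indels, duplicates, GC bias, or
  coverage heterogeneity are modelled.

Everything derives from `numpy` Generator streams keyed on the config
seed, so identical configurations give byte-identical FASTA/FASTQ/VCF.

What passing tests on this generator show: the pipeline's logic —
thresholds, filters, masking, collation, recall, statistics — behaves as
specified under the stated divergence/coverage/error regime. What they do
not show: robustness to real-data pathologies the generator omits
(repeats beyond homeologs, indels, coverage bias, paralogy from ancient
polyploidy), which is why the coverage-SD repeat filter exists but is
only lightly exercised by synthetic data.

## Mapper

Seed-and-extend with exact k-mers (k = 15) on the forward strand of the
reference; the reverse strand is covered by querying the reverse
complement of the read. Candidate diagonals are clustered and each
cluster is scored with a banded local alignment (match +1, mismatch −2,
gap −4 per base, band 10). A linear gap cost was chosen over an
affine open/extend pair because the pipeline's data contain no indels and
a single gap parameter keeps the mapper and its exhaustive-DP test oracle
exactly comparable; the banded optimum equals the full Smith–Waterman
optimum whenever indels are shorter than the band.

Acceptance is exactly `length_fraction_obs >= L AND similarity_obs >= S`,
with `length_fraction_obs = aligned read bases / read length` and
`similarity_obs = identities / alignment columns` (gap columns count in
the denominator). Free end-clipping makes the length fraction meaningful;
full-length alignment is the score optimum whenever clipping does not
pay. Best-score ties across distinct loci are resolved by
`multiread_policy`: the default `random` (seeded) keeps ambiguous
homeologous reads on the reference, which is required for the homeo-SNP
correction to be testable at all; `discard` is available.

## Caller

The genotype model is a quality-weighted binomial mixture with a flat
prior over diploid genotypes on {ref} ∪ observed alleles — the simplest
model faithful to the published filter set, whose original implementation
is unpublished. "Variant probability 50.0" is interpreted as posterior
≥ 0.5 for the best non-reference genotype. Discovery filters: depth ≥ 6,
each reported alternate observed on ≥1 forward and ≥1 reverse read, at
most 4 distinct alternates per site (with single-base substitutions only
3 non-reference bases exist, so the default can never trigger; the filter
is exercised in tests at lower settings). The discovery base-quality
floor is 0; strand is a filter, not likelihood evidence. Alternates are
reported ordered by count, ties alphabetically.

The homeo mask is the set of called positions of the reference-genotype
sample; masking is exact set subtraction by (fragment, position), hence
order-independent and idempotent.

## Collation, recall

Intraspecific candidates require a 100% homozygous non-reference call in
at least one line. The repeat filter removes candidates whose coverage in
any supporting line exceeds that line's mean + k·SD over covered
positions (depth ≥ 1); k defaults to 1, the stricter end of the published
1–2 range, and is configurable — retained sets are monotone in k.
Interspecific positions need a homozygous call with posterior > 0.98 and
are added hierarchically (hirsutum → barbadense → longicalyx), the tier
label being the first species that contained the position. Recall then
re-genotypes every sample at every master position restricted to the
site's allele list, ignoring bases below Q20, with no depth floor: zero
usable bases give an explicit missing call. Discovery and recall are
deliberately asymmetric — discovery is strict to keep the catalogue
clean, recall permissive so the final matrix has few holes.

## Statistics and structure

* Ts/Tv tables decompose multi-allelic records into one ref/alt pair per
  alternate (first-alt-only counting available); percentages print to 1
  decimal, ratios to 2.
* π is Nei's per-site diversity with the small-sample correction,
  π_site = n/(n−1)·(1 − Σ p²) over the 2·(called genotypes) alleles, and
  the summary is the mean over polymorphic sites (sites with ≥2 observed
  alleles); a per-base alternative over total BES length would simply
  rescale it.
* The pairwise matrix counts sites where two samples are homozygous for
  different alleles; heterozygous and missing sites are excluded.
* PCA mean-imputes missing dosages per site, scales by √(p(1−p)), and
  eigendecomposes the sample covariance; coordinates are eigenvectors
  scaled by √eigenvalue, so degenerate (zero-variance) components carry no
  spread, and eigenvalues below 1e−9 of the leading one are treated as
  numerical null space. Sites with zero dosage variance are excluded; an
  all-monomorphic matrix is an error.
* Distances are identity-by-state dissimilarities, mean |dosage
  difference|/2 over co-called sites (pairwise deletion). The dendrogram
  is plain average-linkage (UPGMA) with deterministic tie-breaking; the
  cited permutation-based cluster-significance machinery is out of scope.
  Newick branch lengths follow ultrametric merge heights (height =
  distance/2).
* Subgenome assignment places each ≤101-bp IUPAC-coded flank gaplessly
  and full-length (length fraction 1.0, similarity 0.96, seeds k = 15) in
  the two diploid-relative genomes; the ambiguity base matches either of
  its alleles, otherwise every flank would carry one guaranteed mismatch.
  Unique placement in exactly one genome assigns the subgenome; placement
  in both gives `both`; multiple placements within one genome give
  `unplaced`. Gapless placement is a documented substitute for the
  original aligner's unstated settings.
* Genic classification is half-open interval overlap against supplied
  (or simulated) feature intervals — an in-repo stand-in for
  protein-database annotation, which needs external databases.
* Screening rates: overall rate = Good/total; per-iteration success =
  Good/(Good+Bad) over non-NA final results, with "Maybe" assays excluded
  from both numerator and denominator; percentages to 1 decimal.

## Verification scale

The test suite and the acceptance script run the full pipeline on
scaled-down panels — 20 kb ancestral genome, 32 fragments, 6 intraspecific
lines, error-free 20× reads — once per property regime: boundary
divergence 0.02 for sensitivity/concordance, and 0.002 (cross-similarity
well above the mapping threshold) for homeo-mask efficacy. These sizes
give a few hundred truth events per measurement, enough to resolve the
90–99% levels the properties assert, while a full run stays under a
minute. Rates, coverage, and thresholds are the defaults above; only the
genome size and line count are reduced.

## Known limitations

* The caller is substitution-only; indels, haplotype assembly, and joint
  multi-sample discovery are out of scope.
* The mask inherits the sampling noise of a single self-sample run:
  artifact sites whose cross-mapped coverage hovers at the filter
  thresholds can be called in some samples but missed in the self-sample.
  At the verification scale this leaves a few percent of artifact calls
  unmasked — the measured removal rates are 93–100%, not 100%.
* Genotype-given-alleles cannot represent alleles outside a site's list;
  a sample carrying a third allele at a known site is silently genotyped
  within the list, exactly as the original recall tool behaves.
* The published Iteration-1 success figure cannot be reconstructed from
  the printed screening table's columns (which give 8/11, not 11/18);
  the package computes rates only from table contents.
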
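# Methods

## The problem and the validation design

Multicopy rDNA amplicon sequencing can, in principle, quantify symbiont
types present at a thousandth of a community — but only if sequencing
error, intra-genomic variation, and copy-number differences between
lineages are handled explicitly. `symdeep` validates its entire pipeline on
simulated cell dilution series of *known* composition: four ITS-2 types
(A13, D1, C1, C3) mixed at 0.1, 1, 5, 85, 97, 99.7 and 100 % of a combined
10⁶ cells across 15 samples, with each type serving once as the dominant
partner over backgrounds of the other three, plus pure samples for three
types. Because every simulated read carries a (type, variant) truth label,
detection limits, quantification accuracy and haplotype inference can all
be scored against ground truth.

## The simulator

**Type panel.** The default panel mirrors the divergence structure of the
real types: C1 and C3 differ by exactly one substitution — a C/T SNP at
position 212 of the C1 panel sequence, the single diagnostic site between
those types — while D1 sits ≈ 12 % and A13 ≈ 20 % away from the clade-C
pair. Each genome carries several intra-genomic rDNA variants (defaults
A13: 5, D1: 4, C1: 3, C3: 2) whose within-genome copy fractions decay
geometrically (½, ¼, …), emulating one dominant tandem-array variant with
minor co-variants. Variants differ from their founder by 1–5 mutation
events (substitutions or 1–3 bp indel runs).

**Copy numbers.** Clade D is known to carry roughly 3× the ITS-1 copies of
clade C (≈ 3,181 ± 69 per cell); per-type ITS-2 copy numbers are not
established, so the default is an equal 1,000 copies/cell for every type —
the neutral choice for a dilution-series calibration — and any mapping
`{type: copies}` can be supplied. Template choice is a single multinomial
over (type, variant) pairs with weight cell_fraction × copy_number ×
copy_fraction; the expected read fraction of type *t* is therefore
f_t = c_t·n_t / Σ_u c_u·n_u. PCR cycle counts are carried as metadata only;
no per-cycle amplification bias is modelled.

**Errors and read lengths.** Substitutions occur per base at rate 0.002
(≈ the 99.75 % per-base accuracy of cleaned-up pyrosequencing data);
homopolymer runs of length ≥ 2 gain or lose one base with probability
0.003 per run, the dominant 454 error class. Read lengths are drawn from
N(380, 40) truncated below at 150 and applied by truncating the assembled
read (barcode + forward primer + insert + reverse-complemented reverse
primer), so roughly two thirds of reads end inside the insert — as real
454 reads do. Qualities are synthesized (constant Phred 38 with a tail
decaying to 24) because only the length and mean-quality filters consume
them. Barcodes are 8-mers at pairwise Hamming distance ≥ 3; barcode and
primer bases are copied error-free so that demultiplexing against the
truth table is exact — sequencing error is confined to the biological
insert. Sample seeds derive deterministically from one series seed.

**What the simulator does not emulate** — chimeras, per-cycle PCR
duplication trees, flowgram-level noise, primer-site mutations, quality
profiles correlated with error. Consequently a green test suite
demonstrates the pipeline's logic (clustering, tie-discard mapping,
pruning, statistics) under realistic error *rates*, not robustness to
every artifact class of real amplicon data.

## Reference selection

All cleaned reads are pooled and dereplicated at 100 % identity with
prefix containment, greedily: unique sequences visited longest-first found
clusters, and a sequence that is an exact prefix of an existing
representative joins the earliest-founded such cluster. Greedy assignment
(rather than transitive closure of containment) is deliberate: a single
read truncated just before the C1/C3 diagnostic site is a prefix of both
types' representatives, and closure would merge the two types into one
cluster.

The reference cut-off works on the cluster-size histogram: size classes
are scanned from largest to smallest and the scan stops at the first class
contributing < `asymptote_gain` (default 1 %) of all reads — beyond that
point the cumulative read-fraction curve has flattened and the remaining
classes are overwhelmingly *recurrent identical errors*: at study depth
(150,000 reads) a deeply sequenced template yields, for every
(position, base) substitution and every homopolymer ±1, an expected ~5–20
identical error reads, i.e. hundreds of clusters above any fixed size
floor. The asymptote rule is what keeps the library at the scale of real
haplotypes (~12–16 references) instead of ~750. When the curve never
flattens, every cluster down to `min_cluster_size` (default 10, exposed as
a flag; reads in smaller clusters are never mapped) becomes a reference.
A selected reference differing from a ≥ 10×-larger reference by nothing
but a single one-base homopolymer indel is additionally screened out as a
pyrosequencing artifact. The known cost of the 1 % rule: a real minor
variant whose cluster gains just under the threshold (e.g. a 3 % copy
fraction of a type at ~38 % of reads) is dropped from the library; its
reads still map to the type's other variants, so type-level quantification
is unaffected — only haplotype resolution shrinks.

## Mapping

Each read is aligned semi-globally (free end gaps) to every reference at
+1 match / −1 mismatch / −2 gap. A read is **mapped** only when a unique
best score exists and alignment identity is ≥ 90 %; an exact score tie
makes it **ambiguous** and it is excluded from counts — maximum
discrimination, so reads that do not span a discriminating position can
never inflate one of two near-identical references. Identity counts
matches over aligned columns + internal gaps + unaligned query bases
(target overhangs are free), so a short accidental match inside an
unrelated sequence cannot pass as high identity.

Implementation notes: references are grouped into single-linkage families
(link distance 15 under global edit distance), and whole families are
excluded per read through the triangle inequality before any member is
touched. Candidates for the exact scorer are shortlisted by a provable
bound — score ≤ n − 2d and the best reference guarantees ≥ n − 3·d_min,
so only references with 2d ≤ 3·d_min can win or tie — making the
shortlist exact, not heuristic. Reads that are exact prefixes of a single
reference bypass alignment entirely (amplicon reads share the reference
start). For unambiguous assignments the reported score is that of the
minimum-edit alignment; the mapped/ambiguous decision itself never
depends on it. Results are cached per read sequence together with their
candidate set, and a cached result is reused after pruning whenever every
candidate survived — a restriction that keeps all candidates cannot
change the outcome.

## Annotation, pruning, consensus

References are annotated to the panel type of highest percent identity.
Exact identity ties between near-identical types are resolved by the
reference's base at a configured diagnostic site (position mapped through
the pairwise alignment with the named panel sequence); remaining ties fall
back to alignment score, and anything still tied is flagged for review
rather than silently broken. The known-dominant pruning rule removes a
reference iff it has zero mapped reads in *any* sample whose designed
fraction of its type is ≥ 85 % — such samples must contain every real
haplotype of the type. Types with no high-abundance sample are kept with a
warning. Per-type consensus sequences (star alignment to the
largest-cluster anchor, column majority, ties toward the anchor, indel
columns decided by majority presence) are reporting artifacts only:
mapping always targets the original references, because editing them
toward the consensus would collapse exactly the haplotype-level signal the
pipeline later analyses.

## Statistics

**Detection limit.** False-positive observations are the percentages of
types designed absent from a sample. The cutoff is mean + 2·SE
(SE = sd/√n). Gross contaminants are excluded first by a leave-one-out
rule: a value is an outlier when it exceeds mean + 5·sd *of the remaining
values*. The leave-one-out form is essential, not cosmetic: the largest
attainable z-score within a sample of n values is (n−1)/√n (≈ 2.7 at
n = 9), so a pooled mean + 5·sd threshold can never flag anything at this
study's n — the excluded value must not contaminate the statistics it is
tested against. Excluded values are always reported.

**Gamma rank correlation.** γ = (N_c − N_d)/(N_c + N_d) over all index
pairs; with tolerance r > 0 (robust variant), pairs differing by ≤ r in
either variable count as ties. Default r = 0. Significance is a one-sided
(positive-association) permutation test, 1000 iterations, with a +1
pseudocount so p is never exactly 0; the test is one-sided because the
validation asks specifically whether observed abundances rise with
expected ones, and the direction is switchable. Expected abundances are
cell fractions by default; a copy-number-weighted expectation is available
to study quantification bias for high-copy clades.

**Bootstrap and residuals.** Percentile (2.5/97.5) bootstrap of the mean,
1000 resamples, seeded. Residuals come from the ordinary least-squares fit
of observed on expected, with per-level counts of positive/negative
residuals summarising over/under-estimation.

**Intra-genomic inference.** A haplotype's percentage *of total mapped
reads per sample* tracks its genome's abundance across the dilution
series, so variants of one genome co-vary while different genomes do not
(the design varies them independently). Haplotype pairs with γ > 0 and
permutation p < α (default 0.05, raw p-values; a Bonferroni option exists
but defaults off) are linked; connected components are the inferred
single-genome variant groups. Within-type proportion tables (rows
renormalised to 100) are emitted for reporting. Note that within-type
proportions themselves are nearly constant across samples (copy fractions
are fixed), which is why grouping uses whole-sample percentages.
Haplotype networks collapse identical sequences (summing reads), use the
mutation distance "substitution columns + contiguous indel runs, one each"
computed on the lexicographically ordered pair (equally optimal alignments
can spread events differently, so a canonical orientation keeps the count
symmetric), and retain the union of all minimum spanning trees: an edge
survives iff its endpoints are not connected by strictly lighter edges, so
equally parsimonious connections are all shown. The distance is a
symmetric pre-metric; triangle-inequality violations are possible in
principle and are not asserted.

## Pipeline and problem sizes

`run_pipeline` executes simulate → preprocess → cluster/select → map →
annotate → prune → re-map → quantify → validate → haplotypes, writing every
stage's outputs plus a consolidated report whose read accounting
reconciles exactly (raw = unassigned + rejected + cleaned; cleaned =
mapped + ambiguous + unmapped). All stochastic stages take a single seed.
CLI stage subcommands re-run the deterministic chain from the configured
inputs, so re-running any stage from saved intermediates reproduces
identical downstream outputs.

Default problem sizes: the dilution series simulates 10,000 reads per
sample (the depth at which a 0.1 % type is expected ~10 reads, coverage
10 at the detection limit); the full 15-sample, 150,000-read pipeline run
completes in under a minute. Unit and property tests use 50–2,000 reads
per sample, which preserves every code path while keeping the suite fast;
the full-depth behaviour (background detection in ≥ 14/15 samples, γ ≥ 0.9
over the 0–5 % cells, copy-number bias) runs in the acceptance tests.

## Numerical choices and degenerate inputs

- Thresholds: min read length 150 bp (strict "less than" discards), mean
  quality 20, barcode mismatches ≤ 1, primer mismatches ≤ 2, cluster floor
  10 reads, asymptote gain 1 %, identity 90 % (annotation floor 70 %),
  high-abundance threshold 85 %, α 0.05, 1000 permutations and resamples.
- Ties: cluster representatives — longest member, then smallest read id;
  annotation — diagnostic site, then score, then flagged; consensus —
  anchor's base; mapping — any score tie is ambiguous by design.
- Degenerate inputs raise explicit signals: empty manifest, all clusters
  below the floor (`EmptyReferenceSelection`), zero-mapped samples
  (flagged, percentages NaN), constant series (`UndefinedGamma`), all-equal
  expected values in the residual fit.

## Known limitations

- The vendor quality filter of the original instrument software is
  unrecoverable; only the 150 bp length rule is guaranteed verbatim, and
  the mean-quality rule is configurable.
- Mapping discards (ambiguous ties) are type-asymmetric when types differ
  in variant structure, which shifts mapped-read percentages by a point or
  two relative to the read-draw expectation at dominant abundances; the
  read-draw itself follows the copy-number-weighted multinomial exactly.
- The e-value tie-break of BLAST-style annotation is replaced by an
  alignment-score tie-break with unresolved ties surfaced, and BLAST
  against public databases by a local curated panel.
- Statistical-parsimony networks (95 % connection limit, gaps as a fifth
  state) are replaced by the deterministic minimum-spanning network with
  the indel-run-as-one-mutation rule.
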
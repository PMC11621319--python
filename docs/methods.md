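# Methods

## Problem and model

A multiplexed single-cell experiment pools cells from several patients;
genotype-based deconvolution yields clusters of cells sharing a genotype, a
per-barcode status (singlet / doublet / unassigned) and a per-cluster
consensus genotype VCF, but no patient identities. `snpdemux` identifies the
clusters by comparing their SNP profiles to per-patient bulk variant calls.

Genotypes are diploid ALT-dosage codes over biallelic loci: 0 (hom-ref), 1
(het), 2 (hom-alt), missing. Any GT with at least one copy of the key's ALT
and at least one other allele codes 1; all-ALT codes 2; no-ALT codes 0; an
uncalled allele codes missing. Multi-allelic records are split into one
biallelic key per ALT and recoded against that ALT, so files that order ALTs
differently still harmonize. Chromosome names are compared after stripping a
leading `chr`. Indel keys are representable but excluded by default
(`--snps-only`), since matching is defined on SNPs.

The distance between cluster *c* and patient *p* is the fraction of loci
typed in both at which the codes disagree (normalized hamming distance).
Normalization is per pair — each pair divides by its own co-typed count —
because cluster profiles are heavily and unevenly missing; normalizing by a
global locus count would make sparse clusters look spuriously close to
everyone. A mismatch costs 1 regardless of dosage difference (hamming
semantics); a dosage-weighted variant (|Δcode|/2) is available as an option
but is not the default.

The cluster → patient mapping is the exact minimum-total-distance injective
assignment (Kuhn–Munkres, via `scipy.optimize.linear_sum_assignment`), not a
row-wise argmin: with noisy profiles two clusters can both be nearest the
same patient, and only the global assignment resolves that consistently. The
reported per-cluster margin (second-best minus chosen distance) lets users
audit rows where the global optimum departs from the row minimum; margins can
legitimately be negative and are reported as-is. With more patients than
clusters the surplus patients are listed as unmatched; more clusters than
patients is an error (the pool cannot contain a patient twice).

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `min_support` | 50 loci | minimum co-typed loci for a (cluster, patient) pair to be trusted; under-supported pairs get a finite penalty cost of 2.0 (> any valid distance ≤ 1) so the assignment stays solvable but such pairings are last-resort. A cluster under-supported against *every* patient is an error, not a silent guess. |
| `min_qual` | 20 | VCF records below this QUAL are skipped; records with missing QUAL (cluster consensus VCFs) are kept. |
| `min_depth` | 5 | records with `INFO/DP` below this are skipped, mirroring common bulk variant-calling minimum-coverage settings; no filter when DP is absent. |
| `snps_only` | true | restrict to single-nucleotide substitutions. |

Cohort evaluation: a SNP is *present* in a sample when its code is 1 or 2 —
a call record only exists where an ALT was observed — while pairwise
discriminatory counts use every co-typed locus including hom-ref, because a
0-vs-2 disagreement discriminates just as well. Pool selection maximizes the
minimum pairwise discriminatory count (bottleneck objective): the worst pair
is what limits demultiplexing, and protecting it is the conservative choice.
Search is exhaustive up to 12 samples and greedy (best pair, then
argmax-of-min additions) above; ties break to the lexicographically first
subset of sample ids.

Region stratification classifies each variant position with priority
CDS > 5'UTR > 3'UTR > intron > other; positions outside all intervals are
intergenic, so every variant lands in exactly one category and counts sum to
the locus count. When a GTF carries no intron features they are derived per
gene as gene span minus exon spans (a gene with no exon lines therefore
contributes its whole span as intron — documented behaviour, not a bug).
BED input (class in column 4) is converted from 0-based half-open to the
internal 1-based inclusive convention at the boundary.

## Benchmarking

Per-cell precision/recall against reference labels: TP are cells whose
predicted label equals the reference label; FP are cells predicted with any
*valid* reference-label value, minus TP; FN are reference-labeled cells minus
TP. Doublet/unassigned predictions are not valid label values and contribute
to FN only. With nothing assigned, precision is undefined and reported as
NaN. The assigned-cell fraction counts patient-assigned singlets plus doublet
calls over all cells.

The downsampling experiment draws, per fraction × replicate, a uniform random
subset of bulk loci without replacement (no stratification) and reruns
distance → assignment → propagation → precision/recall. RNG substreams are
keyed by (fraction index, replicate) off one master seed, so extending the
fraction grid never perturbs existing runs; fraction 1.0 skips the draw
entirely, making its replicates identical by construction. A fraction that
leaves a cluster without `min_support` co-typed loci is recorded as a failed
run with its reason, never silently dropped.

Paired configurations are compared with a two-sided Wilcoxon signed-rank test
on per-replicate differences; zero differences are dropped (and counted), and
an all-zero vector short-circuits to a flagged p = 1 rather than an
exception. Doublet-call agreement is the overlap fraction
|method ∩ reference| / |reference| plus the pairwise method × method Jaccard
table; no multiple-testing correction is applied across fractions.

## Synthetic cohorts

The simulator emulates every pipeline input with known truth: per locus an
ALT allele frequency p ~ Uniform(0.05, 0.5); patient genotypes drawn
independently under Hardy–Weinberg ((1−p)², 2p(1−p), p²); cluster profiles
are the patients' genotypes under a random bijection, degraded by independent
per-entry missingness (default 0.5, emulating sparse single-cell SNP
recovery) and a symmetric error that replaces a typed code by one of the
other two codes with equal probability (default 0 for the clean condition;
0.05 in the noisy-recovery condition). Defaults — 5 patients, 10,000 loci,
1000 cells, 5% doublets — describe a desk-scale pool sized so the full test
suite and the acceptance script run in seconds. Doublets affect only
`clusters.tsv` statuses, as in real deconvolution output; cluster genotypes
come from singlets. Barcodes are deterministic unique 16-mers with a `-1`
suffix (10x format). Simulated bulk VCFs contain one record per locus
*including* hom-ref and missing genotypes, unlike typical call sets that hold
only ALT records; this makes the write/read round trip exactly lossless
(code 0 vs absent key is preserved) while leaving presence semantics (code ∈
{1, 2}) unchanged.

What the simulation does **not** model: read-level noise, allelic dropout
correlated with expression, ambient RNA, linkage between loci, doublet
genotype mixtures, or miscalled singlet/doublet statuses. Passing tests
therefore demonstrate correctness of the matching and benchmarking machinery
under the stated noise model, not field performance on real sequencing data.
The `perturb_profiles` fixture generator covers the main real-world failure
mode the cohort checks exist for: two patients with (near-)identical
profiles, which pool selection must split and which matching cannot resolve.

## Numerical and design choices

* All outputs are deterministic: loci sorted by (chrom, pos, ref, alt),
  tables barcode-sorted, no timestamps, fixed RNG streams — identical inputs
  give byte-identical files.
* Assignment ties resolve to the solver's lowest-index solution; pool-
  selection ties to the lexicographically first subset; group-assignment
  ties are resolved by index and flagged with a warning.
* Distances with zero co-typed loci are NaN, never 0.
* The brute-force permutation minimum used to validate the assignment lives
  only in the test suite and acceptance script; the implementation never
  calls it.
* Problem sizes in tests and the acceptance script (≤ 10,000 loci, ≤ 8
  patients, ≤ 1000 cells, 100 noisy replicates) were chosen as the smallest
  scales at which the statistical checks (Hardy–Weinberg fractions, binomial
  doublet counts, recovery rates) have adequate power.

## Limitations

* Consumes variant calls; it does not call variants, parse BAMs, or lift
  over genome builds — inputs must share a reference.
* The group-assignment path (clusters → known cell tags/clusters) assumes
  majority overlap identifies the group; it is a contingency-table argmax,
  not a probabilistic model.
* Precision/recall follow the per-cell definitions above; cells absent from
  the reference are not scored.
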
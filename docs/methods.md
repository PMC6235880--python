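# Methods

## Scope and data model

The package analyses *trios*: matched normal, primary-tumor and metastasis
whole-genome samples from one patient. The atomic unit is a variant record
(chromosome, 1-based position, ref/alt alleles, per-sample ref/alt read
counts, an upstream caller's somatic/germline verdict, and an optional
trinucleotide context). Coordinates are 1-based inclusive in memory; BED
inputs are shifted at the I/O boundary; `chr` prefixes are stripped.
Multi-allelic sites are split into one record per alternate allele and
treated independently downstream. Records without usable depth are
rejected at parse time rather than treated as zero, because every
downstream rule divides by depth.

## Tumor-in-normal rescue (TiNDA)

Tumor DNA in the matched normal inflates the control B-allele frequency at
true somatic sites, so the upstream caller labels them germline. For each
tumor (and metastasis) sample we form one point per mutated position —
(control BAF, sample BAF) — after removing positions on a user-supplied
common-variant list, then cluster the points and call a cluster
tumor-in-normal when

- ≥ 75% of its points lie strictly above the identity line, and
- its centroid sample MAF exceeds 0.01, and
- its centroid control MAF is below 0.45.

Germline-labelled members of qualifying clusters are promoted to somatic
(in both tumor and metastasis — the mutation is one event); somatic calls
are never demoted.

**Clustering choice.** The procedure needs the germline-heterozygous mode
near (0.5, 0.5) to remain a single cluster. Inertia-minimizing partitioning
(k-means) tends to split that blob down the identity line, and the upper
half-cluster — ≈100% of points above the line, centroid control BAF just
under 0.45 — then satisfies the cluster rules, mass-rescuing true germline
sites. We therefore cluster with a Bayesian Gaussian mixture capped at 9
components (full covariances, 100 EM iterations, fixed seed, single pass —
no model-selection loop). Ties and stray points are handled by a second
guard: a germline member of a qualifying cluster is only rescued if it
individually satisfies the same three bounds. Whether the original
procedure applied the MAF bounds per cluster or per point is not
documented; we apply them at the cluster level and use the per-point form
as a guard, both configurable. Points are sorted by variant key before
clustering, making the rescue set invariant to input order.

## Stratification with MAF cross-rescue

Somatic SNVs of a trio are the union of positions called somatic in tumor
or metastasis (after TiNDA). Presence in the sample *without* a direct
call is granted when its MAF is strictly above 5%, carries at least 2 alt
reads, and is at least twice the control MAF (a control MAF of 0 leaves
only the first two conditions — the ratio rule exists to exclude germline
leakage). Presence flags map to strata: both → shared (truncal), one →
tumor- or metastasis-private. Fractions are reported over somatic SNVs;
indels are stratified under the same rules but flagged as an extension and
excluded from the fractions.

The 2-read floor is a fixed constant, motivated by the expected read
support of a single-copy variant, purity × coverage / ploidy (5.7 reads at
the series medians 0.475, 36×, triploid). `min_alt_reads_for_maf` is
provided as a diagnostic for other coverages. `poisson_support_probability`
is the plain Poisson pmf; note that the pmf at k = 2, μ = 5.7 is ≈ 0.054,
an order of magnitude below a sometimes-quoted 0.54 for the same point —
we implement the standard pmf and do not guess at a different intended
quantity (CDF or survival values differ again).

## Mutational signatures

Catalogs count SNVs over the 96 pyrimidine-centered trinucleotide
substitution classes; purine-reference records are reverse-complemented,
contexts containing N are skipped and counted. Exposures solve the NNLS
problem `argmin_{e≥0} ‖C − W e‖₂` (scipy's Lawson–Hanson solver); the
residual norm is reported. Signature-specific cutoffs act on normalized
exposures: the signature furthest below its cutoff is removed and the fit
re-run, one signature per iteration, until all survivors meet their
cutoffs. One-at-a-time removal keeps the result aligned with the best
admissible subset (bulk removal can discard a signature that would clear
its cutoff after re-fitting); on random 5-signature problems the procedure
matches an exhaustive subset search. The default global cutoff is 0.06 on
normalized exposure, overridable per signature — the cutoffs actually used
by the original analysis are not published. Cohort-level detection fits
the summed cohort catalog with cutoffs; surviving signatures define the
restricted matrix for all per-sample/per-stratum fits.

Strata comparisons use a two-sided **paired Wilcoxon signed-rank test**
per signature across patients (exact distribution for n ≤ 25 without
ties; p = 1 when all paired differences vanish), BH-corrected across
signatures within each strata pair. The original analysis names only the
BH correction, so the test itself is a documented choice. Group
associations (e.g. diploid vs aneuploid) use two-sided Mann–Whitney U,
exact for small tie-free samples. Unsupervised clustering of exposure
matrices is agglomerative with complete linkage and Euclidean distance.

**Signature matrix.** The bundled default is a *synthetic* 96 × 30 matrix
(sparse Dirichlet columns in the COSMIC-v2 layout, ids AC1…AC30) generated
deterministically by `synthetic_signature_matrix`. It mimics the shape of
a curated reference set for simulation and testing and must not be used to
interpret real tumors; real analyses should load a curated matrix via
`read_signature_matrix` (TSV, context labels in the first column).

## Kataegis

Per sample, any run of ≥ 5 consecutive mutations on one chromosome
spanning ≤ 10,000 bp (inclusive, last − first) seeds a locus; overlapping
or index-adjacent qualifying runs merge into maximal loci whose members
are all mutations in the merged range. The detector is equivalent to a
brute-force scan over all contiguous mutation subsets (property-tested).
No per-strand or substitution-class refinement is applied. A locus is
proximal to a gene when locus span and gene span are within 10 kb
(inclusive; overlap = 0). Regions where loci from ≥ 2 samples intersect
are reported as recurrent.

## Copy number

Segments, purity and ploidy are consumed as inputs (the upstream
allele-specific caller is out of scope). A segment is a gain/loss when its
total copy number deviates from the sample's base ploidy by strictly more
than 0.7 (an exact 0.7 deviation is neutral; the comparison is guarded
against binary round-off). LOH means minor-allele copy number < 0.5
(i.e. rounds to zero); unknown minor copy number yields an unknown LOH
state. Arm-level recurrence counts, per arm, the proportion of samples
with ≥ 1 overlapping gain/loss/LOH segment; denominators are samples with
any segment data on that chromosome; centromere-spanning segments count
for both arms; sex chromosomes are excluded by default.

## Cohort statistics

Mutation matrices (genes × samples, binary) are kept per analysis channel
— coding non-silent, non-coding exonic, 3′-UTR — matching the separate
recurrence analyses these channels feed. Without transcript sequence, all
CDS SNVs count as potentially non-silent unless a codon-aware annotation
marks them synonymous; 3′-UTR hits are tracked but are not mutations of
interest. A gene pair is mutually exclusive when at most one sample
carries mutations in both (the alternative reading — at most one sample
mutated in either — would contradict the genes being recurrently
mutated); significance comes from the two-sided Fisher exact test under
the probability-mass rule. χ² tests are Pearson without continuity
correction; enrichment is upper-tail hypergeometric; all families are BH
(step-up) corrected.

## Synthetic cohorts

The generator emulates a 12-patient colorectal trio cohort: per trio
5,000–17,000 somatic SNVs (strata drawn multinomially with fractions
0.65/0.15/0.20 — the published 19% metastasis share is kept as 20% so the
fractions sum to 1), tumor and metastasis purity uniform on [0.35, 0.85],
ploidy drawn from {2, 3}, 36× mean coverage. One dominant clone per
stratum and one mutated copy: expected VAF = purity / (purity × CN +
2(1 − purity)) with CN = ploidy. Read support is depth ~ Poisson(coverage)
truncated at ≥ 1 and alt ~ Binomial(depth, VAF). The emulated caller flags
a record somatic at alt ≥ 3 and MAF ≥ 5%, so low-VAF variants genuinely
require cross-rescue. 5% of truncal variants are contaminated (true
normal VAF uniform on (0.01, 0.15)) and flagged germline in both tumor
and metastasis, exercising TiNDA. 1,000 germline heterozygous sites per
trio (BAF 0.5 everywhere) are generated, 90% of them listed as common
variants, leaving a rare-het cloud the common-variant filter cannot
remove. Contexts are drawn from per-stratum signature exposures (truncal:
clock-like + mismatch-repair-defect; private strata add a
double-strand-break-repair component); half the records are stored on the
purine strand to exercise strand collapsing. Positions are uniform over a
configurable genome (default: the 22 autosomes at GRCh37 lengths).
Everything derives from one seeded generator: identical seeds give
bit-identical datasets.

What the generator does **not** emulate: subclonal structure and multiple
mutated copies (VAF spread beyond binomial noise), mappability and
coverage biases, sequencing errors (no false-positive alt reads),
clustered germline variation, realistic gene footprints (synthetic gene
models are uniform), and copy-number heterogeneity within chromosomes
(synthetic segments are whole-chromosome). Passing tests therefore
demonstrate correctness of the rules and estimators under the stated
noise model, not robustness to artefacts of real sequencing data.

## Problem sizes and numerical choices

Default verification runs use 12 trios × 10,000 SNVs (cohort
stratification), 200 random catalogs (NNLS vs bounded-least-squares
oracle), 500 random chromosomes (kataegis vs brute force), and pooled
3-trio TiNDA experiments — sizes chosen so the whole suite completes in
well under a minute per stage on a single core while keeping multinomial
sampling error far below the tolerances tested. Signature-matrix columns
must sum to 1 within 1e-3 on input (then renormalized exactly); catalogs
with zero total are rejected rather than fitted; empty clusters are
ignored; ties at the CNA threshold and at the identity line are resolved
conservatively (neutral / not-above). Seeds derived for per-trio
generators stay below 2³¹.

## Known limitations

- TiNDA false rescues are not exactly zero: an occasional rare germline
  het realized far from (0.5, 0.5) can satisfy all bounds inside a
  qualifying cluster (measured ≤ ~1% of het sites at the default
  conditions).
- Without transcript sequence, silent CDS SNVs inflate the non-silent
  channel unless a codon-aware annotation is supplied.
- The cluster-level 75%/1%/45% bounds and the 0.06 exposure cutoff are
  configurable defaults; the values used by the original analyses of the
  corresponding real cohort are not all published, so numerical agreement
  with that analysis on real data is not guaranteed.
- Indel stratification follows the SNV rules and is flagged as an
  extension; no indel-specific error model is applied.
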
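# Methods

This note documents the models, parameters, numerical choices, and known
limitations behind `homeopipe`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The synthetic study generator (`synthsim`)

The generator emulates the structure of a two-accession allopolyploid
RNA-seq comparison with complete ground truth. Its defaults describe the
full-scale study conditions; analyses and tests use
`SimulationConfig.desk_scale()`, which shrinks sizes while preserving the
structure (the problem sizes used by each analysis and test are stated in
their drivers and docstrings as the package's own choices).

**Subgenomes.** Each homoeolog pair descends from a random uniform-ACGT
ancestor. Both copies are mutated independently, substitutions only, with
transitions and transversions equiprobable (downstream logic is indel-free
by design — accession comparison removes indels anyway). The per-copy,
per-site rate $m$ solves $2m - \tfrac{4}{3}m^2 = d$ so the *expected
pairwise difference* equals the configured divergence $d$ exactly,
accounting for coincident double hits (two independent mutations agree with
probability 1/3). Default $d = 0.17$ — the ~83% transcript identity of the
AT/AA system. Unpaired genes get novel random sequences. Transcript lengths
are uniform on a configurable range; the generator rejects ranges whose
lower bound is below the downstream k-mer size.

**Accession variants.** Each accession carries
`accession_snp_rate × total AT bp` substitutions on the AT subgenome
(transcript space, homozygous): a *shared core* — identical position and
allele in both accessions, fraction `shared_snp_fraction` (default 0.724,
the shared fraction observed in the two-accession comparison regime) — and
a private remainder. Configured fractions of each category (defaults 0.75
shared, 0.5 private) are also planted into one uniformly chosen member of a
reference panel, so all six cells of the shared/private × in-panel/
not-in-panel partition have construction-known counts; panel members
additionally carry independent background SNPs at disjoint sites. The
default `accession_snp_rate = 0.005`/bp is a free parameter (no per-bp
density is published for the system); at the full scale (13,394 pairs of
~1 kb) it yields ~65k SNPs per accession, the observed order of magnitude.
Planted quality scores are uniform on [20, 60], straddling the >30
reporting filter.

**Expression.** Baselines are log-normal (ln-scale mean 3.0, σ 1.2 —
heavy-tailed like real FPKM distributions, chosen without fitting real
data). Homoeolog partners are *correlated*: both members share a per-pair
level and deviate from it by a smaller log-normal factor (ln σ 0.3), as
real homoeologs do; without this, per-pair dominance ratios would carry the
full cross-gene variance and genome-wide dominance estimates would be
needlessly noisy. The AT subgenome is multiplied by
$2^{\texttt{dominance\_log2}}$ (default 1.0, i.e. 2×). `n_de_genes` genes
receive a ±`de_log2fc` accession effect; `n_coordinated_pairs` of those DE
slots are applied to both members of a homoeolog pair in the same
direction, and the remaining singleton DEGs are chosen so their partner is
never DE (keeping the truth's pair decomposition unambiguous).

**Replicates and reads.** Each replicate jitters per-gene expression by a
log-normal factor (`replicate_log_sd`, default 0.1 ln-scale ≈ 10% CV) —
the biological variability of pooled-tissue replicates grown in a
controlled chamber. Fragment counts per gene are multinomial with
probabilities ∝ expression × length (so FPKM truth is
expression-proportional); fragment lengths are Gaussian (default mean 515,
matching a standard mRNA library insert), clipped to [read length,
transcript length]; when a transcript is shorter than the read length both
mates are the whole fragment (overlapping-mates policy, not an error).
Per-base errors substitute a uniformly random other base. FASTQ quality
strings are constant (the assigner ignores them); read names carry only a
serial, truth lives in the origin table. All randomness flows from one
seed; identical config + seed reproduces outputs bit-identically.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: splicing/isoforms, indels, GC/positional
sequencing bias, organellar transcripts, unequal library sizes,
count overdispersion beyond the log-normal replicate model, genes present
in only one subgenome's annotation, and reference/assembly error. The
misassignment rate of 0 observed on error-free synthetic reads reflects
the idealized uniform-random divergence model; real homoeolog divergence
is clustered and real transcriptomes contain recent paralogs, so real
ambiguity rates are higher.

## Read assignment (`subassign`)

A production mapper is deliberately not reimplemented; at transcript scale
a canonical k-mer score reproduces the decision that matters — *which
subgenome, which gene*. Each fragment is scored per subgenome as the
maximum over genes of shared canonical k-mers summed across mates
(canonical = lexicographic min of k-mer and reverse complement, giving
strand-agnosticism without alignment; a k-mer repeated within a gene counts
once). The winner takes the fragment if its lead over the other subgenome
is at least `min_margin`, else the fragment is ambiguous; zero score on
both sides is unmapped. Defaults k = 21, margin = 2: at 17% divergence a
21-mer is conserved between homoeologs with probability ≈ 0.83²¹ ≈ 2%, so
a 2×150 bp fragment typically carries >100 diagnostic k-mers and the margin
is rarely binding. Ties on score break lexicographically by gene ID
(deterministic). Ambiguous fragments are excluded from per-gene counts but
included in the library-wide mapped total used as the FPKM denominator —
the behaviour of a mapper that reports multi-mapped reads; the choice is
documented here and switchable by constructing counts differently.

`separate_alignments` preserves the external-mapping path: SAM records are
routed by the subgenome of their reference sequence, order-preserving,
unmapped records dropped and counted, unknown references an error.

For variant calling, assigned mates are anchored to their transcript by
modal (orientation, offset) voting over matching k-mers and piled up
ungapped — adequate because the simulation and the intended inputs are
indel-free.

## Expression and differential expression (`expression`)

FPKM uses the whole-library mapped total (both subgenomes + ambiguous) so
homoeolog FPKMs within a sample share a denominator. The conservation
identity $\sum_g \mathrm{FPKM}_g \ell_g M / 10^9 = \sum_g c_g$ is asserted
to 1e-9 in tests.

The DE stage is a documented stand-in for a full RNA-seq model: a
two-sample **pooled-variance** t-test on $\log_2(\mathrm{FPKM}+1)$ with BH
correction at q ≤ 0.05. The pooled (rather than Welch) variant is a
deliberate choice: with three replicates per group Welch's Satterthwaite
degrees of freedom are so noisy that the test is measurably conservative
(null rejection ≈ 0.035 at α = 0.05 even on ideal normal data), while the
pooled test is exactly calibrated under the homoscedastic log-scale
replicate model the generator implements — and the suite verifies that
calibration within 3 binomial SE over 50 null studies. Genes with zero
counts in every sample are skipped; two constant groups get p = 1 by
convention. Direction is the sign of the fold change of group 2 over
group 1 (pseudocount 1).

A scope note on false discoveries: because FPKM measures *relative*
abundance, strongly DE genes shift every other gene's FPKM between groups
(compositional effect). No between-library normalization factors are
computed (out of scope), so the FDR of the DE stage is well behaved only in
the realistic regime where DE genes are a small fraction of transcriptional
mass (~0.5% of genes in the motivating comparison); the recovery test runs
in that regime deliberately.

Dominance ratios follow the "ratio of averages" convention: per pair,
$\log_2$ of (group-mean AT FPKM / group-mean AA FPKM), with pairs excluded
and counted when either side's mean is zero. Positive `dominance_log2`
means AT-dominant; the sign convention is reported, not interpreted,
because the direction of genome-wide dominance is exactly what a user would
want to measure rather than assume.

## Pair statistics (`homeostats`)

`join_pairs` decomposes a DEG list against the homoeolog map; the
identities total = AT-only + AA-only + 2×pairs and per-subgenome total =
only + pairs hold by construction and are fuzz-tested.

The permutation test draws without replacement from the *full quantified
universe* — paired and unpaired genes alike — since that is the pool DE
calling samples from. Implementation is vectorized: batched rejection
sampling (redraw only rows with duplicate indices) for sparse draws, or
random-key partial sort for small/dense universes; pair counting sorts each
row's pair codes and counts adjacent equal non-negative codes (each code
occurs at most twice, so each adjacency is one complete pair). $10^6$
replicates of 148 from 26,788 genes run in well under a minute. The add-one
estimator never reports p = 0; the null maximum is recorded to support
"no replicate reached the observed count" statements.

The exact oracle enumerates draw compositions (j complete pairs, m half
pairs, rest singletons) with exact integer arithmetic — `math.comb` and
`fractions.Fraction` — and is itself validated against brute-force
`itertools.combinations` enumeration on all universes ≤ 8 genes. The
closed-form expectation $E[K] = P\,n(n-1)/(N(N-1))$ checks the permutation
histogram mean.

Degenerate inputs: observed pairs > ⌊n/2⌋ is rejected as impossible;
a universe smaller than the draw is an error; n = 1 yields the trivial
null.

## Variants (`variation`)

A full genotyper is not reimplemented: the accessions are homozygous inbred
lines and variants live in transcript space, so a consensus threshold
(depth ≥ 4, alt fraction ≥ 0.9) suffices, with a Phred-scaled quality from
the upper binomial tail of the alt count under a 1% per-base error model,
capped at 60. Users with proper caller output can supply VCFs instead; the
VCF path (CHROM = transcript, POS 1-based) round-trips through cyvcf2.

SNP identity is the key (transcript, position, alt) — the semantics of
merging per-sample VCFs for comparison; quality filtering retains strictly
> 30; indel removal precedes counting. Panel membership means presence in
≥ 1 panel member. The chi-square SNP-in-DEG test defaults to the two-cell
bp-weighted goodness of fit (expected in-DEG SNPs = total × DEG-bp share);
a 2×2 contingency variant (no continuity correction) sits behind a flag
because the published table layout is ambiguous between the two. Panel
matching is Jaccard over keys, descending, ties broken lexicographically
and flagged.

## Term enrichment (`enrichment`)

Plain one-sided Fisher (upper hypergeometric tail) per term, uncorrected,
with the reporting filter p < 0.05 *and* ≥ 2 annotated genes in the DEG
set (both strict as published). The weighted parent–child-decorrelated
algorithm of topGO is out of scope, so enriched-term lists will not match
outputs of that tool; the stage tests over-representation only. Stress
categories come from a user-supplied term→category table (the motivating
study assigned them manually); a gene annotated with a mixture of distinct
stress categories collapses to "general". Null calibration of the discrete
hypergeometric p-values is tested via a randomized-PIT transform.

## Workflow (`workflow`)

`run_pipeline` executes simulate → assign → quantify → DE → pair stats →
dominance → SNP calling/partition → chi-square → enrichment in-process, one
replicate per accession feeding SNP calling (matching the single-replicate
variant analysis of the motivating design), and assembles a JSON-serializable
report whose arithmetic identities `verify_report` asserts. Config + seed
fully determine the report (verified bit-identically in tests). The
`from-fastq` / `from-alignments` modes run the expression and pair stages
on user data; variant and enrichment sections there require user VCFs and
annotations and are left empty. Enrichment inside the simulate-mode
pipeline uses synthetic annotations with a few deliberately DEG-biased
terms so the stage has true positives to find.

## Problem sizes

Analyses and the acceptance script run the desk-scale study: 200 pairs +
40 unpaired genes, 6 × 60,000 fragments, 5-member panel — sizes chosen so
a full end-to-end run completes in minutes on one CPU while every stage
retains measurable signal. The headline permutation runs at full published
scale (13,394 pairs, 10⁶ replicates) because it is cheap once vectorized.
DE parameter-recovery tests use count-level simulation (the multinomial
layer without read sequences) at 4×10⁶ fragments to reach the "deep
counts" regime where Poisson noise is negligible for low-expression genes.

## Known limitations

- Ungapped transcript-space model throughout: no splicing, indels, or
  genomic coordinates.
- The k-mer assigner is not a read mapper; quality-aware or gapped
  alignment is out of scope, and `min_margin` is an explicit stand-in for
  whatever multi-mapping resolution a real mapper would apply.
- The DE stage is a pluggable simple test, not a dispersion-modelling
  RNA-seq method; see the compositional caveat above.
- The SNP caller assumes homozygosity; heterozygous or polyploid genotype
  calling is out of scope.
- The permutation null is draw-uniform; expression- or length-matched
  nulls are deliberately not implemented.
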
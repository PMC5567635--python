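# homeopipe

Subgenome-aware transcriptome analysis for allopolyploid plants.

An allopolyploid such as *Arabidopsis suecica* carries two complete parental
subgenomes — an *A. thaliana*-derived ("AT") and an *A. arenosa*-derived
("AA") complement — whose homoeologous transcripts share only ~83% sequence
identity. Comparing two natural accessions of such a species raises
questions that ordinary RNA-seq pipelines do not answer directly:

- Which subgenome did each read come from, and hence which **homoeolog** is
  expressed?
- Among the genes differentially expressed between accessions, do complete
  **homoeologous pairs** (both members DE) occur more often than chance —
  evidence of *trans*-acting, pair-coordinated regulation?
- Is one subgenome globally **dominant** in expression?
- How do the accessions' transcript-space **SNPs** partition into shared,
  accession-private, and reference-panel-overlapping classes?

`homeopipe` implements the full analysis as a tested library plus numbered
analysis scripts, driven by a synthetic allopolyploid study generator so
every stage can be validated against known ground truth without any
external data.

## The statistics at the core

**Pair-enrichment permutation test.** Let the quantified universe hold
$N$ genes of which $P$ pairs are homoeologous, and let $n$ genes be called
DE with $k$ complete pairs among them. Each permutation replicate draws $n$
genes uniformly without replacement and counts complete pairs; over $B$
replicates the empirical p-value is

$$p = \frac{1 + \#\{b : k_b \ge k\}}{1 + B},$$

and the largest $k_b$ seen (the *null maximum*) is recorded, so $p <
10^{-6}$ is reportable exactly when no replicate of $10^6$ reaches the
observed count. An exact dynamic-programming oracle computes the same tail
in closed form,

$$\Pr(K \ge k) = \frac{\sum_{j \ge k} \binom{P}{j} \sum_m \binom{P-j}{m} 2^m \binom{S}{\,n-2j-m}}{\binom{N}{n}},$$

with $S = N - 2P$ singleton genes, and the two routes are cross-checked in
the test suite.

**Direction concordance.** For the $k$ complete pairs, an exact two-sided
sign test on same-direction regulation: $p = \min(1,\, 2\Pr(X \ge
\max(c, k-c)))$, $X \sim \mathrm{Bin}(k, 1/2)$. All 21 of 21 pairs
concordant gives $p = 2^{-20} \approx 9.5\times10^{-7}$.

**Quantification.** Fragments are assigned to subgenome and gene by shared
canonical k-mer counting against the two transcript sets (k = 21, winner
must lead by ≥ 2 k-mers), then
$\mathrm{FPKM}_g = 10^9 c_g / (\ell_g \cdot M)$ with $M$ the library-wide
mapped total. Differential expression is a pooled-variance t-test on
$\log_2(\mathrm{FPKM}+1)$ with Benjamini–Hochberg correction; subgenome
dominance is the per-pair $\log_2$ ratio of group-mean AT over AA FPKM,
excluding pairs with a zero mean on either side.

**Variants.** A homozygous consensus caller (depth ≥ 4, alt fraction ≥ 0.9,
Phred-scaled binomial quality) yields per-accession SNP sets keyed by
(transcript, position, alt); set algebra produces the pairwise
shared/private partition and the six-cell partition against a reference
panel, with a bp-normalized two-cell chi-square test for SNP enrichment in
DEG sequence and Jaccard ranking of panel members.

## Worked example

The numbered scripts under `analysis/` run one synthetic study (seed 17,
200 homoeolog pairs, 2 accessions × 3 replicates × 60,000 150-bp paired-end
fragments) end to end:

```bash
python analysis/01_simulate_study.py
python analysis/02_assign_and_quantify.py
python analysis/03_differential_expression.py
python analysis/04_homoeolog_pair_statistics.py
python analysis/05_snp_partition.py
python analysis/06_term_enrichment.py
```

Output of steps 02–04 (abridged):

```
assigned 360000 fragments across 6 samples
  misassigned (wrong gene) : 0 (0.00%)
  ambiguous                : 0 (0.00%)

tested 440 genes; 22 significant at q<=0.05
  vs planted truth (30 DE genes): TP=20 FP=2 FN=10
  acc1 dominance: mean log2(AT/AA) = +1.021 (truth +1.0)

DEG decomposition: 4 AT-only + 8 AA-only + 2x5 pairs = 22
study-universe permutation (100000 reps): p = 2e-05, null max = 5; exact tail = 2.15e-05
direction concordance: 5/5 same direction, sign-test p = 0.0625
full-scale permutation (13,394 pairs, draw 148, observed 21, 10^6 reps):
  p = 1e-06 (< 1e-6: True), null max = 6
```

Reading this: at 17% divergence the k-mer assigner resolves every fragment
to its true gene; the DE stage recovers 20 of 30 planted effects (the
misses are low-coverage genes) with 5 of the 8 planted coordinated pairs
surviving as complete DEG pairs; the permutation test puts that pair count
far in the null tail and agrees with the exact oracle; and at full study
scale a million random 148-gene draws from a 13,394-pair universe never
produce 21 complete pairs, bounding the empirical p below 10⁻⁶ with a null
maximum of 6. Tables land under `results/`; bulky regenerable study data
(FASTQs) under `scratch/`.

## Layout

```
src/homeopipe/      library: synthsim, subassign, expression, homeostats,
                    variation, enrichment, workflow, core
analysis/           numbered narrative drivers over the library
tests/              pytest suite incl. acceptance checks and property tests
scripts/            acceptance.py
docs/methods.md     model, parameter, and design notes
```
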
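# Methods

This note documents the models, conventions and numerical choices behind
`pgxkit`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Content model

A *content bundle* is a TSV directory holding the assay's reportable
range: target variants (GRCh38, one record per alt allele so multiallelic
loci are several records sharing chrom/pos/ref), star-allele definitions
(sets of defining variants; the gene's reference haplotype has the empty
set and is itself content — e.g. a gene may name \*38 rather than \*1 as
wild type), population allele frequencies with a mandatory `GLOBAL`
fallback population, an order-invariant diplotype→phenotype map, and
directed allele-equivalence rewrites used only during concordance scoring.

Allele labels are opaque strings under one total order — numeric part,
then suffix, with non-star labels (e.g. DPYD `c.85T>C`) after all star
alleles. This single ordering is the tie-break everywhere a choice between
equally-scored alternatives must be reproducible.

Bundle linting (`validate_bundle`) reports, without raising: allele pairs
with identical defining sets (the panel cannot distinguish them),
frequency rows and phenotype rows naming undefined alleles. Loading
*fails* on structural errors: dangling rsid references, duplicate loci,
non-idempotent equivalence chains, per-population frequency sums above
1 + 1e−6.

## 2. Genotype QC and merging

Dosages are unphased alt-allele counts in {0, 1, 2}; phase separators are
ignored because calling operates on dosages. Two call sources exist,
`genotyped` and `imputed`; imputed calls carry a likelihood read from a
configurable FORMAT field (default `GP`; a 3-vector contributes its
maximum, a scalar is used as-is). Chromosome names are normalized to the
`chr` dialect before matching.

Threshold conventions (all strict inequalities, as commonly printed):

| rule | default | direction |
| --- | --- | --- |
| sample call rate (autosomal loci) | 0.98 | pass iff rate **>** threshold |
| sample sex concordance | — | fail iff reported ≠ inferred, neither `unknown` |
| site missingness | 0.90 | remove iff **>** threshold |
| site minor allele frequency | 0.005 | remove iff **<** threshold (within-cohort MAF) |
| imputed-call acceptance | 0.8 | keep iff likelihood **>** threshold |

So a call rate of exactly 0.98 fails, and a MAF of exactly 0.005
survives. Merging resolves each (sample, variant) to one record: a
non-missing directly genotyped call always wins; otherwise an imputed call
above the likelihood threshold; otherwise missing. Merging is idempotent
and merging with an empty imputed table is the identity.

Call rate is computed over the autosomal loci present in the input table.
When that table holds only the PGx panel (as in the synthetic fixtures)
the rule is far harsher than on a full chip, where the same threshold is
evaluated over hundreds of thousands of sites; fixtures exercising the
full pipeline therefore use zero missingness unless sample-QC failure is
the behaviour under test.

X-linked loci in males and mitochondrial loci are haploid: a diploid-
looking dosage of 2 is collapsed to 1 with a warning, and diplotype calls
degenerate to single-haplotype calls matched against dosage ∈ {0, 1}.
Sex is read from the sample sheet; array-intensity sex inference belongs
to the upstream clustering software.

## 3. CNV interpretation

Per-sample intensity QC excludes samples with LRR standard deviation
> 0.2, BAF drift > 0.01 or (GC-adjusted) wave factor > 0.05 — their gene
states become `no_call`. Segments need ≥10 probes and a span of ≥250 bp
(span = end − start + 1). A segment covers a gene iff it overlaps ≥50 % of
the gene span (configurable); the fraction is a package choice — partial
and hybrid events are outside the reportable range, and 50 % cleanly
separates whole-gene events from edge overlaps. No covering segment means
diploid; a covering deletion yields state 0 or 1; any covering copy number
> 2 yields "3+" (total-intensity arrays cannot name the duplicated
allele); a deletion and a duplication both covering the gene is reduced to
`no_call` rather than a guess. Hybrid/fusion alleles are deliberately not
modelled.

## 4. Diplotype calling

Candidate enumeration is exhaustive over all C(n+1, 2) unordered pairs of
the gene's n+1 defined haplotypes — panels have tens of alleles, so brute
force is both exact and fast. A pair is consistent iff its combined
carriage equals the observed dosage at every defining variant, with
missing sites pinned to the reference state. This "missing defaults to
wild type, flagged possible" convention is the clinically conservative
choice: a no-call never invents a variant allele, at the cost of
defaulting rare-allele carriers to reference — the characteristic failure
mode of such assays. Dosages at variants defining no allele of the gene
are ignored.

Ambiguity resolution maximizes the Hardy-Weinberg pair prior
f(h₁)·f(h₂)·(2 if h₁ ≠ h₂) under the sample's population (per-allele
fallback to `GLOBAL`, then 0); ties break by the global allele ordering.
The winner is flagged `ambiguous` (and `possible`) whenever more than one
candidate existed; `possible` is also set when any defining site was
missing. An empty candidate set is a no-call (`inconsistent_genotypes`).

CNV adjustment for the modelled gene: state 2 is the identity; a CNV
no-call keeps the SNV call but annotates unknown copy status; state 1
rewrites apparently homozygous X/X to X/\*5 and no-calls a heterozygous
SNV pair (`cn_inconsistent` — two distinct alleles cannot sit on one
copy); state 0 forces \*5/\*5; state 3+ keeps the pair and annotates
"copy number≥3". The deletion-allele label (\*5) is configuration.

## 5. Phenotyping

Lookup genes: order-invariant map query; unmapped pairs are
`Indeterminate`; the `possible` flag propagates from the diplotype call
and is rendered as a "Possible "/"Possibly " prefix only at the report
layer (the flag is canonical, the spelling is a template).

Activity-score gene: the score of a diploid pair is v(a) + v(b) (the
deletion allele contributes 0, so a deletion-substituted pair scores the
surviving allele alone). Under duplication, both assignments of the extra
copy up to `max_copies = 3` total copies are enumerated — scores
2·v(a)+v(b) and v(a)+2·v(b) — giving a range. Endpoints in one bin give
that label; endpoints in different bins are decided by the
higher-frequency permutation, weighted f(x)^copies(x) over the pair
(ties: the permutation duplicating the lower-ordered allele). Duplicated
calls are always `possible`. Default bins ship as editable configuration
following the CPIC-style scheme — Poor [0, 0], Intermediate (0, 1.25),
Normal [1.25, 2.25], Ultrarapid (2.25, ∞) — because guideline bin edges
are curation, not code; they must tile [0, ∞) exactly or the
configuration is rejected. A missing activity value collapses the
phenotype to `Indeterminate` rather than guessing.

## 6. Validation statistics

Confusion classes per (sample, site), given truth dosage t and query q:
no-call (q missing); TN (t = 0 = q); FP (q > t); TP (q = t > 0,
sub-labelled hom/het); FN (0 ≤ q < t, t > 0). The directional rule for
partial dosage mismatches — under-call FN, over-call FP — matches how
array validations treat single-copy and duplicated samples whose truth
VCFs disagree with the physical copy number. Sites absent from the truth
set are `not_in_reference` and excluded. Manual-review overrides are an
explicit TSV (sample, rsid, new category, justification), applied only
through the report and logged — never silent.

Metrics (each None on an empty denominator, never 0):
callability = called/considered; genotype concordance = (TP+TN)/called;
sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
precision = TP/(TP+FP); no-call rate = no-calls/considered.

Wilson score intervals use z = 1.959964 (the 6-decimal two-sided 95 %
normal quantile; the difference from 1.96 is below print resolution but
the value is documented and configurable). All percentages are rounded
half-up to two decimals on the percent scale, matching printed-table
conventions; `wilson(k, n)` and `wilson(n−k, n)` are complements to
rounding, which is why published callability/no-call rows mirror each
other. Bootstrap intervals for means use the percentile method with
10,000 seeded replicates.

Diplotype concordance compares unordered, equivalence-rewritten label
multisets, which also covers genes reported as variant-label lists.
Callability is counted over samples with a truth call; concordance over
samples with both truth and query calls — no-calls are excluded from the
concordance denominator (this convention reproduces the interval
denominators implied by printed validation tables). Phenotype concordance
defaults to label equality ignoring the Possible qualifier; a per-gene
allele-presence comparator is available for genes where one allele drives
the recommendation. Replicate concordance is pairwise agreement among
same-subject replicates, intra- vs inter-run by run id; both-missing
pairs are excluded and one-missing pairs count as disagreement.

## 7. Synthetic cohorts

The generator emulates the validation-study design without external data:
random gene models (distinct defining sets, Dirichlet frequencies summing
to 1 per population, complete phenotype maps, activity values on the
CNV-modelled gene, \*5 reserved for the deletion allele), diploid cohorts
drawn per chromosome under Hardy-Weinberg with no linkage between genes,
whole-gene CNV events at configured rates, and a corruption operator
(independent per-call missingness, uniform flips to a different valid
dosage, imputed-call relabelling with Beta(9, 1) likelihoods — mostly
above the 0.8 acceptance threshold, occasionally below, as imputation
quality scores behave).

Observation model: under a heterozygous whole-gene deletion the diploid
genotyping model reports the surviving allele's variants as apparently
homozygous (dosage doubled); a homozygous deletion reports reference
dosages. Duplications leave SNV dosages at their diploid values, and the
truth diplotype keeps the unduplicated pair with the truth copy state
recorded separately — mirroring an assay whose duplication calls are
annotations, not extra alleles. Default cohort parameters (3 genes,
5 alleles and 6 variants per gene, 500 samples, two populations at
60/40, all corruption and CNV rates 0) are the smallest configuration
exercising every code path including ambiguity; tests state larger sizes
(e.g. 5,000 samples for recovery and rate-calibration checks)
explicitly.

What passing synthetic tests do **not** show about real data: no linkage
disequilibrium (so real ambiguity rates are population-haplotype-
structure-dependent), no intensity-level artefacts (CNV QC statistics are
drawn, not computed), no hybrid/fusion alleles, no imputation-panel error
structure, and the call-rate caveat of §2.

## 8. Determinism

Every stochastic step — generation, corruption, bootstrap — flows from an
explicit integer seed through `numpy.random.default_rng`; no global RNG
state is touched. Identical (params, seed) reruns produce byte-identical
fixtures and metrics files; outputs are sorted so reports are stable under
input sample reordering.

## 9. Known limitations

- Hybrid/fusion star alleles and partial-gene events are out of scope by
  design; such samples surface as ordinary (wrong-but-flaggable) calls or
  CNV no-calls.
- Phasing is not used; alleles distinguishable only by phase resolve by
  frequency and are flagged, not resolved.
- The shipped example/synthetic content is not a curated panel; real use
  requires PharmGKB/CPIC-derived bundles supplied by the user.
- Only 95 % intervals are wired through the reporting layer (the critical
  value is configurable in the statistics module).
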
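# pgxkit

Array-based pharmacogenomics (PGx) interpretation and analytical
validation. `pgxkit` turns SNP-array genotype calls at a curated panel of
pharmacogene loci into star-allele diplotypes and metabolizer phenotypes,
and provides the statistical framework used to validate such an assay
against reference truth sets.

## Who this is for

Groups building or validating a PGx reporting pipeline on genotyping
arrays (e.g. the Illumina GSA family): the array and an imputation engine
produce VCFs, an intensity-based CNV caller produces segment tables, and
this package performs everything downstream — quality control, star-allele
interpretation, and accuracy/precision assessment — on user-supplied
content tables (allele definitions, haplotype frequencies,
diplotype→phenotype maps).

## The model

**Diplotype calling.** A star allele *h* of a gene is a haplotype defined
by a set of panel variants. Given unphased alt-allele dosages
*d(v) ∈ {0,1,2}*, the caller enumerates every unordered allele pair
(*h₁*, *h₂*) with

```
carriers(h1, v) + carriers(h2, v) = d(v)   for every defining variant v,
```

treating missing sites as reference (and flagging the call "possible").
When several pairs remain, the pair maximizing the Hardy-Weinberg prior
under the sample's population allele frequencies,
*f(h₁)·f(h₂)·(2 if h₁≠h₂)*, is reported and flagged "ambiguous".

**Copy number.** Whole-gene CNV states are reduced from filtered segments
(≥10 probes, ≥250 bp, ≥50 % gene overlap). On the CNV-modelled gene
(CYP2D6 in practice) a heterozygous deletion rewrites an apparently
homozygous X/X to X/\*5, a homozygous deletion yields \*5/\*5, and a
duplication annotates the call "copy number≥3" because total intensity
cannot identify the duplicated allele.

**Phenotyping.** Most genes use a curated (gene, diplotype) → phenotype
lookup. The CNV-modelled gene uses an activity score — the sum of
per-allele activity values over carried copies. Under duplication both
copy assignments up to the 3-copy cap are scored, giving a range
[min, max]; if the range spans two phenotype bins, the score of the more
frequent copy permutation decides, and the label is qualified "Possible".

**Validation statistics.** Calls are scored against truth genotypes with
dosage-direction confusion classes (query < truth → FN, query > truth →
FP), summarized as callability, genotype concordance, analytical
sensitivity/specificity, precision and no-call rate, each with a Wilson
score 95 % interval

```
( p̂ + z²/2n  ±  z·sqrt( p̂(1−p̂)/n + z²/4n² ) ) / ( 1 + z²/n ) ,   z = 1.959964
```

Means over samples get percentile-bootstrap intervals (10,000 replicates).
Diplotype/phenotype concordance is computed on unordered,
equivalence-rewritten allele pairs (e.g. CYP2D6 \*2→\*1 when \*2's key
variant is outside the reportable range).

A seeded synthetic module generates content bundles and cohorts with known
truth, so the full pipeline is testable without controlled-access data.

## Worked example

Simulate a 40-sample cohort with whole-gene CNV events, then interpret and
validate it:

```bash
cat > sim.yaml <<EOF
bundle: fix/bundle
simulate:
  n_samples: 40
  seed: 19
  cnv_del_het_rate: 0.08
  cnv_del_hom_rate: 0.03
  cnv_dup_rate: 0.08
EOF
pgxkit simulate --config sim.yaml --out fix

cat > run.yaml <<EOF
bundle: fix/bundle
genotyped_vcf: fix/genotyped.vcf
sample_sheet: fix/samples.tsv
cnv_segments: fix/cnv_segments.tsv
cnv_qc: fix/cnv_qc.tsv
truth_vcf: fix/truth_genotypes.vcf
truth_diplotypes: fix/truth_diplotypes.tsv
truth_copy_states: fix/truth_copy_states.tsv
output_dir: out
EOF
pgxkit interpret --config run.yaml
pgxkit validate --config run.yaml
```

`out/diplotypes.tsv` then contains CNV-adjusted calls such as

```
sample   gene   allele1 allele2 ambiguous possible cnv_annotation  candidates          no_call_reason
S00001   GENE1  *3      *4      0         0        copy number≥3   *3/*4:0.157784
S00007   GENE1  *2      *5      0         0        deletion_applied *2/*2:0.0273595
```

— S00007's SNV genotypes looked homozygous \*2/\*2, but a deletion segment
covering the gene rewrote the call to \*2/\*5. `out/metrics.tsv` holds one
row per metric and stratum with the count pair and its Wilson interval;
on this noiseless fixture every gene scores perfectly, e.g.

```
stratum      metric                 k   n   point  ci_low  ci_high  method  seed
gene.GENE1   diplotype_callability  40  40  100.0  91.24   100.0    wilson  1
gene.GENE1   diplotype_concordance  40  40  100.0  91.24   100.0    wilson  1
```

The point is 100 % but the interval lower bound (91.24 %) reflects the
40-sample denominator — exactly the quantity a validation report needs.

## Layout

- `pgxkit.model` — content bundle types, TSV loaders, bundle linting
- `pgxkit.genotype_qc` — VCF ingestion, sample/site QC, genotyped⊕imputed merge, allele frequencies
- `pgxkit.cnv` — CNV sample QC, segment filters, per-gene copy state
- `pgxkit.diplotyper` — candidate enumeration, frequency resolution, CNV adjustment
- `pgxkit.phenotyper` — phenotype lookup and the activity-score range procedure
- `pgxkit.concordance` — confusion classification, the six metrics, Wilson/bootstrap CIs, concordance and replicate reports
- `pgxkit.synthetic` — seeded bundle/cohort generator and corruption operator
- `pgxkit.cli` — `pgxkit simulate | interpret | validate | bundle-check`

See `docs/methods.md` for the full statistical model, parameter defaults
and known limitations.
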
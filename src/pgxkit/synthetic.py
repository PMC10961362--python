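"""Seeded synthetic content bundles and cohorts with known truth.

Real validation of an array PGx workflow uses controlled-access reference
cell lines; this module stands in with fully synthetic material: a random
star-allele content model (validate-clean by construction), diploid
cohorts whose haplotypes are drawn per chromosome from population-specific
allele frequencies (Hardy-Weinberg, no linkage between genes), whole-gene
CNV events on the copy-number-modelled gene, and a corruption operator
injecting genotyping error, missingness and imputed-call relabelling at
configured rates.  Every function is a pure function of (params, seed).

Generated cohorts exercise every pipeline stage; they do not emulate
linkage disequilibrium, intensity-level artefacts, hybrid/fusion alleles,
or imputation-panel error structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .cnv import CnvSampleQc, CnvSegment
from .genotype_qc import (
    GenotypeTable,
    SOURCE_GENOTYPED,
    SOURCE_IMPUTED,
    SampleInfo,
)
from .model import (
    ActivityConfig,
    ContentBundle,
    EquivalenceRules,
    FrequencyTable,
    GeneDef,
    GLOBAL_POP,
    HaplotypeDef,
    PhenotypeMap,
    VariantDef,
    default_activity_bins,
    normalize_pair,
    write_bundle,
)

_FUNCTION_VALUES = {"no": 0.0, "decreased": 0.5, "normal": 1.0}
_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimulationParams:
    """Study-condition knobs for bundle and cohort generation.

    Rates are per-call probabilities; ``populations`` maps population code
    to cohort mixing proportion (must sum to 1).  The first generated gene
    carries the copy-number model.
    """

    n_genes: int = 3
    alleles_per_gene: int = 5
    variants_per_gene: int = 6
    n_samples: int = 500
    populations: tuple[tuple[str, float], ...] = (("POPA", 0.6), ("POPB", 0.4))
    freq_concentration: float = 1.5
    flip_rate: float = 0.0
    missingness_rate: float = 0.0
    imputed_fraction: float = 0.0
    likelihood_beta: tuple[float, float] = (9.0, 1.0)
    cnv_del_het_rate: float = 0.0
    cnv_del_hom_rate: float = 0.0
    cnv_dup_rate: float = 0.0
    cnv_qc_fail_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("flip_rate", "missingness_rate", "imputed_fraction",
                     "cnv_del_het_rate", "cnv_del_hom_rate", "cnv_dup_rate",
                     "cnv_qc_fail_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} out of [0,1]: {v}")
        if abs(sum(p for _, p in self.populations) - 1.0) > 1e-9:
            raise ValueError("population proportions must sum to 1")


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated cohort."""

    samples: list[str]
    population: dict[str, str]
    diplotypes: dict[tuple[str, str], tuple[str, str]]  # (sample, gene) -> pair
    copy_states: dict[str, str]  # per sample, for the CNV-modelled gene
    dosages: GenotypeTable  # clean truth dosages at every target


def _rng(params: SimulationParams, seed: Optional[int]) -> np.random.Generator:
    return np.random.default_rng(params.seed if seed is None else seed)


def random_gene_model(params: SimulationParams, seed: Optional[int] = None
                      ) -> ContentBundle:
    """Generate a validate-clean content bundle.

    Each gene gets ``variants_per_gene`` biallelic SNVs and
    ``alleles_per_gene`` haplotypes with *distinct* defining sets (the
    reference haplotype *1 has the empty set), population frequencies from
    a Dirichlet draw (summing to 1 per population), a complete phenotype
    map, and activity values on the first (CNV-modelled) gene.
    """
    rng = _rng(params, seed)
    if params.alleles_per_gene < 1:
        raise ValueError("alleles_per_gene must be >= 1")
    n_masks = 2 ** params.variants_per_gene - 1
    if params.alleles_per_gene - 1 > n_masks:
        raise ValueError(
            f"cannot define {params.alleles_per_gene} distinct alleles "
            f"with {params.variants_per_gene} variants")

    genes: dict[str, GeneDef] = {}
    variants: list[VariantDef] = []
    haplotypes: dict[str, dict[str, HaplotypeDef]] = {}
    freqs = FrequencyTable()
    phenos = PhenotypeMap()
    bins = default_activity_bins()
    pops = [p for p, _ in params.populations]
    activity: Optional[ActivityConfig] = None

    for gi in range(params.n_genes):
        gname = f"GENE{gi + 1}"
        chrom = f"chr{10 + gi}"
        start = 1_000_000
        end = start + 5_000
        genes[gname] = GeneDef(gname, chrom, start, end, "*1", "autosomal")

        gvars = []
        for vi in range(params.variants_per_gene):
            ref, alt = rng.choice(len(_BASES), size=2, replace=False)
            v = VariantDef(gname, f"rs{gi + 1}{vi + 1:03d}", chrom,
                           start + 100 * (vi + 1), _BASES[ref], _BASES[alt])
            gvars.append(v)
            variants.append(v)

        # distinct non-empty defining sets drawn without replacement
        masks = 1 + rng.choice(n_masks, size=params.alleles_per_gene - 1, replace=False)
        is_cnv_gene = gi == 0
        halls: dict[str, HaplotypeDef] = {
            "*1": HaplotypeDef(gname, "*1", frozenset(), "normal",
                               1.0 if is_cnv_gene else None)}
        # *5 is reserved for the whole-gene deletion on the CNV-modelled gene
        numbers = (n for n in range(2, 10_000) if not (is_cnv_gene and n == 5))
        for mask in sorted(int(m) for m in masks):
            ai = next(numbers)
            defs = frozenset(gvars[b] for b in range(params.variants_per_gene)
                             if mask >> b & 1)
            func = ("no", "decreased", "normal")[int(rng.integers(3))]
            av = _FUNCTION_VALUES[func] if is_cnv_gene else None
            halls[f"*{ai}"] = HaplotypeDef(gname, f"*{ai}", defs, func, av)
        haplotypes[gname] = halls

        names = sorted(halls)
        pop_fracs = {}
        for pop in pops:
            f = rng.dirichlet(np.full(len(names), params.freq_concentration))
            pop_fracs[pop] = f
            for nm, fi in zip(names, f):
                freqs.set(gname, nm, pop, float(fi))
        mix = np.zeros(len(names))
        for (pop, w) in params.populations:
            mix += w * pop_fracs[pop]
        for nm, fi in zip(names, mix):
            freqs.set(gname, nm, GLOBAL_POP, float(fi))

        # complete phenotype map from summed pseudo-activity of the pair
        values = {nm: _FUNCTION_VALUES[halls[nm].function] for nm in names}
        if is_cnv_gene:
            values["*5"] = 0.0  # whole-gene deletion allele, CNV-defined
        pair_names = sorted(values)
        for i, a in enumerate(pair_names):
            for b in pair_names[i:]:
                score = values[a] + values[b]
                label = next(bb.label for bb in bins if bb.contains(score))
                phenos.set(gname, a, b, label)

        if is_cnv_gene:
            avals = {nm: _FUNCTION_VALUES[halls[nm].function] for nm in names}
            avals["*5"] = 0.0
            activity = ActivityConfig(gene=gname, activity_values=avals)

    bundle = ContentBundle(genes, variants, haplotypes, freqs, phenos,
                           EquivalenceRules(), activity)
    return bundle


def _draw_pair(rng: np.random.Generator, names: Sequence[str],
               probs: np.ndarray) -> tuple[str, str]:
    i, j = rng.choice(len(names), size=2, p=probs)
    return names[int(i)], names[int(j)]


def simulate_cohort(bundle: ContentBundle, params: SimulationParams,
                    seed: Optional[int] = None
                    ) -> tuple[SyntheticTruth, GenotypeTable,
                               list[CnvSegment], dict[str, CnvSampleQc]]:
    """Draw a cohort with known truth from the bundle's frequencies.

    Haplotypes are sampled independently per chromosome from the sample's
    population frequencies.  Whole-gene CNV events on the CNV-modelled
    gene are injected at the configured rates; their segments always pass
    the probe/span filters, and QC statistics are drawn below thresholds
    except for the requested fraction of QC-failing samples.  The returned
    genotype table holds clean (uncorrupted) dosages, identical to the
    truth dosages.
    """
    rng = _rng(params, seed)
    samples = [f"S{i + 1:05d}" for i in range(params.n_samples)]
    pop_names = [p for p, _ in params.populations]
    pop_probs = np.array([w for _, w in params.populations])
    pop_of = {s: pop_names[int(k)] for s, k in
              zip(samples, rng.choice(len(pop_names), size=len(samples), p=pop_probs))}

    meta = {s: SampleInfo(s, reported_sex="F", inferred_sex="F",
                          population=pop_of[s]) for s in samples}
    table = GenotypeTable(samples, bundle.variants, meta)

    cnv_gene = bundle.activity.gene if bundle.activity else None
    del_allele = bundle.activity.deletion_allele if bundle.activity else "*5"

    diplotypes: dict[tuple[str, str], tuple[str, str]] = {}
    copy_states: dict[str, str] = {}
    segments: list[CnvSegment] = []
    qc: dict[str, CnvSampleQc] = {}

    # per-gene allele names and per-population sampling distributions
    gene_alleles = {g: [h.name for h in bundle.alleles_of(g)] for g in bundle.genes}
    gene_pop_probs = {}
    for g, names in gene_alleles.items():
        for pop in pop_names:
            f = np.array([bundle.frequencies.freq(g, nm, pop) for nm in names])
            total = f.sum()
            gene_pop_probs[(g, pop)] = f / total if total > 0 else np.full(len(names), 1 / len(names))

    for s in samples:
        pop = pop_of[s]

        # CNV event for the modelled gene
        state = "2"
        if cnv_gene is not None:
            u = rng.random()
            if u < params.cnv_del_hom_rate:
                state = "0"
            elif u < params.cnv_del_hom_rate + params.cnv_del_het_rate:
                state = "1"
            elif u < (params.cnv_del_hom_rate + params.cnv_del_het_rate
                      + params.cnv_dup_rate):
                state = "3+"
        copy_states[s] = state

        for g in bundle.genes:
            names = gene_alleles[g]
            h1, h2 = _draw_pair(rng, names, gene_pop_probs[(g, pop)])
            if g == cnv_gene:
                if state == "0":
                    pair = (del_allele, del_allele)
                elif state == "1":
                    pair = normalize_pair(h1, del_allele)
                else:
                    pair = normalize_pair(h1, h2)
            else:
                pair = normalize_pair(h1, h2)
            diplotypes[(s, g)] = pair

            hd = bundle.haplotypes[g]
            carried = [hd[a] for a in pair if a in hd]  # deletion allele carries nothing
            for v in bundle.variants_of(g):
                d = sum(h.carriers(v) for h in carried)
                if g == cnv_gene and state == "1":
                    # one physical copy: the diploid genotyping model reports
                    # the surviving allele's variants as apparently homozygous
                    d = 2 * d
                table.set(s, v, float(d), SOURCE_GENOTYPED)

            if g == cnv_gene and state != "2":
                gd = bundle.genes[g]
                cn = {"0": 0, "1": 1, "3+": 3}[state]
                segments.append(CnvSegment(
                    s, gd.chrom, gd.start - 500, gd.end + 500, cn,
                    int(rng.integers(15, 40))))

        if rng.random() < params.cnv_qc_fail_rate:
            qc[s] = CnvSampleQc(s, float(rng.uniform(0.25, 0.45)),
                                float(rng.uniform(0.0, 0.005)),
                                float(rng.uniform(0.0, 0.02)))
        else:
            qc[s] = CnvSampleQc(s, float(rng.uniform(0.05, 0.15)),
                                float(rng.uniform(0.0, 0.005)),
                                float(rng.uniform(0.0, 0.02)))

    truth = SyntheticTruth(samples, pop_of, diplotypes, copy_states, table.copy())
    return truth, table, segments, qc


def corrupt_calls(table: GenotypeTable, params: SimulationParams,
                  seed: Optional[int] = None) -> GenotypeTable:
    """Inject missingness, dosage flips, and imputed-call relabelling.

    Each (sample, site) is independently set missing at
    ``missingness_rate``; each surviving call is flipped to a uniformly
    chosen *different* valid dosage at ``flip_rate``; a fraction
    ``imputed_fraction`` of surviving calls is relabelled as imputed with
    a likelihood drawn from Beta(*likelihood_beta*).
    """
    rng = _rng(params, seed)
    out = table.copy()
    n, m = out.dosage.shape

    miss = rng.random((n, m)) < params.missingness_rate
    out.dosage[miss] = np.nan

    alive = ~np.isnan(out.dosage)
    flip = alive & (rng.random((n, m)) < params.flip_rate)
    # uniformly different valid dosage: add 1 or 2 mod 3
    shift = rng.integers(1, 3, size=(n, m))
    out.dosage[flip] = np.mod(out.dosage[flip] + shift[flip], 3)

    imputed = alive & (rng.random((n, m)) < params.imputed_fraction)
    lik = rng.beta(*params.likelihood_beta, size=(n, m))
    out.source[imputed] = SOURCE_IMPUTED
    out.likelihood[imputed] = lik[imputed]
    return out


# ---------------------------------------------------------------------------
# Fixture I/O


def write_vcf(path: str | Path, table: GenotypeTable,
              with_probabilities: bool = False) -> None:
    """Write the table as a minimal valid VCF v4.2 (one record per target).

    Dosage renders as an unphased diploid genotype; a missing dosage as
    ``./.``.  With ``with_probabilities`` a GP vector is emitted whose
    maximum equals the stored likelihood.
    """
    contigs = sorted({v.chrom for v in table.targets},
                     key=lambda c: (len(c), c))
    order = sorted(range(len(table.targets)),
                   key=lambda j: (table.targets[j].chrom, table.targets[j].pos,
                                  table.targets[j].alt))
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pgxkit-synthetic\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if with_probabilities:
            fh.write('##FORMAT=<ID=GP,Number=G,Type=Float,'
                     'Description="Genotype posterior probabilities">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        fmt = "GT:GP" if with_probabilities else "GT"
        for j in order:
            v = table.targets[j]
            cells = []
            for i in range(len(table.samples)):
                d = table.dosage[i, j]
                gt = "./." if np.isnan(d) else gt_of[int(d)]
                if with_probabilities:
                    lik = table.likelihood[i, j]
                    if np.isnan(d) or np.isnan(lik):
                        cells.append(f"{gt}:.")
                    else:
                        gp = [(1.0 - lik) / 2.0] * 3
                        gp[int(d)] = lik
                        cells.append(gt + ":" + ",".join(f"{p:.4f}" for p in gp))
                else:
                    cells.append(gt)
            fh.write(f"{v.chrom}\t{v.pos}\t{v.rsid}\t{v.ref}\t{v.alt}\t.\tPASS\t.\t"
                     f"{fmt}\t" + "\t".join(cells) + "\n")


def write_truth_diplotypes(path: str | Path,
                           diplotypes: dict[tuple[str, str], tuple[str, ...]]) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgene\tallele1\tallele2\n")
        for (s, g), pair in sorted(diplotypes.items()):
            a2 = pair[1] if len(pair) > 1 else ""
            fh.write(f"{s}\t{g}\t{pair[0]}\t{a2}\n")


def read_truth_copy_states(path: str | Path) -> dict[str, str]:
    """Read per-sample truth copy-number states (sample, gene, state TSV)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        cols = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            r = dict(zip(cols, line.rstrip("\n").split("\t")))
            out[r["sample"]] = r["state"]
    return out


def read_truth_diplotypes(path: str | Path) -> dict[tuple[str, str], tuple[str, ...]]:
    out: dict[tuple[str, str], tuple[str, ...]] = {}
    with open(path) as fh:
        cols = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            r = dict(zip(cols, line.rstrip("\n").split("\t")))
            pair = tuple(a for a in (r["allele1"], r["allele2"]) if a)
            out[(r["sample"], r["gene"])] = pair
    return out


def write_fixture(dir_path: str | Path, bundle: ContentBundle,
                  truth: SyntheticTruth, genotyped: GenotypeTable,
                  imputed: Optional[GenotypeTable] = None,
                  segments: Sequence[CnvSegment] = (),
                  qc: Optional[dict[str, CnvSampleQc]] = None) -> None:
    """Emit a complete on-disk fixture: bundle TSVs, VCFs, CNV and truth tables."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    write_bundle(d / "bundle", bundle)
    write_vcf(d / "genotyped.vcf", genotyped)
    if imputed is not None:
        write_vcf(d / "imputed.vcf", imputed, with_probabilities=True)
    write_vcf(d / "truth_genotypes.vcf", truth.dosages)
    write_truth_diplotypes(d / "truth_diplotypes.tsv", truth.diplotypes)

    with open(d / "samples.tsv", "w") as fh:
        fh.write("sample\treported_sex\tinferred_sex\tpopulation\trun_id\treplicate_id\n")
        for s in genotyped.samples:
            m = genotyped.sample_meta[s]
            fh.write(f"{s}\t{m.reported_sex}\t{m.inferred_sex}\t{m.population}\t"
                     f"{m.run_id}\t{m.replicate_id}\n")

    with open(d / "cnv_segments.tsv", "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tcopy_number\tn_probes\n")
        for seg in segments:
            fh.write(f"{seg.sample}\t{seg.chrom}\t{seg.start}\t{seg.end}\t"
                     f"{seg.copy_number}\t{seg.n_probes}\n")

    with open(d / "cnv_qc.tsv", "w") as fh:
        fh.write("sample\tlrr_sd\tbaf_drift\twave_factor\n")
        for s in genotyped.samples:
            q = (qc or {}).get(s)
            if q is None:
                q = CnvSampleQc(s, 0.1, 0.0, 0.0)
            fh.write(f"{s}\t{q.lrr_sd!r}\t{q.baf_drift!r}\t{q.wave_factor!r}\n")

    with open(d / "truth_copy_states.tsv", "w") as fh:
        fh.write("sample\tgene\tstate\n")
        gene = bundle.activity.gene if bundle.activity else ""
        for s in truth.samples:
            fh.write(f"{s}\t{gene}\t{truth.copy_states.get(s, '2')}\n")
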
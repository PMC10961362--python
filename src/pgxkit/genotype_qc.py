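"""Genotype ingestion, QC and merging for array-based PGx calling.

Genotypes arrive as VCFs from two sources — direct array genotyping and
imputation — restricted here to the panel's target loci.  Sample QC
(autosomal call rate, sex concordance), site pre-filters (missingness,
minor allele frequency) and the genotyped-over-imputed merge rule are
applied before diplotype calling.  Dosages are unphased alt-allele counts;
phase separators are ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from cyvcf2 import VCF

from .model import GeneDef, VariantDef, norm_chrom

MISSING = np.nan

SOURCE_GENOTYPED = "genotyped"
SOURCE_IMPUTED = "imputed"


@dataclass(frozen=True)
class QcThresholds:
    """Sample/site QC thresholds.

    A sample passes on call rate strictly greater than
    ``min_sample_call_rate``; a site is dropped on missingness strictly
    greater than ``max_site_missingness`` or MAF strictly below
    ``min_maf``; an imputed call is accepted on likelihood strictly above
    ``min_imputed_likelihood``.
    """

    min_sample_call_rate: float = 0.98
    max_site_missingness: float = 0.90
    min_maf: float = 0.005
    min_imputed_likelihood: float = 0.8

    def __post_init__(self):
        for name in ("min_sample_call_rate", "max_site_missingness",
                     "min_maf", "min_imputed_likelihood"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} out of [0,1]: {v}")


@dataclass
class SampleInfo:
    sample: str
    reported_sex: str = "unknown"  # M | F | unknown
    inferred_sex: str = "unknown"
    population: str = "GLOBAL"
    run_id: str = ""
    replicate_id: str = ""
    subject: str = ""  # biological sample shared across replicates; defaults to sample

    def __post_init__(self):
        if not self.subject:
            self.subject = self.sample


class GenotypeTable:
    """Per-(sample, target) dosages with source and likelihood.

    Dosage is stored as float with NaN marking a missing call; valid values
    are {0, 1, 2} (diploid) or {0, 1} (hemizygous).  Exactly one record per
    (sample, variant) is kept at all times; merging sources resolves to a
    single record.
    """

    def __init__(self, samples: Sequence[str], targets: Sequence[VariantDef],
                 sample_meta: Mapping[str, SampleInfo] | None = None):
        self.samples = list(samples)
        self.targets = list(targets)
        self._sidx = {s: i for i, s in enumerate(self.samples)}
        self._tidx = {v: j for j, v in enumerate(self.targets)}
        n, m = len(self.samples), len(self.targets)
        self.dosage = np.full((n, m), MISSING, dtype=float)
        self.source = np.full((n, m), SOURCE_GENOTYPED, dtype=object)
        self.likelihood = np.full((n, m), MISSING, dtype=float)
        self.sample_meta: dict[str, SampleInfo] = dict(sample_meta or {})
        for s in self.samples:
            self.sample_meta.setdefault(s, SampleInfo(s))

    # -- element access -----------------------------------------------------
    def set(self, sample: str, variant: VariantDef, dosage: float,
            source: str = SOURCE_GENOTYPED, likelihood: float = MISSING) -> None:
        i, j = self._sidx[sample], self._tidx[variant]
        self.dosage[i, j] = dosage
        self.source[i, j] = source
        self.likelihood[i, j] = likelihood

    def get(self, sample: str, variant: VariantDef) -> float:
        return float(self.dosage[self._sidx[sample], self._tidx[variant]])

    def dosages_for(self, sample: str, variants: Sequence[VariantDef]) -> dict[VariantDef, Optional[int]]:
        """Dosage per variant for one sample; None marks a missing call.

        Variants not held by the table (e.g. removed by the site
        pre-filter) are reported as missing.
        """
        i = self._sidx[sample]
        out: dict[VariantDef, Optional[int]] = {}
        for v in variants:
            j = self._tidx.get(v)
            if j is None:
                out[v] = None
                continue
            d = self.dosage[i, j]
            out[v] = None if np.isnan(d) else int(d)
        return out

    def copy(self) -> "GenotypeTable":
        t = GenotypeTable(self.samples, self.targets, self.sample_meta)
        t.dosage = self.dosage.copy()
        t.source = self.source.copy()
        t.likelihood = self.likelihood.copy()
        return t

    # -- summaries ----------------------------------------------------------
    def call_rate(self, sample: str, target_mask: np.ndarray | None = None) -> float:
        i = self._sidx[sample]
        d = self.dosage[i] if target_mask is None else self.dosage[i, target_mask]
        if d.size == 0:
            return float("nan")
        return float(1.0 - np.isnan(d).mean())

    def site_missingness(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=0)

    def site_maf(self) -> np.ndarray:
        """Minor allele frequency per site from non-missing dosages (NaN if none)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            af = np.nansum(self.dosage, axis=0) / (2.0 * np.sum(~np.isnan(self.dosage), axis=0))
        return np.minimum(af, 1.0 - af)

    def to_records(self) -> list[dict]:
        rows = []
        for i, s in enumerate(self.samples):
            for j, v in enumerate(self.targets):
                d = self.dosage[i, j]
                rows.append({
                    "sample": s, "gene": v.gene, "rsid": v.rsid, "chrom": v.chrom,
                    "pos": v.pos, "ref": v.ref, "alt": v.alt,
                    "dosage": "" if np.isnan(d) else int(d),
                    "source": self.source[i, j],
                    "likelihood": "" if np.isnan(self.likelihood[i, j]) else float(self.likelihood[i, j]),
                })
        return rows


def read_sample_sheet(path: str | Path) -> dict[str, SampleInfo]:
    """Read the sample sheet TSV: sample, reported_sex, inferred_sex, population, run_id, replicate_id."""
    out: dict[str, SampleInfo] = {}
    with open(path) as fh:
        cols = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            r = dict(zip(cols, line.rstrip("\n").split("\t")))
            out[r["sample"]] = SampleInfo(
                sample=r["sample"],
                reported_sex=r.get("reported_sex", "unknown") or "unknown",
                inferred_sex=r.get("inferred_sex", "unknown") or "unknown",
                population=r.get("population", "GLOBAL") or "GLOBAL",
                run_id=r.get("run_id", ""),
                replicate_id=r.get("replicate_id", ""),
                subject=r.get("subject", ""),
            )
    return out


def read_vcf(path: str | Path, targets: Sequence[VariantDef], source_label: str,
             sample_meta: Mapping[str, SampleInfo] | None = None,
             prob_field: str = "GP") -> GenotypeTable:
    """Read genotypes at target loci from a VCF.

    Records are matched to targets by normalized (chrom, pos, ref, alt);
    each alt of a multi-allelic line is matched independently, and the
    dosage counts only the target's specific alt allele.  Loci absent from
    the VCF, and genotypes containing a missing allele, yield a missing
    dosage.  ``prob_field`` names the per-genotype probability FORMAT
    field: a 3-vector (probabilities per genotype class) contributes its
    maximum, a scalar is taken as-is.
    """
    if source_label not in (SOURCE_GENOTYPED, SOURCE_IMPUTED):
        raise ValueError(f"bad source label {source_label!r}")
    path = str(path)
    vcf = VCF(path)
    if not vcf.samples:
        raise ValueError(f"{path}: no sample columns")
    table = GenotypeTable(vcf.samples, targets, sample_meta)
    by_key = {v.key: v for v in targets}
    seen_chroms = set()

    for rec in vcf:
        chrom = norm_chrom(rec.CHROM)
        seen_chroms.add(chrom)
        gts = rec.genotypes  # [a0, a1, phased] per sample
        probs = None
        try:
            probs = rec.format(prob_field)
        except KeyError:
            probs = None
        for alt_idx, alt in enumerate(rec.ALT, start=1):
            target = by_key.get((chrom, rec.POS, rec.REF, alt))
            if target is None:
                continue
            j = table._tidx[target]
            for i, s in enumerate(vcf.samples):
                alleles = gts[i][:-1]
                if any(a < 0 for a in alleles):
                    continue  # stays missing
                dosage = sum(1 for a in alleles if a == alt_idx)
                lik = MISSING
                if probs is not None:
                    row = np.asarray(probs[i], dtype=float)
                    row = row[~np.isnan(row)]
                    if row.size:
                        lik = float(row.max()) if row.size > 1 else float(row[0])
                table.dosage[i, j] = dosage
                table.source[i, j] = source_label
                table.likelihood[i, j] = lik
    vcf.close()

    target_chroms = {v.chrom for v in targets}
    if seen_chroms and target_chroms and not (seen_chroms & target_chroms):
        raise ValueError(
            f"{path}: no chromosome overlap with targets after normalization "
            f"(vcf: {sorted(seen_chroms)[:3]}, targets: {sorted(target_chroms)[:3]})")
    return table


def collapse_hemizygous(table: GenotypeTable, genes: Mapping[str, GeneDef]) -> GenotypeTable:
    """Collapse diploid-looking calls at haploid loci to presence/absence.

    X-linked loci in males and mitochondrial loci in everyone carry one
    copy; a dosage of 2 there is an artefact of the diploid genotyping
    model and is collapsed to 1 with a warning.
    """
    out = table.copy()
    for j, v in enumerate(out.targets):
        g = genes.get(v.gene)
        if g is None or g.ploidy_model == "autosomal":
            continue
        for i, s in enumerate(out.samples):
            haploid = (g.ploidy_model == "mitochondrial"
                       or out.sample_meta[s].inferred_sex == "M")
            if haploid and out.dosage[i, j] > 1:
                warnings.warn(
                    f"collapsing dosage {int(out.dosage[i, j])} to 1 at haploid locus "
                    f"{v.rsid} ({v.gene}) in sample {s}")
                out.dosage[i, j] = 1.0
    return out


@dataclass(frozen=True)
class QcResult:
    passed: bool
    reasons: tuple[str, ...] = ()


def sample_qc(table: GenotypeTable, thresholds: QcThresholds = QcThresholds(),
              genes: Mapping[str, GeneDef] | None = None) -> dict[str, QcResult]:
    """Per-sample QC on the genotyped table.

    Call rate is computed over autosomal loci only (x-linked and
    mitochondrial targets are excluded when gene definitions are given).
    A sample passes only with call rate strictly above the threshold and
    no reported/inferred sex conflict ("unknown" never conflicts).
    """
    if genes:
        mask = np.array([genes[v.gene].ploidy_model == "autosomal"
                         if v.gene in genes else True
                         for v in table.targets])
    else:
        mask = None

    out: dict[str, QcResult] = {}
    for s in table.samples:
        reasons: list[str] = []
        rate = table.call_rate(s, mask)
        if not np.isnan(rate) and rate <= thresholds.min_sample_call_rate:
            reasons.append("call_rate")
        meta = table.sample_meta[s]
        if (meta.reported_sex != "unknown" and meta.inferred_sex != "unknown"
                and meta.reported_sex != meta.inferred_sex):
            reasons.append("sex_mismatch")
        out[s] = QcResult(not reasons, tuple(reasons))
    return out


@dataclass(frozen=True)
class RemovedSite:
    variant: VariantDef
    reasons: tuple[str, ...]


def site_prefilter(table: GenotypeTable, thresholds: QcThresholds = QcThresholds()
                   ) -> tuple[GenotypeTable, list[RemovedSite]]:
    """Drop sites with missingness > threshold or MAF < threshold (strict).

    Applied to the genotyped table before any imputation merge; a site can
    carry both removal reasons and both are recorded.
    """
    miss = table.site_missingness()
    maf = table.site_maf()
    removed: list[RemovedSite] = []
    keep_idx: list[int] = []
    for j, v in enumerate(table.targets):
        reasons = []
        if miss[j] > thresholds.max_site_missingness:
            reasons.append("missingness")
        if not np.isnan(maf[j]) and maf[j] < thresholds.min_maf:
            reasons.append("maf")
        if reasons:
            removed.append(RemovedSite(v, tuple(reasons)))
        else:
            keep_idx.append(j)

    kept = GenotypeTable(table.samples, [table.targets[j] for j in keep_idx],
                         table.sample_meta)
    kept.dosage = table.dosage[:, keep_idx].copy()
    kept.source = table.source[:, keep_idx].copy()
    kept.likelihood = table.likelihood[:, keep_idx].copy()
    return kept, removed


def merge_calls(genotyped: GenotypeTable, imputed: GenotypeTable,
                thresholds: QcThresholds = QcThresholds()) -> GenotypeTable:
    """Merge genotyped and imputed calls per (sample, variant).

    A non-missing directly genotyped call always wins.  Otherwise the
    imputed call is kept only with likelihood strictly above the
    acceptance threshold; a likelihood at or below it (or absent) leaves
    the site missing.  Source and likelihood provenance are preserved.
    """
    if set(genotyped.samples) != set(imputed.samples):
        raise ValueError("sample sets differ between genotyped and imputed tables")

    out = genotyped.copy()
    imp_tidx = imputed._tidx
    for j, v in enumerate(out.targets):
        ji = imp_tidx.get(v)
        if ji is None:
            continue
        for i, s in enumerate(out.samples):
            if not np.isnan(out.dosage[i, j]):
                continue
            ii = imputed._sidx[s]
            d = imputed.dosage[ii, ji]
            lik = imputed.likelihood[ii, ji]
            if (not np.isnan(d) and not np.isnan(lik)
                    and lik > thresholds.min_imputed_likelihood):
                out.dosage[i, j] = d
                out.source[i, j] = SOURCE_IMPUTED
                out.likelihood[i, j] = lik
    return out


def allele_frequencies(table: GenotypeTable,
                       pop_assign: Mapping[str, str] | None = None
                       ) -> dict[tuple[VariantDef, str], float]:
    """Alt-allele frequency per (variant, population), plus a pooled "ALL".

    AF = sum(dosage) / (2 * n_nonmissing).  A population with zero
    non-missing calls at a variant contributes no entry (absent, not 0).
    """
    if pop_assign is None:
        pop_assign = {s: table.sample_meta[s].population for s in table.samples}
    pops: dict[str, list[int]] = {"ALL": list(range(len(table.samples)))}
    for i, s in enumerate(table.samples):
        pops.setdefault(pop_assign.get(s, "GLOBAL"), []).append(i)

    out: dict[tuple[VariantDef, str], float] = {}
    for pop, idx in pops.items():
        sub = table.dosage[idx, :]
        n_called = np.sum(~np.isnan(sub), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            af = np.nansum(sub, axis=0) / (2.0 * n_called)
        for j, v in enumerate(table.targets):
            if n_called[j] > 0:
                out[(v, pop)] = float(af[j])
    return out


def write_genotype_table(path: str | Path, table: GenotypeTable) -> None:
    """Write the merged genotype table TSV."""
    with open(path, "w") as fh:
        fh.write("sample\tgene\trsid\tchrom\tpos\tref\talt\tdosage\tsource\tlikelihood\n")
        for r in table.to_records():
            fh.write("\t".join(str(r[c]) for c in
                               ("sample", "gene", "rsid", "chrom", "pos", "ref",
                                "alt", "dosage", "source", "likelihood")) + "\n")
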
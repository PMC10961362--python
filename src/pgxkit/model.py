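"""Content model for pharmacogene star-allele interpretation.

A *content bundle* is the curated knowledge a PGx interpretation pipeline
runs against: the target variant panel, the star-allele (haplotype)
definitions built from those variants, population allele frequencies used
to resolve ambiguous diplotypes, the diplotype-to-phenotype map, activity
values for the copy-number-modelled gene, and the allele-equivalence
rewrites applied before concordance scoring.

Bundles are plain TSV directories so they can be curated by hand and
diffed; :func:`load_bundle` / :func:`write_bundle` round-trip them.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

__all__ = [
    "VariantDef",
    "GeneDef",
    "HaplotypeDef",
    "FrequencyTable",
    "PhenotypeMap",
    "ActivityBin",
    "ActivityConfig",
    "EquivalenceRules",
    "ContentBundle",
    "BundleError",
    "Finding",
    "allele_sort_key",
    "normalize_pair",
    "norm_chrom",
    "load_bundle",
    "write_bundle",
    "validate_bundle",
    "default_activity_bins",
]

GLOBAL_POP = "GLOBAL"

_STAR_RE = re.compile(r"^\*(\d+)([A-Za-z0-9.+_-]*)$")


def allele_sort_key(name: str) -> tuple:
    """Total order over allele labels: numeric part, then suffix.

    Star alleles sort by their number then suffix ("*2" < "*10" < "*10A");
    non-star labels (e.g. DPYD variant names like "c.85T>C") sort after all
    star alleles, lexicographically.  This single ordering is the global
    tie-break used everywhere calls must be reproducible.
    """
    m = _STAR_RE.match(name)
    if m:
        return (0, int(m.group(1)), m.group(2))
    return (1, name, "")


def normalize_pair(a: str, b: str) -> tuple[str, str]:
    """Order-normalize an unordered allele pair by the global allele ordering."""
    return (a, b) if allele_sort_key(a) <= allele_sort_key(b) else (b, a)


def norm_chrom(chrom: str) -> str:
    """Normalize a chromosome name to the ``chr``-prefixed dialect."""
    c = str(chrom).strip()
    if c.upper().startswith("CHR"):
        return "chr" + c[3:]
    return "chr" + c


class BundleError(ValueError):
    """Raised on malformed or internally inconsistent bundle content."""


@dataclass(frozen=True, order=True)
class VariantDef:
    """A single target locus: one (chrom, pos, ref, alt) record.

    Multi-allelic loci are represented as several records sharing
    (chrom, pos, ref) and differing in ``alt``.
    """

    gene: str
    rsid: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.pos < 1:
            raise BundleError(f"{self.rsid}: pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise BundleError(f"{self.rsid}: ref == alt ({self.ref})")
        object.__setattr__(self, "chrom", norm_chrom(self.chrom))

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class GeneDef:
    gene: str
    chrom: str
    start: int
    end: int
    reference_allele_name: str
    ploidy_model: str = "autosomal"  # autosomal | x_linked | mitochondrial

    def __post_init__(self):
        if self.start > self.end:
            raise BundleError(f"{self.gene}: start > end")
        if self.ploidy_model not in ("autosomal", "x_linked", "mitochondrial"):
            raise BundleError(f"{self.gene}: unknown ploidy_model {self.ploidy_model!r}")
        object.__setattr__(self, "chrom", norm_chrom(self.chrom))

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class HaplotypeDef:
    """A named star allele: the set of panel variants it carries.

    The gene's reference haplotype has an empty defining set.  ``function``
    is the curated allele function label; ``activity_value`` the numeric
    activity contribution (for activity-score genes), or None.
    """

    gene: str
    name: str
    defining_variants: frozenset[VariantDef] = frozenset()
    function: str = "uncertain"
    activity_value: Optional[float] = None

    def __post_init__(self):
        for v in self.defining_variants:
            if v.gene != self.gene:
                raise BundleError(
                    f"{self.gene} {self.name}: defining variant {v.rsid} belongs to {v.gene}"
                )
        if self.activity_value is not None and self.activity_value < 0:
            raise BundleError(f"{self.gene} {self.name}: negative activity value")

    def carriers(self, variant: VariantDef) -> int:
        """Copies of ``variant`` on one chromosome bearing this haplotype (0 or 1)."""
        return 1 if variant in self.defining_variants else 0


class FrequencyTable:
    """Population frequencies of star alleles.

    Lookup falls back to the reserved ``GLOBAL`` population, then to 0.0:
    an allele absent from the table is treated as never observed, which
    makes it lose every frequency-based tie deterministically.
    """

    def __init__(self, entries: Mapping[tuple[str, str, str], float] | None = None):
        self._entries: dict[tuple[str, str, str], float] = {}
        if entries:
            for (gene, allele, pop), f in entries.items():
                self.set(gene, allele, pop, f)

    def set(self, gene: str, allele: str, pop: str, freq: float) -> None:
        if not (0.0 <= freq <= 1.0):
            raise BundleError(f"frequency out of [0,1]: {gene} {allele} {pop} = {freq}")
        self._entries[(gene, allele, pop)] = float(freq)

    def freq(self, gene: str, allele: str, pop: str = GLOBAL_POP) -> float:
        v = self._entries.get((gene, allele, pop))
        if v is None:
            v = self._entries.get((gene, allele, GLOBAL_POP))
        return 0.0 if v is None else v

    def populations(self) -> set[str]:
        return {p for (_, _, p) in self._entries}

    def items(self):
        return self._entries.items()

    def check_sums(self, tol: float = 1e-6) -> list[str]:
        sums: dict[tuple[str, str], float] = {}
        for (gene, _, pop), f in self._entries.items():
            sums[(gene, pop)] = sums.get((gene, pop), 0.0) + f
        return [
            f"frequencies for {gene}/{pop} sum to {s:.8f} > 1"
            for (gene, pop), s in sorted(sums.items())
            if s > 1.0 + tol
        ]

    def __eq__(self, other):
        return isinstance(other, FrequencyTable) and self._entries == other._entries

    def __len__(self):
        return len(self._entries)


class PhenotypeMap:
    """Order-invariant (gene, diplotype) -> phenotype label lookup."""

    def __init__(self):
        self._map: dict[tuple[str, tuple[str, str]], str] = {}

    def set(self, gene: str, a1: str, a2: str, phenotype: str) -> None:
        self._map[(gene, normalize_pair(a1, a2))] = phenotype

    def get(self, gene: str, a1: str, a2: str) -> Optional[str]:
        return self._map.get((gene, normalize_pair(a1, a2)))

    def items(self):
        return self._map.items()

    def alleles_used(self, gene: str) -> set[str]:
        out: set[str] = set()
        for (g, pair) in self._map:
            if g == gene:
                out.update(pair)
        return out

    def __eq__(self, other):
        return isinstance(other, PhenotypeMap) and self._map == other._map

    def __len__(self):
        return len(self._map)


@dataclass(frozen=True)
class ActivityBin:
    """One metabolizer bin: a half-open-or-closed interval of activity score."""

    label: str
    low: float
    high: float  # math.inf allowed
    low_inclusive: bool = True
    high_inclusive: bool = True

    def contains(self, score: float) -> bool:
        lo_ok = score >= self.low if self.low_inclusive else score > self.low
        hi_ok = score <= self.high if self.high_inclusive else score < self.high
        return lo_ok and hi_ok


def default_activity_bins() -> list[ActivityBin]:
    """CPIC-style CYP2D6 activity-score bins.

    Poor [0, 0]; Intermediate (0, 1.25); Normal [1.25, 2.25];
    Ultrarapid (2.25, inf).  Shipped as editable configuration — guideline
    bin edges change over time and must be swappable without code changes.
    """
    return [
        ActivityBin("Poor Metabolizer", 0.0, 0.0, True, True),
        ActivityBin("Intermediate Metabolizer", 0.0, 1.25, False, False),
        ActivityBin("Normal Metabolizer", 1.25, 2.25, True, True),
        ActivityBin("Ultrarapid Metabolizer", 2.25, math.inf, False, True),
    ]


@dataclass
class ActivityConfig:
    """Activity-score configuration for the copy-number-modelled gene.

    ``activity_values`` includes CNV-only alleles (the whole-gene deletion
    allele, conventionally *5 with value 0) that carry no defining SNVs and
    therefore do not appear in the haplotype table.  ``max_copies`` caps the
    copy-number permutations considered under duplication (default 3).
    """

    gene: str = "CYP2D6"
    activity_values: dict[str, float] = field(default_factory=dict)
    bins: list[ActivityBin] = field(default_factory=default_activity_bins)
    max_copies: int = 3
    deletion_allele: str = "*5"

    def __post_init__(self):
        if self.max_copies < 2:
            raise BundleError("max_copies must be >= 2")
        errs = self.validate_bins()
        if errs:
            raise BundleError("; ".join(errs))

    def validate_bins(self) -> list[str]:
        """Bins must tile [0, inf) without gaps or overlaps."""
        if not self.bins:
            return ["no activity bins configured"]
        bins = sorted(self.bins, key=lambda b: (b.low, not b.low_inclusive))
        errs = []
        if not (bins[0].low == 0.0 and bins[0].low_inclusive):
            errs.append("bins do not start at [0")
        for prev, nxt in zip(bins, bins[1:]):
            if prev.high != nxt.low or prev.high_inclusive == nxt.low_inclusive:
                errs.append(f"gap/overlap between {prev.label!r} and {nxt.label!r}")
        if bins[-1].high != math.inf:
            errs.append("bins do not extend to infinity")
        return errs

    def value(self, allele: str) -> Optional[float]:
        return self.activity_values.get(allele)

    def bin_label(self, score: float) -> str:
        for b in self.bins:
            if b.contains(score):
                return b.label
        return "Indeterminate"


class EquivalenceRules:
    """Directed allele rewrites applied to both sides before concordance.

    Rewrites must be idempotent: the image of every rewrite is a fixed
    point (checked at load time).
    """

    def __init__(self):
        self._rules: dict[str, dict[str, str]] = {}

    def add(self, gene: str, from_allele: str, to_allele: str) -> None:
        self._rules.setdefault(gene, {})[from_allele] = to_allele

    def rewrite(self, gene: str, allele: str) -> str:
        return self._rules.get(gene, {}).get(allele, allele)

    def rewrite_pair(self, gene: str, pair: tuple[str, ...]) -> tuple[str, ...]:
        rewritten = tuple(self.rewrite(gene, a) for a in pair)
        if len(rewritten) == 2:
            return normalize_pair(*rewritten)
        return rewritten

    def check_idempotent(self) -> list[str]:
        errs = []
        for gene, rules in self._rules.items():
            for src, dst in rules.items():
                if dst in rules and rules[dst] != dst:
                    errs.append(f"{gene}: rewrite {src}->{dst} is not idempotent")
        return errs

    def items(self):
        for gene, rules in self._rules.items():
            for src, dst in rules.items():
                yield gene, src, dst

    def __eq__(self, other):
        return isinstance(other, EquivalenceRules) and self._rules == other._rules


@dataclass
class ContentBundle:
    genes: dict[str, GeneDef]
    variants: list[VariantDef]
    haplotypes: dict[str, dict[str, HaplotypeDef]]  # gene -> name -> def
    frequencies: FrequencyTable
    phenotypes: PhenotypeMap
    equivalences: EquivalenceRules
    activity: Optional[ActivityConfig] = None

    def variants_of(self, gene: str) -> list[VariantDef]:
        return [v for v in self.variants if v.gene == gene]

    def alleles_of(self, gene: str) -> list[HaplotypeDef]:
        return sorted(
            self.haplotypes.get(gene, {}).values(),
            key=lambda h: allele_sort_key(h.name),
        )

    def reference_haplotype(self, gene: str) -> HaplotypeDef:
        name = self.genes[gene].reference_allele_name
        return self.haplotypes[gene][name]

    def __eq__(self, other):
        if not isinstance(other, ContentBundle):
            return NotImplemented
        return (
            self.genes == other.genes
            and sorted(self.variants) == sorted(other.variants)
            and self.haplotypes == other.haplotypes
            and self.frequencies == other.frequencies
            and self.phenotypes == other.phenotypes
            and self.equivalences == other.equivalences
        )


@dataclass(frozen=True)
class Finding:
    """One bundle-validation finding (never an exception)."""

    kind: str
    gene: str
    detail: str

    def __str__(self):
        return f"[{self.kind}] {self.gene}: {self.detail}"


# ---------------------------------------------------------------------------
# TSV I/O

_FILES = {
    "genes": "genes.tsv",
    "variants": "variants.tsv",
    "haplotypes": "haplotypes.tsv",
    "frequencies": "frequencies.tsv",
    "phenotypes": "phenotypes.tsv",
    "equivalences": "equivalences.tsv",
}


def _read_tsv(path: Path, required: Iterable[str]) -> list[dict[str, str]]:
    if not path.exists():
        raise BundleError(f"missing bundle file: {path}")
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        missing = set(required) - set(cols)
        if missing:
            raise BundleError(f"{path}: missing columns {sorted(missing)}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(cols):
                raise BundleError(f"{path}:{lineno}: expected {len(cols)} fields, got {len(parts)}")
            rows.append(dict(zip(cols, parts), _lineno=str(lineno)))
    return rows


def load_bundle(dir_path: str | Path, activity_gene: str | None = None) -> ContentBundle:
    """Load and cross-reference a content bundle from a TSV directory.

    Unresolved references (an allele table naming an absent rsid) raise
    :class:`BundleError` naming the offending file, line and identifier.
    ``activity_gene`` selects the gene for which an :class:`ActivityConfig`
    is assembled from the haplotype table's activity values (default: the
    first gene with any activity value, if any).
    """
    d = Path(dir_path)

    genes: dict[str, GeneDef] = {}
    for r in _read_tsv(d / _FILES["genes"],
                       ["gene", "chrom", "start", "end", "reference_allele_name", "ploidy_model"]):
        g = GeneDef(r["gene"], r["chrom"], int(r["start"]), int(r["end"]),
                    r["reference_allele_name"], r["ploidy_model"])
        if g.gene in genes:
            raise BundleError(f"genes.tsv:{r['_lineno']}: duplicate gene {g.gene}")
        genes[g.gene] = g

    variants: list[VariantDef] = []
    by_key: dict[tuple, VariantDef] = {}
    by_rsid: dict[tuple[str, str], list[VariantDef]] = {}
    for r in _read_tsv(d / _FILES["variants"], ["gene", "rsid", "chrom", "pos", "ref", "alt"]):
        if r["gene"] not in genes:
            raise BundleError(f"variants.tsv:{r['_lineno']}: unknown gene {r['gene']}")
        v = VariantDef(r["gene"], r["rsid"], r["chrom"], int(r["pos"]), r["ref"], r["alt"])
        if v.key in by_key:
            raise BundleError(f"variants.tsv:{r['_lineno']}: duplicate locus {v.key}")
        by_key[v.key] = v
        by_rsid.setdefault((v.gene, v.rsid), []).append(v)
        variants.append(v)

    haplotypes: dict[str, dict[str, HaplotypeDef]] = {g: {} for g in genes}
    for r in _read_tsv(d / _FILES["haplotypes"],
                       ["gene", "allele", "rsids", "function", "activity_value"]):
        gene, name = r["gene"], r["allele"]
        if gene not in genes:
            raise BundleError(f"haplotypes.tsv:{r['_lineno']}: unknown gene {gene}")
        if name in haplotypes[gene]:
            raise BundleError(f"haplotypes.tsv:{r['_lineno']}: duplicate allele {gene} {name}")
        defs: set[VariantDef] = set()
        for rsid in filter(None, r["rsids"].split(";")):
            hits = by_rsid.get((gene, rsid))
            if not hits:
                raise BundleError(
                    f"haplotypes.tsv:{r['_lineno']}: allele {gene} {name} references "
                    f"unknown rsid {rsid}")
            defs.update(hits)
        av = float(r["activity_value"]) if r["activity_value"] not in ("", "NA") else None
        haplotypes[gene][name] = HaplotypeDef(gene, name, frozenset(defs), r["function"], av)

    # every gene gets its reference haplotype even if the allele table omits it
    for gene, g in genes.items():
        ref = g.reference_allele_name
        if ref not in haplotypes[gene]:
            haplotypes[gene][ref] = HaplotypeDef(gene, ref, frozenset(), "normal", None)
        elif haplotypes[gene][ref].defining_variants:
            raise BundleError(
                f"reference haplotype {gene} {ref} has a non-empty defining set")

    freqs = FrequencyTable()
    for r in _read_tsv(d / _FILES["frequencies"], ["gene", "allele", "population", "frequency"]):
        freqs.set(r["gene"], r["allele"], r["population"], float(r["frequency"]))

    phenos = PhenotypeMap()
    for r in _read_tsv(d / _FILES["phenotypes"], ["gene", "allele1", "allele2", "phenotype"]):
        phenos.set(r["gene"], r["allele1"], r["allele2"], r["phenotype"])

    equiv = EquivalenceRules()
    eq_path = d / _FILES["equivalences"]
    if eq_path.exists():
        for r in _read_tsv(eq_path, ["gene", "from_allele", "to_allele"]):
            equiv.add(r["gene"], r["from_allele"], r["to_allele"])
    bad = equiv.check_idempotent()
    if bad:
        raise BundleError("; ".join(bad))

    sum_errs = freqs.check_sums()
    if sum_errs:
        raise BundleError("; ".join(sum_errs))

    activity = None
    if activity_gene is None:
        for gene in genes:
            if any(h.activity_value is not None for h in haplotypes[gene].values()):
                activity_gene = gene
                break
    if activity_gene is not None:
        vals = {
            h.name: h.activity_value
            for h in haplotypes.get(activity_gene, {}).values()
            if h.activity_value is not None
        }
        activity = ActivityConfig(gene=activity_gene, activity_values=vals)
        activity.activity_values.setdefault(activity.deletion_allele, 0.0)

    return ContentBundle(genes, variants, haplotypes, freqs, phenos, equiv, activity)


def write_bundle(dir_path: str | Path, bundle: ContentBundle) -> None:
    """Write a bundle back to its TSV directory layout (inverse of load)."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)

    with open(d / _FILES["genes"], "w") as fh:
        fh.write("gene\tchrom\tstart\tend\treference_allele_name\tploidy_model\n")
        for g in sorted(bundle.genes.values(), key=lambda g: g.gene):
            fh.write(f"{g.gene}\t{g.chrom}\t{g.start}\t{g.end}\t"
                     f"{g.reference_allele_name}\t{g.ploidy_model}\n")

    with open(d / _FILES["variants"], "w") as fh:
        fh.write("gene\trsid\tchrom\tpos\tref\talt\n")
        for v in sorted(bundle.variants):
            fh.write(f"{v.gene}\t{v.rsid}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\n")

    with open(d / _FILES["haplotypes"], "w") as fh:
        fh.write("gene\tallele\trsids\tfunction\tactivity_value\n")
        for gene in sorted(bundle.haplotypes):
            for h in bundle.alleles_of(gene):
                rsids = ";".join(sorted({v.rsid for v in h.defining_variants}))
                av = "" if h.activity_value is None else repr(h.activity_value)
                fh.write(f"{gene}\t{h.name}\t{rsids}\t{h.function}\t{av}\n")

    with open(d / _FILES["frequencies"], "w") as fh:
        fh.write("gene\tallele\tpopulation\tfrequency\n")
        for (gene, allele, pop), f in sorted(bundle.frequencies.items()):
            fh.write(f"{gene}\t{allele}\t{pop}\t{f!r}\n")

    with open(d / _FILES["phenotypes"], "w") as fh:
        fh.write("gene\tallele1\tallele2\tphenotype\n")
        for (gene, pair), label in sorted(bundle.phenotypes.items()):
            fh.write(f"{gene}\t{pair[0]}\t{pair[1]}\t{label}\n")

    with open(d / _FILES["equivalences"], "w") as fh:
        fh.write("gene\tfrom_allele\tto_allele\n")
        for gene, src, dst in sorted(bundle.equivalences.items()):
            fh.write(f"{gene}\t{src}\t{dst}\n")


def validate_bundle(bundle: ContentBundle) -> list[Finding]:
    """Enumerate content problems that do not prevent loading.

    Deterministic and side-effect free; an empty list means the bundle is
    internally consistent.  Reported findings:

    * ``indistinguishable_pair`` — two alleles of one gene with identical
      defining-variant sets (the panel cannot tell them apart);
    * ``frequency_unknown_allele`` — a frequency row for an allele the
      haplotype table does not define;
    * ``phenotype_unknown_allele`` — a phenotype-map row naming an
      undefined allele.
    """
    findings: list[Finding] = []
    deletion = bundle.activity.deletion_allele if bundle.activity else None

    for gene in sorted(bundle.haplotypes):
        alleles = bundle.alleles_of(gene)
        for i, h1 in enumerate(alleles):
            for h2 in alleles[i + 1:]:
                if h1.defining_variants == h2.defining_variants:
                    findings.append(Finding(
                        "indistinguishable_pair", gene, f"{h1.name} and {h2.name}"))

    known = {(gene, name) for gene, hs in bundle.haplotypes.items() for name in hs}
    if deletion is not None:
        known |= {(gene, deletion) for gene in bundle.haplotypes}

    for (gene, allele, pop), _ in sorted(bundle.frequencies.items()):
        if (gene, allele) not in known:
            findings.append(Finding(
                "frequency_unknown_allele", gene, f"{allele} (population {pop})"))

    for (gene, pair), _ in sorted(bundle.phenotypes.items()):
        for a in pair:
            if (gene, a) not in known:
                findings.append(Finding("phenotype_unknown_allele", gene, a))

    return findings
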
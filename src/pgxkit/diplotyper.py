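"""Star-allele diplotype calling from unphased alt-allele dosages.

For each gene the caller enumerates every unordered pair of defined
haplotypes whose combined variant carriage reproduces the observed
dosages, then resolves ambiguity (multiple consistent pairs) by
population-specific haplotype frequency under Hardy-Weinberg pair
weighting.  Missing defining sites default to the reference state, which
biases towards the wild-type allele and is flagged on the call as
"possible" — the clinically conservative behaviour for an assay whose
no-calls must not silently invent variant alleles.

Whole-gene copy-number states feed in afterwards: a deletion rewrites an
apparently homozygous pair to carry the deletion allele (*5 by
convention), and a duplication annotates the call with "copy number>=3"
because array intensity cannot say which allele is duplicated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

from .cnv import STATE_3PLUS, STATE_NO_CALL, CopyNumberState
from .model import (
    ContentBundle,
    FrequencyTable,
    HaplotypeDef,
    VariantDef,
    allele_sort_key,
    normalize_pair,
)

CN_GTE3 = "copy number≥3"  # "copy number≥3"
ANNOT_DELETION = "deletion_applied"
ANNOT_CNV_NO_CALL = "cnv_no_call"


@dataclass(frozen=True)
class CandidateDiplotype:
    """One allele pair consistent with the observed dosages."""

    pair: tuple[str, ...]  # order-normalized; length 1 for hemizygous calls
    prior: float = 0.0
    consistent_with_missing: bool = False


@dataclass(frozen=True)
class DiplotypeCall:
    gene: str
    sample: str
    pair: Optional[tuple[str, ...]] = None
    no_call_reason: str = ""
    ambiguous: bool = False
    possible: bool = False
    candidates: tuple[CandidateDiplotype, ...] = ()
    cnv_annotation: str = ""

    @property
    def is_call(self) -> bool:
        return self.pair is not None


def _pair_key(pair: tuple[str, ...]) -> tuple:
    return tuple(allele_sort_key(a) for a in pair)


def enumerate_candidates(dosages: Mapping[VariantDef, Optional[int]],
                         alleles: Sequence[HaplotypeDef]) -> list[CandidateDiplotype]:
    """All unordered haplotype pairs consistent with the dosages.

    A pair (h1, h2) is consistent iff at every defining variant with a
    non-missing dosage d, carriers(h1) + carriers(h2) = d.  Missing
    dosages are treated as 0 for the consistency test; if any defining
    site of the gene is missing, every returned candidate is flagged
    ``consistent_with_missing`` (its selection relied on assuming the
    reference state there).  Dosages at variants that define no allele of
    this gene are ignored.  Returns candidates sorted by the global allele
    ordering; empty list when no pair is consistent.
    """
    defining_universe: set[VariantDef] = set()
    for h in alleles:
        defining_universe |= h.defining_variants
    # a site absent from the mapping, or mapped to None, is a missing call
    target = {v: (dosages.get(v) if dosages.get(v) is not None else 0)
              for v in defining_universe}
    any_missing = any(dosages.get(v) is None for v in defining_universe)

    ordered = sorted(alleles, key=lambda h: allele_sort_key(h.name))
    out: list[CandidateDiplotype] = []
    for i, h1 in enumerate(ordered):
        for h2 in ordered[i:]:
            if all(h1.carriers(v) + h2.carriers(v) == d for v, d in target.items()):
                out.append(CandidateDiplotype(
                    pair=normalize_pair(h1.name, h2.name),
                    consistent_with_missing=any_missing,
                ))
    out.sort(key=lambda c: _pair_key(c.pair))
    return out


def enumerate_candidates_haploid(dosages: Mapping[VariantDef, Optional[int]],
                                 alleles: Sequence[HaplotypeDef]) -> list[CandidateDiplotype]:
    """Single-haplotype candidates for hemizygous samples (dosage in {0,1})."""
    defining_universe: set[VariantDef] = set()
    for h in alleles:
        defining_universe |= h.defining_variants
    target = {v: (min(dosages.get(v), 1) if dosages.get(v) is not None else 0)
              for v in defining_universe}
    any_missing = any(dosages.get(v) is None for v in defining_universe)

    out = []
    for h in sorted(alleles, key=lambda a: allele_sort_key(a.name)):
        if all(h.carriers(v) == d for v, d in target.items()):
            out.append(CandidateDiplotype((h.name,), consistent_with_missing=any_missing))
    return out


def _prior(pair: tuple[str, ...], gene: str, population: str,
           freqs: FrequencyTable) -> float:
    """Hardy-Weinberg pair prior from population allele frequencies.

    f(a)·f(b), doubled for heterozygous pairs; hemizygous calls use f(a)
    alone.  Alleles absent from the table under both the population and
    GLOBAL codes contribute frequency 0.
    """
    if len(pair) == 1:
        return freqs.freq(gene, pair[0], population)
    a, b = pair
    p = freqs.freq(gene, a, population) * freqs.freq(gene, b, population)
    return 2.0 * p if a != b else p


def resolve_ambiguity(gene: str, sample: str,
                      candidates: Sequence[CandidateDiplotype],
                      population: str, freqs: FrequencyTable) -> DiplotypeCall:
    """Pick one diplotype from the consistent candidates.

    A single candidate is returned unflagged (apart from any missing-site
    fallback).  With several candidates the frequency-weighted prior is
    maximized; ties break by the global allele ordering of the pair, so
    resolution is deterministic even on degenerate frequency content.
    Ambiguously resolved calls are flagged both ``ambiguous`` and
    ``possible``.
    """
    if not candidates:
        raise ValueError("resolve_ambiguity requires a non-empty candidate list")

    scored = tuple(
        replace(c, prior=_prior(c.pair, gene, population, freqs)) for c in candidates
    )
    winner = min(scored, key=lambda c: (-c.prior, _pair_key(c.pair)))
    ambiguous = len(scored) > 1
    return DiplotypeCall(
        gene=gene,
        sample=sample,
        pair=winner.pair,
        ambiguous=ambiguous,
        possible=ambiguous or winner.consistent_with_missing,
        candidates=scored,
    )


def apply_cyp2d6_cnv(call: DiplotypeCall, state: CopyNumberState,
                     deletion_allele: str = "*5") -> DiplotypeCall:
    """Adjust a diplotype call for the gene's whole-gene copy-number state.

    state 2 — unchanged.  CNV no_call — SNV call kept, annotated that CNV
    status is unknown.  state 1 — a homozygous-looking pair X/X becomes
    X/*5 (one physical copy); a heterozygous pair cannot coexist with one
    copy and becomes no_call.  state 0 — *5/*5 regardless of SNV dosages.
    state 3+ — pair kept, annotated "copy number>=3" (the duplicated
    allele cannot be specified from array data).
    """
    if state.state == STATE_NO_CALL:
        return replace(call, cnv_annotation=ANNOT_CNV_NO_CALL)
    if state.state == "2":
        return call
    if state.state == "0":
        return replace(call, pair=(deletion_allele, deletion_allele),
                       cnv_annotation=ANNOT_DELETION, no_call_reason="")
    if state.state == "1":
        if not call.is_call:
            return call
        if len(call.pair) == 2 and call.pair[0] == call.pair[1]:
            pair = normalize_pair(call.pair[0], deletion_allele)
            return replace(call, pair=pair, cnv_annotation=ANNOT_DELETION)
        return replace(call, pair=None, no_call_reason="cn_inconsistent",
                       cnv_annotation=ANNOT_DELETION)
    if state.state == STATE_3PLUS:
        return replace(call, cnv_annotation=CN_GTE3)
    raise ValueError(f"unknown copy-number state {state.state!r}")


def call_gene(bundle: ContentBundle, dosages: Mapping[VariantDef, Optional[int]],
              gene: str, sample: str, population: str,
              copy_state: Optional[CopyNumberState] = None,
              hemizygous: bool = False) -> DiplotypeCall:
    """End-to-end diplotype call for one sample and gene."""
    alleles = bundle.alleles_of(gene)
    if hemizygous:
        cands = enumerate_candidates_haploid(dosages, alleles)
    else:
        cands = enumerate_candidates(dosages, alleles)
    if not cands:
        call = DiplotypeCall(gene, sample, no_call_reason="inconsistent_genotypes")
    else:
        call = resolve_ambiguity(gene, sample, cands, population, bundle.frequencies)
    if copy_state is not None and bundle.activity and gene == bundle.activity.gene:
        call = apply_cyp2d6_cnv(call, copy_state, bundle.activity.deletion_allele)
    return call


def write_diplotype_calls(path, calls: Sequence[DiplotypeCall]) -> None:
    """Write the diplotype TSV (one row per sample x gene, sorted)."""
    with open(path, "w") as fh:
        fh.write("sample\tgene\tallele1\tallele2\tambiguous\tpossible\t"
                 "cnv_annotation\tcandidates\tno_call_reason\n")
        for c in sorted(calls, key=lambda c: (c.sample, c.gene)):
            a1 = c.pair[0] if c.is_call else ""
            a2 = c.pair[1] if c.is_call and len(c.pair) > 1 else ""
            cands = ";".join(f"{'/'.join(k.pair)}:{k.prior:.6g}" for k in c.candidates)
            fh.write(f"{c.sample}\t{c.gene}\t{a1}\t{a2}\t{int(c.ambiguous)}\t"
                     f"{int(c.possible)}\t{c.cnv_annotation}\t{cands}\t{c.no_call_reason}\n")
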
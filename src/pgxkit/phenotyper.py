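"""Diplotype-to-metabolizer-phenotype interpretation.

Most genes are a curated lookup: (gene, unordered diplotype) -> phenotype
label.  The copy-number-modelled gene (CYP2D6 in practice) instead uses an
activity score — the sum of per-allele activity values over the copies
carried.  Under a duplication the duplicated allele is unknown, so both
copy assignments are enumerated up to the configured copy cap (default 3
total copies), giving a *range* of activity scores; when the range spans
two phenotype bins, the score of the more population-frequent copy
assignment decides the label, and the call is qualified as "Possible".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .cnv import STATE_3PLUS, CopyNumberState
from .diplotyper import CN_GTE3, DiplotypeCall
from .model import (
    ActivityConfig,
    ContentBundle,
    FrequencyTable,
    GLOBAL_POP,
    PhenotypeMap,
    allele_sort_key,
)

INDETERMINATE = "Indeterminate"


@dataclass(frozen=True)
class CopyPermutation:
    """One assignment of copy counts to the two alleles under duplication."""

    copies: tuple[tuple[str, int], ...]  # ((allele, n_copies), ...)
    score: float
    weight: float  # Hardy-Weinberg-style frequency weight

    @property
    def duplicated_allele(self) -> str:
        return max(self.copies, key=lambda c: c[1])[0]


@dataclass(frozen=True)
class ActivityScoreRange:
    low: float
    high: float
    permutations: tuple[CopyPermutation, ...] = ()


@dataclass(frozen=True)
class PhenotypeCall:
    gene: str
    sample: str
    label: str
    possible: bool = False
    activity_low: Optional[float] = None
    activity_high: Optional[float] = None

    def rendered(self, template: str = "Possible {label}") -> str:
        """Report-layer rendering; the ``possible`` flag is canonical."""
        return template.format(label=self.label) if self.possible else self.label


def phenotype_from_diplotype(call: DiplotypeCall, pmap: PhenotypeMap) -> PhenotypeCall:
    """Order-invariant phenotype lookup; unmapped pairs are Indeterminate."""
    if not call.is_call:
        return PhenotypeCall(call.gene, call.sample, INDETERMINATE)
    pair = call.pair if len(call.pair) == 2 else (call.pair[0], call.pair[0])
    label = pmap.get(call.gene, *pair)
    if label is None:
        return PhenotypeCall(call.gene, call.sample, INDETERMINATE, possible=call.possible)
    return PhenotypeCall(call.gene, call.sample, label, possible=call.possible)


def cyp2d6_activity_range(pair: tuple[str, str], state: str, cfg: ActivityConfig,
                          freqs: Optional[FrequencyTable] = None,
                          population: str = GLOBAL_POP) -> Optional[ActivityScoreRange]:
    """Activity-score range for an allele pair under a copy-number state.

    Diploid (and deletion-substituted) states give a point score: the sum
    of the two allele values (the deletion allele contributes 0).  Under
    duplication ("3+") both assignments of the extra copy are enumerated
    up to ``cfg.max_copies`` total copies: scores 2·v(a)+v(b) and
    v(a)+2·v(b), weighted by the frequency of each copy assignment,
    f(x)^copies(x) per allele.  Returns None when either allele lacks an
    activity value (the phenotype then falls back to Indeterminate).
    """
    a, b = pair
    va, vb = cfg.value(a), cfg.value(b)
    if va is None or vb is None:
        return None

    if state != STATE_3PLUS:
        s = va + vb
        return ActivityScoreRange(s, s)

    def weight(copies: dict[str, int]) -> float:
        if freqs is None:
            return 0.0
        w = 1.0
        for allele, n in copies.items():
            w *= freqs.freq(cfg.gene, allele, population) ** n
        return w

    extra = cfg.max_copies - 2  # extra copies available beyond the diploid pair
    perms = []
    # enumerate which allele receives the extra copies (cap 3 => one extra copy)
    seen = set()
    for dup, other, vdup, voth in ((a, b, va, vb), (b, a, vb, va)):
        copies = {dup: 1 + extra, other: 1} if dup != other else {dup: 2 + extra}
        key = tuple(sorted(copies.items()))
        if key in seen:
            continue
        seen.add(key)
        score = sum(cfg.value(al) * n for al, n in copies.items())
        perms.append(CopyPermutation(key, score, weight(copies)))

    scores = [p.score for p in perms]
    return ActivityScoreRange(min(scores), max(scores), tuple(perms))


def metabolizer_from_activity(rng: ActivityScoreRange, cfg: ActivityConfig,
                              duplicated: bool = False,
                              gene: str = "", sample: str = "") -> PhenotypeCall:
    """Bin an activity-score range into a metabolizer label.

    When the range endpoints fall in different bins, the label follows the
    score of the highest-weight copy permutation (tie: the permutation
    whose duplicated allele sorts first in the global allele ordering).
    Any duplicated call is qualified "Possible" — another profile remains
    possible because the duplicated allele is unresolved.
    """
    gene = gene or cfg.gene
    lo_label = cfg.bin_label(rng.low)
    hi_label = cfg.bin_label(rng.high)
    if lo_label == hi_label:
        label = lo_label
    else:
        best = min(rng.permutations,
                   key=lambda p: (-p.weight, allele_sort_key(p.duplicated_allele)))
        label = cfg.bin_label(best.score)
    return PhenotypeCall(gene, sample, label, possible=duplicated,
                         activity_low=rng.low, activity_high=rng.high)


def phenotype_call(bundle: ContentBundle, call: DiplotypeCall,
                   population: str = GLOBAL_POP) -> PhenotypeCall:
    """Phenotype one diplotype call, routing the activity-score gene.

    The activity path is taken for the configured copy-number gene when a
    duplication annotation is present (the lookup table has no entry for
    an unresolved three-copy diplotype) or when the pair carries activity
    values; otherwise the curated map is consulted.
    """
    cfg = bundle.activity
    if (call.is_call and cfg is not None and call.gene == cfg.gene
            and len(call.pair) == 2):
        duplicated = call.cnv_annotation == CN_GTE3
        state = STATE_3PLUS if duplicated else "2"
        rng = cyp2d6_activity_range(call.pair, state, cfg, bundle.frequencies,
                                    population)
        if rng is not None:
            pheno = metabolizer_from_activity(rng, cfg, duplicated,
                                              gene=call.gene, sample=call.sample)
            if not duplicated and call.possible:
                pheno = PhenotypeCall(pheno.gene, pheno.sample, pheno.label, True,
                                      pheno.activity_low, pheno.activity_high)
            return pheno
    return phenotype_from_diplotype(call, bundle.phenotypes)


def write_phenotype_calls(path, calls: Sequence[PhenotypeCall]) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgene\tphenotype\tpossible\tactivity_low\tactivity_high\n")
        for c in sorted(calls, key=lambda c: (c.sample, c.gene)):
            lo = "" if c.activity_low is None else c.activity_low
            hi = "" if c.activity_high is None else c.activity_high
            fh.write(f"{c.sample}\t{c.gene}\t{c.label}\t{int(c.possible)}\t{lo}\t{hi}\n")
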
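"""Analytical-validation statistics for genotype and diplotype calls.

Implements the accuracy framework used to validate an array PGx assay
against truth sets: per-(sample, site) confusion classification with
dosage-mismatch handling, the six summary metrics (callability, genotype
concordance, analytical sensitivity/specificity, precision, no-call rate)
with Wilson score intervals, bootstrap percentile intervals for means,
equivalence-adjusted diplotype and phenotype concordance, per-site
concordance reports, and intra-/inter-run replicate concordance.

All percentages are reported on the percent scale rounded to two decimals
(half-up), matching how such validation tables are conventionally printed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

from .model import ContentBundle, EquivalenceRules, VariantDef
from .genotype_qc import GenotypeTable

# Two-sided 95% normal critical value; kept at 6 decimals rather than the
# rounded 1.96 — the difference is below 2-decimal print resolution.
Z_DEFAULT = 1.959964

CAT_TP_HOM = "TP_hom"
CAT_TP_HET = "TP_het"
CAT_TN = "TN"
CAT_FP = "FP"
CAT_FN = "FN"
CAT_NO_CALL = "no_call"
CAT_NOT_IN_REF = "not_in_reference"


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (printed tables round 0.005 away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def wilson_interval(k: int, n: int, conf: float = 0.95,
                    z: float = Z_DEFAULT) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, on the percent scale.

    Returns (low, high) in percent, rounded to 2 decimals.  Well-behaved at
    proportions of 0 and 1, unlike the Wald interval.
    """
    if n < 1:
        raise ValueError("wilson_interval requires n >= 1")
    if not (0 <= k <= n):
        raise ValueError(f"k={k} out of [0, n={n}]")
    if conf != 0.95:
        # inverse-normal via the Acklam-style rational approximation is
        # overkill here; the framework only reports 95% intervals and the
        # critical value is configuration
        raise ValueError("only conf=0.95 is supported; override z directly for others")
    p = k / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (round_half_up(100.0 * (center - half)),
            round_half_up(100.0 * (center + half)))


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion (percent) with its confidence interval."""

    name: str
    point: float  # percent, 2 decimals
    k: int
    n: int
    ci_low: float
    ci_high: float
    method: str = "wilson"
    conf: float = 0.95

    def __post_init__(self):
        if not (0.0 <= self.ci_low <= self.ci_high <= 100.0):
            raise ValueError(f"{self.name}: bad CI [{self.ci_low}, {self.ci_high}]")


def proportion_estimate(name: str, k: int, n: int) -> Optional[MetricEstimate]:
    """k/n as a percent with its Wilson interval; None on an empty denominator."""
    if n == 0:
        return None
    lo, hi = wilson_interval(k, n)
    return MetricEstimate(name, round_half_up(100.0 * k / n), k, n, lo, hi)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0
    no_call: int = 0

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn, self.no_call) < 0:
            raise ValueError("negative confusion count")

    @property
    def considered(self) -> int:
        return self.tp + self.tn + self.fp + self.fn + self.no_call


def classify_dosages(truth: int, query: Optional[int]) -> str:
    """Confusion category for one (truth, query) dosage pair.

    Partial dosage mismatches follow the direction of the error: the assay
    reporting fewer alt copies than truth (q < t) under-calls the variant
    (FN); reporting more (q > t, truth non-zero) over-calls it (FP).
    """
    if query is None:
        return CAT_NO_CALL
    if truth == 0:
        return CAT_TN if query == 0 else CAT_FP
    if query == truth:
        return CAT_TP_HOM if truth == 2 else CAT_TP_HET
    if query < truth:
        return CAT_FN
    return CAT_FP


def classify_site_calls(query: GenotypeTable, truth: GenotypeTable,
                        targets: Sequence[VariantDef] | None = None
                        ) -> tuple[ConfusionCounts, dict[tuple[str, VariantDef], str]]:
    """Classify every (sample, target) call against the truth table.

    Sites missing from the truth table for a sample are
    ``not_in_reference`` and excluded from the counts.  Raises when the
    truth table lacks any requested target entirely.
    """
    targets = list(targets) if targets is not None else list(query.targets)
    missing_t = [v for v in targets if v not in truth._tidx]
    missing_q = [v for v in targets if v not in query._tidx]
    if missing_t or missing_q:
        raise ValueError(
            f"target universe mismatch: {len(missing_t)} absent from truth, "
            f"{len(missing_q)} absent from query")

    categories: dict[tuple[str, VariantDef], str] = {}
    counts = {c: 0 for c in (CAT_TP_HOM, CAT_TP_HET, CAT_TN, CAT_FP, CAT_FN, CAT_NO_CALL)}
    for s in query.samples:
        qd = query.dosages_for(s, targets)
        td = truth.dosages_for(s, targets) if s in truth._sidx else {v: None for v in targets}
        for v in targets:
            t = td[v]
            if t is None:
                categories[(s, v)] = CAT_NOT_IN_REF
                continue
            cat = classify_dosages(t, qd[v])
            categories[(s, v)] = cat
            counts[cat] += 1
    cc = ConfusionCounts(tp=counts[CAT_TP_HOM] + counts[CAT_TP_HET], tn=counts[CAT_TN],
                         fp=counts[CAT_FP], fn=counts[CAT_FN], no_call=counts[CAT_NO_CALL])
    return cc, categories


@dataclass(frozen=True)
class CategoryOverride:
    """A manual-review override of one (sample, site) category.

    Discordances in structurally complex genes are sometimes resolved by
    external evidence (known copy number, sex); such adjustments are
    consumed from an explicit, auditable table — never applied silently.
    """

    sample: str
    rsid: str
    new_category: str
    justification: str


def apply_overrides(categories: Mapping[tuple[str, VariantDef], str],
                    overrides: Iterable[CategoryOverride]
                    ) -> dict[tuple[str, VariantDef], str]:
    out = dict(categories)
    by_rsid: dict[tuple[str, str], list[tuple[str, VariantDef]]] = {}
    for (s, v) in out:
        by_rsid.setdefault((s, v.rsid), []).append((s, v))
    for ov in overrides:
        for key in by_rsid.get((ov.sample, ov.rsid), []):
            out[key] = ov.new_category
    return out


def counts_from_categories(categories: Mapping[tuple[str, VariantDef], str]) -> ConfusionCounts:
    c = {k: 0 for k in (CAT_TP_HOM, CAT_TP_HET, CAT_TN, CAT_FP, CAT_FN, CAT_NO_CALL)}
    for cat in categories.values():
        if cat in c:
            c[cat] += 1
    return ConfusionCounts(tp=c[CAT_TP_HOM] + c[CAT_TP_HET], tn=c[CAT_TN],
                           fp=c[CAT_FP], fn=c[CAT_FN], no_call=c[CAT_NO_CALL])


def metrics(counts: ConfusionCounts) -> dict[str, Optional[MetricEstimate]]:
    """The six accuracy metrics with Wilson intervals.

    callability      = called / considered
    concordance      = (TP+TN) / called
    sensitivity      = TP / (TP+FN)        (truth-variant sites recovered)
    specificity      = TN / (TN+FP)        (truth-reference sites recovered)
    precision        = TP / (TP+FP)        (reported variants that are real)
    no_call_rate     = no-calls / considered

    A metric with an empty denominator is reported as None, not 0.
    """
    called = counts.tp + counts.tn + counts.fp + counts.fn
    return {
        "callability": proportion_estimate("callability", called, counts.considered),
        "genotype_concordance": proportion_estimate(
            "genotype_concordance", counts.tp + counts.tn, called),
        "sensitivity": proportion_estimate(
            "sensitivity", counts.tp, counts.tp + counts.fn),
        "specificity": proportion_estimate(
            "specificity", counts.tn, counts.tn + counts.fp),
        "precision": proportion_estimate(
            "precision", counts.tp, counts.tp + counts.fp),
        "no_call_rate": proportion_estimate(
            "no_call_rate", counts.no_call, counts.considered),
    }


def bootstrap_mean_ci(values: Sequence[float], reps: int = 10000,
                      seed: int = 0, conf: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap interval for the mean of per-sample values."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("bootstrap_mean_ci requires at least one value")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(reps, vals.size))
    means = vals[idx].mean(axis=1)
    alpha = (1.0 - conf) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Diplotype / phenotype concordance


def _as_multiset(pair: Sequence[str]) -> tuple[str, ...]:
    return tuple(sorted(pair))


def pairs_concordant(query: Sequence[str], truth: Sequence[str],
                     gene: str, rules: EquivalenceRules) -> bool:
    """Unordered, equivalence-rewritten comparison of two allele-label lists.

    Works for classic two-allele diplotypes and for genes reported as a
    list of variant labels (compared as multisets, order-insensitive).
    """
    q = _as_multiset(rules.rewrite(gene, a) for a in query)
    t = _as_multiset(rules.rewrite(gene, a) for a in truth)
    return q == t


@dataclass(frozen=True)
class GeneConcordance:
    gene: str
    callability: Optional[MetricEstimate]
    concordance: Optional[MetricEstimate]


def diplotype_concordance(query: Mapping[tuple[str, str], Optional[tuple[str, ...]]],
                          truth: Mapping[tuple[str, str], tuple[str, ...]],
                          rules: EquivalenceRules) -> dict[str, GeneConcordance]:
    """Per-gene diplotype callability and concordance against a truth set.

    ``query`` maps (sample, gene) to the called allele tuple or None for a
    no-call; ``truth`` holds reference diplotypes.  Callability counts
    query calls over samples *with* a truth call; concordance counts
    matches over samples with both.
    """
    genes = sorted({g for (_, g) in truth})
    out: dict[str, GeneConcordance] = {}
    for gene in genes:
        with_truth = [(s, g) for (s, g) in truth if g == gene]
        called = [k for k in with_truth if query.get(k) is not None]
        concordant = [
            k for k in called
            if pairs_concordant(query[k], truth[k], gene, rules)
        ]
        out[gene] = GeneConcordance(
            gene,
            callability=proportion_estimate(f"{gene}.diplotype_callability",
                                            len(called), len(with_truth)),
            concordance=proportion_estimate(f"{gene}.diplotype_concordance",
                                            len(concordant), len(called)),
        )
    return out


def strip_possible(label: str) -> str:
    for prefix in ("Possibly ", "Possible "):
        if label.startswith(prefix):
            return label[len(prefix):]
    return label


def label_comparator(query: str, truth: str) -> bool:
    """Default phenotype comparator: exact label, ignoring the Possible qualifier."""
    return strip_possible(query) == strip_possible(truth)


def allele_presence_comparator(allele: str) -> Callable[[str, str], bool]:
    """Comparator on "/"-joined diplotype strings: agree on presence of one allele.

    Used for genes where a single allele drives the recommendation, so any
    two diplotypes agreeing on its presence/absence are phenotype-equivalent.
    """
    def cmp(query: str, truth: str) -> bool:
        return (allele in query.split("/")) == (allele in truth.split("/"))
    return cmp


def phenotype_concordance(query: Mapping[tuple[str, str], Optional[str]],
                          truth: Mapping[tuple[str, str], str],
                          comparators: Mapping[str, Callable[[str, str], bool]] | None = None
                          ) -> dict[str, GeneConcordance]:
    """Per-gene phenotype callability and concordance.

    Values are phenotype labels (or diplotype strings for genes using an
    allele-presence comparator); a None query value is a no-call.
    """
    comparators = comparators or {}
    genes = sorted({g for (_, g) in truth})
    out: dict[str, GeneConcordance] = {}
    for gene in genes:
        cmp = comparators.get(gene, label_comparator)
        with_truth = [(s, g) for (s, g) in truth if g == gene]
        called = [k for k in with_truth if query.get(k) is not None]
        concordant = [k for k in called if cmp(query[k], truth[k])]
        out[gene] = GeneConcordance(
            gene,
            callability=proportion_estimate(f"{gene}.phenotype_callability",
                                            len(called), len(with_truth)),
            concordance=proportion_estimate(f"{gene}.phenotype_concordance",
                                            len(concordant), len(called)),
        )
    return out


# ---------------------------------------------------------------------------
# Per-site and replicate reports


@dataclass(frozen=True)
class SiteReport:
    variant: VariantDef
    counts: dict
    concordance: Optional[float]  # percent over in-reference, non-missing calls
    evaluable_with_tp: bool


def per_site_report(categories: Mapping[tuple[str, VariantDef], str],
                    threshold: float = 95.0
                    ) -> tuple[list[SiteReport], dict[str, float | int]]:
    """Per-site concordance table and the fraction of sites above threshold.

    Site concordance is (TP+TN)/(TP+TN+FP+FN) over samples where the site
    is in the reference and called; a site is evaluable-with-TP when at
    least one true positive was observed for it.
    """
    per_site: dict[VariantDef, dict[str, int]] = {}
    for (s, v), cat in categories.items():
        per_site.setdefault(v, {}).setdefault(cat, 0)
        per_site[v][cat] += 1

    reports = []
    n_above = 0
    n_scored = 0
    for v in sorted(per_site):
        c = per_site[v]
        correct = c.get(CAT_TP_HOM, 0) + c.get(CAT_TP_HET, 0) + c.get(CAT_TN, 0)
        compared = correct + c.get(CAT_FP, 0) + c.get(CAT_FN, 0)
        conc = round_half_up(100.0 * correct / compared) if compared else None
        if conc is not None:
            n_scored += 1
            if conc >= threshold:
                n_above += 1
        reports.append(SiteReport(
            v, dict(c), conc,
            evaluable_with_tp=(c.get(CAT_TP_HOM, 0) + c.get(CAT_TP_HET, 0)) > 0))
    summary = {
        "sites_scored": n_scored,
        "sites_at_or_above_threshold": n_above,
        "fraction_percent": round_half_up(100.0 * n_above / n_scored) if n_scored else float("nan"),
        "threshold": threshold,
    }
    return reports, summary


@dataclass(frozen=True)
class ReplicateCall:
    sample: str
    run_id: str
    replicate_id: str
    value: Optional[str]  # genotype/diplotype/phenotype rendering; None = missing


def replicate_concordance(calls: Sequence[ReplicateCall]
                          ) -> dict[str, Optional[MetricEstimate]]:
    """Pairwise agreement among same-sample replicates.

    Pairs within one run contribute to intra-run concordance, pairs across
    runs to inter-run.  Pairs where both replicates are missing are
    excluded; a pair with exactly one missing value counts as disagreement.
    Returns None estimates when no pair exists at a level.
    """
    by_sample: dict[str, list[ReplicateCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample, []).append(c)

    agree = {"intra_run": 0, "inter_run": 0}
    total = {"intra_run": 0, "inter_run": 0}
    for reps in by_sample.values():
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                a, b = reps[i], reps[j]
                if a.value is None and b.value is None:
                    continue
                level = "intra_run" if a.run_id == b.run_id else "inter_run"
                total[level] += 1
                if a.value == b.value:
                    agree[level] += 1
    return {
        level: proportion_estimate(f"{level}_concordance", agree[level], total[level])
        for level in ("intra_run", "inter_run")
    }


def haplotype_coverage(truth: Mapping[tuple[str, str], tuple[str, ...]],
                       bundle: ContentBundle) -> Optional[MetricEstimate]:
    """Fraction of the bundle's haplotypes observed in the truth diplotypes."""
    defined = {(g, h.name) for g, hs in bundle.haplotypes.items() for h in hs.values()}
    observed = {
        (gene, a) for (_, gene), pair in truth.items() for a in pair
    } & defined
    return proportion_estimate("haplotype_coverage", len(observed), len(defined))
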
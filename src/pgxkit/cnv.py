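"""Copy-number segment QC, filtering and per-gene state reduction.

Consumes CNV segments and per-sample array QC statistics produced by an
upstream intensity-based CNV caller.  Samples with noisy intensity
profiles (high LRR standard deviation, BAF drift, or wave factor) are
excluded; surviving segments are filtered by probe support and span and
reduced to a per-gene copy-number state: 0, 1, 2, "3+" (the duplicated
allele cannot be resolved from array data), or no_call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .model import GeneDef, norm_chrom

STATE_3PLUS = "3+"
STATE_NO_CALL = "no_call"


@dataclass(frozen=True)
class CnvQcThresholds:
    max_lrr_sd: float = 0.2
    max_baf_drift: float = 0.01
    max_wave_factor: float = 0.05


@dataclass(frozen=True)
class CnvSampleQc:
    """Array intensity QC statistics for one sample.

    ``wave_factor`` is assumed already GC-adjusted by the upstream caller.
    """

    sample: str
    lrr_sd: float
    baf_drift: float
    wave_factor: float

    def __post_init__(self):
        if self.lrr_sd < 0 or self.baf_drift < 0:
            raise ValueError(f"{self.sample}: negative QC statistic")


@dataclass(frozen=True)
class CnvSegment:
    """One departure-from-diploid segment (copy_number != 2)."""

    sample: str
    chrom: str
    start: int
    end: int
    copy_number: int
    n_probes: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.sample}: segment start > end")
        if self.copy_number == 2:
            raise ValueError(f"{self.sample}: copy_number 2 is not a CNV segment")
        if self.copy_number < 0 or self.n_probes < 1:
            raise ValueError(f"{self.sample}: bad segment {self.copy_number=} {self.n_probes=}")
        object.__setattr__(self, "chrom", norm_chrom(self.chrom))

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CopyNumberState:
    sample: str
    gene: str
    state: str  # "0" | "1" | "2" | "3+" | "no_call"
    segments: tuple[CnvSegment, ...] = ()
    reason: str = ""


@dataclass(frozen=True)
class CnvQcResult:
    passed: bool
    reasons: tuple[str, ...] = ()


def cnv_sample_qc(qc: CnvSampleQc, thresholds: CnvQcThresholds = CnvQcThresholds()
                  ) -> CnvQcResult:
    """Fail a sample iff any statistic strictly exceeds its threshold."""
    reasons = []
    if qc.lrr_sd > thresholds.max_lrr_sd:
        reasons.append("lrr_sd")
    if qc.baf_drift > thresholds.max_baf_drift:
        reasons.append("baf_drift")
    if qc.wave_factor > thresholds.max_wave_factor:
        reasons.append("wave_factor")
    return CnvQcResult(not reasons, tuple(reasons))


def filter_segments(segs: Iterable[CnvSegment], min_probes: int = 10,
                    min_span_bp: int = 250) -> list[CnvSegment]:
    """Keep segments with >= min_probes probes AND span >= min_span_bp.

    Order-preserving and idempotent; small/poorly-supported segments are
    the dominant source of array CNV false positives.
    """
    return [s for s in segs if s.n_probes >= min_probes and s.span >= min_span_bp]


def _overlap_bp(seg: CnvSegment, gene: GeneDef) -> int:
    if seg.chrom != gene.chrom:
        return 0
    return max(0, min(seg.end, gene.end) - max(seg.start, gene.start) + 1)


def gene_copy_state(segs: Sequence[CnvSegment], gene: GeneDef, qc_pass: bool,
                    min_overlap_frac: float = 0.5) -> CopyNumberState:
    """Reduce filtered segments to one copy-number state for a gene.

    A segment covers the gene iff it overlaps at least ``min_overlap_frac``
    of the gene span (default 50%); partial/hybrid events below that are
    outside the reportable range.  No covering segment means diploid.  A
    deletion segment yields its copy number (0 or 1); a duplication yields
    "3+" — the duplicated allele is not resolvable from total intensity.
    Deletion and duplication both covering the gene is unresolvable and
    yields no_call.
    """
    sample = segs[0].sample if segs else ""
    if not qc_pass:
        return CopyNumberState(sample, gene.gene, STATE_NO_CALL, (), "cnv_sample_qc")

    covering = tuple(
        s for s in segs
        if _overlap_bp(s, gene) >= min_overlap_frac * gene.span
    )
    if not covering:
        return CopyNumberState(sample, gene.gene, "2", ())

    states = {STATE_3PLUS if s.copy_number > 2 else str(s.copy_number) for s in covering}
    if len(states) > 1:
        return CopyNumberState(sample, gene.gene, STATE_NO_CALL, covering,
                               "conflicting_segments")
    return CopyNumberState(covering[0].sample, gene.gene, states.pop(), covering)


# ---------------------------------------------------------------------------
# TSV I/O (mirrors common CNV-caller text output)

def read_segments(path: str | Path) -> list[CnvSegment]:
    segs = []
    with open(path) as fh:
        cols = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            r = dict(zip(cols, line.rstrip("\n").split("\t")))
            segs.append(CnvSegment(r["sample"], r["chrom"], int(r["start"]),
                                   int(r["end"]), int(r["copy_number"]),
                                   int(r["n_probes"])))
    return segs


def read_cnv_qc(path: str | Path) -> dict[str, CnvSampleQc]:
    out = {}
    with open(path) as fh:
        cols = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            r = dict(zip(cols, line.rstrip("\n").split("\t")))
            out[r["sample"]] = CnvSampleQc(r["sample"], float(r["lrr_sd"]),
                                           float(r["baf_drift"]), float(r["wave_factor"]))
    return out


def write_copy_states(path: str | Path, states: Iterable[CopyNumberState]) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgene\tstate\treason\n")
        for st in states:
            fh.write(f"{st.sample}\t{st.gene}\t{st.state}\t{st.reason}\n")
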
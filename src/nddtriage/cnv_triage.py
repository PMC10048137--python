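"""Dual-caller CNV consensus filtering and prioritization.

Calls from two exome CNV callers (caller A, XHMM-like; caller B,
ExomeDepth-like) are filtered in order:

    cohort recurrence -> population SV overlap -> single-caller quality

and surviving calls are promoted to candidates when a matched A/B pair
reaches Phred >= 30 (A) and >= 20 (B).  Interval matching throughout uses
reciprocal overlap; intervals are half-open 0-based.

"Other calls" in the recurrence filter means calls from *other samples* of
the same CNV type; dual-caller support means a same-sample, same-type call
from the other caller with reciprocal overlap >= 0.8.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "CnvType",
    "Caller",
    "CnvCall",
    "PopulationSv",
    "CnvThresholds",
    "CnvStatus",
    "CnvDecision",
    "CnvEvent",
    "CnvTriageResult",
    "reciprocal_overlap",
    "cohort_recurrence_filter",
    "population_sv_filter",
    "caller_concordance_filter",
    "prioritize_cnv",
    "run_cnv_triage",
]


class CnvType(str, Enum):
    DEL = "DEL"
    DUP = "DUP"


class Caller(str, Enum):
    A = "caller_A"  # XHMM-like
    B = "caller_B"  # ExomeDepth-like


@dataclass(frozen=True)
class CnvCall:
    sample_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    type: CnvType
    caller: Caller
    phred: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"malformed CNV interval {self.chrom}:{self.start}-{self.end}")
        if self.phred < 0:
            raise ValueError("Phred quality must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PopulationSv:
    chrom: str
    start: int
    end: int
    type: CnvType
    ac: Optional[int] = None
    af: Optional[float] = None
    source: str = "DGV"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("malformed SV interval")
        if self.ac is None and self.af is None:
            raise ValueError("population SV needs at least one of ac/af")


@dataclass
class CnvThresholds:
    recurrence_ro: float = 0.8
    #: fail when matched by MORE than this many other-sample calls
    recurrence_max_others: int = 3
    popsv_ro: float = 0.9
    popsv_max_ac: int = 10
    popsv_max_af: float = 0.0001
    match_ro: float = 0.8  # dual-caller support stringency
    single_min_phred_a: float = 20.0
    single_min_phred_b: float = 3.0
    candidate_min_phred_a: float = 30.0
    candidate_min_phred_b: float = 20.0


class CnvStatus(str, Enum):
    DISCARDED_RECURRENT = "discarded_recurrent"
    DISCARDED_POPULATION = "discarded_population"
    DISCARDED_CONCORDANCE = "discarded_concordance"
    RETAINED = "retained"
    CANDIDATE = "candidate"

    @property
    def kept(self) -> bool:
        return self in (CnvStatus.RETAINED, CnvStatus.CANDIDATE)


@dataclass
class CnvDecision:
    status: CnvStatus
    reasons: list[str] = field(default_factory=list)


def reciprocal_overlap(a, b) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 across chromosomes.

    ``a``/``b`` are any objects with chrom/start/end attributes.
    """
    if a.end <= a.start or b.end <= b.start:
        raise ValueError("zero-length interval")
    if a.chrom != b.chrom:
        return 0.0
    overlap = min(a.end, b.end) - max(a.start, b.start)
    if overlap <= 0:
        return 0.0
    return min(overlap / (a.end - a.start), overlap / (b.end - b.start))


def cohort_recurrence_filter(
    call: CnvCall,
    cohort_calls: Sequence[CnvCall],
    thresholds: Optional[CnvThresholds] = None,
) -> tuple[bool, Optional[str]]:
    """Fail calls matched (RO >= 0.8, same type) in more than 3 other samples' calls."""
    th = thresholds or CnvThresholds()
    n_others = sum(
        1
        for other in cohort_calls
        if other.sample_id != call.sample_id
        and other.type == call.type
        and reciprocal_overlap(call, other) >= th.recurrence_ro
    )
    if n_others > th.recurrence_max_others:
        return False, "recurrent_in_cohort"
    return True, None


def population_sv_filter(
    call: CnvCall,
    sv_resource: Sequence[PopulationSv],
    thresholds: Optional[CnvThresholds] = None,
) -> tuple[bool, Optional[str]]:
    """Fail calls matching (RO >= 0.9, same type) a common population SV.

    "Common" means allele count > 10 or allele frequency > 1e-4; an absent
    count/frequency simply fails that sub-condition.
    """
    th = thresholds or CnvThresholds()
    for sv in sv_resource:
        if sv.type != call.type:
            continue
        if reciprocal_overlap(call, sv) < th.popsv_ro:
            continue
        common = (sv.ac is not None and sv.ac > th.popsv_max_ac) or (
            sv.af is not None and sv.af > th.popsv_max_af
        )
        if common:
            return False, f"common_in_{sv.source}"
    return True, None


def _dual_support(
    call: CnvCall, cohort_calls: Sequence[CnvCall], th: CnvThresholds
) -> list[CnvCall]:
    """Same-sample, same-type calls from the other caller with RO >= match_ro."""
    return [
        other
        for other in cohort_calls
        if other.sample_id == call.sample_id
        and other.caller != call.caller
        and other.type == call.type
        and reciprocal_overlap(call, other) >= th.match_ro
    ]


def caller_concordance_filter(
    call: CnvCall,
    cohort_calls: Sequence[CnvCall],
    thresholds: Optional[CnvThresholds] = None,
) -> tuple[bool, Optional[str]]:
    """Fail low-quality single-caller calls (A < Phred 20, B < Phred 3)."""
    th = thresholds or CnvThresholds()
    if _dual_support(call, cohort_calls, th):
        return True, None
    floor = th.single_min_phred_a if call.caller == Caller.A else th.single_min_phred_b
    if call.phred < floor:
        return False, "single_caller_low_quality"
    return True, None


def prioritize_cnv(
    call: CnvCall,
    cohort_calls: Sequence[CnvCall],
    thresholds: Optional[CnvThresholds] = None,
) -> CnvDecision:
    """Candidate iff a matched A/B pair has A >= 30 and B >= 20 Phred."""
    th = thresholds or CnvThresholds()
    partners = _dual_support(call, cohort_calls, th)
    if call.caller == Caller.A:
        a_phred, b_phreds = call.phred, [p.phred for p in partners]
    else:
        a_phred, b_phreds = max((p.phred for p in partners), default=-1.0), [call.phred]
        if partners:
            a_phred = max(p.phred for p in partners)
    if (
        partners
        and a_phred >= th.candidate_min_phred_a
        and max(b_phreds) >= th.candidate_min_phred_b
    ):
        return CnvDecision(CnvStatus.CANDIDATE, ["dual_caller_high_quality"])
    return CnvDecision(CnvStatus.RETAINED, ["no_priority_route"])


@dataclass(frozen=True)
class CnvEvent:
    """A merged per-sample candidate event (union of the matched A/B pair)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    type: CnvType


@dataclass
class CnvTriageResult:
    calls: list[CnvCall]
    decisions: list[CnvDecision]
    events: list[CnvEvent]

    def candidates(self) -> list[CnvCall]:
        return [
            c
            for c, d in zip(self.calls, self.decisions)
            if d.status == CnvStatus.CANDIDATE
        ]


def run_cnv_triage(
    calls_a: Iterable[CnvCall],
    calls_b: Iterable[CnvCall],
    sv_resource: Sequence[PopulationSv] = (),
    thresholds: Optional[CnvThresholds] = None,
) -> CnvTriageResult:
    """Filter and prioritize the pooled call set of both callers.

    Matching contexts (recurrence counting, dual-caller support) are
    evaluated against the full input call set, so per-call decisions are
    order-independent and equal an independent per-call re-evaluation.
    """
    th = thresholds or CnvThresholds()
    calls = list(calls_a) + list(calls_b)
    decisions: list[CnvDecision] = []
    for call in calls:
        ok, reason = cohort_recurrence_filter(call, calls, th)
        if not ok:
            decisions.append(CnvDecision(CnvStatus.DISCARDED_RECURRENT, [reason]))
            continue
        ok, reason = population_sv_filter(call, sv_resource, th)
        if not ok:
            decisions.append(CnvDecision(CnvStatus.DISCARDED_POPULATION, [reason]))
            continue
        ok, reason = caller_concordance_filter(call, calls, th)
        if not ok:
            decisions.append(CnvDecision(CnvStatus.DISCARDED_CONCORDANCE, [reason]))
            continue
        decisions.append(prioritize_cnv(call, calls, th))

    # merge dual-caller candidates into one union-interval event per sample
    events: dict[tuple, CnvEvent] = {}
    for call, dec in zip(calls, decisions):
        if dec.status != CnvStatus.CANDIDATE:
            continue
        partners = _dual_support(call, calls, th)
        start = min([call.start] + [p.start for p in partners])
        end = max([call.end] + [p.end for p in partners])
        ev = CnvEvent(call.sample_id, call.chrom, start, end, call.type)
        events[(ev.sample_id, ev.chrom, ev.start, ev.end, ev.type)] = ev
    merged = sorted(
        events.values(), key=lambda e: (e.sample_id, e.chrom, e.start, e.end)
    )
    return CnvTriageResult(calls, decisions, merged)
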
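"""SNV/indel filter cascade, re-analysis rules and the recessive extension.

Stage order in :func:`run_triage`:

    panel restriction -> quality -> frequency -> consequence -> prioritize
    -> (re-analysis mode only) recurrent-artifact flagging

The primary quality rule discards depth < 10 and VAF < 30%.  Re-analysis
keeps the depth rule but relaxes VAF: in the 10 <= depth < 50 band the bound
is 20% for LoF and 25% for non-LoF variants; at depth >= 50 any VAF >= 10%
survives, which is what recovers mosaic calls.  Because every re-analysis
bound is <= 0.30 and the depth rule is shared, the re-analysis retained set
is always a superset of the primary one.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from .variant_model import (
    ClinvarStatus,
    Consequence,
    FilterThresholds,
    FunctionalAnnotation,
    PanelDefinition,
    TriageDecision,
    TriageStatus,
    VariantRecord,
    in_panel,
    is_lof,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TriageMode",
    "quality_filter",
    "frequency_filter",
    "splice_ensemble",
    "consequence_filter",
    "missense_majority_vote",
    "strong_effect",
    "prioritize",
    "flag_recurrent_artifacts",
    "recessive_filter",
    "run_triage",
    "TriageResult",
    "RecessiveResult",
]


class TriageMode(str, Enum):
    PRIMARY = "primary"
    REANALYSIS = "reanalysis"


def quality_filter(
    variant: VariantRecord,
    thresholds: FilterThresholds,
    mode: TriageMode = TriageMode.PRIMARY,
) -> tuple[bool, Optional[str]]:
    """Depth/VAF rule. Returns (passed, failure-reason)."""
    depth = variant.genotype.depth
    vaf = variant.genotype.vaf
    if depth == 0 or vaf is None:
        return False, "no_coverage"
    if depth < thresholds.min_depth:
        return False, "low_depth"
    if mode == TriageMode.PRIMARY:
        if vaf < thresholds.min_vaf_primary:
            return False, "low_vaf"
        return True, None
    # re-analysis: banded VAF bounds
    if depth < thresholds.lowdp_max:
        bound = (
            thresholds.min_vaf_lof_lowdp
            if is_lof(variant.annotation)
            else thresholds.min_vaf_nonlof_lowdp
        )
        if vaf < bound:
            return False, "low_vaf_lowdp_band"
        return True, None
    if vaf < thresholds.mosaic_min_vaf:
        return False, "low_vaf_mosaic_band"
    return True, None


def frequency_filter(
    variant: VariantRecord, thresholds: FilterThresholds
) -> tuple[bool, Optional[str]]:
    """Discard variants with a population allele count above the cap."""
    ac = variant.population.ac
    if ac is not None and ac > thresholds.max_gnomad_ac:
        return False, "gnomad_ac_gt_max"
    return True, None


def splice_ensemble(
    annotation: FunctionalAnnotation, thresholds: Optional[FilterThresholds] = None
) -> bool:
    """True iff any available splice score reaches the cutoff (default 0.5)."""
    cutoff = (thresholds or FilterThresholds()).splice_cutoff
    scores = [s for s in annotation.splice_scores.values() if s is not None]
    return bool(scores) and max(scores) >= cutoff


#: Consequence classes kept regardless of splice scores.
_PROTEIN_AFFECTING = frozenset(
    {
        Consequence.STOP_GAIN,
        Consequence.FRAMESHIFT,
        Consequence.CANONICAL_SPLICE,
        Consequence.START_LOSS,
        Consequence.STOP_LOSS,
        Consequence.INFRAME_INDEL,
        Consequence.MISSENSE,
    }
)


def consequence_filter(
    annotation: FunctionalAnnotation, thresholds: Optional[FilterThresholds] = None
) -> tuple[bool, Optional[str]]:
    """Keep protein-affecting classes plus predicted splice-affecting variants.

    Synonymous and intronic variants only survive via the splice ensemble.
    """
    if annotation.consequence in _PROTEIN_AFFECTING:
        return True, None
    if splice_ensemble(annotation, thresholds):
        return True, None
    return False, "consequence_not_relevant"


def missense_majority_vote(
    annotation: FunctionalAnnotation, thresholds: Optional[FilterThresholds] = None
) -> bool:
    """Deleterious call by at least half of the *available* predictors.

    Zero available predictors is not evidence of deleteriousness -> False.
    """
    frac = (thresholds or FilterThresholds()).majority_fraction
    calls = [c for c in annotation.predictor_calls.values() if c in ("D", "T")]
    if not calls:
        return False
    deleterious = sum(1 for c in calls if c == "D")
    return deleterious / len(calls) >= frac


def strong_effect(
    annotation: FunctionalAnnotation, thresholds: Optional[FilterThresholds] = None
) -> bool:
    """Predicted strong effect on protein function.

    LoF; in-frame indel with PROVEAN <= -2.5; missense with a deleterious
    majority; or any variant the splice ensemble flags.
    """
    th = thresholds or FilterThresholds()
    if is_lof(annotation):
        return True
    if annotation.consequence == Consequence.INFRAME_INDEL:
        if annotation.provean is None:
            logger.warning("in-frame indel with missing PROVEAN score: not strong")
        elif annotation.provean <= th.provean_cutoff:
            return True
    if annotation.consequence == Consequence.MISSENSE and missense_majority_vote(
        annotation, th
    ):
        return True
    return splice_ensemble(annotation, th)


def prioritize(
    variant: VariantRecord, thresholds: Optional[FilterThresholds] = None
) -> TriageDecision:
    """Candidate/retained split for a variant that passed all filters.

    Three routes: ClinVar P/LP, absence from gnomAD, predicted strong
    effect.  ``priority_mode="any"`` (default) promotes on any route;
    ``"conjunction"`` requires all three.
    """
    th = thresholds or FilterThresholds()
    routes: list[str] = []
    if variant.annotation.clinvar in (
        ClinvarStatus.PATHOGENIC,
        ClinvarStatus.LIKELY_PATHOGENIC,
    ):
        routes.append("clinvar_plp")
    if variant.population.absent:
        routes.append("gnomad_absent")
    if strong_effect(variant.annotation, th):
        routes.append("strong_effect")

    if th.priority_mode == "any":
        promoted = bool(routes)
    else:
        promoted = len(routes) == 3
    if promoted:
        return TriageDecision(TriageStatus.CANDIDATE, reasons=routes)
    return TriageDecision(TriageStatus.RETAINED, reasons=["no_priority_route"])


def flag_recurrent_artifacts(
    variants: Sequence[VariantRecord],
    decisions: Sequence[TriageDecision],
    thresholds: Optional[FilterThresholds] = None,
) -> None:
    """Mark likely sequencing artifacts on surviving decisions, in place.

    A site absent from gnomAD but carried by >= ``artifact_min_carriers``
    distinct samples in the cohort is flagged on every carrier.  The flag is
    advisory: statuses are never changed, and it is only set on variants
    whose decision is retained/candidate (discarded variants never surface).
    """
    th = thresholds or FilterThresholds()
    carriers: dict[tuple, set[str]] = defaultdict(set)
    for v in variants:
        if v.population.absent:
            carriers[v.site_key].add(v.sample_id)
    flagged_sites = {k for k, s in carriers.items() if len(s) >= th.artifact_min_carriers}
    for v, d in zip(variants, decisions):
        if v.site_key in flagged_sites and d.status.kept:
            d.artifact_flag = True
            d.reasons.append("recurrent_in_cohort")


@dataclass
class RecessiveResult:
    """Survivors of the recessive-model frequency filter for one sample."""

    homozygous: list[VariantRecord] = field(default_factory=list)
    #: gene -> >=2 surviving heterozygous variants (phase unknown)
    compound_het: dict[str, list[VariantRecord]] = field(default_factory=dict)
    phasing: str = "unphased"


def recessive_filter(
    sample_variants: Sequence[VariantRecord],
    thresholds: Optional[FilterThresholds] = None,
) -> RecessiveResult:
    """Recessive-model filter for one sample's variants.

    Discards anything with population AF >= 0.1% or seen in homozygosity in
    more than four individuals; reports homozygous survivors and genes with
    at least two surviving heterozygous variants as compound-het candidates.
    """
    th = thresholds or FilterThresholds()
    survivors: list[VariantRecord] = []
    for v in sample_variants:
        af = v.population.af
        hom = v.population.hom
        if af is not None and af >= th.recessive_max_af:
            continue
        if hom is not None and hom > th.recessive_max_hom:
            continue
        survivors.append(v)

    result = RecessiveResult()
    hets_by_gene: dict[str, list[VariantRecord]] = defaultdict(list)
    for v in survivors:
        if v.genotype.zygosity == "hom":
            result.homozygous.append(v)
        elif v.genotype.zygosity == "het":
            hets_by_gene[v.gene].append(v)
    result.compound_het = {g: vs for g, vs in hets_by_gene.items() if len(vs) >= 2}
    return result


@dataclass
class TriageResult:
    variants: list[VariantRecord]
    decisions: list[TriageDecision]
    mode: TriageMode
    per_sample: dict[str, dict[str, int]]
    eliminated_fraction: float

    def kept(self) -> list[VariantRecord]:
        return [v for v, d in zip(self.variants, self.decisions) if d.status.kept]

    def candidates(self) -> list[VariantRecord]:
        return [
            v
            for v, d in zip(self.variants, self.decisions)
            if d.status == TriageStatus.CANDIDATE
        ]


def _triage_one(
    variant: VariantRecord,
    panel: Optional[PanelDefinition],
    th: FilterThresholds,
    mode: TriageMode,
) -> TriageDecision:
    if panel is not None:
        if not in_panel(variant, panel):
            return TriageDecision(TriageStatus.DISCARDED_PANEL, ["not_in_panel"])
        if variant.gene and panel.genes and variant.gene not in panel.genes:
            logger.warning(
                "variant %s annotated to %s, not a panel gene; kept (in target region)",
                variant.site_key,
                variant.gene,
            )
    ok, reason = quality_filter(variant, th, mode)
    if not ok:
        return TriageDecision(TriageStatus.DISCARDED_QUALITY, [reason])
    ok, reason = frequency_filter(variant, th)
    if not ok:
        return TriageDecision(TriageStatus.DISCARDED_FREQUENCY, [reason])
    ok, reason = consequence_filter(variant.annotation, th)
    if not ok:
        return TriageDecision(TriageStatus.DISCARDED_CONSEQUENCE, [reason])
    return prioritize(variant, th)


def run_triage(
    variants: Sequence[VariantRecord],
    panel: Optional[PanelDefinition] = None,
    thresholds: Optional[FilterThresholds] = None,
    mode: TriageMode = TriageMode.PRIMARY,
) -> TriageResult:
    """Run the full cascade over a cohort variant table.

    Returns one decision per input variant (same order) plus per-sample
    kept/candidate counts and the cohort-wide eliminated fraction.
    """
    th = thresholds or FilterThresholds()
    mode = TriageMode(mode)
    decisions = [_triage_one(v, panel, th, mode) for v in variants]
    if mode == TriageMode.REANALYSIS:
        flag_recurrent_artifacts(variants, decisions, th)

    per_sample: dict[str, dict[str, int]] = {}
    for v in variants:
        per_sample.setdefault(v.sample_id, {"total": 0, "kept": 0, "candidates": 0})
    for v, d in zip(variants, decisions):
        s = per_sample[v.sample_id]
        s["total"] += 1
        if d.status.kept:
            s["kept"] += 1
        if d.status == TriageStatus.CANDIDATE:
            s["candidates"] += 1

    n = len(variants)
    n_kept = sum(1 for d in decisions if d.status.kept)
    eliminated = 1.0 - n_kept / n if n else 0.0
    return TriageResult(list(variants), decisions, mode, per_sample, eliminated)
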
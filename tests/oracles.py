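"""Independent brute-force oracles used to cross-check the pipeline.

These deliberately re-state every rule with plain loops and literal
comparisons, sharing no code with the package implementations.
"""

from __future__ import annotations

DEFAULTS = dict(
    min_depth=10,
    max_gnomad_ac=4,
    min_vaf_primary=0.30,
    lowdp_max=50,
    min_vaf_lof_lowdp=0.20,
    min_vaf_nonlof_lowdp=0.25,
    mosaic_min_vaf=0.10,
    artifact_min_carriers=4,
    splice_cutoff=0.5,
    provean_cutoff=-2.5,
    majority_fraction=0.5,
    priority_mode="any",
)

LOF = {"stop_gain", "frameshift", "canonical_splice", "start_loss"}
PROTEIN = LOF | {"stop_loss", "inframe_indel", "missense"}


def panel_contains_oracle(regions, chrom, pos0):
    """Per-base membership check by linear scan."""
    return any(c == chrom and s <= pos0 < e for c, s, e, _g in regions)


def snv_status_oracle(v, regions, mode, **overrides):
    """Terminal status of one variant by straight-line rule evaluation.

    ``v`` is a VariantRecord; ``regions`` a list of (chrom, start, end, gene)
    or None for no panel restriction.
    """
    t = {**DEFAULTS, **overrides}
    if regions is not None and not panel_contains_oracle(regions, v.chrom, v.pos - 1):
        return "discarded_panel"

    depth = v.genotype.depth
    if depth == 0:
        return "discarded_quality"
    vaf = v.genotype.alt_reads / depth
    cons = v.annotation.consequence.value
    if depth < t["min_depth"]:
        return "discarded_quality"
    if mode == "primary":
        if vaf < t["min_vaf_primary"]:
            return "discarded_quality"
    else:
        if depth < t["lowdp_max"]:
            bound = t["min_vaf_lof_lowdp"] if cons in LOF else t["min_vaf_nonlof_lowdp"]
            if vaf < bound:
                return "discarded_quality"
        else:
            if vaf < t["mosaic_min_vaf"]:
                return "discarded_quality"

    ac = v.population.ac
    if ac is not None and ac > t["max_gnomad_ac"]:
        return "discarded_frequency"

    splice = False
    for score in v.annotation.splice_scores.values():
        if score is not None and score >= t["splice_cutoff"]:
            splice = True
    if cons not in PROTEIN and not splice:
        return "discarded_consequence"

    navail = ndel = 0
    for call in v.annotation.predictor_calls.values():
        if call == "D":
            navail += 1
            ndel += 1
        elif call == "T":
            navail += 1
    majority = navail > 0 and ndel / navail >= t["majority_fraction"]
    strong = (
        cons in LOF
        or (
            cons == "inframe_indel"
            and v.annotation.provean is not None
            and v.annotation.provean <= t["provean_cutoff"]
        )
        or (cons == "missense" and majority)
        or splice
    )
    plp = v.annotation.clinvar.value in ("pathogenic", "likely_pathogenic")
    absent = v.population.ac is None or v.population.ac == 0
    if t["priority_mode"] == "any":
        promoted = plp or absent or strong
    else:
        promoted = plp and absent and strong
    return "candidate" if promoted else "retained"


def artifact_sites_oracle(variants, min_carriers=4):
    carriers = {}
    for v in variants:
        if v.population.ac is None or v.population.ac == 0:
            key = (v.chrom, v.pos, v.ref, v.alt)
            carriers.setdefault(key, set()).add(v.sample_id)
    return {k for k, s in carriers.items() if len(s) >= min_carriers}


# --- CNV oracles ------------------------------------------------------------


def ro_basecount_oracle(chrom_a, a0, a1, chrom_b, b0, b1):
    """Reciprocal overlap by counting shared integer bases."""
    if chrom_a != chrom_b:
        return 0.0
    shared = len(set(range(a0, a1)) & set(range(b0, b1)))
    return min(shared / (a1 - a0), shared / (b1 - b0))


def _ro(a, b):
    if a.chrom != b.chrom:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return min(ov / (a.end - a.start), ov / (b.end - b.start))


def cnv_status_oracle(call, all_calls, popsv):
    """Per-call decision by straight-line evaluation, default thresholds."""
    n_other = 0
    for other in all_calls:
        if other.sample_id == call.sample_id:
            continue
        if other.type != call.type:
            continue
        if _ro(call, other) >= 0.8:
            n_other += 1
    if n_other > 3:
        return "discarded_recurrent"

    for sv in popsv:
        if sv.type != call.type:
            continue
        if _ro(call, sv) < 0.9:
            continue
        if (sv.ac is not None and sv.ac > 10) or (sv.af is not None and sv.af > 0.0001):
            return "discarded_population"

    partners = [
        o
        for o in all_calls
        if o.sample_id == call.sample_id
        and o.caller != call.caller
        and o.type == call.type
        and _ro(call, o) >= 0.8
    ]
    if not partners:
        if call.caller.value == "caller_A" and call.phred < 20:
            return "discarded_concordance"
        if call.caller.value == "caller_B" and call.phred < 3:
            return "discarded_concordance"
        return "retained"

    if call.caller.value == "caller_A":
        a_ok = call.phred >= 30
        b_ok = any(p.phred >= 20 for p in partners)
    else:
        a_ok = any(p.phred >= 30 for p in partners)
        b_ok = call.phred >= 20
    return "candidate" if (a_ok and b_ok) else "retained"
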
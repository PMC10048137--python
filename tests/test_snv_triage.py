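from __future__ import annotations

import hypothesis.strategies as st
import pytest
from hypothesis import given, settings

from nddtriage.snv_triage import (
    TriageMode,
    consequence_filter,
    flag_recurrent_artifacts,
    frequency_filter,
    missense_majority_vote,
    prioritize,
    quality_filter,
    recessive_filter,
    run_triage,
    splice_ensemble,
    strong_effect,
)
from nddtriage.variant_model import (
    ClinvarStatus,
    Consequence,
    FilterThresholds,
    FunctionalAnnotation,
    PanelDefinition,
    TriageStatus,
)

from conftest import make_variant
from oracles import snv_status_oracle

PRIMARY = TriageMode.PRIMARY
REANALYSIS = TriageMode.REANALYSIS


class TestQualityFilter:
    @pytest.mark.parametrize("mode", [PRIMARY, REANALYSIS])
    def test_depth_below_10_fails_either_mode(self, thresholds, mode):
        v = make_variant(depth=9, alt_reads=9)
        ok, reason = quality_filter(v, thresholds, mode)
        assert not ok and reason == "low_depth"

    def test_mosaic_band_differs_between_modes(self, thresholds):
        v = make_variant(depth=100, alt_reads=29)  # VAF 0.29
        assert quality_filter(v, thresholds, PRIMARY) == (False, "low_vaf")
        assert quality_filter(v, thresholds, REANALYSIS) == (True, None)

    def test_lowdp_band_lof_vs_nonlof(self, thresholds):
        lof = make_variant(depth=30, alt_reads=6, consequence=Consequence.FRAMESHIFT)
        assert quality_filter(lof, thresholds, REANALYSIS)[0]  # VAF 0.20, LoF
        nonlof = make_variant(depth=25, alt_reads=6)  # VAF 0.24, non-LoF
        assert not quality_filter(nonlof, thresholds, REANALYSIS)[0]

    @pytest.mark.parametrize("mode", [PRIMARY, REANALYSIS])
    def test_homozygous_passes_both_modes(self, thresholds, mode):
        v = make_variant(depth=100, alt_reads=100)
        assert quality_filter(v, thresholds, mode) == (True, None)

    @pytest.mark.parametrize("mode", [PRIMARY, REANALYSIS])
    def test_zero_depth_fails_with_no_coverage(self, thresholds, mode):
        v = make_variant(depth=0, alt_reads=0)
        assert quality_filter(v, thresholds, mode) == (False, "no_coverage")

    def test_depth_exactly_50_is_in_mosaic_band(self, thresholds):
        v = make_variant(depth=50, alt_reads=6)  # VAF 0.12
        assert quality_filter(v, thresholds, REANALYSIS)[0]
        assert not quality_filter(
            make_variant(depth=49, alt_reads=6), thresholds, REANALYSIS
        )[0]


class TestFrequencyFilter:
    def test_ac_five_fails(self, thresholds):
        assert frequency_filter(make_variant(ac=5), thresholds) == (
            False,
            "gnomad_ac_gt_max",
        )

    def test_ac_four_boundary_passes(self, thresholds):
        assert frequency_filter(make_variant(ac=4), thresholds)[0]

    def test_absent_passes(self, thresholds):
        assert frequency_filter(make_variant(ac=None), thresholds)[0]


class TestSpliceEnsemble:
    def test_single_tool_over_cutoff(self):
        a = FunctionalAnnotation(
            Consequence.SYNONYMOUS, splice_scores={"spliceai": 0.6}
        )
        assert splice_ensemble(a)

    def test_all_just_below_cutoff(self):
        a = FunctionalAnnotation(
            Consequence.SYNONYMOUS,
            splice_scores={t: 0.49 for t in ("squirls", "spliceai", "ada", "rf")},
        )
        assert not splice_ensemble(a)

    def test_all_missing(self):
        assert not splice_ensemble(FunctionalAnnotation(Consequence.SYNONYMOUS))


class TestConsequenceFilter:
    def test_synonymous_with_high_spliceai_passes(self):
        a = FunctionalAnnotation(Consequence.SYNONYMOUS, splice_scores={"spliceai": 0.9})
        assert consequence_filter(a)[0]

    def test_intronic_without_splice_signal_fails(self):
        a = FunctionalAnnotation(
            Consequence.INTRONIC, splice_scores={"spliceai": 0.4, "ada": 0.2}
        )
        assert consequence_filter(a) == (False, "consequence_not_relevant")

    def test_missense_passes_without_splice_scores(self):
        assert consequence_filter(FunctionalAnnotation(Consequence.MISSENSE))[0]

    def test_stop_loss_passes(self):
        assert consequence_filter(FunctionalAnnotation(Consequence.STOP_LOSS))[0]


def _preds(n_del: int, n_tol: int) -> dict:
    calls = {f"P{i}": "D" for i in range(n_del)}
    calls.update({f"Q{i}": "T" for i in range(n_tol)})
    return calls


class TestMajorityVote:
    def test_half_of_available_is_enough(self):
        a = FunctionalAnnotation(Consequence.MISSENSE, predictor_calls=_preds(5, 5))
        assert missense_majority_vote(a)

    def test_below_half_fails(self):
        a = FunctionalAnnotation(Consequence.MISSENSE, predictor_calls=_preds(4, 6))
        assert not missense_majority_vote(a)

    def test_zero_available_is_not_deleterious(self):
        assert not missense_majority_vote(FunctionalAnnotation(Consequence.MISSENSE))


class TestStrongEffect:
    def test_inframe_provean_at_cutoff(self):
        a = FunctionalAnnotation(Consequence.INFRAME_INDEL, provean=-2.5)
        assert strong_effect(a)

    def test_inframe_provean_above_cutoff(self):
        a = FunctionalAnnotation(Consequence.INFRAME_INDEL, provean=-2.4)
        assert not strong_effect(a)

    def test_inframe_missing_provean_not_strong(self):
        assert not strong_effect(FunctionalAnnotation(Consequence.INFRAME_INDEL))

    def test_frameshift_is_strong(self):
        assert strong_effect(FunctionalAnnotation(Consequence.FRAMESHIFT))


class TestPrioritize:
    def test_clinvar_route_any_mode(self):
        v = make_variant(ac=2, clinvar=ClinvarStatus.PATHOGENIC)
        d = prioritize(v)
        assert d.status == TriageStatus.CANDIDATE
        assert "clinvar_plp" in d.reasons

    def test_two_routes_any_vs_conjunction(self):
        v = make_variant(
            ac=None,
            clinvar=ClinvarStatus.ABSENT,
            predictor_calls=_preds(8, 2),
        )
        assert prioritize(v).status == TriageStatus.CANDIDATE
        conj = FilterThresholds(priority_mode="conjunction")
        assert prioritize(v, conj).status == TriageStatus.RETAINED

    def test_no_route_retained(self):
        v = make_variant(ac=3, clinvar=ClinvarStatus.ABSENT, predictor_calls=_preds(3, 7))
        assert prioritize(v).status == TriageStatus.RETAINED


class TestArtifactFlag:
    def _cohort(self, n_samples, ac=None):
        return [
            make_variant(sample_id=f"S{i}", pos=777, ac=ac, predictor_calls=_preds(9, 1))
            for i in range(n_samples)
        ]

    def _run(self, variants):
        res = run_triage(variants, panel=None, mode=REANALYSIS)
        return res.decisions

    def test_four_absent_carriers_all_flagged(self):
        decisions = self._run(self._cohort(4))
        assert all(d.artifact_flag for d in decisions)
        assert all("recurrent_in_cohort" in d.reasons for d in decisions)

    def test_three_carriers_not_flagged(self):
        assert not any(d.artifact_flag for d in self._run(self._cohort(3)))

    def test_population_presence_prevents_flag(self):
        assert not any(d.artifact_flag for d in self._run(self._cohort(5, ac=2)))

    def test_statuses_unchanged_by_flagging(self):
        variants = self._cohort(5)
        flagged = self._run(variants)
        plain = [
            prioritize(v) for v in variants
        ]
        assert [d.status for d in flagged] == [d.status for d in plain]

    def test_duplicate_carrier_counts_once(self):
        variants = self._cohort(3) + [
            make_variant(sample_id="S0", pos=777, predictor_calls=_preds(9, 1))
        ]
        decisions = self._run(variants)
        assert not any(d.artifact_flag for d in decisions)


class TestRecessiveFilter:
    def test_af_at_point_one_percent_discarded(self):
        v = make_variant(ac=2, af=0.001, hom=0, zygosity="hom")
        res = recessive_filter([v])
        assert res.homozygous == [] and res.compound_het == {}

    def test_hom_count_five_discarded(self):
        v = make_variant(ac=2, af=0.0001, hom=5, zygosity="hom")
        assert recessive_filter([v]).homozygous == []

    def test_hom_count_four_boundary_kept(self):
        v = make_variant(ac=2, af=0.0001, hom=4, zygosity="hom")
        assert recessive_filter([v]).homozygous == [v]

    def test_compound_het_pair(self):
        v1 = make_variant(pos=100, ac=1, af=0.0005, hom=0, zygosity="het", gene="G")
        v2 = make_variant(pos=200, ac=1, af=0.0005, hom=0, zygosity="het", gene="G")
        res = recessive_filter([v1, v2])
        assert res.compound_het == {"G": [v1, v2]}
        assert res.phasing == "unphased"

    def test_single_het_not_reported(self):
        v = make_variant(ac=1, af=0.0005, hom=0, zygosity="het")
        assert recessive_filter([v]).compound_het == {}


TOY_PANEL = PanelDefinition([("chr1", 0, 10_000, "GENE1")])


def _toy_cohort():
    """3 samples x 8 variants covering every cascade stage.

    Expected primary statuses enumerated by hand, per sample:
      v1 out of panel           -> discarded_panel
      v2 depth 5                -> discarded_quality
      v3 VAF 0.2                -> discarded_quality (primary) / retained band varies
      v4 ac 9                   -> discarded_frequency
      v5 intronic, low splice   -> discarded_consequence
      v6 stop_gain, absent      -> candidate
      v7 missense 2/10 del, ac3 -> retained
      v8 synonymous, ada 0.8    -> candidate (splice route, gnomAD-absent too)
    """
    cohort = []
    for s in ("S1", "S2", "S3"):
        cohort += [
            make_variant(sample_id=s, chrom="chr9", pos=50, ac=None),
            make_variant(sample_id=s, pos=101, depth=5, alt_reads=3, ac=None),
            make_variant(sample_id=s, pos=102, depth=100, alt_reads=20, ac=None),
            make_variant(sample_id=s, pos=103, ac=9),
            make_variant(
                sample_id=s,
                pos=104,
                ac=None,
                consequence=Consequence.INTRONIC,
                splice_scores={"rf": 0.3},
            ),
            make_variant(
                sample_id=s, pos=105, ac=None, consequence=Consequence.STOP_GAIN
            ),
            make_variant(
                sample_id=s, pos=106, ac=3, predictor_calls=_preds(2, 8)
            ),
            make_variant(
                sample_id=s,
                pos=107,
                ac=None,
                consequence=Consequence.SYNONYMOUS,
                splice_scores={"ada": 0.8},
            ),
        ]
    return cohort


EXPECTED_PRIMARY = [
    TriageStatus.DISCARDED_PANEL,
    TriageStatus.DISCARDED_QUALITY,
    TriageStatus.DISCARDED_QUALITY,
    TriageStatus.DISCARDED_FREQUENCY,
    TriageStatus.DISCARDED_CONSEQUENCE,
    TriageStatus.CANDIDATE,
    TriageStatus.RETAINED,
    TriageStatus.CANDIDATE,
] * 3


class TestRunTriage:
    def test_toy_cohort_matches_hand_enumeration(self):
        res = run_triage(_toy_cohort(), TOY_PANEL, mode=PRIMARY)
        assert [d.status for d in res.decisions] == EXPECTED_PRIMARY

    def test_per_sample_counts(self):
        res = run_triage(_toy_cohort(), TOY_PANEL, mode=PRIMARY)
        for s in ("S1", "S2", "S3"):
            assert res.per_sample[s] == {"total": 8, "kept": 3, "candidates": 2}

    def test_all_low_depth_fully_eliminated(self):
        variants = [
            make_variant(sample_id=f"S{i}", pos=100 + i, depth=5, alt_reads=2)
            for i in range(10)
        ]
        res = run_triage(variants, TOY_PANEL, mode=PRIMARY)
        assert res.eliminated_fraction == 1.0

    def test_reanalysis_retains_superset(self):
        variants = _toy_cohort()
        primary = run_triage(variants, TOY_PANEL, mode=PRIMARY)
        re = run_triage(variants, TOY_PANEL, mode=REANALYSIS)
        kept_primary = {
            v.key for v, d in zip(variants, primary.decisions) if d.status.kept
        }
        kept_re = {v.key for v, d in zip(variants, re.decisions) if d.status.kept}
        assert kept_primary <= kept_re
        # the VAF-0.2 variant at depth 100 is exactly the mosaic gain
        assert any(k[1] == 102 for k in kept_re - kept_primary)


# --- property tests ---------------------------------------------------------

variant_strategy = st.builds(
    make_variant,
    sample_id=st.sampled_from(["S1", "S2", "S3", "S4", "S5"]),
    pos=st.integers(min_value=1, max_value=9_999),
    depth=st.integers(min_value=0, max_value=300),
    alt_reads=st.just(0),  # replaced below
    ac=st.one_of(st.none(), st.integers(min_value=0, max_value=30)),
    consequence=st.sampled_from(list(Consequence)),
    clinvar=st.sampled_from(list(ClinvarStatus)),
    predictor_calls=st.dictionaries(
        st.sampled_from([f"P{i}" for i in range(12)]),
        st.sampled_from(["D", "T"]),
        max_size=12,
    ),
    provean=st.one_of(st.none(), st.floats(min_value=-10, max_value=5)),
    splice_scores=st.dictionaries(
        st.sampled_from(["squirls", "spliceai", "ada", "rf"]),
        st.floats(min_value=0, max_value=1),
        max_size=4,
    ),
)


@st.composite
def variants_with_reads(draw):
    v = draw(variant_strategy)
    alt = draw(st.integers(min_value=0, max_value=v.genotype.depth))
    return make_variant(
        sample_id=v.sample_id,
        pos=v.pos,
        depth=v.genotype.depth,
        alt_reads=alt,
        ac=v.population.ac,
        consequence=v.annotation.consequence,
        clinvar=v.annotation.clinvar,
        predictor_calls=dict(v.annotation.predictor_calls),
        provean=v.annotation.provean,
        splice_scores=dict(v.annotation.splice_scores),
    )


cohort_strategy = st.lists(variants_with_reads(), min_size=1, max_size=30)


@settings(max_examples=60, deadline=None)
@given(cohort=cohort_strategy)
def test_reanalysis_superset_property(cohort):
    primary = run_triage(cohort, TOY_PANEL, mode=PRIMARY)
    re = run_triage(cohort, TOY_PANEL, mode=REANALYSIS)
    for dp, dr in zip(primary.decisions, re.decisions):
        if dp.status.kept:
            assert dr.status.kept


@settings(max_examples=40, deadline=None)
@given(cohort=cohort_strategy)
def test_monotonicity_of_thresholds(cohort):
    base = run_triage(cohort, TOY_PANEL, FilterThresholds(), PRIMARY)
    stricter = [
        FilterThresholds(min_depth=30),
        FilterThresholds(min_vaf_primary=0.5),
        FilterThresholds(max_gnomad_ac=1),
    ]
    kept_base = {i for i, d in enumerate(base.decisions) if d.status.kept}
    for th in stricter:
        res = run_triage(cohort, TOY_PANEL, th, PRIMARY)
        kept = {i for i, d in enumerate(res.decisions) if d.status.kept}
        assert kept <= kept_base


@settings(max_examples=60, deadline=None)
@given(cohort=cohort_strategy)
def test_decision_completeness_and_oracle(cohort):
    regions = list(TOY_PANEL.regions())
    for mode in (PRIMARY, REANALYSIS):
        res = run_triage(cohort, TOY_PANEL, mode=mode)
        assert len(res.decisions) == len(cohort)
        for v, d in zip(cohort, res.decisions):
            assert d.status in TriageStatus
            assert d.status.value == snv_status_oracle(v, regions, mode.value)
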
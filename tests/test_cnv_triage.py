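from __future__ import annotations

import numpy as np
import pytest

from nddtriage.cnv_triage import (
    Caller,
    CnvCall,
    CnvStatus,
    CnvType,
    PopulationSv,
    caller_concordance_filter,
    cohort_recurrence_filter,
    population_sv_filter,
    prioritize_cnv,
    reciprocal_overlap,
    run_cnv_triage,
)
from nddtriage.synthetic_cohort import SimConfig, generate

from oracles import cnv_status_oracle, ro_basecount_oracle


def call(sample="S1", chrom="chr1", start=0, end=100, type=CnvType.DEL,
         caller=Caller.A, phred=50.0) -> CnvCall:
    return CnvCall(sample, chrom, start, end, type, caller, phred)


class TestReciprocalOverlap:
    def test_half_overlap(self):
        assert reciprocal_overlap(call(start=100, end=200), call(start=150, end=250)) == 0.5

    def test_identical(self):
        a = call(start=100, end=200)
        assert reciprocal_overlap(a, a) == 1.0

    def test_disjoint(self):
        assert reciprocal_overlap(call(start=0, end=100), call(start=100, end=200)) == 0.0

    def test_cross_chromosome(self):
        assert reciprocal_overlap(call(chrom="chr1"), call(chrom="chr2")) == 0.0

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            reciprocal_overlap(call(start=5, end=5, phred=1), call())

    def test_symmetric_and_matches_base_counting(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            s1 = int(rng.integers(0, 500))
            e1 = s1 + int(rng.integers(1, 200))
            s2 = int(rng.integers(0, 500))
            e2 = s2 + int(rng.integers(1, 200))
            a, b = call(start=s1, end=e1), call(start=s2, end=e2)
            ro = reciprocal_overlap(a, b)
            assert ro == reciprocal_overlap(b, a)
            assert 0.0 <= ro <= 1.0
            assert ro == pytest.approx(
                ro_basecount_oracle("chr1", s1, e1, "chr1", s2, e2), abs=1e-12
            )


def _matched_cohort(n_other_samples, ro=1.0, type=CnvType.DEL):
    """A probe call plus matching calls in n other samples."""
    probe = call(sample="probe", start=0, end=1000)
    shift = int(round((1 - ro) * 1000 / (2 - ro))) if ro < 1 else 0
    others = [
        call(sample=f"O{i}", start=shift, end=1000 + shift, type=type)
        for i in range(n_other_samples)
    ]
    return probe, [probe] + others


class TestRecurrenceFilter:
    def test_matched_in_four_other_samples_fails(self):
        probe, cohort = _matched_cohort(4)
        assert cohort_recurrence_filter(probe, cohort) == (False, "recurrent_in_cohort")

    def test_three_others_passes(self):
        probe, cohort = _matched_cohort(3)
        assert cohort_recurrence_filter(probe, cohort)[0]

    def test_ro_below_threshold_passes(self):
        probe = call(sample="probe", start=0, end=1000)
        # RO = 790/1000 = 0.79 each
        others = [
            call(sample=f"O{i}", start=210, end=1000, type=CnvType.DEL)
            for i in range(4)
        ]
        for o in others:
            assert reciprocal_overlap(probe, o) == pytest.approx(0.79)
        assert cohort_recurrence_filter(probe, [probe] + others)[0]

    def test_same_sample_other_caller_not_counted(self):
        probe = call(sample="S1", caller=Caller.A, start=0, end=1000)
        dups = [call(sample="S1", caller=Caller.B, start=0, end=1000) for _ in range(5)]
        assert cohort_recurrence_filter(probe, [probe] + dups)[0]

    def test_cross_type_not_counted(self):
        probe, cohort = _matched_cohort(5, type=CnvType.DUP)
        assert cohort_recurrence_filter(probe, cohort)[0]


class TestPopulationSvFilter:
    def test_common_by_allele_count_fails(self):
        sv = PopulationSv("chr1", 0, 1000, CnvType.DEL, ac=11)
        c = call(start=0, end=1000)
        assert population_sv_filter(c, [sv]) == (False, "common_in_DGV")

    def test_ac_boundary_and_absent_af_passes(self):
        sv = PopulationSv("chr1", 0, 1000, CnvType.DEL, ac=10, af=None)
        assert population_sv_filter(call(start=0, end=1000), [sv])[0]

    def test_ro_below_point_nine_passes(self):
        # RO = 890/1000 = 0.89
        sv = PopulationSv("chr1", 110, 1110, CnvType.DEL, af=0.5, ac=None)
        c = call(start=0, end=1000)
        assert population_sv_filter(c, [sv])[0]

    def test_af_boundary_passes(self):
        sv = PopulationSv("chr1", 0, 1000, CnvType.DEL, af=0.0001)
        assert population_sv_filter(call(start=0, end=1000), [sv])[0]

    def test_type_mismatch_ignored(self):
        sv = PopulationSv("chr1", 0, 1000, CnvType.DUP, ac=100)
        assert population_sv_filter(call(start=0, end=1000), [sv])[0]


class TestConcordanceFilter:
    def test_single_caller_a_low_phred_fails(self):
        c = call(caller=Caller.A, phred=19)
        assert caller_concordance_filter(c, [c]) == (False, "single_caller_low_quality")

    def test_single_caller_b_boundary_passes(self):
        c = call(caller=Caller.B, phred=3)
        assert caller_concordance_filter(c, [c])[0]

    def test_dual_support_rescues_low_phred(self):
        a = call(caller=Caller.A, phred=5)
        b = call(caller=Caller.B, phred=5)
        assert caller_concordance_filter(a, [a, b])[0]
        assert caller_concordance_filter(b, [a, b])[0]


class TestPrioritizeCnv:
    def test_thresholds_met(self):
        a = call(caller=Caller.A, phred=30)
        b = call(caller=Caller.B, phred=20)
        assert prioritize_cnv(a, [a, b]).status == CnvStatus.CANDIDATE
        assert prioritize_cnv(b, [a, b]).status == CnvStatus.CANDIDATE

    def test_a_below_30_retained(self):
        a = call(caller=Caller.A, phred=29)
        b = call(caller=Caller.B, phred=25)
        assert prioritize_cnv(a, [a, b]).status == CnvStatus.RETAINED

    def test_single_caller_never_candidate(self):
        a = call(caller=Caller.A, phred=99)
        assert prioritize_cnv(a, [a]).status == CnvStatus.RETAINED


class TestRunCnvTriage:
    def test_toy_cohort_hand_enumeration(self):
        popsv = [PopulationSv("chr2", 0, 1000, CnvType.DEL, ac=50)]
        # recurrent interval in 5 samples
        recurrent = [
            call(sample=f"R{i}", chrom="chr3", start=0, end=1000) for i in range(5)
        ]
        common = call(sample="S1", chrom="chr2", start=0, end=1000)  # popsv hit
        low_single = call(sample="S2", chrom="chr4", phred=10)  # concordance fail
        ok_single = call(sample="S3", chrom="chr4", phred=25)  # retained
        pair_a = call(sample="S4", chrom="chr5", caller=Caller.A, phred=40)
        pair_b = call(sample="S4", chrom="chr5", caller=Caller.B, phred=22)
        calls_a = recurrent + [common, low_single, ok_single, pair_a]
        res = run_cnv_triage(calls_a, [pair_b], popsv)
        statuses = [d.status for d in res.decisions]
        assert statuses[:5] == [CnvStatus.DISCARDED_RECURRENT] * 5
        assert statuses[5] == CnvStatus.DISCARDED_POPULATION
        assert statuses[6] == CnvStatus.DISCARDED_CONCORDANCE
        assert statuses[7] == CnvStatus.RETAINED
        assert statuses[8] == CnvStatus.CANDIDATE
        assert statuses[9] == CnvStatus.CANDIDATE
        assert len(res.events) == 1
        ev = res.events[0]
        assert (ev.sample_id, ev.chrom, ev.start, ev.end) == ("S4", "chr5", 0, 100)

    def test_empty_inputs(self):
        res = run_cnv_triage([], [], [])
        assert res.calls == [] and res.decisions == [] and res.events == []

    def test_interval_replicated_across_five_samples_removed(self):
        calls = [call(sample=f"S{i}", start=0, end=5000) for i in range(5)]
        res = run_cnv_triage(calls, [], [])
        assert all(d.status == CnvStatus.DISCARDED_RECURRENT for d in res.decisions)

    def test_candidates_pass_every_filter(self):
        bundle = generate(SimConfig(n_patients=40, cnv_plant_prob=0.3, seed=11))
        res = run_cnv_triage(bundle.cnv_a, bundle.cnv_b, bundle.popsv)
        all_calls = res.calls
        for c, d in zip(res.calls, res.decisions):
            if d.status == CnvStatus.CANDIDATE:
                assert cohort_recurrence_filter(c, all_calls)[0]
                assert population_sv_filter(c, bundle.popsv)[0]
                assert caller_concordance_filter(c, all_calls)[0]

    def test_pipeline_equals_brute_force_oracle(self):
        bundle = generate(
            SimConfig(n_patients=60, cnv_plant_prob=0.3, cnv_background_mean=2.0, seed=3)
        )
        res = run_cnv_triage(bundle.cnv_a, bundle.cnv_b, bundle.popsv)
        assert len(res.calls) <= 400
        for c, d in zip(res.calls, res.decisions):
            assert d.status.value == cnv_status_oracle(c, res.calls, bundle.popsv)

    def test_filters_commute_on_independent_calls(self):
        # population and concordance filters evaluate a call independently;
        # either order yields the same verdict
        a = call(caller=Caller.A, phred=15, chrom="chr2", start=0, end=1000)
        popsv = [PopulationSv("chr2", 0, 1000, CnvType.DEL, ac=50)]
        p1 = population_sv_filter(a, popsv)[0]
        c1 = caller_concordance_filter(a, [a])[0]
        assert (p1 and c1) == (c1 and p1)
        assert not p1 and not c1
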
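import math

import numpy as np
import pytest

from clonechron.allelic_cn import AllelicState
from clonechron.event_timing import (
    ComplexHistoryError,
    UntimeableEventError,
    assign_multiplicity,
    bootstrap_ci,
    detect_wgd,
    fusion_duplication_test,
    multiplicity_counts,
    mutation_interval,
    rate_consistency,
    time_event,
    time_segment,
)
from clonechron.io_formats import GenomicSegment, SegmentCNRecord, SomaticMutation
from clonechron.purity import correct_allelic_cn
from clonechron.synthetic_data import SimConfig, SimEvent, default_genome, simulate_tumor

AA = AllelicState(2, 0)
AAB = AllelicState(2, 1)
AABB = AllelicState(2, 2)


class TestAssignMultiplicity:
    @pytest.mark.parametrize(
        "alt,depth,state,expected",
        [
            (100, 100, AA, 2),   # homozygous-looking somatic on UPD: pre-event
            (52, 105, AA, 1),    # post-duplication single copy
            (26, 105, AABB, 1),  # tetraploid quarter-coverage
            (53, 105, AABB, 2),  # pre-WGD mutation at half coverage
            (70, 105, AAB, 2),   # 2/3 lattice on trisomy
        ],
    )
    def test_lattice(self, alt, depth, state, expected):
        m = SomaticMutation("m", "chr1", 1, depth - alt, alt)
        assert assign_multiplicity(m, state, alpha=0.0) == expected

    def test_contamination_shifts_lattice(self):
        # alpha=0.2 on AA: m=1 expects 0.4, m=2 expects 0.8
        m = SomaticMutation("m", "chr1", 1, 25, 80)
        assert assign_multiplicity(m, AA, alpha=0.2) == 2


class TestTimeEvent:
    def test_boundary_cases(self):
        assert time_event("cn_loh_dup", {1: 100, 2: 0}) == 0.0
        assert time_event("cn_loh_dup", {1: 0, 2: 50}) == 1.0
        assert time_event("wgd", {1: 100, 2: 100}) == pytest.approx(2 / 3)

    def test_untimeable(self):
        with pytest.raises(UntimeableEventError):
            time_event("cn_loh_dup", {})
        with pytest.raises(UntimeableEventError):
            time_event("loss", {1: 50})

    @pytest.mark.parametrize("event_class", ["cn_loh_dup", "wgd", "trisomy_gain"])
    @pytest.mark.parametrize("t", np.arange(0.05, 0.96, 0.1))
    def test_identity_on_expected_counts(self, event_class, t):
        # plugging the model's expected counts back in must return t exactly
        lam_L = 1000.0
        if event_class == "cn_loh_dup":
            counts = {2: lam_L * t, 1: 2 * lam_L * (1 - t)}
        elif event_class == "wgd":
            counts = {2: 2 * lam_L * t, 1: 4 * lam_L * (1 - t)}
        else:
            counts = {2: lam_L * t, 1: lam_L * t + 3 * lam_L * (1 - t)}
        assert time_event(event_class, counts) == pytest.approx(t, abs=1e-12)

    @pytest.mark.parametrize("event_class", ["cn_loh_dup", "wgd", "trisomy_gain"])
    def test_consistent_with_generative_oracle(self, event_class, rng):
        # independent oracle: Poisson draws straight from the per-copy
        # accumulation model at lambda*L = 10000, t = 2/3
        t, lam_L = 2 / 3, 10_000
        if event_class == "cn_loh_dup":
            n2 = rng.poisson(lam_L * t)
            n1 = rng.poisson(2 * lam_L * (1 - t))
        elif event_class == "wgd":
            n2 = rng.poisson(2 * lam_L * t)
            n1 = rng.poisson(4 * lam_L * (1 - t))
        else:
            n2 = rng.poisson(lam_L * t)
            n1 = rng.poisson(lam_L * t + 3 * lam_L * (1 - t))
        assert time_event(event_class, {1: n1, 2: n2}) == pytest.approx(t, abs=0.02)


class TestBootstrapCI:
    def test_zero_pre_event_counts(self):
        lo, hi = bootstrap_ci("cn_loh_dup", {1: 200, 2: 0}, seed=1)
        assert lo == 0.0 and hi >= 0.0

    def test_contains_point_and_concentrates(self):
        counts = {1: 500, 2: 500}
        lo, hi = bootstrap_ci("wgd", counts, seed=1)
        assert lo <= 2 / 3 <= hi and hi - lo < 0.1
        lo10, hi10 = bootstrap_ci("wgd", {1: 5000, 2: 5000}, seed=1)
        assert hi10 - lo10 < hi - lo


class TestMutationInterval:
    @pytest.mark.parametrize(
        "event_class,m,t,expected",
        [
            ("cn_loh_dup", 2, 0.26, (0.0, 0.26)),  # pre-UPD, e.g. VAF 0.95 on chr5
            ("cn_loh_dup", 1, 0.26, (0.26, 1.0)),
            ("gain", 2, 0.21, (0.0, 0.21)),        # pre-gain of 12p
            ("trisomy_gain", 1, 0.5, (0.0, 1.0)),  # unduplicated-allele ambiguity
            ("wgd", 2, 0.62, (0.0, 0.62)),
        ],
    )
    def test_rules(self, event_class, m, t, expected):
        from clonechron.event_timing import CNEvent

        ev = CNEvent(None, AllelicState(1, 1), AA, event_class, t)
        mt = mutation_interval("mut", m, ev)
        assert mt.interval == pytest.approx(expected)

    def test_balanced_segment_uninformative(self):
        mt = mutation_interval("mut", 1, None)
        assert mt.interval == (0.0, 1.0)
        assert mt.midpoint == 0.5


def _corrected_records(result, alpha):
    out = []
    for rec in result.segments:
        cn_t, laf_t = correct_allelic_cn(rec.cn_obs, rec.laf_obs, alpha)
        out.append(SegmentCNRecord(rec.segment, cn_t, laf_t))
    return out


class TestTimeSegment:
    def test_upd_timing_recovery(self):
        cfg = SimConfig(
            seed=3, alpha=0.16, lambda_rate=16.0,
            segments=[GenomicSegment("chr5", 0, 50_000_000)],
            events=[SimEvent("chr5", "cn_loh_dup", 0.26)],
            het_density=10.0,
        )
        res = simulate_tumor(cfg)
        rec = _corrected_records(res, 0.16)[0]
        ev = time_segment(rec, res.mutations, alpha=0.16)
        assert ev.event_class == "cn_loh_dup"
        assert ev.t == pytest.approx(0.26, abs=0.05)
        assert ev.ci[0] <= ev.t <= ev.ci[1]

    def test_balanced_segment_returns_none(self):
        rec = SegmentCNRecord(GenomicSegment("chr1", 0, 1_000_000), 2.0, 0.5)
        assert time_segment(rec, []) is None

    def test_complex_state_flagged(self):
        rec = SegmentCNRecord(GenomicSegment("chr1", 0, 1_000_000), 4.0, 0.25)
        with pytest.raises(ComplexHistoryError):  # AAAB needs two events
            time_segment(rec, [])


class TestDetectWGD:
    def _wgd_tumor(self, times_by_chrom, seed=11, alpha=0.16):
        genome = default_genome(scale=0.25, chroms=list(times_by_chrom))
        events = [
            SimEvent(c, "tetrasomy", t) for c, t in times_by_chrom.items()
        ]
        cfg = SimConfig(
            seed=seed, alpha=alpha, lambda_rate=6.0, segments=genome,
            events=events, het_density=50.0,
        )
        return simulate_tumor(cfg)

    def test_single_wgd_concordant(self):
        chroms = {f"chr{i}": 0.62 for i in range(1, 9)}
        res = self._wgd_tumor(chroms)
        call = detect_wgd(_corrected_records(res, 0.16), res.mutations, alpha=0.16)
        assert call.is_wgd
        assert call.tetraploid_fraction == pytest.approx(1.0)
        assert call.t_mean == pytest.approx(0.62, abs=0.05)
        assert call.concordance < 0.05

    def test_two_independent_tetrasomies_flagged(self):
        chroms = {f"chr{i}": (0.3 if i <= 4 else 0.8) for i in range(1, 9)}
        res = self._wgd_tumor(chroms, seed=13)
        call = detect_wgd(_corrected_records(res, 0.16), res.mutations, alpha=0.16)
        assert call.is_wgd
        assert call.concordance > 0.2  # not a single event

    def test_diploid_genome_not_called(self):
        genome = default_genome(scale=0.2, chroms=[f"chr{i}" for i in range(1, 7)])
        cfg = SimConfig(seed=9, alpha=0.16, lambda_rate=3.0, segments=genome,
                        het_density=50.0)
        res = simulate_tumor(cfg)
        call = detect_wgd(_corrected_records(res, 0.16), res.mutations, alpha=0.16)
        assert not call.is_wgd
        assert call.tetraploid_fraction == 0.0


class TestFusionDuplicationTest:
    def test_junction_at_half_coverage_predates_wgd(self):
        assert fusion_duplication_test(52, 105, wgd=True) == "before_wgd"

    def test_junction_at_quarter_coverage_postdates_wgd(self):
        assert fusion_duplication_test(26, 105, wgd=True) == "after_wgd"

    def test_without_wgd_indeterminate(self):
        assert fusion_duplication_test(52, 105, wgd=False) == "indeterminate"
        assert fusion_duplication_test(52, 0, wgd=True) == "indeterminate"

    def test_midway_count_indeterminate(self):
        # ~39/105 sits between the 1/4 and 2/4 expectations
        assert fusion_duplication_test(39, 105, wgd=True) == "indeterminate"


class TestRateConsistency:
    def test_exactly_proportional(self):
        lengths = [249, 198, 159, 135, 90, 59]
        counts = [3 * l for l in lengths]
        fit = rate_consistency(counts, lengths)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(3.0)

    def test_uniform_rate_genome(self, rng):
        lengths = np.array([249, 243, 198, 191, 181, 171, 159, 146, 141, 136,
                            135, 134, 115, 107, 103, 90, 81, 78, 59, 63, 48, 51])
        counts = rng.poisson(1.4 * lengths)  # ~4000 mutations genome-wide
        fit = rate_consistency(counts, lengths)
        assert fit.r_squared > 0.98

    def test_outlier_chromosome_breaks_consistency(self, rng):
        lengths = np.array([249, 243, 198, 191, 181, 171, 159, 146])
        counts = rng.poisson(1.4 * lengths).astype(float)
        counts[0] *= 10  # one chromosome mutating 10x faster
        fit = rate_consistency(counts, lengths)
        assert fit.r_squared < 0.9

    def test_requires_five_chromosomes(self):
        with pytest.raises(ValueError):
            rate_consistency([10, 20], [1.0, 2.0])
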
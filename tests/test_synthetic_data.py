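import numpy as np
import pandas as pd
import pytest

from clonechron.allelic_cn import estimate_laf
from clonechron.event_timing import detect_wgd, time_segment
from clonechron.io_formats import (
    GenomicSegment,
    SegmentCNRecord,
    read_het_sites,
    read_mutations,
    read_segments,
)
from clonechron.purity import correct_allelic_cn, estimate_purity
from clonechron.synthetic_data import (
    ConfigError,
    SimConfig,
    SimEvent,
    SubcloneConfig,
    default_genome,
    make_fixture,
    simulate_tumor,
)


def _seg(chrom="chr1", mb=30):
    return [GenomicSegment(chrom, 0, mb * 1_000_000)]


def test_seeded_determinism():
    cfg = dict(seed=5, alpha=0.1, lambda_rate=5.0, segments=_seg(),
               events=[SimEvent("chr1", "trisomy_gain", 0.4)], het_density=20.0)
    a, b = simulate_tumor(SimConfig(**cfg)), simulate_tumor(SimConfig(**cfg))
    assert [(m.id, m.pos, m.ref_count, m.alt_count) for m in a.mutations] == [
        (m.id, m.pos, m.ref_count, m.alt_count) for m in b.mutations
    ]
    pd.testing.assert_frame_equal(a.het_sites, b.het_sites)
    assert a.segments[0].cn_obs == b.segments[0].cn_obs
    assert a.segments[0].laf_obs == b.segments[0].laf_obs


def test_quiet_diploid_marginals():
    cfg = SimConfig(seed=1, alpha=0.0, lambda_rate=30.0, segments=_seg(),
                    het_density=30.0)
    res = simulate_tumor(cfg)
    vafs = np.array([m.vaf_obs for m in res.mutations])
    n = len(vafs)
    # clonal het VAFs concentrate at 0.5 (3 SE of the binomial at depth 105)
    se = np.sqrt(0.25 / 105 / n)
    assert abs(vafs.mean() - 0.5) < 3 * se + 1e-3
    assert res.segments[0].cn_obs == 2.0
    assert estimate_laf(res.het_sites) > 0.45
    assert (res.truth.mutations["multiplicity"] == 1).all()


def test_contaminated_diploid_vaf_mean():
    # alpha = 0.16: observed het-somatic VAF mean = (1 - 0.16)/2 = 0.42
    cfg = SimConfig(seed=2, alpha=0.16, lambda_rate=30.0, segments=_seg(),
                    het_density=0.0)
    res = simulate_tumor(cfg)
    vafs = np.array([m.vaf_obs for m in res.mutations])
    se = np.sqrt(0.25 / 105 / len(vafs))
    assert abs(vafs.mean() - 0.42) < 3 * se + 1e-3


def test_wgd_multiplicity_ratio():
    # WGD at t=0.5: expected m2:m1 counts 2*lambda*t : 4*lambda*(1-t) = 1:2
    cfg = SimConfig(seed=3, alpha=0.0, lambda_rate=200.0, segments=_seg(mb=50),
                    events=[SimEvent("chr1", "wgd", 0.5)], het_density=0.0)
    res = simulate_tumor(cfg)
    counts = res.truth.mutations["multiplicity"].value_counts()
    assert counts[2] / counts[1] == pytest.approx(0.5, rel=0.05)
    assert res.segments[0].cn_obs == 4.0


def test_upd_removes_lost_allele_mutations():
    cfg = SimConfig(seed=4, alpha=0.0, lambda_rate=50.0, segments=_seg(),
                    events=[SimEvent("chr1", "cn_loh_dup", 0.3)], het_density=20.0)
    res = simulate_tumor(cfg)
    truth = res.truth.mutations
    # pre-event survivors are duplicated; none carry the lost allele
    pre = truth[truth["time"] < 0.3]
    assert (pre["multiplicity"] == 2).all()
    assert res.segments[0].laf_obs < 0.02
    assert res.segments[0].cn_obs == 2.0


def test_subclone_ccf_and_fraction():
    cfg = SimConfig(
        seed=6, alpha=0.0, lambda_rate=30.0, segments=_seg(),
        subclones=[SubcloneConfig(phi=0.3, t_branch=0.5)], het_density=0.0,
    )
    res = simulate_tumor(cfg)
    truth = res.truth.mutations
    assert set(truth["lineage"]) == {"trunk", "major", "subclone"}
    assert (truth.loc[truth["lineage"] == "trunk", "ccf"] == 1.0).all()
    assert (truth.loc[truth["lineage"] == "major", "ccf"] == 0.7).all()
    assert (truth.loc[truth["lineage"] == "subclone", "ccf"] == 0.3).all()
    sub_vaf = np.array(
        [m.vaf_obs for m in res.mutations
         if m.id in set(truth.loc[truth["lineage"] == "subclone", "id"])]
    )
    assert sub_vaf.mean() == pytest.approx(0.15, abs=0.02)


class TestConfigValidation:
    def test_event_on_lost_allele(self):
        cfg = SimConfig(
            seed=0, segments=_seg(),
            events=[SimEvent("chr1", "cn_loh_dup", 0.2),
                    SimEvent("chr1", "cn_loh_dup", 0.6)],
            het_density=0.0,
        )
        with pytest.raises(ConfigError, match="both alleles"):
            simulate_tumor(cfg)

    def test_subclone_fractions_bounded(self):
        with pytest.raises(ConfigError):
            SimConfig(subclones=[SubcloneConfig(0.6, 0.2), SubcloneConfig(0.5, 0.3)])

    def test_private_event_after_branch(self):
        with pytest.raises(ConfigError):
            SubcloneConfig(0.3, 0.5, (SimEvent("chr1", "gain", 0.4),))

    def test_event_time_in_unit_interval(self):
        with pytest.raises(ConfigError):
            SimEvent("chr1", "gain", 1.2)


class TestFixtures:
    def test_unknown_name(self, tmp_path):
        with pytest.raises(ValueError):
            make_fixture("nope", tmp_path)

    def test_null_diploid_no_wgd(self, tmp_path):
        paths = make_fixture("null_diploid", tmp_path)
        muts = read_mutations(paths["mutations"])
        segs = read_segments(paths["segments"])
        est = estimate_purity(segs, muts)
        assert est.alpha == pytest.approx(0.16, abs=0.02)
        corrected = [
            SegmentCNRecord(r.segment, *correct_allelic_cn(r.cn_obs, r.laf_obs, est.alpha))
            for r in segs
        ]
        assert not detect_wgd(corrected, muts, est.alpha).is_wgd

    def test_pfp_like_wgd_at_midlife(self, tmp_path):
        paths = make_fixture("pfp_like", tmp_path)
        muts = read_mutations(paths["mutations"])
        segs = read_segments(paths["segments"])
        est = estimate_purity(segs, muts)
        corrected = [
            SegmentCNRecord(r.segment, *correct_allelic_cn(r.cn_obs, r.laf_obs, est.alpha))
            for r in segs
        ]
        call = detect_wgd(corrected, muts, est.alpha)
        assert call.is_wgd
        assert call.t_mean == pytest.approx(0.62, abs=0.05)
        assert call.concordance < 0.05

    def test_pfn_like_chr11_upd_earliest(self, tmp_path):
        paths = make_fixture("pfn_like", tmp_path)
        muts = read_mutations(paths["mutations"])
        segs = read_segments(paths["segments"])
        het = read_het_sites(paths["het_sites"])
        assert len(het) > 1000
        est = estimate_purity(segs, muts)
        assert est.alpha == pytest.approx(0.12, abs=0.02)
        times = {}
        for rec in segs:
            cn_t, laf_t = correct_allelic_cn(rec.cn_obs, rec.laf_obs, est.alpha)
            corrected = SegmentCNRecord(rec.segment, cn_t, laf_t)
            on_seg = [m for m in muts if rec.segment.contains(m.chrom, m.pos)]
            ev = time_segment(corrected, on_seg, est.alpha)
            if ev is not None:
                times[rec.segment.chrom] = ev.t
        assert set(times) == {"chr11", "chr9", "chr5", "chr7", "chr17",
                              "chr13", "chr20"}
        earliest = min(times, key=times.get)
        assert earliest in ("chr11", "chr9")
        assert times["chr11"] == pytest.approx(0.14, abs=0.06)
        assert times["chr13"] == pytest.approx(0.77, abs=0.06)
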
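"""Marker derivation: TMB, POLE/TP53 calls, MSI scoring, FGA, CN rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecsubtype import (
    CallerConfig,
    CNSegment,
    Consequence,
    MicrosatelliteLocus,
    Variant,
    assess_pole,
    assess_tp53,
    build_profile,
    call_msi,
    classify_cn,
    compute_fga,
    compute_tmb,
    score_locus_instability,
)
from ecsubtype.markers import ConfigError, NotEvaluableError


def mkvar(gene="PTEN", consequence=Consequence.MISSENSE, vaf=0.3, hgvs_p="p.R130G"):
    return Variant(chrom="chr1", pos=1000, ref="A", alt="G", gene=gene,
                   hgvs_p=hgvs_p, consequence=consequence, vaf=vaf)


BASELINE = {10: 0.1, 11: 0.2, 12: 0.4, 13: 0.2, 14: 0.1}


def mklocus(observed, locus_id="MS01"):
    return MicrosatelliteLocus(locus_id=locus_id, repeat_unit="A",
                               baseline_hist=BASELINE, observed_hist=observed)


class TestTMB:
    def test_empty_is_zero(self, config):
        assert compute_tmb([], config) == 0.0

    def test_per_megabase_scaling(self):
        cfg = CallerConfig(panel_size_mb=0.5)
        variants = [mkvar(vaf=0.2) for _ in range(50)]
        assert compute_tmb(variants, cfg) == 100.0

    def test_vaf_filter_and_synonymous_excluded(self, config):
        variants = [mkvar(vaf=0.2)] * 6 + [mkvar(vaf=0.01)] * 4
        assert compute_tmb(variants, config) == 6.0
        variants += [mkvar(consequence=Consequence.SYNONYMOUS)] * 3
        assert compute_tmb(variants, config) == 6.0

    def test_bad_panel_size_rejected(self):
        with pytest.raises(ConfigError):
            CallerConfig(panel_size_mb=0.0)

    @given(vaf=st.floats(0.05, 1.0))
    @settings(max_examples=30, derandomize=True)
    def test_raising_vaf_above_threshold_never_lowers_tmb(self, config, vaf):
        low = [mkvar(vaf=0.04)]
        high = [mkvar(vaf=vaf)]
        assert compute_tmb(high, config) >= compute_tmb(low, config)


class TestPOLE:
    def test_hotspot_positive(self, config):
        assert assess_pole([mkvar("POLE", hgvs_p="p.P286R", vaf=0.25)], tmb=5, config=config)

    def test_synonymous_only_negative(self, config):
        v = mkvar("POLE", consequence=Consequence.SYNONYMOUS, hgvs_p="p.P286P")
        assert not assess_pole([v], tmb=5, config=config)

    def test_edm_missense_requires_ultramutation(self, config):
        v = mkvar("POLE", hgvs_p="p.T278M")  # in EDM, not on hotspot list
        assert not assess_pole([v], tmb=50, config=config)
        assert assess_pole([v], tmb=150, config=config)

    def test_non_edm_missense_not_rescued_by_tmb(self, config):
        v = mkvar("POLE", hgvs_p="p.K777N")
        assert not assess_pole([v], tmb=500, config=config)

    def test_empty_variants(self, config):
        assert not assess_pole([], tmb=0, config=config)


class TestTP53:
    @pytest.mark.parametrize(
        "consequence,expected",
        [
            (Consequence.MISSENSE, True),
            (Consequence.NONSENSE, True),
            (Consequence.FRAMESHIFT, True),
            (Consequence.SYNONYMOUS, False),
        ],
    )
    def test_consequence_classes(self, config, consequence, expected):
        v = mkvar("TP53", consequence=consequence, hgvs_p="p.R273H", vaf=0.4)
        assert assess_tp53([v], config) is expected

    def test_absent_gene_is_wildtype(self, config):
        assert not assess_tp53([mkvar("PTEN")], config)


class TestLocusInstability:
    def test_baseline_supported_reads_are_stable(self, config):
        locus = mklocus({10: 10, 11: 20, 12: 40, 13: 20, 14: 10})
        assert not score_locus_instability(locus, config)

    def test_novel_fraction_above_tau_is_unstable(self, config):
        locus = mklocus({7: 15, 8: 15, 12: 70})  # 30/100 novel
        assert score_locus_instability(locus, config)

    def test_exact_tau_is_stable_by_strict_inequality(self, config):
        locus = mklocus({7: 10, 12: 90})  # exactly 0.10
        assert not score_locus_instability(locus, config)

    def test_zero_reads_not_evaluable(self, config):
        with pytest.raises(NotEvaluableError):
            score_locus_instability(mklocus({12: 0}), config)

    @given(scale=st.integers(2, 50))
    @settings(max_examples=20, derandomize=True)
    def test_invariant_to_rescaling_read_counts(self, config, scale):
        base_counts = {7: 12, 12: 70, 13: 18}
        scaled = {k: v * scale for k, v in base_counts.items()}
        assert score_locus_instability(mklocus(base_counts), config) == \
            score_locus_instability(mklocus(scaled), config)


class TestCallMSI:
    def unstable(self, i):
        return mklocus({7: 40, 12: 60}, locus_id=f"U{i}")

    def stable(self, i):
        return mklocus({12: 100}, locus_id=f"S{i}")

    def test_msi_high_needs_fraction_and_hypermutation(self, config):
        loci = [self.unstable(i) for i in range(10)] + [self.stable(i) for i in range(15)]
        assert call_msi(loci, tmb=20, config=config) == "MSI-H"
        assert call_msi(loci, tmb=5, config=config) != "MSI-H"

    def test_low_fraction_is_msi_l(self, config):
        loci = [self.unstable(i) for i in range(3)] + [self.stable(i) for i in range(22)]
        assert call_msi(loci, tmb=20, config=config) == "MSI-L"

    def test_no_unstable_is_mss(self, config):
        assert call_msi([self.stable(i) for i in range(5)], tmb=0, config=config) == "MSS"

    def test_zero_scoreable_loci_raises(self, config):
        with pytest.raises(NotEvaluableError):
            call_msi([mklocus({12: 0})], tmb=0, config=config)

    def test_zero_read_locus_excluded_from_denominator(self, config):
        loci = [self.unstable(0), self.stable(1), mklocus({12: 0}, "Z")]
        # 1/2 unstable, not 1/3
        assert call_msi(loci, tmb=20, config=config) == "MSI-H"

    def test_adding_unstable_locus_never_moves_toward_mss(self, config):
        rank = {"MSS": 0, "MSI-L": 1, "MSI-H": 2}
        loci = [self.unstable(i) for i in range(2)] + [self.stable(i) for i in range(18)]
        before = call_msi(loci, tmb=20, config=config)
        after = call_msi(loci + [self.unstable(99)], tmb=20, config=config)
        assert rank[after] >= rank[before]


class TestFGA:
    def test_all_neutral_is_zero(self, config):
        segs = [CNSegment("chr1", 0, 1000, 0.1), CNSegment("chr1", 1000, 2000, -0.2)]
        assert compute_fga(segs, config) == 0.0

    def test_half_altered(self, config):
        segs = [CNSegment("chr1", 0, 1_000_000, 0.9),
                CNSegment("chr1", 1_000_000, 2_000_000, 0.0)]
        assert compute_fga(segs, config) == 0.5

    def test_no_segments_is_zero(self, config):
        assert compute_fga([], config) == 0.0

    def test_matches_base_by_base_enumeration(self, config):
        segs = [
            CNSegment("chr1", 0, 137, 0.45),
            CNSegment("chr1", 137, 400, -0.1),
            CNSegment("chr1", 450, 700, -0.8),
            CNSegment("chr2", 10, 260, 0.29),
            CNSegment("chr2", 300, 333, 1.4),
        ]
        altered = covered = 0
        for seg in segs:  # oracle: enumerate every base at 1 bp resolution
            for _base in range(seg.start, seg.end):
                covered += 1
                altered += abs(seg.log2_ratio) > config.fga_log2_threshold
        assert compute_fga(segs, config) == pytest.approx(altered / covered)

    @given(cut=st.integers(1, 999))
    @settings(max_examples=25, derandomize=True)
    def test_invariant_to_splitting_segments(self, config, cut):
        whole = [CNSegment("chr1", 0, 1000, 0.8), CNSegment("chr2", 0, 500, 0.0)]
        split = [CNSegment("chr1", 0, cut, 0.8), CNSegment("chr1", cut, 1000, 0.8),
                 CNSegment("chr2", 0, 500, 0.0)]
        assert compute_fga(split, config) == pytest.approx(compute_fga(whole, config))


class TestCNRule:
    def test_tp53_drives_cnh(self, config):
        assert classify_cn(True, 0.0, config) == "CNH"

    def test_low_fga_wildtype_is_cnl(self, config):
        assert classify_cn(False, 0.05, config) == "CNL"

    def test_fga_clause_depends_on_rule(self):
        or_rule = CallerConfig(cn_rule="tp53_or_fga")
        only = CallerConfig(cn_rule="tp53_only")
        assert classify_cn(False, 0.35, or_rule) == "CNH"
        assert classify_cn(False, 0.35, only) == "CNL"


def test_quiet_sample_yields_null_profile(config):
    """Empty variants, baseline-identical loci and flat segments give the
    all-negative marker profile."""
    loci = [mklocus({10: 10, 11: 20, 12: 40, 13: 20, 14: 10})]
    segs = [CNSegment("chr1", 0, 1000, 0.0)]
    profile = build_profile([], loci, segs, config)
    assert (profile.pole_positive, profile.tp53_mutated, profile.tmb,
            profile.msi_status, profile.fga) == (False, False, 0.0, "MSS", 0.0)


def test_config_json_round_trip():
    cfg = CallerConfig(vaf_min=0.03, cn_rule="tp53_only",
                       per_gene_vaf_min={"KRAS": 0.01})
    assert CallerConfig.from_json(cfg.to_json()) == cfg


def test_config_fraction_ordering_enforced():
    with pytest.raises(ConfigError):
        CallerConfig(msi_l_locus_fraction=0.5, msi_h_locus_fraction=0.3)
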
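import numpy as np
import pytest

from haploxo.io_formats import (
    AnnotationTrack,
    GenomicInterval,
    HaplotypeSequence,
    RepeatAnnotation,
)
from haploxo.pairwise_align import anchor_align
from haploxo.snp_calling import (
    FilterParams,
    apply_filters,
    call_raw_substitutions,
    count_snps,
    counted_positions,
    segment_counts,
)

from conftest import mutate_at, random_seq


def _pair(rng, length=20_000, mut_positions=(), n_run=None):
    s = random_seq(rng, length)
    t = s
    for p in mut_positions:
        t = mutate_at(t, p, rng)
    if n_run is not None:
        start, ln = n_run
        t = t[:start] + "N" * ln + t[start + ln:]
    a, b = HaplotypeSequence("a", s), HaplotypeSequence("b", t)
    return a, b, anchor_align(a, b)


def _empty_tracks():
    return AnnotationTrack("a", []), AnnotationTrack("b", [])


def _filtered(rng, **kw):
    a, b, aln = _pair(rng, **kw)
    snps, n_sites = call_raw_substitutions(aln, a, b)
    ta, tb = _empty_tracks()
    return apply_filters(snps, aln, a, b, ta, tb, n_sites=n_sites), (a, b, aln)


class TestRawCalls:
    def test_identical_sequences_give_no_calls(self, rng):
        a, b, aln = _pair(rng)
        snps, n_sites = call_raw_substitutions(aln, a, b)
        assert snps == [] and n_sites == []

    def test_single_substitution(self, rng):
        a, b, aln = _pair(rng, mut_positions=[5_000])
        (snp,), n_sites = call_raw_substitutions(aln, a, b)
        assert (snp.pos_a, snp.pos_b) == (5_000, 5_000)
        assert snp.allele_a == a.seq[5_000] and snp.allele_b == b.seq[5_000]
        assert n_sites == []

    def test_n_column_is_site_not_substitution(self, rng):
        a, b, aln = _pair(rng, n_run=(5_000, 1))
        snps, n_sites = call_raw_substitutions(aln, a, b)
        assert snps == []
        assert (5_000, 5_000) in n_sites

    def test_id_mismatch_rejected(self, rng):
        a, b, aln = _pair(rng)
        with pytest.raises(ValueError, match="alignment"):
            call_raw_substitutions(aln, b, a)


class TestDenseClusterFilter:
    def test_six_in_fifty_all_removed(self, rng):
        cluster = [5_000, 5_008, 5_016, 5_024, 5_032, 5_040]
        snps, _ = _filtered(rng, mut_positions=cluster + [10_000])
        clustered = [s for s in snps if s.pos_a in cluster]
        assert len(clustered) == 6
        assert all("DENSE_CLUSTER" in s.filters for s in clustered)
        assert all(not s.counted for s in clustered)
        (lone,) = [s for s in snps if s.pos_a == 10_000]
        assert lone.counted

    def test_five_in_fifty_all_counted(self, rng):
        cluster = [5_000, 5_010, 5_020, 5_030, 5_040]
        snps, _ = _filtered(rng, mut_positions=cluster)
        assert all(s.counted for s in snps if s.pos_a in cluster)

    def test_matches_exhaustive_window_oracle(self, rng):
        positions = sorted(
            int(p) for p in rng.choice(3_000, size=60, replace=False)
        )
        positions = [p + 1_000 for p in positions]
        snps, _ = _filtered(rng, length=10_000, mut_positions=positions)
        pos = sorted(s.pos_a for s in snps)
        # oracle: scan every 50-nt window offset
        flagged = set()
        for w0 in range(min(pos), max(pos) + 1):
            members = [p for p in pos if w0 <= p < w0 + 50]
            if len(members) > 5:
                flagged.update(members)
        got = {s.pos_a for s in snps if "DENSE_CLUSTER" in s.filters}
        assert got == flagged


class TestNProximityFilter:
    def test_within_50bp_removed_at_51_counted(self, rng):
        # N-run at [5000, 5100); substitutions 30 bp and 51 bp past its end
        near, far = 5_100 - 1 + 30, 5_100 - 1 + 51
        snps, _ = _filtered(rng, mut_positions=[near, far], n_run=(5_000, 100))
        by_pos = {s.pos_a: s for s in snps}
        assert "N_PROXIMAL" in by_pos[near].filters
        assert by_pos[far].counted

    def test_short_n_stretch_ignored(self, rng):
        # 2-nt N stretch is below min_n_run=3: no proximity zone, but the
        # N columns themselves are never substitutions
        snps, _ = _filtered(rng, mut_positions=[5_040], n_run=(5_000, 2))
        (snp,) = [s for s in snps if s.pos_a == 5_040]
        assert "N_PROXIMAL" not in snp.filters


class TestGapProximityFilter:
    def test_snp_near_long_gap_removed(self, rng):
        s = random_seq(rng, 20_000)
        t = s[:5_000] + s[5_200:]      # 200-bp deletion in b
        t = mutate_at(t, 5_030, rng)   # 30 bp right of the gap (b coords)
        t = mutate_at(t, 10_000, rng)  # control far from the gap
        a, b = HaplotypeSequence("a", s), HaplotypeSequence("b", t)
        aln = anchor_align(a, b)
        snps, n_sites = call_raw_substitutions(aln, a, b)
        ta, tb = _empty_tracks()
        snps = apply_filters(snps, aln, a, b, ta, tb, n_sites=n_sites)
        # the gap-adjacent substitution is either absorbed into the optimal
        # gap placement or excluded by the gap-proximity filter
        assert all("GAP_PROXIMAL" in s.filters for s in snps
                   if abs(s.pos_a - 5_200) < 80)
        (control,) = [s for s in snps if s.pos_b == 10_000]
        assert control.counted


class TestSequenceContextFilters:
    def test_homopolymer_substitution_removed(self, rng):
        s = random_seq(rng, 10_000)
        s = s[:5_000] + "A" * 12 + s[5_012:]
        t = s[:5_006] + "G" + s[5_007:]  # break the run on b only
        a, b = HaplotypeSequence("a", s), HaplotypeSequence("b", t)
        aln = anchor_align(a, b)
        snps, _ = call_raw_substitutions(aln, a, b)
        snps = apply_filters(snps, aln, a, b, *_empty_tracks())
        (snp,) = [s_ for s_ in snps if s_.pos_a == 5_006]
        assert "HOMOPOLYMER" in snp.filters

    def test_simple_repeat_annotation_masks_snp(self, rng):
        a, b, aln = _pair(rng, mut_positions=[5_000, 9_000])
        track_a = AnnotationTrack(
            "a",
            [RepeatAnnotation(GenomicInterval("a", 4_900, 5_100), "(AC)n",
                              "Simple_repeat")],
        )
        track_b = AnnotationTrack("b", [])
        snps, _ = call_raw_substitutions(aln, a, b)
        snps = apply_filters(snps, aln, a, b, track_a, track_b)
        by_pos = {s.pos_a: s for s in snps}
        assert "SIMPLE_REPEAT" in by_pos[5_000].filters
        assert by_pos[9_000].counted

    def test_tandem_fallback_without_track(self, rng):
        s = random_seq(rng, 10_000)
        s = s[:5_000] + "ACACACACACACACAC" + s[5_016:]
        t = mutate_at(s, 5_008, rng)
        a, b = HaplotypeSequence("a", s), HaplotypeSequence("b", t)
        aln = anchor_align(a, b)
        snps, _ = call_raw_substitutions(aln, a, b)
        snps = apply_filters(snps, aln, a, b)  # no tracks: fallback detector
        (snp,) = [s_ for s_ in snps if s_.pos_a == 5_008]
        assert "SIMPLE_REPEAT" in snp.filters


class TestConservationProperties:
    def test_raw_equals_counted_plus_filtered(self, rng):
        positions = sorted(int(p) for p in rng.choice(18_000, size=80,
                                                      replace=False))
        snps, _ = _filtered(rng, mut_positions=positions, n_run=(19_000, 300))
        counted = [s for s in snps if s.counted]
        filtered = [s for s in snps if s.filters]
        assert len(counted) + len(filtered) == len(snps)
        assert all(bool(s.filters) != s.counted for s in snps)

    def test_adding_artifact_never_adds_counted_snps(self, rng):
        positions = [2_000, 6_000, 9_500, 14_000]
        a, b, aln = _pair(rng, mut_positions=positions)
        snps, ns = call_raw_substitutions(aln, a, b)
        base = set(counted_positions(
            apply_filters(snps, aln, a, b, *_empty_tracks(), n_sites=ns)
        ))
        # same pair with an extra N-run artifact near one SNP
        a2, b2, aln2 = _pair(rng, mut_positions=positions, n_run=(6_020, 100))
        snps2, ns2 = call_raw_substitutions(aln2, a2, b2)
        with_artifact = set(counted_positions(
            apply_filters(snps2, aln2, a2, b2, *_empty_tracks(), n_sites=ns2)
        ))
        assert with_artifact <= base


class TestCounting:
    def test_count_matches_brute_force_on_random_intervals(self, rng):
        positions = sorted(int(p) for p in rng.choice(18_000, size=60,
                                                      replace=False))
        snps, _ = _filtered(rng, mut_positions=positions)
        pos = counted_positions(snps)
        for _ in range(200):
            lo, hi = sorted(rng.integers(0, 20_000, size=2))
            if lo == hi:
                continue
            iv = GenomicInterval("a", int(lo), int(hi))
            assert count_snps(snps, iv) == sum(1 for p in pos if lo <= p < hi)

    def test_segment_counts_total_and_conservation(self, rng):
        positions = [1_000, 3_000, 7_000, 12_000, 18_000]
        snps, _ = _filtered(rng, mut_positions=positions)
        segs = [
            ("left", GenomicInterval("a", 0, 10_000)),
            ("right", GenomicInterval("a", 10_000, 20_000)),
        ]
        df = segment_counts(snps, segs)
        total = df[df["segment"] == "total"].iloc[0]
        assert total["count"] == df[df["segment"] != "total"]["count"].sum()
        assert total["count"] == count_snps(snps, GenomicInterval("a", 0, 20_000))

    def test_overlapping_segments_rejected(self, rng):
        snps, _ = _filtered(rng, mut_positions=[1_000])
        segs = [
            ("x", GenomicInterval("a", 0, 10_000)),
            ("y", GenomicInterval("a", 5_000, 20_000)),
        ]
        with pytest.raises(ValueError, match="overlap"):
            segment_counts(snps, segs)


def test_filter_params_validated():
    with pytest.raises(ValueError):
        FilterParams(cluster_max=0)
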
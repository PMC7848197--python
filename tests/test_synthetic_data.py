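import numpy as np
import pytest

from haploxo.io_formats import GenomicInterval, HaplotypeSequence
from haploxo.pairwise_align import anchor_align
from haploxo.snp_calling import apply_filters, call_raw_substitutions, counted_positions
from haploxo.synthetic_data import (
    ArtifactSpec,
    SimulationConfig,
    build_mosaic_haplotype,
    generate_ancestral_pool,
    inject_artifacts,
    inject_marker_indels,
    simulate_haplotype_pair,
    write_truth_tsv,
)

from conftest import random_seq


class TestAncestralPool:
    def test_zero_rate_gives_identical_lineages(self):
        cfg = SimulationConfig(region_length=10_000, n_lineages=3,
                               between_lineage_rate=0.0, seed=1)
        pool = generate_ancestral_pool(cfg)
        assert pool[0] == pool[1] == pool[2]

    def test_pairwise_mismatches_match_poisson_expectation(self):
        # rate 7/kb over 500 kb: expected 3500 substitutions, sd ~59
        cfg = SimulationConfig(region_length=500_000, seed=11)
        pool = generate_ancestral_pool(cfg)
        mismatches = sum(x != y for x, y in zip(pool[0], pool[1]))
        assert abs(mismatches - 3_500) < 3 * np.sqrt(3_500)

    def test_same_seed_reproduces_pool(self):
        cfg = SimulationConfig(region_length=20_000, seed=5)
        assert generate_ancestral_pool(cfg) == generate_ancestral_pool(cfg)

    def test_tiny_region_rejected(self):
        with pytest.raises(ValueError, match="1 kb"):
            generate_ancestral_pool(SimulationConfig(region_length=500))


class TestMosaic:
    def _pool(self):
        cfg = SimulationConfig(region_length=30_000, n_lineages=3, seed=2)
        return generate_ancestral_pool(cfg)

    def test_single_block_equals_lineage(self):
        pool = self._pool()
        hap, truth = build_mosaic_haplotype(
            pool, [(GenomicInterval("h", 0, 30_000), 1)], "h"
        )
        assert hap.seq == pool[1]
        assert truth.breakpoints == []

    def test_shared_prefix_confines_divergence(self):
        pool = self._pool()
        hap_a, _ = build_mosaic_haplotype(
            pool, [(GenomicInterval("a", 0, 30_000), 0)], "a"
        )
        blocks = [
            (GenomicInterval("b", 0, 20_000), 0),
            (GenomicInterval("b", 20_000, 30_000), 1),
        ]
        hap_b, truth = build_mosaic_haplotype(pool, blocks, "b")
        diff = [i for i, (x, y) in enumerate(zip(hap_a.seq, hap_b.seq)) if x != y]
        assert truth.breakpoints == [20_000]
        assert all(i >= 20_000 for i in diff)

    def test_three_blocks_record_two_breakpoints(self):
        pool = self._pool()
        blocks = [
            (GenomicInterval("h", 0, 10_000), 0),
            (GenomicInterval("h", 10_000, 20_000), 1),
            (GenomicInterval("h", 20_000, 30_000), 0),
        ]
        _, truth = build_mosaic_haplotype(pool, blocks, "h")
        assert truth.breakpoints == [10_000, 20_000]

    def test_gap_in_tiling_rejected(self):
        pool = self._pool()
        blocks = [
            (GenomicInterval("h", 0, 10_000), 0),
            (GenomicInterval("h", 15_000, 30_000), 1),
        ]
        with pytest.raises(ValueError, match="tile"):
            build_mosaic_haplotype(pool, blocks, "h")


class TestSimulatePair:
    def test_deterministic_for_fixed_seed(self):
        cfg = SimulationConfig(region_length=50_000, breakpoints=[25_000], seed=3)
        a1, b1, *_ = simulate_haplotype_pair(cfg)
        a2, b2, *_ = simulate_haplotype_pair(cfg)
        assert a1.seq == a2.seq and b1.seq == b2.seq

    def test_counted_snps_subset_of_planted_divergence(self):
        """With artifacts off, every counted SNP is a planted between-lineage
        substitution; the only planted sites not counted are those falling in
        intrinsic sequence contexts (homopolymers / chance tandem runs)."""
        cfg = SimulationConfig(region_length=60_000, breakpoints=[30_000],
                               within_lineage_rate=0.0, seed=9)
        a, b, _, _ = simulate_haplotype_pair(cfg)
        pool = generate_ancestral_pool(cfg)
        planted = {i for i, (x, y) in enumerate(zip(pool[0], pool[1]))
                   if x != y and i >= 30_000}
        aln = anchor_align(a, b)
        snps, ns = call_raw_substitutions(aln, a, b)
        filtered = apply_filters(snps, aln, a, b, n_sites=ns)
        counted = set(counted_positions(filtered))
        assert counted <= planted
        missed = planted - counted
        context_filtered = {
            s.pos_a for s in filtered
            if s.filters <= {"HOMOPOLYMER", "SIMPLE_REPEAT", "DENSE_CLUSTER"}
            and s.filters
        }
        assert missed <= context_filtered

    def test_same_lineage_pair_with_zero_within_rate_has_no_counted_snps(self):
        cfg = SimulationConfig(region_length=50_000, breakpoints=[],
                               within_lineage_rate=0.0, seed=4)
        a, b, _, _ = simulate_haplotype_pair(cfg)
        aln = anchor_align(a, b)
        snps, _ = call_raw_substitutions(aln, a, b)
        assert snps == []


class TestMarkerInjection:
    def test_all_absent_with_no_relic_leaves_sequence_unchanged(
        self, marker_panel, marker_defs
    ):
        no_relic = [d for d in marker_defs if not d.absent_content]
        (hap, track), rng = marker_panel(6)
        hap2, track2, truth = inject_marker_indels(
            hap, track, no_relic, {d.name: 1 for d in no_relic}, rng
        )
        assert hap2.seq == hap.seq
        assert all(v == 1 for v in truth.marker_truth.values())

    def test_present_hervk9_track_shows_provirus_between_flanks(
        self, marker_panel, marker_defs
    ):
        hervk9 = [d for d in marker_defs if d.name == "HERVK9"]
        (hap, track), rng = marker_panel(7)
        hap2, track2, _ = inject_marker_indels(
            hap, track, hervk9, {"HERVK9": 2}, rng
        )
        names = [a.repeat_name for a in track2]
        i = names.index("HERVK9-int")
        assert names[i - 1] == "MER9" and names[i + 1] == "MER9"
        assert len(hap2.seq) > len(hap.seq)

    def test_tsd_motif_duplicated_around_insertion(self, marker_panel,
                                                   marker_defs):
        aluhg = [d for d in marker_defs if d.name == "AluHG"]
        (hap, track), rng = marker_panel(8)
        assert hap.seq.count("CACTTAAACAT") == 1
        hap2, _, _ = inject_marker_indels(hap, track, aluhg, {"AluHG": 2}, rng)
        assert hap2.seq.count("CACTTAAACAT") == 2

    def test_missing_flank_signature_raises(self, marker_defs, rng):
        hervk9 = next(d for d in marker_defs if d.name == "HERVK9")
        hap = HaplotypeSequence("h", random_seq(rng, 5_000))
        from haploxo.io_formats import AnnotationTrack

        with pytest.raises(ValueError, match="HERVK9"):
            inject_marker_indels(hap, AnnotationTrack("h", []), [hervk9],
                                 {"HERVK9": 2}, rng)


class TestArtifacts:
    def test_n_run_written(self, rng):
        hap = HaplotypeSequence("h", random_seq(rng, 20_000))
        out, truth = inject_artifacts(
            hap, [ArtifactSpec("n_run", 10_000, 200)], rng
        )
        assert out.seq[10_000:10_200] == "N" * 200
        assert out.seq[:10_000] == hap.seq[:10_000]
        assert truth.artifact_intervals[0][1] == "n_run"

    def test_dense_cluster_removed_by_downstream_filter(self, rng):
        s = random_seq(rng, 20_000)
        a = HaplotypeSequence("a", s)
        b, _ = inject_artifacts(
            HaplotypeSequence("b", s),
            [ArtifactSpec("dense_cluster", 5_000, 50)],
            rng,
        )
        aln = anchor_align(a, b)
        snps, ns = call_raw_substitutions(aln, a, b)
        assert len(snps) == 6
        filtered = apply_filters(snps, aln, a, b, n_sites=ns)
        assert all("DENSE_CLUSTER" in s_.filters for s_ in filtered)
        assert counted_positions(filtered) == []

    def test_microsat_variant_creates_tandem(self, rng):
        hap = HaplotypeSequence("h", random_seq(rng, 5_000))
        out, _ = inject_artifacts(hap, [ArtifactSpec("microsat", 1_000, 40)], rng)
        assert out.seq[1_000:1_040] == "AC" * 20

    def test_deletion_shortens_sequence(self, rng):
        hap = HaplotypeSequence("h", random_seq(rng, 5_000))
        out, _ = inject_artifacts(hap, [ArtifactSpec("deletion", 1_000, 300)], rng)
        assert out.length == 4_700
        assert out.seq == hap.seq[:1_000] + hap.seq[1_300:]

    def test_empty_plan_is_identity(self, rng):
        hap = HaplotypeSequence("h", random_seq(rng, 2_000))
        out, truth = inject_artifacts(hap, [], rng)
        assert out.seq == hap.seq and truth.artifact_intervals == []

    def test_overlapping_intervals_rejected(self, rng):
        hap = HaplotypeSequence("h", random_seq(rng, 2_000))
        plan = [ArtifactSpec("n_run", 100, 100), ArtifactSpec("n_run", 150, 100)]
        with pytest.raises(ValueError, match="overlap"):
            inject_artifacts(hap, plan, rng)


def test_truth_tsv_round_trips_breakpoints(tmp_path):
    cfg = SimulationConfig(region_length=20_000, breakpoints=[10_000], seed=12)
    _, _, ta, tb = simulate_haplotype_pair(cfg)
    p = tmp_path / "truth.tsv"
    write_truth_tsv([ta, tb], p)
    lines = p.read_text().strip().split("\n")
    bp_lines = [l for l in lines if "\tbreakpoint\t" in l]
    assert any(l.startswith("hapB\tbreakpoint\t10000") for l in bp_lines)
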
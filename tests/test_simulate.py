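"""Synthetic-data generator: determinism, hairpin construction, truth."""

import io
from collections import Counter

import numpy as np
import pytest

from mirnome.discovery import DEFAULT_PRESETS, classify_hairpin, fold_nussinov
from mirnome.mapping import revcomp
from mirnome.qc import classify_read
from mirnome.simulate import (
    ConfigError,
    LibraryConfig,
    PlacementError,
    TruthTable,
    dinucleotide_shuffle,
    generate_genome,
    make_truth,
    plant_hairpin,
    simulate_agoip,
    simulate_library,
    write_fastq,
)


class TestGenerateGenome:
    def test_fixed_seed_reproducible(self):
        g1 = generate_genome(10_000, 0.5, seed=7)
        g2 = generate_genome(10_000, 0.5, seed=7)
        assert g1.sequence == g2.sequence

    def test_different_seed_differs(self):
        assert (
            generate_genome(10_000, 0.5, seed=7).sequence
            != generate_genome(10_000, 0.5, seed=8).sequence
        )

    def test_gc_concentration(self):
        g = generate_genome(100_000, 0.4, seed=1)
        gc = sum(g.sequence.count(b) for b in "GC") / g.length
        assert 0.37 <= gc <= 0.43

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(500, 0.5, seed=0)


class TestPlantHairpin:
    def test_planted_precursor_passes_all_presets(self):
        g = generate_genome(5_000, 0.42, seed=3)
        planted = []
        p = plant_hairpin(g, 2_000, planted, seed=11)
        precursor = g.sequence[p.precursor_interval[0] - 1 : p.precursor_interval[1]]
        fold = fold_nussinov(precursor)
        mature_local = (1, len(p.mature_seq))
        for preset in DEFAULT_PRESETS:
            assert classify_hairpin(fold, mature_local, preset).passed

    def test_structure_of_planted_record(self):
        g = generate_genome(5_000, 0.42, seed=3)
        planted = []
        p = plant_hairpin(g, 2_000, planted, mature_len=22, loop_len=12, seed=11)
        ps, pe = p.precursor_interval
        ms, me = p.mature_interval
        assert ps <= ms <= me <= pe
        assert pe - ps + 1 == 2 * 22 + 12
        assert g.sequence[ms - 1 : me] == p.mature_seq
        # star arm is a near-reverse-complement of the mature (<= 3 mismatches)
        star = g.sequence[pe - 22 : pe]
        mismatches = sum(a != b for a, b in zip(star, revcomp(p.mature_seq)))
        assert mismatches <= 3

    def test_overlapping_plant_rejected(self):
        g = generate_genome(5_000, 0.42, seed=3)
        planted = []
        plant_hairpin(g, 2_000, planted, seed=11)
        with pytest.raises(PlacementError):
            plant_hairpin(g, 2_010, planted, seed=12)

    def test_mature_unique_in_genome(self):
        """Exhaustive substring scan: the planted mature occurs exactly once
        on either strand."""
        g = generate_genome(20_000, 0.42, seed=5)
        planted = []
        p = plant_hairpin(g, 9_000, planted, seed=21)
        n = g.sequence.count(p.mature_seq) + g.sequence.count(revcomp(p.mature_seq))
        assert n == 1


class TestSimulateLibrary:
    @staticmethod
    def _tiny_world():
        g = generate_genome(5_000, 0.42, seed=3)
        planted = []
        plant_hairpin(g, 1_500, planted, seed=11, mirna_id="m1")
        plant_hairpin(g, 2_500, planted, seed=12, mirna_id="m2")
        return g, planted

    def test_no_contaminants_all_keep(self):
        g, planted = self._tiny_world()
        truth = make_truth(planted, {"a": {"m1": 1.0, "m2": 1.0}}, baseline="b")
        reads, counts = simulate_library(
            g, planted, truth, LibraryConfig(n_reads=500, seed=1), "a"
        )
        assert len(reads) == 500 and counts["mirna"] == 500
        assert all(classify_read(r)[0] == "keep" for r in reads)

    def test_class_counts_sum_to_n_reads(self):
        g, planted = self._tiny_world()
        truth = make_truth(
            planted,
            {"a": {"m1": 2.0, "m2": 0.5}},
            baseline="b",
            contaminants={"polyA": 0.1, "ambiguous": 0.05, "adapter5": 0.05},
        )
        reads, counts = simulate_library(
            g, planted, truth, LibraryConfig(n_reads=2_000, seed=2), "a"
        )
        assert len(reads) == 2_000
        assert sum(counts.values()) == 2_000

    def test_fixed_seed_byte_identical_fastq(self, tmp_path):
        g, planted = self._tiny_world()
        truth = make_truth(planted, {"a": {"m1": 1.0, "m2": 1.0}}, baseline="b")
        cfg = LibraryConfig(n_reads=300, seed=9)
        for name in ("one", "two"):
            reads, _ = simulate_library(g, planted, truth, cfg, "a")
            write_fastq(reads, tmp_path / f"{name}.fastq")
        assert (tmp_path / "one.fastq").read_bytes() == (tmp_path / "two.fastq").read_bytes()

    def test_unknown_condition_and_missing_mirnas(self):
        g, planted = self._tiny_world()
        truth = make_truth(planted, {"a": {"m1": 1.0, "m2": 1.0}}, baseline="b")
        with pytest.raises(ConfigError):
            simulate_library(g, planted, truth, LibraryConfig(n_reads=10, seed=0), "zzz")
        with pytest.raises(ConfigError):
            simulate_library(g, [], truth, LibraryConfig(n_reads=10, seed=0), "a")


class TestSimulateAgoip:
    def test_supported_depth_guaranteed(self):
        g, planted = TestSimulateLibrary._tiny_world()
        datasets = simulate_agoip(planted, {"m1"}, depth_per_candidate=5, n_datasets=9, seed=4)
        assert len(datasets) == 9  # the study re-analysed nine RIP datasets
        m1 = next(p for p in planted if p.mirna_id == "m1")
        for reads in datasets:
            covering = [r for r in reads if r.seq.startswith(m1.mature_seq)]
            assert len(covering) >= 5

    def test_errors(self):
        g, planted = TestSimulateLibrary._tiny_world()
        with pytest.raises(ConfigError):
            simulate_agoip(planted, {"m1"}, n_datasets=0)
        with pytest.raises(ConfigError):
            simulate_agoip(planted, {"nope"})


class TestTruth:
    def test_abundances_sum_to_one_and_folds_exact(self):
        g, planted = TestSimulateLibrary._tiny_world()
        g2 = generate_genome(5_000, 0.42, seed=8, chrom_name="chrT")
        plant_hairpin(g2, 1_500, planted, seed=31, mirna_id="m3")
        plant_hairpin(g2, 2_500, planted, seed=32, mirna_id="m4")
        req = {"a": {"m1": 2.0, "m2": 0.5, "m3": 4.0, "m4": 1.0}}
        truth = make_truth(planted, req, baseline="base")
        for cond in truth.conditions:
            assert abs(sum(truth.abundance[cond].values()) - 1.0) < 1e-12
        for mid, f in req["a"].items():
            assert truth.fold(mid, "a", "base") == pytest.approx(f, rel=1e-9)

    def test_invalid_contaminants_rejected(self):
        g, planted = TestSimulateLibrary._tiny_world()
        with pytest.raises(ValueError):
            make_truth(
                planted,
                {"a": {"m1": 1.0, "m2": 1.0}},
                contaminants={"polyA": 0.7, "mrna": 0.5},
            )

    def test_truth_table_invariant_enforced(self):
        with pytest.raises(ValueError):
            TruthTable("b", {"b": {"m1": 0.6, "m2": 0.6}}, {}, 0)


class TestWorldFixture:
    def test_every_planted_hairpin_validates(self, world):
        for p in world.planted:
            seq = world.genome.sequence[
                p.precursor_interval[0] - 1 : p.precursor_interval[1]
            ]
            fold = fold_nussinov(seq)
            ms = p.mature_interval[0] - p.precursor_interval[0] + 1
            me = p.mature_interval[1] - p.precursor_interval[0] + 1
            assert classify_hairpin(fold, (ms, me), DEFAULT_PRESETS[1]).passed

    def test_mrna_transcripts_clear_of_planted_loci(self, world):
        for s, e in world.mrna_intervals:
            for p in world.planted:
                ps, pe = p.precursor_interval
                assert e < ps or s > pe


def test_dinucleotide_shuffle_preserves_composition():
    rng = np.random.default_rng(0)
    seq = generate_genome(1_000, 0.42, seed=2).sequence[:80]
    shuffled = dinucleotide_shuffle(seq, rng)
    def dinucs(s):
        return Counter(s[i : i + 2] for i in range(len(s) - 1))
    assert len(shuffled) == len(seq)
    assert dinucs(shuffled) == dinucs(seq)
    assert shuffled[0] == seq[0] and shuffled[-1] == seq[-1]
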
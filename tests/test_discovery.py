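"""Folding, hairpin classification, stacks, consensus and Ago verification."""

from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirnome.discovery import (
    DEFAULT_PRESET,
    DEFAULT_PRESETS,
    FoldResult,
    build_stacks,
    can_pair,
    classify_hairpin,
    consensus_detect,
    fold_nussinov,
    pairs_to_structure,
    star_scan,
    structure_to_pairs,
    terminal_loops,
    unannotated_placements,
    verify_agoip,
)
from mirnome.mapping import Placement
from mirnome.qc import process_reads
from mirnome.simulate import (
    dinucleotide_shuffle,
    generate_genome,
    plant_hairpin,
)


def max_pairs_enumeration(seq: str, min_loop: int = 3) -> int:
    """Independent oracle: exhaustive recursion over all nested structures."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        top = best(i + 1, j)  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if can_pair(seq[i], seq[k]):
                top = max(top, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return top

    return best(0, len(seq) - 1)


class TestFoldNussinov:
    def test_perfect_stem(self):
        fold = fold_nussinov("GGGAAACCC")
        assert fold.n_pairs == 3
        assert fold.structure == "(((...)))"

    def test_unpairable(self):
        assert fold_nussinov("AAAAAAAA").n_pairs == 0

    def test_min_loop_respected(self):
        for i, j in fold_nussinov("GCGCAAAGCGC").pairing:
            assert j - i > 3

    def test_length_bounds(self):
        with pytest.raises(ValueError):
            fold_nussinov("A")
        with pytest.raises(ValueError):
            fold_nussinov("A" * 201)

    def test_deterministic(self):
        seq = generate_genome(1_000, 0.5, seed=3).sequence[:60]
        assert fold_nussinov(seq) == fold_nussinov(seq)

    @settings(deadline=None, derandomize=True, max_examples=150)
    @given(st.text(alphabet="ACGT", min_size=5, max_size=12))
    def test_equals_exhaustive_enumeration(self, seq):
        assert fold_nussinov(seq).n_pairs == max_pairs_enumeration(seq)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(0, 2**31 - 1))
    def test_dot_bracket_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=40))
        fold = fold_nussinov(seq)
        assert structure_to_pairs(fold.structure) == fold.pairing
        assert pairs_to_structure(fold.pairing, len(seq)) == fold.structure

    def test_pairing_invariants(self):
        seq = generate_genome(1_000, 0.5, seed=9).sequence[:80]
        fold = fold_nussinov(seq)
        seen = set()
        for i, j in fold.pairing:
            assert i < j and can_pair(seq[i - 1], seq[j - 1])
            assert i not in seen and j not in seen
            seen |= {i, j}
        for a, b in fold.pairing:  # non-crossing
            for x, y in fold.pairing:
                assert not (a < x < b < y)


def planted_fold(seed):
    g = generate_genome(5_000, 0.42, seed=seed)
    planted = []
    p = plant_hairpin(g, 2_000, planted, seed=seed + 1)
    seq = g.sequence[p.precursor_interval[0] - 1 : p.precursor_interval[1]]
    return fold_nussinov(seq), (1, len(p.mature_seq)), seq


class TestClassifyHairpin:
    def test_planted_passes_all_presets(self):
        fold, mature, _ = planted_fold(100)
        for preset in DEFAULT_PRESETS:
            assert classify_hairpin(fold, mature, preset).passed

    def test_mature_straddling_loop_fails(self):
        fold, _, seq = planted_fold(101)
        li, lj = terminal_loops(fold.pairing)[0]
        call = classify_hairpin(fold, (li - 2, lj + 2), DEFAULT_PRESET)
        assert not call.passed
        assert "mature_overlaps_terminal_loop" in call.reasons

    def test_unstructured_fails_with_no_stem(self):
        fold = FoldResult("A" * 30, (), "." * 30)
        assert classify_hairpin(fold, (1, 22), DEFAULT_PRESET).reasons == ("no_stem",)

    def test_shuffled_precursors_rejected(self):
        """Dinucleotide-shuffled precursors lose the planted duplex and are
        rejected under the default preset in >= 95% of shuffles."""
        fold, mature, seq = planted_fold(102)
        rng = np.random.default_rng(7)
        rejected = 0
        for _ in range(100):
            shuffled = dinucleotide_shuffle(seq, rng)
            call = classify_hairpin(fold_nussinov(shuffled), mature, DEFAULT_PRESET)
            rejected += not call.passed
        assert rejected >= 95

    def test_mature_outside_precursor_rejected(self):
        fold, _, _ = planted_fold(103)
        with pytest.raises(ValueError):
            classify_hairpin(fold, (0, 22), DEFAULT_PRESET)


class TestBuildStacks:
    @staticmethod
    def _placed(triples):
        return [
            (Placement("A" * length, "c1", start, "+"), count)
            for start, length, count in triples
        ]

    def test_nearby_tags_one_stack(self):
        stacks = build_stacks(self._placed([(100, 22, 5), (125, 22, 5)]), max_gap=10)
        assert len(stacks) == 1
        assert stacks[0].interval == (100, 146)
        assert stacks[0].total_count == 10

    def test_distant_tags_two_stacks(self):
        stacks = build_stacks(self._placed([(100, 22, 5), (300, 22, 5)]))
        assert len(stacks) == 2

    def test_min_reads_filter(self):
        assert build_stacks(self._placed([(100, 22, 4)]), min_reads=5) == []

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        triples = [
            (int(rng.integers(1, 2_000)), int(rng.integers(18, 25)), 1)
            for _ in range(int(rng.integers(2, 60)))
        ]
        max_gap = int(rng.integers(0, 30))
        placed = self._placed(triples)
        stacks = build_stacks(placed, max_gap=max_gap, min_reads=1)
        # oracle: brute-force transitive closure of the "within gap" relation
        intervals = [(p.start, p.end) for p, _ in placed]
        n = len(intervals)
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for j in range(i + 1, n):
                (s1, e1), (s2, e2) = intervals[i], intervals[j]
                gap = max(s1, s2) - min(e1, e2) - 1
                if gap <= max_gap:
                    parent[find(i)] = find(j)
        n_components = len({find(i) for i in range(n)})
        assert len(stacks) == n_components
        assert sum(len(s.tags) for s in stacks) == n


@pytest.fixture(scope="session")
def detected(world, refset, annotated_by_condition):
    placed = []
    for cond in world.conditions:
        placed += unannotated_placements(annotated_by_condition[cond][0])
    stacks = build_stacks(placed)
    genome = {world.genome.chrom_name: world.genome.sequence}
    return stacks, consensus_detect(stacks, genome)


class TestConsensusAndAgo:
    def test_planted_novel_recall(self, world, detected):
        _, candidates = detected
        found = 0
        for p in world.novel:
            found += any(
                c.consensus and abs(c.mature_interval[0] - p.mature_interval[0]) < 5
                for c in candidates
            )
        assert found >= 9

    def test_star_scan_locates_planted_star(self, world):
        p = world.novel[0]
        ms, me = p.mature_interval
        ws, we = ms - 70, me + 70
        wseq = world.genome.sequence[ws - 1 : we]
        spans = star_scan(wseq, (ms - ws + 1, me - ws + 1))
        ps, pe = p.precursor_interval
        best = spans[0]
        assert ws + best[0] - 1 >= ps - 2 and ws + best[1] - 1 <= pe + 2

    def test_consensus_monotone_in_quorum(self, world, detected):
        stacks, _ = detected
        genome = {world.genome.chrom_name: world.genome.sequence}
        by_quorum = {
            q: {c.candidate_id for c in consensus_detect(stacks, genome, quorum=q) if c.consensus}
            for q in (1, 2, 3)
        }
        assert by_quorum[3] <= by_quorum[2] <= by_quorum[1]

    def test_quorum_and_preset_validation(self, world, detected):
        stacks, _ = detected
        genome = {world.genome.chrom_name: world.genome.sequence}
        with pytest.raises(ValueError):
            consensus_detect(stacks, genome, quorum=4)
        with pytest.raises(ValueError):
            consensus_detect(stacks, genome, presets=(DEFAULT_PRESET, DEFAULT_PRESET))

    def test_decoy_control_yields_no_consensus(self, decoy_world):
        from mirnome.mapping import ReferenceSet

        w = decoy_world
        refset = ReferenceSet(
            {w.genome.chrom_name: w.genome.sequence}, w.mrna_seqs, w.known_annotations()
        )
        placed = []
        for cond in w.conditions:
            tags, _ = process_reads(w.libraries[cond])
            placed += unannotated_placements(refset.annotate_library(tags))
        stacks = build_stacks(placed)
        candidates = consensus_detect(stacks, {w.genome.chrom_name: w.genome.sequence})
        assert stacks, "decoy loci must still produce read stacks"
        assert sum(c.consensus for c in candidates) == 0

    def test_ago_verification_recovers_supported_set(self, world, refset, detected):
        _, candidates = detected
        ago_libs = []
        for reads in world.ago_libraries:
            tags, _ = process_reads(reads)
            ago_libs.append(refset.annotate_library(tags))
        verified = verify_agoip(candidates, ago_libs, min_reads=5, min_datasets=1)
        truth_by_pos = {p.mature_interval[0]: p.mirna_id for p in world.novel}
        got = {
            truth_by_pos[c.mature_interval[0]]
            for c in verified
            if c.ago_verified and c.mature_interval[0] in truth_by_pos
        }
        assert got == set(world.ago_supported)
        # every supported candidate has full depth in every dataset
        for c in verified:
            if c.ago_verified:
                assert all(n >= 5 for n in c.ago_reads_per_dataset)

    def test_no_ago_libraries_all_unverified(self, detected):
        _, candidates = detected
        assert all(not c.ago_verified for c in verify_agoip(candidates, []))
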
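"""Engines: balance, permutation uniformity, seeding, reproducibility."""
from __future__ import annotations

import itertools
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from rrapp import (
    GenerationError,
    resolve_strata,
    RandomizationSpec,
    StrataSpec,
    derive_stratum_seed,
    draw_block,
    generate,
    generate_block,
    generate_permuted_block,
    generate_simple,
)
from conftest import ALL_TECHNIQUES, make_random_spec


class TestSimple:
    def test_zero_subjects_gives_empty_list(self):
        assert generate_simple(seed=1, n_arms=2, total_n=0) == []

    def test_length_and_code_range(self):
        codes = generate_simple(seed=5, n_arms=3, total_n=100)
        assert len(codes) == 100
        assert set(codes) <= {1, 2, 3}

    def test_same_seed_same_sequence(self):
        a = generate_simple(seed=11, n_arms=2, total_n=50)
        b = generate_simple(seed=11, n_arms=2, total_n=50)
        assert a == b

    def test_equal_ratio_is_a_fair_coin(self):
        # one fixed seed: arm counts must be consistent with Binomial(n, 1/2)
        codes = generate_simple(seed=202610, n_arms=2, total_n=4000)
        counts = [codes.count(1), codes.count(2)]
        p = stats.chisquare(counts).pvalue
        assert p > 1e-3

    def test_two_to_one_ratio(self):
        codes = generate_simple(seed=7, n_arms=2, total_n=6000, allocation_ratio=[2, 1])
        freq = codes.count(1) / len(codes)
        assert abs(freq - 2 / 3) < 0.03


class TestDrawBlock:
    @pytest.mark.parametrize(("n_arms", "block_size"), [(2, 2), (2, 4), (3, 6), (4, 8)])
    def test_each_arm_fills_exactly_its_share(self, n_arms, block_size):
        rng = np.random.default_rng(3)
        for _ in range(20):
            block = draw_block(n_arms, block_size, rng)
            assert Counter(block) == {a: block_size // n_arms for a in range(1, n_arms + 1)}

    def test_two_slot_block_is_ab_or_ba(self):
        rng = np.random.default_rng(4)
        seen = {tuple(draw_block(2, 2, rng)) for _ in range(50)}
        assert seen == {(1, 2), (2, 1)}

    def test_non_multiple_size_rejected(self):
        with pytest.raises(GenerationError) as exc:
            draw_block(2, 5, np.random.default_rng(0))
        assert exc.value.code == "BLOCK_SIZE_NOT_MULTIPLE"

    def test_uniform_over_balanced_orderings(self):
        # oracle: brute-force enumeration of the distinct orderings of AABB
        support = sorted(set(itertools.permutations([1, 1, 2, 2])))
        assert len(support) == 6
        rng = np.random.default_rng(99)
        counts = Counter(tuple(draw_block(2, 4, rng)) for _ in range(12_000))
        assert set(counts) == set(support)
        p = stats.chisquare([counts[s] for s in support]).pvalue
        assert p > 1e-3


class TestGenerateBlock:
    def test_twelve_subjects_three_blocks_six_per_arm(self):
        out = generate_block(seed=42, n_arms=2, total_n=12, block_size=4)
        assert len(out) == 12
        assert {a.block_index for a in out} == {1, 2, 3}
        for b in (1, 2, 3):
            block = [a.arm_code for a in out if a.block_index == b]
            assert Counter(block) == {1: 2, 2: 2}
        assert Counter(a.arm_code for a in out) == {1: 6, 2: 6}
        assert [a.sequence for a in out] == list(range(1, 13))

    def test_single_block_when_n_equals_block_size(self):
        out = generate_block(seed=0, n_arms=2, total_n=4, block_size=4)
        assert {a.block_index for a in out} == {1}

    def test_strict_mode_requires_divisibility(self):
        with pytest.raises(GenerationError) as exc:
            generate_block(seed=1, n_arms=2, total_n=10, block_size=4)
        assert exc.value.code == "N_NOT_MULTIPLE_OF_BLOCK"

    def test_truncation_cuts_final_block(self):
        out = generate_block(seed=1, n_arms=2, total_n=10, block_size=4, allow_truncation=True)
        assert len(out) == 10
        last = [a for a in out if a.block_index == 3]
        assert len(last) == 2 and all(a.block_size_used == 4 for a in last)

    def test_balanced_at_every_block_boundary(self, rng):
        for _ in range(200):
            n_arms = int(rng.integers(2, 5))
            b = n_arms * int(rng.integers(1, 4))
            total = b * int(rng.integers(1, 6))
            out = generate_block(int(rng.integers(0, 10**6)), n_arms, total, b)
            counts = Counter()
            for a in out:
                counts[a.arm_code] += 1
                if a.sequence % b == 0:  # boundary
                    assert len(set(counts.values())) == 1


class TestGeneratePermutedBlock:
    def test_default_candidates_for_two_arms_are_four_and_six(self):
        out = generate_permuted_block(seed=3, n_arms=2, total_n=20)
        assert {a.block_size_used for a in out} <= {4, 6}

    def test_ten_subjects_only_four_six_or_six_four(self, rng):
        seqs = Counter()
        for _ in range(500):
            out = generate_permuted_block(int(rng.integers(0, 10**6)), 2, 10)
            sizes = []
            for a in out:
                if a.block_index > len(sizes):
                    sizes.append(a.block_size_used)
            seqs[tuple(sizes)] += 1
        assert set(seqs) == {(4, 6), (6, 4)}
        assert 0.4 < seqs[(4, 6)] / 500 < 0.6

    def test_single_candidate_reduces_to_fixed_block(self):
        fixed = generate_block(seed=17, n_arms=3, total_n=18, block_size=6)
        permuted = generate_permuted_block(seed=17, n_arms=3, total_n=18, block_size_candidates=[6])
        assert permuted == fixed

    def test_unreachable_total_rejected_in_strict_mode(self):
        with pytest.raises(GenerationError) as exc:
            generate_permuted_block(seed=1, n_arms=2, total_n=5, block_size_candidates=[4, 6])
        assert exc.value.code == "TOTAL_UNREACHABLE_BY_CANDIDATES"

    def test_truncation_mode_cuts_last_block(self):
        out = generate_permuted_block(
            seed=1, n_arms=2, total_n=5, block_size_candidates=[4], allow_truncation=True
        )
        assert len(out) == 5
        assert [a.block_size_used for a in out] == [4] * 5
        assert sum(1 for a in out if a.block_index == 2) == 1

    def test_every_completed_block_is_balanced(self, rng):
        for _ in range(100):
            n_arms = int(rng.integers(2, 4))
            cands = [2 * n_arms, 3 * n_arms]
            total = int(sum(rng.choice(cands) for _ in range(int(rng.integers(1, 5)))))
            out = generate_permuted_block(int(rng.integers(0, 10**6)), n_arms, total, cands)
            by_block: dict[int, list] = {}
            for a in out:
                by_block.setdefault(a.block_index, []).append(a)
            for block in by_block.values():
                size = block[0].block_size_used
                assert len(block) == size  # strict mode: no truncation
                assert Counter(a.arm_code for a in block) == {
                    arm: size // n_arms for arm in range(1, n_arms + 1)
                }


class TestStratumSeeds:
    def test_deterministic(self):
        assert derive_stratum_seed(123, 7) == derive_stratum_seed(123, 7)

    def test_injective_over_ten_thousand_indices(self):
        seeds = {derive_stratum_seed(42, i) for i in range(10_000)}
        assert len(seeds) == 10_000

    def test_distinct_masters_never_collide(self):
        seen = set()
        for master in range(100):
            for i in range(10):
                seen.add(derive_stratum_seed(master, i))
        assert len(seen) == 1000

    def test_changing_master_changes_every_sub_seed(self):
        a = [derive_stratum_seed(1, i) for i in range(100)]
        b = [derive_stratum_seed(2, i) for i in range(100)]
        assert all(x != y for x, y in zip(a, b))

    @pytest.mark.parametrize("index", [-1, 10_000])
    def test_index_out_of_range(self, index):
        with pytest.raises(GenerationError):
            derive_stratum_seed(1, index)


class TestStratified:
    def _spec_2x2_block(self, per_n=(8, 8, 8, 8), seed=5):
        return RandomizationSpec(
            technique="stratified_block", seed=seed, n_arms=2, block_size=4,
            strata=StrataSpec(
                factors=[("sex", ["male", "female"]), ("race", ["white", "nonwhite"])],
                per_stratum_n=list(per_n),
            ),
        )

    def test_four_strata_of_eight_give_32_balanced_assignments(self):
        scheme = generate(self._spec_2x2_block())
        assert len(scheme.assignments) == 32
        for label in ("male|white", "male|nonwhite", "female|white", "female|nonwhite"):
            sub = [a for a in scheme.assignments if a.stratum_label == label]
            assert len(sub) == 8
            assert Counter(a.arm_code for a in sub) == {1: 4, 2: 4}
            assert [a.sequence for a in sub] == list(range(1, 9))

    def test_single_stratum_equals_base_engine_under_sub_seed(self):
        spec = RandomizationSpec(
            technique="stratified_block", seed=9, n_arms=2, block_size=4,
            strata=StrataSpec(count=1, per_stratum_n=[8]),
        )
        scheme = generate(spec)
        base = generate_block(
            derive_stratum_seed(9, 0), 2, 8, 4, stratum_label="Stratum_1"
        )
        assert scheme.assignments == base

    def test_stratified_simple_gives_independent_lists_per_subgroup(self):
        spec = RandomizationSpec(
            technique="stratified", seed=21, n_arms=2,
            strata=StrataSpec(
                factors=[("sex", ["male", "female"]), ("race", ["white", "nonwhite"])],
                per_stratum_n=[10, 10, 10, 10],
            ),
        )
        scheme = generate(spec)
        by_label = {}
        for a in scheme.assignments:
            by_label.setdefault(a.stratum_label, []).append(a.arm_code)
        assert len(by_label) == 4
        for label, codes in by_label.items():
            idx = [s.label for s in resolve_strata(spec)].index(label)
            expected = generate_simple(derive_stratum_seed(21, idx), 2, 10)
            assert codes == expected

    def test_editing_one_stratum_leaves_others_bit_identical(self, rng):
        for _ in range(30):
            spec = make_random_spec(
                rng, technique=str(rng.choice(
                    ["stratified", "stratified_block", "stratified_permuted_block"]))
            )
            st_spec = spec.strata
            sizes = st_spec.resolve_per_stratum_n(st_spec.n_strata())
            if len(sizes) < 2:
                continue
            before = generate(spec)
            j = int(rng.integers(0, len(sizes)))
            bumped = list(sizes)
            # grow stratum j by one full allocation unit so the spec stays valid
            if spec.technique.value == "stratified_block":
                bumped[j] += spec.block_size
            elif spec.technique.value == "stratified_permuted_block":
                bumped[j] += spec.resolved_candidates()[0]
            else:
                bumped[j] += 1
            after = generate(
                spec.model_copy(update={"strata": st_spec.model_copy(
                    update={"per_stratum_n": bumped, "total_n": None})})
            )
            labels = [s.label for s in resolve_strata(spec)]
            for i, label in enumerate(labels):
                if i == j:
                    continue
                sub_before = [a for a in before.assignments if a.stratum_label == label]
                sub_after = [a for a in after.assignments if a.stratum_label == label]
                assert sub_before == sub_after


class TestReproducibility:
    @pytest.mark.parametrize("technique", ALL_TECHNIQUES)
    def test_same_spec_same_scheme(self, technique, rng):
        for _ in range(5):
            spec = make_random_spec(rng, technique=technique)
            a = generate(spec)
            b = generate(spec)
            assert a.assignments == b.assignments
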
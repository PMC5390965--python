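"""Canonicalization, string-space moments, normalization, and entropy."""

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rigc.scoring import (
    canonical_form,
    falling_factorial,
    first_order_entropy,
    mean_complexity,
    response_complexity,
    restricted_growth_strings,
    score_response,
    string_space_moments,
)
from rigc.tasks import TASKS, TaskSpec


class TestCanonicalForm:
    def test_relabels_by_first_occurrence(self):
        assert canonical_form("221212", 3) == "001010"

    def test_idempotent_on_canonical_input(self):
        assert canonical_form("001010", 3) == "001010"

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 5), min_size=1, max_size=15))
    def test_idempotence_property(self, seq):
        once = canonical_form(seq, 6)
        assert canonical_form(once, 6) == once

    def test_out_of_range_symbol_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            canonical_form("017", 6)

    def test_binary_length3_has_four_classes(self):
        classes = {canonical_form("".join(s), 2) for s in product("01", repeat=3)}
        assert len(classes) == 4


class TestClassEnumeration:
    @pytest.mark.parametrize("k,length", [(2, 3), (2, 12), (3, 5), (6, 4), (9, 3)])
    def test_class_weights_cover_the_full_space(self, k, length):
        total = sum(
            falling_factorial(k, d)
            for _, d in restricted_growth_strings(length, min(k, length))
        )
        assert total == k**length

    def test_class_count_equals_set_partition_count(self):
        """#canonical die strings of length 10 = set partitions of 10 items
        into at most 6 blocks (computed by an independent Stirling DP)."""
        # DP oracle: S(n, j) = S(n-1, j-1) + j * S(n-1, j)
        S = np.zeros((11, 11), dtype=object)
        S[0, 0] = 1
        for n in range(1, 11):
            for j in range(1, n + 1):
                S[n, j] = S[n - 1, j - 1] + j * S[n - 1, j]
        expected = sum(S[10, j] for j in range(1, 7))
        observed = sum(1 for _ in restricted_growth_strings(10, 6))
        assert observed == expected


class TestMoments:
    @pytest.mark.parametrize(
        "alphabet,length,table_ref,block",
        [(2, 3, "bin1d", 3), (2, 12, "bin1d", 3), (3, 6, "sym5", 3)],
    )
    def test_weighted_moments_equal_direct_enumeration(
        self, task_tables, alphabet, length, table_ref, block
    ):
        """Class-weighted moments must equal brute force over every string
        wherever the full space is small enough to enumerate."""
        table = next(tb for tid, tb in task_tables.items() if TASKS[tid].table_ref == table_ref)
        spec = TaskSpec("probe", alphabet, length, 1, table_ref, block)
        mu, sigma = string_space_moments(spec, table)
        ks = [
            response_complexity("".join(map(str, s)), spec, table)[0]
            for s in product(range(alphabet), repeat=length)
        ]
        assert mu == pytest.approx(np.mean(ks), abs=1e-9)
        assert sigma == pytest.approx(np.std(ks), abs=1e-9)

    def test_degenerate_table_rejected(self, bin1d):
        import copy

        flat = copy.deepcopy(bin1d)
        flat.complexity = {k: 5.0 for k in flat.complexity}
        flat.fallback_value = 5.0
        flat.moments_cache = {}
        spec = TaskSpec("probe", 2, 3, 1, "bin1d", 3)
        with pytest.raises(ValueError, match="degenerate"):
            string_space_moments(spec, flat)


class TestNormalization:
    @pytest.mark.parametrize("task_id", list(TASKS))
    def test_full_space_z_has_mean_zero_sd_one(self, task_tables, task_id):
        """The defining identity of the normalized score: over ALL possible
        strings of the task, weighted mean(z) = 0 and SD(z) = 1."""
        spec = TASKS[task_id]
        table = task_tables[task_id]
        tot = s1 = s2 = 0.0
        for canon, d in restricted_growth_strings(
            spec.length, min(spec.alphabet_size, spec.length)
        ):
            w = falling_factorial(spec.alphabet_size, d)
            z = score_response("".join(map(str, canon)), spec, table).z
            tot += w
            s1 += w * z
            s2 += w * z * z
        assert s1 / tot == pytest.approx(0.0, abs=1e-9)
        assert math.sqrt(s2 / tot - (s1 / tot) ** 2) == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 6), min_size=10, max_size=10))
    def test_permutation_invariant_z(self, task_tables, symbols):
        """Relabeling die faces must not change the normalized score."""
        spec = TASKS["die"]
        table = task_tables["die"]
        s = "".join(str(v - 1) for v in symbols)
        perm = {d: (d + 3) % 6 for d in range(6)}
        t = "".join(str(perm[int(c)]) for c in s)
        assert score_response(s, spec, table).z == score_response(t, spec, table).z

    def test_score_response_is_pure(self, task_tables):
        spec = TASKS["coin"]
        a = score_response("010011010110", spec, task_tables["coin"])
        b = score_response("010011010110", spec, task_tables["coin"])
        assert a == b

    def test_wrong_length_rejected(self, task_tables):
        with pytest.raises(ValueError, match="length"):
            score_response("0101", TASKS["coin"], task_tables["coin"])

    def test_empty_response_rejected(self, task_tables):
        with pytest.raises(ValueError, match="empty"):
            score_response("", TASKS["coin"], task_tables["coin"])


class TestMeanComplexity:
    def test_plain_average(self):
        assert mean_complexity([0.5] * 5) == (0.5, 5)

    def test_missing_tasks_are_skipped(self):
        val, n = mean_complexity([1.0, -1.0, 0.0, 0.0, float("nan")])
        assert val == pytest.approx(0.0) and n == 4

    def test_all_missing_gives_nan_not_error(self):
        val, n = mean_complexity([float("nan")] * 5)
        assert math.isnan(val) and n == 0


class TestEntropy:
    def test_constant_sequence(self):
        assert first_order_entropy("000000000000", 2) == 0.0

    def test_alternating_sequence_is_maximal(self):
        assert first_order_entropy("010101010101", 2) == pytest.approx(1.0)

    def test_hand_computed_die_sequence(self):
        # counts (2,2,2,2,1,1) over 10 symbols
        expected = -(4 * 0.2 * math.log2(0.2) + 2 * 0.1 * math.log2(0.1))
        assert first_order_entropy("0123450123", 6) == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy(self, rng):
        from scipy.stats import entropy as scipy_entropy

        seq = rng.integers(0, 6, size=50)
        counts = np.bincount(seq, minlength=6)
        assert first_order_entropy(list(seq), 6) == pytest.approx(
            scipy_entropy(counts, base=2), abs=1e-12
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            first_order_entropy("", 2)

    def test_alternation_fools_entropy_but_not_complexity(self, task_tables):
        """0101... attains maximal first-order entropy yet scores below the
        weighted-median normalized complexity — the divergence that
        motivates an algorithmic (not purely statistical) measure."""
        spec = TASKS["coin"]
        table = task_tables["coin"]
        alt = "01" * 6
        assert first_order_entropy(alt, 2) == pytest.approx(1.0)
        z_alt = score_response(alt, spec, table).z
        pairs = []
        for canon, d in restricted_growth_strings(12, 2):
            w = falling_factorial(2, d)
            pairs.append((score_response("".join(map(str, canon)), spec, table).z, w))
        pairs.sort()
        cum, half = 0, sum(w for _, w in pairs) / 2
        for z, w in pairs:
            cum += w
            if cum >= half:
                weighted_median = z
                break
        assert z_alt < weighted_median
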
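import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radhap.genotype import (
    AlignedRead,
    HaploidCall,
    LocusKey,
    LocusStack,
    call_leading_haplotype,
    compute_expected_depth,
    filter_excess_depth,
    genotype_individual,
    intersect_shared_loci,
    stack_reads,
)

KEY = LocusKey("chrI", 100, "+")


def _hap(tag: str) -> str:
    return "TGCAGG" + tag * 32  # 70-bp haplotype from a 2-char tag


def _stack(counts: dict[str, int], key: LocusKey = KEY, ind: str = "A") -> LocusStack:
    return LocusStack(key, ind, counts)


def brute_force_call(seq_counts: dict[str, int], min_copies: int) -> tuple[str | None, str]:
    """Independent argmax-with-threshold rule by full enumeration."""
    best, status = None, None
    top = max(seq_counts.values())
    winners = sorted(s for s, c in seq_counts.items() if c == top)
    if len(winners) > 1:
        return None, "tie"
    if top < min_copies:
        return None, "insufficient_copies"
    return winners[0], "called"


class TestStackReads:
    def _read(self, rid, bases, chrom="chrI", pos=100, strand="+"):
        return AlignedRead(rid, "A", chrom, pos, strand, bases)

    def test_counts_identical_sequences(self):
        s1, s2 = _hap("AC"), _hap("GT")
        reads = [self._read(f"r{i}", s1) for i in range(3)]
        reads += [self._read(f"q{i}", s2) for i in range(2)]
        stacks = stack_reads(reads, "A")
        assert len(stacks) == 1
        assert stacks[0].seq_counts == {s1: 3, s2: 2}
        assert stacks[0].depth == 5

    def test_strands_are_distinct_loci(self):
        reads = [self._read("r1", _hap("AC"), strand="+"),
                 self._read("r2", _hap("AC"), strand="-")]
        assert len(stack_reads(reads, "A")) == 2

    def test_empty_input(self):
        assert stack_reads([], "A") == []

    def test_wrong_length_rejected_with_read_id(self):
        with pytest.raises(ValueError, match="r9"):
            stack_reads([self._read("r9", "ACGT")], "A")

    def test_depth_conservation(self, rng):
        reads = [
            self._read(f"r{i}", _hap("AC"), pos=int(rng.integers(1, 5)) * 100)
            for i in range(50)
        ]
        stacks = stack_reads(reads, "A")
        assert sum(s.depth for s in stacks) == 50


class TestLeadingHaplotype:
    def test_unique_leader_called(self):
        call = call_leading_haplotype(_stack({_hap("AA"): 5, _hap("CC"): 2}), min_copies=2)
        assert call.status == "called"
        assert call.haplotype == _hap("AA")
        assert call.support == 5

    def test_singleton_below_min_copies(self):
        call = call_leading_haplotype(_stack({_hap("AA"): 1}), min_copies=2)
        assert call.status == "insufficient_copies" and call.haplotype is None

    def test_tie_excludes_locus(self):
        call = call_leading_haplotype(_stack({_hap("AA"): 3, _hap("CC"): 3}))
        assert call.status == "tie"

    def test_stringent_mode_raises_threshold(self):
        call = call_leading_haplotype(_stack({_hap("AA"): 4}), min_copies=5)
        assert call.status == "insufficient_copies"

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            call_leading_haplotype(_stack({}))

    @given(
        counts=st.lists(st.integers(1, 8), min_size=1, max_size=6),
        min_copies=st.sampled_from([1, 2, 5]),
    )
    @settings(max_examples=200, derandomize=True)
    def test_agrees_with_brute_force_enumeration(self, counts, min_copies):
        seq_counts = {_hap(f"{chr(65 + i)}{chr(65 + i)}"): c for i, c in enumerate(counts)}
        call = call_leading_haplotype(_stack(seq_counts), min_copies)
        hap, status = brute_force_call(seq_counts, min_copies)
        assert call.status == status
        if status == "called":
            assert call.haplotype == hap
            assert call.support == max(seq_counts.values())

    def test_monotonicity_stringent_subset_of_lenient(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 5))
            seq_counts = {_hap(f"{chr(65 + i)}{chr(65 + i)}"): int(rng.integers(1, 10))
                          for i in range(n)}
            lenient = call_leading_haplotype(_stack(seq_counts), 2)
            stringent = call_leading_haplotype(_stack(seq_counts), 5)
            if stringent.status == "called":
                assert lenient.status == "called"
                assert lenient.haplotype == stringent.haplotype


class TestExpectedDepth:
    def test_arithmetic(self):
        assert compute_expected_depth(1000, 100) == 10.0
        assert compute_expected_depth(0, 5) == 0.0
        assert compute_expected_depth(7, 2) == 3.5

    def test_zero_loci_is_an_error(self):
        with pytest.raises(ValueError, match="no loci"):
            compute_expected_depth(10, 0)


class TestExcessDepthFilter:
    def _call(self, depth, key=KEY):
        return HaploidCall("A", key, _hap("AA"), depth, "called", depth)

    def test_strictly_beyond_cutoff_excluded(self):
        out = filter_excess_depth([self._call(46)], expected_depth=10, factor=4.5)
        assert out[0].status == "excess_depth" and out[0].haplotype is None

    def test_exactly_at_cutoff_retained(self):
        out = filter_excess_depth([self._call(45)], expected_depth=10, factor=4.5)
        assert out[0].status == "called"

    def test_low_depth_untouched(self):
        call = HaploidCall("A", KEY, None, 1, "insufficient_copies", 1)
        out = filter_excess_depth([call], expected_depth=10)
        assert out[0].status == "insufficient_copies"

    def test_lower_factor_never_retains_more(self, rng):
        calls = [self._call(int(d), LocusKey("chrI", 100 + 10 * i, "+"))
                 for i, d in enumerate(rng.integers(1, 100, size=40))]
        kept = [
            sum(c.status == "called"
                for c in filter_excess_depth(calls, 10.0, factor=f))
            for f in (6.0, 4.5, 3.0, 1.0)
        ]
        assert kept == sorted(kept, reverse=True)


class TestGenotypeIndividual:
    def test_expected_depth_uses_all_stacks_before_exclusion(self):
        # 9 loci at depth 5 + 1 at depth 55: expected = 100/10 = 10, cutoff 45
        stacks = [_stack({_hap("AA"): 5}, LocusKey("chrI", 100 + i, "+")) for i in range(9)]
        stacks.append(_stack({_hap("CC"): 55}, LocusKey("chrI", 500, "+")))
        calls, summary = genotype_individual(stacks)
        assert summary["expected_depth"] == 10.0
        assert summary["loci_excess_depth"] == 1
        assert summary["loci_called"] == 9

    def test_status_counts_partition_stacked_loci(self, rng):
        stacks = []
        for i in range(30):
            n = int(rng.integers(1, 4))
            stacks.append(_stack(
                {_hap(f"{chr(65 + j)}{chr(65 + j)}"): int(rng.integers(1, 30))
                 for j in range(n)},
                LocusKey("chrI", 100 * (i + 1), "+"),
            ))
        _, s = genotype_individual(stacks)
        total = (s["loci_called"] + s["loci_tie"] + s["loci_insufficient_copies"]
                 + s["loci_excess_depth"])
        assert total == s["loci_stacked"] == 30


class TestIntersectSharedLoci:
    def _calls(self, ind, keys, status="called"):
        return [
            HaploidCall(ind, k, _hap("AA") if status == "called" else None,
                        5, status, 5)
            for k in keys
        ]

    def test_intersection_of_called_loci(self):
        a = LocusKey("chrI", 100, "+")
        b = LocusKey("chrI", 200, "+")
        c = LocusKey("chrI", 300, "+")
        table = intersect_shared_loci({
            "i1": self._calls("i1", [a, b, c]),
            "i2": self._calls("i2", [a, c]),
            "i3": self._calls("i3", [a, b, c]),
        })
        assert table.loci == [a, c]
        assert table.individuals == ["i1", "i2", "i3"]

    def test_empty_intersection_names_culprit(self):
        a = LocusKey("chrI", 100, "+")
        with pytest.raises(ValueError, match="i2"):
            intersect_shared_loci({
                "i1": self._calls("i1", [a]),
                "i2": self._calls("i2", [a], status="tie"),
            })

    def test_complete_table_has_no_missing_cells(self):
        keys = [LocusKey("chrI", 100 * i, "+") for i in range(1, 5)]
        table = intersect_shared_loci({
            "i1": self._calls("i1", keys),
            "i2": self._calls("i2", keys),
        })
        for ind in table.individuals:
            for key in table.loci:
                assert len(table.haplotype(ind, key)) == 70

    def test_requires_two_individuals(self):
        with pytest.raises(ValueError):
            intersect_shared_loci({"i1": self._calls("i1", [KEY])})

    def test_locus_order_is_total_ordering(self):
        keys = [LocusKey("chrII", 50, "+"), LocusKey("chrI", 200, "-"),
                LocusKey("chrI", 200, "+"), LocusKey("chrI", 100, "+")]
        table = intersect_shared_loci({
            "i1": self._calls("i1", keys), "i2": self._calls("i2", keys)
        })
        assert table.loci == sorted(keys)
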
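"""Adapter trimming, filtering, collapsing and the library bookkeeping."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from droughtmir.preprocess import (CleanReadSet, collapse, expand,
                                   filter_clean, library_stats,
                                   size_distribution, stats_table,
                                   trim_adapter)

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"
SEQ = st.text(alphabet="ACGT", min_size=16, max_size=30)


class TestTrimAdapter:
    def test_full_adapter_removed(self):
        assert trim_adapter("ACGTACGT" + ADAPTER, ADAPTER) == "ACGTACGT"

    def test_short_read_without_adapter_passes_through(self):
        read = "A" * 24
        assert trim_adapter(read, ADAPTER) == read

    def test_adapter_only_read_yields_no_insert(self):
        assert trim_adapter(ADAPTER, ADAPTER) is None

    def test_long_read_without_adapter_is_dropped(self):
        assert trim_adapter("ACGT" * 10, ADAPTER) is None

    def test_partial_adapter_at_three_prime_end(self):
        insert = "ACGTACGTACGTACGTACGTACGT"
        assert trim_adapter(insert + ADAPTER[:8], ADAPTER) == insert

    def test_overlap_below_minimum_not_trimmed(self):
        insert = "ACGCACGCACGCACGCACGC"
        read = insert + ADAPTER[:4]
        assert trim_adapter(read, ADAPTER) == read

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError):
            trim_adapter("ACGT1234", ADAPTER)
        with pytest.raises(ValueError):
            trim_adapter("ACGT", "")

    @given(SEQ)
    @settings(max_examples=200, deadline=None)
    def test_idempotent_on_adapter_free_inserts(self, insert):
        trimmed = trim_adapter(insert + ADAPTER, ADAPTER)
        if trimmed is not None and not any(
                trimmed.endswith(ADAPTER[:k]) for k in range(6, len(trimmed) + 1)):
            assert trim_adapter(trimmed, ADAPTER) == trimmed


class TestFilterClean:
    @pytest.mark.parametrize("length,kept", [(15, False), (16, True),
                                             (30, True), (31, False)])
    def test_length_boundaries(self, length, kept):
        out = filter_clean([("A" * length, "I" * length)], "L")
        assert (out.retained == 1) is kept
        if not kept:
            assert out.length_dropped == 1

    def test_high_quality_insert_kept(self):
        out = filter_clean([("ACGT" * 6, "I" * 24)], "L")
        assert out.reads == ["ACGT" * 6]

    def test_n_and_low_quality_dropped(self):
        reads = [("ACGTNACGTACGTACGTACGT", "I" * 21),
                 ("ACGTACGTACGTACGTACGTACGT", "#" * 24),
                 (None, None)]
        out = filter_clean(reads, "L")
        assert out.quality_dropped == 2
        assert out.adapter_dropped == 1
        assert out.check_conservation()

    def test_every_read_counted_once(self):
        inserts = [("A" * 20, "I" * 20), (None, None), ("C" * 40, "I" * 40),
                   ("G" * 24, "#" * 24)]
        out = filter_clean(inserts, "L")
        assert out.total_raw == 4
        assert out.check_conservation()


class TestCollapse:
    def test_basic_counts(self):
        cs = CleanReadSet("L1", reads=["A" * 24, "A" * 24, "C" * 24])
        tags = collapse([cs])
        assert tags.loc["A" * 24, "L1"] == 2
        assert tags.loc["C" * 24, "L1"] == 1

    def test_empty_library_zero_column(self):
        c1 = CleanReadSet("L1", reads=["A" * 20])
        c2 = CleanReadSet("L2", reads=[])
        tags = collapse([c1, c2])
        assert (tags["L2"] == 0).all()

    def test_round_trip_identity(self):
        reads = {"L1": sorted(["ACGT" * 5, "ACGT" * 5, "TTTT" * 5]),
                 "L2": sorted(["ACGT" * 5])}
        sets = [CleanReadSet(lib, reads=list(r)) for lib, r in reads.items()]
        recovered = expand(collapse(sets))
        assert {k: sorted(v) for k, v in recovered.items()} == reads

    def test_fixture_conservation(self, small_clean_sets, small_tags):
        for cs in small_clean_sets:
            assert small_tags[cs.library].sum() == cs.retained
            assert cs.check_conservation()


class TestSizeDistribution:
    def test_single_tag(self):
        cs = CleanReadSet("L1", reads=["A" * 24] * 5)
        hist = size_distribution(collapse([cs]))
        assert hist.loc[24, "unique_tags"] == 1
        assert hist.loc[24, "total_reads"] == 5
        assert hist.drop(24).sum().sum() == 0

    def test_empty_input_all_zero(self):
        hist = size_distribution(collapse([CleanReadSet("L1")]))
        assert (hist == 0).all().all()

    def test_sums_match_totals(self, small_tags):
        hist = size_distribution(small_tags)
        assert hist["unique_tags"].sum() == len(small_tags)
        assert hist["total_reads"].sum() == small_tags.sum().sum()


class TestLibraryStats:
    @pytest.mark.parametrize("raw,clean,unique,clean_pct,unique_pct", [
        (20653733, 12005904, 650391, 58.13, 3.15),
        (19546412, 10544528, 1046638, 53.95, 5.35),
        (100, 100, 100, 100.00, 100.00),
    ])
    def test_percentages(self, raw, clean, unique, clean_pct, unique_pct):
        stats = library_stats(raw, clean, unique)
        assert stats["clean_pct"] == clean_pct
        assert stats["unique_pct"] == unique_pct

    def test_zero_raw_errors(self):
        with pytest.raises(ValueError):
            library_stats(0, 0, 0)

    def test_stats_table_layout(self, small_clean_sets, small_tags):
        table = stats_table(small_clean_sets, small_tags)
        assert list(table.index) == ["C1", "T1", "C2", "T2"]
        for row in table.itertuples():
            assert row.clean_pct == round(
                row.clean_total / row.total_raw * 100, 2)
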
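import numpy as np
import pytest

from conftest import random_kmer_table
from naive_reference import naive_crawl
from tdcrawl import (
    FormatError,
    KmerTable,
    TopDownCrawlAligner,
    crawl,
    overlap_candidates,
    single_bp_neighbors,
)


class TestSingleBpNeighbors:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AC", {"CC", "GC", "TC", "AA", "AG", "AT"}),
            ("A", {"C", "G", "T"}),
        ],
    )
    def test_small_cases(self, seq, expected):
        assert single_bp_neighbors(seq) == expected

    def test_count_and_hamming_distance(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            k = int(rng.integers(1, 9))
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=k))
            neighbors = single_bp_neighbors(seq)
            assert len(neighbors) == 3 * k
            for q in neighbors:
                assert sum(a != b for a, b in zip(seq, q)) == 1


class TestOverlapCandidates:
    def test_five_prime_extension_gets_minus_one(self):
        # AGTAAAC shares its last 6 bp with GTAAACA's first 6 bp
        assert overlap_candidates("GTAAACA", {"AGTAAAC"}) == [("AGTAAAC", -1)]

    def test_three_prime_extension_gets_plus_one(self):
        assert overlap_candidates("GTAAACA", {"TAAACAG"}) == [("TAAACAG", +1)]

    def test_two_bp_overlaps(self):
        assert overlap_candidates("GTAAACA", {"CCGTAAA"}) == [("CCGTAAA", -2)]
        assert overlap_candidates("GTAAACA", {"AAACAGG"}) == [("AAACAGG", +2)]

    def test_reference_never_its_own_candidate(self):
        assert overlap_candidates("AAAAAAA", {"AAAAAAA"}) == []

    def test_multi_offset_match_takes_smallest_shift(self):
        # AAAC matches both the k-1 overlap at +1 and the k-2 overlap at +2
        assert overlap_candidates("AAAA", {"AAAC"}) == [("AAAC", +1)]

    def test_k_below_three_fatal(self):
        with pytest.raises(FormatError, match="k=2"):
            overlap_candidates("AC", {"CA"})

    def test_precedence_order_in_output(self):
        ref = "ACGTACG"
        universe = {
            "CACGTAC",  # -1
            "CGTACGA",  # +1
            "GGACGTA",  # -2
            "GTACGAA",  # +2
        }
        cands = overlap_candidates(ref, universe)
        assert [c[1] for c in cands] == [-1, +1, -2, +2]


class TestCrawl:
    def test_worked_example(self, worked_table):
        alignment, trace = crawl(worked_table)
        assert alignment.shift_of == {"GTAAACA": 0, "AGTAAAC": -1}
        assert trace.references[0] == "GTAAACA"

    def test_single_kmer(self):
        table = KmerTable(("ACGTA",), np.array([1.0]))
        alignment, trace = crawl(table)
        assert alignment.shift_of == {"ACGTA": 0}
        assert len(trace) == 1

    def test_disconnected_kmer_stays_unaligned(self):
        table = KmerTable(("AAAA", "CCCC"), np.array([3.0, 2.0]))
        alignment, _ = crawl(table)
        assert alignment.shift_of == {"AAAA": 0}
        assert "CCCC" not in alignment.aligned

    def test_seed_is_max_metric_kmer(self):
        rng = np.random.default_rng(5)
        for trial in range(10):
            table = random_kmer_table(rng, k=4, n=60)
            alignment, _ = crawl(table)
            best = table.sequences[int(np.argmax(table.metrics))]
            assert alignment.shift_of[best] == 0

    def test_each_round_completes_exactly_one_reference(self):
        rng = np.random.default_rng(11)
        table = random_kmer_table(rng, k=4, n=120)
        alignment, trace = crawl(table)
        assert len(trace) == len(alignment.shift_of)
        assert alignment.completed == alignment.aligned
        assert sum(n for _, n in trace.rounds) == len(alignment.shift_of) - 1

    def test_matches_naive_rescan_oracle_small(self):
        rng = np.random.default_rng(23)
        for trial in range(10):
            k = int(rng.integers(3, 6))
            table = random_kmer_table(rng, k=k, n=int(rng.integers(8, 120)))
            alignment, _ = crawl(table)
            assert alignment.shift_of == naive_crawl(
                table.sequences, table.metrics
            )

    def test_tied_metrics_resolve_deterministically(self):
        table = KmerTable(
            ("ACGT", "CGTA", "TACG"), np.array([1.0, 1.0, 1.0])
        )
        first, _ = crawl(table)
        second, _ = crawl(table)
        assert first.shift_of == second.shift_of
        # lexicographically smallest of the tied maxima seeds at 0
        assert first.shift_of["ACGT"] == 0


class TestRevcompMerge:
    def test_pair_collapses_to_canonical_strand(self):
        table = KmerTable(("ACG", "CGT"), np.array([2.0, 2.0]))
        alignment, _ = crawl(table, revcomp_merge=True)
        # revcomp(CGT) = ACG: one canonical species remains
        assert set(alignment.shift_of) == {"ACG"}
        assert alignment.orientation_of == {"ACG": "+", "CGT": "-"}

    def test_conflicting_metrics_fatal(self):
        table = KmerTable(("ACG", "CGT"), np.array([2.0, 3.0]))
        with pytest.raises(FormatError, match="conflicting"):
            crawl(table, revcomp_merge=True)


class TestAlignerEstimator:
    def test_fit_transform_and_attributes(self, worked_table):
        aligner = TopDownCrawlAligner().fit(worked_table)
        assert aligner.k_ == 7
        assert aligner.shift_of_ == {"GTAAACA": 0, "AGTAAAC": -1}
        np.testing.assert_array_equal(
            aligner.transform(["AGTAAAC", "GTAAACA"]), [-1.0, 0.0]
        )
        assert np.isnan(aligner.transform(["TTTTTTT"]))[0]

    def test_fit_from_sequences_and_metrics(self):
        aligner = TopDownCrawlAligner().fit(
            ["GTAAACA", "AGTAAAC"], np.array([9.0, 5.0])
        )
        assert aligner.shift_of_["AGTAAAC"] == -1

    def test_aligned_table_export(self, worked_table):
        aligner = TopDownCrawlAligner().fit(worked_table)
        aligned = aligner.to_aligned_table()
        assert set(aligned.sequences) == {"_GTAAACA", "AGTAAAC_"}

    def test_get_params_round_trip(self):
        aligner = TopDownCrawlAligner(revcomp_merge=True)
        assert aligner.get_params() == {"revcomp_merge": True}
        aligner.set_params(revcomp_merge=False)
        assert not aligner.revcomp_merge
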
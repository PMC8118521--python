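"""K-mer index construction, five-way read-pair classification, Table-style
summaries, and the partition/symmetry invariants."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xenosort.kmer import (
    CLASSES,
    ClassificationSummary,
    KmerIndex,
    KmerReadClassifier,
    build_kmer_index,
    canonical_kmers,
    classify_dataset,
    classify_read_pair,
    summarize_classification,
)
from xenosort.simulate import reverse_complement, simulate_read_pairs
from xenosort._seqio import read_fastq, write_fastq

dna = st.text(alphabet="ACGT", min_size=0, max_size=80)


def brute_canonical(seq: str, k: int) -> set[str]:
    out = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if set(km) <= set("ACGT"):
            out.add(min(km, reverse_complement(km)))
    return out


class TestCanonicalKmers:
    def test_hand_enumeration_reverse_complement_merge(self):
        """AAAACCCC vs GGGGTTTT share all five canonical 4-mers."""
        host = set(canonical_kmers("AAAACCCC", 4))
        graft = set(canonical_kmers("GGGGTTTT", 4))
        assert host == graft == {"AAAA", "AAAC", "AACC", "ACCC", "CCCC"}

    def test_partial_overlap_matches_brute_force(self):
        host = set(canonical_kmers("AAAACCCC", 4))
        graft = set(canonical_kmers("AAGGAAGG", 4))
        assert host == brute_canonical("AAAACCCC", 4)
        assert graft == brute_canonical("AAGGAAGG", 4)
        assert host & graft == brute_canonical("AAAACCCC", 4) & brute_canonical("AAGGAAGG", 4)

    @given(seq=dna, k=st.sampled_from([3, 5, 7, 11]))
    @settings(deadline=None, max_examples=100)
    def test_matches_brute_force_and_strand_invariant(self, seq, k):
        got = set(canonical_kmers(seq, k))
        assert got == brute_canonical(seq, k)
        assert got == set(canonical_kmers(reverse_complement(seq), k))

    def test_ambiguous_bases_skipped(self):
        # windows overlapping the N are dropped; canonical(AAA) = AAA
        assert set(canonical_kmers("AAANAAA", 3)) == {"AAA"}


class TestBuildKmerIndex:
    def test_sets_are_disjoint_and_cover_all_kmers(self, tiny_refs, tiny_index):
        host, graft, _ = tiny_refs
        idx = tiny_index
        assert not idx.host_only & idx.graft_only
        assert not idx.host_only & idx.shared
        assert not idx.graft_only & idx.shared
        all_host = set().union(*(brute_canonical(t.sequence, 25) for t in host))
        all_graft = set().union(*(brute_canonical(t.sequence, 25) for t in graft))
        assert idx.host_only | idx.shared == all_host
        assert idx.graft_only | idx.shared == all_graft

    def test_identical_references_give_only_shared(self):
        seqs = ["ACGTACGTACGTACGTACGTACGTACGTAC"]
        idx = build_kmer_index(seqs, list(seqs), k=25)
        assert idx.host_only == idx.graft_only == frozenset()
        assert len(idx.shared) > 0

    def test_even_or_out_of_range_k_rejected(self, tiny_refs):
        host, graft, _ = tiny_refs
        hseq = [t.sequence for t in host]
        gseq = [t.sequence for t in graft]
        with pytest.raises(ValueError):
            build_kmer_index(hseq, gseq, k=24)
        with pytest.raises(ValueError):
            build_kmer_index(hseq, gseq, k=9)
        with pytest.raises(ValueError):
            build_kmer_index(hseq, [], k=25)

    def test_round_trips_through_serialization(self, tiny_index, tmp_path):
        path = tmp_path / "index.tsv"
        tiny_index.save(path)
        loaded = KmerIndex.load(path)
        assert loaded.k == tiny_index.k
        assert loaded.host_only == tiny_index.host_only
        assert loaded.graft_only == tiny_index.graft_only
        assert loaded.shared == tiny_index.shared


class TestClassifyReadPair:
    def test_truth_table_rules(self):
        idx = KmerIndex(
            k=11,
            host_only=frozenset({"AAAAAAAAAAA"}),
            graft_only=frozenset({"ACACACACACA"}),
            shared=frozenset({"AGAGAGAGAGA"}),
        )
        far = "GGTTGGTTGGTTGGT"  # hits nothing
        assert classify_read_pair(far, far, idx) == "neither"
        assert classify_read_pair("AAAAAAAAAAA", far, idx) == "host"
        assert classify_read_pair(far, "ACACACACACA", idx) == "graft"
        assert classify_read_pair("AAAAAAAAAAA", "ACACACACACA", idx) == "ambiguous"
        assert classify_read_pair("AGAGAGAGAGA", far, idx) == "both"

    def test_reads_shorter_than_k_are_neither(self, tiny_index):
        assert classify_read_pair("ACGT", "ACGT", tiny_index) == "neither"
        with pytest.raises(ValueError):
            classify_read_pair("", "ACGT", tiny_index)

    def test_agrees_with_substring_search_oracle(
        self, tiny_refs, tiny_truth, tiny_index, substring_oracle
    ):
        """Error-free reads at divergence 0.2: k-mer classes match brute-force
        substring search against the full references."""
        host, graft, _ = tiny_refs
        hseqs = [t.sequence for t in host]
        gseqs = [t.sequence for t in graft]
        r1, r2, _ = simulate_read_pairs(host + graft, tiny_truth, 400, 100, 0.0, 0.5, seed=31)
        for (_, s1, _), (_, s2, _) in zip(r1, r2):
            got = classify_read_pair(s1, s2, tiny_index)
            expected = substring_oracle(s1, s2, hseqs, gseqs)
            assert got == expected

    def test_swapping_references_swaps_host_and_graft(self, tiny_refs, tiny_truth):
        host, graft, _ = tiny_refs
        fwd = build_kmer_index([t.sequence for t in host], [t.sequence for t in graft], 25)
        rev = build_kmer_index([t.sequence for t in graft], [t.sequence for t in host], 25)
        r1, r2, _ = simulate_read_pairs(host + graft, tiny_truth, 200, 100, 0.01, 0.5, seed=32)
        swap = {"host": "graft", "graft": "host"}
        for (_, s1, _), (_, s2, _) in zip(r1, r2):
            a = classify_read_pair(s1, s2, fwd)
            b = classify_read_pair(s1, s2, rev)
            assert b == swap.get(a, a)

    def test_unique_fraction_grows_with_divergence(self):
        """More divergent references never make reads harder to assign."""
        from xenosort.simulate import assign_expression_profiles, generate_reference_pair

        fractions = []
        for div in (0.02, 0.1, 0.3):
            host, graft, table = generate_reference_pair(10, 10, 10, (400, 400), div, seed=50)
            truth = assign_expression_profiles(table, 0, 1.0, seed=51)
            idx = build_kmer_index([t.sequence for t in host], [t.sequence for t in graft], 25)
            r1, r2, _ = simulate_read_pairs(host + graft, truth, 600, 100, 0.0, 0.5, seed=52)
            classes = [classify_read_pair(a[1], b[1], idx) for a, b in zip(r1, r2)]
            fractions.append(sum(c in ("host", "graft") for c in classes) / len(classes))
        assert fractions[0] <= fractions[1] + 0.02
        assert fractions[1] <= fractions[2] + 0.02


class TestKmerReadClassifierEstimator:
    def test_sklearn_api_fit_predict_and_params(self, tiny_refs):
        host, graft, _ = tiny_refs
        clf = KmerReadClassifier(k=25)
        assert clf.get_params() == {"k": 25}
        clf.set_params(k=21)
        clf.fit([t.sequence for t in host], [t.sequence for t in graft])
        assert clf.index_.k == 21
        pred = clf.predict([(host[0].sequence[:100], host[0].sequence[:100])])
        assert pred.shape == (1,)
        assert pred[0] in CLASSES

    def test_predict_before_fit_raises(self):
        with pytest.raises(ValueError):
            KmerReadClassifier().predict([("ACGT" * 30, "ACGT" * 30)])


class TestClassifyDataset:
    def test_partition_conserves_reads_and_order(self, tiny_refs, tiny_truth, tiny_index, tmp_path):
        host, graft, _ = tiny_refs
        r1, r2, _ = simulate_read_pairs(host + graft, tiny_truth, 500, 100, 0.005, 0.4, seed=41)
        p1, p2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        write_fastq(r1, p1)
        write_fastq(r2, p2)
        summary = classify_dataset(p1, p2, tiny_index, tmp_path / "out")
        assert summary.total == 500
        written = 0
        seen = []
        for cls in CLASSES:
            recs = list(read_fastq(tmp_path / "out" / f"{cls}_1.fastq"))
            assert len(recs) == summary.counts[cls]
            written += len(recs)
            seen.extend(t for t, _, _ in recs)
        assert written == 500
        assert sorted(seen) == sorted(t for t, _, _ in r1)
        assert sum(summary.percentages.values()) == pytest.approx(100.0)

    def test_mismatched_record_counts_reported_with_index(self, tiny_index, tmp_path):
        r1 = [("p0/1", "A" * 30, "I" * 30), ("p1/1", "A" * 30, "I" * 30)]
        r2 = [("p0/2", "A" * 30, "I" * 30)]
        write_fastq(r1, tmp_path / "r1.fastq")
        write_fastq(r2, tmp_path / "r2.fastq")
        with pytest.raises(ValueError, match="record index 1"):
            classify_dataset(tmp_path / "r1.fastq", tmp_path / "r2.fastq", tiny_index, tmp_path / "o")

    def test_empty_input_reports_zero_percentages_with_warning(self, tiny_index, tmp_path):
        (tmp_path / "e1.fastq").write_text("")
        (tmp_path / "e2.fastq").write_text("")
        summary = classify_dataset(tmp_path / "e1.fastq", tmp_path / "e2.fastq", tiny_index, tmp_path / "o")
        assert summary.total == 0
        with pytest.warns(UserWarning):
            assert all(v == 0.0 for v in summary.percentages.values())


class TestSummarizeClassification:
    def test_counts_to_percentages(self):
        s = ClassificationSummary("t", dict(zip(CLASSES, (523, 426, 30, 8, 13))))
        assert s.percentages == pytest.approx(
            dict(zip(CLASSES, (52.3, 42.6, 3.0, 0.8, 1.3)))
        )

    def test_three_sample_average_at_table_precision(self):
        rows = pd.DataFrame(
            [
                {"host": 52.30, "graft": 42.60, "ambiguous": 3.00, "both": 0.77, "neither": 1.30},
                {"host": 39.50, "graft": 54.10, "ambiguous": 3.50, "both": 0.97, "neither": 1.90},
                {"host": 64.70, "graft": 30.20, "ambiguous": 2.90, "both": 0.88, "neither": 1.34},
            ]
        )
        avg = summarize_classification(rows)
        assert avg["host"] == 52.2
        assert avg["graft"] == 42.3
        assert avg["ambiguous"] == 3.1
        assert avg["both"] == 0.87
        assert avg["neither"] == 1.51

    def test_single_summary_is_identity(self):
        s = ClassificationSummary("t", dict(zip(CLASSES, (40, 40, 10, 5, 5))))
        avg = summarize_classification([s])
        assert avg["host"] == 40.0
        assert avg["both"] == 5.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            summarize_classification([])
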
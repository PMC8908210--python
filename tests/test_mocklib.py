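"""Mock k-mer library and Hamming-bounded scanning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from equiomics.mocklib import (
    DsRNAConstruct,
    MockKmer,
    TranscriptHit,
    build_seed_index,
    combine_offtargets,
    enumerate_kmers,
    group_kmers_by_sequence,
    hamming_distance,
    hamming_search,
    revcomp,
)
from equiomics import synthetic


def naive_hits(kmers, transcripts, max_mm):
    """Independent brute-force oracle: all k-mers x all offsets."""
    found = set()
    seqs = dict(transcripts)
    for km in kmers:
        k = len(km.sequence)
        for tid, seq in seqs.items():
            for start in range(len(seq) - k + 1):
                d = sum(x != y for x, y in zip(km.sequence, seq[start : start + k]))
                if d <= max_mm:
                    found.add((km.sequence, km.strand, km.start, tid, start, d))
    return found


def as_tuples(hits):
    return {
        (h.kmer.sequence, h.kmer.strand, h.kmer.start, h.transcript_id, h.start, h.mismatches)
        for h in hits
    }


class TestEnumerate:
    def test_sense_21mer_count(self, dsrna):
        kmers = enumerate_kmers(dsrna, 21, 21, both_strands=False)
        assert len(kmers) == 876 - 21 + 1 == 856
        assert all(km.strand == "sense" for km in kmers)
        starts = [km.start for km in kmers]
        assert starts == sorted(starts)

    def test_full_library_count(self, dsrna):
        kmers = enumerate_kmers(dsrna, 21, 24, both_strands=True)
        assert len(kmers) == 2 * sum(876 - k + 1 for k in range(21, 25)) == 6836

    def test_k_equal_length(self):
        ds = DsRNAConstruct("d", "ACGTACGTACGTACGTACGTACGT")
        kmers = enumerate_kmers(ds, ds.length, ds.length)
        assert len(kmers) == 2
        sense, anti = kmers
        assert sense.sequence == ds.sequence
        assert anti.sequence == revcomp(ds.sequence)

    def test_antisense_is_revcomp_of_window(self, dsrna):
        kmers = enumerate_kmers(dsrna, 21, 21)
        for km in kmers[:50]:
            window = dsrna.sequence[km.start : km.start + 21]
            expected = window if km.strand == "sense" else revcomp(window)
            assert km.sequence == expected

    def test_k_exceeding_length_rejected(self, dsrna):
        with pytest.raises(ValueError):
            enumerate_kmers(dsrna, 21, 877)


class TestHammingSearch:
    def test_exact_hit_at_planted_offset(self):
        t = {"t1": "A" * 10 + "CGTACGTACGTACGTACGTAC" + "A" * 10}
        km = MockKmer("CGTACGTACGTACGTACGTAC", 21, "sense", 0)
        hits = hamming_search([km], t, max_mm=0)
        assert len(hits) == 1
        h = hits[0]
        assert (h.transcript_id, h.start, h.end, h.mismatches) == ("t1", 10, 31, 0)
        assert (h.start_1based, h.end_1based) == (11, 31)

    def test_distance_filter(self, rng):
        base = "".join(rng.choice(list("ACGT"), 21))
        mutate = lambda s, idx: s[:idx] + {"A": "C", "C": "G", "G": "T", "T": "A"}[s[idx]] + s[idx + 1 :]
        d1 = mutate(base, 3)
        d3 = mutate(mutate(mutate(base, 0), 7), 14)
        t = {"near": "TT" + d1 + "TT", "far": "TT" + d3 + "TT"}
        km = MockKmer(base, 21, "sense", 0)
        hits = hamming_search([km], t, max_mm=2)
        assert {h.transcript_id for h in hits} == {"near"}
        assert hits[0].mismatches == 1

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2), st.integers(0, 10_000))
    def test_indexed_equals_bruteforce(self, max_mm, seed):
        rng = np.random.default_rng(seed)
        ds = synthetic.gen_dsrna(60, 0.5, seed=seed)
        transcripts = [
            (f"t{i}", "".join(rng.choice(list("ACGT"), rng.integers(15, 120))))
            for i in range(8)
        ]
        # mix random transcripts with one embedding a construct window
        transcripts.append(("emb", transcripts[0][1][:10] + ds.sequence[5:40]))
        kmers = enumerate_kmers(ds, 21, 22)
        idx = build_seed_index(transcripts, seed_length=21 // (max_mm + 1))
        hits = hamming_search(kmers, transcripts, max_mm=max_mm, index=idx)
        assert as_tuples(hits) == naive_hits(kmers, transcripts, max_mm)

    def test_monotone_in_mismatch_budget(self, rng):
        ds = synthetic.gen_dsrna(80, 0.5, seed=3)
        transcripts, _ = synthetic.gen_transcriptome(
            6, (60, 120), ds, planted=[(21, 0), (21, 1), (21, 2)], seed=4
        )
        kmers = enumerate_kmers(ds, 21, 21)
        previous = set()
        for m in (0, 1, 2):
            current = {
                (h.kmer.sequence, h.transcript_id, h.start)
                for h in hamming_search(kmers, transcripts, max_mm=m)
            }
            assert previous <= current
            previous = current

    def test_strand_symmetry(self):
        """Scanning reverse-complemented transcripts mirrors coordinates."""
        ds = synthetic.gen_dsrna(50, 0.5, seed=9)
        transcripts, _ = synthetic.gen_transcriptome(
            3, (40, 80), ds, planted=[(21, 1)], seed=10
        )
        kmers = enumerate_kmers(ds, 21, 21, both_strands=True)
        fwd = hamming_search(kmers, transcripts, max_mm=2)
        rc = [(tid, revcomp(seq)) for tid, seq in transcripts]
        rev = hamming_search(kmers, rc, max_mm=2)
        lengths = {tid: len(seq) for tid, seq in transcripts}
        mirrored = {
            (revcomp(h.kmer.sequence), h.transcript_id,
             lengths[h.transcript_id] - h.end, h.mismatches)
            for h in rev
        }
        original = {
            (h.kmer.sequence, h.transcript_id, h.start, h.mismatches) for h in fwd
        }
        assert original == mirrored

    def test_empty_transcripts_give_empty_result(self, dsrna):
        kmers = enumerate_kmers(dsrna, 21, 21)[:5]
        assert hamming_search(kmers, {}, max_mm=2) == []

    def test_invalid_transcript_skipped(self, dsrna, caplog):
        km = MockKmer(dsrna.sequence[:21], 21, "sense", 0)
        t = {"ok": dsrna.sequence[:40], "bad": "ACGTNNNACGT" + "A" * 30}
        hits = hamming_search([km], t, max_mm=0)
        assert {h.transcript_id for h in hits} == {"ok"}

    def test_duplicate_kmers_keep_all_source_positions(self):
        ds = DsRNAConstruct("d", "ACGTACGTACGTACGTACGTACGTACGTA")  # periodic
        kmers = enumerate_kmers(ds, 21, 21, both_strands=False)
        groups = group_kmers_by_sequence(kmers)
        assert any(len(v) > 1 for v in groups.values())
        t = {"t": ds.sequence}
        hits = hamming_search(kmers, t, max_mm=0)
        # every source position of a duplicated sequence is attributed
        assert len(hits) == len(naive_hits(kmers, t, 0))


class TestSeedIndex:
    def test_own_prefix_found(self):
        idx = build_seed_index({"t": "ACGTACGTGGCC"}, seed_length=4)
        assert ("t", 0) in idx.occurrences["ACGT"]

    def test_short_transcript_falls_back(self):
        ds = synthetic.gen_dsrna(40, 0.5, seed=5)
        km = MockKmer(ds.sequence[:21], 21, "sense", 0)
        # transcript shorter than seed would be with big seed_length
        t = {"short": ds.sequence[:21]}
        idx = build_seed_index(t, seed_length=25)
        assert "short" in idx.unindexed
        hits = hamming_search([km], t, max_mm=0, index=idx)
        assert len(hits) == 1

    def test_invalid_seed_length(self):
        with pytest.raises(ValueError):
            build_seed_index({"t": "ACGT"}, seed_length=0)


class TestCombine:
    def _hit(self, tid, mm, seq="A" * 21):
        km = MockKmer(seq, 21, "sense", 0)
        return TranscriptHit(tid, km, mm, 0, 21)

    def test_cumulative_tiers(self):
        report = combine_offtargets([self._hit("g1", 1), self._hit("g2", 2)])
        assert report.tier_counts == {0: 0, 1: 1, 2: 2}
        # tiers are cumulative-consistent by construction
        counts = [report.tier_counts[m] for m in sorted(report.tier_counts)]
        assert counts == sorted(counts)

    def test_expressed_only_empty_evidence(self):
        report = combine_offtargets([self._hit("g1", 0)], set(), mode="expressed_only")
        assert report.n_transcripts == 0

    def test_expressed_only_accepts_revcomp(self):
        seq = "ACGTACGTACGTACGTACGTA"
        report = combine_offtargets(
            [self._hit("g1", 0, seq)], {revcomp(seq)}, mode="expressed_only"
        )
        assert report.n_transcripts == 1

    def test_all_mock_ignores_evidence(self):
        hits = [self._hit("g1", 0)]
        assert combine_offtargets(hits, set(), mode="all_mock").n_transcripts == 1

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            combine_offtargets([], mode="both")


def test_hamming_distance_basics():
    assert hamming_distance("ACGT", "ACGT") == 0
    assert hamming_distance("ACGT", "ACGA") == 1
    assert hamming_distance("AAAA", "TTTT", limit=2) == 3  # early exit at limit+1
    with pytest.raises(ValueError):
        hamming_distance("ACG", "ACGT")
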
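"""Mock siRNA library construction and Hamming-bounded transcriptome scanning.

A plant transformed with an inverted-repeat transgene transcribes a dsRNA
hairpin that Dicer processes into 21-24 nt siRNAs from both strands.  Any
of those siRNAs could in principle silence a host transcript it matches
closely enough, so the off-target screen enumerates every 21-24 nt window
of the construct (the *mock library*) and scans the transcript set for
occurrences within a mismatch budget.

Matching is pure Hamming distance: substitutions only, no gaps.  The scan
has two interchangeable execution paths — a brute-force all-offsets scan
and a pigeonhole seed index (a match of a k-mer with at most ``m``
mismatches must contain one of ``m + 1`` disjoint exact seed chunks) —
which are required to return identical hit sets.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")

SENSE = "sense"
ANTISENSE = "antisense"


def revcomp(sequence: str) -> str:
    """Reverse complement of a DNA string."""
    return sequence.translate(_COMPLEMENT)[::-1]


def normalize_sequence(sequence: str) -> str:
    """Uppercase and convert RNA U to DNA T."""
    return sequence.upper().replace("U", "T")


def hamming_distance(a: str, b: str, limit: int | None = None) -> int:
    """Number of substitutions between equal-length strings.

    With ``limit`` the count stops at ``limit + 1``; callers only need to
    know that the distance exceeded the budget.
    """
    if len(a) != len(b):
        raise ValueError("hamming_distance requires equal-length sequences")
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if limit is not None and d > limit:
                return d
    return d


@dataclass(frozen=True)
class DsRNAConstruct:
    """The inverted-repeat dsRNA construct; source of all mock k-mers."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = normalize_sequence(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError("dsRNA sequence must be non-empty")
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"dsRNA contains non-ACGT characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def antisense(self) -> str:
        return revcomp(self.sequence)


@dataclass(frozen=True)
class MockKmer:
    """One candidate siRNA k-mer cut from the construct.

    ``start`` is the 0-based offset of the window on the *sense*
    coordinate system regardless of strand; antisense k-mers carry the
    reverse complement of that window.
    """

    sequence: str
    k: int
    strand: str
    start: int

    def __post_init__(self) -> None:
        if len(self.sequence) != self.k:
            raise ValueError("k must equal the k-mer length")
        if self.strand not in (SENSE, ANTISENSE):
            raise ValueError(f"unknown strand: {self.strand!r}")


@dataclass(frozen=True)
class TranscriptHit:
    """A Hamming-bounded occurrence of a mock k-mer on a transcript.

    Coordinates are 0-based half-open internally; report writers convert
    to 1-based inclusive.
    """

    transcript_id: str
    kmer: MockKmer
    mismatches: int
    start: int
    end: int

    @property
    def start_1based(self) -> int:
        return self.start + 1

    @property
    def end_1based(self) -> int:
        return self.end  # half-open end == 1-based inclusive end


@dataclass
class OffTargetReport:
    """Per-transcript minimum mismatch and cumulative mismatch-tier counts."""

    mode: str
    min_mismatches: dict[str, int]
    tier_counts: dict[int, int]

    @property
    def n_transcripts(self) -> int:
        return len(self.min_mismatches)


# ---------------------------------------------------------------------------
# library construction


def enumerate_kmers(
    dsrna: DsRNAConstruct,
    k_min: int = 21,
    k_max: int = 24,
    both_strands: bool = True,
) -> list[MockKmer]:
    """Cut every k-mer window, k_min..k_max, from the construct.

    For each k there are ``length - k + 1`` windows per strand, emitted in
    order of start position.  Antisense k-mers are the reverse complements
    of the sense windows, positioned on sense coordinates.  Duplicate
    sequences are retained with their positions; use
    :func:`group_kmers_by_sequence` for the deduplicated view.
    """
    if not (1 <= k_min <= k_max):
        raise ValueError("need 1 <= k_min <= k_max")
    if k_max > dsrna.length:
        raise ValueError(
            f"k_max={k_max} exceeds construct length {dsrna.length}"
        )
    kmers: list[MockKmer] = []
    seq = dsrna.sequence
    for k in range(k_min, k_max + 1):
        for start in range(dsrna.length - k + 1):
            window = seq[start : start + k]
            kmers.append(MockKmer(window, k, SENSE, start))
            if both_strands:
                kmers.append(MockKmer(revcomp(window), k, ANTISENSE, start))
    return kmers


def group_kmers_by_sequence(kmers: Iterable[MockKmer]) -> dict[str, list[MockKmer]]:
    """Deduplicated sequence set; each sequence keeps all source positions."""
    groups: dict[str, list[MockKmer]] = defaultdict(list)
    for km in kmers:
        groups[km.sequence].append(km)
    return dict(groups)


# ---------------------------------------------------------------------------
# transcript handling


def _as_transcript_dict(transcripts) -> dict[str, str]:
    """Accept dict, (id, seq) pairs, or Biopython SeqRecords.

    Records with non-ACGT characters are skipped with a logged warning,
    matching the scan contract (bad records must not abort a run).
    """
    items: list[tuple[str, str]]
    if isinstance(transcripts, Mapping):
        items = [(str(k), str(v)) for k, v in transcripts.items()]
    else:
        items = []
        for rec in transcripts:
            if hasattr(rec, "id") and hasattr(rec, "seq"):
                items.append((str(rec.id), str(rec.seq)))
            else:
                tid, seq = rec
                items.append((str(tid), str(seq)))
    out: dict[str, str] = {}
    for tid, seq in items:
        norm = normalize_sequence(seq)
        if set(norm) - _VALID:
            log.warning("skipping transcript %s: non-ACGT characters", tid)
            continue
        out[tid] = norm
    return out


# ---------------------------------------------------------------------------
# seed index (pigeonhole filtration)


@dataclass
class SeedIndex:
    """Exact-seed occurrence index over a transcript set.

    ``occurrences[seed]`` lists ``(transcript_id, offset)`` for every
    window of ``seed_length``.  Transcripts shorter than the seed length
    contribute no seeds and are kept on ``unindexed`` so searches can fall
    back to direct scanning for them.
    """

    seed_length: int
    sequences: dict[str, str]
    occurrences: dict[str, list[tuple[str, int]]] = field(repr=False)
    unindexed: tuple[str, ...] = ()


def build_seed_index(transcripts, seed_length: int) -> SeedIndex:
    if seed_length < 1:
        raise ValueError("seed_length must be >= 1")
    seqs = _as_transcript_dict(transcripts)
    occ: dict[str, list[tuple[str, int]]] = defaultdict(list)
    short: list[str] = []
    for tid, seq in seqs.items():
        if len(seq) < seed_length:
            short.append(tid)
            continue
        for i in range(len(seq) - seed_length + 1):
            occ[seq[i : i + seed_length]].append((tid, i))
    return SeedIndex(seed_length, seqs, dict(occ), tuple(short))


# ---------------------------------------------------------------------------
# search


def _scan_offsets(seq: str, query: str, max_mm: int) -> list[tuple[int, int]]:
    """All (offset, distance) with Hamming(query, window) <= max_mm."""
    k = len(query)
    out = []
    for start in range(len(seq) - k + 1):
        d = hamming_distance(query, seq[start : start + k], max_mm)
        if d <= max_mm:
            out.append((start, d))
    return out


def hamming_search(
    kmers: Sequence[MockKmer],
    transcripts,
    max_mm: int = 2,
    index: SeedIndex | None = None,
    use_index: bool = True,
) -> list[TranscriptHit]:
    """Report every k-mer occurrence on the transcripts within ``max_mm``.

    Each (k-mer sequence, transcript, offset) within the budget yields one
    hit per source :class:`MockKmer` carrying that sequence, so duplicated
    library windows keep all their origin coordinates.  With ``use_index``
    a pigeonhole seed index accelerates the scan; it must (and, by the
    test suite, does) return exactly the brute-force hit set.  Every hit's
    distance is recomputed before emission.
    """
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    seqs = index.sequences if index is not None else _as_transcript_dict(transcripts)
    if not seqs:
        return []
    groups = group_kmers_by_sequence(kmers)
    if not groups:
        return []

    if index is None and use_index:
        k_min = min(len(s) for s in groups)
        seed_len = k_min // (max_mm + 1)
        if seed_len >= 1:
            index = build_seed_index(seqs, seed_len)

    hits: list[TranscriptHit] = []
    for qseq, sources in groups.items():
        k = len(qseq)
        found: dict[str, list[tuple[int, int]]] = {}
        if index is not None and (max_mm + 1) * index.seed_length <= k:
            s = index.seed_length
            candidates: set[tuple[str, int]] = set()
            for chunk_i in range(max_mm + 1):
                off = chunk_i * s
                for tid, pos in index.occurrences.get(qseq[off : off + s], ()):
                    start = pos - off
                    if 0 <= start <= len(index.sequences[tid]) - k:
                        candidates.add((tid, start))
            for tid, start in candidates:
                d = hamming_distance(qseq, index.sequences[tid][start : start + k], max_mm)
                if d <= max_mm:
                    found.setdefault(tid, []).append((start, d))
            for tid in index.unindexed:
                occs = _scan_offsets(index.sequences[tid], qseq, max_mm)
                if occs:
                    found.setdefault(tid, []).extend(occs)
        else:
            for tid, tseq in seqs.items():
                occs = _scan_offsets(tseq, qseq, max_mm)
                if occs:
                    found[tid] = occs
        for tid, occs in found.items():
            for start, d in occs:
                # recheck-on-emit: stored distance must match a direct recount
                assert hamming_distance(qseq, seqs[tid][start : start + k]) == d
                for km in sources:
                    hits.append(TranscriptHit(tid, km, d, start, start + k))

    hits.sort(
        key=lambda h: (h.transcript_id, h.start, h.kmer.k, h.kmer.strand, h.kmer.start)
    )
    return hits


# ---------------------------------------------------------------------------
# evidence combination


def combine_offtargets(
    mock_hits: Iterable[TranscriptHit],
    expressed_sirnas: Iterable[str] | None = None,
    mode: str = "all_mock",
) -> OffTargetReport:
    """Summarize hits into per-transcript tiers, optionally requiring
    expressed-siRNA evidence.

    ``all_mock`` keeps every transcript with at least one mock-library
    hit.  ``expressed_only`` keeps only hits whose k-mer sequence (or its
    reverse complement) was actually observed among sequenced siRNAs,
    combining the in-silico library with the expression evidence.  Tier
    counts are cumulative: ``tier_counts[m]`` is the number of transcripts
    whose best hit has at most ``m`` mismatches.
    """
    if mode not in ("all_mock", "expressed_only"):
        raise ValueError(f"unknown mode: {mode!r}")
    hits = list(mock_hits)
    if mode == "expressed_only":
        expressed = {
            normalize_sequence(s) for s in (expressed_sirnas or ())
        }
        hits = [
            h
            for h in hits
            if h.kmer.sequence in expressed or revcomp(h.kmer.sequence) in expressed
        ]
    best: dict[str, int] = {}
    for h in hits:
        prev = best.get(h.transcript_id)
        if prev is None or h.mismatches < prev:
            best[h.transcript_id] = h.mismatches
    max_tier = max(best.values(), default=0)
    tiers = {
        m: sum(1 for v in best.values() if v <= m) for m in range(max_tier + 1)
    }
    return OffTargetReport(mode=mode, min_mismatches=best, tier_counts=tiers)
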
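"""Expressed small-RNA profiling against the dsRNA construct.

Sequenced 18-30 nt reads are collapsed to unique sequences, mapped
*exactly* (no gaps, no mismatches) to either strand of the construct —
guaranteeing that everything profiled derives from the inverted repeat —
and summarized as the standard small-RNA analytics: read-length
distribution, first-base coverage along the construct, a position
frequency matrix with per-column information content, overall GC
fraction, and the A/U share of the first five 5' positions (a correlate
of guide-strand loading and silencing efficacy).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .mocklib import ANTISENSE, SENSE, DsRNAConstruct, normalize_sequence

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SmallRNARead:
    """A collapsed small-RNA sequence with its read multiplicity."""

    id: str
    sequence: str
    count: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if self.count < 1:
            raise ValueError("count must be >= 1")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadAlignment:
    """One exact occurrence of a read on a construct strand.

    ``position`` is the 0-based first-base offset on that strand's own
    coordinates; ``multi_mapped`` flags reads with more than one
    occurrence across both strands.
    """

    read: SmallRNARead
    strand: str
    position: int
    multi_mapped: bool = False


@dataclass
class BasePreference:
    """Position frequency matrix and sequence-composition statistics."""

    pfm: pd.DataFrame  # positions x (A, C, G, T), rows sum to 1
    information_bits: np.ndarray  # 2 - Shannon entropy per position
    gc_fraction: float
    au5_fraction: float
    n_reads: float  # weighted read count entering the matrix

    @property
    def is_empty(self) -> bool:
        return self.n_reads == 0


@dataclass
class SiRNAProfile:
    size_distribution: dict[int, int]
    first_base_coverage: dict[str, np.ndarray]
    base_preference: BasePreference | None
    total_mapped: int
    n_multi_mapped: int = 0


# ---------------------------------------------------------------------------


def collapse_reads(records: Iterable) -> list[SmallRNARead]:
    """Collapse identical sequences into one read with a multiplicity.

    Accepts ``(id, sequence)`` pairs, Biopython SeqRecords, or
    :class:`SmallRNARead` (whose counts are summed).
    """
    counts: Counter[str] = Counter()
    for rec in records:
        if isinstance(rec, SmallRNARead):
            counts[rec.sequence] += rec.count
        elif hasattr(rec, "seq"):
            counts[normalize_sequence(str(rec.seq))] += 1
        else:
            counts[normalize_sequence(rec[1])] += 1
    return [
        SmallRNARead(f"u{i:06d}", seq, n)
        for i, (seq, n) in enumerate(sorted(counts.items()))
    ]


def filter_by_length(
    reads: Iterable[SmallRNARead], min_len: int = 18, max_len: int = 30
) -> list[SmallRNARead]:
    """Keep reads with min_len <= length <= max_len (both inclusive)."""
    return [r for r in reads if min_len <= r.length <= max_len]


def map_exact_to_dsrna(
    reads: Iterable[SmallRNARead], dsrna: DsRNAConstruct
) -> list[ReadAlignment]:
    """Map each read as an exact substring of either construct strand.

    All occurrences are reported; a read occurring more than once (on one
    strand or across strands) has every alignment flagged multi-mapped.
    """
    strands = {SENSE: dsrna.sequence, ANTISENSE: dsrna.antisense}
    alignments: list[ReadAlignment] = []
    for read in reads:
        occ: list[tuple[str, int]] = []
        for strand, seq in strands.items():
            start = seq.find(read.sequence)
            while start != -1:
                occ.append((strand, start))
                start = seq.find(read.sequence, start + 1)
        multi = len(occ) > 1
        for strand, pos in occ:
            alignments.append(ReadAlignment(read, strand, pos, multi))
    return alignments


def _unique_reads(alignments: Iterable[ReadAlignment]) -> list[SmallRNARead]:
    seen: dict[int, SmallRNARead] = {}
    for aln in alignments:
        seen.setdefault(id(aln.read), aln.read)
    return list(seen.values())


def size_distribution(alignments: Iterable[ReadAlignment]) -> dict[int, int]:
    """Read counts per length; each mapped read counted once even when
    multi-mapped, weighted by its collapse multiplicity."""
    dist: Counter[int] = Counter()
    for read in _unique_reads(alignments):
        dist[read.length] += read.count
    return dict(sorted(dist.items()))


def first_base_coverage(
    alignments: Iterable[ReadAlignment], dsrna_length: int
) -> dict[str, np.ndarray]:
    """Per-strand coverage of read first-base positions, count-weighted.

    Every (read, occurrence) pair contributes, so the totals equal the
    number of weighted alignments.
    """
    cov = {
        SENSE: np.zeros(dsrna_length, dtype=float),
        ANTISENSE: np.zeros(dsrna_length, dtype=float),
    }
    for aln in alignments:
        cov[aln.strand][aln.position] += aln.read.count
    return cov


def base_preference(
    alignments: Iterable[ReadAlignment], k: int = 21, min_count: int = 1
) -> BasePreference:
    """Position frequency matrix over mapped reads of length ``k``.

    Frequencies are weighted by read multiplicity.  Information content
    per column is ``2 - H`` bits with the plug-in Shannon entropy and no
    small-sample correction.  ``gc_fraction`` covers all bases of the
    reads used; ``au5_fraction`` is the A/T share over positions 1-5.
    An empty (flagged, not raising) profile is returned when no read
    qualifies.
    """
    reads = [
        r
        for r in _unique_reads(alignments)
        if r.length == k and r.count >= min_count
    ]
    if not reads:
        return BasePreference(
            pfm=pd.DataFrame(columns=list(BASES)),
            information_bits=np.zeros(0),
            gc_fraction=float("nan"),
            au5_fraction=float("nan"),
            n_reads=0,
        )
    counts = np.zeros((k, 4))
    base_index = {b: i for i, b in enumerate(BASES)}
    for r in reads:
        for pos, base in enumerate(r.sequence):
            counts[pos, base_index[base]] += r.count
    freqs = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    pfm = pd.DataFrame(freqs, columns=list(BASES))
    pfm.index.name = "position"
    total = counts.sum()
    gc = (counts[:, base_index["G"]].sum() + counts[:, base_index["C"]].sum()) / total
    au5 = freqs[:5, [base_index["A"], base_index["T"]]].sum(axis=1).mean()
    n_reads = float(sum(r.count for r in reads))
    return BasePreference(pfm, info, float(gc), float(au5), n_reads)


def profile_reads(
    reads: Iterable[SmallRNARead],
    dsrna: DsRNAConstruct,
    k: int = 21,
    min_count: int = 1,
) -> SiRNAProfile:
    """Full profiling pipeline for one library: filter, map, summarize."""
    kept = filter_by_length(reads)
    alignments = map_exact_to_dsrna(kept, dsrna)
    uniq = _unique_reads(alignments)
    multi = {id(a.read): a.read.count for a in alignments if a.multi_mapped}
    return SiRNAProfile(
        size_distribution=size_distribution(alignments),
        first_base_coverage=first_base_coverage(alignments, dsrna.length),
        base_preference=base_preference(alignments, k=k, min_count=min_count),
        total_mapped=int(sum(r.count for r in uniq)),
        n_multi_mapped=int(sum(multi.values())),
    )


def abundance_ratio(a, b, pseudocount: float | None = None) -> float:
    """Ratio of mapped totals between two libraries (e.g. GE vs non-GE).

    ``a`` and ``b`` may be :class:`SiRNAProfile` objects or raw totals.
    With a pseudocount the ratio is ``(a + c) / (b + c)``, the documented
    convention when the denominator library has no mapped reads; without
    one a zero denominator raises.
    """
    ta = float(a.total_mapped if isinstance(a, SiRNAProfile) else a)
    tb = float(b.total_mapped if isinstance(b, SiRNAProfile) else b)
    if ta < 0 or tb < 0:
        raise ValueError("totals must be >= 0")
    if pseudocount is not None:
        return (ta + pseudocount) / (tb + pseudocount)
    if tb == 0:
        raise ZeroDivisionError(
            "undefined ratio: denominator library has no mapped reads "
            "(pass a pseudocount)"
        )
    return ta / tb
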
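"""Self-mapping mappability mask.

To find the reference positions where 31-bp reads map unambiguously, every
possible read-length window of the reference (both strands) is aligned back
to the reference allowing up to one mismatch, with multi-mapping permitted.
At a position where all 2L spanning windows align only to their own origin,
exactly 2L = 62 fake reads cover the position; any extra alignment (a
repeat, or a near-repeat within the mismatch allowance) pushes the
self-mapping coverage above 62.  The uniquely-mappable flag is exactly
``self_coverage == 2L``.

The mismatch model is whole-read Hamming distance (both strands).  The
search is exact but uses pigeonhole seeding for speed: any placement within
Hamming distance 1 matches at least one of the two read halves exactly, so
candidate placements are found by hashing half-length substrings and then
verified in full.

Nuclear contigs are linear (positions within L-1 of an end are covered by
fewer than 2L windows and can never be unique); the mitochondrial contig is
circular and windows wrap across the origin.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .io_formats import GenomeSequence

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def revcomp(seq: str) -> str:
    return seq.encode().translate(_COMPLEMENT).decode()[::-1]


@dataclass(frozen=True)
class SelfMapParams:
    """Parameters of the self-mapping procedure.

    read_length
        Fake-read length L; 31 in the published analysis.  Validated odd so
        that no window can equal its own reverse complement exactly.
    max_mismatch
        Whole-read Hamming allowance, 0 or 1.
    """

    read_length: int = 31
    max_mismatch: int = 1

    def __post_init__(self) -> None:
        if self.read_length < 2:
            raise ValueError("read_length must be >= 2")
        if self.read_length % 2 == 0:
            raise ValueError(
                "read_length must be odd (an even-length window could be "
                "its own reverse complement, making strand counts ambiguous)"
            )
        if self.max_mismatch not in (0, 1):
            raise ValueError("max_mismatch must be 0 or 1")


@dataclass
class MappabilityMask:
    """Per-position self-mapping coverage and the uniquely-mappable flag."""

    contig: str
    read_length: int
    self_coverage: np.ndarray  # int64, length = contig length
    unique: np.ndarray  # bool

    def __post_init__(self) -> None:
        if len(self.self_coverage) != len(self.unique):
            raise ValueError("coverage/unique length mismatch")

    def __len__(self) -> int:
        return len(self.unique)

    def unique_blocks(self) -> Iterator[tuple[int, int]]:
        """Maximal runs of unique positions as 0-based half-open intervals."""
        u = np.asarray(self.unique, dtype=bool)
        if not u.any():
            return
        d = np.diff(u.astype(np.int8))
        starts = list(np.flatnonzero(d == 1) + 1)
        ends = list(np.flatnonzero(d == -1) + 1)
        if u[0]:
            starts.insert(0, 0)
        if u[-1]:
            ends.append(len(u))
        yield from zip(starts, ends)


def enumerate_self_reads(
    genome: GenomeSequence, params: SelfMapParams
) -> Iterator[tuple[str, int, str]]:
    """All length-L windows of the genome, both strands.

    Yields ``(window, origin_offset, strand)`` with origin_offset 0-based.
    Circular genomes wrap across the origin, giving one window pair per
    position; linear genomes give length - L + 1 offsets.  A linear genome
    shorter than L yields nothing (with a warning).
    """
    L = params.read_length
    seq = genome.sequence
    n = len(seq)
    if genome.circular:
        ext = seq + seq[: L - 1]
        offsets = range(n)
    else:
        if n < L:
            warnings.warn(
                f"contig {genome.name!r} shorter than read length {L}; "
                "no self-reads",
                stacklevel=2,
            )
            return
        ext = seq
        offsets = range(n - L + 1)
    for o in offsets:
        w = ext[o : o + L]
        yield w, o, "+"
        yield revcomp(w), o, "-"


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def self_map_coverage(
    genome: GenomeSequence, params: SelfMapParams
) -> MappabilityMask:
    """Align every fake read to every position (both strands) at Hamming
    distance <= max_mismatch and accumulate per-position coverage.

    A forward window and its reverse complement have mirror-image placement
    sets spanning identical positions (aligning W to the reverse strand at
    offset p is the same comparison as aligning revcomp(W) to the forward
    strand at p), so each placement found for a forward window against
    either target strand contributes 2 to the coverage of its span.
    """
    L = params.read_length
    mm = params.max_mismatch
    seq = genome.sequence
    n = len(seq)

    cov_len = n + (L - 1 if genome.circular else 0)
    diff = np.zeros(cov_len + 1, dtype=np.int64)

    if genome.circular:
        ext = seq + seq[: L - 1]
        n_offsets = n
    else:
        if n < L:
            warnings.warn(
                f"contig {genome.name!r} shorter than read length {L}; "
                "empty mask",
                stacklevel=2,
            )
            return MappabilityMask(
                contig=genome.name,
                read_length=L,
                self_coverage=np.zeros(n, dtype=np.int64),
                unique=np.zeros(n, dtype=bool),
            )
        ext = seq
        n_offsets = n - L + 1

    arr = _encode(ext)
    windows = np.lib.stride_tricks.sliding_window_view(arr, L)[:n_offsets]

    k = L // 2  # pigeonhole halves: [0, k) and [k, L)
    half1: dict[bytes, list[int]] = defaultdict(list)
    half2: dict[bytes, list[int]] = defaultdict(list)
    wbytes = [ext[o : o + L].encode() for o in range(n_offsets)]
    for o, wb in enumerate(wbytes):
        half1[wb[:k]].append(o)
        half2[wb[k:]].append(o)

    def placements(read_bytes: bytes) -> np.ndarray:
        """Offsets where read matches the forward target at Hamming <= mm."""
        if mm == 0:
            cand = half1.get(read_bytes[:k], [])
            out = [p for p in cand if wbytes[p] == read_bytes]
            return np.asarray(out, dtype=np.int64)
        cand = set(half1.get(read_bytes[:k], ()))
        cand.update(half2.get(read_bytes[k:], ()))
        if not cand:
            return np.empty(0, dtype=np.int64)
        idx = np.fromiter(cand, dtype=np.int64, count=len(cand))
        rv = np.frombuffer(read_bytes, dtype=np.uint8)
        dist = (windows[idx] != rv).sum(axis=1)
        return idx[dist <= mm]

    for o in range(n_offsets):
        wb = wbytes[o]
        rc = wb.translate(_COMPLEMENT)[::-1]
        for read in (wb, rc):
            for p in placements(read):
                diff[p] += 2
                diff[p + L] -= 2

    cov_ext = np.cumsum(diff[:-1])
    if genome.circular:
        cov = cov_ext[:n].copy()
        cov[: L - 1] += cov_ext[n:]
    else:
        cov = cov_ext

    return MappabilityMask(
        contig=genome.name,
        read_length=L,
        self_coverage=cov,
        unique=(cov == 2 * L),
    )


def unique_fraction(mask: MappabilityMask) -> tuple[float, int]:
    """Fraction of the contig that is uniquely mappable, and the base count."""
    count = int(mask.unique.sum())
    return count / len(mask), count
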
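"""Read-level preprocessing and contaminant-read detection.

Covers the short-read hygiene steps applied before assembly: force-trimming
the spurious extra cycle some runs emit, two-sided Phred/Mott quality
trimming, read-based GC%, detection of simple-sequence-repeat (SSR)
contaminant fragments present in both mates, k-mer matching against a
contaminant reference (with a Hamming-distance allowance), and seeded
pair subsampling.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .seqio import revcomp

__all__ = [
    "Read", "SSRMotif", "force_trim", "quality_trim", "read_gc_percent",
    "detect_ssr_contaminants", "filter_reads_by_kmer", "subsample_pairs",
]


@dataclass(frozen=True)
class Read:
    """A sequencing read: id, bases (ACGTN) and per-base Phred qualities."""

    id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self):
        if len(self.bases) != len(self.quals):
            raise ValueError(f"{self.id}: {len(self.bases)} bases vs "
                             f"{len(self.quals)} quality values")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class SSRMotif:
    """A simple-sequence-repeat unit in canonical rotation.

    The canonical form is the lexicographically smallest rotation of the
    unit or of its reverse complement, so a motif is invariant to phase
    and strand.
    """

    unit: str

    def __post_init__(self):
        if len(self.unit) not in (8, 10):
            raise ValueError("SSR unit length must be 8 or 10")

    @staticmethod
    def canonicalize(unit: str) -> "SSRMotif":
        n = len(unit)
        rc = revcomp(unit)
        best = min(min(unit[i:] + unit[:i] for i in range(n)),
                   min(rc[i:] + rc[:i] for i in range(n)))
        return SSRMotif(best)


def force_trim(read: Read, keep_length: int) -> Read:
    """Truncate a read to its first ``keep_length`` bases (BBDuk ftr-style).

    Reads already at or below the limit are returned unchanged.
    """
    if keep_length < 1:
        raise ValueError("keep_length must be >= 1")
    if len(read) <= keep_length:
        return read
    return Read(read.id, read.bases[:keep_length], read.quals[:keep_length])


def _mott_right_cut(quals: Sequence[int], q: int) -> int:
    """End index (exclusive) of the right cut under the Mott recurrence.

    Scanning left to right, s <- max(0, s + (q_i - q)); the cut is one past
    the last position where s attained its running maximum. Returns 0 when
    no position rises above the threshold.
    """
    s = 0
    best = 0
    cut = 0
    for i, qi in enumerate(quals):
        s = max(0, s + (qi - q))
        if s > best:
            best = s
            cut = i + 1
    return cut


def quality_trim(read: Read, q_threshold: int = 10,
                 min_length: int = 51) -> Optional[Read]:
    """Two-sided Phred/Mott quality trimming (BBDuk qtrim=rl semantics).

    Both ends are trimmed independently: the right cut point comes from a
    left-to-right Mott scan and the left cut point from the mirrored
    right-to-left scan. Returns ``None`` (discard) when the surviving
    window is shorter than ``min_length``.
    """
    if q_threshold < 0:
        raise ValueError("q_threshold must be >= 0")
    right = _mott_right_cut(read.quals, q_threshold)
    left = len(read) - _mott_right_cut(read.quals[::-1], q_threshold)
    if right <= left or right - left < min_length:
        return None
    return Read(read.id, read.bases[left:right], read.quals[left:right])


def read_gc_percent(reads: Iterable[Read | str]) -> float:
    """GC% of a read collection, N bases excluded from both counts."""
    gc = at = 0
    for r in reads:
        s = r if isinstance(r, str) else r.bases
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("no non-N bases in input")
    return 100.0 * gc / (gc + at)


def _ssr_dominant_motif(bases: str, periods: Sequence[int],
                        dominance: float) -> Optional[SSRMotif]:
    """Canonical motif whose tandem repeat covers >= dominance of the read.

    For period p, a maximal tandem run through position i extends while
    base[i] == base[i-p]; the run covers its p seed positions too. Ns never
    match.
    """
    n = len(bases)
    for p in periods:
        if n < 2 * p:
            continue
        run = 0
        for i in range(p, n):
            if bases[i] == bases[i - p] and bases[i] != "N":
                run += 1
            else:
                run = 0
            if run + p >= dominance * n:
                unit = bases[i - p + 1:i + 1]
                return SSRMotif.canonicalize(unit)
    return None


def detect_ssr_contaminants(read_pairs: Sequence[tuple[Read, Read]],
                            periods: Sequence[int] = (8, 10),
                            dominance: float = 0.8,
                            ) -> tuple[set[SSRMotif], list[str]]:
    """Flag read pairs whose BOTH mates are dominated by the same SSR.

    A read is SSR-dominated when a period-8 or period-10 tandem repeat (any
    rotation, either strand) covers at least ``dominance`` of its length;
    only fragments showing the same canonical motif on both mates are
    called contaminants, since genuine genomic SSR loci rarely fill both
    reads of a 350 bp insert.
    """
    motifs: set[SSRMotif] = set()
    flagged: list[str] = []
    for r1, r2 in read_pairs:
        m1 = _ssr_dominant_motif(r1.bases, periods, dominance)
        if m1 is None:
            continue
        m2 = _ssr_dominant_motif(r2.bases, periods, dominance)
        if m2 == m1:
            motifs.add(m1)
            flagged.append(r1.id)
    return motifs, flagged


def _kmer_index(seqs: Iterable[str], k: int) -> tuple[dict, dict, int]:
    """Index contaminant k-mers by exact halves for pigeonhole lookup."""
    half = k // 2
    left: dict[str, list[str]] = defaultdict(list)
    right: dict[str, list[str]] = defaultdict(list)
    for seq in seqs:
        for s in (seq, revcomp(seq)):
            for i in range(len(s) - k + 1):
                km = s[i:i + k]
                left[km[:half]].append(km)
                right[km[half:]].append(km)
    return left, right, half


def _hamming_le(a: str, b: str, limit: int) -> bool:
    d = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            d += 1
            if d > limit:
                return False
    return True


def _read_matches(bases: str, left: dict, right: dict, half: int,
                  k: int, hdist: int) -> bool:
    for i in range(len(bases) - k + 1):
        window = bases[i:i + k]
        # pigeonhole: a window within hdist<=1 of an indexed k-mer agrees
        # exactly on at least one half
        for cand in left.get(window[:half], ()):
            if _hamming_le(window, cand, hdist):
                return True
        for cand in right.get(window[half:], ()):
            if _hamming_le(window, cand, hdist):
                return True
    return False


def filter_reads_by_kmer(read_pairs: Sequence[tuple[Read, Read]],
                         contaminant_seqs: Sequence[str],
                         k: int = 75, hdist: int = 1,
                         ) -> list[tuple[Read, Read]]:
    """Remove pairs where either mate shares a k-mer with a contaminant.

    A mate matches when any of its length-k windows lies within Hamming
    distance ``hdist`` of any length-k window of a contaminant sequence on
    either strand (BBDuk k/hdist semantics). N positions count as
    mismatches. Survivors pass through untouched.
    """
    if hdist > 1:
        raise ValueError("pigeonhole matcher supports hdist <= 1")
    if not contaminant_seqs:
        return list(read_pairs)
    left, right, half = _kmer_index(contaminant_seqs, k)
    survivors = []
    for r1, r2 in read_pairs:
        if len(r1) < k and len(r2) < k:
            survivors.append((r1, r2))
            continue
        if (_read_matches(r1.bases, left, right, half, k, hdist)
                or _read_matches(r2.bases, left, right, half, k, hdist)):
            continue
        survivors.append((r1, r2))
    return survivors


def subsample_pairs(read_pairs: Sequence[tuple[Read, Read]], rate: float,
                    seed: int) -> list[tuple[Read, Read]]:
    """Keep each pair independently with probability ``rate`` (seeded)."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    keep = rng.random(len(read_pairs)) < rate
    return [p for p, k in zip(read_pairs, keep) if k]
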
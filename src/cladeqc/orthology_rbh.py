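"""Reciprocal-best-hit enhancer orthology and alignment summary statistics.

Given ~2 kb feature tiles annotated on a reference genome and their
liftOver remappings onto a second genome, orthology is tested the classic
way: the remapped sequence is aligned back to the reference genome and
the tile sequence to the second genome; a tile is a reciprocal best hit
(RBH) when each direction's highest-scoring local alignment overlaps the
expected location (>= 1 bp). For RBH pairs, the tile-vs-ortholog
alignment is reduced to non-overlapping hits (lower-scoring hits nested
in higher-scoring ones removed, partial overlaps trimmed on the query)
and summarized as query coverage and length-weighted percent identity.

The built-in aligner is an exact affine-gap Smith-Waterman (numba
kernel) with BLASTN-style nucleotide scoring (reward +2, penalty -3, gap
open 5, gap extend 2; a length-L gap costs 5 + 2L). Against genome-scale
subjects, exact word-11 seeds restrict the DP to candidate windows;
small subjects are aligned in full, so the reported top score is exact.
E-values follow the Karlin-Altschul form E = K*m*n*exp(-lambda*S); the
(lambda, K) pair is configuration with defaults for this scoring scheme,
and only the E-value's monotone behavior is relied on.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .seqio import BedInterval, revcomp

__all__ = [
    "ScoringScheme", "AlignmentHit", "RBHResult", "evalue_threshold",
    "local_align", "best_hit", "classify_rbh", "trim_overlapping_hits",
    "alignment_summary", "GenomeAligner", "rbh_screen",
    "read_tabular_hits", "write_tabular_hits",
]

_ENC = np.zeros(256, dtype=np.uint8) + 4  # non-ACGT -> 4 (N)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_MASKED = 5  # sentinel for query positions consumed by an earlier hit


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    # Karlin-Altschul constants for E = K*m*n*exp(-lam*S) under this scheme
    lam: float = 0.625
    k_const: float = 0.41

    def evalue(self, score: float, m: int, n: int) -> float:
        return self.k_const * m * n * math.exp(-self.lam * score)

    def min_score(self, e_max: float, m: int, n: int) -> float:
        return math.log(self.k_const * m * n / e_max) / self.lam


DEFAULT_SCORING = ScoringScheme()


def evalue_threshold(n_fragments: int) -> float:
    """Reciprocal of the fragment count, rounded to 2 significant figures."""
    if n_fragments < 1:
        raise ValueError("need at least one fragment")
    e = 1.0 / n_fragments
    return float(f"{e:.1e}")


@dataclass(frozen=True)
class AlignmentHit:
    """A local alignment hit; query coords are forward-strand 0-based."""

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    score: int
    percent_identity: float
    alignment_length: int  # query-side bases
    e_value: float
    mismatches: int = 0
    gap_opens: int = 0
    trimmed: bool = False


@njit(cache=True)
def _sw_kernel(q, s, match, mismatch, gap_open, gap_extend):
    """Affine-gap local alignment; returns pointer matrices + best cell.

    States: H (match/mismatch), E (gap consuming subject), F (gap
    consuming query). ptr_h: 0 stop, 1 diag, 2 from E, 3 from F.
    ptr_e/ptr_f: 1 when the gap extends an existing gap.
    Codes > 3 score mismatch; code 5 (masked) is effectively forbidden.
    """
    m, n = len(q), len(s)
    NEG = -(1 << 28)
    h_prev = np.zeros(n + 1, np.int32)
    h_cur = np.zeros(n + 1, np.int32)
    f_row = np.full(n + 1, NEG, np.int32)
    ptr_h = np.zeros((m + 1, n + 1), np.uint8)
    ptr_e = np.zeros((m + 1, n + 1), np.uint8)
    ptr_f = np.zeros((m + 1, n + 1), np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        e_val = NEG
        h_cur[0] = 0
        qa = q[i - 1]
        for j in range(1, n + 1):
            eo = h_cur[j - 1] - gap_open - gap_extend
            ee = e_val - gap_extend
            if ee > eo:
                e_val = ee
                ptr_e[i, j] = 1
            else:
                e_val = eo
            fo = h_prev[j] - gap_open - gap_extend
            fe = f_row[j] - gap_extend
            if fe > fo:
                f_row[j] = fe
                ptr_f[i, j] = 1
            else:
                f_row[j] = fo
            sb = s[j - 1]
            if qa > 3 or sb > 3:
                sub = -(1 << 24) if (qa == 5 or sb == 5) else mismatch
            elif qa == sb:
                sub = match
            else:
                sub = mismatch
            d = h_prev[j - 1] + sub
            h = 0
            p = 0
            if d > h:
                h = d
                p = 1
            if e_val > h:
                h = e_val
                p = 2
            if f_row[j] > h:
                h = f_row[j]
                p = 3
            h_cur[j] = h
            ptr_h[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
        h_prev, h_cur = h_cur, h_prev
    return best, bi, bj, ptr_h, ptr_e, ptr_f


def _traceback(q, s, bi, bj, ptr_h, ptr_e, ptr_f):
    """Walk pointers from the best cell; returns hit geometry and counts."""
    i, j = bi, bj
    matches = mismatches = gap_opens = 0
    state = "H"
    while True:
        if state == "H":
            p = ptr_h[i, j]
            if p == 0:
                break
            if p == 1:
                if q[i - 1] == s[j - 1] and q[i - 1] <= 3:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ext = ptr_e[i, j]
            j -= 1
            if not ext:
                gap_opens += 1
                state = "H"
        else:
            ext = ptr_f[i, j]
            i -= 1
            if not ext:
                gap_opens += 1
                state = "H"
    return i, j, matches, mismatches, gap_opens


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def _align_masked(q_codes, s_codes, scoring):
    """One exact SW pass; returns geometry or None when nothing aligns."""
    best, bi, bj, ph, pe, pf = _sw_kernel(
        q_codes, s_codes, scoring.match, scoring.mismatch,
        scoring.gap_open, scoring.gap_extend)
    if best <= 0:
        return None
    i0, j0, matches, mismatches, gap_opens = _traceback(
        q_codes, s_codes, bi, bj, ph, pe, pf)
    return best, i0, bi, j0, bj, matches, mismatches, gap_opens


def local_align(query: str, subject: str,
                scoring: ScoringScheme = DEFAULT_SCORING,
                e_max: float = 10.0,
                query_id: str = "query", subject_id: str = "subject",
                max_hits: int = 10,
                search_space: Optional[tuple[int, int]] = None,
                subject_offset: int = 0,
                strands: str = "+-") -> list[AlignmentHit]:
    """Exact local alignments of query vs subject, best-first.

    Both strands are searched; after each hit the consumed query interval
    is masked and the alignment repeated, yielding the next-best
    non-query-overlapping hit, until the E-value threshold or ``max_hits``
    is reached. ``search_space`` (m, n) overrides the E-value search-space
    sizes when the subject is a window of a larger sequence (whose start
    is ``subject_offset``).
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    m, n = search_space if search_space else (len(query), len(subject))
    min_score = scoring.min_score(e_max, m, n)
    qlen = len(query)
    s_codes = _encode(subject)
    q_fwd = _encode(query)
    q_rev = _encode(revcomp(query))
    mask = np.zeros(qlen, dtype=bool)
    hits: list[AlignmentHit] = []
    while len(hits) < max_hits:
        q_fwd_m = q_fwd.copy()
        q_fwd_m[mask] = _MASKED
        q_rev_m = q_rev.copy()
        q_rev_m[mask[::-1]] = _MASKED
        candidates = []
        if "+" in strands:
            r = _align_masked(q_fwd_m, s_codes, scoring)
            if r:
                candidates.append(("+", r))
        if "-" in strands:
            r = _align_masked(q_rev_m, s_codes, scoring)
            if r:
                candidates.append(("-", r))
        if not candidates:
            break
        strand, (score, qi0, qi1, sj0, sj1, mat, mis, gaps) = max(
            candidates, key=lambda c: c[1][0])
        if score < min_score:
            break
        if strand == "+":
            q_start, q_end = qi0, qi1
        else:
            q_start, q_end = qlen - qi1, qlen - qi0
        cols = mat + mis  # aligned (non-gap) columns
        hits.append(AlignmentHit(
            query_id=query_id, subject_id=subject_id,
            q_start=q_start, q_end=q_end,
            s_start=subject_offset + sj0, s_end=subject_offset + sj1,
            strand=strand, score=int(score),
            percent_identity=100.0 * mat / cols if cols else 0.0,
            alignment_length=q_end - q_start,
            e_value=scoring.evalue(score, m, n),
            mismatches=mis, gap_opens=gaps))
        mask[q_start:q_end] = True
        if mask.all():
            break
    return hits


def best_hit(hits: Sequence[AlignmentHit]) -> AlignmentHit:
    """Highest raw score; ties -> longer hit, then (subject_id, s_start)."""
    if not hits:
        raise ValueError("no hits")
    return sorted(hits, key=lambda h: (-h.score, -h.alignment_length,
                                       h.subject_id, h.s_start))[0]


@dataclass
class RBHResult:
    fragment_id: str
    remapped: Optional[BedInterval]
    forward_best_overlaps: bool = False
    reverse_best_overlaps: bool = False
    query_coverage: Optional[float] = None
    weighted_identity: Optional[float] = None

    @property
    def is_rbh(self) -> bool:
        return self.forward_best_overlaps and self.reverse_best_overlaps


def _overlaps(hit: AlignmentHit, interval: BedInterval) -> bool:
    return (hit.subject_id == interval.chrom
            and hit.s_start < interval.end and interval.start < hit.s_end)


def classify_rbh(fragment: BedInterval, lifted: BedInterval,
                 best_hit_2to1: Optional[AlignmentHit],
                 best_hit_1to2: Optional[AlignmentHit]) -> RBHResult:
    """Bidirectional best-hit test for one fragment.

    Forward criterion: the best hit of the lifted genome-2 sequence back
    onto genome 1 overlaps (>= 1 bp) the original fragment interval.
    Reverse criterion: the best hit of the genome-1 fragment onto genome 2
    overlaps the lifted interval. RBH requires both.
    """
    fwd = best_hit_2to1 is not None and _overlaps(best_hit_2to1, fragment)
    rev = best_hit_1to2 is not None and _overlaps(best_hit_1to2, lifted)
    return RBHResult(fragment.name, lifted, fwd, rev)


def trim_overlapping_hits(hits: Sequence[AlignmentHit]) -> list[AlignmentHit]:
    """Reduce one query's hits to non-overlapping query intervals.

    Hits are processed in descending score (ties: longer, then leftmost).
    A hit nested entirely inside already-occupied query positions is
    dropped; a partially overlapping hit is trimmed to its longest free
    contiguous stretch, its query-side length reduced accordingly and its
    subject coordinates proportionally adjusted (flagged ``trimmed``).
    """
    occupied: list[tuple[int, int]] = []

    def free_runs(a: int, b: int) -> list[tuple[int, int]]:
        runs = []
        cur = a
        for s, e in sorted(occupied):
            if e <= cur or s >= b:
                continue
            if s > cur:
                runs.append((cur, min(s, b)))
            cur = max(cur, e)
        if cur < b:
            runs.append((cur, b))
        return runs

    out = []
    for h in sorted(hits, key=lambda h: (-h.score, -h.alignment_length,
                                         h.q_start)):
        runs = free_runs(h.q_start, h.q_end)
        if not runs:
            continue
        a, b = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
        if (a, b) == (h.q_start, h.q_end):
            out.append(h)
        else:
            frac0 = (a - h.q_start) / h.alignment_length
            frac1 = (h.q_end - b) / h.alignment_length
            s_len = h.s_end - h.s_start
            if h.strand == "+":
                s0 = h.s_start + round(frac0 * s_len)
                s1 = h.s_end - round(frac1 * s_len)
            else:
                s0 = h.s_start + round(frac1 * s_len)
                s1 = h.s_end - round(frac0 * s_len)
            out.append(replace(h, q_start=a, q_end=b,
                               alignment_length=b - a,
                               s_start=min(s0, s1), s_end=max(s0, s1),
                               trimmed=True))
        occupied.append((a, b))
    return out


def alignment_summary(trimmed_hits: Sequence[AlignmentHit],
                      query_length: int
                      ) -> tuple[float, Optional[float]]:
    """(query coverage %, length-weighted percent identity) of one query."""
    if not trimmed_hits:
        return 0.0, None
    covered = set()
    for h in trimmed_hits:
        covered.update(range(h.q_start, h.q_end))
    total_len = sum(h.alignment_length for h in trimmed_hits)
    weighted = sum(h.alignment_length * h.percent_identity
                   for h in trimmed_hits) / total_len
    return 100.0 * len(covered) / query_length, weighted


class GenomeAligner:
    """Aligns queries against a multi-scaffold genome, seeding when large.

    Scaffolds small enough for direct DP are aligned in full; larger ones
    are scanned for exact ``word``-length seed matches (both strands),
    seeds are clustered by diagonal, and the exact DP runs on padded
    windows around each cluster. Word indexes are built once per scaffold.
    """

    def __init__(self, genome: dict[str, str],
                 scoring: ScoringScheme = DEFAULT_SCORING,
                 word: int = 11, direct_limit: int = 2_000_000):
        self.genome = genome
        self.scoring = scoring
        self.word = word
        self.direct_limit = direct_limit
        self._indexes: dict[str, dict[str, list[int]]] = {}

    def _index(self, name: str) -> dict[str, list[int]]:
        if name not in self._indexes:
            seq = self.genome[name]
            w = self.word
            idx: dict[str, list[int]] = defaultdict(list)
            for i in range(len(seq) - w + 1):
                kw = seq[i:i + w]
                if "N" not in kw:
                    idx[kw].append(i)
            self._indexes[name] = idx
        return self._indexes[name]

    def _windows(self, query: str, name: str) -> list[tuple[str, int, int]]:
        """(strand, lo, hi) subject windows around seed diagonal clusters."""
        idx = self._index(name)
        w = self.word
        qlen = len(query)
        slen = len(self.genome[name])
        pad = min(qlen, 500)
        out: list[tuple[str, int, int]] = []
        for strand, qseq in (("+", query), ("-", revcomp(query))):
            diags: list[tuple[int, int, int]] = []
            for qi in range(0, len(qseq) - w + 1, 2):
                for si in idx.get(qseq[qi:qi + w], ()):
                    diags.append((si - qi, si, qi))
            if not diags:
                continue
            diags.sort()
            clusters: list[list[tuple[int, int]]] = [[]]
            prev_d = None
            for d, si, qi in diags:
                if prev_d is not None and d - prev_d > 64:
                    clusters.append([])
                clusters[-1].append((si, qi))
                prev_d = d
            # two seeds on one diagonal band rules out chance 11-mer matches
            raw = []
            for cl in clusters:
                if len(cl) < 2:
                    continue
                # subject range the full query occupies on these diagonals
                lo = max(0, min(si - qi for si, qi in cl) - pad)
                hi = min(slen, max(si + (qlen - qi) for si, qi in cl) + pad)
                raw.append((lo, hi))
            if not raw:
                continue
            raw.sort()
            merged = [raw[0]]
            for lo, hi in raw[1:]:
                if lo <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
                else:
                    merged.append((lo, hi))
            out.extend((strand, lo, hi) for lo, hi in merged)
        return out

    def align(self, query: str, query_id: str = "query",
              e_max: float = 10.0, max_hits: int = 10) -> list[AlignmentHit]:
        hits: list[AlignmentHit] = []
        total_n = sum(len(s) for s in self.genome.values())
        for name, seq in self.genome.items():
            if len(query) * len(seq) <= self.direct_limit:
                hits.extend(local_align(
                    query, seq, self.scoring, e_max, query_id, name,
                    max_hits, search_space=(len(query), total_n)))
            else:
                for strand, lo, hi in self._windows(query, name):
                    hits.extend(local_align(
                        query, seq[lo:hi], self.scoring, e_max, query_id,
                        name, max_hits,
                        search_space=(len(query), total_n),
                        subject_offset=lo, strands=strand))
        hits.sort(key=lambda h: (-h.score, -h.alignment_length,
                                 h.subject_id, h.s_start))
        return hits[:max_hits]


def rbh_screen(genome1: dict[str, str], genome2: dict[str, str],
               tiles: Sequence[BedInterval], chains,
               scoring: ScoringScheme = DEFAULT_SCORING,
               min_match: float = 0.1,
               e_max: Optional[float] = None) -> list[RBHResult]:
    """End-to-end enhancer-orthology screen.

    For each tile on genome 1: liftOver through the chains (largest span
    retained on multiple remappings), bidirectional best-hit test, and -
    for RBH pairs - trimmed-hit query coverage and length-weighted
    identity of the tile-vs-ortholog alignment. Tiles that fail to remap
    come back with ``remapped=None``.
    """
    from .coordinate_lift import lift_interval, select_largest_span

    if e_max is None:
        e_max = evalue_threshold(len(tiles))
    a1 = GenomeAligner(genome1, scoring)
    a2 = GenomeAligner(genome2, scoring)
    results = []
    for tile in tiles:
        lr = lift_interval(tile, chains, min_match=min_match, multiple=True)
        if lr.unmapped:
            results.append(RBHResult(tile.name, None))
            continue
        span = select_largest_span(lr)
        lifted = BedInterval(span.q_name, span.start, span.end, tile.name,
                             strand=span.strand)
        seq2 = genome2[lifted.chrom][lifted.start:lifted.end]
        seq1 = genome1[tile.chrom][tile.start:tile.end]
        back = a1.align(seq2, query_id=tile.name, e_max=e_max, max_hits=1)
        fwd = a2.align(seq1, query_id=tile.name, e_max=e_max, max_hits=1)
        res = classify_rbh(tile, lifted,
                           best_hit(back) if back else None,
                           best_hit(fwd) if fwd else None)
        if res.is_rbh:
            pair_hits = local_align(seq1, seq2, scoring, e_max,
                                    tile.name, lifted.chrom, max_hits=10)
            cov, wid = alignment_summary(trim_overlapping_hits(pair_hits),
                                         len(seq1))
            res.query_coverage = cov
            res.weighted_identity = wid
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# 12-column blast-tabular adapter (1-based inclusive coordinates on disk)

def write_tabular_hits(path, hits: Sequence[AlignmentHit]) -> None:
    with open(path, "w") as fh:
        for h in hits:
            if h.strand == "+":
                ss, se = h.s_start + 1, h.s_end
            else:
                ss, se = h.s_end, h.s_start + 1
            fh.write("\t".join(str(x) for x in (
                h.query_id, h.subject_id, f"{h.percent_identity:.2f}",
                h.alignment_length, h.mismatches, h.gap_opens,
                h.q_start + 1, h.q_end, ss, se,
                f"{h.e_value:.2e}", h.score)) + "\n")


def read_tabular_hits(path) -> list[AlignmentHit]:
    """Read externally produced 12-column tabular hits (outfmt-6 dialect)."""
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            qs, qe = int(f[6]) - 1, int(f[7])
            ss, se = int(f[8]), int(f[9])
            if ss <= se:
                strand, s0, s1 = "+", ss - 1, se
            else:
                strand, s0, s1 = "-", se - 1, ss
            hits.append(AlignmentHit(
                query_id=f[0], subject_id=f[1], q_start=qs, q_end=qe,
                s_start=s0, s_end=s1, strand=strand,
                score=int(round(float(f[11]))),
                percent_identity=float(f[2]),
                alignment_length=int(f[3]), e_value=float(f[10]),
                mismatches=int(f[4]), gap_opens=int(f[5])))
    return hits
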
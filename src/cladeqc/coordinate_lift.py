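"""UCSC chain parsing and liftOver-style interval remapping.

A chain records a co-linear pairwise alignment as a header (target and
query coordinates, strands, score) plus an ordered list of gapless blocks
separated by target-only (dt) and query-only (dq) gaps. Interval
remapping projects every base of a target interval that falls inside an
aligned block through its block's offset; a remapping is reported when at
least ``min_match`` of the interval's bases project (liftOver's
-minMatch), one result per qualifying chain (-multiple). Chain gaps
interior to the projection are bridged: the reported query interval spans
min..max of the projected positions. Minus-strand query coordinates
follow the UCSC convention (coordinates on the reversed sequence) and are
converted to forward-strand coordinates on output.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .seqio import BedInterval

__all__ = ["ChainBlock", "Chain", "RemappedInterval", "LiftResult",
           "parse_chain", "write_chain", "lift_interval",
           "select_largest_span"]


@dataclass(frozen=True)
class ChainBlock:
    size: int
    dt: int = 0  # gap on target after this block (absent on last block)
    dq: int = 0  # gap on query after this block


@dataclass
class Chain:
    score: float
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: int
    blocks: list[ChainBlock]
    t_strand: str = "+"

    def __post_init__(self):
        t_span = sum(b.size + b.dt for b in self.blocks)
        q_span = sum(b.size + b.dq for b in self.blocks)
        if t_span != self.t_end - self.t_start:
            raise ValueError(f"chain {self.chain_id}: target block span "
                             f"{t_span} != header span {self.t_end - self.t_start}")
        if q_span != self.q_end - self.q_start:
            raise ValueError(f"chain {self.chain_id}: query block span "
                             f"{q_span} != header span {self.q_end - self.q_start}")
        if self.t_strand != "+":
            raise ValueError("target strand must be +")
        if self.q_strand not in "+-":
            raise ValueError("query strand must be + or -")


def parse_chain(text_or_path) -> list[Chain]:
    """Parse UCSC chain text (or a path to a chain file)."""
    p = Path(str(text_or_path))
    if "\n" not in str(text_or_path) and p.is_file():
        text = p.read_text()
    else:
        text = str(text_or_path)
    chains: list[Chain] = []
    header = None
    blocks: list[ChainBlock] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("chain"):
            if header is not None:
                raise ValueError(f"line {lineno}: chain without terminating "
                                 "bare-size block line")
            f = line.split()
            if len(f) != 13:
                raise ValueError(f"line {lineno}: malformed chain header")
            header = f
            blocks = []
        else:
            if header is None:
                raise ValueError(f"line {lineno}: block outside a chain")
            f = line.split()
            if len(f) == 3:
                blocks.append(ChainBlock(int(f[0]), int(f[1]), int(f[2])))
            elif len(f) == 1:
                blocks.append(ChainBlock(int(f[0])))
                chains.append(Chain(
                    score=float(header[1]),
                    t_name=header[2], t_size=int(header[3]),
                    t_start=int(header[5]), t_end=int(header[6]),
                    q_name=header[7], q_size=int(header[8]),
                    q_strand=header[9],
                    q_start=int(header[10]), q_end=int(header[11]),
                    chain_id=int(header[12]), blocks=blocks,
                    t_strand=header[4],
                ))
                header = None
            else:
                raise ValueError(f"line {lineno}: malformed block line")
    if header is not None:
        raise ValueError("truncated chain at end of input")
    return chains


def write_chain(path, chains: Iterable[Chain]) -> None:
    with open(path, "w") as fh:
        for c in chains:
            fh.write(f"chain {c.score:g} {c.t_name} {c.t_size} {c.t_strand} "
                     f"{c.t_start} {c.t_end} {c.q_name} {c.q_size} "
                     f"{c.q_strand} {c.q_start} {c.q_end} {c.chain_id}\n")
            for b in c.blocks[:-1]:
                fh.write(f"{b.size}\t{b.dt}\t{b.dq}\n")
            fh.write(f"{c.blocks[-1].size}\n\n")


@dataclass(frozen=True)
class RemappedInterval:
    q_name: str
    start: int
    end: int
    strand: str
    chain_id: int
    bases_mapped: int

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class LiftResult:
    source: BedInterval
    remapped: list[RemappedInterval]

    @property
    def unmapped(self) -> bool:
        return not self.remapped


def _project_through(chain: Chain, start: int, end: int
                     ) -> Optional[RemappedInterval]:
    """Project [start, end) on the target through one chain's blocks."""
    tcur, qcur = chain.t_start, chain.q_start
    bases = 0
    qmin = qmax = None
    for b in chain.blocks:
        lo = max(start, tcur)
        hi = min(end, tcur + b.size)
        if lo < hi:
            q_lo = qcur + (lo - tcur)
            q_hi = qcur + (hi - tcur)
            qmin = q_lo if qmin is None else min(qmin, q_lo)
            qmax = q_hi if qmax is None else max(qmax, q_hi)
            bases += hi - lo
        tcur += b.size + b.dt
        qcur += b.size + b.dq
        if tcur >= end:
            break
    if bases == 0:
        return None
    if chain.q_strand == "-":
        fwd_start, fwd_end = chain.q_size - qmax, chain.q_size - qmin
    else:
        fwd_start, fwd_end = qmin, qmax
    return RemappedInterval(chain.q_name, fwd_start, fwd_end,
                            chain.q_strand, chain.chain_id, bases)


def lift_interval(interval: BedInterval, chains: Sequence[Chain],
                  min_match: float = 0.1,
                  multiple: bool = True) -> LiftResult:
    """Remap a target interval through chains.

    One candidate remapping per chain whose aligned blocks capture at
    least ``min_match`` of the interval's bases; with ``multiple=False``
    only the highest-scoring qualifying chain's remapping is kept.
    """
    if not 0 < min_match <= 1:
        raise ValueError("min_match must be in (0, 1]")
    hits: list[tuple[float, RemappedInterval]] = []
    for chain in chains:
        if chain.t_name != interval.chrom:
            continue
        r = _project_through(chain, interval.start, interval.end)
        if r is not None and r.bases_mapped / interval.length >= min_match:
            hits.append((chain.score, r))
    if not multiple and hits:
        hits = [max(hits, key=lambda sr: sr[0])]
    return LiftResult(interval, [r for _, r in hits])


def select_largest_span(result: LiftResult) -> RemappedInterval:
    """Pick the remapping with the largest coordinate span.

    Ties go to the remapping with more aligned bases, then to the lower
    chain id.
    """
    if result.unmapped:
        raise ValueError("no remapped intervals to choose from")
    return max(result.remapped,
               key=lambda r: (r.span, r.bases_mapped, -r.chain_id))
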
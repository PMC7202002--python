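"""Assembly-level contamination screening by GC% x k-mer coverage.

Contaminant scaffolds (bacteria, yeast) in an insect assembly usually
separate from the host cloud in a plot of per-scaffold GC% against average
read-k-mer coverage: their base composition differs and their abundance in
the library rarely matches the host's. This module computes per-scaffold
signatures from a read-derived k-mer count table and applies a rectangular
gate on the two axes to nominate candidate contaminant scaffolds. The
gates are sample-specific configuration; confirmation against a sequence
database is deliberately outside the computational core, so the module
accepts an externally confirmed id list when emitting the contaminant
reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .kmer_profile import KmerCounts, iter_codes
from .scaffold_ops import ScaffoldRecord

__all__ = ["ScaffoldSignature", "scaffold_signatures", "classify_candidates",
           "contaminant_reference"]


@dataclass(frozen=True)
class ScaffoldSignature:
    scaffold_id: str
    gc_percent: float
    avg_kmer_coverage: float
    length: int


def scaffold_signatures(assembly: Sequence[ScaffoldRecord],
                        counts: KmerCounts,
                        min_length: int = 1000) -> list[ScaffoldSignature]:
    """Per-scaffold GC% and mean read-spectrum k-mer multiplicity.

    GC is computed over ACGT only; coverage averages the read-count-table
    multiplicity of the scaffold's canonical k-mers (N-containing windows
    skipped). Scaffolds shorter than ``min_length`` are excluded;
    scaffolds shorter than k raise.
    """
    k = counts.k
    out = []
    for scaf in assembly:
        if len(scaf) < min_length:
            continue
        if len(scaf) < k:
            raise ValueError(f"{scaf.id} shorter than k={k}")
        s = scaf.bases
        gc = s.count("G") + s.count("C")
        at = s.count("A") + s.count("T")
        n_win = 0
        total = 0
        for code in iter_codes(s, k):
            total += counts.counts.get(code, 0)
            n_win += 1
        out.append(ScaffoldSignature(
            scaf.id,
            100.0 * gc / (gc + at) if gc + at else 0.0,
            total / n_win if n_win else 0.0,
            len(scaf)))
    return out


def classify_candidates(signatures: Sequence[ScaffoldSignature],
                        gc_range: tuple[float, float],
                        cov_range: tuple[float, float]) -> list[str]:
    """Ids of scaffolds inside the rectangular (GC, coverage) gate.

    Both bounds on both axes are inclusive.
    """
    gc_lo, gc_hi = gc_range
    cov_lo, cov_hi = cov_range
    if gc_lo > gc_hi or cov_lo > cov_hi:
        raise ValueError("gate lower bound exceeds upper bound")
    return [s.scaffold_id for s in signatures
            if gc_lo <= s.gc_percent <= gc_hi
            and cov_lo <= s.avg_kmer_coverage <= cov_hi]


def contaminant_reference(assembly: Sequence[ScaffoldRecord],
                          candidate_ids: Sequence[str],
                          confirmed_ids: Optional[Sequence[str]] = None,
                          ) -> dict[str, str]:
    """Contaminant reference sequences from (optionally confirmed) candidates.

    When an externally produced confirmation list is supplied, only
    candidates on it are emitted; otherwise all candidates are.
    """
    wanted = set(candidate_ids)
    if confirmed_ids is not None:
        wanted &= set(confirmed_ids)
    return {s.id: s.bases for s in assembly if s.id in wanted}
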
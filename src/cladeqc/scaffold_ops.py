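"""Assembly-sequence surgery.

Post-assembly scaffold editing: splitting scaffolds at implausibly large
gaps (N-runs longer than the library insert can support), extracting
contigs by splitting on every N, hard-masking regions with a fixed-length
N block, resolving residual IUPAC ambiguity codes, dropping sub-kilobase
scaffolds, and excising contaminant spans (trim at scaffold ends, split in
the middle).

All coordinates are 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScaffoldRecord", "split_on_oversized_gaps", "extract_contigs",
    "hard_mask_region", "resolve_ambiguities", "drop_short_scaffolds",
    "excise_contaminant_span",
]

_N_RUN = re.compile("N+")
IUPAC_OPTIONS = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
}
_VALID = set("ACGTN") | set(IUPAC_OPTIONS)


@dataclass
class ScaffoldRecord:
    """A scaffold sequence with its maximal N-run (gap) coordinates."""

    id: str
    bases: str
    gap_runs: list[tuple[int, int]] = field(init=False)

    def __post_init__(self):
        self.gap_runs = [m.span() for m in _N_RUN.finditer(self.bases)]

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def total_gap_length(self) -> int:
        return sum(e - s for s, e in self.gap_runs)


def split_on_oversized_gaps(scaffold: ScaffoldRecord,
                            max_gap: int = 600) -> list[ScaffoldRecord]:
    """Split a scaffold at every N-run longer than ``max_gap``.

    Gap runs of length <= max_gap (the threshold is inclusive) are retained
    verbatim; children are named ``id.1``, ``id.2``, ... left to right.
    A scaffold with no oversized gap is returned as-is under its original
    name.
    """
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    cuts = [(s, e) for s, e in scaffold.gap_runs if e - s > max_gap]
    if not cuts:
        return [scaffold]
    pieces = []
    prev = 0
    for s, e in cuts:
        if s > prev:
            pieces.append(scaffold.bases[prev:s])
        prev = e
    if prev < len(scaffold):
        pieces.append(scaffold.bases[prev:])
    return [ScaffoldRecord(f"{scaffold.id}.{i}", p)
            for i, p in enumerate(pieces, start=1)]


def extract_contigs(scaffold: ScaffoldRecord) -> list[ScaffoldRecord]:
    """Maximal N-free runs, in order (split on every N, including single Ns)."""
    out = []
    for i, piece in enumerate(_N_RUN.split(scaffold.bases), start=1):
        if piece:
            out.append(ScaffoldRecord(f"{scaffold.id}.ctg{i}", piece))
    return out


def hard_mask_region(scaffold: ScaffoldRecord, start: int, end: int,
                     mask_length: int = 300) -> ScaffoldRecord:
    """Replace [start, end) with exactly ``mask_length`` Ns.

    Used to hard-mask single-N seams (tandem-allele artifacts) together
    with their flanking sequence; downstream coordinates shift by
    ``mask_length - (end - start)``.
    """
    if not 0 <= start < end <= len(scaffold):
        raise ValueError(f"region [{start},{end}) out of bounds for "
                         f"{scaffold.id} (length {len(scaffold)})")
    return ScaffoldRecord(scaffold.id,
                          scaffold.bases[:start] + "N" * mask_length
                          + scaffold.bases[end:])


def resolve_ambiguities(scaffold: ScaffoldRecord, seed: int) -> ScaffoldRecord:
    """Assign each non-N IUPAC ambiguity code to a random compatible base.

    N is left untouched; the draw is uniform over the encoded bases and
    deterministic under ``seed``.
    """
    bad = set(scaffold.bases) - _VALID
    if bad:
        raise ValueError(f"non-IUPAC characters in {scaffold.id}: {sorted(bad)}")
    if not (set(scaffold.bases) & set(IUPAC_OPTIONS)):
        return scaffold
    rng = np.random.default_rng(seed)
    out = list(scaffold.bases)
    for i, b in enumerate(out):
        options = IUPAC_OPTIONS.get(b)
        if options:
            out[i] = options[rng.integers(len(options))]
    return ScaffoldRecord(scaffold.id, "".join(out))


def drop_short_scaffolds(assembly: list[ScaffoldRecord],
                         min_length: int = 1000) -> list[ScaffoldRecord]:
    """Remove scaffolds shorter than ``min_length`` (>= is kept)."""
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    return [s for s in assembly if len(s) >= min_length]


def excise_contaminant_span(scaffold: ScaffoldRecord,
                            span: tuple[int, int]) -> list[ScaffoldRecord]:
    """Remove a contaminant span: trim if terminal, split if internal.

    Returns zero (span covers the scaffold), one (terminal trim) or two
    (internal split, children ``id.1``/``id.2``) scaffolds.
    """
    start, end = span
    if not 0 <= start < end <= len(scaffold):
        raise ValueError(f"span [{start},{end}) out of bounds")
    if start == 0 and end == len(scaffold):
        return []
    if start == 0:
        return [ScaffoldRecord(scaffold.id, scaffold.bases[end:])]
    if end == len(scaffold):
        return [ScaffoldRecord(scaffold.id, scaffold.bases[:start])]
    return [ScaffoldRecord(f"{scaffold.id}.1", scaffold.bases[:start]),
            ScaffoldRecord(f"{scaffold.id}.2", scaffold.bases[end:])]
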
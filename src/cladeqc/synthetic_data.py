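"""Synthetic inputs for the whole pipeline.

Generates everything the toolkit consumes, with known truth: diploid
genomes with tunable repeat content and heterozygosity (SNPs, indels,
optional structural variants), 100 bp paired-end reads from ~350 bp
inserts with tunable error, phase-set-tagged phased variant calls with
per-allele read depths, diverged ~2 kb feature tiles embedded in
optionally rearranged scaffolds, and truth chain files linking the two
genomes.

Determinism: one global seed expands into per-stage child seeds by fixed
enumeration (numpy SeedSequence spawn keys), so identical specs and seeds
produce byte-identical outputs and individual stages can be re-run
independently.

Deliberate simplifications: bases are i.i.d. at the GC target (no
dinucleotide structure), read errors are uniform substitutions (no
machine-specific profiles), and tile divergence is substitution-only so
that truth chains stay gapless. Reads carry their haplotype of origin
and fragment coordinates in their names, which makes coverage and
error-rate oracles possible without a mapper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .coordinate_lift import Chain, ChainBlock
from .haplotype_consensus import Variant
from .read_prep import Read
from .seqio import BedInterval, revcomp

__all__ = [
    "SimGenomeSpec", "SimReadSpec", "TruthSet", "TileSet",
    "simulate_diploid", "simulate_reads", "simulate_phased_vcf",
    "simulate_ortholog_tiles",
]

_BASES = np.array(list("ACGT"))


def _child_rng(seed: int, stage: int) -> np.random.Generator:
    """Per-stage child generator by fixed enumeration of one global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


@dataclass(frozen=True)
class SimGenomeSpec:
    """Parameters of a simulated diploid genome.

    ``het_rate`` is the expected heterozygous variants per bp;
    ``repeat_families`` lists (unit_length, copy_number, per-copy
    divergence) tuples; ``sv_rate`` is structural variants (indels >=
    50 bp) per Mb.
    """

    length: int
    gc_target: float = 0.42
    repeat_families: tuple[tuple[int, int, float], ...] = ()
    het_rate: float = 0.0
    snp_indel_ratio: float = 10.0
    indel_length_mean: float = 2.0
    sv_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("length must be > 0")
        if not 0 <= self.gc_target <= 1:
            raise ValueError("gc_target must be in [0, 1]")
        if self.het_rate < 0 or self.sv_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.het_rate >= 1:
            raise ValueError("het_rate implies > 1 variant per bp")


@dataclass(frozen=True)
class SimReadSpec:
    """Parameters of a simulated paired-end library."""

    read_length: int = 100
    insert_mean: int = 350
    insert_sd: int = 20
    coverage: float = 30.0
    error_rate: float = 0.0
    quality_model: str = "constant"  # or "ramp"
    base_quality: int = 37
    seed: int = 0

    def __post_init__(self):
        if self.read_length > self.insert_mean:
            raise ValueError("insert_mean must be >= read_length")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")


@dataclass
class TruthSet:
    """A simulated diploid: two haplotypes plus the variants between them.

    Applying ``truth_variants`` (alt alleles) to haplotype A reconstructs
    haplotype B exactly. ``repeat_placements`` records where each mutated
    repeat copy landed on haplotype A, as (family_index, start, end).
    """

    chrom: str
    haplotype_a: str
    haplotype_b: str
    truth_variants: list[Variant]
    repeat_placements: list[tuple[int, int, int]] = field(default_factory=list)


def _place_repeats(rng, seq: list[str], spec: SimGenomeSpec
                   ) -> list[tuple[int, int, int]]:
    placements = []
    occupied: list[tuple[int, int]] = []
    for fam_idx, (unit_len, copies, divergence) in enumerate(spec.repeat_families):
        unit = _random_bases(rng, unit_len, spec.gc_target)
        placed = 0
        attempts = 0
        while placed < copies and attempts < copies * 50:
            attempts += 1
            start = int(rng.integers(0, spec.length - unit_len))
            end = start + unit_len
            if any(s < end and start < e for s, e in occupied):
                continue
            copy = list(unit)
            n_mut = rng.binomial(unit_len, divergence)
            for pos in rng.choice(unit_len, size=n_mut, replace=False):
                copy[pos] = rng.choice([b for b in "ACGT" if b != copy[pos]])
            seq[start:end] = copy
            occupied.append((start, end))
            placements.append((fam_idx, start, end))
            placed += 1
        if placed < copies:
            raise ValueError(f"could not place repeat family {fam_idx}: "
                             "genome too small")
    return placements


def _draw_variants(rng, hap_a: str, spec: SimGenomeSpec) -> list[Variant]:
    length = spec.length
    positions = np.flatnonzero(rng.random(length) < spec.het_rate)
    n_sv = rng.poisson(spec.sv_rate * length / 1e6)
    sv_positions = rng.integers(0, length, size=n_sv) if n_sv else []
    p_snp = spec.snp_indel_ratio / (spec.snp_indel_ratio + 1)

    drafts = []  # (pos0, is_sv)
    for p in positions:
        drafts.append((int(p), False))
    for p in sv_positions:
        drafts.append((int(p), True))
    drafts.sort()

    variants = []
    prev_end = 0  # exclusive 0-based end of the previous variant's ref span
    for pos0, is_sv in drafts:
        if pos0 < max(prev_end, 1):  # keep pos >= 2 so indels have an anchor
            continue
        ref_base = hap_a[pos0]
        if is_sv:
            sv_len = 50 + int(rng.geometric(1 / 150))
            if rng.random() < 0.5 and pos0 + sv_len + 1 <= length:
                ref = hap_a[pos0:pos0 + sv_len + 1]  # deletion
                alt = ref[0]
            else:
                ref = ref_base
                alt = ref + _random_bases(rng, sv_len, spec.gc_target)
        elif rng.random() < p_snp:
            ref = ref_base
            alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
        else:
            ilen = min(int(rng.geometric(1 / max(spec.indel_length_mean, 1.001))),
                       SV_CAP)
            if rng.random() < 0.5 and pos0 + ilen + 1 <= length:
                ref = hap_a[pos0:pos0 + ilen + 1]  # deletion
                alt = ref[0]
            else:
                ref = ref_base
                alt = ref + _random_bases(rng, ilen, spec.gc_target)
        variants.append(Variant("chr1", pos0 + 1, ref, (alt,),
                                genotype=(0, 1)))
        prev_end = pos0 + len(ref)
    return variants


SV_CAP = 49  # small-indel lengths stay below the SV convention


def _build_haplotype_b(hap_a: str, variants: Sequence[Variant]) -> str:
    """Independent (generator-side) construction of haplotype B."""
    pieces = []
    cursor = 0
    for v in sorted(variants, key=lambda v: v.pos):
        s = v.pos - 1
        assert hap_a[s:s + len(v.ref)] == v.ref
        pieces.append(hap_a[cursor:s])
        pieces.append(v.alts[0])
        cursor = s + len(v.ref)
    pieces.append(hap_a[cursor:])
    return "".join(pieces)


def simulate_diploid(spec: SimGenomeSpec) -> TruthSet:
    """Simulate a diploid genome with known truth variants.

    Haplotype A is the reference-like haplotype (repeats planted, i.i.d.
    background at the GC target); haplotype B differs from A exactly at
    the returned truth variants, which carry genotype 0|1 (allele 0 on A,
    allele 1 on B).
    """
    rng_seq = _child_rng(spec.seed, 0)
    rng_rep = _child_rng(spec.seed, 1)
    rng_var = _child_rng(spec.seed, 2)
    seq = list(_random_bases(rng_seq, spec.length, spec.gc_target))
    placements = _place_repeats(rng_rep, seq, spec)
    hap_a = "".join(seq)
    variants = _draw_variants(rng_var, hap_a, spec)
    hap_b = _build_haplotype_b(hap_a, variants)
    return TruthSet("chr1", hap_a, hap_b, variants, placements)


def simulate_reads(truth: TruthSet, spec: SimReadSpec
                   ) -> list[tuple[Read, Read]]:
    """Paired 100-bp-style reads from uniformly drawn fragments.

    Each fragment is sampled from haplotype A or B with probability 1/2;
    mate 1 reads the fragment 5' end forward, mate 2 the 3' end on the
    reverse strand. Read names encode haplotype, fragment coordinates and
    pair index, e.g. ``sim:A:1234:1584:17``.
    """
    haps = {"A": truth.haplotype_a, "B": truth.haplotype_b}
    if not haps["A"] or not haps["B"]:
        raise ValueError("empty haplotype")
    rng = _child_rng(spec.seed, 10)
    mean_len = (len(haps["A"]) + len(haps["B"])) / 2
    n_pairs = int(round(spec.coverage * mean_len / (2 * spec.read_length)))
    rl = spec.read_length
    pairs = []
    for i in range(n_pairs):
        hap_name = "A" if rng.random() < 0.5 else "B"
        hap = haps[hap_name]
        insert = max(rl, int(round(rng.normal(spec.insert_mean,
                                              spec.insert_sd))))
        insert = min(insert, len(hap))
        start = int(rng.integers(0, len(hap) - insert + 1))
        end = start + insert
        b1 = hap[start:start + rl]
        b2 = revcomp(hap[end - rl:end])
        if spec.error_rate > 0:
            b1 = _add_errors(rng, b1, spec.error_rate)
            b2 = _add_errors(rng, b2, spec.error_rate)
        quals = _qualities(rl, spec)
        name = f"sim:{hap_name}:{start}:{end}:{i}"
        pairs.append((Read(name + "/1", b1, quals),
                      Read(name + "/2", b2, quals)))
    return pairs


def _add_errors(rng, bases: str, rate: float) -> str:
    out = list(bases)
    for pos in np.flatnonzero(rng.random(len(out)) < rate):
        out[pos] = rng.choice([b for b in "ACGT" if b != out[pos]])
    return "".join(out)


def _qualities(n: int, spec: SimReadSpec) -> tuple[int, ...]:
    if spec.quality_model == "constant":
        return (spec.base_quality,) * n
    ramp = np.linspace(spec.base_quality, max(2, spec.base_quality - 20), n)
    return tuple(int(q) for q in ramp)


def simulate_phased_vcf(truth: TruthSet, depth: float,
                        phase_block_mean: float = 50_000,
                        unphased_fraction: float = 0.1,
                        seed: int = 0,
                        swap_rate: float = 0.0) -> list[Variant]:
    """Phased variant calls with phase-set tags and allele depths.

    Truth variants are partitioned into phase blocks whose genomic lengths
    are exponential with mean ``phase_block_mean``; the phase-set id is
    the position of the block's first phased variant. Each block's
    orientation is flipped (genotype 1|0 instead of 0|1) with probability
    ``swap_rate``, emulating phasing errors; a ``unphased_fraction`` of
    variants lose their phasing entirely. Per-allele read depths are
    Poisson around depth/2 per haplotype.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if not truth.truth_variants:
        return []
    rng = _child_rng(seed, 20)
    variants = sorted(truth.truth_variants, key=lambda v: v.pos)
    # block boundaries along the genome, exponential spacing
    boundaries = []
    x = rng.exponential(phase_block_mean)
    while x < len(truth.haplotype_a):
        boundaries.append(x)
        x += rng.exponential(phase_block_mean)
    block_of = np.searchsorted(boundaries, [v.pos for v in variants])

    unphased = rng.random(len(variants)) < unphased_fraction
    flip_block = {b: rng.random() < swap_rate for b in set(block_of)}
    # phase-set id: position of the first PHASED variant of the block
    ps_id: dict[int, int] = {}
    for v, b, up in zip(variants, block_of, unphased):
        if not up and b not in ps_id:
            ps_id[b] = v.pos

    out = []
    for v, b, up in zip(variants, block_of, unphased):
        ad = (int(rng.poisson(depth / 2)), int(rng.poisson(depth / 2)))
        if up:
            out.append(Variant(v.chrom, v.pos, v.ref, v.alts,
                               genotype=(0, 1), phased=False,
                               allele_depths=ad))
        else:
            gt = (1, 0) if flip_block[b] else (0, 1)
            out.append(Variant(v.chrom, v.pos, v.ref, v.alts,
                               genotype=gt, phased=True,
                               phase_set=ps_id[b], allele_depths=ad))
    return out


@dataclass
class TileSet:
    """A reference genome, a diverged copy, tile truth and truth chains."""

    reference: dict[str, str]
    diverged: dict[str, str]
    tiles_reference: list[BedInterval]
    tiles_diverged: list[BedInterval]
    chains: list[Chain]


def simulate_ortholog_tiles(n_tiles: int = 50, tile_length: int = 2000,
                            target_identity: float = 0.75,
                            scaffold_shuffle: bool = False,
                            seed: int = 0,
                            spacer: int = 1000,
                            gc: float = 0.42,
                            n_segments: int = 4,
                            n_inversions: int = 1) -> TileSet:
    """A reference genome with embedded tiles and a diverged counterpart.

    The diverged genome is the reference with i.i.d. substitutions at rate
    ``1 - target_identity`` (no indels, so truth chains are gapless).
    With ``scaffold_shuffle`` the diverged genome is split into
    ``n_segments`` scaffolds at spacer midpoints, reordered, and
    ``n_inversions`` of them inverted; tiles never span a breakpoint.
    Truth chains map reference (target) coordinates onto the diverged
    (query) scaffolds.
    """
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must be in (0, 1]")
    genome_length = n_tiles * (tile_length + spacer) + spacer
    if n_tiles * tile_length > genome_length:
        raise ValueError("tiles exceed genome length")
    rng = _child_rng(seed, 30)
    ref_seq = _random_bases(rng, genome_length, gc)
    tiles_ref = []
    for i in range(n_tiles):
        start = spacer + i * (tile_length + spacer)
        tiles_ref.append(BedInterval("ref1", start, start + tile_length,
                                     f"tile{i:04d}"))
    # substitution-diverged copy
    if target_identity < 1:
        div = list(ref_seq)
        for pos in np.flatnonzero(rng.random(genome_length)
                                  < 1 - target_identity):
            div[pos] = rng.choice([b for b in "ACGT" if b != div[pos]])
        div_seq = "".join(div)
    else:
        div_seq = ref_seq

    if not scaffold_shuffle:
        chain = Chain(score=genome_length, t_name="ref1",
                      t_size=genome_length, t_start=0, t_end=genome_length,
                      q_name="scaf1", q_size=genome_length, q_strand="+",
                      q_start=0, q_end=genome_length, chain_id=1,
                      blocks=[ChainBlock(genome_length)])
        tiles_div = [BedInterval("scaf1", t.start, t.end, t.name)
                     for t in tiles_ref]
        return TileSet({"ref1": ref_seq}, {"scaf1": div_seq}, tiles_ref,
                       tiles_div, [chain])

    # split at spacer midpoints so tiles stay intact
    n_segments = min(n_segments, n_tiles)
    cut_tiles = sorted(rng.choice(np.arange(1, n_tiles), size=n_segments - 1,
                                  replace=False)) if n_segments > 1 else []
    cuts = [0] + [tiles_ref[t].start - spacer // 2 for t in cut_tiles] \
        + [genome_length]
    segments = [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)]
    order = rng.permutation(len(segments))
    inverted = set(rng.choice(len(segments), size=min(n_inversions,
                                                      len(segments)),
                              replace=False))
    diverged: dict[str, str] = {}
    chains: list[Chain] = []
    seg_map: dict[int, tuple[str, bool]] = {}
    for rank, seg_idx in enumerate(order, start=1):
        s, e = segments[seg_idx]
        name = f"scaf{rank}"
        piece = div_seq[s:e]
        inv = seg_idx in inverted
        diverged[name] = revcomp(piece) if inv else piece
        seg_map[seg_idx] = (name, inv)
        chains.append(Chain(
            score=e - s, t_name="ref1", t_size=genome_length,
            t_start=s, t_end=e, q_name=name, q_size=e - s,
            q_strand="-" if inv else "+", q_start=0, q_end=e - s,
            chain_id=rank, blocks=[ChainBlock(e - s)]))
    tiles_div = []
    for t in tiles_ref:
        seg_idx = next(i for i, (s, e) in enumerate(segments)
                       if s <= t.start and t.end <= e)
        s, e = segments[seg_idx]
        name, inv = seg_map[seg_idx]
        if inv:
            start = e - t.end
            end = e - t.start
        else:
            start = t.start - s
            end = t.end - s
        tiles_div.append(BedInterval(name, start, end, t.name,
                                     strand="-" if inv else "+"))
    return TileSet({"ref1": ref_seq}, diverged, tiles_ref, tiles_div, chains)
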
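"""Phase-set majority-haplotype consensus calling.

Short-read assemblies of heterozygous samples end up as mosaics of the two
haplotypes, creating recombinant sequences that exist in no real
chromosome. Given read-phased variant calls (phase-set tagged, with
per-allele read depths), this module rebuilds a consensus that follows the
MAJORITY haplotype within every phase set:

1. overlapping variant calls are reduced to one per locus (a structural
   variant wins; otherwise the best-supported call);
2. each phase set is scored by the cumulative read depth of the alleles on
   haplotype A vs haplotype B, indels (and SVs) weighted half as much as
   SNPs because indel alignments inflate/deflate depths;
3. phased variants whose allele on the majority haplotype is non-reference
   are retained (as homozygous calls); un-phased variants keep their
   majority allele;
4. the retained variants are applied to the un-phased assembly.

Ties in the A/B score go to haplotype A; an un-phased variant whose ref
and alt depths tie keeps the reference (is dropped). Both rules are
deterministic stand-ins for cases the procedure leaves open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "Variant", "PhaseSetScore", "SV_MIN_LENGTH", "resolve_overlaps",
    "score_phase_set", "select_consensus_variants", "apply_variants",
    "read_vcf", "write_vcf",
]

SV_MIN_LENGTH = 50  # bp; alleles at least this long are structural variants
INDEL_WEIGHT = 0.5


@dataclass(frozen=True)
class Variant:
    """A VCF-style variant call (1-based pos; allele 0 is the reference)."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotype: tuple[int, int] = (0, 1)
    phased: bool = False
    phase_set: Optional[int] = None
    allele_depths: Optional[tuple[int, ...]] = None

    def __post_init__(self):
        if not self.ref or not all(self.alts):
            raise ValueError(f"{self.chrom}:{self.pos}: empty allele")
        if self.phased and self.phase_set is None:
            raise ValueError(f"{self.chrom}:{self.pos}: phased without PS")

    @property
    def kind(self) -> str:
        longest = max(len(self.ref), max(len(a) for a in self.alts))
        if longest >= SV_MIN_LENGTH or any(a.startswith("<") for a in self.alts):
            return "SV"
        if longest == 1:
            return "SNP"
        return "INS" if max(len(a) for a in self.alts) > len(self.ref) else "DEL"

    @property
    def weight(self) -> float:
        return 1.0 if self.kind == "SNP" else INDEL_WEIGHT

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open reference span."""
        return self.pos - 1, self.pos - 1 + len(self.ref)

    def depth_of(self, allele: int) -> int:
        if self.allele_depths is None or allele >= len(self.allele_depths):
            return 0
        return self.allele_depths[allele]

    @property
    def best_alt_depth(self) -> int:
        return max(self.depth_of(i) for i in range(1, len(self.alts) + 1))


def resolve_overlaps(variants: Sequence[Variant]) -> list[Variant]:
    """Keep one variant per overlapping cluster on a chromosome.

    Variants cluster when their reference spans intersect (which subsumes
    shared start positions). Within a cluster an SV wins; among SVs (or,
    with no SV, among all members) the greatest supporting alt depth wins,
    ties broken by longer reference span then position.
    """
    ordered = sorted(variants, key=lambda v: (v.chrom, v.pos))
    out: list[Variant] = []
    cluster: list[Variant] = []
    cluster_end = -1
    cluster_chrom = None

    def flush():
        if not cluster:
            return
        svs = [v for v in cluster if v.kind == "SV"]
        pool = svs if svs else cluster
        best = max(pool, key=lambda v: (v.best_alt_depth,
                                        len(v.ref), -v.pos))
        out.append(best)

    for v in ordered:
        s, e = v.span
        if cluster and v.chrom == cluster_chrom and s < cluster_end:
            cluster.append(v)
            cluster_end = max(cluster_end, e)
        else:
            flush()
            cluster = [v]
            cluster_chrom = v.chrom
            cluster_end = e
    flush()
    return out


@dataclass
class PhaseSetScore:
    phase_set: int
    score_a: float
    score_b: float

    @property
    def majority(self) -> str:
        return "A" if self.score_a >= self.score_b else "B"


def score_phase_set(variants: Sequence[Variant]) -> PhaseSetScore:
    """Weighted cumulative read-count score of one phase set.

    Each variant's haplotype-A allele contributes its read depth times the
    variant weight (1 for SNPs, 0.5 for indels/SVs) to score A, and
    likewise for B. Variants without depths contribute nothing.
    """
    ps_ids = {v.phase_set for v in variants}
    if len(ps_ids) != 1 or None in ps_ids:
        raise ValueError("variants must share one phase-set id")
    score_a = score_b = 0.0
    for v in variants:
        w = v.weight
        score_a += w * v.depth_of(v.genotype[0])
        score_b += w * v.depth_of(v.genotype[1])
    return PhaseSetScore(next(iter(ps_ids)), score_a, score_b)


def select_consensus_variants(variants: Sequence[Variant]) -> list[Variant]:
    """Retain the majority-haplotype allele of every variant.

    Phased variants follow their phase set's majority haplotype and are
    kept (as homozygous calls) only when that haplotype carries a
    non-reference allele. Un-phased variants keep whichever of ref/alt has
    the greater read depth. Overlaps must already be resolved.
    """
    by_ps: dict[tuple[str, int], list[Variant]] = {}
    for v in variants:
        if v.phased:
            by_ps.setdefault((v.chrom, v.phase_set), []).append(v)
    majority = {key: score_phase_set(group).majority
                for key, group in by_ps.items()}

    retained = []
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
        if v.phased:
            hap = majority[(v.chrom, v.phase_set)]
            allele = v.genotype[0 if hap == "A" else 1]
        else:
            best_alt = max(range(1, len(v.alts) + 1), key=v.depth_of)
            allele = best_alt if v.depth_of(best_alt) > v.depth_of(0) else 0
        if allele != 0:
            retained.append(replace(v, genotype=(allele, allele),
                                    phased=False, phase_set=None))
    return retained


def apply_variants(sequences: dict[str, str],
                   variants: Sequence[Variant]) -> dict[str, str]:
    """Apply non-overlapping variants to an assembly.

    Each variant substitutes its chosen allele - the first non-reference
    allele in its genotype, so both consensus calls (i/i) and truth
    heterozygotes (0|1) apply their alt - for the reference span. The
    reference allele must match the assembly exactly at its position or a
    ValueError names the offending site.
    """
    by_chrom: dict[str, list[Variant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    out = dict(sequences)
    for chrom, vs in by_chrom.items():
        if chrom not in sequences:
            raise ValueError(f"unknown chromosome {chrom}")
        seq = sequences[chrom]
        vs = sorted(vs, key=lambda v: v.pos)
        pieces = []
        cursor = 0
        for v in vs:
            s, e = v.span
            if s < cursor:
                raise ValueError(f"overlapping variants at {chrom}:{v.pos}")
            if seq[s:e] != v.ref:
                raise ValueError(
                    f"reference mismatch at {chrom}:{v.pos}: assembly has "
                    f"{seq[s:e]!r}, variant ref is {v.ref!r}")
            allele = next((a for a in v.genotype if a != 0), 0)
            alt = v.ref if allele == 0 else v.alts[allele - 1]
            pieces.append(seq[cursor:s])
            pieces.append(alt)
            cursor = e
        pieces.append(seq[cursor:])
        out[chrom] = "".join(pieces)
    return out


# ---------------------------------------------------------------------------
# VCF v4.2 I/O (GT with | for phased, PS integer tag, AD per-allele depths)

def read_vcf(path) -> list[Variant]:
    """Load variants from a (plain-text or bgzipped) VCF via pysam."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            sample = rec.samples[0]
            gt = sample.get("GT")
            if gt is None or len(gt) != 2 or None in gt:
                continue
            ad = sample.get("AD")
            ps = sample.get("PS")
            out.append(Variant(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref,
                alts=tuple(rec.alts or ()),
                genotype=(gt[0], gt[1]),
                phased=bool(sample.phased) and ps is not None,
                phase_set=int(ps) if (sample.phased and ps is not None) else None,
                allele_depths=tuple(int(x) for x in ad) if ad is not None else None,
            ))
    return out


def write_vcf(path, variants: Sequence[Variant],
              contigs: Optional[dict[str, int]] = None,
              sample: str = "sample") -> None:
    """Write variants as a minimal VCF v4.2 text file."""
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
             '##FORMAT=<ID=AD,Number=R,Type=Integer,'
             'Description="Per-allele read depths">',
             '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">']
    for name, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + sample)
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
        sep = "|" if v.phased else "/"
        gt = f"{v.genotype[0]}{sep}{v.genotype[1]}"
        fmt = ["GT"]
        vals = [gt]
        if v.allele_depths is not None:
            fmt.append("AD")
            vals.append(",".join(str(d) for d in v.allele_depths))
        if v.phased:
            fmt.append("PS")
            vals.append(str(v.phase_set))
        lines.append("\t".join([
            v.chrom, str(v.pos), ".", v.ref, ",".join(v.alts) or ".",
            ".", "PASS", ".", ":".join(fmt), ":".join(vals)]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
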
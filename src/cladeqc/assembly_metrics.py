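"""Assembly contiguity and completeness statistics.

NG50 and the NG graph measure contiguity against the ESTIMATED genome
size rather than the total assembly length: NG(x) is the scaffold length
at which the descending cumulative sum of scaffold lengths first reaches
x% of the estimated genome size, so assemblies of different completeness
remain comparable. Contig statistics split scaffolds on every N (single
Ns included). The module also provides the downstream analyses run over
per-assembly summary tables: the fraction of the assembly in gene-sized
(>= 6.3 kb) scaffolds, the assembled fraction of the estimated genome
size, Pearson correlation and OLS regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .scaffold_ops import ScaffoldRecord, extract_contigs

__all__ = [
    "AssemblyStats", "ng_value", "ng_graph", "assembly_stats",
    "gene_sized_fraction", "percent_genome_assembled", "pearson_r",
    "ols_fit",
]

GENE_SIZED_THRESHOLD = 6300  # bp; average gene length in a close relative


def ng_value(lengths: Sequence[int], genome_size: int, x: int) -> Optional[int]:
    """NG(x): length whose descending cumulative sum first reaches x% of G.

    Returns None (undefined) when the whole assembly sums to less than
    x% of the genome size - the case where the NG curve never intersects
    the x-axis.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    if not 1 <= x <= 100:
        raise ValueError("x must be in 1..100")
    need = genome_size * x / 100
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc >= need:
            return length
    return None


def ng_graph(lengths: Sequence[int], genome_size: int) -> list[Optional[int]]:
    """NG(1)..NG(100) in one descending cumulative sweep."""
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    ordered = sorted(lengths, reverse=True)
    cum = np.cumsum(ordered) if ordered else np.array([])
    out: list[Optional[int]] = []
    j = 0
    for x in range(1, 101):
        need = genome_size * x / 100
        while j < len(cum) and cum[j] < need:
            j += 1
        out.append(int(ordered[j]) if j < len(cum) else None)
    return out


@dataclass
class AssemblyStats:
    total_scaffold_length: int
    scaffold_n50: Optional[int]
    scaffold_ng50: Optional[int]
    ng_graph: list[Optional[int]]
    longest_scaffold: int
    contig_ng50: Optional[int]
    longest_contig: int
    total_gap_length: int


def assembly_stats(assembly: Sequence[ScaffoldRecord],
                   genome_size: int) -> AssemblyStats:
    """Table-style contiguity summary of an assembly.

    Contig lengths come from splitting scaffolds on every N; the total gap
    length is the total N count.
    """
    if not assembly:
        raise ValueError("empty assembly")
    scaf_lengths = [len(s) for s in assembly]
    contig_lengths = [len(c) for s in assembly for c in extract_contigs(s)]
    total = sum(scaf_lengths)
    return AssemblyStats(
        total_scaffold_length=total,
        scaffold_n50=ng_value(scaf_lengths, total, 50),
        scaffold_ng50=ng_value(scaf_lengths, genome_size, 50),
        ng_graph=ng_graph(scaf_lengths, genome_size),
        longest_scaffold=max(scaf_lengths),
        contig_ng50=ng_value(contig_lengths, genome_size, 50)
        if contig_lengths else None,
        longest_contig=max(contig_lengths) if contig_lengths else 0,
        total_gap_length=sum(s.total_gap_length for s in assembly),
    )


def gene_sized_fraction(lengths: Sequence[int],
                        threshold: int = GENE_SIZED_THRESHOLD) -> float:
    """% of total scaffold length in scaffolds >= threshold (inclusive)."""
    total = sum(lengths)
    if total == 0:
        raise ValueError("empty length set")
    return 100.0 * sum(l for l in lengths if l >= threshold) / total


def percent_genome_assembled(total_scaffold_length: int,
                             est_genome_size: int) -> float:
    """Assembled fraction of the estimated genome size, in percent."""
    if est_genome_size <= 0:
        raise ValueError("est_genome_size must be > 0")
    return 100.0 * total_scaffold_length / est_genome_size


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with a two-sided t-test p-value; NA pairs dropped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def ols_fit(response: Sequence[float], predictors) -> "sm.regression.linear_model.RegressionResultsWrapper":
    """Ordinary least squares with intercept (statsmodels).

    Rows with any NA in response or predictors are dropped pairwise.
    Returns the fitted results object (params, bse, pvalues ...).
    """
    y = np.asarray(response, dtype=float)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    keep = ~(np.isnan(y) | np.isnan(X).any(axis=1))
    y, X = y[keep], X[keep]
    if len(y) <= X.shape[1] + 1:
        raise ValueError("not enough complete observations")
    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError("rank-deficient design matrix")
    return sm.OLS(y, Xc).fit()
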
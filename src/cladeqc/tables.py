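"""Packaged per-assembly summary tables and the analyses run over them.

The three TSVs under ``cladeqc/data`` transcribe the published
per-assembly summary statistics of the 23-genome *Drosophila montium*
resource: genome-size estimates and contiguity metrics, sample coverage /
GC / de Bruijn branch frequencies, and enhancer remapping / RBH counts.
The functions here recompute the headline quantities (clade mean and
median genome size and NG50, assembled fractions, the genome-size vs
log10 repeat-content correlation, remapping success and RBH rates) from
those tables.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .assembly_metrics import pearson_r, percent_genome_assembled

__all__ = [
    "load_assembly_table", "load_sample_table", "load_remapping_table",
    "clade_summary",
]


def _load(name: str) -> pd.DataFrame:
    with resources.files("cladeqc.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", na_values=["NA"])


def load_assembly_table() -> pd.DataFrame:
    """Genome-size estimates and assembly statistics, one row per species."""
    return _load("table1_assembly_stats.tsv")


def load_sample_table() -> pd.DataFrame:
    """Coverage, GC% and de Bruijn branch frequencies per sample."""
    return _load("table2_sample_info.tsv")


def load_remapping_table() -> pd.DataFrame:
    """Enhancer remapping and reciprocal-best-hit counts per species."""
    return _load("table3_enhancer_remapping.tsv")


def clade_summary() -> dict[str, float]:
    """Headline clade-level statistics recomputed from the tables."""
    t1 = load_assembly_table()
    t2 = load_sample_table()
    t3 = load_remapping_table()

    def assembled_pct(species: str) -> float:
        row = t1[t1.species == species].iloc[0]
        return round(percent_genome_assembled(row.total_scaffold_length_bp,
                                              row.est_genome_size_bp), 1)

    merged = t1.merge(t2, on="species")
    r, p = pearson_r(merged.est_genome_size_bp,
                     np.log10(merged.freq_repeat_branches_k41))
    watanabei = t1[t1.species == "D. watanabei"].iloc[0]
    return {
        "mean_genome_size_mb": t1.est_genome_size_bp.mean() / 1e6,
        "median_genome_size_mb": t1.est_genome_size_bp.median() / 1e6,
        "mean_scaffold_ng50_bp": t1.scaffold_ng50_bp.mean(),
        "median_scaffold_ng50_bp": float(t1.scaffold_ng50_bp.median()),
        "pct_assembled_pectinifera": assembled_pct("D. pectinifera"),
        "pct_assembled_kanapiae": assembled_pct("D. kanapiae"),
        "pct_assembled_mayri": assembled_pct("D. mayri"),
        "watanabei_excess_mb": (watanabei.total_scaffold_length_bp
                                - watanabei.est_genome_size_bp) / 1e6,
        "genome_size_repeat_r": r,
        "genome_size_repeat_p": p,
        "n_species_correlated": int(
            merged.freq_repeat_branches_k41.notna().sum()),
        "mean_pct_rbh": t3.pct_successful_rbh.mean(),
        "min_pct_successful_remapping": float(
            t3.pct_successful_remappings.min()),
    }
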
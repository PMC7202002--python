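"""Shared fixtures: the expensive simulations are session-scoped so the
recovery tests and the acceptance tests reuse one realization."""

import pytest

from cladeqc import kmer_profile as kp
from cladeqc import orthology_rbh as orb
from cladeqc import synthetic_data as sd


@pytest.fixture(scope="session")
def homozygous_profile():
    """Error-free 30x reads over a 100 kb nonrepetitive homozygous genome,
    with their canonical 41-mer counts."""
    truth = sd.simulate_diploid(sd.SimGenomeSpec(length=100_000, het_rate=0.0,
                                                 seed=11))
    reads = sd.simulate_reads(truth, sd.SimReadSpec(coverage=30.0,
                                                    error_rate=0.0, seed=12))
    counts = kp.count_kmers([r.bases for pair in reads for r in pair], k=41)
    return truth, reads, counts


@pytest.fixture(scope="session")
def branch_sweep_counts():
    """41-mer counts for paired simulations sweeping heterozygosity and
    repeat content (same seed family, 80 kb at 25x, error-free)."""
    out = {}
    for label, het, repeats in [
        ("low_het", 0.0002, ()),
        ("high_het", 0.002, ()),
        ("with_repeats", 0.0002, ((500, 20, 0.01),)),
    ]:
        truth = sd.simulate_diploid(sd.SimGenomeSpec(
            length=80_000, het_rate=het, repeat_families=repeats, seed=21))
        reads = sd.simulate_reads(truth, sd.SimReadSpec(coverage=25.0,
                                                        seed=22))
        out[label] = kp.count_kmers([r.bases for p in reads for r in p], 41)
    return out


@pytest.fixture(scope="session")
def rbh_screens():
    """50-tile (2 kb) RBH screens at decreasing tile identity, with
    scaffold shuffling and one inversion in the diverged genome."""
    results = {}
    for ident in (1.0, 0.9, 0.75):
        ts = sd.simulate_ortholog_tiles(n_tiles=50, tile_length=2000,
                                        target_identity=ident,
                                        scaffold_shuffle=True, seed=31)
        results[ident] = (ts, orb.rbh_screen(ts.reference, ts.diverged,
                                             ts.tiles_reference, ts.chains))
    return results
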
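"""Overlap resolution, phase-set scoring, consensus selection/application."""

import numpy as np
import pytest

from cladeqc import synthetic_data as sd
from cladeqc.haplotype_consensus import (Variant, apply_variants, read_vcf,
                                         resolve_overlaps, score_phase_set,
                                         select_consensus_variants,
                                         write_vcf)


def snp(pos, ref="A", alt="C", ad=(10, 10), ps=None, gt=(0, 1), chrom="chr1"):
    return Variant(chrom, pos, ref, (alt,), genotype=gt,
                   phased=ps is not None, phase_set=ps, allele_depths=ad)


class TestVariantKinds:
    def test_kind_classification(self):
        assert snp(5).kind == "SNP"
        assert Variant("c", 5, "A", ("ATT",)).kind == "INS"
        assert Variant("c", 5, "ATT", ("A",)).kind == "DEL"
        assert Variant("c", 5, "A" * 51, ("A",)).kind == "SV"
        assert Variant("c", 5, "A", ("<DEL>",)).kind == "SV"

    def test_weights(self):
        assert snp(5).weight == 1.0
        assert Variant("c", 5, "AT", ("A",)).weight == 0.5


class TestResolveOverlaps:
    def test_sv_beats_nested_snp(self):
        dele = Variant("c", 80, "A" * 51, ("A",), allele_depths=(5, 3))
        inner = snp(100, ad=(2, 8), chrom="c")
        assert resolve_overlaps([inner, dele]) == [dele]

    def test_same_position_majority_wins(self):
        a = snp(100, alt="C", ad=(5, 10))
        b = snp(100, alt="G", ad=(5, 3))
        assert resolve_overlaps([a, b]) == [a]

    def test_disjoint_kept(self):
        a, b = snp(100), snp(200)
        assert resolve_overlaps([a, b]) == [a, b]

    def test_output_spans_disjoint(self):
        rng = np.random.default_rng(0)
        variants = []
        for _ in range(200):
            pos = int(rng.integers(1, 2000))
            reflen = int(rng.integers(1, 30))
            variants.append(Variant("c", pos, "A" * reflen, ("A",),
                                    allele_depths=(int(rng.integers(20)),
                                                   int(rng.integers(20)))))
        resolved = sorted(resolve_overlaps(variants), key=lambda v: v.pos)
        for u, v in zip(resolved, resolved[1:]):
            assert u.span[1] <= v.span[0]


class TestScorePhaseSet:
    def test_worked_weighted_sum(self):
        # A side: SNP depths 12 and 6, indel 4; B side: SNP 9, indel 10
        vs = [
            snp(10, ad=(12, 9), ps=1),                      # A=12, B=9
            snp(20, ad=(6, 0), ps=1),                       # A=6
            Variant("chr1", 30, "AT", ("A",), genotype=(0, 1), phased=True,
                    phase_set=1, allele_depths=(4, 10)),     # indel A=4 B=10
        ]
        s = score_phase_set(vs)
        assert s.score_a == 12 + 6 + 0.5 * 4
        assert s.score_b == 9 + 0 + 0.5 * 10
        assert s.majority == "A"

    def test_single_variant_b_majority(self):
        s = score_phase_set([snp(10, ad=(0, 7), ps=3)])
        assert s.majority == "B"

    def test_tie_goes_to_a(self):
        s = score_phase_set([snp(10, ad=(5, 5), ps=1)])
        assert s.majority == "A"

    def test_missing_depths_contribute_zero(self):
        v = Variant("chr1", 10, "A", ("C",), genotype=(0, 1), phased=True,
                    phase_set=1, allele_depths=None)
        s = score_phase_set([v, snp(20, ad=(3, 9), ps=1)])
        assert (s.score_a, s.score_b) == (3, 9)

    def test_mixed_phase_sets_rejected(self):
        with pytest.raises(ValueError):
            score_phase_set([snp(10, ps=1), snp(20, ps=2)])

    def test_thousand_random_sets_match_oracle(self):
        rng = np.random.default_rng(1)
        for ps in range(1000):
            n = int(rng.integers(1, 8))
            vs = []
            for i in range(n):
                if rng.random() < 0.7:
                    v = snp(10 * i + 1, ad=(int(rng.integers(30)),
                                            int(rng.integers(30))),
                            ps=ps, gt=(0, 1) if rng.random() < 0.5 else (1, 0))
                else:
                    v = Variant("chr1", 10 * i + 1, "AT", ("A",),
                                genotype=(0, 1) if rng.random() < 0.5 else (1, 0),
                                phased=True, phase_set=ps,
                                allele_depths=(int(rng.integers(30)),
                                               int(rng.integers(30))))
                vs.append(v)
            # independent weighted-sum oracle
            oa = sum((1.0 if len(v.ref) == len(v.alts[0]) == 1 else 0.5)
                     * v.allele_depths[v.genotype[0]] for v in vs)
            ob = sum((1.0 if len(v.ref) == len(v.alts[0]) == 1 else 0.5)
                     * v.allele_depths[v.genotype[1]] for v in vs)
            expected = "A" if oa >= ob else "B"
            assert score_phase_set(vs).majority == expected


class TestSelectConsensus:
    def test_alt_on_majority_haplotype_retained(self):
        v = snp(10, ad=(2, 20), ps=1, gt=(1, 0))  # alt on A, A has depth 20
        (kept,) = select_consensus_variants([v])
        assert kept.genotype == (1, 1)

    def test_ref_on_majority_haplotype_dropped(self):
        v = snp(10, ad=(20, 2), ps=1, gt=(0, 1))  # A majority, A carries ref
        assert select_consensus_variants([v]) == []

    def test_unphased_majority_allele(self):
        keep = snp(10, ad=(12, 20))
        drop = snp(30, ad=(20, 12))
        tie = snp(50, ad=(15, 15))
        kept = select_consensus_variants([keep, drop, tie])
        assert [v.pos for v in kept] == [10]


class TestApplyVariants:
    def test_snp(self):
        out = apply_variants({"c": "ACGT"}, [Variant("c", 2, "C", ("T",))])
        assert out["c"] == "ATGT"

    def test_anchored_deletion(self):
        out = apply_variants({"c": "ACGT"}, [Variant("c", 2, "CG", ("C",))])
        assert out["c"] == "ACT"

    def test_insertion(self):
        out = apply_variants({"c": "ACGT"}, [Variant("c", 2, "C", ("CTT",))])
        assert out["c"] == "ACTTGT"

    def test_ref_mismatch_names_site(self):
        with pytest.raises(ValueError, match="c:3"):
            apply_variants({"c": "ACGT"}, [Variant("c", 3, "T", ("A",))])

    def test_truth_roundtrip_reconstructs_haplotype_b(self):
        truth = sd.simulate_diploid(sd.SimGenomeSpec(
            length=50_000, het_rate=0.003, snp_indel_ratio=5, sv_rate=20,
            seed=5))
        assert truth.truth_variants, "expected variants"
        out = apply_variants({"chr1": truth.haplotype_a}, truth.truth_variants)
        assert out["chr1"] == truth.haplotype_b

    def test_consensus_alphabet_stays_acgtn(self):
        truth = sd.simulate_diploid(sd.SimGenomeSpec(length=20_000,
                                                     het_rate=0.005, seed=6))
        calls = sd.simulate_phased_vcf(truth, depth=20, seed=7)
        retained = select_consensus_variants(resolve_overlaps(calls))
        out = apply_variants({"chr1": truth.haplotype_a}, retained)
        assert set(out["chr1"]) <= set("ACGTN")


class TestEndToEndRecovery:
    def _expected_mosaic(self, truth, calls):
        """Oracle: enumerate both haplotype options per phase set and keep
        the one with the larger weighted depth; un-phased keep majority."""
        chosen = []
        by_ps = {}
        for v in calls:
            if v.phased:
                by_ps.setdefault(v.phase_set, []).append(v)
        for ps_vars in by_ps.values():
            wa = sum(v.weight * v.allele_depths[v.genotype[0]] for v in ps_vars)
            wb = sum(v.weight * v.allele_depths[v.genotype[1]] for v in ps_vars)
            pick = 0 if wa >= wb else 1
            for v in ps_vars:
                if v.genotype[pick] != 0:
                    chosen.append(v)
        for v in calls:
            if not v.phased and v.allele_depths[1] > v.allele_depths[0]:
                chosen.append(v)
        return {(v.chrom, v.pos) for v in chosen}

    def test_consensus_matches_per_block_majority_oracle(self):
        truth = sd.simulate_diploid(sd.SimGenomeSpec(
            length=100_000, het_rate=0.002, snp_indel_ratio=10, seed=8))
        calls = sd.simulate_phased_vcf(truth, depth=20,
                                       phase_block_mean=5_000,
                                       unphased_fraction=0.1, seed=9,
                                       swap_rate=0.3)
        retained = select_consensus_variants(resolve_overlaps(calls))
        expected_sites = self._expected_mosaic(truth, calls)
        got_sites = {(v.chrom, v.pos) for v in retained}
        assert got_sites == expected_sites
        # applying the retained variants reproduces the oracle mosaic exactly
        chosen = [v for v in truth.truth_variants
                  if ("chr1", v.pos) in expected_sites]
        oracle_seq = apply_variants({"chr1": truth.haplotype_a}, chosen)
        consensus = apply_variants({"chr1": truth.haplotype_a}, retained)
        assert consensus["chr1"] == oracle_seq["chr1"]


class TestVCFRoundTrip:
    def test_write_read_roundtrip(self, tmp_path):
        truth = sd.simulate_diploid(sd.SimGenomeSpec(length=20_000,
                                                     het_rate=0.002, seed=10))
        calls = sd.simulate_phased_vcf(truth, depth=30, seed=11)
        path = tmp_path / "calls.vcf"
        write_vcf(path, calls, {"chr1": 20_000})
        back = read_vcf(path)
        assert len(back) == len(calls)
        for a, b in zip(sorted(calls, key=lambda v: v.pos), back):
            assert (a.chrom, a.pos, a.ref, a.alts) == (b.chrom, b.pos, b.ref,
                                                       b.alts)
            assert a.genotype == b.genotype
            assert a.phased == b.phased and a.phase_set == b.phase_set
            assert a.allele_depths == b.allele_depths
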
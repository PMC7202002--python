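"""Local alignment, RBH classification, hit trimming and summaries."""

import numpy as np
import pytest

from cladeqc.orthology_rbh import (AlignmentHit, GenomeAligner,
                                   alignment_summary, best_hit, classify_rbh,
                                   evalue_threshold, local_align,
                                   read_tabular_hits, trim_overlapping_hits,
                                   write_tabular_hits, DEFAULT_SCORING)
from cladeqc.seqio import BedInterval, revcomp


def sw_oracle(q, s, match=2, mismatch=-3, gap_open=5, gap_extend=2):
    """Quadratic-DP affine-gap Smith-Waterman top score, pure Python."""
    m, n = len(q), len(s)
    NEG = -10**9
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            E[i][j] = max(E[i][j - 1] - gap_extend,
                          H[i][j - 1] - gap_open - gap_extend)
            F[i][j] = max(F[i - 1][j] - gap_extend,
                          H[i - 1][j] - gap_open - gap_extend)
            sub = match if qi == s[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestLocalAlign:
    def test_identical_twenty_mers(self):
        rng = np.random.default_rng(0)
        s = rand_seq(rng, 20)
        (hit,) = local_align(s, s, e_max=1e6, max_hits=1)
        assert hit.score == 40 and hit.percent_identity == 100.0
        assert (hit.q_start, hit.q_end) == (0, 20)

    def test_single_mismatch_score(self):
        rng = np.random.default_rng(1)
        s = rand_seq(rng, 20)
        q = list(s)
        q[10] = "ACGT"["ACGT".index(q[10]) - 1]
        hits = local_align("".join(q), s, e_max=1e6)
        assert best_hit(hits).score == 2 * 19 - 3

    def test_reverse_strand_found(self):
        rng = np.random.default_rng(2)
        s = rand_seq(rng, 60)
        (hit,) = local_align(revcomp(s), s, e_max=1e6, max_hits=1)
        assert hit.strand == "-" and hit.score == 120

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")

    def test_matches_dp_oracle_on_random_pairs(self):
        """Top score equals the quadratic-DP oracle on 100 random pairs."""
        rng = np.random.default_rng(3)
        for trial in range(100):
            n1 = int(rng.integers(20, 220))
            n2 = int(rng.integers(20, 220))
            q = rand_seq(rng, n1)
            s = rand_seq(rng, n2)
            if trial % 4 == 0:  # plant a diverged shared segment
                seg = rand_seq(rng, int(rng.integers(15, 60)))
                q = q[: n1 // 2] + seg + q[n1 // 2:]
                mut = list(seg)
                for p in rng.integers(0, len(seg), size=len(seg) // 8 + 1):
                    mut[p] = "ACGT"[("ACGT".index(mut[p]) + 1) % 4]
                s = s[: n2 // 2] + "".join(mut) + s[n2 // 2:]
            expected = max(sw_oracle(q, s), sw_oracle(revcomp(q), s))
            hits = local_align(q, s, e_max=1e9, max_hits=1)
            got = hits[0].score if hits else 0
            assert got == expected

    def test_evalue_monotone_in_score_and_search_space(self):
        sc = DEFAULT_SCORING
        assert sc.evalue(50, 100, 100) < sc.evalue(40, 100, 100)
        assert sc.evalue(50, 100, 100) < sc.evalue(50, 1000, 1000)


class TestEvalueThreshold:
    def test_enhancer_set_reciprocal(self):
        assert evalue_threshold(3457) == 0.00029

    def test_small_counts(self):
        assert evalue_threshold(1) == 1.0
        assert evalue_threshold(10) == 0.1

    def test_rejects_zero(self):
        with pytest.raises(ValueError):
            evalue_threshold(0)


def mkhit(score, q0, q1, sid="s1", s0=0, s1=None, ident=90.0, qid="q"):
    s1 = s1 if s1 is not None else s0 + (q1 - q0)
    return AlignmentHit(qid, sid, q0, q1, s0, s1, "+", score, ident,
                        q1 - q0, 1e-10)


class TestBestHit:
    def test_max_score(self):
        hits = [mkhit(40, 0, 20), mkhit(35, 0, 20), mkhit(12, 0, 20)]
        assert best_hit(hits).score == 40

    def test_tie_longer_wins(self):
        a = mkhit(40, 0, 20)
        b = mkhit(40, 0, 25)
        assert best_hit([a, b]) is b

    def test_matches_max_scan(self):
        rng = np.random.default_rng(4)
        hits = [mkhit(int(s), 0, int(l))
                for s, l in zip(rng.integers(1, 100, 30),
                                rng.integers(10, 50, 30))]
        assert best_hit(hits).score == max(h.score for h in hits)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            best_hit([])


class TestClassifyRBH:
    FRAG = BedInterval("chr2L", 1000, 3000, "tile1")
    LIFT = BedInterval("scaf3", 500, 2500, "tile1")

    def test_both_overlap_is_rbh(self):
        fwd = mkhit(100, 0, 2000, sid="chr2L", s0=1500, s1=2900)
        rev = mkhit(100, 0, 2000, sid="scaf3", s0=600, s1=2400)
        r = classify_rbh(self.FRAG, self.LIFT, fwd, rev)
        assert r.is_rbh

    def test_wrong_scaffold_breaks_rbh(self):
        fwd = mkhit(100, 0, 2000, sid="chr2L", s0=1500, s1=2900)
        rev = mkhit(100, 0, 2000, sid="scaf7", s0=600, s1=2400)
        r = classify_rbh(self.FRAG, self.LIFT, fwd, rev)
        assert r.forward_best_overlaps and not r.reverse_best_overlaps
        assert not r.is_rbh

    def test_missing_hit_fails(self):
        r = classify_rbh(self.FRAG, self.LIFT, None, None)
        assert not r.is_rbh


class TestTrimOverlaps:
    def test_partial_overlap_trimmed(self):
        h1 = mkhit(100, 0, 100)
        h2 = mkhit(50, 50, 150)
        out = trim_overlapping_hits([h1, h2])
        trimmed = next(h for h in out if h.trimmed)
        assert (trimmed.q_start, trimmed.q_end) == (100, 150)
        assert trimmed.alignment_length == 50

    def test_nested_removed(self):
        h1 = mkhit(100, 0, 100)
        h2 = mkhit(50, 20, 80)
        out = trim_overlapping_hits([h1, h2])
        assert len(out) == 1 and out[0] is h1

    def test_disjoint_unchanged(self):
        h1 = mkhit(100, 0, 100)
        h2 = mkhit(50, 200, 300)
        assert set(trim_overlapping_hits([h1, h2])) == {h1, h2}

    def test_output_pairwise_disjoint(self):
        rng = np.random.default_rng(5)
        hits = [mkhit(int(rng.integers(1, 100)), q0, q0 + int(rng.integers(10, 80)))
                for q0 in rng.integers(0, 400, size=40)]
        out = sorted(trim_overlapping_hits(hits), key=lambda h: h.q_start)
        for a, b in zip(out, out[1:]):
            assert a.q_end <= b.q_start


class TestAlignmentSummary:
    def test_half_coverage(self):
        assert alignment_summary([mkhit(10, 0, 500, ident=80.0)], 1000) == \
            (50.0, 80.0)

    def test_weighted_mean(self):
        cov, wid = alignment_summary([mkhit(10, 0, 500, ident=90.0),
                                      mkhit(10, 500, 1000, ident=70.0)], 2000)
        assert (cov, wid) == (50.0, 80.0)

    def test_weighted_identity_bounded(self):
        rng = np.random.default_rng(6)
        hits, q0 = [], 0
        for _ in range(10):
            ln = int(rng.integers(10, 50))
            hits.append(mkhit(10, q0, q0 + ln,
                              ident=float(rng.uniform(50, 100))))
            q0 += ln + 5
        _, wid = alignment_summary(hits, q0)
        idents = [h.percent_identity for h in hits]
        assert min(idents) <= wid <= max(idents)

    def test_no_hits(self):
        assert alignment_summary([], 100) == (0.0, None)


class TestTabularRoundTrip:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(7)
        q = rand_seq(rng, 120)
        s = rand_seq(rng, 60) + q[10:90] + rand_seq(rng, 60)
        hits = local_align(q, s, e_max=10)
        path = tmp_path / "hits.tsv"
        write_tabular_hits(path, hits)
        back = read_tabular_hits(path)
        assert len(back) == len(hits)
        for a, b in zip(hits, back):
            assert (a.q_start, a.q_end, a.s_start, a.s_end, a.strand) == \
                (b.q_start, b.q_end, b.s_start, b.s_end, b.strand)
            assert a.score == b.score


class TestEndToEnd:
    def test_perfect_identity_all_rbh(self, rbh_screens):
        _, results = rbh_screens[1.0]
        assert all(r.is_rbh for r in results)
        assert all(r.query_coverage == 100.0 for r in results)
        assert all(r.weighted_identity == 100.0 for r in results)

    def test_rbh_rate_at_75_percent_identity(self, rbh_screens):
        _, results = rbh_screens[0.75]
        remapped = [r for r in results if r.remapped is not None]
        assert len(remapped) / len(results) >= 0.99
        rate = sum(r.is_rbh for r in remapped) / len(remapped)
        assert rate >= 0.9

    def test_rbh_rate_non_increasing_in_divergence(self, rbh_screens):
        rates = []
        for ident in (1.0, 0.9, 0.75):
            _, results = rbh_screens[ident]
            rates.append(sum(r.is_rbh for r in results) / len(results))
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_weighted_identity_tracks_simulated_divergence(self, rbh_screens):
        _, results = rbh_screens[0.75]
        wids = [r.weighted_identity for r in results if r.is_rbh]
        assert 70 <= float(np.mean(wids)) <= 80

    def test_genome_aligner_finds_planted_copy(self):
        rng = np.random.default_rng(8)
        genome = {"g1": rand_seq(rng, 30_000)}
        query = genome["g1"][12_000:14_000]
        aligner = GenomeAligner(genome, direct_limit=1000)
        hit = best_hit(aligner.align(query, e_max=1e-5, max_hits=1))
        assert hit.s_start == 12_000 and hit.s_end == 14_000
        assert hit.score == 4000
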
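"""Diploid haplotype-likelihood caller vs exhaustive enumeration oracle."""

import numpy as np
import pytest

from amplicall.align import build_pileup
from amplicall.caller import (
    CallerParams,
    CandidateSite,
    VariantCall,
    call_haplotypes,
    enumerate_candidates,
    filter_small_indels,
    fix_homopolymers,
)

from _oracles import diploid_best_config
from conftest import reads_with_alleles, site_tuple


def _setup(ref, sites, rows):
    alns = reads_with_alleles(ref, sites, rows)
    pile = build_pileup(alns, ref)
    candidates = [
        CandidateSite(pos, rb, ab,
                      int(pile.depth[pos]),
                      int(sum(1 for r in rows if r[k] == 1)))
        for k, (pos, rb, ab) in enumerate(sites)
    ]
    return alns, pile, candidates


class TestEnumerateCandidates:
    def test_clean_site_not_candidate(self, small_ref):
        sites = [site_tuple(small_ref, 500)]
        alns, pile, _ = _setup(small_ref, sites, [[0]] * 30)
        assert enumerate_candidates(pile, small_ref) == []

    def test_half_alt_is_candidate(self, small_ref):
        sites = [site_tuple(small_ref, 500)]
        rows = [[1]] * 50 + [[0]] * 50
        _, pile, _ = _setup(small_ref, sites, rows)
        cands = enumerate_candidates(pile, small_ref)
        assert len(cands) == 1 and cands[0].position == 500
        assert cands[0].alt_fraction == pytest.approx(0.5)

    @pytest.mark.parametrize("frac,expected", [(0.11, 0), (0.31, 1)])
    def test_aberrant_fraction_threshold(self, small_ref, frac, expected):
        """Systematic-error-level sites: 11% stays sub-candidate at the
        default 0.2 cutoff, 31% becomes a candidate."""
        sites = [site_tuple(small_ref, 500)]
        n_alt = int(round(frac * 100))
        rows = [[1]] * n_alt + [[0]] * (100 - n_alt)
        _, pile, _ = _setup(small_ref, sites, rows)
        assert len(enumerate_candidates(pile, small_ref)) == expected


class TestCallHaplotypes:
    def test_all_alt_reads_called_hom(self, small_ref):
        sites = [site_tuple(small_ref, 500)]
        alns, pile, cands = _setup(small_ref, sites, [[1]] * 100)
        calls = call_haplotypes(cands, alns, pile, error_rate=0.05)
        assert len(calls) == 1
        assert calls[0].genotype == "hom"
        # hom must beat het for the same data
        M = np.ones((100, 1), dtype=np.int8)
        (v1, v2), best, ref_ll = diploid_best_config(M, 0.05)
        assert (v1, v2) == (1, 1)

    def test_half_alt_reads_match_oracle(self, small_ref):
        sites = [site_tuple(small_ref, 500)]
        rows = [[1]] * 50 + [[0]] * 50
        alns, pile, cands = _setup(small_ref, sites, rows)
        calls = call_haplotypes(cands, alns, pile, error_rate=0.05)
        assert len(calls) == 1 and calls[0].genotype == "het"
        M = np.array(rows, dtype=np.int8)
        (v1, v2), best, ref_ll = diploid_best_config(M, 0.05)
        assert sorted((v1, v2)) == [0, 1]  # het in the oracle too
        import math
        assert calls[0].quality == pytest.approx(
            (best - ref_ll) * 10 / math.log(10), rel=1e-9)

    def test_linked_cis_candidates_share_haplotype(self, small_ref):
        sites = [site_tuple(small_ref, 500), site_tuple(small_ref, 530)]
        rows = [[1, 1]] * 15 + [[0, 0]] * 15
        alns, pile, cands = _setup(small_ref, sites, rows)
        calls = call_haplotypes(cands, alns, pile, error_rate=0.05)
        assert len(calls) == 2
        assert calls[0].hap_alleles == calls[1].hap_alleles
        (v1, v2), *_ = diploid_best_config(np.array(rows, np.int8), 0.05)
        assert sorted((v1, v2)) == [0, 3]  # both alts on one haplotype

    def test_trans_candidates_on_opposite_haplotypes(self, small_ref):
        sites = [site_tuple(small_ref, 500), site_tuple(small_ref, 530)]
        rows = [[1, 0]] * 15 + [[0, 1]] * 15
        alns, pile, cands = _setup(small_ref, sites, rows)
        calls = call_haplotypes(cands, alns, pile, error_rate=0.05)
        assert len(calls) == 2
        a1, a2 = calls[0].hap_alleles, calls[1].hap_alleles
        assert a1 != a2 and a1[0] + a1[1] == 1 and a2[0] + a2[1] == 1

    def test_randomized_oracle_equivalence(self, small_ref):
        """Windows with <=3 candidates and <=30 noisy reads: configuration
        and quality equal the exhaustive enumeration, instance by
        instance."""
        import math

        rng = np.random.default_rng(7)
        e = 0.07
        n_checked = 0
        for trial in range(25):
            S = int(rng.integers(1, 4))
            n = int(rng.integers(20, 31))
            positions = sorted(rng.choice(np.arange(460, 508), S,
                                          replace=False).tolist())
            sites = [site_tuple(small_ref, p) for p in positions]
            truth_v1 = int(rng.integers(0, 1 << S))
            truth_v2 = int(rng.integers(0, 1 << S))
            rows = []
            for _ in range(n):
                hap = truth_v1 if rng.random() < 0.5 else truth_v2
                row = []
                for s in range(S):
                    allele = (hap >> s) & 1
                    if rng.random() < e:
                        allele = 1 - allele
                    row.append(allele)
                rows.append(row)
            M = np.array(rows, dtype=np.int8)
            alns, pile, cands = _setup(small_ref, sites, rows)
            calls = call_haplotypes(cands, alns, pile,
                                    CallerParams(min_depth=10),
                                    error_rate=e)
            (v1, v2), best, ref_ll = diploid_best_config(M, e)
            expected = {}
            for s in range(S):
                a = ((v1 >> s) & 1, (v2 >> s) & 1)
                if a != (0, 0):
                    expected[positions[s]] = "hom" if a == (1, 1) else "het"
            got = {c.position: c.genotype for c in calls}
            assert got == expected
            q = (best - ref_ll) * 10 / math.log(10)
            for c in calls:
                assert c.quality == pytest.approx(max(0.0, q), rel=1e-9)
            n_checked += 1
        assert n_checked == 25


class TestPostFilters:
    def _del_call(self, pos, length):
        return VariantCall(pos, "N" * length, "", "het", 50.0, 100,
                           type="del", length=length)

    def test_one_base_del_in_homopolymer_flagged(self, small_ref):
        runs = [i for i in range(len(small_ref.gene_seq) - 5)
                if len(set(small_ref.gene_seq[i:i + 5])) == 1]
        assert runs, "reference contains a 5-mer homopolymer"
        call = self._del_call(runs[0] + 1, 1)
        out = fix_homopolymers([call], small_ref)
        assert out[0].homopolymer

    def test_snv_in_homopolymer_not_flagged(self, small_ref):
        runs = [i for i in range(len(small_ref.gene_seq) - 5)
                if len(set(small_ref.gene_seq[i:i + 5])) == 1]
        snv = VariantCall(runs[0] + 1, small_ref.gene_seq[runs[0] + 1], "A",
                          "het", 50.0, 100)
        out = fix_homopolymers([snv], small_ref)
        assert not out[0].homopolymer

    def test_long_deletion_not_flagged(self, full_ref):
        from amplicall.benchmark import recombinant_spec

        rec = recombinant_spec(full_ref).recombinant
        call = self._del_call(rec.del_start, rec.del_len)
        out = fix_homopolymers([call], full_ref)
        assert not out[0].homopolymer

    def test_small_indel_filter_threshold(self):
        calls = [self._del_call(100 * i, i) for i in range(1, 11)]
        kept = filter_small_indels(calls, min_len=5)
        assert sorted(c.length for c in kept) == [5, 6, 7, 8, 9, 10]

    def test_snvs_pass_through(self):
        snvs = [VariantCall(10, "A", "G", "het", 5.0, 50)]
        assert filter_small_indels(snvs) == snvs

    def test_empty_set(self):
        assert filter_small_indels([]) == []


class TestQualityOrdering:
    def test_hom_beats_het_every_replicate(self, small_ref):
        """Same depth and error rate: the hom call's quality exceeds the
        het call's in every one of 30 replicates."""
        rng = np.random.default_rng(9)
        e = 0.07
        for _ in range(30):
            n = 60
            site_h = [site_tuple(small_ref, 500)]
            rows_hom = [[0] if rng.random() < e else [1] for _ in range(n)]
            rows_het = [[1 - int(rng.random() < e)] if rng.random() < 0.5
                        else [int(rng.random() < e)] for _ in range(n)]
            alns, pile, cands = _setup(small_ref, site_h, rows_hom)
            hom_calls = call_haplotypes(cands, alns, pile, error_rate=e)
            alns, pile, cands = _setup(small_ref, site_h, rows_het)
            het_calls = call_haplotypes(cands, alns, pile, error_rate=e)
            assert hom_calls and het_calls
            assert hom_calls[0].quality > het_calls[0].quality
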
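"""Alignment: affine-gap DP vs oracles, target assignment, chimeras,
pileups, SAM round-trip."""

import numpy as np

from amplicall.align import (
    AlignParams,
    align_read,
    align_reads,
    build_pileup,
    read_sam,
    smith_waterman,
    write_sam,
    _edlib_band,
)
from amplicall.refsim import ErrorModel, SampleSpec, plant_variants, simulate_reads

from _oracles import sw_affine_score
from conftest import simulate_sample, synthetic_alignment


def _mutate(rng, seq, sub=0.05, indel=0.02):
    out = []
    bases = "ACGT"
    for ch in seq:
        u = rng.random()
        if u < indel / 2:
            continue  # deletion
        if u < indel:
            out.append(bases[rng.integers(4)])  # insertion before
        if rng.random() < sub:
            ch = bases[(bases.index(ch) + rng.integers(1, 4)) % 4]
        out.append(ch)
    return "".join(out)


class TestSmithWaterman:
    def test_exact_gene_substring(self, small_ref, small_align_params):
        sub = small_ref.gene_seq[100:1100]
        aln = align_read(("r", sub), small_ref, small_align_params,
                         check_chimera=False)
        assert aln.target == "gene"
        assert aln.start == 100
        assert aln.cigar == [("=", 1000)]

    def test_exact_pseudogene_substring(self, small_ref, small_align_params):
        sub = small_ref.pseudo_seq[200:1200]
        aln = align_read(("r", sub), small_ref, small_align_params,
                         check_chimera=False)
        assert aln.target == "pseudogene"
        assert aln.start == 200

    def test_reverse_strand_recovered(self, small_ref, small_align_params):
        from amplicall.refsim import revcomp

        sub = revcomp(small_ref.gene_seq[100:1100])
        aln = align_read(("r", sub), small_ref, small_align_params,
                         check_chimera=False)
        assert aln.strand == "-"
        assert aln.target == "gene"
        assert aln.cigar == [("=", 1000)]

    def test_score_matches_python_oracle_random_pairs(self):
        """Random 100-mers vs 500-base references: full DP == Gotoh oracle."""
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        for _ in range(15):
            q = "".join(rng.choice(bases, 100))
            r = "".join(rng.choice(bases, 500))
            score, *_ = smith_waterman(q, r)
            assert score == sw_affine_score(q, r)

    def test_score_matches_oracle_related_pairs(self):
        rng = np.random.default_rng(1)
        bases = np.array(list("ACGT"))
        for _ in range(10):
            r = "".join(rng.choice(bases, 400))
            q = _mutate(rng, r[50:350])
            score, *_ = smith_waterman(q, r)
            assert score == sw_affine_score(q, r)

    def test_banded_equals_full_dp(self):
        """200 error-laden substring reads: the seeded band reproduces the
        full dynamic program exactly."""
        rng = np.random.default_rng(2)
        bases = np.array(list("ACGT"))
        params = AlignParams()
        for _ in range(200):
            r = "".join(rng.choice(bases, 600))
            start = int(rng.integers(0, 250))
            q = _mutate(rng, r[start:start + 300])
            band, _ = _edlib_band(q, r, params.band_pad)
            full = smith_waterman(q, r, params)
            banded = smith_waterman(q, r, params, band=band)
            assert banded[0] == full[0]

    def test_cigar_consumes_query(self, small_ref, small_error_model,
                                  small_align_params):
        haps, _ = plant_variants(small_ref, SampleSpec("S", ()), seed=0)
        reads = simulate_reads(small_ref, haps, small_error_model, 15, seed=1)
        for aln in align_reads(reads, small_ref, small_align_params,
                               check_chimera=False):
            consumed = sum(l for op, l in aln.cigar if op in "=XI")
            assert consumed == aln.query_end - aln.query_start
            assert aln.ref_end <= len(small_ref.gene_seq)

    def test_short_read_unaligned(self, small_ref):
        aln = align_read(("r", "ACGT" * 50), small_ref, AlignParams())
        assert not aln.mapped

    def test_gene_assignment_specificity(self, small_ref, small_error_model,
                                         small_align_params):
        """>=99% of gene-origin reads assigned to the gene at default
        divergence."""
        haps, _ = plant_variants(small_ref, SampleSpec("S", ()), seed=0)
        reads = simulate_reads(small_ref, haps, small_error_model, 150, seed=2)
        alns = align_reads(reads, small_ref, small_align_params,
                           check_chimera=False)
        gene = sum(1 for a in alns if a.target == "gene")
        assert gene >= 0.99 * len(alns)


class TestChimera:
    def test_pure_read_single_segment(self, small_ref, small_error_model,
                                      small_align_params):
        haps, _ = plant_variants(small_ref, SampleSpec("S", ()), seed=0)
        reads = simulate_reads(small_ref, haps, small_error_model, 10, seed=3)
        alns = align_reads(reads, small_ref, small_align_params,
                           check_chimera=True)
        assert all(not a.is_chimera and len(a.segments) == 1 for a in alns)

    def test_simulated_chimeras_detected(self, full_ref):
        haps, _ = plant_variants(full_ref, SampleSpec("S", ()), seed=0)
        model = ErrorModel(chimera_rate=0.15)
        reads = simulate_reads(full_ref, haps, model, 60, seed=4)
        alns = align_reads(reads, full_ref)
        tmap = {r.read_id: r.truth for r in reads}
        n_true = sum(t.is_chimera for t in tmap.values())
        assert n_true >= 3
        detected = [a for a in alns if a.is_chimera]
        tp = [a for a in detected if tmap[a.read_id].is_chimera]
        # no false chimeras, most true ones found, junction within a window
        assert len(detected) == len(tp)
        assert len(tp) >= 0.8 * n_true
        for a in tp:
            assert abs(a.junction - tmap[a.read_id].junction) <= 256
            targets = [s.target for s in a.segments]
            assert targets == ["gene", "pseudogene"]

    def test_chimera_rate_recovered(self, full_ref):
        haps, _ = plant_variants(full_ref, SampleSpec("S", ()), seed=0)
        model = ErrorModel(chimera_rate=0.05)
        reads = simulate_reads(full_ref, haps, model, 80, seed=5)
        alns = align_reads(reads, full_ref)
        n = sum(a.is_chimera for a in alns)
        sd = np.sqrt(80 * 0.05 * 0.95)
        assert abs(n - 0.05 * 80) <= 3 * sd + 1


class TestPileup:
    def test_depth_invariant_and_counts(self, small_ref):
        site = 500
        rb = small_ref.gene_seq[site]
        alt = "A" if rb != "A" else "G"
        alns = []
        for i in range(10):
            seq = list(small_ref.gene_seq[400:700])
            if i < 5:
                seq[site - 400] = alt
            alns.append(synthetic_alignment(small_ref, f"r{i}", 400,
                                            "".join(seq)))
        pile = build_pileup(alns, small_ref)
        assert pile.depth[site] == 10
        assert pile.base_counts[:, :, site].sum() == 10
        assert pile.base_fraction(site, alt) == 0.5
        total = pile.base_counts.sum(axis=(0, 1)) + pile.del_span
        assert (pile.depth == total).all()

    def test_het_deletion_span_fraction(self, small_ref, small_error_model,
                                        small_align_params):
        from amplicall.refsim import Recombinant

        s = small_ref.exons[1][0] + 20
        spec = SampleSpec("S", (), recombinant=Recombinant(s, s + 40, (), hap=0))
        _, alns, pile, _ = simulate_sample(small_ref, spec, small_error_model,
                                           depth=80, seed=6,
                                           align_params=small_align_params)
        frac = pile.del_span[s + 20] / pile.depth[s + 20]
        assert 0.3 <= frac <= 0.7

    def test_excludes_chimeras_and_pseudogene(self, small_ref):
        a = synthetic_alignment(small_ref, "g", 0, small_ref.gene_seq[:500])
        b = synthetic_alignment(small_ref, "p", 0, small_ref.pseudo_seq[:500])
        b.target = "pseudogene"
        c = synthetic_alignment(small_ref, "c", 0, small_ref.gene_seq[:500])
        c.is_chimera = True
        pile = build_pileup([a, b, c], small_ref)
        assert pile.depth[100] == 1


class TestSamRoundTrip:
    def test_records_survive(self, small_ref, small_error_model,
                             small_align_params, tmp_path):
        haps, _ = plant_variants(small_ref, SampleSpec("S", ()), seed=0)
        reads = simulate_reads(small_ref, haps, small_error_model, 20, seed=7)
        alns = align_reads(reads, small_ref, small_align_params,
                           check_chimera=False)
        path = tmp_path / "out.sam"
        write_sam(alns, small_ref, path)
        back = read_sam(path)
        assert len(back) == len(alns)
        for a, b in zip(alns, back):
            assert (a.read_id, a.target, a.strand, a.start) == \
                   (b.read_id, b.target, b.strand, b.start)
            assert a.cigar == b.cigar
            assert a.score == b.score
            assert (a.query_start, a.query_end) == (b.query_start, b.query_end)
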
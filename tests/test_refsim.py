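"""Reference builder, variant planting and read simulator."""

import numpy as np
import pytest

from amplicall.refsim import (
    ConfigError,
    ErrorModel,
    PlantedVariant,
    SampleSpec,
    SystematicSite,
    build_reference,
    plant_variants,
    simulate_reads,
    write_fastq,
)

from conftest import TRANSITION


class TestBuildReference:
    def test_default_geometry(self, full_ref):
        assert len(full_ref.gene_seq) == 8911
        assert len(full_ref.pseudo_seq) == 8911
        assert len(full_ref.exons) == 11
        # exons disjoint, sorted, in range
        prev = 0
        for s, e in full_ref.exons:
            assert prev <= s < e <= 8911
            prev = e

    def test_exonic_identity_realized(self):
        ref = build_reference(exon_identity=96.0, seed=1)
        assert 95.5 <= ref.exonic_identity() <= 96.5
        assert set(ref.homology_map) == set(range(11))

    def test_identity_100_exons_equal(self):
        ref = build_reference(exon_identity=100.0, intron_identity=100.0, seed=2)
        assert ref.pseudo_seq == ref.gene_seq

    @pytest.mark.parametrize("kwargs", [
        {"span": 500},
        {"exon_identity": 101.0},
        {"exon_identity": 40.0},
        {"span": 1200, "n_exons": 11, "exon_len": 170},
    ])
    def test_config_errors(self, kwargs):
        with pytest.raises(ConfigError):
            build_reference(**kwargs)


class TestPlantVariants:
    def test_empty_spec_identity(self, small_ref):
        haps, truth = plant_variants(small_ref, SampleSpec("S", ()), seed=0)
        assert haps[0].seq == small_ref.gene_seq
        assert haps[1].seq == small_ref.gene_seq
        assert truth == []

    def test_hom_snv_on_both_haplotypes(self, small_ref):
        pos = small_ref.exons[0][0] + 5
        rb = small_ref.gene_seq[pos]
        spec = SampleSpec("S", (PlantedVariant(pos, rb, TRANSITION[rb], "hom"),))
        haps, _ = plant_variants(small_ref, spec, seed=0)
        for hap in haps:
            diffs = [i for i, (a, b) in enumerate(zip(hap.seq, small_ref.gene_seq))
                     if a != b]
            assert diffs == [pos]

    def test_het_snv_on_exactly_one(self, small_ref):
        pos = small_ref.exons[0][0] + 5
        rb = small_ref.gene_seq[pos]
        spec = SampleSpec("S", (PlantedVariant(pos, rb, TRANSITION[rb], "het",
                                               hap=1),))
        haps, _ = plant_variants(small_ref, spec, seed=0)
        assert haps[0].seq == small_ref.gene_seq
        assert haps[1].seq != small_ref.gene_seq

    def test_recombinant_deletion_in_cis(self, full_ref):
        from amplicall.benchmark import recombinant_spec

        spec = recombinant_spec(full_ref)
        haps, truth = plant_variants(full_ref, spec, seed=0)
        assert len(haps[0]) == len(full_ref.gene_seq) - 55
        assert len(haps[1]) == len(full_ref.gene_seq)
        del_truth = [t for t in truth if t["kind"] == "del"]
        assert len(del_truth) == 1 and del_truth[0]["length"] == 55
        # linked SNVs share the carrier haplotype
        for t in truth:
            if t.get("linked"):
                assert t["haps"] == del_truth[0]["haps"]

    def test_overlapping_variants_rejected(self, small_ref):
        pos = small_ref.exons[0][0] + 5
        rb = small_ref.gene_seq[pos]
        spec = SampleSpec("S", (
            PlantedVariant(pos, rb, TRANSITION[rb], "hom"),
            PlantedVariant(pos, rb, "C" if rb != "C" else "A", "hom"),
        ))
        with pytest.raises(ConfigError):
            plant_variants(small_ref, spec, seed=0)

    def test_ref_allele_mismatch_rejected(self, small_ref):
        pos = small_ref.exons[0][0] + 5
        wrong = "A" if small_ref.gene_seq[pos] != "A" else "C"
        spec = SampleSpec("S", (PlantedVariant(pos, wrong, "G", "hom"),))
        with pytest.raises(ConfigError):
            plant_variants(small_ref, spec, seed=0)


class TestErrorModelValidation:
    def test_bad_rates_rejected(self):
        with pytest.raises(ConfigError):
            ErrorModel(sub_rate=1.5)
        with pytest.raises(ConfigError):
            ErrorModel(transition_shares={"G": {"A": 0.9, "C": 0.3}})


class TestSimulateReads:
    def test_error_free_reads_are_substrings(self, small_ref):
        haps, _ = plant_variants(small_ref, SampleSpec("S", ()), seed=0)
        model = ErrorModel(sub_rate=0.0, homopolymer_indel_rate=0.0,
                           chimera_rate=0.0, min_read_len=500, motif_factor=1.0)
        reads = simulate_reads(small_ref, haps, model, 20, seed=3)
        from amplicall.refsim import revcomp

        for r in reads:
            seq = revcomp(r.seq) if r.truth.strand == "-" else r.seq
            assert seq in small_ref.gene_seq

    def test_seed_determinism_bytes(self, small_ref, small_error_model, tmp_path):
        haps, _ = plant_variants(small_ref, SampleSpec("S", ()), seed=0)
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        write_fastq(simulate_reads(small_ref, haps, small_error_model, 30,
                                   seed=9), p1)
        write_fastq(simulate_reads(small_ref, haps, small_error_model, 30,
                                   seed=9), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_substitution_rate_recovery(self, small_ref):
        haps, _ = plant_variants(small_ref, SampleSpec("S", ()), seed=0)
        model = ErrorModel(sub_rate=0.05, homopolymer_indel_rate=0.0,
                           chimera_rate=0.0, min_read_len=500, motif_factor=1.0)
        reads = simulate_reads(small_ref, haps, model, 100, seed=4)
        n_bases = sum(r.truth.length for r in reads)
        n_subs = sum(1 for r in reads for e in r.truth.errors if e[1] == "sub")
        expect = n_bases * 0.05
        sd = np.sqrt(n_bases * 0.05 * 0.95)
        assert abs(n_subs - expect) < 3 * sd

    def test_transition_share_recovery(self, small_ref):
        haps, _ = plant_variants(small_ref, SampleSpec("S", ()), seed=0)
        model = ErrorModel(homopolymer_indel_rate=0.0, chimera_rate=0.0,
                           min_read_len=500, motif_factor=1.0)
        reads = simulate_reads(small_ref, haps, model, 200, seed=5)
        g_errors = [e for r in reads for e in r.truth.errors
                    if e[1] == "sub" and e[2] == "G"]
        share = sum(1 for e in g_errors if e[3] == "A") / len(g_errors)
        want = model.transition_shares["G"]["A"]
        sd = np.sqrt(want * (1 - want) / len(g_errors))
        assert abs(share - want) < 4 * sd

    def test_het_hom_allele_fractions(self, small_het_sample):
        pile = small_het_sample["pileup"]
        ref = small_het_sample["ref"]
        for key, lo, hi in (("pos_het", 0.35, 0.62), ("pos_hom", 0.85, 1.0)):
            pos = small_het_sample[key]
            alt = TRANSITION[ref.gene_seq[pos]]
            assert lo <= pile.base_fraction(pos, alt) <= hi

    def test_chimera_fraction_binomial(self, small_ref):
        haps, _ = plant_variants(small_ref, SampleSpec("S", ()), seed=0)
        model = ErrorModel(chimera_rate=0.05, min_read_len=500)
        reads = simulate_reads(small_ref, haps, model, 400, seed=6)
        n = sum(r.truth.is_chimera for r in reads)
        sd = np.sqrt(400 * 0.05 * 0.95)
        assert abs(n - 20) < 3 * sd

    def test_dropout_haplotype(self, small_ref, small_error_model):
        haps, _ = plant_variants(small_ref, SampleSpec("S", ()), seed=0)
        reads = simulate_reads(small_ref, haps, small_error_model, 40, seed=7,
                               dropout_haplotype=0)
        assert all(r.truth.hap == 1 for r in reads)

    def test_systematic_site_fraction_and_strand_bias(self, small_ref):
        haps, _ = plant_variants(small_ref, SampleSpec("S", ()), seed=0)
        pos = 700
        alt = TRANSITION[small_ref.gene_seq[pos]]
        model = ErrorModel(sub_rate=0.0, homopolymer_indel_rate=0.0,
                           chimera_rate=0.0, min_read_len=500, motif_factor=1.0,
                           systematic_sites=(SystematicSite(pos, alt, 0.2,
                                                            strand_ratio=4.0),))
        reads = simulate_reads(small_ref, haps, model, 600, seed=8)
        hits = [r for r in reads if any(e[1] == "sys" for e in r.truth.errors)]
        frac = len(hits) / len(reads)
        assert abs(frac - 0.2) < 3 * np.sqrt(0.2 * 0.8 / len(reads))
        fwd = sum(1 for r in hits if r.truth.strand == "+")
        assert fwd > len(hits) / 2  # biased toward the forward strand
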
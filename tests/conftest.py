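"""Shared fixtures: a compact duplicated locus for fast end-to-end tests, a
full-size locus, and helpers for constructing synthetic alignments."""

from __future__ import annotations

import pytest
from hypothesis import settings

from amplicall.align import AlignParams, AlignedRead, align_reads, build_pileup
from amplicall.refsim import (
    DuplicatedReference,
    ErrorModel,
    PlantedVariant,
    SampleSpec,
    build_reference,
    plant_variants,
    simulate_reads,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@pytest.fixture(scope="session")
def full_ref() -> DuplicatedReference:
    return build_reference()


@pytest.fixture(scope="session")
def small_ref() -> DuplicatedReference:
    """A 1.5 kb three-exon locus: same structure, fast to align."""
    return build_reference(span=1500, n_exons=3, exon_len=120, seed=0)


@pytest.fixture(scope="session")
def small_align_params() -> AlignParams:
    return AlignParams(min_read_len=400)


@pytest.fixture(scope="session")
def small_error_model() -> ErrorModel:
    return ErrorModel(min_read_len=500, chimera_rate=0.0)


def simulate_sample(ref, spec, model, depth, seed, align_params=None,
                    check_chimera=False):
    """Simulate + align + pileup in one step for tests."""
    haps, truth = plant_variants(ref, spec, seed=seed)
    reads = simulate_reads(ref, haps, model, depth, seed=seed,
                           sample_id=spec.sample_id)
    params = align_params or AlignParams(min_read_len=400)
    aligned = align_reads(reads, ref, params, check_chimera=check_chimera)
    pileup = build_pileup(aligned, ref)
    return reads, aligned, pileup, truth


@pytest.fixture(scope="session")
def small_het_sample(small_ref, small_error_model):
    """One het + one hom SNV on the small locus at depth 120."""
    pos_het = small_ref.exons[1][0] + 30
    pos_hom = small_ref.exons[2][0] + 40
    spec = SampleSpec("T1", (
        PlantedVariant(pos_het, small_ref.gene_seq[pos_het],
                       TRANSITION[small_ref.gene_seq[pos_het]], "het", hap=0),
        PlantedVariant(pos_hom, small_ref.gene_seq[pos_hom],
                       TRANSITION[small_ref.gene_seq[pos_hom]], "hom"),
    ))
    reads, aligned, pileup, truth = simulate_sample(
        small_ref, spec, small_error_model, depth=120, seed=42)
    return {"ref": small_ref, "spec": spec, "reads": reads,
            "aligned": aligned, "pileup": pileup, "truth": truth,
            "pos_het": pos_het, "pos_hom": pos_hom}


@pytest.fixture(scope="session")
def benchmark_result():
    """The packaged six-sample calibration benchmark (shared: it is the
    expensive end-to-end scenario)."""
    from amplicall.benchmark import run_benchmark

    return run_benchmark(seed=1)


def synthetic_alignment(ref, read_id, start, seq, strand="+"):
    """An all-match alignment carrying ``seq`` at ``start`` on the gene."""
    aln = AlignedRead(read_id, "gene", strand, start, [("=", len(seq))],
                      2 * len(seq), seq, query_start=0, query_end=len(seq))
    return aln


def reads_with_alleles(ref, sites, allele_rows, start=0, length=None,
                       id_prefix="syn"):
    """Synthetic gene alignments whose bases at ``sites`` follow
    ``allele_rows`` (0 ref, 1 alt=transition partner, -1 leave reference)."""
    length = length or len(ref.gene_seq)
    out = []
    for r, row in enumerate(allele_rows):
        seq = list(ref.gene_seq[start:start + length])
        for (pos, _rb, ab), allele in zip(sites, row):
            if allele == 1:
                seq[pos - start] = ab
        out.append(synthetic_alignment(ref, f"{id_prefix}{r}", start,
                                       "".join(seq)))
    return out


def site_tuple(ref, pos):
    rb = ref.gene_seq[pos]
    return (pos, rb, TRANSITION[rb])
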
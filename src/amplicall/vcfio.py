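"""VCF 4.2 output for SNV, indel and structural-variant calls.

Positions are 1-based in the file (the package is 0-based half-open
internally); QUAL carries the Phred-scaled haplotype log-likelihood-ratio
quality; INFO records depth (DP), coverage-adjusted score (ADJQ), strand
bias p (SBP) and filter evidence; phased heterozygous genotypes use '|'
with a PS block tag.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import pysam

from .caller import VariantCall
from .fpfilter import FilterVerdict
from .phase import HaplotypeBlock
from .refsim import DuplicatedReference
from .sv import SVCall

__all__ = ["write_vcf", "read_calls"]

_HEADER_LINES = [
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth at site">',
    '##INFO=<ID=ADJQ,Number=1,Type=Float,Description="Coverage-adjusted quality Q/N (calibrated)">',
    '##INFO=<ID=SBP,Number=1,Type=Float,Description="Strand bias Fisher exact p">',
    '##INFO=<ID=TRANSITION,Number=0,Type=Flag,Description="Substitution is a transition">',
    '##INFO=<ID=RECUR,Number=1,Type=Float,Description="Median cross-sample aberrant-base fraction">',
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Structural variant length">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End of structural variant">',
    '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting reads">',
    '##FILTER=<ID=fp,Description="Classified false positive">',
    '##FILTER=<ID=indet,Description="Indeterminate adjusted score">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">',
]


def _make_header(ref: DuplicatedReference, sample_id: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID=gene,length={len(ref.gene_seq)}>")
    header.add_line(f"##contig=<ID=pseudogene,length={len(ref.pseudo_seq)}>")
    for line in _HEADER_LINES:
        header.add_line(line)
    header.add_sample(sample_id)
    return header


def write_vcf(
    calls: Sequence[VariantCall],
    ref: DuplicatedReference,
    path: str | Path,
    sample_id: str = "S",
    verdicts: Optional[dict[int, FilterVerdict]] = None,
    blocks: Optional[Sequence[HaplotypeBlock]] = None,
    sv_calls: Optional[Sequence[SVCall]] = None,
) -> None:
    header = _make_header(ref, sample_id)
    verdicts = verdicts or {}
    blocks = blocks or []
    records = []

    for call in calls:
        if call.type == "snv":
            start = call.position
            alleles = (call.ref, call.alt)
            stop = start + 1
        elif call.type == "del":
            start = max(0, call.position - 1)
            anchor = ref.gene_seq[start]
            alleles = (anchor + call.ref, anchor)
            stop = start + len(alleles[0])
        else:  # ins
            start = max(0, call.position - 1)
            anchor = ref.gene_seq[start]
            alleles = (anchor, anchor + call.alt)
            stop = start + 1
        records.append((start, stop, alleles, call))

    seen_filters: set[str] = set()
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for start, stop, alleles, call in sorted(records, key=lambda t: t[0]):
            rec = out.new_record(contig="gene", start=start, stop=stop,
                                 alleles=alleles, qual=round(call.quality, 2))
            rec.info["DP"] = call.depth
            verdict = verdicts.get(call.position)
            if verdict is not None:
                rec.info["ADJQ"] = round(verdict.adjusted_score, 4)
                rec.info["SBP"] = round(verdict.strand_bias_p, 6)
                if verdict.is_transition:
                    rec.info["TRANSITION"] = True
                if verdict.recurrence_fraction > 0:
                    rec.info["RECUR"] = round(verdict.recurrence_fraction, 4)
                if verdict.verdict == "false_positive":
                    rec.filter.add("fp")
                    seen_filters.add("fp")
                elif verdict.verdict == "indeterminate":
                    rec.filter.add("indet")
                    seen_filters.add("indet")
                else:
                    rec.filter.add("PASS")
            phase = None
            if call.genotype == "het":
                for block in blocks:
                    p = block.phase_of(call.position)
                    if p is not None:
                        phase = (block, p)
                        break
            sample = rec.samples[sample_id]
            if call.genotype == "hom":
                sample["GT"] = (1, 1)
            elif phase is not None:
                block, p = phase
                sample["GT"] = (1, 0) if p == 0 else (0, 1)
                sample.phased = True
                sample["PS"] = block.span[0] + 1
            else:
                sample["GT"] = (0, 1)
            out.write(rec)
        for sv in sv_calls or []:
            start = max(0, sv.start - 1)
            anchor = ref.gene_seq[start]
            rec = out.new_record(
                contig="gene", start=start,
                stop=sv.end,
                alleles=(anchor + ref.gene_seq[sv.start:sv.end], anchor),
            )
            rec.info["SVTYPE"] = "DEL"
            rec.info["SVLEN"] = -sv.length
            rec.info["END"] = sv.end
            rec.info["SUPPORT"] = sv.support
            rec.samples[sample_id]["GT"] = (1, 1) if sv.genotype == "hom" else (0, 1)
            out.write(rec)


def read_calls(path: str | Path) -> list[dict]:
    """Light VCF reader returning dict records (for round-trips and tests)."""
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            out.append({
                "pos0": rec.start,
                "ref": rec.ref,
                "alts": rec.alts,
                "qual": rec.qual,
                "info": dict(rec.info),
                "filter": list(rec.filter.keys()),
                "samples": {name: dict(s) for name, s in rec.samples.items()},
            })
    return out
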
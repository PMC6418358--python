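"""Structural-variant (deletion) detection from gapped alignments.

Multi-base exonic deletions — the signature of a recombinant allele arising
from gene conversion with the pseudogene — appear as long D operations in
individual read alignments and as a coverage drop over the deleted interval.
Reads whose CIGAR carries a deletion of at least ``min_sv_len`` bases are
clustered by breakpoint midpoint; each cluster's consensus breakpoints are
the per-read medians, left-normalized when the flanking sequence allows the
event to shift.  A call requires ``min_support`` reads and is genotyped from
the fraction of covering reads that span the interval with a deletion
(~0.5 heterozygous, ~1.0 homozygous).

Deletions below ``min_sv_len`` are the caller module's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .align import AlignedRead, Pileup
from .caller import _cluster_events, _collect_deletion_ops
from .refsim import DuplicatedReference

__all__ = ["SVParams", "SVCall", "detect_deletions"]


@dataclass(frozen=True)
class SVParams:
    min_sv_len: int = 30
    merge_dist: int = 20
    min_support: int = 10
    hom_fraction: float = 0.8
    het_fraction: float = 0.25


@dataclass
class SVCall:
    type: str                # "deletion"
    start: int               # 0-based half-open on gene
    end: int
    support: int
    het_fraction: float      # deletion-span coverage fraction in the interval
    genotype: str            # "het" | "hom"
    overlap_flag: bool = False
    linked_snvs: list = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def _left_normalize(seq: str, start: int, length: int) -> int:
    """Shift a deletion left while the base leaving on the right equals the
    base entering on the left (standard VCF-style normalization)."""
    while start > 0 and seq[start - 1] == seq[start + length - 1]:
        start -= 1
    return start


def detect_deletions(
    aligned_reads: Sequence[AlignedRead],
    pileup: Pileup,
    ref: DuplicatedReference,
    params: SVParams = SVParams(),
) -> list[SVCall]:
    """Cluster long deletion CIGAR operations into consensus deletion calls."""
    events = [
        ev for ev in _collect_deletion_ops(aligned_reads, min_len=params.min_sv_len)
    ]
    calls: list[SVCall] = []
    clusters = _cluster_events(events, params.merge_dist)
    for cluster in clusters:
        if len(cluster) < params.min_support:
            continue
        starts = np.array([s for _, s, _ in cluster])
        lengths = np.array([l for _, _, l in cluster])
        start = int(np.median(starts))
        length = int(np.median(lengths))
        start = _left_normalize(ref.gene_seq, start, length)
        end = start + length
        inner = pileup.del_span[start:end]
        depth = pileup.depth[start:end]
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = float(np.median(
                np.where(depth > 0, inner / np.maximum(depth, 1), 0.0)))
        if frac < params.het_fraction:
            continue
        genotype = "hom" if frac >= params.hom_fraction else "het"
        calls.append(SVCall("deletion", start, end, len(cluster), frac, genotype))

    calls.sort(key=lambda c: c.start)
    for i, a in enumerate(calls):
        for b in calls[i + 1:]:
            if b.start < a.end and a.start < b.end:
                a.overlap_flag = b.overlap_flag = True
    return calls
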
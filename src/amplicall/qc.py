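"""Run-level quality metrics for long-read amplicon data.

Implements the NanoOK-style summary statistics used to judge a run and to
characterize its systematic errors: read-length N50, aligned identity with
and without indels (ABID / IBAB), the erroneous-substitution spectrum, and
ranked error-prone k-mer motifs.  Identity metrics are computed over
gene-target alignments only; pseudogene-attracted reads are a separate
quantity reported by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .align import AlignedRead
from .refsim import DuplicatedReference, seq_to_codes

__all__ = [
    "RunMetrics",
    "compute_n50",
    "compute_identity",
    "substitution_spectrum",
    "kmer_error_motifs",
    "run_metrics",
]

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_B = "ACGT"


@dataclass
class RunMetrics:
    n50: int
    abid: float
    ibab: float
    sub_spectrum: dict
    kmer_error_table: pd.DataFrame
    mean_coverage: float

    def to_frame(self) -> pd.DataFrame:
        rows = {"n50": self.n50, "abid": self.abid, "ibab": self.ibab,
                "mean_coverage": self.mean_coverage,
                "transitions": self.sub_spectrum.get("transitions", 0.0)}
        pairs = sorted(k for k in self.sub_spectrum if isinstance(k, tuple))
        for rb, ab in pairs:
            rows[f"sub_{rb}>{ab}"] = self.sub_spectrum[(rb, ab)]
        return pd.DataFrame([rows])


def compute_n50(read_lengths: Sequence[int]) -> int:
    """Largest length x such that reads of length >= x hold half the bases."""
    if len(read_lengths) == 0:
        raise ValueError("compute_n50 requires a non-empty length list")
    lengths = np.sort(np.asarray(read_lengths, dtype=np.int64))[::-1]
    if (lengths <= 0).any():
        raise ValueError("read lengths must be positive")
    half = lengths.sum() / 2.0
    cum = np.cumsum(lengths)
    return int(lengths[np.searchsorted(cum, half)])


def _gene_alignments(alignments: Sequence[AlignedRead]) -> list[AlignedRead]:
    return [a for a in alignments
            if a.mapped and a.target == "gene" and not a.is_chimera]


def compute_identity(alignments: Sequence[AlignedRead]) -> tuple[float, float]:
    """(ABID, IBAB) percent identities pooled over gene alignments.

    ABID = 100 * matches / (matches + mismatches);
    IBAB = 100 * matches / (matches + mismatches + inserted + deleted bases).
    """
    gene = _gene_alignments(alignments)
    if not gene:
        raise ValueError("compute_identity requires >=1 gene alignment")
    m = x = ins = dele = 0
    for a in gene:
        for op, length in a.cigar:
            if op == "=":
                m += length
            elif op == "X":
                x += length
            elif op == "I":
                ins += length
            elif op == "D":
                dele += length
    if m + x == 0:
        raise ValueError("alignments contain no aligned (match/mismatch) columns")
    abid = 100.0 * m / (m + x)
    ibab = 100.0 * m / (m + x + ins + dele)
    return abid, ibab


def _mismatch_positions(
    alignments: Sequence[AlignedRead],
    ref: DuplicatedReference,
) -> tuple[np.ndarray, np.ndarray]:
    """(ref positions, observed base codes) of every mismatch column."""
    ref_codes = ref.gene_codes
    pos_list = []
    obs_list = []
    for a in _gene_alignments(alignments):
        codes = seq_to_codes(a.seq)
        q, r = a.query_start, a.start
        for op, length in a.cigar:
            if op in "=XM":
                # compare bases rather than trusting the op, so M-style
                # CIGARs are handled identically
                pos_list.append(np.arange(r, r + length))
                obs_list.append(codes[q:q + length])
                q += length
                r += length
            elif op == "I":
                q += length
            elif op == "D":
                r += length
    if not pos_list:
        return np.empty(0, np.int64), np.empty(0, np.uint8)
    pos = np.concatenate(pos_list)
    obs = np.concatenate(obs_list)
    keep = ref_codes[pos] != obs
    return pos[keep], obs[keep]


def substitution_spectrum(
    alignments: Sequence[AlignedRead],
    ref: DuplicatedReference,
) -> dict:
    """Share of each ref>alt substitution among all mismatch columns.

    Returns a dict with 12 ``(ref, alt)`` keys (shares summing to 1 when any
    mismatches exist) plus a ``"transitions"`` subtotal.
    """
    pos, obs = _mismatch_positions(alignments, ref)
    spectrum = {(rb, ab): 0.0 for rb in _B for ab in _B if rb != ab}
    if len(pos) == 0:
        return {**spectrum, "transitions": 0.0}
    ref_codes = ref.gene_codes[pos]
    counts = np.zeros((4, 4), dtype=np.int64)
    np.add.at(counts, (ref_codes, obs), 1)
    total = counts.sum()
    for i, rb in enumerate(_B):
        for j, ab in enumerate(_B):
            if i != j:
                spectrum[(rb, ab)] = counts[i, j] / total
    spectrum["transitions"] = sum(
        v for k, v in spectrum.items() if isinstance(k, tuple) and k in TRANSITIONS
    )
    return spectrum


def kmer_error_motifs(
    alignments: Sequence[AlignedRead],
    ref: DuplicatedReference,
    k: int = 4,
    error_pos: int = 2,
) -> pd.DataFrame:
    """Rank reference k-mers by substitution errors at a fixed in-kmer offset.

    For each k-mer, counts mismatch columns that fall at offset ``error_pos``
    (0-based; default the third base of a 4-mer) of an occurrence of that
    k-mer in the reference, and reports an enrichment ratio against the
    error share expected from the k-mer's frequency in the reference.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not (0 <= error_pos < k):
        raise ValueError("error_pos must lie inside the k-mer")
    pos, _ = _mismatch_positions(alignments, ref)
    seq = ref.gene_seq
    L = len(seq)

    kmer_freq: dict[str, int] = {}
    for i in range(L - k + 1):
        km = seq[i:i + k]
        kmer_freq[km] = kmer_freq.get(km, 0) + 1

    err_counts: dict[str, int] = {}
    for p in pos:
        start = p - error_pos
        if 0 <= start <= L - k:
            km = seq[start:start + k]
            err_counts[km] = err_counts.get(km, 0) + 1

    total_err = max(1, len(pos))
    total_kmers = max(1, L - k + 1)
    rows = []
    for km, cnt in err_counts.items():
        expected_share = kmer_freq.get(km, 0) / total_kmers
        share = cnt / total_err
        rows.append({
            "kmer": km, "errors": cnt, "share": share,
            "ref_occurrences": kmer_freq.get(km, 0),
            "enrichment": share / expected_share if expected_share > 0 else np.inf,
        })
    table = pd.DataFrame(rows, columns=["kmer", "errors", "share",
                                        "ref_occurrences", "enrichment"])
    return table.sort_values(["errors", "kmer"],
                             ascending=[False, True]).reset_index(drop=True)


def run_metrics(
    alignments: Sequence[AlignedRead],
    ref: DuplicatedReference,
    pileup_depth: Optional[np.ndarray] = None,
) -> RunMetrics:
    """Aggregate QC report for one sample."""
    lengths = [a.query_len for a in alignments if a.query_len > 0]
    abid, ibab = compute_identity(alignments)
    spectrum = substitution_spectrum(alignments, ref)
    table = kmer_error_motifs(alignments, ref)
    if pileup_depth is not None:
        mean_cov = float(np.mean(pileup_depth))
    else:
        mean_cov = float(len(_gene_alignments(alignments)))
    return RunMetrics(compute_n50(lengths), abid, ibab, spectrum, table, mean_cov)
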
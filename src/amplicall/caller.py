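"""Haplotype-likelihood diploid variant calling in base space.

Candidate SNVs are considered jointly within windows: for every subset of a
window's candidates and every assignment of the chosen alternate alleles to
the two haplotypes of a diploid configuration, the read set's log-likelihood
is computed under a per-base error model (a read base matches its haplotype
base with probability 1-e, else e/3).  A read's likelihood under a diploid
configuration is the even 50/50 mixture over the two configuration
haplotypes, the standard diploid genotype likelihood; a hard max-assignment
variant is available behind a flag.  The winning configuration's variants
are emitted, each with quality

    Q = (log L(called configuration) - log L(homozygous reference)) * 10/ln 10,

i.e. a Phred-scaled log-likelihood ratio against the reference haplotype
pair, the quantity that downstream coverage-adjusted filtering divides by
read depth.  Ploidy is fixed at 2.

The error rate e is estimated per sample from the aligned base identity
(ABID) of the same alignments unless supplied.

Indel events (from deletion/insertion CIGAR operations) are genotyped with
the same two-allele machinery; calls shorter than ``min_indel_len`` (default
5, reflecting the unreliability of small nanopore indels) are removed, and
indel calls inside homopolymer runs are flagged and suppressed by default.
Deletions at or above the structural-variant boundary (default 30) are left
to the sv module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .align import AlignedRead, Pileup
from .refsim import DuplicatedReference, seq_to_codes

__all__ = [
    "CallerParams",
    "CandidateSite",
    "VariantCall",
    "enumerate_candidates",
    "call_haplotypes",
    "fix_homopolymers",
    "filter_small_indels",
    "call_variants",
    "estimate_error_rate",
]

_B = "ACGT"
PHRED = 10.0 / math.log(10.0)


@dataclass(frozen=True)
class CallerParams:
    min_frac: float = 0.2
    min_depth: int = 20
    window: int = 100
    merge_dist: int = 50
    max_candidates: int = 8
    error_rate: Optional[float] = None
    hard_assign: bool = False
    min_indel_len: int = 5
    sv_boundary: int = 30
    homopolymer_min_run: int = 4


@dataclass(frozen=True)
class CandidateSite:
    position: int
    ref: str
    alt: str
    depth: int
    alt_count: int

    @property
    def alt_fraction(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0


@dataclass
class VariantCall:
    position: int            # 0-based on gene
    ref: str
    alt: str
    genotype: str            # "het" | "hom"
    quality: float           # Phred-scaled log-likelihood ratio vs hom-ref
    depth: int
    strand_counts: tuple = (0, 0, 0, 0)  # ref_fwd, ref_rev, alt_fwd, alt_rev
    type: str = "snv"        # "snv" | "ins" | "del"
    length: int = 0
    homopolymer: bool = False
    hap_alleles: tuple = (0, 0)

    @property
    def adjusted_score(self) -> float:
        return self.quality / self.depth if self.depth else 0.0


def estimate_error_rate(alignments: Sequence[AlignedRead]) -> float:
    """Per-base mismatch rate from ABID; clamped to a sane range."""
    from .qc import compute_identity

    abid, _ = compute_identity(alignments)
    return float(np.clip(1.0 - abid / 100.0, 1e-4, 0.5))


# ---------------------------------------------------------------------------
# Candidate enumeration
# ---------------------------------------------------------------------------

def enumerate_candidates(
    pileup: Pileup,
    ref: DuplicatedReference,
    params: CallerParams = CallerParams(),
) -> list[CandidateSite]:
    """Sites whose best non-reference base reaches the candidate thresholds."""
    counts = pileup.base_counts.sum(axis=0)       # (4, L)
    depth = pileup.depth
    ref_codes = ref.gene_codes
    L = pileup.length
    nonref = counts.copy()
    nonref[ref_codes, np.arange(L)] = -1
    best_alt = nonref.argmax(axis=0)
    best_cnt = nonref.max(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(depth > 0, best_cnt / np.maximum(depth, 1), 0.0)
    hits = np.flatnonzero((depth >= params.min_depth) & (frac >= params.min_frac))
    return [
        CandidateSite(int(p), _B[ref_codes[p]], _B[best_alt[p]],
                      int(depth[p]), int(best_cnt[p]))
        for p in hits
    ]


def _windows(candidates: list[CandidateSite], params: CallerParams) -> list[list[CandidateSite]]:
    """Group candidates into windows: break on gaps > merge_dist or when the
    window exceeds its width; cap the subset search at max_candidates."""
    groups: list[list[CandidateSite]] = []
    for cand in sorted(candidates, key=lambda c: c.position):
        if groups:
            cur = groups[-1]
            if (cand.position - cur[-1].position <= params.merge_dist
                    and cand.position - cur[0].position <= params.window
                    and len(cur) < params.max_candidates):
                cur.append(cand)
                continue
        groups.append([cand])
    return groups


# ---------------------------------------------------------------------------
# Read evidence
# ---------------------------------------------------------------------------

def _site_matrix(
    aligned_reads: Sequence[AlignedRead],
    sites: Sequence[CandidateSite],
) -> np.ndarray:
    """Reads x sites observation matrix: 1 alt, 0 ref, -1 missing/other."""
    positions = np.array([s.position for s in sites])
    ref_codes = np.array([seq_to_codes(s.ref)[0] for s in sites])
    alt_codes = np.array([seq_to_codes(s.alt)[0] for s in sites])
    rows = []
    for aln in aligned_reads:
        if not aln.mapped or aln.target != "gene" or aln.is_chimera:
            continue
        start, arr = aln.ref_profile()
        row = np.full(len(sites), -1, dtype=np.int8)
        inside = (positions >= start) & (positions < start + len(arr))
        obs = arr[positions[inside] - start]
        vals = np.full(obs.shape, -1, dtype=np.int8)
        vals[obs == ref_codes[inside]] = 0
        vals[obs == alt_codes[inside]] = 1
        row[inside] = vals
        rows.append(row)
    if not rows:
        return np.empty((0, len(sites)), dtype=np.int8)
    return np.vstack(rows)


# ---------------------------------------------------------------------------
# Diploid configuration search
# ---------------------------------------------------------------------------

def _hap_logliks(M: np.ndarray, e: float) -> np.ndarray:
    """Log-likelihood of each read under each haplotype allele vector.

    Returns (n_reads, 2**S); column v encodes alt alleles at the bits of v.
    """
    n, S = M.shape
    V = 1 << S
    H = ((np.arange(V)[None, :] >> np.arange(S)[:, None]) & 1).astype(np.float64)
    A1 = (M == 1).astype(np.float64)
    A0 = (M == 0).astype(np.float64)
    obs = A1 + A0
    match = A1 @ H + A0 @ (1.0 - H)
    total = obs.sum(axis=1, keepdims=True)
    log_m = math.log1p(-e)
    log_x = math.log(e / 3.0)
    return match * log_m + (total - match) * log_x


def _config_loglik(hl: np.ndarray, v1: int, v2: int, hard: bool) -> float:
    a = hl[:, v1]
    b = hl[:, v2]
    if hard:
        return float(np.maximum(a, b).sum())
    return float(np.logaddexp(a, b).sum()) - hl.shape[0] * math.log(2.0)


def _best_configuration(
    hl: np.ndarray, S: int, hard: bool
) -> tuple[tuple[int, int], float, float]:
    """Exhaustive diploid configuration search over 2^S x 2^S (unordered)."""
    V = 1 << S
    n = hl.shape[0]
    if hard:
        def pair_ll(i):
            return np.maximum(hl[:, i:i + 1], hl[:, i:]).sum(axis=0)
    else:
        def pair_ll(i):
            return np.logaddexp(hl[:, i:i + 1], hl[:, i:]).sum(axis=0) - n * math.log(2.0)

    best_ll = -np.inf
    best_pair = (0, 0)
    best_weight = 0
    for i in range(V):
        lls = pair_ll(i)
        for off in range(lls.shape[0]):
            j = i + off
            ll = lls[off]
            w = int(bin(i).count("1") + bin(j).count("1"))
            if ll > best_ll + 1e-9 or (abs(ll - best_ll) <= 1e-9 and w < best_weight):
                best_ll = float(ll)
                best_pair = (i, j)
                best_weight = w
    ref_ll = _config_loglik(hl, 0, 0, hard)
    return best_pair, best_ll, ref_ll


def call_haplotypes(
    candidates: Sequence[CandidateSite],
    aligned_reads: Sequence[AlignedRead],
    pileup: Pileup,
    params: CallerParams = CallerParams(),
    error_rate: Optional[float] = None,
) -> list[VariantCall]:
    """Window-wise exhaustive diploid haplotype-likelihood calling."""
    e = error_rate if error_rate is not None else (
        params.error_rate if params.error_rate is not None
        else estimate_error_rate(aligned_reads)
    )
    calls: list[VariantCall] = []
    for window in _windows(list(candidates), params):
        M = _site_matrix(aligned_reads, window)
        if M.shape[0] == 0:
            continue
        S = len(window)
        hl = _hap_logliks(M, e)
        (v1, v2), best_ll, ref_ll = _best_configuration(hl, S, params.hard_assign)
        if (v1, v2) == (0, 0):
            continue
        q = max(0.0, (best_ll - ref_ll) * PHRED)
        for s_idx, site in enumerate(window):
            a1 = (v1 >> s_idx) & 1
            a2 = (v2 >> s_idx) & 1
            if a1 == 0 and a2 == 0:
                continue
            genotype = "hom" if (a1 and a2) else "het"
            calls.append(VariantCall(
                site.position, site.ref, site.alt, genotype, q,
                site.depth, pileup.strand_counts(site.position, site.ref, site.alt),
                "snv", 0, hap_alleles=(a1, a2),
            ))
    return calls


# ---------------------------------------------------------------------------
# Indel events
# ---------------------------------------------------------------------------

def _collect_deletion_ops(aligned_reads: Sequence[AlignedRead], min_len: int = 1):
    """(read_index, start, length) of deletion CIGAR ops on gene alignments,
    merging D ops separated by <= 5 aligned bases within a read."""
    events = []
    for idx, aln in enumerate(aligned_reads):
        if not aln.mapped or aln.target != "gene" or aln.is_chimera:
            continue
        r = aln.start
        raw = []
        for op, length in aln.cigar:
            if op == "D":
                raw.append([r, length])
                r += length
            elif op in "=X":
                r += length
        merged = []
        for s, l in raw:
            if merged and s - (merged[-1][0] + merged[-1][1]) <= 5:
                merged[-1][1] = s + l - merged[-1][0]
            else:
                merged.append([s, l])
        for s, l in merged:
            if l >= min_len:
                events.append((idx, s, l))
    return events


def _cluster_events(events, merge_dist: int):
    """Cluster (read, start, length) deletion events by breakpoint midpoint."""
    clusters: list[list[tuple[int, int, int]]] = []
    for ev in sorted(events, key=lambda t: (t[1] + t[1] + t[2]) / 2):
        mid = ev[1] + ev[2] / 2
        if clusters:
            last = clusters[-1]
            last_mid = float(np.median([s + l / 2 for _, s, l in last]))
            if abs(mid - last_mid) <= merge_dist:
                last.append(ev)
                continue
        clusters.append([ev])
    return clusters


def call_indels(
    aligned_reads: Sequence[AlignedRead],
    pileup: Pileup,
    ref: DuplicatedReference,
    params: CallerParams = CallerParams(),
    error_rate: Optional[float] = None,
    min_len: int = 1,
    max_len: Optional[int] = None,
) -> list[VariantCall]:
    """Genotype clustered deletion events with the two-allele likelihood."""
    e = error_rate if error_rate is not None else (
        params.error_rate if params.error_rate is not None
        else estimate_error_rate(aligned_reads)
    )
    max_len = max_len if max_len is not None else params.sv_boundary - 1
    events = _collect_deletion_ops(aligned_reads, min_len=min_len)
    calls: list[VariantCall] = []
    for cluster in _cluster_events(events, merge_dist=20):
        start = int(np.median([s for _, s, _ in cluster]))
        length = int(np.median([l for _, _, l in cluster]))
        if not (min_len <= length <= max_len):
            continue
        support = len(cluster)
        mid = start + length // 2
        depth = int(pileup.depth[min(mid, pileup.length - 1)])
        if depth < params.min_depth or support / max(depth, 1) < params.min_frac:
            continue
        # two-allele likelihood: allele 1 = carries the deletion
        n_alt = support
        n_ref = max(depth - support, 0)
        log_m, log_x = math.log1p(-e), math.log(e / 3.0)
        def geno_ll(f_alt_hap1, f_alt_hap2):
            # mixture over haplotypes for each read class
            ll = 0.0
            for count, is_alt in ((n_alt, 1), (n_ref, 0)):
                p1 = log_m if f_alt_hap1 == is_alt else log_x
                p2 = log_m if f_alt_hap2 == is_alt else log_x
                ll += count * (np.logaddexp(p1, p2) - math.log(2.0))
            return ll
        ll_ref = geno_ll(0, 0)
        ll_het = geno_ll(1, 0)
        ll_hom = geno_ll(1, 1)
        best = max(ll_het, ll_hom)
        if best <= ll_ref:
            continue
        genotype = "hom" if ll_hom >= ll_het else "het"
        q = max(0.0, (best - ll_ref) * PHRED)
        calls.append(VariantCall(
            start, ref.gene_seq[start:start + length], "", genotype, q, depth,
            (0, 0, 0, 0), "del", length,
            hap_alleles=(1, 1) if genotype == "hom" else (1, 0),
        ))
    return calls


# ---------------------------------------------------------------------------
# Post-call filters
# ---------------------------------------------------------------------------

def _homopolymer_runs(seq: str, min_run: int) -> list[tuple[int, int]]:
    runs = []
    i = 0
    L = len(seq)
    while i < L:
        j = i
        while j < L and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            runs.append((i, j))
        i = j
    return runs


def fix_homopolymers(
    calls: Sequence[VariantCall],
    ref: DuplicatedReference,
    min_run: int = 4,
) -> list[VariantCall]:
    """Flag indel calls whose interval lies inside a homopolymer run.

    SNVs are untouched.  Flagged calls are downweighted (suppressed by the
    pipeline), not deleted here.
    """
    runs = _homopolymer_runs(ref.gene_seq, min_run)
    out = []
    for call in calls:
        if call.type == "snv":
            out.append(call)
            continue
        lo = call.position
        hi = call.position + max(call.length, 1)
        inside = any(s <= lo and hi <= e + 1 for s, e in runs)
        out.append(replace(call, homopolymer=True) if inside else call)
    return out


def filter_small_indels(
    calls: Sequence[VariantCall],
    min_len: int = 5,
) -> list[VariantCall]:
    """Remove indel calls shorter than ``min_len`` bases; SNVs pass through."""
    return [c for c in calls if c.type == "snv" or c.length >= min_len]


def call_variants(
    aligned_reads: Sequence[AlignedRead],
    pileup: Pileup,
    ref: DuplicatedReference,
    params: CallerParams = CallerParams(),
) -> list[VariantCall]:
    """Full per-sample calling: SNVs + sub-SV indels, homopolymer and size
    filtered."""
    e = (params.error_rate if params.error_rate is not None
         else estimate_error_rate(aligned_reads))
    candidates = enumerate_candidates(pileup, ref, params)
    calls = call_haplotypes(candidates, aligned_reads, pileup, params, error_rate=e)
    calls += call_indels(aligned_reads, pileup, ref, params, error_rate=e)
    calls = fix_homopolymers(calls, ref, params.homopolymer_min_run)
    calls = [c for c in calls if not c.homopolymer]
    calls = filter_small_indels(calls, params.min_indel_len)
    return sorted(calls, key=lambda c: c.position)
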
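"""Synthetic duplicated locus and nanopore-like amplicon read simulation.

This module builds a gene/pseudogene pair that mimics a hard clinical target:
an ~8.9 kb single-amplicon gene whose coding exons share ~96% identity with a
nearby pseudogene, so that misalignment, PCR chimerism and recombinant alleles
are all realistically confusable.  On top of the reference it plants diploid
variant sets (het/hom SNVs, a recombinant haplotype carrying a multi-base
exonic deletion with linked SNVs in cis, a multi-SNP phased haplotype) and
simulates long reads with the error structure characteristic of nanopore
amplicon runs: transition-dominated substitutions, homopolymer-length indels,
sequence-motif error hotspots, strand-biased systematic error sites, and
gene/pseudogene PCR chimeras.

Every read carries a truth record, so downstream modules can be scored
without external ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DuplicatedReference",
    "ErrorModel",
    "SystematicSite",
    "PlantedVariant",
    "Recombinant",
    "SampleSpec",
    "Haplotype",
    "ReadTruth",
    "SimRead",
    "build_reference",
    "plant_variants",
    "simulate_reads",
    "write_fasta",
    "write_fastq",
    "write_exon_bed",
    "write_truth_tsv",
    "DEFAULT_SPAN",
    "DEFAULT_REGION_LABEL",
]

# Target span mirrors an 8.9 kb amplicon: chr1:155,202,296-155,211,206 inclusive.
DEFAULT_SPAN = 155_211_206 - 155_202_296 + 1  # 8911
DEFAULT_REGION_LABEL = "chr1:155202296-155211206"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i
_COMP = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G in code space


class ConfigError(ValueError):
    """Raised for invalid reference / simulation configuration."""


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode an ACGT string as uint8 codes 0..3."""
    arr = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return arr


def codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


def revcomp(seq: str) -> str:
    return codes_to_seq(revcomp_codes(seq_to_codes(seq)))


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DuplicatedReference:
    """Gene + pseudogene pair with exon annotation.

    Coordinates are 0-based half-open on the gene copy throughout the
    package; only VCF output is 1-based.
    """

    gene_seq: str
    pseudo_seq: str
    exons: tuple[tuple[int, int], ...]
    homology_map: dict[int, float]
    region_label: str = DEFAULT_REGION_LABEL

    def __post_init__(self):
        L = len(self.gene_seq)
        prev_end = 0
        for start, end in self.exons:
            if not (0 <= start < end <= L):
                raise ConfigError(f"exon ({start},{end}) outside [0,{L})")
            if start < prev_end:
                raise ConfigError("exons overlap or are unsorted")
            prev_end = end

    @property
    def gene_codes(self) -> np.ndarray:
        return seq_to_codes(self.gene_seq)

    @property
    def pseudo_codes(self) -> np.ndarray:
        return seq_to_codes(self.pseudo_seq)

    def exon_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.gene_seq), dtype=bool)
        for s, e in self.exons:
            mask[s:e] = True
        return mask

    def exonic_identity(self) -> float:
        """Realized percent identity between gene and pseudogene over exons."""
        mask = self.exon_mask()
        g = self.gene_codes[mask]
        p = self.pseudo_codes[mask]
        return 100.0 * float((g == p).mean())


def _default_exons(span: int, n_exons: int, exon_len: int) -> tuple[tuple[int, int], ...]:
    margin = min(400, span // 10)
    usable = span - 2 * margin
    if usable < n_exons * exon_len + (n_exons - 1) * 10:
        raise ConfigError(
            f"span {span} too short for {n_exons} exons of {exon_len} bases"
        )
    if n_exons == 1:
        starts = [margin]
    else:
        step = (usable - exon_len) / (n_exons - 1)
        starts = [margin + int(round(i * step)) for i in range(n_exons)]
    return tuple((s, s + exon_len) for s in starts)


def build_reference(
    span: int = DEFAULT_SPAN,
    n_exons: int = 11,
    exon_len: int = 170,
    exon_identity: float = 96.0,
    intron_identity: float = 97.0,
    seed: int = 0,
    region_label: str = DEFAULT_REGION_LABEL,
) -> DuplicatedReference:
    """Build the synthetic duplicated locus.

    The pseudogene copy is derived from the gene copy by seeded random
    substitutions: enough exonic substitutions to realize ``exon_identity``
    percent identity over exons, and intronic substitutions to realize
    ``intron_identity`` outside them.  Intronic divergence is kept slightly
    higher-identity than a fully random neighbour but nonzero, so that
    read windows are informative about their template everywhere along the
    amplicon (as they are for a real pseudogene), not only inside exons.
    """
    if span < 1000:
        raise ConfigError("configured span must be >= 1 kb")
    for name, ident in (("exon_identity", exon_identity), ("intron_identity", intron_identity)):
        if not (50.0 < ident <= 100.0):
            raise ConfigError(f"{name} must lie in (50, 100], got {ident}")
    exons = _default_exons(span, n_exons, exon_len)

    rng = np.random.default_rng(seed)
    gene = rng.integers(0, 4, size=span).astype(np.uint8)
    pseudo = gene.copy()

    mask = np.zeros(span, dtype=bool)
    for s, e in exons:
        mask[s:e] = True
    for region_mask, ident in ((mask, exon_identity), (~mask, intron_identity)):
        positions = np.flatnonzero(region_mask)
        n_sub = int(round(len(positions) * (100.0 - ident) / 100.0))
        if n_sub == 0:
            continue
        chosen = rng.choice(positions, size=n_sub, replace=False)
        shift = rng.integers(1, 4, size=n_sub).astype(np.uint8)
        pseudo[chosen] = (pseudo[chosen] + shift) % 4

    gene_seq = codes_to_seq(gene)
    pseudo_seq = codes_to_seq(pseudo)
    homology = {}
    for i, (s, e) in enumerate(exons):
        homology[i] = 100.0 * float((gene[s:e] == pseudo[s:e]).mean())
    return DuplicatedReference(gene_seq, pseudo_seq, exons, homology, region_label)


# ---------------------------------------------------------------------------
# Sample specification and haplotype construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedVariant:
    position: int           # 0-based on gene
    ref: str
    alt: str
    zygosity: str           # "het" | "hom"
    hap: Optional[int] = None  # for het: 0 or 1; None -> assigned by seed

    def __post_init__(self):
        if self.zygosity not in ("het", "hom"):
            raise ConfigError(f"zygosity must be het|hom, got {self.zygosity}")
        if self.hap is not None and self.hap not in (0, 1):
            raise ConfigError("hap must be 0 or 1")


@dataclass(frozen=True)
class Recombinant:
    """A recombinant-allele signature: exonic deletion + linked SNVs in cis."""

    del_start: int
    del_end: int            # half-open
    linked_snvs: tuple[tuple[int, str, str], ...] = ()
    hap: int = 0

    @property
    def del_len(self) -> int:
        return self.del_end - self.del_start


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    variants: tuple[PlantedVariant, ...] = ()
    recombinant: Optional[Recombinant] = None
    haplotype_snps: tuple[tuple[int, str, str], ...] = ()
    haplotype_snps_hap: Optional[int] = 1  # None -> hom (both haplotypes)
    depth: int = 100


@dataclass(frozen=True)
class Haplotype:
    """One parental sequence plus a map back to gene coordinates.

    ``to_gene[i]`` is the gene coordinate of haplotype base ``i``; bases
    deleted on this haplotype have no entry.
    """

    seq: str
    to_gene: np.ndarray
    events: tuple = ()

    def __len__(self) -> int:
        return len(self.seq)


def _apply_events(
    gene_codes: np.ndarray,
    snvs: Sequence[tuple[int, str, str]],
    deletion: Optional[tuple[int, int]],
) -> Haplotype:
    codes = gene_codes.copy()
    for pos, ref, alt in snvs:
        if _CODE[ord(ref)] != codes[pos]:
            raise ConfigError(
                f"planted ref allele {ref} does not match reference at {pos}"
            )
        codes[pos] = _CODE[ord(alt)]
    to_gene = np.arange(len(codes), dtype=np.int64)
    if deletion is not None:
        s, e = deletion
        keep = np.ones(len(codes), dtype=bool)
        keep[s:e] = False
        codes = codes[keep]
        to_gene = to_gene[keep]
    return Haplotype(codes_to_seq(codes), to_gene, tuple(snvs))


def plant_variants(
    ref: DuplicatedReference,
    spec: SampleSpec,
    seed: int = 0,
) -> tuple[tuple[Haplotype, Haplotype], list[dict]]:
    """Construct the diploid haplotype pair for a sample spec.

    Hom variants go on both haplotypes; het variants on exactly one (the
    spec's ``hap`` if given, else a seeded coin flip).  The recombinant
    deletion and its linked SNVs are placed in cis on one haplotype.
    Returns the pair and a truth table (one record per planted event with
    its haplotype assignment).
    """
    rng = np.random.default_rng(seed)
    L = len(ref.gene_seq)
    per_hap: list[list[tuple[int, str, str]]] = [[], []]
    truth: list[dict] = []
    seen: dict[tuple[int, int], str] = {}

    all_snvs = list(spec.variants)
    for pos, rb, ab in spec.haplotype_snps:
        zyg = "hom" if spec.haplotype_snps_hap is None else "het"
        all_snvs.append(PlantedVariant(pos, rb, ab, zyg, spec.haplotype_snps_hap))

    for var in all_snvs:
        if not (0 <= var.position < L):
            raise ConfigError(f"planted site {var.position} outside gene span")
        haps = (0, 1) if var.zygosity == "hom" else (
            (var.hap,) if var.hap is not None else (int(rng.integers(0, 2)),)
        )
        for h in haps:
            key = (h, var.position)
            if key in seen:
                raise ConfigError(
                    f"overlapping planted variants at {var.position} on haplotype {h}"
                )
            seen[key] = var.alt
            per_hap[h].append((var.position, var.ref, var.alt))
        truth.append({
            "position": var.position, "ref": var.ref, "alt": var.alt,
            "zygosity": var.zygosity, "haps": haps, "kind": "snv",
        })

    deletion_by_hap: list[Optional[tuple[int, int]]] = [None, None]
    if spec.recombinant is not None:
        rec = spec.recombinant
        if not (0 <= rec.del_start < rec.del_end <= L):
            raise ConfigError("recombinant deletion interval outside gene span")
        flank = 20
        if not any(s - flank <= rec.del_start and rec.del_end <= e + flank
                   for s, e in ref.exons):
            raise ConfigError("recombinant deletion must lie within one exon (± flanks)")
        deletion_by_hap[rec.hap] = (rec.del_start, rec.del_end)
        for pos, rb, ab in rec.linked_snvs:
            key = (rec.hap, pos)
            if key in seen:
                raise ConfigError(f"linked SNV collides at {pos}")
            seen[key] = ab
            per_hap[rec.hap].append((pos, rb, ab))
            truth.append({
                "position": pos, "ref": rb, "alt": ab, "zygosity": "het",
                "haps": (rec.hap,), "kind": "snv", "linked": True,
            })
        truth.append({
            "position": rec.del_start, "end": rec.del_end,
            "ref": ref.gene_seq[rec.del_start:rec.del_end], "alt": "",
            "zygosity": "het", "haps": (rec.hap,), "kind": "del",
            "length": rec.del_len,
        })

    gene_codes = ref.gene_codes
    pair = tuple(
        _apply_events(gene_codes, sorted(per_hap[h]), deletion_by_hap[h])
        for h in (0, 1)
    )
    return pair, truth  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Error model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SystematicSite:
    """A recurrent error hotspot: a transition seen in a fraction of reads.

    ``fraction`` is the mean per-read aberrant probability; ``strand_ratio``
    r biases it to r:1 between forward and reverse reads while preserving
    the mean.
    """

    position: int
    alt: str
    fraction: float
    strand_ratio: float = 1.0

    def strand_probs(self) -> tuple[float, float]:
        r = self.strand_ratio
        p_fwd = min(1.0, self.fraction * 2.0 * r / (r + 1.0))
        p_rev = min(1.0, self.fraction * 2.0 / (r + 1.0))
        return p_fwd, p_rev


# Conditional substitution spectrum: given an erroneous base call at a
# reference base, the probability of each alternative.  Transitions dominate
# (G>A, A>G, C>T, T>C); constants are calibration values chosen so the
# measured whole-run spectrum reproduces the transition shares that NanoOK
# reports on real amplicon runs (G>A ~13.3%, A>G ~12.7%, C>T ~12.0% of all
# erroneous substitutions) once base composition and motif hotspots are
# accounted for.
DEFAULT_TRANSITION_SHARES: dict[str, dict[str, float]] = {
    "G": {"A": 0.512, "C": 0.244, "T": 0.244},
    "A": {"G": 0.506, "C": 0.247, "T": 0.247},
    "C": {"T": 0.478, "A": 0.261, "G": 0.261},
    "T": {"C": 0.450, "A": 0.275, "G": 0.275},
}

# Per-base substitution probability calibrated so aligned base identity
# excluding indels (ABID) lands at ~93.2%.
DEFAULT_SUB_RATE = 0.0672


@dataclass(frozen=True)
class ErrorModel:
    sub_rate: float = DEFAULT_SUB_RATE
    transition_shares: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRANSITION_SHARES.items()}
    )
    homopolymer_indel_rate: float = 0.02
    chimera_rate: float = 0.02
    read_len_mean_frac: float = 0.95
    read_len_sd_frac: float = 0.05
    min_read_len: int = 2000
    motif: str = "CAGC"
    motif_pos: int = 2       # 0-based offset of the error-prone base in the motif
    motif_factor: float = 4.0
    systematic_sites: tuple[SystematicSite, ...] = ()
    seed: Optional[int] = None

    def __post_init__(self):
        for name in ("sub_rate", "homopolymer_indel_rate", "chimera_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        for base, shares in self.transition_shares.items():
            total = sum(shares.values())
            if total > 1.0 + 1e-9:
                raise ConfigError(f"transition shares for {base} sum to {total} > 1")
        for site in self.systematic_sites:
            if not (0.0 <= site.fraction <= 1.0):
                raise ConfigError("systematic site fraction must be in [0,1]")

    def replace(self, **kwargs) -> "ErrorModel":
        return dataclasses.replace(self, **kwargs)

    def share_cdf(self) -> np.ndarray:
        """4x4 cumulative alt-choice table in code space (row=ref code)."""
        cdf = np.zeros((4, 4))
        for rb, shares in self.transition_shares.items():
            r = _CODE[ord(rb)]
            probs = np.zeros(4)
            for ab, s in shares.items():
                probs[_CODE[ord(ab)]] = s
            total = probs.sum()
            if total > 0:
                probs /= total
            cdf[r] = np.cumsum(probs)
        return cdf


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadTruth:
    read_id: str
    hap: int
    origin: str              # "gene" | "chimera"
    strand: str
    start: int               # haplotype coordinate of first template base
    length: int
    is_chimera: bool
    junction: Optional[int]  # gene coordinate of chimeric junction
    errors: list             # (gene_pos, kind, ref_base, obs) tuples


@dataclass
class SimRead:
    read_id: str
    seq: str
    qual: str
    truth: ReadTruth


def _motif_positions(ref: DuplicatedReference, model: ErrorModel) -> np.ndarray:
    """Gene coordinates of the error-prone base of each motif occurrence."""
    if not model.motif or model.motif_factor == 1.0:
        return np.empty(0, dtype=np.int64)
    seq = ref.gene_seq
    out = []
    idx = seq.find(model.motif)
    while idx >= 0:
        out.append(idx + model.motif_pos)
        idx = seq.find(model.motif, idx + 1)
    return np.asarray(out, dtype=np.int64)


def _find_runs(codes: np.ndarray, min_len: int = 3) -> list[tuple[int, int]]:
    """(start, length) of homopolymer runs of length >= min_len."""
    if len(codes) == 0:
        return []
    change = np.flatnonzero(np.diff(codes) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(codes)]))
    return [(int(s), int(e - s)) for s, e in zip(starts, ends) if e - s >= min_len]


def simulate_reads(
    ref: DuplicatedReference,
    haplotypes: tuple[Haplotype, Haplotype],
    model: ErrorModel,
    depth: int,
    seed: int,
    sample_id: str = "S",
    dropout_haplotype: Optional[int] = None,
) -> list[SimRead]:
    """Simulate ``depth`` nanopore-like reads from a diploid pair.

    Reads are drawn evenly (fair binomial) from the two haplotypes, are
    near-full-amplicon length (truncated normal), and receive systematic
    site errors, motif-boosted transition-dominated substitutions, and
    homopolymer indels.  A ``chimera_rate`` fraction are PCR chimeras whose
    suffix (in gene coordinates) is replaced by pseudogene sequence.
    ``dropout_haplotype`` simulates allele dropout by suppressing one
    parental haplotype entirely.
    """
    if depth < 1:
        raise ConfigError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    pseudo_codes = ref.pseudo_codes
    gene_codes = ref.gene_codes
    motif_sites = _motif_positions(ref, model)
    cdf = model.share_cdf()
    sys_sites = sorted(model.systematic_sites, key=lambda s: s.position)

    reads: list[SimRead] = []
    for i in range(depth):
        hap_idx = int(rng.integers(0, 2))
        if dropout_haplotype is not None:
            hap_idx = 1 - dropout_haplotype
        hap = haplotypes[hap_idx]
        L = len(hap)
        mean = model.read_len_mean_frac * L
        sd = max(1.0, model.read_len_sd_frac * L)
        rlen = int(np.clip(round(rng.normal(mean, sd)), min(model.min_read_len, L), L))
        start = int(rng.integers(0, L - rlen + 1))
        codes = seq_to_codes(hap.seq)[start:start + rlen].copy()
        gene_pos = hap.to_gene[start:start + rlen]
        strand = "+" if rng.random() < 0.5 else "-"
        errors: list[tuple] = []

        is_chimera = bool(rng.random() < model.chimera_rate)
        junction = None
        if is_chimera:
            j = int(rng.integers(rlen // 10, rlen - rlen // 10))
            codes[j:] = pseudo_codes[gene_pos[j:]]
            junction = int(gene_pos[j])

        # systematic error hotspots (strand-biased transitions)
        for site in sys_sites:
            j = int(np.searchsorted(gene_pos, site.position))
            if j >= rlen or gene_pos[j] != site.position:
                continue
            p_fwd, p_rev = site.strand_probs()
            p = p_fwd if strand == "+" else p_rev
            if rng.random() < p:
                old = codes[j]
                codes[j] = _CODE[ord(site.alt)]
                errors.append((site.position, "sys", codes_to_seq(np.array([old], np.uint8)), site.alt))

        # substitution errors with motif hotspot boost
        p_vec = np.full(rlen, model.sub_rate)
        if len(motif_sites):
            in_motif = np.isin(gene_pos, motif_sites)
            p_vec[in_motif] = np.minimum(1.0, p_vec[in_motif] * model.motif_factor)
        err_mask = rng.random(rlen) < p_vec
        err_idx = np.flatnonzero(err_mask)
        if len(err_idx):
            u = rng.random(len(err_idx))
            for j, uu in zip(err_idx, u):
                old = int(codes[j])
                alt = int(np.searchsorted(cdf[old], uu, side="right"))
                alt = min(alt, 3)
                if alt == old:  # zero-share self-transition guard
                    alt = (old + 1) % 4
                codes[j] = alt
                errors.append((int(gene_pos[j]), "sub",
                               chr(_BASES[old]), chr(_BASES[alt])))

        # per-base quality encodes the substitution probability used
        quals = np.minimum(60, np.maximum(2, np.round(
            -10.0 * np.log10(np.maximum(p_vec, 1e-6))))).astype(np.uint8)

        # homopolymer indels: probability grows with run length
        if model.homopolymer_indel_rate > 0:
            template = seq_to_codes(hap.seq)[start:start + rlen]
            edits = []  # (read_pos, +1 insert / -1 delete, base_code)
            for run_start, run_len in _find_runs(template):
                p_run = min(1.0, model.homopolymer_indel_rate * (run_len - 2))
                if rng.random() < p_run:
                    kind = 1 if rng.random() < 0.5 else -1
                    edits.append((run_start + run_len - 1, kind, int(template[run_start])))
                    errors.append((int(gene_pos[run_start]),
                                   "ins" if kind > 0 else "del",
                                   chr(_BASES[template[run_start]]), ""))
            for pos, kind, base in sorted(edits, reverse=True):
                if kind > 0:
                    codes = np.insert(codes, pos, base)
                    quals = np.insert(quals, pos, quals[min(pos, len(quals) - 1)])
                else:
                    codes = np.delete(codes, pos)
                    quals = np.delete(quals, pos)

        if strand == "-":
            codes = revcomp_codes(codes)
            quals = quals[::-1]

        read_id = f"{sample_id}_r{i:05d}"
        qual_str = (quals + 33).tobytes().decode()
        truth = ReadTruth(read_id, hap_idx, "chimera" if is_chimera else "gene",
                          strand, start, rlen, is_chimera, junction, errors)
        reads.append(SimRead(read_id, codes_to_seq(codes), qual_str, truth))
    return reads


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_reference(fasta: str | Path, bed: str | Path) -> DuplicatedReference:
    """Load a two-record (gene, pseudogene) FASTA plus an exon BED."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(fasta), "fasta"))
    if len(records) != 2:
        raise ConfigError("reference FASTA must contain exactly two records")
    gene, pseudo = str(records[0].seq).upper(), str(records[1].seq).upper()
    exons = []
    with open(bed) as fh:
        for line in fh:
            if line.strip():
                fields = line.split("\t")
                exons.append((int(fields[1]), int(fields[2])))
    ref = DuplicatedReference(gene, pseudo, tuple(sorted(exons)), {},
                              records[0].id)
    homology = {i: 100.0 * float((ref.gene_codes[s:e] == ref.pseudo_codes[s:e]).mean())
                for i, (s, e) in enumerate(ref.exons)}
    return DuplicatedReference(gene, pseudo, ref.exons, homology, records[0].id)


def write_fasta(ref: DuplicatedReference, path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(ref.gene_seq), id="gene", description=ref.region_label),
        SeqRecord(Seq(ref.pseudo_seq), id="pseudogene", description="derived copy"),
    ]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(reads: Sequence[SimRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual}\n")


def write_exon_bed(ref: DuplicatedReference, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (s, e) in enumerate(ref.exons):
            fh.write(f"gene\t{s}\t{e}\texon{i + 1}\n")


def write_truth_tsv(reads: Sequence[SimRead], path: str | Path) -> None:
    """Tab-separated truth sidecar: one row per read."""
    with open(path, "w") as fh:
        fh.write("read_id\thap\torigin\tstrand\tstart\tlength\tis_chimera\t"
                 "junction\terrors\n")
        for r in reads:
            t = r.truth
            err = ";".join(f"{p}:{k}:{rb}>{ob}" for p, k, rb, ob in t.errors)
            fh.write(f"{t.read_id}\t{t.hap}\t{t.origin}\t{t.strand}\t{t.start}\t"
                     f"{t.length}\t{int(t.is_chimera)}\t"
                     f"{'' if t.junction is None else t.junction}\t{err}\n")
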
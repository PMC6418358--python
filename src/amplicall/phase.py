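"""Read-backed phasing of heterozygous variants.

Full-length amplicon reads usually co-cover every heterozygous site, so the
read-variant graph typically forms a single block.  Within a block the phase
vector is chosen to minimize MEC (minimum error correction): the number of
read bases that would have to be flipped for every read to be consistent
with one of the two haplotypes.  Blocks of up to ``exact_limit`` variants
are solved exactly by exhaustive search over the 2^(k-1) distinct phase
vectors; larger blocks fall back to greedy extension with local flips.

On top of blocks the module derives cis/trans (compound heterozygosity)
relations and matches samples against a named multi-SNP haplotype
definition (e.g. an 8-SNP Pv1.1-style classifier allele).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .align import AlignedRead
from .caller import VariantCall
from .refsim import seq_to_codes

__all__ = [
    "HaplotypeBlock",
    "NamedHaplotype",
    "ReadAlleles",
    "alleles_from_alignments",
    "phase_block",
    "phase_all",
    "mec_cost",
    "compound_het",
    "assign_named_haplotype",
]

EXACT_LIMIT = 15


@dataclass
class ReadAlleles:
    """Observation matrix for phasing: reads x het sites.

    ``matrix[r, s]`` is 1 if read r shows the alt allele at het site s,
    0 for the ref allele, -1 if the read does not (cleanly) cover the site.
    """

    positions: np.ndarray          # sorted site positions
    matrix: np.ndarray             # (n_reads, n_sites) int8
    read_ids: list = field(default_factory=list)


def alleles_from_alignments(
    het_variants: Sequence[VariantCall],
    aligned_reads: Sequence[AlignedRead],
) -> ReadAlleles:
    variants = sorted(het_variants, key=lambda v: v.position)
    positions = np.array([v.position for v in variants], dtype=np.int64)
    ref_codes = np.array([seq_to_codes(v.ref)[0] for v in variants])
    alt_codes = np.array([seq_to_codes(v.alt)[0] if v.alt else 255 for v in variants])
    rows, ids = [], []
    for aln in aligned_reads:
        if not aln.mapped or aln.target != "gene" or aln.is_chimera:
            continue
        start, arr = aln.ref_profile()
        row = np.full(len(variants), -1, dtype=np.int8)
        inside = (positions >= start) & (positions < start + len(arr))
        obs = arr[positions[inside] - start]
        vals = np.full(obs.shape, -1, dtype=np.int8)
        vals[obs == ref_codes[inside]] = 0
        vals[obs == alt_codes[inside]] = 1
        row[inside] = vals
        rows.append(row)
        ids.append(aln.read_id)
    matrix = np.vstack(rows) if rows else np.empty((0, len(variants)), np.int8)
    return ReadAlleles(positions, matrix, ids)


@dataclass
class HaplotypeBlock:
    variants: list                 # VariantCall or positions, block order
    phase: np.ndarray              # 0/1 per variant: allele on haplotype 1
    mec: int
    read_partition: dict = field(default_factory=dict)  # read_id -> 0|1
    span: tuple = (0, 0)

    def phase_of(self, position: int) -> Optional[int]:
        for v, p in zip(self.variants, self.phase):
            pos = v.position if hasattr(v, "position") else v
            if pos == position:
                return int(p)
        return None


def mec_cost(matrix: np.ndarray, phase: np.ndarray) -> int:
    """Flipped-base count when each read picks its best-matching haplotype."""
    obs = matrix >= 0
    h1 = phase[None, :]
    h2 = 1 - h1
    mis1 = ((matrix != h1) & obs).sum(axis=1)
    mis2 = ((matrix != h2) & obs).sum(axis=1)
    return int(np.minimum(mis1, mis2).sum())


def _exact_phase(matrix: np.ndarray) -> tuple[np.ndarray, int]:
    n_sites = matrix.shape[1]
    best_phase = np.zeros(n_sites, dtype=np.int8)
    best_cost = mec_cost(matrix, best_phase)
    # fix site 0 to haplotype-1 allele 0: phases are defined up to relabeling
    for bits in range(1 << (n_sites - 1)) if n_sites > 1 else range(1):
        phase = np.zeros(n_sites, dtype=np.int8)
        for s in range(1, n_sites):
            phase[s] = (bits >> (s - 1)) & 1
        cost = mec_cost(matrix, phase)
        if cost < best_cost:
            best_cost = cost
            best_phase = phase
    return best_phase, best_cost


def _greedy_phase(matrix: np.ndarray) -> tuple[np.ndarray, int]:
    n_sites = matrix.shape[1]
    phase = np.zeros(n_sites, dtype=np.int8)
    # seed from pairwise majority linkage to site 0, then local flips
    for s in range(1, n_sites):
        both = (matrix[:, 0] >= 0) & (matrix[:, s] >= 0)
        same = (matrix[both, 0] == matrix[both, s]).sum()
        phase[s] = 0 if same >= both.sum() - same else 1
    improved = True
    cost = mec_cost(matrix, phase)
    while improved:
        improved = False
        for s in range(1, n_sites):
            phase[s] ^= 1
            new = mec_cost(matrix, phase)
            if new < cost:
                cost = new
                improved = True
            else:
                phase[s] ^= 1
    return phase, cost


def _components(matrix: np.ndarray) -> list[np.ndarray]:
    """Connected components of sites under read co-coverage."""
    n_sites = matrix.shape[1]
    parent = list(range(n_sites))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for row in matrix:
        covered = np.flatnonzero(row >= 0)
        for b in covered[1:]:
            ra, rb = find(int(covered[0])), find(int(b))
            if ra != rb:
                parent[rb] = ra
    groups: dict[int, list[int]] = {}
    for s in range(n_sites):
        groups.setdefault(find(s), []).append(s)
    return [np.array(g) for g in groups.values()]


def phase_block(
    het_variants: Sequence[VariantCall],
    evidence: ReadAlleles | Sequence[AlignedRead],
    exact_limit: int = EXACT_LIMIT,
) -> list[HaplotypeBlock]:
    """Phase het variants into MEC-minimal blocks.

    Variants never co-covered by a read fall into separate blocks.  Exact
    exhaustive MEC minimization is used for blocks of up to ``exact_limit``
    variants, greedy extension with local flips beyond that.
    """
    for v in het_variants:
        zyg = getattr(v, "genotype", "het")
        if zyg != "het":
            raise ValueError("phase_block accepts heterozygous variants only")
    if not isinstance(evidence, ReadAlleles):
        evidence = alleles_from_alignments(het_variants, evidence)
    variants = sorted(het_variants, key=lambda v: v.position)
    matrix = evidence.matrix
    blocks: list[HaplotypeBlock] = []
    for comp in _components(matrix):
        sub = matrix[:, comp]
        covering = (sub >= 0).any(axis=1)
        sub = sub[covering]
        if len(comp) <= exact_limit:
            phase, cost = _exact_phase(sub)
        else:
            phase, cost = _greedy_phase(sub)
        obs = sub >= 0
        mis1 = ((sub != phase[None, :]) & obs).sum(axis=1)
        mis2 = ((sub != 1 - phase[None, :]) & obs).sum(axis=1)
        assign = (mis2 < mis1).astype(int)
        ids = [rid for rid, c in zip(evidence.read_ids, covering) if c] \
            if evidence.read_ids else list(np.flatnonzero(covering))
        block_vars = [variants[i] for i in comp]
        positions = [v.position for v in block_vars]
        blocks.append(HaplotypeBlock(
            block_vars, phase, cost,
            dict(zip(ids, assign.tolist())),
            (min(positions), max(positions) + 1),
        ))
    blocks.sort(key=lambda b: b.span)
    return blocks


def phase_all(
    calls: Sequence[VariantCall],
    aligned_reads: Sequence[AlignedRead],
    exact_limit: int = EXACT_LIMIT,
) -> list[HaplotypeBlock]:
    """Phase the heterozygous subset of a call set; hom calls are attached
    to both haplotypes for reporting and excluded from MEC."""
    hets = [c for c in calls if c.genotype == "het" and c.type == "snv"]
    if len(hets) < 2:
        return []
    return phase_block(hets, aligned_reads, exact_limit)


def compound_het(
    blocks: Sequence[HaplotypeBlock],
    variant_a: VariantCall,
    variant_b: VariantCall,
) -> str:
    """cis / trans / unknown relation between two heterozygous variants."""
    for v in (variant_a, variant_b):
        if v.genotype != "het":
            raise ValueError("compound_het is defined for het variants only")
    for block in blocks:
        pa = block.phase_of(variant_a.position)
        pb = block.phase_of(variant_b.position)
        if pa is not None and pb is not None:
            return "cis" if pa == pb else "trans"
    return "unknown"


@dataclass(frozen=True)
class NamedHaplotype:
    """A named classifier haplotype defined by a fixed SNP set."""

    name: str
    snps: tuple[tuple[int, str, str], ...]   # (position, ref, alt)

    @property
    def span(self) -> int:
        positions = [p for p, _, _ in self.snps]
        return max(positions) - min(positions)


def write_haplotagged_sam(
    aligned_reads,
    blocks: Sequence[HaplotypeBlock],
    ref,
    path,
) -> None:
    """Write alignments with an HP tag (1/2) from the block read partition,
    for haplotype-colored genome-browser inspection."""
    from .align import write_sam

    assignment: dict[str, int] = {}
    for block in blocks:
        for read_id, hap in block.read_partition.items():
            assignment.setdefault(read_id, hap + 1)
    write_sam(aligned_reads, ref, path)
    import pysam

    tagged = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        header = fh.header.to_dict()
        for rec in fh:
            hp = assignment.get(rec.query_name)
            if hp is not None:
                rec.set_tag("HP", hp)
            tagged.append(rec)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in tagged:
            out.write(rec)


def load_named_haplotype(ref, path=None) -> NamedHaplotype:
    """Load a named-haplotype definition from YAML.

    The packaged default defines 8 positions over ~6.7 kb of the synthetic
    locus; ref alleles are read off the reference and alts default to the
    transition partner unless the YAML lists explicit ``snps`` triples.
    """
    import yaml
    from importlib import resources

    if path is None:
        text = resources.files("amplicall").joinpath("config/pv11.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    partner = {"A": "G", "G": "A", "C": "T", "T": "C"}
    if "snps" in cfg:
        snps = tuple((int(p), r, a) for p, r, a in cfg["snps"])
    else:
        L = len(ref.gene_seq)
        snps = tuple(
            (int(p), ref.gene_seq[int(p)], partner[ref.gene_seq[int(p)]])
            for p in cfg["positions"] if int(p) < L
        )
    return NamedHaplotype(cfg["name"], snps)


def assign_named_haplotype(
    calls: Sequence[VariantCall],
    blocks: Sequence[HaplotypeBlock],
    definition: NamedHaplotype,
) -> dict:
    """Sample status against a named haplotype: hom+ / het / hom- / mixed.

    hom+ when every defining allele is homozygous; het when every defining
    allele is present heterozygously and phased onto one haplotype; hom-
    when none is present; anything partial is 'mixed' and flagged.
    """
    by_pos = {c.position: c for c in calls if c.type == "snv"}
    states = []
    for pos, _ref, alt in definition.snps:
        call = by_pos.get(pos)
        if call is None or call.alt != alt:
            states.append("absent")
        else:
            states.append(call.genotype)
    if all(s == "absent" for s in states):
        return {"name": definition.name, "status": "hom-", "carrier_hap": None}
    if all(s == "hom" for s in states):
        return {"name": definition.name, "status": "hom+", "carrier_hap": "both"}
    if all(s == "het" for s in states):
        phases = [
            next((b.phase_of(pos) for b in blocks if b.phase_of(pos) is not None), None)
            for pos, _, _ in definition.snps
        ]
        if None not in phases and len(set(phases)) == 1:
            return {"name": definition.name, "status": "het",
                    "carrier_hap": f"hap{phases[0] + 1}"}
        return {"name": definition.name, "status": "mixed", "carrier_hap": None,
                "flag": "het alleles not phased onto one haplotype"}
    return {"name": definition.name, "status": "mixed", "carrier_hap": None,
            "flag": "partial defining-allele match"}
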
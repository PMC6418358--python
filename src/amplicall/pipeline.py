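"""End-to-end orchestration: simulate -> align -> QC -> gate -> call ->
filter -> SV -> phase, with a run manifest and coverage gating.

A sample enters variant calling only if its mean read depth over the coding
exons plus 50 flanking bases reaches the coverage gate (default 100); gated
samples are recorded in the manifest, and with ``strict`` the run fails.
Every stage logs in/out counts so the filter funnel is auditable, and the
manifest (config hash + seeds + per-stage parameters) suffices to re-run any
stage identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .align import AlignParams, Pileup, align_reads, build_pileup, write_sam
from .caller import CallerParams, call_variants, estimate_error_rate
from .fpfilter import FilterParams, calibrate, filter_calls, recurrence_scan
from .phase import load_named_haplotype, assign_named_haplotype, phase_all
from .qc import run_metrics
from .refsim import (
    DuplicatedReference,
    ErrorModel,
    PlantedVariant,
    Recombinant,
    SampleSpec,
    SystematicSite,
    build_reference,
    plant_variants,
    simulate_reads,
    write_exon_bed,
    write_fasta,
    write_fastq,
    write_truth_tsv,
)
from .sv import SVParams, detect_deletions
from .vcfio import write_vcf

__all__ = ["RunManifest", "coverage_gate", "run_pipeline", "load_config"]

log = logging.getLogger("amplicall")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    sample_seeds: dict = field(default_factory=dict)
    coverage: dict = field(default_factory=dict)
    gate_decisions: dict = field(default_factory=dict)
    calibration: float = 1.0
    stage_params: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def coverage_gate(
    pileup: Pileup,
    exons: Sequence[tuple[int, int]],
    flank: int = 50,
    gate: float = 100.0,
) -> tuple[bool, float]:
    """Mean depth over the union of flanked exons, compared (>=) to the gate.

    Flanked exons are merged before averaging so overlapping flanks are not
    double counted.
    """
    if not exons:
        raise ValueError("coverage_gate requires a non-empty exon set")
    L = pileup.length
    flanked = _merge_intervals([(max(0, s - flank), min(L, e + flank))
                                for s, e in exons])
    depths = np.concatenate([pileup.depth[s:e] for s, e in flanked])
    mean_cov = float(depths.mean())
    return mean_cov >= gate, mean_cov


# ---------------------------------------------------------------------------
# Config handling
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _reference_from_config(cfg: dict) -> DuplicatedReference:
    r = cfg.get("reference", {})
    return build_reference(
        span=r.get("span", 8911),
        n_exons=r.get("n_exons", 11),
        exon_len=r.get("exon_len", 170),
        exon_identity=r.get("exon_identity", 96.0),
        intron_identity=r.get("intron_identity", 97.0),
        seed=r.get("seed", 0),
    )


def _sample_specs_from_config(cfg: dict, ref: DuplicatedReference) -> list[SampleSpec]:
    samples = cfg.get("samples", {})
    if isinstance(samples, dict):  # benchmark-style autogenerated cohort
        from .benchmark import benchmark_sample_specs

        return benchmark_sample_specs(ref, depth=samples.get("depth", 140))[
            : samples.get("n_samples", 6)]
    specs = []
    for s in samples:
        variants = []
        for v in s.get("variants", []):
            pos = int(v["position"])
            rb = v.get("ref", ref.gene_seq[pos])
            variants.append(PlantedVariant(pos, rb, v["alt"], v["zygosity"],
                                           v.get("hap")))
        rec = None
        if "recombinant" in s:
            rc = s["recombinant"]
            rec = Recombinant(int(rc["del_start"]), int(rc["del_end"]),
                              tuple((int(p), r, a) for p, r, a in
                                    rc.get("linked_snvs", [])),
                              hap=rc.get("hap", 0))
        specs.append(SampleSpec(s["sample_id"], tuple(variants), rec,
                                depth=s.get("depth", 100)))
    return specs


def _error_model_from_config(cfg: dict, ref: DuplicatedReference,
                             rng: np.random.Generator) -> ErrorModel:
    em = dict(cfg.get("error_model", {}))
    sites_cfg = cfg.get("systematic_sites")
    sites: tuple[SystematicSite, ...] = ()
    if sites_cfg:
        from .benchmark import TRANSITION_PARTNER, _intronic

        lo, hi = sites_cfg.get("fraction_range", [0.14, 0.30])
        ratio = sites_cfg.get("strand_ratio", 3.0)
        out = []
        for f in sites_cfg.get("position_fractions", []):
            pos = _intronic(ref, int(f * len(ref.gene_seq)), set())
            out.append(SystematicSite(pos, TRANSITION_PARTNER[ref.gene_seq[pos]],
                                      float(rng.uniform(lo, hi)), ratio))
        sites = tuple(out)
    known = {f.name for f in ErrorModel.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    em = {k: v for k, v in em.items() if k in known}
    return ErrorModel(systematic_sites=sites, **em)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    config: dict | str | Path,
    outdir: str | Path,
    seed: int = 0,
    strict: bool = False,
) -> RunManifest:
    """Run the full pipeline for every configured sample.

    Writes, under ``outdir``: the reference FASTA and exon BED, then per
    sample FASTQ + truth sidecar, SAM, QC TSV, filtered VCF (SNVs, indels,
    SVs, phased genotypes) and a verdict TSV; plus a cross-sample manifest.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]

    ref = _reference_from_config(config)
    write_fasta(ref, outdir / "reference.fasta")
    write_exon_bed(ref, outdir / "exons.bed")

    gates = config.get("gates", {})
    flank = gates.get("flank", 50)
    gate = gates.get("coverage_gate", 100)
    fcfg = config.get("filter", {})
    base_filter = (FilterParams.preset(fcfg["preset"])
                   if "preset" in fcfg else FilterParams())

    # the alignment length cutoff follows the configured read-length floor
    min_rl = config.get("error_model", {}).get("min_read_len", 2000)
    align_params = AlignParams(min_read_len=min_rl)

    rng = np.random.default_rng(seed)
    manifest = RunManifest(cfg_hash, seed)
    manifest.stage_params = {
        "align": asdict(align_params),
        "caller": {k: v for k, v in asdict(CallerParams()).items()},
        "sv": asdict(SVParams()),
        "gate": {"flank": flank, "coverage_gate": gate},
    }

    specs = _sample_specs_from_config(config, ref)
    passed = []
    for spec in specs:
        sim_seed = int(rng.integers(2 ** 31))
        manifest.sample_seeds[spec.sample_id] = sim_seed
        model = _error_model_from_config(config, ref,
                                         np.random.default_rng(sim_seed))
        haps, truth = plant_variants(ref, spec, seed=sim_seed)
        reads = simulate_reads(ref, haps, model, spec.depth, seed=sim_seed,
                               sample_id=spec.sample_id)
        write_fastq(reads, outdir / f"{spec.sample_id}.fastq")
        write_truth_tsv(reads, outdir / f"{spec.sample_id}.truth.tsv")
        log.info("%s: simulated %d reads", spec.sample_id, len(reads))

        aligned = align_reads(reads, ref, align_params)
        write_sam(aligned, ref, outdir / f"{spec.sample_id}.sam")
        n_gene = sum(1 for a in aligned if a.mapped and a.target == "gene")
        n_chim = sum(1 for a in aligned if a.is_chimera)
        log.info("%s: aligned %d/%d to gene, %d chimeric",
                 spec.sample_id, n_gene, len(aligned), n_chim)

        pileup = build_pileup(aligned, ref)
        metrics = run_metrics(aligned, ref, pileup.depth)
        metrics.to_frame().to_csv(outdir / f"{spec.sample_id}.qc.tsv",
                                  sep="\t", index=False)

        ok, mean_cov = coverage_gate(pileup, ref.exons, flank, gate)
        manifest.coverage[spec.sample_id] = mean_cov
        manifest.gate_decisions[spec.sample_id] = "pass" if ok else "fail"
        if not ok:
            log.warning("%s: mean flanked-exon coverage %.1f below gate %s "
                        "- excluded from calling", spec.sample_id, mean_cov, gate)
            continue
        passed.append((spec, aligned, pileup, truth))

    # calling + cross-sample filtering over gated samples
    results = []
    for spec, aligned, pileup, truth in passed:
        e = estimate_error_rate(aligned)
        calls = call_variants(aligned, pileup, ref,
                              CallerParams(error_rate=e))
        log.info("%s: %d calls (error rate %.4f)", spec.sample_id, len(calls), e)
        results.append({"spec": spec, "aligned": aligned, "pileup": pileup,
                        "truth": truth, "calls": calls})

    site_keys: dict[int, tuple[int, str, str]] = {}
    for r in results:
        for c in r["calls"]:
            if c.type == "snv":
                site_keys.setdefault(c.position, (c.position, c.ref, c.alt))
    recurrence: dict[int, float] = {}
    if len(results) >= 2 and site_keys:
        recurrence = recurrence_scan(
            [r["pileup"] for r in results], list(site_keys.values()),
            [{c.position for c in r["calls"]} for r in results],
        )

    cal = 1.0
    true_het_calls = [
        c for r in results for c in r["calls"]
        if c.genotype == "het" and c.type == "snv"
        and any(t["position"] == c.position and t["zygosity"] == "het"
                for t in r["truth"])
    ]
    if true_het_calls:
        cal = calibrate(true_het_calls, anchor=fcfg.get("anchor", 3.5))
    manifest.calibration = cal
    fparams = FilterParams(tau_true=base_filter.tau_true,
                           tau_false=base_filter.tau_false,
                           recur_min=fcfg.get("recur_min", 0.10),
                           calibration=cal)

    pv11 = load_named_haplotype(ref)
    for r in results:
        spec = r["spec"]
        verdicts = filter_calls(r["calls"], fparams, recurrence)
        sv_calls = detect_deletions(r["aligned"], r["pileup"], ref)
        blocks = phase_all(r["calls"], r["aligned"])
        if blocks:
            from .phase import write_haplotagged_sam

            write_haplotagged_sam(r["aligned"], blocks, ref,
                                  outdir / f"{spec.sample_id}.haplotagged.sam")
        hap_status = assign_named_haplotype(r["calls"], blocks, pv11)
        vmap = {v.call.position: v for v in verdicts}
        write_vcf(r["calls"], ref, outdir / f"{spec.sample_id}.vcf",
                  spec.sample_id, vmap, blocks, sv_calls)
        with open(outdir / f"{spec.sample_id}.verdicts.tsv", "w") as fh:
            fh.write("position\tref\talt\tgenotype\tQ\tN\tadjusted\tverdict\treasons\n")
            for v in verdicts:
                c = v.call
                fh.write(f"{c.position}\t{c.ref}\t{c.alt}\t{c.genotype}\t"
                         f"{c.quality:.2f}\t{c.depth}\t{v.adjusted_score:.3f}\t"
                         f"{v.verdict}\t{';'.join(v.reasons)}\n")
        with open(outdir / f"{spec.sample_id}.haplotype.tsv", "w") as fh:
            fh.write("name\tstatus\tcarrier_hap\n")
            fh.write(f"{hap_status['name']}\t{hap_status['status']}\t"
                     f"{hap_status['carrier_hap']}\n")
        n_pass = sum(1 for v in verdicts if v.verdict == "true_positive")
        log.info("%s: %d/%d calls pass filter, %d SV calls, %d phase blocks",
                 spec.sample_id, n_pass, len(verdicts), len(sv_calls), len(blocks))

    manifest.write(outdir / "manifest.json")
    if strict and any(d == "fail" for d in manifest.gate_decisions.values()):
        raise SystemExit("coverage gate failed for at least one sample (--strict)")
    return manifest
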
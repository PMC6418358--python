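"""Coverage titration: quality-vs-depth linearity and adjusted-score
constancy.

Downsampling alignments by factors of 2, 4 and 10 and re-calling exposes two
properties of the haplotype log-likelihood-ratio quality: Q grows linearly
with read depth for true variants (each additional supporting read adds the
same expected evidence), while the coverage-adjusted score Q/N stays
essentially constant, which is what makes it a transferable discriminator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlignedRead, build_pileup
from .caller import CallerParams, VariantCall, call_variants
from .refsim import DuplicatedReference

__all__ = ["TitrationResult", "downsample_reads", "run_titration"]

DEFAULT_FACTORS = (1, 2, 4, 10)


@dataclass
class TitrationResult:
    table: pd.DataFrame          # variant, factor, depth, quality, adjusted
    regressions: dict            # position -> (slope, intercept, r2)
    adjusted_cv: dict            # position -> CV of adjusted score
    dropouts: list = field(default_factory=list)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def downsample_reads(
    aligned_reads: Sequence[AlignedRead],
    factor: float,
    seed: int,
) -> list[AlignedRead]:
    """Keep each read independently with probability 1/factor (seeded)."""
    if factor < 1:
        raise ValueError("downsampling factor must be >= 1")
    if factor == 1:
        return list(aligned_reads)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(aligned_reads)) < 1.0 / factor
    return [r for r, k in zip(aligned_reads, keep) if k]


def _match(calls: Sequence[VariantCall], position: int) -> Optional[VariantCall]:
    for c in calls:
        if c.position == position and c.type == "snv":
            return c
    return None


def run_titration(
    aligned_reads: Sequence[AlignedRead],
    ref: DuplicatedReference,
    target_positions: Sequence[int],
    factors: Sequence[float] = DEFAULT_FACTORS,
    reps: int = 1,
    seed: int = 0,
    caller_params: CallerParams = CallerParams(),
) -> TitrationResult:
    """Re-call target variants at each downsampling factor.

    Variants lost at a factor are recorded as dropouts and excluded from
    that variant's regression.  Q ~ depth is fit by least squares per
    variant over all (factor, rep) observations; the constancy statistic is
    the coefficient of variation of Q/N across the per-factor means, so
    replicate-level binomial sampling noise (large at heavily downsampled
    depths) is averaged out and the statistic measures the systematic
    dependence of the adjusted score on coverage.
    """
    rows = []
    dropouts = []
    for factor in factors:
        n_reps = 1 if factor == 1 else reps
        for rep in range(n_reps):
            sub = downsample_reads(aligned_reads, factor, seed + 1000 * rep + int(factor))
            try:
                pileup = build_pileup(sub, ref)
            except ValueError:
                for pos in target_positions:
                    dropouts.append({"position": pos, "factor": factor, "rep": rep})
                continue
            calls = call_variants(sub, pileup, ref, caller_params)
            for pos in target_positions:
                call = _match(calls, pos)
                if call is None:
                    dropouts.append({"position": pos, "factor": factor, "rep": rep})
                    continue
                rows.append({
                    "position": pos, "factor": factor, "rep": rep,
                    "depth": call.depth, "quality": call.quality,
                    "adjusted": call.adjusted_score, "genotype": call.genotype,
                })
    table = pd.DataFrame(rows, columns=["position", "factor", "rep", "depth",
                                        "quality", "adjusted", "genotype"])
    regressions = {}
    adjusted_cv = {}
    for pos in target_positions:
        sub = table[table.position == pos]
        if len(sub) >= 3 and sub.depth.nunique() >= 2:
            fit = stats.linregress(sub.depth, sub.quality)
            regressions[pos] = (float(fit.slope), float(fit.intercept),
                                float(fit.rvalue ** 2))
        if len(sub) >= 2 and sub.adjusted.mean() > 0:
            factor_means = sub.groupby("factor").adjusted.mean()
            adjusted_cv[pos] = float(factor_means.std(ddof=1)
                                     / factor_means.mean())
    return TitrationResult(table, regressions, adjusted_cv, dropouts)


def plot_titration(result: TitrationResult, path) -> None:  # pragma: no cover
    """Q vs depth and adjusted score vs factor, one panel each."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    for pos, sub in result.table.groupby("position"):
        ax1.plot(sub.depth, sub.quality, "o-", label=str(pos))
        ax2.plot(sub.factor, sub.adjusted, "o-", label=str(pos))
    ax1.set_xlabel("depth (reads)")
    ax1.set_ylabel("quality Q")
    ax2.set_xlabel("downsampling factor")
    ax2.set_ylabel("adjusted score Q/N")
    ax2.set_xscale("log")
    ax1.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
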
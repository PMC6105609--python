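"""Genomic-control correction and the stratified curve statistics.

The "cumulative distribution of -log10(p)" underlying the fold curves is the
COMPLEMENTARY empirical CDF — the proportion of SNPs at or beyond each
-log10(p) abscissa — so that an excess of small p-values in a stratum gives
fold > 1 (an upward deflection), and the matching conditional Q-Q curve
deflects leftward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io_formats import GenotypePanel, SumstatsTable
from .ld_annotation import (
    DEFAULT_WINDOW_BP,
    LD_R2_FLOOR,
    _prune_from_adjacency,
    ld_neighbors,
)

__all__ = [
    "QQCurve",
    "FoldCurve",
    "CHI2_1_MEDIAN",
    "NEGLOG10_P_CAP",
    "lambda_gc",
    "gc_correct",
    "conditional_qq",
    "fold_enrichment",
]

#: Median of the chi-square distribution with 1 degree of freedom.
CHI2_1_MEDIAN = float(chi2.ppf(0.5, df=1))  # 0.4549364...

#: Curves are restricted to sub-genome-wide-significant SNPs:
#: -log10(p) < 7.3, i.e. p > 5e-8.
NEGLOG10_P_CAP = 7.3


@dataclass
class QQCurve:
    """One stratum's conditional Q-Q curve as (-log10 empirical, -log10 nominal)."""

    label: str
    neglog_empirical: np.ndarray
    neglog_nominal: np.ndarray
    n_total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": self.label,
                "neglog10_empirical": self.neglog_empirical,
                "neglog10_nominal": self.neglog_nominal,
            }
        )


@dataclass
class FoldCurve:
    """Fold enrichment CDF_stratum/CDF_all on a grid of -log10(p) abscissae."""

    label: str
    grid: np.ndarray
    fold: np.ndarray
    n_stratum: np.ndarray  # numerator counts at each abscissa
    n_all: np.ndarray  # denominator counts at each abscissa
    reliable: np.ndarray  # denominator count >= 5 and fold defined

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": self.label,
                "neglog10_p": self.grid,
                "fold": self.fold,
                "n_stratum": self.n_stratum,
                "n_all": self.n_all,
                "reliable": self.reliable,
            }
        )


def lambda_gc(
    sumstats: SumstatsTable | np.ndarray,
    intergenic_mask: np.ndarray,
    panel: GenotypePanel,
    iterations: int = 100,
    rng_seed: int | np.random.Generator = 0,
    r2_threshold: float = LD_R2_FLOOR,
    window_bp: int = DEFAULT_WINDOW_BP,
    aggregate: str = "median",
) -> float:
    """Genomic-control inflation factor from LD-pruned intergenic SNPs.

    For each of `iterations` seeded pruning draws of the intergenic set, the
    median squared z-score of the pruned (independent) set is recorded;
    lambda_GC is the median (or mean, per `aggregate`) of those medians
    divided by the chi-square(1 df) median 0.4549364.

    `sumstats` must be row-aligned with `panel` (or be a bare z array of
    length panel.n_snps).
    """
    z = sumstats if isinstance(sumstats, np.ndarray) else sumstats.z
    if len(z) != panel.n_snps or len(intergenic_mask) != panel.n_snps:
        raise ValueError("sumstats/mask must be aligned with the panel")
    idx = np.flatnonzero(intergenic_mask)
    if len(idx) == 0:
        raise ValueError("empty intergenic set")
    if len(idx) < 100:
        warnings.warn(f"only {len(idx)} intergenic SNPs; lambda_GC will be noisy")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    neighbors = ld_neighbors(panel, idx, r2_threshold, window_bp)
    z2 = z[idx] ** 2
    medians = np.empty(iterations)
    for it in range(iterations):
        kept = _prune_from_adjacency(neighbors, rng)
        medians[it] = np.median(z2[kept])
    agg = np.median if aggregate == "median" else np.mean
    return float(agg(medians) / CHI2_1_MEDIAN)


def gc_correct(sumstats: SumstatsTable, lambda_gc_value: float) -> SumstatsTable:
    """Divide z by sqrt(lambda_GC) (recomputing p) when lambda_GC > 1;
    identity otherwise."""
    if lambda_gc_value <= 0:
        raise ValueError(f"lambda_GC must be positive, got {lambda_gc_value}")
    if lambda_gc_value <= 1:
        return sumstats
    return sumstats.with_z(sumstats.z / np.sqrt(lambda_gc_value))


def conditional_qq(
    sumstats: SumstatsTable,
    strata: Mapping[str, np.ndarray],
    neglog_cap: float = NEGLOG10_P_CAP,
) -> list[QQCurve]:
    """Conditional Q-Q curves for each stratum mask.

    Within a stratum, p-values are sorted ascending; the empirical p for rank
    r of n is r/(n+1) (ties broken by a stable sort on snp_id); only points
    with nominal -log10(p) < `neglog_cap` are emitted.
    """
    curves = []
    for label, mask in strata.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() == 0:
            warnings.warn(f"stratum {label!r} has 0 SNPs; skipped")
            continue
        sub = sumstats.df[mask]
        sub = sub.sort_values("snp_id", kind="stable").sort_values(
            "p", kind="stable"
        )
        p = sub["p"].to_numpy()
        n = len(p)
        emp = np.arange(1, n + 1) / (n + 1)
        nominal = -np.log10(p)
        keep = nominal < neglog_cap
        curves.append(
            QQCurve(
                label=label,
                neglog_empirical=-np.log10(emp[keep]),
                neglog_nominal=nominal[keep],
                n_total=n,
            )
        )
    return curves


def fold_enrichment(
    sumstats: SumstatsTable,
    stratum_mask: np.ndarray,
    grid: Sequence[float],
    label: str = "stratum",
    neglog_cap: float = NEGLOG10_P_CAP,
    min_count: int = 5,
) -> FoldCurve:
    """Fold enrichment of a stratum over all SNPs on a -log10(p) grid.

    At abscissa x, CDF_s(x) is the proportion of stratum SNPs with
    -log10(p) >= x; fold(x) = CDF_s(x)/CDF_all(x). fold(0) = 1 by
    construction. Points with denominator count below `min_count`, or with
    CDF_all = 0, are flagged unreliable (the latter are NaN).
    """
    grid = np.asarray(grid, dtype=float)
    if (grid < 0).any() or (grid >= neglog_cap).any():
        raise ValueError(f"grid must lie within [0, {neglog_cap})")
    mask = np.asarray(stratum_mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty stratum")
    neglog = -np.log10(sumstats.p)
    # restrict to sub-threshold SNPs, as for the Q-Q curves
    sub_all = neglog[neglog < neglog_cap]
    sub_s = neglog[mask & (neglog < neglog_cap)]
    n_all = np.array([(sub_all >= x).sum() for x in grid])
    n_s = np.array([(sub_s >= x).sum() for x in grid])
    with np.errstate(divide="ignore", invalid="ignore"):
        cdf_all = n_all / len(sub_all)
        cdf_s = n_s / len(sub_s)
        fold = np.where(n_all > 0, cdf_s / cdf_all, np.nan)
    reliable = (n_all >= min_count) & (n_all > 0)
    return FoldCurve(
        label=label,
        grid=grid,
        fold=fold,
        n_stratum=n_s,
        n_all=n_all,
        reliable=reliable,
    )
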
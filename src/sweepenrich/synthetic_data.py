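"""Synthetic reference panels, annotation tracks and GWAS summary statistics.

The generator realizes exactly the model the enrichment regression inverts:
within each LD block with standardized-genotype correlation R,

    beta_j ~ Normal(0, sum_c a_jc * tau_c)
    z      = sqrt(N) * R beta + eta,   eta ~ MVN(0, inflation * R)

so that E[chi2_j] = inflation + N * sum_c tau_c * ell(j, c) with ell built
from the same R. Summary statistics are simulated directly at the z level
(no individual phenotypes) for speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io_formats import GenotypePanel, RegionSet, SumstatsTable, p_from_z
from .ld_annotation import AnnotationSet

__all__ = [
    "CategorySpec",
    "SimConfig",
    "TrueParams",
    "generate_panel",
    "generate_tracks",
    "generate_sumstats",
    "taus_for_fold",
    "block_bounds",
]

#: tracks that must not overlap each other when placed
GENIC_GROUP = ("exon", "intron", "utr3", "utr5")
#: tracks that participate in intergenic classification but carry no signal
CONTEXT_TRACKS = ("ncRNA", "TFBS", "miRNA")


@dataclass(frozen=True)
class CategorySpec:
    """Genome fraction covered by a track and its per-SNP heritability
    coefficient tau (added on top of any other category the SNP is in)."""

    fraction: float
    tau: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    M: int = 2000
    n_blocks_ld: int = 100
    block_rho: float = 0.6
    n_panel: int = 200
    N_gwas: int = 50_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    category_spec: Mapping[str, CategorySpec] = field(
        default_factory=lambda: {
            "base": CategorySpec(fraction=1.0, tau=0.0),
            "HD": CategorySpec(fraction=0.05, tau=0.0),
        }
    )
    intercept_inflation: float = 1.0
    rng_seed: int = 0
    n_chrom: int = 2
    spacing_bp: int = 20_000
    track_run_len: int = 25

    def __post_init__(self) -> None:
        if not (0 <= self.block_rho < 1):
            raise ValueError("block_rho must lie in [0, 1)")
        if not (0 < self.maf_range[0] < self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo < hi <= 0.5")
        if self.intercept_inflation < 1:
            raise ValueError("intercept_inflation must be >= 1")
        for name, spec in self.category_spec.items():
            if spec.tau < 0:
                raise ValueError(f"tau for {name!r} must be >= 0")
            if not (0 <= spec.fraction <= 1):
                raise ValueError(f"fraction for {name!r} must lie in [0, 1]")
        genic = sum(
            self.category_spec[c].fraction
            for c in GENIC_GROUP
            if c in self.category_spec
        )
        if genic > 1:
            raise ValueError("disjoint genic track fractions sum above 1")
        if self.h2_total() > 1:
            raise ValueError(f"h2_total = {self.h2_total():.3f} exceeds 1")

    def h2_total(self) -> float:
        """Expected total heritability sum_c tau_c * M_c implied by the spec."""
        h2 = 0.0
        for name, spec in self.category_spec.items():
            frac = 1.0 if name == "base" else spec.fraction
            h2 += spec.tau * frac * self.M
        return h2

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, rng_seed=seed)


def block_bounds(cfg: SimConfig) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Contiguous LD-block index ranges and the chromosome label per SNP.

    Block sizes are deliberately heterogeneous (drawn deterministically from
    the config seed) so per-SNP LD scores vary enough to identify the
    regression slope. Chromosome boundaries are aligned to block boundaries
    so no LD block spans two chromosomes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 0xB10C]))
    weights = rng.uniform(0.25, 1.75, size=cfg.n_blocks_ld)
    edges = np.round(np.cumsum(weights) / weights.sum() * cfg.M).astype(int)
    edges = np.unique(np.concatenate([[0], edges[:-1], [cfg.M]]))
    blocks = [
        (int(s), int(e)) for s, e in zip(edges[:-1], edges[1:]) if e > s
    ]
    chrom = np.empty(cfg.M, dtype=object)
    for c, group in enumerate(np.array_split(np.arange(len(blocks)), cfg.n_chrom)):
        for b in group:
            s, e = blocks[b]
            chrom[s:e] = str(c + 1)
    return blocks, chrom


def _positions(cfg: SimConfig, chrom: np.ndarray) -> np.ndarray:
    pos = np.empty(cfg.M, dtype=np.int64)
    for c in pd.unique(chrom):
        sel = np.flatnonzero(chrom == c)
        pos[sel] = 10_000 + (np.arange(len(sel)) + 1) * cfg.spacing_bp
    return pos


def generate_panel(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> GenotypePanel:
    """Block-correlated dosage panel in {0,1,2}.

    Haplotypes come from a Gaussian copula with block-exchangeable latent
    correlation `block_rho`, thresholded at the per-SNP MAF quantile; the two
    haplotypes per sample are summed. Monomorphic columns are resampled
    (keeping the shared block factor) and, as a last resort, one genotype is
    flipped so every column has positive variance.
    """
    if cfg.n_panel < 10:
        raise ValueError("n_panel must be >= 10")
    rng = rng or np.random.default_rng(cfg.rng_seed)
    blocks, chrom = block_bounds(cfg)
    pos = _positions(cfg, chrom)
    maf = rng.uniform(*cfg.maf_range, size=cfg.M)
    thresh = norm.ppf(maf)
    n_hap = 2 * cfg.n_panel
    dosages = np.empty((cfg.n_panel, cfg.M))
    sqrt_rho = np.sqrt(cfg.block_rho)
    sqrt_1mrho = np.sqrt(1 - cfg.block_rho)
    for s, e in blocks:
        width = e - s
        g = rng.standard_normal((n_hap, 1))
        eps = rng.standard_normal((n_hap, width))
        z = sqrt_rho * g + sqrt_1mrho * eps
        hap = (z < thresh[s:e]).astype(float)
        block_dos = hap[: cfg.n_panel] + hap[cfg.n_panel :]
        for _ in range(50):
            mono = np.flatnonzero(block_dos.std(axis=0) == 0)
            if len(mono) == 0:
                break
            eps_new = rng.standard_normal((n_hap, len(mono)))
            z_new = sqrt_rho * g + sqrt_1mrho * eps_new
            hap_new = (z_new < thresh[s:e][mono]).astype(float)
            block_dos[:, mono] = hap_new[: cfg.n_panel] + hap_new[cfg.n_panel :]
        for j in np.flatnonzero(block_dos.std(axis=0) == 0):
            block_dos[0, j] = 1.0 if block_dos[1, j] != 1.0 else 0.0
        dosages[:, s:e] = block_dos
    ids = np.array([f"snp{j + 1:07d}" for j in range(cfg.M)], dtype=object)
    return GenotypePanel(
        dosages=dosages,
        snp_id=ids,
        chrom=chrom,
        pos=pos,
        a1=np.full(cfg.M, "A", dtype=object),
        a2=np.full(cfg.M, "G", dtype=object),
    )


def _runs_to_regions(
    panel: GenotypePanel, chosen: np.ndarray, label: str
) -> RegionSet:
    """Interval cover of a chosen-SNP mask: one interval per consecutive run,
    spanning [pos(first) - 1, pos(last)) so it contains exactly those SNPs."""
    idx = np.flatnonzero(chosen)
    if len(idx) == 0:
        return RegionSet.from_intervals([], label=label)
    ivs = []
    run_start = idx[0]
    prev = idx[0]
    for j in idx[1:]:
        if j != prev + 1 or panel.chrom[j] != panel.chrom[prev]:
            ivs.append(
                (panel.chrom[run_start], int(panel.pos[run_start]) - 1,
                 int(panel.pos[prev]))
            )
            run_start = j
        prev = j
    ivs.append(
        (panel.chrom[run_start], int(panel.pos[run_start]) - 1, int(panel.pos[prev]))
    )
    return RegionSet.from_intervals(ivs, label=label)


def _place_runs(
    free: np.ndarray,
    target: int,
    run_len: int,
    chrom: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mark exactly `target` SNPs as chosen, in runs of up to `run_len`
    consecutive free SNPs that never cross a chromosome boundary."""
    chosen = np.zeros(len(free), dtype=bool)
    need = target
    while need > 0:
        candidates = np.flatnonzero(free)
        if len(candidates) == 0:
            raise ValueError("no free SNPs left to place track")
        start = int(rng.choice(candidates))
        j = start
        while (
            need > 0
            and j < len(free)
            and free[j]
            and chrom[j] == chrom[start]
            and j - start < run_len
        ):
            chosen[j] = True
            free[j] = False
            need -= 1
            j += 1
    return chosen


def generate_tracks(
    cfg: SimConfig,
    panel: GenotypePanel,
    rng: np.random.Generator | None = None,
) -> dict[str, RegionSet]:
    """Region tracks covering the configured SNP fractions exactly.

    The HD (swept-region) track is block-aligned — whole LD blocks are
    selected at random, the last trimmed so the SNP count is exact — so
    LD-tagging of HD membership is realistic. The genic tracks are placed as
    mutually disjoint random runs; brain and context tracks are placed
    independently. A merged "genes" track (union of the genic tracks) is
    always emitted.
    """
    rng = rng or np.random.default_rng(cfg.rng_seed + 1)
    blocks, chrom = block_bounds(cfg)
    tracks: dict[str, RegionSet] = {}

    if "HD" in cfg.category_spec:
        target = round(cfg.category_spec["HD"].fraction * cfg.M)
        chosen = np.zeros(cfg.M, dtype=bool)
        need = target
        for b in rng.permutation(len(blocks)):
            if need <= 0:
                break
            s, e = blocks[b]
            take = min(need, e - s)
            chosen[s : s + take] = True
            need -= take
        tracks["HD"] = _runs_to_regions(panel, chosen, "HD")

    genic_free = np.ones(cfg.M, dtype=bool)
    for name in GENIC_GROUP:
        if name not in cfg.category_spec:
            continue
        target = round(cfg.category_spec[name].fraction * cfg.M)
        chosen = _place_runs(genic_free, target, cfg.track_run_len, chrom, rng)
        tracks[name] = _runs_to_regions(panel, chosen, name)

    for name in ("brain",) + CONTEXT_TRACKS:
        if name not in cfg.category_spec:
            continue
        target = round(cfg.category_spec[name].fraction * cfg.M)
        free = np.ones(cfg.M, dtype=bool)
        chosen = _place_runs(free, target, cfg.track_run_len, chrom, rng)
        tracks[name] = _runs_to_regions(panel, chosen, name)

    genes = RegionSet.from_intervals([], label="genes")
    for name in GENIC_GROUP:
        if name in tracks:
            genes = genes.union(tracks[name], label="genes")
    tracks["genes"] = genes
    return tracks


@dataclass
class TrueParams:
    """Ground truth returned alongside simulated summary statistics."""

    tau: dict[str, float]
    sigma2: np.ndarray
    h2_total: float
    true_fold: dict[str, float]
    intercept_inflation: float


def generate_sumstats(
    panel: GenotypePanel,
    annotations: AnnotationSet,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[SumstatsTable, TrueParams]:
    """Simulate z-scores under the partitioned polygenic model (see module
    docstring), using the panel's empirical within-block correlation as R."""
    rng = rng or np.random.default_rng(cfg.rng_seed + 2)
    if panel.n_snps != cfg.M:
        raise ValueError("panel does not match cfg.M")
    tau_vec = np.array(
        [
            cfg.category_spec[name].tau if name in cfg.category_spec else 0.0
            for name in annotations.names
        ]
    )
    sigma2 = annotations.binary @ tau_vec
    h2_total = float(sigma2.sum())
    if h2_total > 1:
        raise ValueError(f"h2_total = {h2_total:.3f} exceeds 1")

    blocks, _ = block_bounds(cfg)
    Xs = panel.standardized()
    n = panel.n_samples
    rootN = np.sqrt(cfg.N_gwas)
    root_infl = np.sqrt(cfg.intercept_inflation)
    z = np.empty(cfg.M)
    for s, e in blocks:
        R = Xs[:, s:e].T @ Xs[:, s:e] / n
        L = _safe_cholesky(R)
        beta = rng.standard_normal(e - s) * np.sqrt(sigma2[s:e])
        eta = root_infl * (L @ rng.standard_normal(e - s))
        z[s:e] = rootN * (R @ beta) + eta

    df = pd.DataFrame(
        {
            "snp_id": panel.snp_id,
            "chrom": panel.chrom,
            "pos": panel.pos,
            "a1": "A",
            "a2": "G",
            "z": z,
            "p": p_from_z(z),
            "n": cfg.N_gwas,
        }
    )
    true_fold = {}
    mean_sigma2 = h2_total / cfg.M
    for k, name in enumerate(annotations.names):
        member = annotations.binary[:, k].astype(bool)
        if member.sum() == 0 or mean_sigma2 == 0:
            true_fold[name] = float("nan")
        else:
            true_fold[name] = float(sigma2[member].mean() / mean_sigma2)
    truth = TrueParams(
        tau={name: float(t) for name, t in zip(annotations.names, tau_vec)},
        sigma2=sigma2,
        h2_total=h2_total,
        true_fold=true_fold,
        intercept_inflation=cfg.intercept_inflation,
    )
    return SumstatsTable(df), truth


def _safe_cholesky(R: np.ndarray) -> np.ndarray:
    for jitter in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            return np.linalg.cholesky(R + jitter * np.eye(len(R)))
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("block correlation matrix not positive definite")


def taus_for_fold(
    fold: float, fraction: float, h2_total: float, M: int
) -> tuple[float, float]:
    """(tau_base, tau_extra) giving a target enrichment fold for a category
    covering `fraction` of the genome, with the stated total heritability.

    Solves h2_total = M*(tau_base + fraction*tau_extra) and
    fold = (tau_base + tau_extra) / (h2_total / M).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    per_snp = h2_total / M
    tau_base = per_snp * (1 - fraction * fold) / (1 - fraction)
    tau_extra = per_snp * (fold - 1) / (1 - fraction)
    if tau_base < 0 or tau_extra < 0:
        raise ValueError(
            f"fold {fold} not achievable with fraction {fraction} "
            "and non-negative coefficients"
        )
    return tau_base, tau_extra
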
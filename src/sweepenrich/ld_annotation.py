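"""LD computations and SNP annotation.

Two distinct LD-weighting procedures live here and must not be conflated:

* :func:`ld_weighted_region_score` — per-SNP sum of r^2 to panel SNPs inside
  a region set, with r^2 < 0.2 zeroed and the self term fixed at 1.0. Used
  for the region annotation columns (swept regions, exon/intron/UTR, brain).
* :func:`partitioned_ld_scores` — per-category LD scores for the enrichment
  regression, using the bias-adjusted estimator
  ``r~^2 = r^2 - (1 - r^2)/(n - 2)`` with NO 0.2 threshold. Individual
  adjusted r~^2 values may be negative; sums are not clipped.

All windows are symmetric +/- `window_bp` by position on the same chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenotypePanel, RegionSet

__all__ = [
    "AnnotationSet",
    "LDScoreTable",
    "pairwise_r2",
    "ld_weighted_region_score",
    "partitioned_ld_scores",
    "build_annotations",
    "binary_annotations",
    "classify_intergenic",
    "mhc_exclusion_mask",
    "ld_neighbors",
    "ld_prune",
]

DEFAULT_WINDOW_BP = 1_000_000
LD_R2_FLOOR = 0.2

# extended MHC, genome build 19 (1-based, inclusive)
MHC_CHROM = "6"
MHC_START = 25_119_106
MHC_END = 33_854_733


def _iter_banded(
    panel: GenotypePanel, window_bp: int, chunk: int = 512
) -> Iterator[tuple[int, int, int, int, np.ndarray]]:
    """Yield (cs, ce, lo, hi, R) where R[k - lo, j - cs] = corr(SNP k, SNP j)
    for SNP chunks [cs, ce) and their +/- window_bp neighbourhood [lo, hi),
    all on one chromosome. Indices are global panel indices."""
    Xs = panel.standardized()
    n = panel.n_samples
    for _, sl in panel.chrom_slices():
        pos = panel.pos[sl.start : sl.stop]
        for cs in range(sl.start, sl.stop, chunk):
            ce = min(cs + chunk, sl.stop)
            lo = sl.start + int(
                np.searchsorted(pos, panel.pos[cs] - window_bp, side="left")
            )
            hi = sl.start + int(
                np.searchsorted(pos, panel.pos[ce - 1] + window_bp, side="right")
            )
            R = Xs[:, lo:hi].T @ Xs[:, cs:ce] / n
            yield cs, ce, lo, hi, R


def _window_mask(R: np.ndarray, cs: int, ce: int, lo: int, hi: int,
                 pos: np.ndarray, window_bp: int) -> np.ndarray:
    """Boolean mask, same shape as R, of pairs within +/- window_bp."""
    return (
        np.abs(pos[lo:hi, None] - pos[None, cs:ce]) <= window_bp
    )


def pairwise_r2(
    panel: GenotypePanel, i: int, window_bp: int = DEFAULT_WINDOW_BP
) -> dict[int, float]:
    """Squared Pearson correlation of SNP `i` with every panel SNP within
    +/- window_bp on the same chromosome, as a map j -> r2 (r2_ii = 1.0)."""
    if not 0 <= i < panel.n_snps:
        raise IndexError(f"SNP index {i} out of range")
    Xs = panel.standardized()
    for chrom, sl in panel.chrom_slices():
        if sl.start <= i < sl.stop:
            pos = panel.pos[sl.start : sl.stop]
            lo = sl.start + int(np.searchsorted(pos, panel.pos[i] - window_bp))
            hi = sl.start + int(
                np.searchsorted(pos, panel.pos[i] + window_bp, side="right")
            )
            r = Xs[:, lo:hi].T @ Xs[:, i] / panel.n_samples
            out = {int(j): float(r[j - lo] ** 2) for j in range(lo, hi)}
            out[i] = 1.0
            return out
    raise IndexError(f"SNP index {i} not located")  # pragma: no cover


def ld_weighted_region_score(
    panel: GenotypePanel,
    regions: RegionSet,
    window_bp: int = DEFAULT_WINDOW_BP,
    r2_floor: float = LD_R2_FLOOR,
) -> np.ndarray:
    """LD-weighted region annotation score per panel SNP.

    score_i = sum_j delta_j * r2_ij over panel SNPs j within the window,
    where delta_j = 1 iff SNP j lies inside `regions`, r2 values below
    `r2_floor` are set to 0 and r2_ii = 1.0 exactly. A member SNP therefore
    scores >= 1; an empty region set gives the zero vector.
    """
    delta = regions.contains(panel.chrom, panel.pos).astype(float)
    scores = np.zeros(panel.n_snps)
    if not delta.any():
        return scores
    for cs, ce, lo, hi, R in _iter_banded(panel, window_bp):
        r2 = R**2
        r2[r2 < r2_floor] = 0.0
        cols = np.arange(cs, ce)
        r2[cols - lo, cols - cs] = 1.0  # self term, exact
        r2 *= _window_mask(r2, cs, ce, lo, hi, panel.pos, window_bp)
        scores[cs:ce] = delta[lo:hi] @ r2
    return scores


@dataclass
class AnnotationSet:
    """Per-SNP binary memberships and LD-weighted scores over named categories.

    binary is M x C in {0,1}; weighted is M x C with weighted >= binary
    entrywise (self r^2 = 1 guarantees a member SNP scores >= 1).
    """

    names: list[str]
    binary: np.ndarray
    weighted: np.ndarray

    def __post_init__(self) -> None:
        self.binary = np.asarray(self.binary)
        self.weighted = np.asarray(self.weighted, dtype=float)
        if self.binary.shape != self.weighted.shape or self.binary.shape[1] != len(
            self.names
        ):
            raise ValueError("binary/weighted/names shapes disagree")
        if not np.isin(self.binary, (0, 1)).all():
            raise ValueError("binary entries must be 0/1")

    def column(self, name: str, kind: str = "binary") -> np.ndarray:
        j = self.names.index(name)
        return (self.binary if kind == "binary" else self.weighted)[:, j]

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def to_frame(self, panel: GenotypePanel) -> pd.DataFrame:
        df = pd.DataFrame(
            {"snp_id": panel.snp_id, "chrom": panel.chrom, "pos": panel.pos}
        )
        for k, name in enumerate(self.names):
            df[f"{name}.bin"] = self.binary[:, k]
            df[f"{name}.ld"] = self.weighted[:, k]
        return df


def build_annotations(
    panel: GenotypePanel,
    tracks: Mapping[str, RegionSet],
    window_bp: int = DEFAULT_WINDOW_BP,
    include_base: bool = True,
    intersections: Mapping[str, tuple[str, str]] | None = None,
) -> AnnotationSet:
    """Binary membership + LD-weighted score for each region track.

    `intersections` adds derived categories as pairwise binary intersections
    (e.g. ``{"HDBrain": ("HD", "brain")}``); their weighted column is the
    LD-weighted score of the intersected binary membership.
    """
    names: list[str] = []
    bin_cols: list[np.ndarray] = []
    wt_cols: list[np.ndarray] = []
    if include_base:
        names.append("base")
        bin_cols.append(np.ones(panel.n_snps, dtype=np.int8))
        wt_cols.append(
            ld_weighted_region_score(
                panel,
                RegionSet.from_intervals(
                    [
                        (c, 0, int(panel.pos[sl.stop - 1]) + 1)
                        for c, sl in panel.chrom_slices()
                    ],
                    label="base",
                ),
                window_bp=window_bp,
            )
        )
    for name, rs in tracks.items():
        names.append(name)
        bin_cols.append(rs.contains(panel.chrom, panel.pos).astype(np.int8))
        wt_cols.append(ld_weighted_region_score(panel, rs, window_bp=window_bp))
    binary = np.column_stack(bin_cols)
    weighted = np.column_stack(wt_cols)
    ann = AnnotationSet(names=names, binary=binary, weighted=weighted)
    if intersections:
        for name, (a, b) in intersections.items():
            inter = ann.column(a) * ann.column(b)
            member_idx = np.flatnonzero(inter)
            rs = _regionset_from_snps(panel, member_idx, name)
            wt = ld_weighted_region_score(panel, rs, window_bp=window_bp)
            ann.names.append(name)
            ann.binary = np.column_stack([ann.binary, inter.astype(np.int8)])
            ann.weighted = np.column_stack([ann.weighted, wt])
    return ann


def binary_annotations(
    panel: GenotypePanel,
    tracks: Mapping[str, RegionSet],
    include_base: bool = True,
    intersections: Mapping[str, tuple[str, str]] | None = None,
) -> AnnotationSet:
    """Membership-only AnnotationSet (weighted column = binary column).

    Cheap alternative to :func:`build_annotations` when the LD-weighted
    scores are not needed, e.g. as input to the partitioned LD-score
    computation or the summary-statistics simulator.
    """
    names: list[str] = []
    cols: list[np.ndarray] = []
    if include_base:
        names.append("base")
        cols.append(np.ones(panel.n_snps, dtype=np.int8))
    for name, rs in tracks.items():
        names.append(name)
        cols.append(rs.contains(panel.chrom, panel.pos).astype(np.int8))
    binary = np.column_stack(cols)
    ann = AnnotationSet(names=names, binary=binary, weighted=binary.astype(float))
    if intersections:
        for name, (a, b) in intersections.items():
            inter = (ann.column(a) * ann.column(b)).astype(np.int8)
            ann.names.append(name)
            ann.binary = np.column_stack([ann.binary, inter])
            ann.weighted = np.column_stack([ann.weighted, inter.astype(float)])
    return ann


def _regionset_from_snps(
    panel: GenotypePanel, idx: np.ndarray, label: str
) -> RegionSet:
    """Minimal interval cover of the given panel SNPs (one point interval each)."""
    ivs = [
        (panel.chrom[j], int(panel.pos[j]) - 1, int(panel.pos[j])) for j in idx
    ]
    return RegionSet.from_intervals(ivs, label=label)


@dataclass
class LDScoreTable:
    """Partitioned LD scores ell(j, c) for the regression SNP subset.

    ell_total(j) is the LD score towards ALL panel SNPs; M_c are per-category
    panel SNP counts; `overlap` is the C x C annotation co-membership matrix
    A'A over panel SNPs, needed for per-category heritability under
    overlapping annotations.
    """

    snp_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    names: list[str]
    ell: np.ndarray
    ell_total: np.ndarray
    M_c: np.ndarray
    M: int
    overlap: np.ndarray
    panel_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __len__(self) -> int:
        return len(self.pos)

    def column(self, name: str) -> np.ndarray:
        return self.ell[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"snp_id": self.snp_id, "chrom": self.chrom, "pos": self.pos}
        )
        for k, name in enumerate(self.names):
            df[f"L2.{name}"] = self.ell[:, k]
        df["L2.total"] = self.ell_total
        return df


def partitioned_ld_scores(
    panel: GenotypePanel,
    annotations: AnnotationSet,
    regression_snps: Sequence[str] | None = None,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> LDScoreTable:
    """Per-category LD scores with the unbiased-estimator adjustment.

    ell(j, c) = sum_k a_kc * r~2_jk over panel SNPs k within the window,
    r~2 = r2 - (1 - r2)/(n_samples - 2), self term exactly 1. No threshold
    is applied (distinct from ld_weighted_region_score); sums may include
    negative adjusted terms and are not clipped.
    """
    n = panel.n_samples
    if n < 3:
        raise ValueError("need >= 3 samples for the r2 bias adjustment")
    A = annotations.binary.astype(float)
    M = panel.n_snps
    ell = np.zeros((M, A.shape[1]))
    ell_total = np.zeros(M)
    for cs, ce, lo, hi, R in _iter_banded(panel, window_bp):
        r2 = R**2
        r2adj = r2 - (1.0 - r2) / (n - 2)
        cols = np.arange(cs, ce)
        r2adj[cols - lo, cols - cs] = 1.0
        r2adj *= _window_mask(r2adj, cs, ce, lo, hi, panel.pos, window_bp)
        ell[cs:ce] = r2adj.T @ A[lo:hi]
        ell_total[cs:ce] = r2adj.sum(axis=0)
    if regression_snps is not None:
        idx = panel.index_of(regression_snps)
    else:
        idx = np.arange(M)
    return LDScoreTable(
        snp_id=panel.snp_id[idx],
        chrom=panel.chrom[idx],
        pos=panel.pos[idx],
        names=list(annotations.names),
        ell=ell[idx],
        ell_total=ell_total[idx],
        M_c=annotations.binary.sum(axis=0).astype(np.int64),
        M=M,
        overlap=annotations.binary.T.astype(float) @ annotations.binary.astype(float),
        panel_index=idx,
    )


GENIC_CATEGORIES = ("exon", "intron", "utr3", "utr5")


def classify_intergenic(
    annotations: AnnotationSet,
    panel: GenotypePanel,
    gene_context: Mapping[str, RegionSet],
    gene_pad_bp: int = 100_000,
    window_bp: int = DEFAULT_WINDOW_BP,
    r2_threshold: float = LD_R2_FLOOR,
) -> np.ndarray:
    """Mask of putatively null intergenic SNPs.

    A SNP is intergenic iff its LD-weighted exon/intron/3'UTR/5'UTR scores
    are all zero AND it is in LD (r2 >= threshold, self included) with no
    panel SNP inside protein-coding genes +/- gene_pad_bp, ncRNAs, TFBSs or
    miRNA binding sites. `gene_context` must contain a "genes" track (padded
    here); other tracks are used as-is.
    """
    missing = [c for c in GENIC_CATEGORIES if c not in annotations]
    if missing:
        raise ValueError(f"annotations lack genic LD-score columns: {missing}")
    genic = np.zeros(panel.n_snps, dtype=bool)
    for c in GENIC_CATEGORIES:
        genic |= annotations.column(c, "weighted") > 0

    context = np.zeros(panel.n_snps, dtype=bool)
    for name, rs in gene_context.items():
        if name == "genes":
            rs = rs.expand(gene_pad_bp)
        context |= rs.contains(panel.chrom, panel.pos)

    tags_context = np.zeros(panel.n_snps, dtype=bool)
    if context.any():
        m = context.astype(float)
        for cs, ce, lo, hi, R in _iter_banded(panel, window_bp):
            hit = (R**2 >= r2_threshold) & _window_mask(
                R, cs, ce, lo, hi, panel.pos, window_bp
            )
            cols = np.arange(cs, ce)
            hit[cols - lo, cols - cs] = True  # self r2 = 1
            tags_context[cs:ce] = (hit.T @ m[lo:hi]) > 0
    return ~genic & ~tags_context


def mhc_exclusion_mask(
    panel: GenotypePanel,
    sumstats=None,  # accepted for interface symmetry; unused
    chrom: str = MHC_CHROM,
    start: int = MHC_START,
    end: int = MHC_END,
    r2_threshold: float = 0.1,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> np.ndarray:
    """Keep-mask excluding the extended MHC and its LD partners.

    Excludes SNPs on `chrom` with start <= pos <= end (1-based, inclusive)
    and any SNP with r2 > r2_threshold (within the window) to an excluded
    SNP. All-True if no SNPs fall in the interval.
    """
    chrom_hit = (panel.chrom == chrom) | (panel.chrom == f"chr{chrom}")
    core = chrom_hit & (panel.pos >= start) & (panel.pos <= end)
    if not core.any():
        return np.ones(panel.n_snps, dtype=bool)
    tagged = np.zeros(panel.n_snps, dtype=bool)
    m = core.astype(float)
    for cs, ce, lo, hi, R in _iter_banded(panel, window_bp):
        hit = (R**2 > r2_threshold) & _window_mask(
            R, cs, ce, lo, hi, panel.pos, window_bp
        )
        tagged[cs:ce] = (hit.T @ m[lo:hi]) > 0
    return ~(core | tagged)


def ld_neighbors(
    panel: GenotypePanel,
    idx: np.ndarray,
    r2_threshold: float = LD_R2_FLOOR,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[np.ndarray]:
    """Adjacency lists among the SNP subset `idx` (panel indices, sorted):
    neighbors[k] holds subset positions with r2 >= threshold to subset SNP k."""
    idx = np.asarray(idx, dtype=np.int64)
    sub = panel.subset(idx)
    m = len(idx)
    neighbors: list[np.ndarray] = [np.empty(0, dtype=np.int64)] * m
    for cs, ce, lo, hi, R in _iter_banded(sub, window_bp):
        hit = (R**2 >= r2_threshold) & _window_mask(
            R, cs, ce, lo, hi, sub.pos, window_bp
        )
        for j in range(cs, ce):
            rows = np.flatnonzero(hit[:, j - cs]) + lo
            neighbors[j] = rows[rows != j]
    return neighbors


def _prune_from_adjacency(
    neighbors: list[np.ndarray], rng: np.random.Generator
) -> np.ndarray:
    """Greedy random-order pruning; returns surviving subset positions."""
    m = len(neighbors)
    alive = np.ones(m, dtype=bool)
    kept = []
    for k in rng.permutation(m):
        if alive[k]:
            kept.append(k)
            alive[neighbors[k]] = False
    return np.array(sorted(kept), dtype=np.int64)


def ld_prune(
    panel: GenotypePanel,
    candidate_ids: Sequence[str],
    r2_threshold: float = LD_R2_FLOOR,
    rng_seed: int | np.random.Generator = 0,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[str]:
    """Greedy random LD pruning to an approximately independent id subset.

    Repeatedly picks a remaining candidate uniformly at random, keeps it and
    removes all remaining candidates with r2 >= threshold to it. The result
    has max pairwise r2 < threshold and is reproducible given the seed.
    """
    if len(candidate_ids) == 0:
        return []
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    idx = panel.index_of(candidate_ids)
    idx.sort()
    neighbors = ld_neighbors(panel, idx, r2_threshold, window_bp)
    kept = _prune_from_adjacency(neighbors, rng)
    return [str(s) for s in panel.snp_id[idx[kept]]]
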
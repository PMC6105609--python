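import numpy as np
import pytest

from sweepenrich.io_formats import GenotypePanel, RegionSet
from sweepenrich import synthetic_data as synth


def panel_with_corr(
    C: np.ndarray,
    pos: np.ndarray,
    chrom: str = "1",
    n_samples: int = 24,
    seed: int = 0,
) -> GenotypePanel:
    """Panel whose EMPIRICAL column correlation equals C exactly.

    Columns are built as sqrt(n) * L @ H where L = chol(C) and H holds
    orthonormal mean-zero rows, so sample means are 0 and the ddof=0
    correlation matrix is exactly C. Values are shifted into [0, 2].
    """
    m = len(C)
    if n_samples < m + 1:
        raise ValueError("need n_samples > number of SNPs")
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n_samples, n_samples))
    A[:, 0] = 1.0
    Q, _ = np.linalg.qr(A)
    H = Q[:, 1 : m + 1].T  # m orthonormal rows, each orthogonal to 1 => mean 0
    L = np.linalg.cholesky(C)
    X = np.sqrt(n_samples) * (L @ H)  # m x n, empirical corr = C
    X = X.T
    scale = 0.9 / np.abs(X).max()
    dosages = 1.0 + scale * X
    return GenotypePanel(
        dosages=dosages,
        snp_id=np.array([f"s{j}" for j in range(m)], dtype=object),
        chrom=np.full(m, chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
    )


# --- dense brute-force oracles (independent of the banded implementation) ---


def dense_r2(panel: GenotypePanel) -> np.ndarray:
    """Full pairwise r^2 via per-pair Pearson correlation."""
    M = panel.n_snps
    out = np.ones((M, M))
    for i in range(M):
        for j in range(i + 1, M):
            r = np.corrcoef(panel.dosages[:, i], panel.dosages[:, j])[0, 1]
            out[i, j] = out[j, i] = r**2
    return out


def _in_window(panel, i, j, window_bp):
    return panel.chrom[i] == panel.chrom[j] and abs(
        int(panel.pos[i]) - int(panel.pos[j])
    ) <= window_bp


def dense_region_score(panel, regions, window_bp=1_000_000, floor=0.2):
    delta = regions.contains(panel.chrom, panel.pos)
    r2 = dense_r2(panel)
    M = panel.n_snps
    scores = np.zeros(M)
    for i in range(M):
        for j in range(M):
            if not _in_window(panel, i, j, window_bp) or not delta[j]:
                continue
            v = 1.0 if i == j else r2[i, j]
            if v < floor:
                v = 0.0
            scores[i] += v
    return scores


def dense_partitioned_ld(panel, binary, window_bp=1_000_000):
    n = panel.n_samples
    r2 = dense_r2(panel)
    M, C = binary.shape
    ell = np.zeros((M, C))
    total = np.zeros(M)
    for i in range(M):
        for j in range(M):
            if not _in_window(panel, i, j, window_bp):
                continue
            v = 1.0 if i == j else r2[i, j] - (1 - r2[i, j]) / (n - 2)
            total[i] += v
            for c in range(C):
                if binary[j, c]:
                    ell[i, c] += v
    return ell, total


# --- shared small synthetic fixtures ---


@pytest.fixture(scope="session")
def small_cfg() -> synth.SimConfig:
    return synth.SimConfig(
        M=400,
        n_blocks_ld=25,
        block_rho=0.5,
        n_panel=80,
        N_gwas=20_000,
        category_spec={
            "base": synth.CategorySpec(1.0, 0.0),
            "HD": synth.CategorySpec(0.1, 0.0),
            "exon": synth.CategorySpec(0.05, 0.0),
            "intron": synth.CategorySpec(0.1, 0.0),
            "utr3": synth.CategorySpec(0.02, 0.0),
            "utr5": synth.CategorySpec(0.02, 0.0),
            "brain": synth.CategorySpec(0.1, 0.0),
        },
        rng_seed=42,
    )


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return synth.generate_panel(small_cfg)


@pytest.fixture(scope="session")
def small_tracks(small_cfg, small_panel):
    return synth.generate_tracks(small_cfg, small_panel)
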
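"""Readers/writers for the file formats the pipeline touches.

Coordinate conventions
----------------------
* BED intervals are 0-based half-open ``[start, end)``.
* SNP positions are 1-based (VCF convention).
* A SNP at 1-based position ``pos`` lies inside a BED interval iff
  ``start < pos <= end``, i.e. ``pos - 1`` falls in ``[start, end)``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SumstatsTable",
    "RegionSet",
    "GenotypePanel",
    "ValidationReport",
    "read_sumstats",
    "write_sumstats",
    "read_regions",
    "write_regions",
    "read_panel",
    "write_panel",
    "harmonize",
]

# canonical column -> accepted header spellings (lower-cased)
_DEFAULT_DIALECT: dict[str, tuple[str, ...]] = {
    "snp_id": ("snp", "snp_id", "rsid", "markername", "id"),
    "chrom": ("chr", "chrom", "chromosome"),
    "pos": ("pos", "bp", "position", "base_pair_location"),
    "a1": ("a1", "allele1", "effect_allele", "ea"),
    "a2": ("a2", "allele2", "other_allele", "oa"),
    "z": ("z", "zscore", "z_score"),
    "p": ("p", "pval", "p_value", "pvalue"),
    "n": ("n", "n_total", "samplesize", "sample_size"),
    "beta": ("beta", "b", "effect", "or_sign", "direction"),
}

_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

_CHROM_RE = re.compile(r"^(?:chr)?(.+)$", re.IGNORECASE)


def _chrom_sort_key(chrom: str):
    """Natural ordering: numeric chromosomes first, then lexicographic."""
    m = _CHROM_RE.match(str(chrom))
    body = m.group(1) if m else str(chrom)
    if body.isdigit():
        return (0, int(body), "")
    return (1, 0, body)


@dataclass
class ValidationReport:
    """Row-level accounting produced by :func:`read_sumstats`."""

    n_input: int = 0
    n_kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())

    def add(self, reason: str, count: int) -> None:
        if count:
            self.dropped[reason] = self.dropped.get(reason, 0) + int(count)


@dataclass
class SumstatsTable:
    """Per-SNP association records for one phenotype.

    Wraps a dataframe with columns ``snp_id, chrom, pos, a1, a2, z, p, n``,
    sorted by (chrom, pos). ``p`` and ``z`` satisfy ``p = 2 * Phi(-|z|)``.
    """

    df: pd.DataFrame

    REQUIRED = ("snp_id", "chrom", "pos", "a1", "a2", "z", "p", "n")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"sumstats missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_id(self) -> np.ndarray:
        return self.df["snp_id"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].astype(str).to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.df["pos"].to_numpy(dtype=np.int64)

    @property
    def z(self) -> np.ndarray:
        return self.df["z"].to_numpy(dtype=float)

    @property
    def p(self) -> np.ndarray:
        return self.df["p"].to_numpy(dtype=float)

    @property
    def n(self) -> np.ndarray:
        return self.df["n"].to_numpy(dtype=np.int64)

    @property
    def chisq(self) -> np.ndarray:
        return self.z**2

    def with_z(self, z: np.ndarray) -> "SumstatsTable":
        """Return a copy with new z-scores and p recomputed from them."""
        df = self.df.copy()
        df["z"] = np.asarray(z, dtype=float)
        df["p"] = p_from_z(df["z"].to_numpy())
        return SumstatsTable(df)


def p_from_z(z: np.ndarray) -> np.ndarray:
    """Two-sided p-value, floored away from 0 so it stays in (0, 1]."""
    p = 2.0 * norm.sf(np.abs(z))
    return np.clip(p, np.finfo(float).tiny, 1.0)


def z_from_p(p: np.ndarray, sign: np.ndarray) -> np.ndarray:
    """Signed z reconstructed from a two-sided p: sign * Phi^-1(1 - p/2)."""
    return np.sign(sign) * norm.isf(np.asarray(p, dtype=float) / 2.0)


def _resolve_columns(
    columns: Sequence[str], dialect: Mapping[str, str] | None
) -> dict[str, str]:
    lower = {c.lower(): c for c in columns}
    resolved: dict[str, str] = {}
    dialect = dialect or {}
    for canon, aliases in _DEFAULT_DIALECT.items():
        if canon in dialect:
            if dialect[canon] in columns:
                resolved[canon] = dialect[canon]
            continue
        for alias in aliases:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
    return resolved


def read_sumstats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    z_p_rtol: float = 1e-6,
) -> tuple[SumstatsTable, ValidationReport]:
    """Read a whitespace/tab delimited summary-statistics file.

    ``dialect`` maps canonical names (snp_id, chrom, pos, a1, a2, z, p, n,
    beta) to the file's column headers; unmapped names fall back to common
    spellings. Rows that fail validation are dropped and tallied in the
    returned :class:`ValidationReport`. When only ``p`` plus an effect sign
    is present, ``z`` is reconstructed as ``sign * Phi^-1(1 - p/2)``.
    """
    raw = pd.read_csv(path, sep=r"\s+", dtype={"chrom": str})
    cols = _resolve_columns(raw.columns, dialect)

    mandatory = ["snp_id", "chrom", "pos", "n"]
    missing = [c for c in mandatory if c not in cols]
    if "z" not in cols and "p" not in cols:
        missing.append("z or p")
    if missing:
        raise ValueError(f"cannot resolve mandatory sumstats columns: {missing}")

    report = ValidationReport(n_input=len(raw))
    df = pd.DataFrame(
        {
            "snp_id": raw[cols["snp_id"]].astype(str),
            "chrom": raw[cols["chrom"]].astype(str),
            "pos": pd.to_numeric(raw[cols["pos"]], errors="coerce"),
            "n": pd.to_numeric(raw[cols["n"]], errors="coerce"),
        }
    )
    for allele in ("a1", "a2"):
        df[allele] = (
            raw[cols[allele]].astype(str).str.upper() if allele in cols else "."
        )
    df["z"] = pd.to_numeric(raw[cols["z"]], errors="coerce") if "z" in cols else np.nan
    df["p"] = pd.to_numeric(raw[cols["p"]], errors="coerce") if "p" in cols else np.nan

    has_z = df["z"].notna()
    has_p = df["p"].notna()

    bad_p = has_p & ~((df["p"] > 0) & (df["p"] <= 1))
    report.add("p_out_of_range", bad_p.sum())
    df, has_z, has_p = df[~bad_p], has_z[~bad_p], has_p[~bad_p]

    if "beta" in cols:
        sign = np.sign(pd.to_numeric(raw.loc[df.index, cols["beta"]], errors="coerce"))
    else:
        sign = pd.Series(1.0, index=df.index)

    need_z = ~has_z & has_p
    if need_z.any():
        df.loc[need_z, "z"] = z_from_p(df.loc[need_z, "p"], sign[need_z])
    need_p = has_z & ~has_p
    if need_p.any():
        df.loc[need_p, "p"] = p_from_z(df.loc[need_p, "z"].to_numpy())

    both = has_z & has_p
    if both.any():
        expect = p_from_z(df.loc[both, "z"].to_numpy())
        rel = np.abs(df.loc[both, "p"].to_numpy() - expect) / expect
        bad = pd.Series(False, index=df.index)
        bad.loc[both[both].index] = rel > z_p_rtol
        report.add("z_p_inconsistent", bad.sum())
        df = df[~bad]

    invalid = (
        df["z"].isna()
        | df["pos"].isna()
        | (df["pos"] < 1)
        | df["n"].isna()
        | (df["n"] <= 0)
    )
    report.add("invalid_fields", invalid.sum())
    df = df[~invalid]

    dup = df["snp_id"].duplicated(keep="first")
    report.add("duplicate_snp_id", dup.sum())
    df = df[~dup]

    df = df.astype({"pos": np.int64, "n": np.int64})
    df["_ck"] = df["chrom"].map(_chrom_sort_key)
    df = df.sort_values(["_ck", "pos"], kind="stable").drop(columns="_ck")
    df = df[["snp_id", "chrom", "pos", "a1", "a2", "z", "p", "n"]]
    report.n_kept = len(df)
    return SumstatsTable(df.reset_index(drop=True)), report


def write_sumstats(table: SumstatsTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Regions


@dataclass
class RegionSet:
    """A labelled set of genomic intervals, merged and sorted on creation.

    Intervals are 0-based half-open, stored per-chromosome as parallel
    start/end arrays to support vectorised membership queries.
    """

    label: str
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[tuple[str, int, int]], label: str
    ) -> "RegionSet":
        grouped: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            start, end = int(start), int(end)
            if start >= end:
                raise ValueError(f"interval start >= end: {chrom}:{start}-{end}")
            if start < 0:
                raise ValueError(f"negative interval start: {chrom}:{start}-{end}")
            grouped.setdefault(str(chrom), []).append((start, end))
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in sorted(grouped, key=_chrom_sort_key):
            merged = _merge(sorted(grouped[chrom]))
            starts = np.array([s for s, _ in merged], dtype=np.int64)
            ends = np.array([e for _, e in merged], dtype=np.int64)
            by_chrom[chrom] = (starts, ends)
        return cls(label=label, by_chrom=by_chrom)

    @property
    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom, (starts, ends) in self.by_chrom.items():
            out.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
        return out

    def __len__(self) -> int:
        return sum(len(s) for s, _ in self.by_chrom.values())

    @property
    def total_length(self) -> int:
        return int(sum((e - s).sum() for s, e in self.by_chrom.values()))

    def contains(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Membership mask for 1-based SNP positions (start < pos <= end)."""
        chrom = np.asarray(chrom, dtype=object)
        pos0 = np.asarray(pos, dtype=np.int64) - 1  # to 0-based
        out = np.zeros(len(pos0), dtype=bool)
        for c, (starts, ends) in self.by_chrom.items():
            sel = chrom == c
            if not sel.any():
                continue
            idx = np.searchsorted(starts, pos0[sel], side="right") - 1
            ok = idx >= 0
            hit = np.zeros(sel.sum(), dtype=bool)
            hit[ok] = pos0[sel][ok] < ends[idx[ok]]
            out[sel] = hit
        return out

    def expand(self, pad: int) -> "RegionSet":
        """Pad every interval by `pad` bp on both sides (clipped at 0) and re-merge."""
        ivs = [
            (c, max(0, s - pad), e + pad) for c, s, e in self.intervals
        ]
        return RegionSet.from_intervals(ivs, label=self.label)

    def union(self, other: "RegionSet", label: str | None = None) -> "RegionSet":
        return RegionSet.from_intervals(
            self.intervals + other.intervals, label=label or self.label
        )


def _merge(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in pairs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def read_regions(path: str | Path, label: str) -> RegionSet:
    """Read a 3+ column BED file into a merged, sorted :class:`RegionSet`."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            intervals.append((chrom, start, end))
    return RegionSet.from_intervals(intervals, label=label)


def write_regions(regions: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Genotype panel


@dataclass
class GenotypePanel:
    """Reference dosage matrix; the source of all r^2 values.

    ``dosages`` is n_samples x M with values in [0, 2]; SNP coordinates are
    sorted by (chrom, pos) with strictly increasing positions within each
    chromosome and no monomorphic columns.
    """

    dosages: np.ndarray
    snp_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    a1: np.ndarray | None = None
    a2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.pos):
            raise ValueError("dosages must be n_samples x M matching coordinates")
        if self.dosages.std(axis=0).min() <= 0:
            raise ValueError("panel contains monomorphic SNPs; filter them first")
        seen: dict[str, int] = {}
        last_chrom = None
        for j, c in enumerate(self.chrom):
            if c != last_chrom:
                if c in seen:
                    raise ValueError(f"chromosome {c} not contiguous in panel")
                seen[c] = j
                last_chrom = c
            elif self.pos[j] <= self.pos[j - 1]:
                raise ValueError(
                    f"positions not strictly increasing on {c} at index {j}"
                )
        self._std: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def standardized(self) -> np.ndarray:
        """Column-standardized dosages (mean 0, sd 1, ddof=0), cached."""
        if self._std is None:
            d = self.dosages
            self._std = (d - d.mean(axis=0)) / d.std(axis=0)
        return self._std

    def chrom_slices(self) -> list[tuple[str, slice]]:
        out = []
        start = 0
        for j in range(1, self.n_snps + 1):
            if j == self.n_snps or self.chrom[j] != self.chrom[start]:
                out.append((self.chrom[start], slice(start, j)))
                start = j
        return out

    def subset(self, idx: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            dosages=self.dosages[:, idx],
            snp_id=self.snp_id[idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            a1=None if self.a1 is None else self.a1[idx],
            a2=None if self.a2 is None else self.a2[idx],
        )

    def index_of(self, snp_ids: Sequence[str]) -> np.ndarray:
        """Indices of the given ids; unknown ids dropped with a warning."""
        lookup = {s: j for j, s in enumerate(self.snp_id)}
        idx, missing = [], 0
        for s in snp_ids:
            j = lookup.get(s)
            if j is None:
                missing += 1
            else:
                idx.append(j)
        if missing:
            warnings.warn(f"{missing} SNP ids not found in panel; dropped")
        return np.array(idx, dtype=np.int64)


def read_panel(
    path: str | Path, missing_policy: str = "mean"
) -> GenotypePanel:
    """Read a reference panel from a VCF (by extension) or a TSV dosage matrix.

    Multi-allelic VCF records are skipped with a warning; missing genotypes
    are mean-imputed (the default policy); monomorphic SNPs are removed.
    """
    path = Path(path)
    if path.suffix in (".vcf", ".bcf") or str(path).endswith(".vcf.gz"):
        return _read_panel_vcf(path, missing_policy)
    return _read_panel_tsv(path)


def _read_panel_vcf(path: Path, missing_policy: str) -> GenotypePanel:
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    if len(vcf.samples) == 0:
        raise ValueError(f"{path}: VCF has no samples")
    rows, ids, chroms, poss, a1s, a2s = [], [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            warnings.warn(f"skipping multi-allelic record at {var.CHROM}:{var.POS}")
            continue
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = np.asarray(var.gt_types, dtype=float)
        dosage = np.where(gt == 3, 2.0, gt)
        miss = gt == 2
        if miss.all():
            continue
        if miss.any():
            if missing_policy == "mean":
                dosage[miss] = dosage[~miss].mean()
            else:
                raise ValueError(f"unsupported missing-genotype policy {missing_policy}")
        if dosage.std() == 0:
            continue
        rows.append(dosage)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        a1s.append(var.ALT[0])
        a2s.append(var.REF)
    if not rows:
        raise ValueError(f"{path}: no usable biallelic records")
    return GenotypePanel(
        dosages=np.array(rows).T,
        snp_id=np.array(ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        a1=np.array(a1s, dtype=object),
        a2=np.array(a2s, dtype=object),
    )


def _read_panel_tsv(path: Path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta = ["snp_id", "chrom", "pos"]
    if not all(c in df.columns for c in meta):
        raise ValueError(f"{path}: dosage TSV must have columns {meta} + samples")
    has_alleles = "a1" in df.columns and "a2" in df.columns
    sample_cols = [c for c in df.columns if c not in meta + ["a1", "a2"]]
    if not sample_cols:
        raise ValueError(f"{path}: dosage TSV has no sample columns")
    dos = df[sample_cols].to_numpy(dtype=float).T
    poly = dos.std(axis=0) > 0
    df = df[poly].reset_index(drop=True)
    return GenotypePanel(
        dosages=dos[:, poly],
        snp_id=df["snp_id"].astype(str).to_numpy(dtype=object),
        chrom=df["chrom"].astype(str).to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=np.int64),
        a1=df["a1"].to_numpy(dtype=object) if has_alleles else None,
        a2=df["a2"].to_numpy(dtype=object) if has_alleles else None,
    )


def write_panel(panel: GenotypePanel, path: str | Path) -> None:
    """Write the TSV dosage-matrix representation consumed by read_panel."""
    df = pd.DataFrame(
        {"snp_id": panel.snp_id, "chrom": panel.chrom, "pos": panel.pos}
    )
    if panel.a1 is not None:
        df["a1"] = panel.a1
        df["a2"] = panel.a2
    for i in range(panel.n_samples):
        df[f"s{i + 1}"] = panel.dosages[i]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Harmonization


def harmonize(
    sumstats: SumstatsTable, panel: GenotypePanel
) -> tuple[SumstatsTable, np.ndarray, ValidationReport]:
    """Align sumstats rows to panel SNPs by (chrom, pos).

    Returns the aligned table (panel order), the panel indices it covers, and
    a report. When both sides carry alleles: swapped a1/a2 flips the z sign,
    strand-ambiguous (A/T, C/G) SNPs and allele mismatches are dropped.
    """
    report = ValidationReport(n_input=len(sumstats))
    panel_key = {
        (c, int(p)): j for j, (c, p) in enumerate(zip(panel.chrom, panel.pos))
    }
    rows, panel_idx = [], []
    n_unmatched = n_ambig = n_mismatch = n_flip = 0
    for row in sumstats.df.itertuples(index=False):
        j = panel_key.get((row.chrom, int(row.pos)))
        if j is None:
            n_unmatched += 1
            continue
        z = row.z
        if panel.a1 is not None and row.a1 != "." and row.a2 != ".":
            if (row.a1, row.a2) in _AMBIGUOUS_PAIRS:
                n_ambig += 1
                continue
            pa1, pa2 = panel.a1[j], panel.a2[j]
            if (row.a1, row.a2) == (pa1, pa2):
                pass
            elif (row.a1, row.a2) == (pa2, pa1):
                z = -z
                n_flip += 1
            else:
                n_mismatch += 1
                continue
        rows.append(row._replace(z=z, p=row.p))
        panel_idx.append(j)
    report.add("unmatched_position", n_unmatched)
    report.add("strand_ambiguous", n_ambig)
    report.add("allele_mismatch", n_mismatch)

    order = np.argsort(panel_idx, kind="stable")
    df = pd.DataFrame(rows, columns=list(SumstatsTable.REQUIRED))
    df = df.iloc[order].reset_index(drop=True)
    report.n_kept = len(df)
    return SumstatsTable(df), np.asarray(panel_idx, dtype=np.int64)[order], report
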
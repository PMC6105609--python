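"""Fisher's combined probability test over trait groups.

Independence of the combined tests is assumed (in practice GWAS of related
traits share samples, so the combined p is approximate); no dependence
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = ["MetaResult", "fisher_combine", "combine_groups"]


@dataclass
class MetaResult:
    label: str
    k: int
    chi2_stat: float
    df: int
    p_combined: float


def fisher_combine(pvalues: Sequence[float], label: str = "") -> MetaResult:
    """Combine k independent p-values: chi2 = -2 * sum(ln p) ~ chi2(2k)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("all p-values must lie in (0, 1]")
    stat = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return MetaResult(
        label=label,
        k=int(p.size),
        chi2_stat=stat,
        df=df,
        p_combined=float(max(chi2.sf(stat, df), np.finfo(float).tiny)),
    )


def combine_groups(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group Fisher combination of a (phenotype, group, p) table."""
    for col in ("group", "p"):
        if col not in table.columns:
            raise ValueError(f"input table must have a {col!r} column")
    rows = []
    for group, sub in table.groupby("group", sort=False):
        res = fisher_combine(sub["p"].to_numpy(), label=str(group))
        rows.append(
            {
                "group": res.label,
                "k": res.k,
                "chi2": res.chi2_stat,
                "df": res.df,
                "p_combined": res.p_combined,
            }
        )
    return pd.DataFrame(rows, columns=["group", "k", "chi2", "df", "p_combined"])
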
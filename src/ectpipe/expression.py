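"""Relative qPCR quantification (ΔΔCt) and group statistics.

Expression is normalized to the arithmetic mean Ct of the reference genes
(equivalent to their geometric mean in expression space), referenced to the
mean ΔCt of a calibrator group:

    ΔCt   = Ct_gene − mean(Ct_refs)
    ΔΔCt  = ΔCt − mean ΔCt(calibrator)
    RQ    = E^(−ΔΔCt)        (amplification efficiency E = 2 by default)

Group comparisons follow the study design: a two-tailed unpaired t-test for
two groups, one-way ANOVA with Šidák-adjusted pairwise comparisons
(p_adj = 1 − (1 − p)^m) for more.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtTable",
    "relative_quantify",
    "gene_ratio",
    "compare_groups",
    "sidak_adjust",
]


@dataclass
class CtTable:
    """Long-format Ct table with QC on duplicate spread.

    ``data`` columns: ``sample``, ``group``, ``gene``, ``replicate``,
    ``ct``.  Every sample must carry every reference gene; duplicate wells
    whose Ct spread exceeds ``qc_spread`` cycles are flagged (kept, but
    listed in ``flagged``).
    """

    data: pd.DataFrame
    ref_genes: tuple[str, ...]
    qc_spread: float = 0.5
    flagged: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        need = {"sample", "group", "gene", "replicate", "ct"}
        if not need.issubset(self.data.columns):
            raise ValueError(f"Ct table needs columns {sorted(need)}")
        for ref in self.ref_genes:
            per_sample = self.data[self.data.gene == ref].groupby("sample").size()
            missing = set(self.data["sample"]) - set(per_sample.index)
            if missing:
                raise ValueError(f"reference gene {ref} missing for samples {sorted(missing)}")
        spread = (
            self.data.groupby(["sample", "gene"])["ct"].agg(lambda v: v.max() - v.min())
        )
        bad = spread[spread > self.qc_spread]
        self.flagged = bad.reset_index().rename(columns={"ct": "ct_spread"})


def relative_quantify(
    table: CtTable, calibrator: str, efficiency: float = 2.0
) -> pd.DataFrame:
    """Per sample-gene RQ and log2 fold-change vs. the calibrator group.

    Duplicate wells are averaged; ΔCt subtracts the mean reference-gene Ct
    of the same sample; ΔΔCt subtracts the calibrator group's mean ΔCt for
    that gene; RQ = efficiency^(−ΔΔCt).  Returns a long table with columns
    ``sample, group, gene, ct, dct, ddct, rq, log2fc``.
    """
    df = table.data
    if calibrator not in set(df["group"]):
        raise ValueError(f"calibrator group {calibrator!r} not present")
    ct = df.groupby(["sample", "group", "gene"], as_index=False)["ct"].mean()
    ref = (
        ct[ct.gene.isin(table.ref_genes)]
        .groupby("sample")["ct"]
        .mean()
        .rename("ref_ct")
    )
    out = ct.merge(ref, on="sample")
    out["dct"] = out["ct"] - out["ref_ct"]
    cal = (
        out[out.group == calibrator]
        .groupby("gene")["dct"]
        .mean()
        .rename("cal_dct")
    )
    out = out.merge(cal, on="gene")
    out["ddct"] = out["dct"] - out["cal_dct"]
    out["rq"] = efficiency ** (-out["ddct"])
    out["log2fc"] = -out["ddct"] * np.log2(efficiency)
    return out.drop(columns=["ref_ct", "cal_dct"])


def gene_ratio(
    rq_table: pd.DataFrame, numerator: str, denominator: str
) -> pd.DataFrame:
    """Per-group mean ± SEM of the per-sample RQ ratio numerator/denominator."""
    piv = rq_table.pivot_table(index=["sample", "group"], columns="gene", values="rq")
    for g in (numerator, denominator):
        if g not in piv.columns or piv[g].isna().any():
            raise ValueError(f"gene {g!r} missing for some samples")
    ratio = (piv[numerator] / piv[denominator]).rename("ratio").reset_index()
    return (
        ratio.groupby("group")["ratio"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
             n="size")
        .reset_index()
    )


def sidak_adjust(p: float, m: int) -> float:
    """Šidák multiplicity adjustment: ``1 − (1 − p)^m``."""
    return float(1.0 - (1.0 - p) ** m)


def compare_groups(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> pd.DataFrame:
    """Two-group t-test or one-way ANOVA with Šidák-adjusted pairwise tests.

    For two groups: a two-tailed unpaired t-test (one row).  For more: the
    one-way ANOVA row first, then every pairwise comparison with both raw
    and Šidák-adjusted p (m = number of pairwise comparisons).  Columns:
    ``comparison, statistic, p, p_adj, significant``.
    """
    names = list(groups)
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs n >= 2")
    rows = []
    if len(names) == 2:
        a, b = arrays[names[0]], arrays[names[1]]
        t, p = stats.ttest_ind(a, b)
        rows.append({"comparison": f"{names[0]} vs {names[1]}", "test": "t-test",
                     "statistic": float(t), "p": float(p), "p_adj": float(p),
                     "significant": bool(p < alpha)})
    elif len(names) > 2:
        f, p = stats.f_oneway(*arrays.values())
        rows.append({"comparison": "ANOVA", "test": "one-way ANOVA",
                     "statistic": float(f), "p": float(p), "p_adj": float(p),
                     "significant": bool(p < alpha)})
        pairs = list(combinations(names, 2))
        m = len(pairs)
        for x, y in pairs:
            t, praw = stats.ttest_ind(arrays[x], arrays[y])
            padj = sidak_adjust(float(praw), m)
            rows.append({"comparison": f"{x} vs {y}", "test": "pairwise t (Sidak)",
                         "statistic": float(t), "p": float(praw), "p_adj": padj,
                         "significant": bool(padj < alpha)})
    else:
        raise ValueError("need at least two groups")
    return pd.DataFrame(rows)
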
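"""Compositional differential abundance by pairwise log-ratio testing (ANCOM).

For each taxon i, the log-ratio of its (pseudocounted) counts against every
other taxon j is tested between the two groups; W_i counts the rejected
tests after within-taxon multiple-testing correction.  A taxon is called
differentially abundant when W_i / (m - 1) exceeds the configured cutoff
(strictly).  The centred log-ratio (CLR) group-mean difference gives the
effect size and direction for volcano-style output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables import CountTable

__all__ = ["AncomConfig", "AncomResult", "clr_transform", "ancom", "volcano_table"]


@dataclass(frozen=True)
class AncomConfig:
    pseudocount: float = 1.0
    per_ratio_alpha: float = 0.05
    correction: str = "bh"  # "bh" (Benjamini-Hochberg), "by", or "none"
    w_ratio_cutoff: float = 0.7

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if not (0 < self.per_ratio_alpha < 1):
            raise ValueError("per_ratio_alpha must be in (0, 1)")
        if not (0 < self.w_ratio_cutoff <= 1):
            raise ValueError("w_ratio_cutoff must be in (0, 1]")
        if self.correction not in ("bh", "by", "none"):
            raise ValueError("correction must be 'bh', 'by' or 'none'")


@dataclass(frozen=True)
class AncomResult:
    table: pd.DataFrame  # index asv_id; W, w_ratio, clr_mean_diff, significant, direction
    m: int
    group_labels: tuple[str, str]

    @property
    def significant(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def clr_transform(table: CountTable, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centred log-ratio values per sample: log(count + c) minus the row mean.

    Rows sum to zero by construction.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    y = np.log(table.data.to_numpy(dtype=float) + pseudocount)
    clr = y - y.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=table.data.index, columns=table.data.columns)


def _adjust(pvals: np.ndarray, method: str) -> np.ndarray:
    if method == "none":
        return pvals
    return stats.false_discovery_control(pvals, method=method)


def ancom(
    table: CountTable,
    groups: Sequence[str] | pd.Series,
    cfg: AncomConfig = AncomConfig(),
    seed: int | None = None,
) -> AncomResult:
    """Two-group ANCOM with rank-sum per-ratio tests.

    ``groups`` gives one label per sample (exactly two distinct labels).
    The per-ratio test is the two-sided Wilcoxon rank-sum; its m - 1
    p-values per taxon are corrected with ``cfg.correction`` before counting
    rejections at ``cfg.per_ratio_alpha``.  ``seed`` is accepted for
    interface symmetry with the stochastic stages; the rank-sum procedure
    itself is deterministic.
    """
    del seed
    labels = pd.Series(list(groups), index=table.data.index)
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"exactly two group labels required, got {uniq}")
    m = table.shape[1]
    if m < 3:
        raise ValueError("at least 3 taxa are required")
    mask_a = (labels == uniq[0]).to_numpy()
    mask_b = (labels == uniq[1]).to_numpy()
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError("each group needs at least 3 samples")

    logx = np.log(table.data.to_numpy(dtype=float) + cfg.pseudocount)
    w = np.zeros(m, dtype=int)
    keep = ~np.eye(m, dtype=bool)
    for i in range(m):
        # log-ratios of taxon i against every other taxon, all samples at once
        ratios = (logx[:, i : i + 1] - logx)[:, keep[i]]
        with np.errstate(invalid="ignore"):
            p_i = stats.ranksums(ratios[mask_a], ratios[mask_b], axis=0).pvalue
        p_i = np.nan_to_num(p_i, nan=1.0)  # constant ratios carry no evidence
        w[i] = int((_adjust(p_i, cfg.correction) <= cfg.per_ratio_alpha).sum())
    w_ratio = w / (m - 1)

    clr = clr_transform(table, cfg.pseudocount).to_numpy()
    diff = clr[mask_a].mean(axis=0) - clr[mask_b].mean(axis=0)
    direction = np.where(diff >= 0, uniq[0], uniq[1])
    out = pd.DataFrame(
        {
            "W": w,
            "w_ratio": w_ratio,
            "clr_mean_diff": diff,
            "significant": w_ratio > cfg.w_ratio_cutoff,
            "direction": direction,
        },
        index=table.data.columns,
    )
    return AncomResult(out, m, (uniq[0], uniq[1]))


def volcano_table(result: AncomResult) -> pd.DataFrame:
    """Volcano-style listing: w_ratio desc, then |clr_mean_diff| desc, then id."""
    df = result.table.rename_axis("asv_id").copy()
    df["_abs"] = df["clr_mean_diff"].abs()
    df = df.sort_values(
        by=["w_ratio", "_abs", "asv_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).drop(columns="_abs")
    return df[["clr_mean_diff", "W", "w_ratio", "significant", "direction"]]
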
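"""Expression-level operations: FPKM, differential expression, presence sets.

Abundance is normalized as FPKM (fragments per kilobase of transcript per
million mapped fragments): FPKM_fs = count_fs * 1e9 / (length_f * total_s).
Differential expression between a high (H) and low (L) group uses a Welch
two-sample t-test on log2(FPKM + pseudocount) with the dual threshold
p < alpha and |log2 fold change| >= lfc_min (fold change from group means
with the same pseudocount); no multiple-testing correction is applied to DE
calls. The 2^-ddCt helper implements relative qPCR quantification.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ExpressionMatrix:
    """Features x samples abundance table with the sample design attached."""

    values: pd.DataFrame  # features x samples, non-negative
    design: pd.Series  # sample -> group
    unit: str = "count"  # {"count", "FPKM"}

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise ValueError(f"samples without a group assignment: {missing}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.design[s] == group]


def compute_fpkm(
    counts: ExpressionMatrix, lengths: Mapping[str, int]
) -> ExpressionMatrix:
    """FPKM_fs = count_fs * 1e9 / (length_f * total_s); totals per sample."""
    if counts.unit != "count":
        raise ValueError("compute_fpkm expects a count matrix")
    missing = [f for f in counts.values.index if f not in lengths]
    if missing:
        raise ValueError(f"features without a length: {missing[:5]}")
    length_vec = np.array([lengths[f] for f in counts.values.index], dtype=float)
    if (length_vec <= 0).any():
        bad = [f for f in counts.values.index if lengths[f] <= 0]
        raise ValueError(f"non-positive feature lengths: {bad[:5]}")
    totals = counts.values.sum(axis=0).to_numpy(float)
    zero = [s for s, t in zip(counts.values.columns, totals) if t == 0]
    if zero:
        raise ValueError(f"samples with zero total counts: {zero}")
    fpkm = counts.values.to_numpy(float) * 1e9 / (length_vec[:, None] * totals[None, :])
    return ExpressionMatrix(
        pd.DataFrame(fpkm, index=counts.values.index, columns=counts.values.columns),
        counts.design,
        unit="FPKM",
    )


def differential_expression(
    expr: ExpressionMatrix,
    contrast: tuple[str, str],
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-feature Welch-t DE calls for contrast (group_H, group_L).

    Returns a frame indexed by feature with columns log2fc (H over L, with
    pseudocount), p_value, direction ('up'/'down' relative to H), and
    significant (p < alpha AND |log2fc| >= lfc_min, the threshold inclusive).
    """
    group_h, group_l = contrast
    cols_h = expr.group_samples(group_h)
    cols_l = expr.group_samples(group_l)
    for name, cols in ((group_h, cols_h), (group_l, cols_l)):
        if len(cols) < 2:
            raise ValueError(f"group {name} has {len(cols)} samples; need >= 2")
    h = expr.values[cols_h].to_numpy(float)
    l = expr.values[cols_l].to_numpy(float)
    log2fc = np.log2((h.mean(axis=1) + pseudocount) / (l.mean(axis=1) + pseudocount))

    lh, ll = np.log2(h + pseudocount), np.log2(l + pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(lh, ll, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: p = 1 when the means agree, else 0
    degenerate = (lh.std(axis=1) == 0) & (ll.std(axis=1) == 0)
    equal_means = np.isclose(lh.mean(axis=1), ll.mean(axis=1))
    p = np.where(degenerate, np.where(equal_means, 1.0, 0.0), p)

    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p,
            "direction": np.where(log2fc >= 0, "up", "down"),
            "significant": (p < alpha) & (np.abs(log2fc) >= lfc_min),
        },
        index=expr.values.index.rename("feature_id"),
    )
    out.attrs["contrast"] = f"{group_h}:{group_l}"
    return out


def de_directions(de: pd.DataFrame) -> dict[str, str]:
    """Map of significant features to their DE direction (relative to H)."""
    sig = de[de["significant"]]
    return dict(zip(sig.index, sig["direction"]))


def group_presence_sets(
    expr: ExpressionMatrix, min_expr: float = 0.0
) -> tuple[dict[str, set[str]], dict[tuple[str, ...], int], set[str]]:
    """Presence sets per group (mean abundance > min_expr) and Venn regions.

    Returns (per-group sets, exclusive Venn region sizes keyed by the sorted
    group combination, the all-groups intersection).
    """
    groups = sorted(set(expr.design[s] for s in expr.values.columns))
    sets: dict[str, set[str]] = {}
    for g in groups:
        means = expr.values[expr.group_samples(g)].mean(axis=1)
        sets[g] = set(means.index[means > min_expr])
    venn: dict[tuple[str, ...], int] = {}
    for r in range(1, len(groups) + 1):
        for combo in itertools.combinations(groups, r):
            inside = set.intersection(*(sets[g] for g in combo))
            outside = set.union(set(), *(sets[g] for g in groups if g not in combo))
            venn[combo] = len(inside - outside)
    intersection = set.intersection(*sets.values()) if sets else set()
    return sets, venn, intersection


def delta_delta_ct(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_calib: float,
    ct_ref_calib: float,
) -> float:
    """Relative expression by the 2^-ddCt method."""
    ddct = (ct_target_test - ct_ref_test) - (ct_target_calib - ct_ref_calib)
    if not np.isfinite(ddct):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** -ddct)
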
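"""Hypergeometric over-representation analysis with Benjamini-Hochberg control.

For a query of n genes drawn from a background of N, a term annotating K
background genes and hitting k query genes is scored with the hypergeometric
upper tail P(X >= k), X ~ Hypergeometric(N, K, n). Raw p-values are adjusted
across all tested terms with the Benjamini-Hochberg step-up procedure
(configurable to Bonferroni); a term is significant when its adjusted p-value
is < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int  # hits in query
    K: int  # term size in background
    n: int  # query size
    N: int  # background size
    p_value: float
    p_adjusted: float
    significant: bool
    description: str = ""


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed in log space."""
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if K > N or n > N:
        raise ValueError(f"need K <= N and n <= N; got K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float], method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """GMT-style TSV: term id, description, then one gene per column."""
    terms: dict[str, tuple[str, list[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"bad GMT line: {line!r}")
        terms[fields[0]] = (fields[1], [g for g in fields[2:] if g])
    return terms


def enrich(
    query_genes: Iterable[str],
    background_genes: Iterable[str],
    term_map: Mapping[str, tuple[str, list[str]]],
    alpha: float = 0.05,
    method: str = "fdr_bh",
) -> list[EnrichmentResult]:
    """Over-representation of each term in the query against the background.

    Terms with no background gene are skipped; terms with zero query hits are
    reported with p = 1. Adjustment runs across all tested terms.
    """
    query = set(query_genes)
    background = set(background_genes)
    if not term_map:
        raise ValueError("term map is empty")
    offenders = sorted(query - background)
    if offenders:
        raise ValueError(f"query genes outside the background: {offenders[:10]}")
    N, n = len(background), len(query)
    rows = []
    for term_id in sorted(term_map):
        desc, genes = term_map[term_id]
        members = set(genes) & background
        if not members:
            continue
        k = len(members & query)
        p = 1.0 if k == 0 else hypergeom_upper_tail(k, len(members), n, N)
        rows.append((term_id, desc, k, len(members), p))
    adjusted = bh_adjust([r[4] for r in rows], method=method)
    return [
        EnrichmentResult(
            term_id=term_id,
            k=k,
            K=K,
            n=n,
            N=N,
            p_value=p,
            p_adjusted=float(p_adj),
            significant=bool(p_adj < alpha),
            description=desc,
        )
        for (term_id, desc, k, K, p), p_adj in zip(rows, adjusted)
    ]


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "description": r.description,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=[
            "term_id", "description", "k", "K", "n", "N",
            "p_value", "p_adjusted", "significant",
        ],
    )
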
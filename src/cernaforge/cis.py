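"""Neighboring gene pairs: cis windows, orientation classes, correlation nulls.

Candidate cis-regulatory pairs are coding:coding and lncRNA:coding gene pairs
whose gene-span gap is < 10 kb (strict) on the same chromosome. Orientation is
classified from the ordered pair: same strand -> tandem; opposite strands with
the left gene on '-' -> divergent (transcription pointing apart), otherwise
convergent; overlapping opposite-strand genes are ordered by their 5'-most
coordinates, so the rule is total and tie-free. Expression agreement of
neighbor pairs is contrasted against seeded random coding pairs with a
two-sided Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import TranscriptCatalog


@dataclass(frozen=True)
class GenePair:
    feature_a: str
    feature_b: str
    pair_class: str  # {coding-coding, lncRNA-coding, random}
    distance: int = 0  # nt between nearest span ends; 0 if overlapping
    chrom: str | None = None
    pearson_r: float | None = None


@dataclass(frozen=True)
class _GeneSpan:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    kind: str  # coding | lncRNA | other


def _gene_spans(
    catalog: TranscriptCatalog, lncrna_ids: Iterable[str]
) -> list[_GeneSpan]:
    lncrna_ids = set(lncrna_ids)
    spans = []
    for gene_id, transcripts in sorted(catalog.genes().items()):
        chrom, start, end, strand = catalog.gene_span(gene_id)
        if any(t.transcript_id in lncrna_ids for t in transcripts):
            kind = "lncRNA"
        elif any(t.declared_biotype == "protein_coding" for t in transcripts):
            kind = "coding"
        else:
            kind = "other"
        spans.append(_GeneSpan(gene_id, chrom, start, end, strand, kind))
    return spans


def _pair_class(kind_a: str, kind_b: str) -> str | None:
    kinds = {kind_a, kind_b}
    if kinds == {"coding"}:
        return "coding-coding"
    if kinds == {"lncRNA", "coding"}:
        return "lncRNA-coding"
    return None


def span_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap between two half-open spans; 0 if they overlap or touch."""
    return max(a_start, b_start) - min(a_end, b_end) if (
        max(a_start, b_start) > min(a_end, b_end)
    ) else 0


def find_neighbors(
    catalog: TranscriptCatalog,
    lncrna_ids: Iterable[str],
    max_dist: int = 10_000,
) -> list[GenePair]:
    """All lncRNA:coding and coding:coding gene pairs with span gap < max_dist."""
    spans = sorted(_gene_spans(catalog, lncrna_ids), key=lambda g: (g.chrom, g.start, g.end))
    pairs = []
    for i, a in enumerate(spans):
        for b in spans[i + 1 :]:
            if b.chrom != a.chrom or b.start - a.end >= max_dist:
                break
            klass = _pair_class(a.kind, b.kind)
            if klass is None:
                continue
            gap = span_gap(a.start, a.end, b.start, b.end)
            if gap < max_dist:
                x, y = sorted((a.gene_id, b.gene_id))
                pairs.append(GenePair(x, y, klass, gap, a.chrom))
    pairs.sort(key=lambda p: (p.chrom, p.feature_a, p.feature_b))
    return pairs


def classify_orientation(pair: GenePair, catalog: TranscriptCatalog) -> str:
    """Orientation of a non-random neighbor pair: divergent/convergent/tandem."""
    if pair.pair_class == "random":
        raise ValueError("orientation is defined only for non-random pairs")
    spans = {g: catalog.gene_span(g) for g in (pair.feature_a, pair.feature_b)}
    (left_id, right_id) = sorted(spans, key=lambda g: (spans[g][1], spans[g][2]))
    left_strand, right_strand = spans[left_id][3], spans[right_id][3]
    if left_strand == right_strand:
        return "tandem"
    return "divergent" if left_strand == "-" else "convergent"


def gene_level_expression(
    values: pd.DataFrame, catalog: TranscriptCatalog
) -> pd.DataFrame:
    """Aggregate a transcript-level matrix to gene level (sum of transcripts)."""
    gene_of = {t.transcript_id: t.gene_id for t in catalog}
    sub = values.loc[values.index.isin(gene_of)]
    return sub.groupby(sub.index.map(gene_of.get)).sum()


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> float:
    return float(stats.pearsonr(x, y).statistic)


def pair_correlations(
    pairs: Sequence[GenePair], values: pd.DataFrame
) -> tuple[list[GenePair], int]:
    """Attach Pearson r across all samples; zero-variance pairs are dropped.

    Returns (pairs with ``pearson_r`` set, number of dropped pairs).
    """
    if values.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation")
    out, dropped = [], 0
    for pair in pairs:
        for g in (pair.feature_a, pair.feature_b):
            if g not in values.index:
                raise ValueError(f"feature {g} missing from expression matrix")
        x = values.loc[pair.feature_a].to_numpy(float)
        y = values.loc[pair.feature_b].to_numpy(float)
        if x.std() == 0 or y.std() == 0:
            dropped += 1
            continue
        out.append(replace(pair, pearson_r=_pearson_rows(x, y)))
    return out, dropped


def random_pair_null(
    values: pd.DataFrame,
    coding_features: Sequence[str],
    n_pairs: int,
    seed: int | np.random.Generator = 0,
) -> tuple[list[GenePair], int]:
    """Seeded uniform random distinct coding:coding pairs with correlations."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coding_features = sorted(set(coding_features))
    n = len(coding_features)
    if n_pairs == 0:
        return [], 0
    if n < 2:
        raise ValueError("need >= 2 coding features")
    if n_pairs > n * (n - 1) // 2:
        raise ValueError("n_pairs exceeds the number of distinct pairs")
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < n_pairs:
        i, j = rng.choice(n, 2, replace=False)
        chosen.add((min(i, j), max(i, j)))
    pairs = [
        GenePair(coding_features[i], coding_features[j], "random")
        for i, j in sorted(chosen)
    ]
    return pair_correlations(pairs, values)


def compare_correlation_distributions(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float, float]:
    """(mean_a, mean_b, two-sided Mann-Whitney U p-value)."""
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both correlation groups need >= 2 values")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(a.mean()), float(b.mean()), float(res.pvalue)
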
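"""miRNA response element (MRE) prediction and trans-target inference.

Candidate sites are found by seed matching: the target must carry the reverse
complement of the miRNA 6mer core (positions 2-7), extended into the canonical
site classes — 8mer (core + complement of position 8 + target A opposite
position 1), 7mer-m8 (core + position 8), 7mer-A1 (core + target A). Only
Watson-Crick pairing is accepted in the seed. Candidates are then scored by an
ungapped complementarity alignment of the full miRNA against the target window
(+5 per Watson-Crick pair, +2 per G:U wobble outside the seed, -3 per
mismatch, floored at 0) with a pseudo-energy term -(2*GC + 1*AU + 0.5*GU) over
paired positions. Sites pass when align_score >= score_min and
energy <= energy_max. The weights are declared, configurable stand-ins that
preserve the structure of alignment-plus-energy target predictors.

Trans regulation is inferred purely from expression: all lncRNA x gene pairs
with |Pearson r| > 0.95 (strict) across the shared samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import TranscriptCatalog
from .seqtools import dna, is_gu_wobble, is_watson_crick, revcomp_dna, rna

SEED_START = 1  # 0-based: seed = mature positions 2-8
SEED_END = 8


@dataclass(frozen=True)
class MiRNARecord:
    """A mature miRNA; ``seed`` is nucleotides 2-8 of the mature sequence."""

    mirna_id: str
    mature_seq: str  # RNA alphabet, 5'->3'

    def __post_init__(self) -> None:
        seq = rna(self.mature_seq)
        object.__setattr__(self, "mature_seq", seq)
        if not (18 <= len(seq) <= 24):
            raise ValueError(f"{self.mirna_id}: mature length {len(seq)} outside 18-24")
        if any(c not in "ACGU" for c in seq):
            raise ValueError(f"{self.mirna_id}: mature sequence must be RNA (ACGU)")

    @property
    def seed(self) -> str:
        return self.mature_seq[SEED_START:SEED_END]

    @property
    def perfect_site(self) -> str:
        """Full-length perfect-duplex 8mer site (DNA): revcomp(positions 2..L) + A."""
        return revcomp_dna(self.mature_seq[SEED_START:]) + "A"


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    transcript_id: str
    start: int  # 0-based on the target transcript
    seed_class: str  # {8mer, 7mer-m8, 7mer-A1}
    align_score: float
    energy: float

    @property
    def m1_position(self) -> int:
        """Target index opposite miRNA position 1 (the A1 slot)."""
        return self.start + (7 if self.seed_class in ("8mer", "7mer-m8") else 6)


def find_seed_sites(mirna: MiRNARecord, target_seq: str) -> list[TargetSite]:
    """All classified seed sites of ``mirna`` on ``target_seq`` (unscored).

    Scans for reverse-complement matches to the 6mer core (positions 2-7) and
    classifies by the m8 complement and the A opposite position 1; matches
    qualifying as neither (bare 6mers) are not emitted. Scores/energies are
    filled by :func:`score_site`.
    """
    if not target_seq:
        raise ValueError("empty target sequence")
    target = dna(target_seq)
    mature = dna(mirna.mature_seq)
    core_match = revcomp_dna(mature[SEED_START : SEED_END - 1])  # pairs m7..m2
    m8_complement = revcomp_dna(mature[SEED_END - 1])
    sites = []
    pos = target.find(core_match)
    while pos != -1:
        has_m8 = pos >= 1 and target[pos - 1] == m8_complement
        has_a1 = pos + 6 < len(target) and target[pos + 6] == "A"
        if has_m8 and has_a1:
            sites.append(TargetSite(mirna.mirna_id, "", pos - 1, "8mer", 0.0, 0.0))
        elif has_m8:
            sites.append(TargetSite(mirna.mirna_id, "", pos - 1, "7mer-m8", 0.0, 0.0))
        elif has_a1:
            sites.append(TargetSite(mirna.mirna_id, "", pos, "7mer-A1", 0.0, 0.0))
        pos = target.find(core_match, pos + 1)
    return sites


def score_site(
    mirna: MiRNARecord, target_seq: str, site: TargetSite
) -> tuple[float, float]:
    """Ungapped complementarity score and pseudo-energy for one candidate site.

    miRNA position k (1-based) is paired against target index
    m1_position - (k - 1); positions falling off the target are skipped
    (window truncated at sequence ends). Within the seed (positions 2-8) only
    Watson-Crick pairs count; G:U there scores as a mismatch and contributes
    no energy.
    """
    target = dna(target_seq)
    mature = dna(mirna.mature_seq)
    anchor = site.m1_position
    score = 0.0
    energy = 0.0
    for k in range(1, len(mature) + 1):
        j = anchor - (k - 1)
        if not 0 <= j < len(target):
            continue
        m, t = mature[k - 1], target[j]
        in_seed = SEED_START + 1 <= k <= SEED_END  # 1-based positions 2..8
        if is_watson_crick(m, t):
            score += 5.0
            energy -= 2.0 if {m, t} == {"C", "G"} else 1.0
        elif is_gu_wobble(m, t) and not in_seed:
            score += 2.0
            energy -= 0.5
        else:
            score -= 3.0
    return max(score, 0.0), energy


def target_search_regions(
    catalog: TranscriptCatalog, lncrna_ids: Iterable[str]
) -> dict[str, tuple[int, str]]:
    """Map transcript id -> (offset, searchable sequence) for MRE scanning.

    lncRNAs are searched over their whole sequence; protein-coding transcripts
    over the annotated 3'UTR when present, else the whole transcript. Other
    transcripts are skipped.
    """
    lncrna_ids = set(lncrna_ids)
    regions: dict[str, tuple[int, str]] = {}
    for rec in catalog:
        if rec.transcript_id in lncrna_ids:
            regions[rec.transcript_id] = (0, rec.sequence)
        elif rec.declared_biotype == "protein_coding":
            if rec.utr3 is not None:
                s, e = rec.utr3
                regions[rec.transcript_id] = (s, rec.sequence[s:e])
            else:
                regions[rec.transcript_id] = (0, rec.sequence)
    return regions


def predict_targets(
    mirnas: Sequence[MiRNARecord],
    regions: Mapping[str, tuple[int, str]],
    score_min: float = 80.0,
    energy_max: float = -7.0,
) -> list[TargetSite]:
    """All scored sites passing both thresholds, in deterministic order.

    ``regions`` maps transcript id -> (offset, sequence to search); reported
    site starts are transcript coordinates (offset added back). See
    :func:`target_search_regions`.
    """
    out: list[TargetSite] = []
    for mirna in sorted(mirnas, key=lambda m: m.mirna_id):
        for tid in sorted(regions):
            offset, seq = regions[tid]
            if not seq:
                continue
            for cand in find_seed_sites(mirna, seq):
                score, energy = score_site(mirna, seq, cand)
                if score >= score_min and energy <= energy_max:
                    out.append(
                        TargetSite(
                            mirna.mirna_id,
                            tid,
                            cand.start + offset,
                            cand.seed_class,
                            score,
                            energy,
                        )
                    )
    out.sort(key=lambda s: (s.mirna_id, s.transcript_id, s.start))
    return out


def sites_to_frame(sites: Sequence[TargetSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": s.mirna_id,
                "transcript_id": s.transcript_id,
                "start": s.start,
                "seed_class": s.seed_class,
                "align_score": s.align_score,
                "energy": s.energy,
            }
            for s in sites
        ],
        columns=["mirna_id", "transcript_id", "start", "seed_class", "align_score", "energy"],
    )


def trans_targets(
    lncrna_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    r_min: float = 0.95,
) -> tuple[list[tuple[str, str, float]], int]:
    """Trans targets by expression alone: |Pearson r| > r_min (strict).

    Both frames are features x samples over the same sample set (>= 3
    samples). Zero-variance features are skipped; the second return value
    counts skipped pairs.
    """
    if list(lncrna_expr.columns) != list(gene_expr.columns):
        raise ValueError("lncRNA and gene expression must share the same samples")
    if lncrna_expr.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation")
    lv = lncrna_expr.to_numpy(float)
    gv = gene_expr.to_numpy(float)
    l_ok = lv.std(axis=1) > 0
    g_ok = gv.std(axis=1) > 0
    n_skipped = int((~l_ok).sum() * gene_expr.shape[0] + l_ok.sum() * (~g_ok).sum())
    lz = (lv[l_ok] - lv[l_ok].mean(axis=1, keepdims=True)) / lv[l_ok].std(axis=1, keepdims=True)
    gz = (gv[g_ok] - gv[g_ok].mean(axis=1, keepdims=True)) / gv[g_ok].std(axis=1, keepdims=True)
    r = lz @ gz.T / lv.shape[1]
    out = []
    l_ids = lncrna_expr.index[l_ok]
    g_ids = gene_expr.index[g_ok]
    for i, lid in enumerate(l_ids):
        for j, gid in enumerate(g_ids):
            if abs(r[i, j]) > r_min:
                out.append((lid, gid, float(r[i, j])))
    return out, n_skipped
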
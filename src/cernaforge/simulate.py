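"""Seeded synthetic-data generator with planted ceRNA ground truth.

Emulates the study design this pipeline targets: 16 ovary RNA-seq libraries in
four groups (LH, LL, FH, FL; 4 replicates each, luteal/follicular phase x
high/low fertility), a transcript catalog with protein-coding genes and
multi-exon lncRNAs on both strands, mature miRNAs of 20-24 nt (mode 22), and
negative-binomial counts. Ground truth is planted so every downstream stage is
checkable: true ceRNA triads get a full-length perfect-duplex 8mer MRE for the
shared miRNA written into the lncRNA and into the mRNA 3'UTR, differential
expression is planted as group-mean shifts with the miRNA sign opposite to its
partners, and divergent neighbor pairs share a latent expression factor.

Every accidental occurrence of a miRNA seed's reverse complement is scrubbed
from non-target transcripts, and lncRNA sequences are kept strictly noncoding
(no ORF >= 300 nt, hexamer score below 0), so planted signals are the only
signals and recovery can be scored exactly against the truth.

All randomness flows from ``SimulationConfig.seed`` through named
``numpy.random.Generator`` streams; identical configs give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import cis
from .catalog import (
    TranscriptCatalog,
    TranscriptRecord,
    longest_orf,
    hexamer_score,
    train_hexamer_table,
    write_gtf,
    write_transcript_fasta,
)
from .seqtools import revcomp_dna, rna
from .targets import MiRNARecord

CONTRASTS = ("LH:LL", "FH:FL")

_BASES = np.array(list("ACGT"))
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
# GC3 bias: codons ending in G/C are favoured, giving coding sequences a
# detectable in-frame hexamer signature against shuffled background.
_CODON_WEIGHTS = np.array([3.0 if c[2] in "GC" else 1.0 for c in _SENSE_CODONS])
_CODON_WEIGHTS /= _CODON_WEIGHTS.sum()

_ORF_MIN = 300  # generator-side guarantee matching the cascade's default
_HEXAMER_MARGIN = -0.05


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults encode a scaled-down version of the 16-sample two-phase design:
    4 groups x 4 replicates, moderate negative-binomial overdispersion, and
    planted effects of |log2FC| = 2 (comfortably past the |log2FC| >= 1 call
    threshold).
    """

    n_coding_genes: int = 150
    n_lncrnas: int = 60
    n_mirnas: int = 20
    n_true_triads: int = 10
    n_de_features_per_contrast: int = 25
    de_log2fc_effect: float = 2.0
    replicates_per_group: int = 4
    groups: tuple[str, ...] = ("LH", "LL", "FH", "FL")
    nb_dispersion: float = 0.1
    library_size_mean: int = 1_000_000
    seed: int = 0
    antisense_fraction: float = 0.26
    cis_pair_fraction: float = 0.35
    coexpression_sd: float = 0.6  # log2 sd of the shared factor of divergent pairs
    n_terms: int = 25
    term_size_range: tuple[int, int] = (5, 30)

    def validate(self) -> None:
        counts = {
            "n_coding_genes": self.n_coding_genes,
            "n_lncrnas": self.n_lncrnas,
            "n_mirnas": self.n_mirnas,
            "n_true_triads": self.n_true_triads,
            "n_de_features_per_contrast": self.n_de_features_per_contrast,
            "replicates_per_group": self.replicates_per_group,
            "library_size_mean": self.library_size_mean,
        }
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.n_true_triads > min(self.n_lncrnas, self.n_mirnas, self.n_coding_genes):
            raise ValueError(
                "n_true_triads must be <= min(n_lncrnas, n_mirnas, n_coding_genes)"
            )
        if self.n_true_triads and self.de_log2fc_effect < 1:
            raise ValueError("de_log2fc_effect must be >= 1 so planted effects are callable")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not 0 <= self.antisense_fraction <= 1:
            raise ValueError("antisense_fraction must be in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Named, independent generator stream derived from the one seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        )


@dataclass(frozen=True)
class TriadTruth:
    lncrna_id: str
    mirna_id: str
    mrna_id: str
    contrast: str  # "LH:LL" or "FH:FL"


@dataclass
class GroundTruth:
    """Planted truth: triads, signed DE effects, MRE positions, co-expressed pairs."""

    true_triads: list[TriadTruth] = field(default_factory=list)
    de_features: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_sites: list[tuple[str, str, int]] = field(default_factory=list)
    coexpressed_pairs: list[tuple[str, str]] = field(default_factory=list)

    def validate(self) -> None:
        site_index = {(m, t) for m, t, _ in self.planted_sites}
        for triad in self.true_triads:
            de = self.de_features.get(triad.contrast, {})
            for member in (triad.lncrna_id, triad.mirna_id, triad.mrna_id):
                if member not in de:
                    raise AssertionError(
                        f"triad member {member} missing from DE effects of {triad.contrast}"
                    )
            if not (
                np.sign(de[triad.mirna_id]) == -np.sign(de[triad.lncrna_id])
                and np.sign(de[triad.lncrna_id]) == np.sign(de[triad.mrna_id])
            ):
                raise AssertionError(f"triad {triad} violates the DE sign pattern")
            if (triad.mirna_id, triad.lncrna_id) not in site_index:
                raise AssertionError(f"no planted site on lncRNA of {triad}")
            if (triad.mirna_id, triad.mrna_id) not in site_index:
                raise AssertionError(f"no planted site on mRNA of {triad}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_triads": [dataclasses.asdict(t) for t in self.true_triads],
            "de_features": self.de_features,
            "planted_sites": [list(s) for s in self.planted_sites],
            "coexpressed_pairs": [list(p) for p in self.coexpressed_pairs],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            true_triads=[TriadTruth(**t) for t in payload["true_triads"]],
            de_features=payload["de_features"],
            planted_sites=[tuple(s) for s in payload["planted_sites"]],
            coexpressed_pairs=[tuple(p) for p in payload["coexpressed_pairs"]],
        )


# ---------------------------------------------------------------------------
# sequence construction helpers
# ---------------------------------------------------------------------------


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASE_BYTES[rng.integers(0, 4, n)].tobytes().decode()


def _coding_sequence(rng: np.random.Generator) -> tuple[str, tuple[int, int]]:
    """UTR5 + codon-biased CDS + UTR3; returns (sequence, cds interval)."""
    utr5 = int(rng.integers(30, 121))
    utr3 = int(rng.integers(250, 451))
    n_internal = int(rng.integers(158, 319))
    codons = rng.choice(len(_SENSE_CODONS), size=n_internal, p=_CODON_WEIGHTS)
    cds = "ATG" + "".join(_SENSE_CODONS[i] for i in codons)
    cds += ["TAA", "TAG", "TGA"][rng.integers(0, 3)]
    seq = _random_seq(rng, utr5) + cds + _random_seq(rng, utr3)
    return seq, (utr5, utr5 + len(cds))


def _noncoding_sequence(
    rng: np.random.Generator, length: int, table: dict[str, float]
) -> str:
    """Random sequence with no ORF >= 300 nt and hexamer score below margin."""
    for _ in range(500):
        seq = _random_seq(rng, length)
        if longest_orf(seq).length < _ORF_MIN and hexamer_score(seq, table) <= _HEXAMER_MARGIN:
            return seq
    raise RuntimeError("could not sample a noncoding sequence")  # pragma: no cover


def _split_exons(length: int, n_exons: int, rng: np.random.Generator) -> list[int]:
    """Partition a transcript length into exon lengths (each >= 40 nt)."""
    n_exons = min(n_exons, max(1, length // 80))
    if n_exons == 1:
        return [length]
    base = length // n_exons
    cuts = sorted(
        int(i * base + rng.integers(-base // 4, base // 4 + 1))
        for i in range(1, n_exons)
    )
    bounds = [0] + cuts + [length]
    return [b - a for a, b in zip(bounds, bounds[1:])]


@dataclass
class _GenePrototype:
    gene_id: str
    transcript_id: str
    biotype: str
    sequence: str
    exon_lengths: list[int]
    intron_lengths: list[int]
    cds: tuple[int, int] | None = None
    hosted: "_GenePrototype | None" = None  # antisense lncRNA inside intron 0
    strand: str | None = None

    @property
    def genomic_span(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)


def _place(proto: _GenePrototype, chrom: str, start: int, catalog: TranscriptCatalog) -> None:
    exons = []
    pos = start
    for i, el in enumerate(proto.exon_lengths):
        exons.append((pos, pos + el))
        pos += el
        if i < len(proto.intron_lengths):
            pos += proto.intron_lengths[i]
    catalog.add(
        TranscriptRecord(
            transcript_id=proto.transcript_id,
            gene_id=proto.gene_id,
            chrom=chrom,
            strand=proto.strand,
            exons=exons,
            sequence=proto.sequence,
            declared_biotype=proto.biotype,
            cds=proto.cds,
        )
    )
    if proto.hosted is not None:
        # antisense lncRNA inside the host's first intron, opposite strand
        proto.hosted.strand = "-" if proto.strand == "+" else "+"
        _place(proto.hosted, chrom, exons[0][1] + 150, catalog)


# ---------------------------------------------------------------------------
# [OP] generate_annotation
# ---------------------------------------------------------------------------


def _generate_catalog(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> TranscriptCatalog:
    config.validate()
    rng = rng or config.rng(0)
    catalog = TranscriptCatalog()
    if config.n_coding_genes == 0 and config.n_lncrnas == 0:
        return catalog

    coding: list[_GenePrototype] = []
    for i in range(config.n_coding_genes):
        seq, cds = _coding_sequence(rng)
        n_ex = int(rng.integers(2, 8))
        exon_lengths = _split_exons(len(seq), n_ex, rng)
        intron_lengths = [int(rng.integers(200, 1501)) for _ in exon_lengths[:-1]]
        coding.append(
            _GenePrototype(
                gene_id=f"CG{i + 1:04d}",
                transcript_id=f"CT{i + 1:04d}",
                biotype="protein_coding",
                sequence=seq,
                exon_lengths=exon_lengths,
                intron_lengths=intron_lengths,
                cds=cds,
            )
        )

    table = train_hexamer_table([p.sequence for p in coding]) if coding else {}

    n_antisense = round(config.antisense_fraction * config.n_lncrnas)
    if n_antisense > config.n_coding_genes:
        raise ValueError("not enough coding genes to host the antisense lncRNAs")
    lncrnas: list[_GenePrototype] = []
    for i in range(config.n_lncrnas):
        length = int(rng.integers(400, 2001))
        seq = _noncoding_sequence(rng, length, table)
        n_ex = int(rng.integers(2, 5))
        exon_lengths = _split_exons(length, n_ex, rng)
        if len(exon_lengths) < 2:  # pragma: no cover - lengths >= 400 guarantee 2+
            exon_lengths = [length // 2, length - length // 2]
        intron_lengths = [int(rng.integers(150, 601)) for _ in exon_lengths[:-1]]
        lncrnas.append(
            _GenePrototype(
                gene_id=f"LG{i + 1:04d}",
                transcript_id=f"LT{i + 1:04d}",
                biotype="lncRNA",
                sequence=seq,
                exon_lengths=exon_lengths,
                intron_lengths=intron_lengths,
            )
        )

    # host the first n_antisense lncRNAs inside coding-gene introns
    host_ids = rng.choice(len(coding), size=n_antisense, replace=False) if n_antisense else []
    for lnc, host_idx in zip(lncrnas[:n_antisense], host_ids):
        host = coding[host_idx]
        host.intron_lengths[0] = lnc.genomic_span + 300
        host.hosted = lnc

    units: list[_GenePrototype] = coding + lncrnas[n_antisense:]
    order = rng.permutation(len(units))
    units = [units[i] for i in order]

    half = (len(units) + 1) // 2
    for chrom, chrom_units in (("chr1", units[:half]), ("chr2", units[half:])):
        cursor = 1000
        prev: _GenePrototype | None = None
        prev_paired = False
        for proto in chrom_units:
            pair_here = (
                prev is not None
                and not prev_paired
                and rng.random() < config.cis_pair_fraction
            )
            if pair_here:
                gap = int(rng.integers(500, 9000))
                prev.strand = "-"  # left member transcribes leftward -> divergent
                proto.strand = "+"
            else:
                gap = int(rng.integers(11000, 30001))
                proto.strand = "+" if rng.random() < 0.5 else "-"
            start = cursor + gap if prev is not None else cursor
            _place(proto, chrom, start, catalog)
            cursor = start + proto.genomic_span
            prev, prev_paired = proto, pair_here
    return catalog


def build_genome(
    catalog: TranscriptCatalog, config: SimulationConfig
) -> dict[str, str]:
    """Chromosome sequences: seeded random background with exon patches.

    Exons of distinct transcripts never share genomic bases (antisense lncRNAs
    live inside host introns), so patching is conflict-free and the genome is
    consistent with every spliced transcript sequence.
    """
    rng = config.rng(9)
    chrom_len = {}
    for rec in catalog:
        chrom_len[rec.chrom] = max(chrom_len.get(rec.chrom, 0), rec.span[1] + 1000)
    genome = {}
    for chrom in sorted(chrom_len):
        genome[chrom] = _BASE_BYTES[rng.integers(0, 4, chrom_len[chrom])].copy()
    for rec in sorted(catalog, key=lambda r: r.transcript_id):
        concat = rec.sequence if rec.strand == "+" else revcomp_dna(rec.sequence)
        offset = 0
        for s, e in rec.exons:
            genome[rec.chrom][s:e] = np.frombuffer(
                concat[offset : offset + e - s].encode(), dtype=np.uint8
            )
            offset += e - s
    return {c: v.tobytes().decode() for c, v in genome.items()}


def generate_annotation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[TranscriptCatalog, dict[str, str]]:
    """Transcript catalog plus consistent genome sequences (pre-planting)."""
    catalog = _generate_catalog(config, rng)
    return catalog, build_genome(catalog, config)


# ---------------------------------------------------------------------------
# [OP] generate_mirnas
# ---------------------------------------------------------------------------


def generate_mirnas(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[MiRNARecord]:
    """Mature miRNAs of 20-24 nt (mode 22), 5' U, mutually distinct seeds.

    Seeds are unique across the set and no miRNA's seed reverse-complement
    occurs inside another miRNA's perfect-duplex site (or more than once in
    its own), so planted sites can be attributed unambiguously.
    """
    rng = rng or config.rng(1)
    lengths = [20, 21, 22, 23, 24]
    probs = [0.1, 0.2, 0.4, 0.2, 0.1]
    out: list[MiRNARecord] = []
    seeds: set[str] = set()
    attempts = 0
    while len(out) < config.n_mirnas:
        attempts += 1
        if attempts > 100 * max(config.n_mirnas, 1):  # pragma: no cover
            raise RuntimeError("could not sample compatible miRNA set")
        length = int(rng.choice(lengths, p=probs))
        mature = "U" + rna(_random_seq(rng, length - 1))
        cand = MiRNARecord(f"sim-miR-{len(out) + 1:03d}", mature)
        if cand.seed in seeds:
            continue
        patt = revcomp_dna(cand.seed)
        if cand.perfect_site.count(patt) != 1:
            continue
        if any(
            patt in m.perfect_site or revcomp_dna(m.seed) in cand.perfect_site
            for m in out
        ):
            continue
        out.append(cand)
        seeds.add(cand.seed)
    return out


# ---------------------------------------------------------------------------
# [OP] plant_triads_and_sites
# ---------------------------------------------------------------------------


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, pos = [], haystack.find(needle)
    while pos != -1:
        hits.append(pos)
        pos = haystack.find(needle, pos + 1)
    return hits


class _Sanitizer:
    """Removes stray seed matches and keeps lncRNAs noncoding after planting.

    Mutations never touch planted windows; coding-sequence mutations avoid
    creating in-frame stops inside the CDS.
    """

    def __init__(
        self,
        catalog: TranscriptCatalog,
        patterns: dict[str, str],  # mirna_id -> DNA revcomp of its seed
        protected: dict[str, list[tuple[int, int, str]]],  # tid -> (s, e, mirna)
        table: dict[str, float],
        rng: np.random.Generator,
    ) -> None:
        self.catalog = catalog
        self.patterns = patterns
        self.protected = protected
        self.table = table
        self.rng = rng

    def _is_protected(self, tid: str, pos: int) -> bool:
        return any(s <= pos < e for s, e, _ in self.protected.get(tid, []))

    def _creates_pattern(self, old_seq: str, new_seq: str, lo: int, hi: int) -> bool:
        a, b = max(0, lo - 7), hi + 7
        old_win, new_win = old_seq[a:b], new_seq[a:b]
        return any(
            new_win.count(p) > old_win.count(p) for p in self.patterns.values()
        )

    def _try_write(self, rec: TranscriptRecord, pos: int, base: str) -> bool:
        if self._is_protected(rec.transcript_id, pos) or rec.sequence[pos] == base:
            return False
        if rec.cds and rec.cds[0] <= pos < rec.cds[1]:
            codon_start = rec.cds[0] + ((pos - rec.cds[0]) // 3) * 3
            codon = list(rec.sequence[codon_start : codon_start + 3])
            codon[pos - codon_start] = base
            if "".join(codon) in ("TAA", "TAG", "TGA"):
                return False
        new_seq = rec.sequence[:pos] + base + rec.sequence[pos + 1 :]
        if self._creates_pattern(rec.sequence, new_seq, pos, pos + 1):
            return False
        rec.sequence = new_seq
        return True

    def scrub_stray_seeds(self) -> bool:
        """Mutate away seed matches outside planted windows; True if changed."""
        changed = False
        for rec in self.catalog:
            tid = rec.transcript_id
            for mirna_id, patt in self.patterns.items():
                for hit in _find_all(rec.sequence, patt):
                    if any(
                        s <= hit and hit + len(patt) <= e and m == mirna_id
                        for s, e, m in self.protected.get(tid, [])
                    ):
                        continue
                    fixed = False
                    for off in self.rng.permutation(len(patt)):
                        pos = hit + int(off)
                        for base in self.rng.permutation(list("ACGT")):
                            if self._try_write(rec, pos, str(base)):
                                fixed = changed = True
                                break
                        if fixed:
                            break
                    if not fixed:  # pragma: no cover - ample free positions
                        raise RuntimeError(f"cannot scrub seed of {mirna_id} in {tid}")
        return changed

    def enforce_noncoding(self, lncrna_ids: Iterable[str]) -> bool:
        """Break long ORFs / positive hexamer scores in lncRNAs; True if changed."""
        changed = False
        for tid in lncrna_ids:
            rec = self.catalog[tid]
            for _ in range(100):
                orf = longest_orf(rec.sequence)
                if orf.length >= _ORF_MIN:
                    if self._break_orf(rec, orf.start, orf.length):
                        changed = True
                        continue
                    raise RuntimeError(f"cannot break ORF in {tid}")  # pragma: no cover
                if hexamer_score(rec.sequence, self.table) > 0:
                    if self._dampen_hexamers(rec):
                        changed = True
                        continue
                    raise RuntimeError(f"cannot lower hexamer score of {tid}")  # pragma: no cover
                break
        return changed

    def _break_orf(self, rec: TranscriptRecord, start: int, length: int) -> bool:
        # kill the start codon (ATG -> AAG) when possible
        if self._try_write(rec, start + 1, "A"):
            return True
        # otherwise write an early in-frame stop codon inside the ORF
        n_codons = max(length // 3 - 2, 1)
        for k in self.rng.permutation(n_codons):
            c = start + 3 * (int(k) + 1)
            if c + 3 > len(rec.sequence):
                continue
            for stop in ("TAA", "TAG", "TGA"):
                wrote_all = True
                for off in range(3):
                    if rec.sequence[c + off] == stop[off]:
                        continue
                    if not self._try_write(rec, c + off, stop[off]):
                        wrote_all = False
                        break
                if wrote_all:
                    return True
        return False

    def _dampen_hexamers(self, rec: TranscriptRecord) -> bool:
        free = [
            i
            for i in range(len(rec.sequence))
            if not self._is_protected(rec.transcript_id, i)
        ]
        if not free:
            return False
        best = hexamer_score(rec.sequence, self.table)
        for _ in range(500):
            pos = int(self.rng.choice(free))
            base = str(self.rng.choice(list("ACGT")))
            old = rec.sequence
            if not self._try_write(rec, pos, base):
                continue
            score = hexamer_score(rec.sequence, self.table)
            if score <= 0:
                return True
            if score < best:
                best = score  # keep the improving mutation
            else:
                rec.sequence = old
        return False


def plant_triads_and_sites(
    catalog: TranscriptCatalog,
    mirnas: Sequence[MiRNARecord],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Plant MREs and DE effects; mutates catalog sequences in place.

    For each true triad a full-length perfect-duplex 8mer site for the shared
    miRNA is written into the lncRNA and into the mRNA 3'UTR; each triad uses
    a distinct miRNA, lncRNA and mRNA. Triad members receive signed log2
    effects for their contrast with the miRNA opposite to its partners, plus
    additional non-triad DE features up to ``n_de_features_per_contrast`` per
    contrast. When sites are planted, stray seed matches are scrubbed and
    lncRNAs are re-sanitized so generator truth is exact; with
    ``n_true_triads == 0`` sequences are left untouched.
    """
    config.validate()
    rng = rng or config.rng(2)
    truth = GroundTruth(de_features={c: {} for c in CONTRASTS})

    lnc_ids = sorted(
        t.transcript_id for t in catalog if t.declared_biotype == "lncRNA"
    )
    mrna_ids = sorted(catalog.coding_ids())
    truth.coexpressed_pairs = _divergent_close_pairs(catalog, lnc_ids)

    # keep the planted mechanisms orthogonal: genes carrying the shared
    # co-expression factor are not used for DE / triad planting, so each
    # planted signal is recoverable without interference from the other
    coexpr_genes = {g for pair in truth.coexpressed_pairs for g in pair}
    coexpr_tids = {
        t.transcript_id for t in catalog if t.gene_id in coexpr_genes
    }
    lnc_pool = [t for t in lnc_ids if t not in coexpr_tids]
    mrna_pool = [t for t in mrna_ids if t not in coexpr_tids]

    if config.n_true_triads > 0:
        if not len(catalog) or not mirnas:
            raise ValueError("catalog and miRNA set must be nonempty to plant triads")
        max_site = max(len(m.perfect_site) for m in mirnas)
        elig_lnc = [t for t in lnc_pool if catalog[t].length >= max_site + 20]
        elig_mrna = [
            t
            for t in mrna_pool
            if catalog[t].utr3 and catalog[t].utr3[1] - catalog[t].utr3[0] >= max_site + 10
        ]
        if (
            config.n_true_triads > len(elig_lnc)
            or config.n_true_triads > len(elig_mrna)
            or config.n_true_triads > len(mirnas)
        ):
            raise ValueError(
                f"cannot plant {config.n_true_triads} triads: "
                f"{len(elig_lnc)} eligible lncRNAs, {len(elig_mrna)} eligible mRNAs, "
                f"{len(mirnas)} miRNAs"
            )
        pick_lnc = [elig_lnc[i] for i in rng.choice(len(elig_lnc), config.n_true_triads, replace=False)]
        pick_mrna = [elig_mrna[i] for i in rng.choice(len(elig_mrna), config.n_true_triads, replace=False)]
        pick_mir = [mirnas[i] for i in rng.choice(len(mirnas), config.n_true_triads, replace=False)]

        protected: dict[str, list[tuple[int, int, str]]] = {}
        for i, (lnc, mrna, mir) in enumerate(zip(pick_lnc, pick_mrna, pick_mir)):
            contrast = CONTRASTS[i % len(CONTRASTS)]
            site = mir.perfect_site
            for tid, lo, hi in (
                (lnc, 5, catalog[lnc].length - len(site) - 5),
                (mrna, catalog[mrna].utr3[0] + 3, catalog[mrna].length - len(site) - 3),
            ):
                rec = catalog[tid]
                pos = int(rng.integers(lo, hi + 1))
                rec.sequence = rec.sequence[:pos] + site + rec.sequence[pos + len(site) :]
                protected.setdefault(tid, []).append((pos, pos + len(site), mir.mirna_id))
                truth.planted_sites.append((mir.mirna_id, tid, pos + len(site) - 8))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            truth.true_triads.append(TriadTruth(lnc, mir.mirna_id, mrna, contrast))
            truth.de_features[contrast][lnc] = sign * config.de_log2fc_effect
            truth.de_features[contrast][mrna] = sign * config.de_log2fc_effect
            truth.de_features[contrast][mir.mirna_id] = -sign * config.de_log2fc_effect

        coding_seqs = [catalog[t].sequence for t in mrna_ids]
        table = train_hexamer_table(coding_seqs) if coding_seqs else {}
        sanitizer = _Sanitizer(
            catalog,
            {m.mirna_id: revcomp_dna(m.seed) for m in mirnas},
            protected,
            table,
            rng,
        )
        for _ in range(30):
            changed = sanitizer.scrub_stray_seeds()
            changed |= sanitizer.enforce_noncoding(lnc_ids)
            if not changed:
                break
        else:  # pragma: no cover
            raise RuntimeError("sequence sanitation did not converge")

    # additional (non-triad) DE features, random signs
    all_features = sorted(catalog.ids()) + sorted(m.mirna_id for m in mirnas)
    for contrast in CONTRASTS:
        de = truth.de_features[contrast]
        pool = [f for f in all_features if f not in de and f not in coexpr_tids]
        n_extra = max(config.n_de_features_per_contrast - len(de), 0)
        n_extra = min(n_extra, len(pool))
        for idx in rng.choice(len(pool), n_extra, replace=False) if n_extra else []:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            de[pool[int(idx)]] = sign * config.de_log2fc_effect

    truth.validate()
    return truth


def _divergent_close_pairs(
    catalog: TranscriptCatalog, lncrna_ids: list[str]
) -> list[tuple[str, str]]:
    """Divergent neighbor gene pairs (< 10 kb): the planted co-expressed set."""
    if not len(catalog):
        return []
    pairs = cis.find_neighbors(catalog, lncrna_ids)
    out = []
    for p in pairs:
        if cis.classify_orientation(p, catalog) == "divergent":
            out.append(tuple(sorted((p.feature_a, p.feature_b))))
    return sorted(set(out))


# ---------------------------------------------------------------------------
# [OP] simulate_counts
# ---------------------------------------------------------------------------


def negative_binomial_counts(
    mean: float | np.ndarray, dispersion: float, rng: np.random.Generator, size=None
) -> np.ndarray:
    """NB draws with var = mean + dispersion * mean^2."""
    if dispersion <= 0:
        raise ValueError("nb_dispersion must be > 0")
    shape = 1.0 / dispersion
    mean = np.asarray(mean, dtype=float)
    p = shape / (shape + mean)
    return rng.negative_binomial(shape, p, size=size if size is not None else mean.shape)


def simulate_counts(
    catalog: TranscriptCatalog,
    mirnas: Sequence[MiRNARecord],
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """NB count matrix (features x samples) and the sample design table.

    Baseline means are log-normal shares of the target library size; DE
    features are shifted by 2^effect in the H group of their contrast; members
    of planted co-expressed pairs share a per-sample log-normal factor.
    """
    config.validate()
    if not len(catalog) and not mirnas:
        raise ValueError("catalog is empty")
    rng = rng or config.rng(3)

    feature_ids = sorted(catalog.ids()) + sorted(m.mirna_id for m in mirnas)
    samples = [
        f"{g}_{i + 1}" for g in config.groups for i in range(config.replicates_per_group)
    ]
    design = pd.Series(
        {s: s.rsplit("_", 1)[0] for s in samples}, name="group", dtype=object
    )
    F, S = len(feature_ids), len(samples)

    weights = np.exp(rng.normal(0.0, 1.0, F))
    mu = config.library_size_mean * weights / weights.sum()
    M = np.tile(mu[:, None], (1, S))

    fidx = {f: i for i, f in enumerate(feature_ids)}
    for contrast, effects in truth.de_features.items():
        high = contrast.split(":")[0]
        cols = [j for j, s in enumerate(samples) if design[s] == high]
        for feat, eff in effects.items():
            if feat in fidx:
                M[fidx[feat], cols] *= 2.0 ** eff

    gene_to_feats: dict[str, list[int]] = {}
    for rec in catalog:
        gene_to_feats.setdefault(rec.gene_id, []).append(fidx[rec.transcript_id])
    for a, b in truth.coexpressed_pairs:
        z = rng.normal(0.0, config.coexpression_sd, S)
        for gene in (a, b):
            for i in gene_to_feats.get(gene, []):
                M[i, :] *= 2.0 ** z

    lib_factor = np.exp(rng.normal(0.0, 0.1, S))
    M *= lib_factor[None, :]

    counts = negative_binomial_counts(M, config.nb_dispersion, rng)
    frame = pd.DataFrame(counts, index=pd.Index(feature_ids, name="feature_id"), columns=samples)
    return frame, design


# ---------------------------------------------------------------------------
# whole datasets
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    catalog: TranscriptCatalog
    genome: dict[str, str]
    mirnas: list[MiRNARecord]
    truth: GroundTruth
    counts: pd.DataFrame
    design: pd.Series
    terms: dict[str, tuple[str, list[str]]]  # term -> (description, gene list)

    @property
    def lncrna_ids(self) -> set[str]:
        return {
            t.transcript_id for t in self.catalog if t.declared_biotype == "lncRNA"
        }

    def feature_lengths(self) -> dict[str, int]:
        lengths = self.catalog.lengths()
        lengths.update({m.mirna_id: len(m.mature_seq) for m in self.mirnas})
        return lengths


def _generate_terms(
    config: SimulationConfig, coding_ids: list[str], rng: np.random.Generator
) -> dict[str, tuple[str, list[str]]]:
    terms = {}
    lo, hi = config.term_size_range
    for i in range(config.n_terms):
        if not coding_ids:
            break
        size = int(rng.integers(lo, min(hi, len(coding_ids)) + 1))
        members = sorted(
            coding_ids[j] for j in rng.choice(len(coding_ids), size, replace=False)
        )
        terms[f"TERM:{i + 1:04d}"] = (f"synthetic term {i + 1}", members)
    return terms


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run the full generator: annotation, miRNAs, planting, counts, terms."""
    catalog = _generate_catalog(config)
    mirnas = generate_mirnas(config)
    truth = plant_triads_and_sites(catalog, mirnas, config)
    counts, design = simulate_counts(catalog, mirnas, truth, config)
    terms = _generate_terms(config, sorted(catalog.coding_ids()), config.rng(4))
    genome = build_genome(catalog, config)
    return SyntheticDataset(config, catalog, genome, mirnas, truth, counts, design, terms)


def write_mirna_fasta(mirnas: Sequence[MiRNARecord], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(m.mature_seq), id=m.mirna_id, description="") for m in mirnas],
        str(path),
        "fasta",
    )


def load_mirna_fasta(path: str | Path) -> list[MiRNARecord]:
    return [
        MiRNARecord(r.id, rna(str(r.seq))) for r in SeqIO.parse(str(path), "fasta")
    ]


def write_terms_tsv(
    terms: dict[str, tuple[str, list[str]]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for term in sorted(terms):
            desc, genes = terms[term]
            fh.write("\t".join([term, desc] + list(genes)) + "\n")


def write_dataset(
    dataset: SyntheticDataset, out_dir: str | Path, write_genome: bool = False
) -> dict[str, Path]:
    """Write all generator outputs; returns a name -> path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gtf": out / "annotation.gtf",
        "transcripts": out / "transcripts.fa",
        "mirnas": out / "mirnas.fa",
        "counts": out / "counts.tsv",
        "design": out / "design.tsv",
        "lengths": out / "lengths.tsv",
        "truth": out / "truth.json",
        "terms": out / "terms.tsv",
    }
    write_gtf(dataset.catalog, paths["gtf"])
    write_transcript_fasta(dataset.catalog, paths["transcripts"])
    write_mirna_fasta(dataset.mirnas, paths["mirnas"])
    dataset.counts.to_csv(paths["counts"], sep="\t")
    dataset.design.rename_axis("sample").to_frame().to_csv(paths["design"], sep="\t")
    lengths = dataset.feature_lengths()
    pd.Series(lengths, name="length").rename_axis("feature_id").sort_index().to_frame().to_csv(
        paths["lengths"], sep="\t"
    )
    dataset.truth.to_json(paths["truth"])
    write_terms_tsv(dataset.terms, paths["terms"])
    if write_genome:
        paths["genome"] = out / "genome.fa"
        SeqIO.write(
            [SeqRecord(Seq(s), id=c, description="") for c, s in sorted(dataset.genome.items())],
            str(paths["genome"]),
            "fasta",
        )
    return paths
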
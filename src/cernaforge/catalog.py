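"""Transcript catalog: annotation I/O, the lncRNA filter cascade, and genomic features.

Long noncoding RNAs are called from an assembled transcript catalog with a
four-criterion cascade: length > 200 nt, more than one exon, no excluded
declared biotype (protein-coding, miRNA, tRNA, snoRNA, rRNA, pseudogene), and a
unanimous "noncoding" verdict from the internal coding-potential scorers
(ORF-based and hexamer-based). Surviving transcripts are classified as
antisense (an exonic base overlaps a protein-coding transcript on the opposite
strand) or intergenic.

Coordinates are 0-based half-open internally and 1-based inclusive at the GTF
boundary.
"""

from __future__ import annotations

import collections
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqtools import dna, revcomp_dna

#: declared biotypes that can never be lncRNAs
EXCLUDED_BIOTYPES = frozenset(
    {"protein_coding", "miRNA", "tRNA", "snoRNA", "rRNA", "pseudogene"}
)

STOP_CODONS = ("TAA", "TAG", "TGA")

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TranscriptRecord:
    """One transcript: exon structure, strand, spliced sequence, biotype.

    ``exons`` are 0-based half-open genomic intervals, sorted and
    non-overlapping. ``sequence`` is the spliced, stranded (5'->3') sequence,
    so its length equals the summed exon lengths. ``cds`` is the
    transcript-relative half-open CDS interval for coding transcripts, used to
    delimit the 3'UTR for MRE searches.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    sequence: str
    declared_biotype: str | None = None
    cds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if any(s >= e for s, e in self.exons):
            raise ValueError(f"{self.transcript_id}: empty exon interval")
        if sum(e - s for s, e in self.exons) != len(self.sequence):
            raise ValueError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} != "
                f"summed exon length {sum(e - s for s, e in self.exons)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def utr3(self) -> tuple[int, int] | None:
        """Transcript-relative 3'UTR interval (after the CDS), if annotated."""
        if self.cds is None:
            return None
        return self.cds[1], self.length

    # -- coordinate mapping -------------------------------------------------

    def transcript_to_genomic(self, t_start: int, t_end: int) -> list[tuple[int, int]]:
        """Map a transcript-relative half-open interval onto genomic intervals."""
        if not (0 <= t_start <= t_end <= self.length):
            raise ValueError("interval outside transcript")
        if self.strand == "-":
            t_start, t_end = self.length - t_end, self.length - t_start
        out = []
        offset = 0
        for s, e in self.exons:
            lo = max(t_start, offset)
            hi = min(t_end, offset + (e - s))
            if lo < hi:
                out.append((s + lo - offset, s + hi - offset))
            offset += e - s
        return out

    def genomic_to_transcript(self, gpos: int) -> int:
        """Map a genomic position inside an exon to a transcript index."""
        offset = 0
        for s, e in self.exons:
            if s <= gpos < e:
                plus_idx = offset + gpos - s
                return plus_idx if self.strand == "+" else self.length - 1 - plus_idx
            offset += e - s
        raise ValueError(f"{gpos} not exonic in {self.transcript_id}")


class TranscriptCatalog:
    """Container for TranscriptRecords with gene-level helpers."""

    def __init__(self, records: Iterable[TranscriptRecord] = ()) -> None:
        self.records: dict[str, TranscriptRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: TranscriptRecord) -> None:
        if rec.transcript_id in self.records:
            raise ValueError(f"duplicate transcript id {rec.transcript_id}")
        self.records[rec.transcript_id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def __getitem__(self, tid: str) -> TranscriptRecord:
        return self.records[tid]

    def __contains__(self, tid: str) -> bool:
        return tid in self.records

    def ids(self) -> list[str]:
        return list(self.records)

    def coding_ids(self) -> list[str]:
        return [
            t.transcript_id for t in self if t.declared_biotype == "protein_coding"
        ]

    def lengths(self) -> dict[str, int]:
        return {t.transcript_id: t.length for t in self}

    def genes(self) -> dict[str, list[TranscriptRecord]]:
        by_gene: dict[str, list[TranscriptRecord]] = collections.defaultdict(list)
        for t in self:
            by_gene[t.gene_id].append(t)
        return dict(by_gene)

    def gene_span(self, gene_id: str) -> tuple[str, int, int, str]:
        """(chrom, start, end, strand) union span of the gene's transcripts."""
        recs = [t for t in self if t.gene_id == gene_id]
        if not recs:
            raise KeyError(gene_id)
        chroms = {t.chrom for t in recs}
        if len(chroms) != 1:
            raise ValueError(f"gene {gene_id} spans multiple chromosomes")
        return (
            recs[0].chrom,
            min(t.span[0] for t in recs),
            max(t.span[1] for t in recs),
            recs[0].strand,
        )


# ---------------------------------------------------------------------------
# GTF / FASTA I/O
# ---------------------------------------------------------------------------


def _gtf_attributes(rec: TranscriptRecord) -> str:
    biotype = rec.declared_biotype or "unknown"
    return (
        f'gene_id "{rec.gene_id}"; transcript_id "{rec.transcript_id}"; '
        f'gene_biotype "{biotype}";'
    )


def write_gtf(catalog: TranscriptCatalog, path: str | Path) -> None:
    """Write the catalog as GTF (1-based inclusive; transcript/exon/CDS rows)."""
    lines = []
    for rec in sorted(catalog, key=lambda r: (r.chrom, r.span, r.transcript_id)):
        attrs = _gtf_attributes(rec)
        s, e = rec.span
        lines.append(
            f"{rec.chrom}\tcernaforge\ttranscript\t{s + 1}\t{e}\t.\t{rec.strand}\t.\t{attrs}"
        )
        for es, ee in rec.exons:
            lines.append(
                f"{rec.chrom}\tcernaforge\texon\t{es + 1}\t{ee}\t.\t{rec.strand}\t.\t{attrs}"
            )
        if rec.cds is not None:
            for cs, ce in rec.transcript_to_genomic(*rec.cds):
                lines.append(
                    f"{rec.chrom}\tcernaforge\tCDS\t{cs + 1}\t{ce}\t.\t{rec.strand}\t0\t{attrs}"
                )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_transcript_fasta(catalog: TranscriptCatalog, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(rec.sequence), id=rec.transcript_id, description="")
        for rec in sorted(catalog, key=lambda r: r.transcript_id)
    ]
    SeqIO.write(records, str(path), "fasta")


def _validate_gtf_lines(path: Path) -> None:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GTF line {i}: expected 9 fields, got {len(fields)}")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as err:
                raise ValueError(f"malformed GTF line {i}: non-integer coordinates") from err
            if start < 1 or end < start:
                raise ValueError(f"malformed GTF line {i}: bad coordinate range {start}..{end}")
            if fields[6] not in {"+", "-", "."}:
                raise ValueError(f"malformed GTF line {i}: bad strand {fields[6]!r}")


def load_catalog(gtf_path: str | Path, fasta_path: str | Path) -> TranscriptCatalog:
    """Parse a GTF + transcript FASTA into a TranscriptCatalog.

    GTF 1-based inclusive coordinates are converted to 0-based half-open.
    Every transcript in the GTF must have a sequence in the FASTA whose length
    matches its summed exon length; genomic CDS rows are mapped back to
    transcript-relative coordinates.
    """
    gtf_path, fasta_path = Path(gtf_path), Path(fasta_path)
    for p in (gtf_path, fasta_path):
        if not p.exists():
            raise FileNotFoundError(p)
    _validate_gtf_lines(gtf_path)
    seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}

    has_features = any(
        line.strip() and not line.startswith("#")
        for line in gtf_path.read_text().splitlines()
    )
    if not has_features:
        return TranscriptCatalog()

    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    exons: dict[str, list[tuple[int, int]]] = collections.defaultdict(list)
    cds: dict[str, list[tuple[int, int]]] = collections.defaultdict(list)
    meta: dict[str, tuple[str, str, str, str]] = {}
    for feat in db.all_features():
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            continue
        gid = feat.attributes.get("gene_id", [tid])[0]
        biotype = feat.attributes.get("gene_biotype", [None])[0]
        meta.setdefault(tid, (gid, feat.seqid, feat.strand, biotype))
        interval = (feat.start - 1, feat.end)  # to 0-based half-open
        if feat.featuretype == "exon":
            exons[tid].append(interval)
        elif feat.featuretype == "CDS":
            cds[tid].append(interval)

    catalog = TranscriptCatalog()
    for tid, (gid, chrom, strand, biotype) in meta.items():
        if tid not in exons:
            continue
        if tid not in seqs:
            raise ValueError(f"transcript {tid} has no sequence in {fasta_path}")
        rec = TranscriptRecord(
            transcript_id=tid,
            gene_id=gid,
            chrom=chrom,
            strand=strand,
            exons=exons[tid],
            sequence=seqs[tid],
            declared_biotype=biotype,
        )
        if tid in cds:
            t_indices = [
                rec.genomic_to_transcript(g)
                for s, e in cds[tid]
                for g in (s, e - 1)
            ]
            rec.cds = (min(t_indices), max(t_indices) + 1)
        catalog.add(rec)
    return catalog


# ---------------------------------------------------------------------------
# ORF finding and coding potential
# ---------------------------------------------------------------------------


class ORF(NamedTuple):
    length: int  # nt including the stop codon; 0 if no ORF
    frame: int | None
    start: int | None


def longest_orf(sequence: str) -> ORF:
    """Longest ATG->stop ORF over the three forward frames.

    Length is in nucleotides and includes the stop codon. ORFs without an
    in-frame stop are not counted. Returns ORF(0, None, None) when no ORF
    exists. Transcript sequences are already stranded, so only forward frames
    are scanned.
    """
    seq = dna(sequence)
    if any(c not in "ACGT" for c in seq):
        bad = sorted({c for c in seq if c not in "ACGT"})
        raise ValueError(f"non-ACGTU characters in sequence: {bad}")
    best = ORF(0, None, None)
    n = len(seq)
    for frame in range(3):
        open_start: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if open_start is not None:
                    length = i + 3 - open_start
                    if length > best.length:
                        best = ORF(length, frame, open_start)
                    open_start = None
            elif codon == "ATG" and open_start is None:
                open_start = i
    return best


@dataclass
class CodingPotentialReport:
    """Per-transcript coding-potential evidence and scorer verdicts."""

    transcript_id: str
    longest_orf_nt: int
    orf_coverage: float
    hexamer_score: float
    verdicts: dict[str, str] = field(default_factory=dict)

    @property
    def all_noncoding(self) -> bool:
        return all(v == "noncoding" for v in self.verdicts.values())


def _orf_region(seq: str) -> tuple[str, int]:
    """Scoring region for the hexamer model: the longest ORF, else frame 0."""
    orf = longest_orf(seq)
    if orf.length >= 6:
        return seq[orf.start : orf.start + orf.length], orf.length
    return seq, 0


def _inframe_hexamers(region: str) -> Iterable[str]:
    region = dna(region)
    for i in range(0, len(region) - 5, 3):
        yield region[i : i + 6]


def train_hexamer_table(
    coding_sequences: Sequence[str], pseudocount: float = 1.0
) -> dict[str, float]:
    """Log-ratio table of in-frame hexamer frequencies, coding vs shuffled.

    Foreground counts come from in-frame (step 3) hexamers of each coding
    sequence's longest ORF; the background from the same count over a
    deterministic shuffle of each sequence (fixed internal seed, so the table
    is a pure function of its input sequences). Pseudocount 1 on every hexamer.
    """
    rng = np.random.default_rng(0)
    fg: collections.Counter[str] = collections.Counter()
    bg: collections.Counter[str] = collections.Counter()
    for seq in coding_sequences:
        seq = dna(seq)
        region, orf_len = _orf_region(seq)
        if orf_len:
            fg.update(_inframe_hexamers(region))
        shuffled = "".join(rng.permutation(list(seq)))
        bg.update(_inframe_hexamers(shuffled))
    alphabet = "ACGT"
    hexamers = [
        a + b + c + d + e + f
        for a in alphabet for b in alphabet for c in alphabet
        for d in alphabet for e in alphabet for f in alphabet
    ]
    fg_tot = sum(fg.values()) + pseudocount * len(hexamers)
    bg_tot = sum(bg.values()) + pseudocount * len(hexamers)
    return {
        h: math.log(((fg[h] + pseudocount) / fg_tot) / ((bg[h] + pseudocount) / bg_tot))
        for h in hexamers
    }


def hexamer_score(sequence: str, table: Mapping[str, float]) -> float:
    """Mean in-frame hexamer log-ratio over the scoring region (0 if < 6 nt)."""
    seq = dna(sequence)
    if len(seq) < 6:
        return 0.0
    region, _ = _orf_region(seq)
    scores = [table[h] for h in _inframe_hexamers(region) if h in table]
    return float(np.mean(scores)) if scores else 0.0


def coding_potential(
    transcript: TranscriptRecord | str,
    hexamer_table: Mapping[str, float],
    orf_min: int = 300,
    cov_min: float = 0.35,
    transcript_id: str = "",
) -> CodingPotentialReport:
    """Run both internal coding-potential scorers on one transcript.

    ORF scorer: coding iff longest ORF >= ``orf_min`` nt AND ORF coverage
    >= ``cov_min``. Hexamer scorer: coding iff the mean in-frame hexamer
    log-ratio is > 0.
    """
    if isinstance(transcript, TranscriptRecord):
        seq, tid = transcript.sequence, transcript.transcript_id
    else:
        seq, tid = transcript, transcript_id
    orf = longest_orf(seq)
    coverage = orf.length / len(seq) if seq else 0.0
    hscore = hexamer_score(seq, hexamer_table)
    verdicts = {
        "orf": "coding" if (orf.length >= orf_min and coverage >= cov_min) else "noncoding",
        "hexamer": "coding" if hscore > 0 else "noncoding",
    }
    return CodingPotentialReport(
        transcript_id=tid,
        longest_orf_nt=orf.length,
        orf_coverage=coverage,
        hexamer_score=hscore,
        verdicts=verdicts,
    )


def catalog_reports(
    catalog: TranscriptCatalog,
    hexamer_table: Mapping[str, float] | None = None,
    orf_min: int = 300,
    cov_min: float = 0.35,
) -> dict[str, CodingPotentialReport]:
    """Coding-potential reports for every transcript in the catalog.

    When no hexamer table is given, one is trained on the catalog's own
    declared protein-coding set.
    """
    if hexamer_table is None:
        hexamer_table = train_hexamer_table(
            [catalog[tid].sequence for tid in sorted(catalog.coding_ids())]
        )
    return {
        rec.transcript_id: coding_potential(rec, hexamer_table, orf_min, cov_min)
        for rec in catalog
    }


# ---------------------------------------------------------------------------
# filter cascade and classification
# ---------------------------------------------------------------------------


def filter_lncrnas(
    catalog: TranscriptCatalog,
    reports: Mapping[str, CodingPotentialReport],
    length_min: int = 200,
    min_exons: int = 2,
    excluded_biotypes: frozenset[str] = EXCLUDED_BIOTYPES,
) -> set[str]:
    """Apply the four-criterion lncRNA cascade; returns surviving ids.

    Keep a transcript iff length > ``length_min`` (strict), exon count
    >= ``min_exons``, declared biotype not excluded, and ALL coding-potential
    scorers vote noncoding (a single "coding" verdict vetoes the transcript).
    """
    missing = [t.transcript_id for t in catalog if t.transcript_id not in reports]
    if missing:
        raise ValueError(f"no coding-potential report for: {missing[:5]}")
    kept = set()
    for rec in catalog:
        if rec.length <= length_min:
            continue
        if rec.n_exons < min_exons:
            continue
        if rec.declared_biotype in excluded_biotypes:
            continue
        if not reports[rec.transcript_id].all_noncoding:
            continue
        kept.add(rec.transcript_id)
    return kept


@dataclass
class LncRNAClass:
    transcript_id: str
    lncrna_class: str  # "antisense" | "intergenic"


def classify_lncrna(
    lncrna_id: str, catalog: TranscriptCatalog
) -> LncRNAClass:
    """Antisense iff >= 1 exonic base overlaps an opposite-strand coding transcript."""
    rec = catalog[lncrna_id]
    for other in catalog:
        if other.declared_biotype != "protein_coding":
            continue
        if other.chrom != rec.chrom or other.strand == rec.strand:
            continue
        os, oe = other.span
        if any(s < oe and os < e for s, e in rec.exons):
            return LncRNAClass(lncrna_id, "antisense")
    return LncRNAClass(lncrna_id, "intergenic")


def classify_lncrnas(
    lncrna_ids: Iterable[str], catalog: TranscriptCatalog
) -> dict[str, str]:
    return {tid: classify_lncrna(tid, catalog).lncrna_class for tid in lncrna_ids}


def feature_summary(
    ids: Iterable[str],
    catalog: TranscriptCatalog,
    reports: Mapping[str, CodingPotentialReport],
) -> tuple[dict[str, float], pd.DataFrame]:
    """Length / exon-count / ORF-length summaries plus per-feature rows."""
    ids = sorted(ids)
    if not ids:
        raise ValueError("feature_summary requires a nonempty id set")
    rows = pd.DataFrame(
        {
            "transcript_id": ids,
            "length": [catalog[t].length for t in ids],
            "n_exons": [catalog[t].n_exons for t in ids],
            "longest_orf_nt": [reports[t].longest_orf_nt for t in ids],
        }
    ).set_index("transcript_id")
    summary = {
        "n_features": float(len(rows)),
        "mean_length": float(rows["length"].mean()),
        "median_length": float(rows["length"].median()),
        "mean_exon_count": float(rows["n_exons"].mean()),
        "mean_orf_length": float(rows["longest_orf_nt"].mean()),
    }
    return summary, rows
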
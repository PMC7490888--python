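"""Transcript catalog: GTF round-trips, ORF finding, coding potential, cascade."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats

from cernaforge import catalog as cat
from cernaforge.catalog import (
    STOP_CODONS,
    TranscriptCatalog,
    TranscriptRecord,
    coding_potential,
    feature_summary,
    filter_lncrnas,
    classify_lncrna,
    load_catalog,
    longest_orf,
    train_hexamer_table,
    write_gtf,
    write_transcript_fasta,
)
from cernaforge.simulate import SimulationConfig, _coding_sequence, generate_dataset


def orf_oracle(seq: str) -> int:
    """Exhaustive scan over all (frame, start, stop) triples."""
    best = 0
    for frame in range(3):
        for s in range(frame, len(seq) - 2, 3):
            if seq[s : s + 3] != "ATG":
                continue
            for e in range(s + 3, len(seq) - 2, 3):
                if seq[e : e + 3] in STOP_CODONS:
                    best = max(best, e + 3 - s)
                    break
    return best


def _record(tid="t1", gene="g1", chrom="chr1", strand="+", exons=((0, 300),),
            seq=None, biotype=None, cds=None):
    length = sum(e - s for s, e in exons)
    return TranscriptRecord(tid, gene, chrom, strand, list(exons),
                           seq or "A" * length, biotype, cds)


class TestLongestOrf:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("ATGTAA", 6),  # minimal start+stop
            ("CCCCCC", 0),  # no start codon
            ("ATGAAACCC", 0),  # open ORF without stop does not count
            ("CATGTGATAA", 6),  # frame 1: ATG TGA
            ("ATGATGAAATAG", 12),  # longest from the first ATG
        ],
    )
    def test_known_cases(self, seq, expected):
        assert longest_orf(seq).length == expected

    def test_matches_exhaustive_oracle_on_random_sequences(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            seq = "".join(rng.choice(list("ACGT"), 300))
            assert longest_orf(seq).length == orf_oracle(seq)

    def test_accepts_rna_rejects_garbage(self):
        assert longest_orf("AUGUAA").length == 6
        with pytest.raises(ValueError, match="non-ACGTU"):
            longest_orf("ATGNNNTAA")


class TestGtfRoundTrip:
    def test_coordinate_convention(self, tmp_path):
        rec = _record(exons=[(0, 100)], seq="A" * 100)
        catalog = TranscriptCatalog([rec])
        write_gtf(catalog, tmp_path / "x.gtf")
        line = next(
            l for l in (tmp_path / "x.gtf").read_text().splitlines()
            if "\texon\t" in l
        )
        fields = line.split("\t")
        assert (fields[3], fields[4]) == ("1", "100")  # 1-based inclusive
        write_transcript_fasta(catalog, tmp_path / "x.fa")
        loaded = load_catalog(tmp_path / "x.gtf", tmp_path / "x.fa")
        assert loaded["t1"].exons == [(0, 100)]

    def test_empty_gtf_gives_empty_catalog(self, tmp_path):
        (tmp_path / "e.gtf").write_text("")
        (tmp_path / "e.fa").write_text("")
        assert len(load_catalog(tmp_path / "e.gtf", tmp_path / "e.fa")) == 0

    def test_synthetic_fixture_round_trip(self, dataset, tmp_path):
        write_gtf(dataset.catalog, tmp_path / "d.gtf")
        write_transcript_fasta(dataset.catalog, tmp_path / "d.fa")
        loaded = load_catalog(tmp_path / "d.gtf", tmp_path / "d.fa")
        assert set(loaded.ids()) == set(dataset.catalog.ids())
        for tid in loaded.ids():
            a, b = loaded[tid], dataset.catalog[tid]
            assert (a.exons, a.strand, a.sequence, a.declared_biotype, a.cds) == (
                b.exons, b.strand, b.sequence, b.declared_biotype, b.cds,
            )

    def test_malformed_line_reported_with_number(self, tmp_path):
        (tmp_path / "bad.gtf").write_text("chr1\tsrc\texon\t1\t100\t.\t+\t.\tok\nbroken line\n")
        (tmp_path / "bad.fa").write_text("")
        with pytest.raises(ValueError, match="line 2"):
            load_catalog(tmp_path / "bad.gtf", tmp_path / "bad.fa")

    def test_missing_sequence_names_transcript(self, dataset, tmp_path):
        write_gtf(dataset.catalog, tmp_path / "d.gtf")
        (tmp_path / "d.fa").write_text("")
        with pytest.raises(ValueError, match="no sequence"):
            load_catalog(tmp_path / "d.gtf", tmp_path / "d.fa")


class TestCodingPotential:
    def test_planted_coding_transcript_both_verdicts_coding(self, dataset):
        rng = np.random.default_rng(7)
        # an unambiguous coding transcript: 900 nt biased CDS, coverage 0.75
        seq, cds = _coding_sequence(rng)
        table = train_hexamer_table(
            [dataset.catalog[t].sequence for t in sorted(dataset.catalog.coding_ids())]
        )
        report = coding_potential(seq, table, transcript_id="x")
        assert report.longest_orf_nt >= 300
        assert report.verdicts == {"orf": "coding", "hexamer": "coding"}

    def test_short_random_sequence_is_noncoding(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 250))
        report = coding_potential(seq, {}, transcript_id="x")
        assert report.verdicts["orf"] == "noncoding"
        assert report.orf_coverage == report.longest_orf_nt / 250

    def test_hexamer_scores_separate_coding_from_noncoding(self, dataset):
        reports = cat.catalog_reports(dataset.catalog)
        coding = [
            reports[t].hexamer_score for t in dataset.catalog.coding_ids()
        ]
        noncoding = [
            reports[t].hexamer_score for t in sorted(dataset.lncrna_ids)
        ]
        assert np.mean(coding) > np.mean(noncoding)
        assert stats.mannwhitneyu(coding, noncoding, alternative="greater").pvalue < 1e-6

    def test_sequence_shorter_than_hexamer_scores_zero(self):
        report = coding_potential("ACGAC", {}, transcript_id="x")
        assert report.hexamer_score == 0.0
        assert report.verdicts["hexamer"] == "noncoding"


class TestFilterCascade:
    def _reports(self, catalog, noncoding=True):
        v = "noncoding" if noncoding else "coding"
        return {
            t.transcript_id: cat.CodingPotentialReport(
                t.transcript_id, 0, 0.0, -1.0, {"orf": v, "hexamer": v}
            )
            for t in catalog
        }

    def test_length_200_rejected_strictly(self):
        catalog = TranscriptCatalog([_record(exons=[(0, 100), (200, 300)])])
        assert filter_lncrnas(catalog, self._reports(catalog)) == set()
        catalog2 = TranscriptCatalog([_record(exons=[(0, 100), (200, 301)])])
        assert filter_lncrnas(catalog2, self._reports(catalog2)) == {"t1"}

    def test_single_exon_rejected(self):
        catalog = TranscriptCatalog([_record(exons=[(0, 5000)])])
        assert filter_lncrnas(catalog, self._reports(catalog)) == set()

    def test_any_coding_verdict_vetoes(self):
        catalog = TranscriptCatalog([_record(exons=[(0, 300), (400, 700)])])
        reports = self._reports(catalog)
        reports["t1"].verdicts["hexamer"] = "coding"
        assert filter_lncrnas(catalog, reports) == set()

    def test_excluded_biotype_rejected(self):
        catalog = TranscriptCatalog(
            [_record(exons=[(0, 300), (400, 700)], biotype="pseudogene")]
        )
        assert filter_lncrnas(catalog, self._reports(catalog)) == set()

    def test_recovery_equals_generator_truth(self, dataset):
        reports = cat.catalog_reports(dataset.catalog)
        recovered = filter_lncrnas(dataset.catalog, reports)
        assert recovered == dataset.lncrna_ids

    def test_criteria_order_independent(self, dataset):
        reports = cat.catalog_reports(dataset.catalog)
        criteria = {
            "length": {t.transcript_id for t in dataset.catalog if t.length > 200},
            "exons": {t.transcript_id for t in dataset.catalog if t.n_exons >= 2},
            "biotype": {
                t.transcript_id
                for t in dataset.catalog
                if t.declared_biotype not in cat.EXCLUDED_BIOTYPES
            },
            "scorers": {
                tid for tid, r in reports.items() if r.all_noncoding
            },
        }
        expected = filter_lncrnas(dataset.catalog, reports)
        for order in itertools.permutations(criteria):
            acc = set(dataset.catalog.ids())
            for name in order:
                acc &= criteria[name]
            assert acc == expected


class TestClassification:
    def test_antisense_definition_case(self):
        lnc = _record("l1", "gl", exons=[(100, 250), (300, 400)], strand="-")
        coding = _record("c1", "gc", exons=[(300, 600)], strand="+",
                         biotype="protein_coding")
        catalog = TranscriptCatalog([lnc, coding])
        assert classify_lncrna("l1", catalog).lncrna_class == "antisense"

    def test_no_overlap_is_intergenic(self):
        lnc = _record("l1", "gl", exons=[(100, 250), (300, 400)], strand="-")
        coding = _record("c1", "gc", exons=[(5000, 5600)], strand="+",
                         biotype="protein_coding")
        catalog = TranscriptCatalog([lnc, coding])
        assert classify_lncrna("l1", catalog).lncrna_class == "intergenic"

    def test_same_strand_overlap_not_antisense(self):
        lnc = _record("l1", "gl", exons=[(100, 250), (300, 400)], strand="+")
        coding = _record("c1", "gc", exons=[(300, 600)], strand="+",
                         biotype="protein_coding")
        catalog = TranscriptCatalog([lnc, coding])
        assert classify_lncrna("l1", catalog).lncrna_class == "intergenic"

    def test_classes_partition_and_match_planted_fraction(self, dataset):
        classes = cat.classify_lncrnas(sorted(dataset.lncrna_ids), dataset.catalog)
        assert set(classes) == dataset.lncrna_ids
        assert set(classes.values()) <= {"antisense", "intergenic"}
        n_antisense = sum(1 for c in classes.values() if c == "antisense")
        expected = round(
            dataset.config.antisense_fraction * dataset.config.n_lncrnas
        )
        assert n_antisense == expected


class TestFeatureSummary:
    def test_single_and_pair_means(self):
        catalog = TranscriptCatalog(
            [
                _record("a", exons=[(0, 150), (200, 350)]),
                _record("b", exons=[(0, 100), (150, 250), (300, 400), (450, 550)]),
            ]
        )
        reports = {
            "a": cat.CodingPotentialReport("a", 30, 0.1, -1, {}),
            "b": cat.CodingPotentialReport("b", 60, 0.15, -1, {}),
        }
        summary, rows = feature_summary(["a"], catalog, reports)
        assert summary["mean_length"] == 300
        summary2, _ = feature_summary(["a", "b"], catalog, reports)
        assert summary2["mean_exon_count"] == 3.0
        assert summary2["mean_orf_length"] == 45.0

    def test_empty_set_errors(self, dataset):
        with pytest.raises(ValueError):
            feature_summary([], dataset.catalog, {})

    def test_matches_direct_recomputation(self, dataset):
        reports = cat.catalog_reports(dataset.catalog)
        ids = sorted(dataset.lncrna_ids)
        summary, rows = feature_summary(ids, dataset.catalog, reports)
        lengths = [dataset.catalog[t].length for t in ids]
        assert summary["mean_length"] == pytest.approx(np.mean(lengths))
        assert summary["median_length"] == pytest.approx(np.median(lengths))
        assert (rows["length"] > 200).all()
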
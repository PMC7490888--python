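"""Neighbor pairs: window search, orientation, correlations, MWU contrast."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from cernaforge import cis
from cernaforge.catalog import TranscriptCatalog, TranscriptRecord


def _gene(gid, start, end, strand="+", biotype="protein_coding", chrom="chr1"):
    return TranscriptRecord(
        f"t_{gid}", gid, chrom, strand, [(start, end)], "A" * (end - start), biotype
    )


def neighbor_oracle(catalog, lncrna_ids, max_dist):
    """All-vs-all quadratic enumeration over gene spans."""
    lnc = set(lncrna_ids)
    genes = {}
    for t in catalog:
        kind = "lncRNA" if t.transcript_id in lnc else (
            "coding" if t.declared_biotype == "protein_coding" else "other"
        )
        genes[t.gene_id] = (*catalog.gene_span(t.gene_id), kind)
    out = set()
    for (ga, a), (gb, b) in itertools.combinations(sorted(genes.items()), 2):
        if a[0] != b[0]:
            continue
        kinds = {a[4], b[4]}
        if kinds not in ({"coding"}, {"coding", "lncRNA"}):
            continue
        gap = max(0, max(a[1], b[1]) - min(a[2], b[2]))
        if gap < max_dist:
            out.add((min(ga, gb), max(ga, gb), gap))
    return out


class TestFindNeighbors:
    def test_definition_case_and_strict_window(self):
        catalog = TranscriptCatalog([
            _gene("g1", 0, 1000),
            _gene("g2", 5000, 6000),
            _gene("g3", 16000, 17000),   # gap to g2 exactly 10,000 -> excluded
        ])
        pairs = cis.find_neighbors(catalog, [])
        assert [(p.feature_a, p.feature_b, p.distance) for p in pairs] == [
            ("g1", "g2", 4000)
        ]

    def test_overlapping_genes_have_distance_zero(self):
        catalog = TranscriptCatalog([
            _gene("g1", 0, 1000), _gene("g2", 500, 1500, strand="-"),
        ])
        (pair,) = cis.find_neighbors(catalog, [])
        assert pair.distance == 0

    def test_lncrna_lncrna_pairs_excluded(self):
        catalog = TranscriptCatalog([
            _gene("g1", 0, 1000, biotype="lncRNA"),
            _gene("g2", 2000, 3000, biotype="lncRNA"),
            _gene("g3", 4000, 5000),
        ])
        pairs = cis.find_neighbors(catalog, ["t_g1", "t_g2"])
        assert {(p.feature_a, p.feature_b) for p in pairs} == {
            ("g1", "g3"), ("g2", "g3")
        }
        assert all(p.pair_class == "lncRNA-coding" for p in pairs)

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_quadratic_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        records = []
        pos = 0
        for i in range(rng.integers(5, 25)):
            pos += int(rng.integers(0, 15_000))
            length = int(rng.integers(200, 4000))
            biotype = "protein_coding" if rng.random() < 0.7 else "lncRNA"
            chrom = "chr1" if rng.random() < 0.7 else "chr2"
            records.append(_gene(f"g{i}", pos, pos + length, biotype=biotype, chrom=chrom))
            pos += length
        catalog = TranscriptCatalog(records)
        lnc = [t.transcript_id for t in records if t.declared_biotype == "lncRNA"]
        got = {(p.feature_a, p.feature_b, p.distance)
               for p in cis.find_neighbors(catalog, lnc)}
        assert got == neighbor_oracle(catalog, lnc, 10_000)


class TestOrientation:
    def test_divergent_and_convergent_definition_cases(self):
        catalog = TranscriptCatalog([
            _gene("a", 100, 500, strand="-"), _gene("b", 600, 900, strand="+"),
        ])
        pair = cis.GenePair("a", "b", "coding-coding")
        assert cis.classify_orientation(pair, catalog) == "divergent"
        catalog2 = TranscriptCatalog([
            _gene("a", 100, 500, strand="+"), _gene("b", 600, 900, strand="-"),
        ])
        assert cis.classify_orientation(pair, catalog2) == "convergent"

    def test_truth_table_all_strand_order_combinations(self):
        # (left strand, right strand) -> orientation; feature order irrelevant
        table = {
            ("+", "+"): "tandem", ("-", "-"): "tandem",
            ("-", "+"): "divergent", ("+", "-"): "convergent",
        }
        for (sl, sr), expected in table.items():
            catalog = TranscriptCatalog([
                _gene("l", 0, 400, strand=sl), _gene("r", 900, 1300, strand=sr),
            ])
            for a, b in (("l", "r"), ("r", "l")):
                pair = cis.GenePair(a, b, "coding-coding")
                assert cis.classify_orientation(pair, catalog) == expected

    def test_orientation_partitions_pairs(self, dataset):
        lnc = sorted(dataset.lncrna_ids)
        for p in cis.find_neighbors(dataset.catalog, lnc):
            assert cis.classify_orientation(p, dataset.catalog) in {
                "divergent", "convergent", "tandem"
            }

    def test_random_pairs_have_no_orientation(self):
        with pytest.raises(ValueError, match="random"):
            cis.classify_orientation(
                cis.GenePair("a", "b", "random"), TranscriptCatalog([])
            )


class TestCorrelations:
    def _values(self, rows, n=8, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(10, 2, (rows, n)).clip(min=0),
            index=[f"g{i}" for i in range(rows)],
            columns=[f"s{j}" for j in range(n)],
        )

    def test_identity_and_antisymmetry(self):
        values = self._values(2)
        values.loc["g1"] = 20 - values.loc["g0"]  # exactly anticorrelated
        same = [cis.GenePair("g0", "g0", "coding-coding")]
        anti = [cis.GenePair("g0", "g1", "coding-coding")]
        (p1,), _ = cis.pair_correlations(same, values)
        (p2,), _ = cis.pair_correlations(anti, values)
        assert p1.pearson_r == pytest.approx(1.0)
        assert p2.pearson_r == pytest.approx(-1.0)

    def test_matches_from_scratch_formula(self):
        values = self._values(40, seed=3)
        rng = np.random.default_rng(4)
        pairs = [
            cis.GenePair(f"g{i}", f"g{j}", "coding-coding")
            for i, j in rng.choice(40, size=(20, 2), replace=True)
            if i != j
        ]
        with_r, _ = cis.pair_correlations(pairs, values)
        for p in with_r:
            x = values.loc[p.feature_a].to_numpy()
            y = values.loc[p.feature_b].to_numpy()
            xc, yc = x - x.mean(), y - y.mean()
            r = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
            assert p.pearson_r == pytest.approx(r, abs=1e-12)

    def test_zero_variance_pairs_dropped_and_counted(self):
        values = self._values(3)
        values.loc["g2"] = 7.0
        pairs = [
            cis.GenePair("g0", "g1", "coding-coding"),
            cis.GenePair("g0", "g2", "coding-coding"),
        ]
        kept, dropped = cis.pair_correlations(pairs, values)
        assert len(kept) == 1 and dropped == 1

    def test_too_few_samples_errors(self):
        values = self._values(2, n=2)
        with pytest.raises(ValueError, match="3 samples"):
            cis.pair_correlations([cis.GenePair("g0", "g1", "coding-coding")], values)


class TestRandomNull:
    def test_seed_determinism_and_empty(self):
        values = pd.DataFrame(
            np.random.default_rng(0).normal(10, 3, (30, 8)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{j}" for j in range(8)],
        ).clip(lower=0)
        coding = list(values.index)
        a, _ = cis.random_pair_null(values, coding, 50, seed=9)
        b, _ = cis.random_pair_null(values, coding, 50, seed=9)
        assert [(p.feature_a, p.feature_b) for p in a] == [
            (p.feature_a, p.feature_b) for p in b
        ]
        assert all(p.pair_class == "random" for p in a)
        assert cis.random_pair_null(values, coding, 0)[0] == []

    def test_distinct_pairs_only(self):
        values = pd.DataFrame(
            np.random.default_rng(1).normal(10, 3, (6, 8)).clip(min=0),
            index=[f"g{i}" for i in range(6)],
            columns=[f"s{j}" for j in range(8)],
        )
        pairs, _ = cis.random_pair_null(values, list(values.index), 15, seed=2)
        keys = [(p.feature_a, p.feature_b) for p in pairs]
        assert len(keys) == len(set(keys)) == 15  # all C(6,2) pairs


class TestCompareDistributions:
    def test_identical_distributions_p_near_one(self):
        vals = [0.1, 0.2, 0.3, 0.4]
        _, _, p = cis.compare_correlation_distributions(vals, vals)
        assert p > 0.65  # ties push p toward 1

    def test_u_statistic_equals_exhaustive_enumeration(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(21)
        for _ in range(50):
            a = rng.normal(0, 1, 4)
            b = rng.normal(0.5, 1, 4)
            u_brute = sum(
                1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b
            )
            assert mannwhitneyu(a, b, alternative="two-sided").statistic == u_brute

    def test_small_groups_error(self):
        with pytest.raises(ValueError):
            cis.compare_correlation_distributions([0.1], [0.2, 0.3])
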
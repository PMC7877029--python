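"""Count-table container, I/O and basic transforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contamqc.feature_table import (
    DEFAULT_LINEAGE_RULES,
    FeatureTable,
    ParseError,
    SampleRecord,
    TaxonAnnotation,
    ValidationError,
    aggregate_by_rank,
    filter_taxa_by_lineage,
    prevalence,
    read_feature_table,
    read_metadata,
    relative_abundance,
    write_feature_table,
    write_metadata,
)

from conftest import random_table


class TestFeatureTableInvariants:
    def test_duplicate_identifiers_rejected(self):
        with pytest.raises(ValidationError, match="duplicate sample"):
            FeatureTable(["a", "b"], ["s", "s"], np.zeros((2, 2), int))
        with pytest.raises(ValidationError, match="duplicate taxon"):
            FeatureTable(["a", "a"], ["s1", "s2"], np.zeros((2, 2), int))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError, match="negative count"):
            FeatureTable(["a"], ["s"], np.array([[-1]]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="inconsistent"):
            FeatureTable(["a", "b"], ["s"], np.zeros((1, 1), int))


class TestIO:
    def test_tsv_round_trip_preserves_order_and_counts(self, tmp_path):
        t = FeatureTable(["tA", "tB"], ["s1", "s2"], np.array([[5, 0], [1, 3]]))
        p = tmp_path / "t.tsv"
        write_feature_table(t, p)
        back = read_feature_table(p)
        assert back == t

    @pytest.mark.parametrize("fmt", ["tsv", "biom_json"])
    def test_round_trip_random_table(self, tmp_path, rng, fmt):
        t = random_table(rng, 50, 20)
        p = tmp_path / f"t.{fmt}"
        write_feature_table(t, p, fmt)
        assert read_feature_table(p, fmt) == t

    def test_duplicate_header_is_validation_error(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("taxon_id\ts1\ts1\nA\t1\t2\n")
        with pytest.raises(ValidationError):
            read_feature_table(p)

    def test_non_integer_cell_names_location(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("taxon_id\ts1\nA\t1.5x\n")
        with pytest.raises(ParseError, match="'A'.*'s1'"):
            read_feature_table(p)


class TestMetadata:
    def test_row_fields_parsed(self, tmp_path):
        p = tmp_path / "md.tsv"
        p.write_text(
            "sample_id\tbatch\trun\tsample_type\tdna_concentration\n"
            "S1\tbatch1\trun1\tbiological\t2.5\n"
        )
        (rec,) = read_metadata(p)
        assert rec == SampleRecord("S1", "batch1", "run1", "biological", 2.5)

    def test_unknown_sample_type_lists_allowed_values(self, tmp_path):
        p = tmp_path / "md.tsv"
        p.write_text("sample_id\tbatch\trun\tsample_type\nS1\tb\tr\tblank\n")
        with pytest.raises(ValidationError, match="biological"):
            read_metadata(p)

    def test_missing_required_column(self, tmp_path):
        p = tmp_path / "md.tsv"
        p.write_text("sample_id\tbatch\tsample_type\nS1\tb\tbiological\n")
        with pytest.raises(ParseError, match="run"):
            read_metadata(p)

    def test_nonpositive_dna_rejected(self, tmp_path):
        p = tmp_path / "md.tsv"
        p.write_text(
            "sample_id\tbatch\trun\tsample_type\tdna_concentration\nS1\tb\tr\tbiological\t0\n"
        )
        with pytest.raises(ValidationError, match="dna_concentration"):
            read_metadata(p)

    def test_negative_control_panel_round_trip(self, tmp_path):
        # a 72-blank panel like a two-batch study's pooled controls
        recs = [
            SampleRecord(f"NC{i:02d}", "batch1" if i < 15 else "batch2", "r1",
                         "negative_control")
            for i in range(72)
        ]
        p = tmp_path / "md.tsv"
        write_metadata(recs, p)
        back = read_metadata(p)
        assert len(back) == 72
        assert all(r.sample_type == "negative_control" for r in back)


class TestPrevalence:
    def test_hand_values_and_boundaries(self):
        t = FeatureTable(
            ["a", "b", "c"], ["s1", "s2", "s3"],
            np.array([[0, 3, 1], [0, 0, 0], [2, 5, 9]]),
        )
        prev = prevalence(t)
        assert prev["a"] == pytest.approx(2 / 3)
        assert prev["b"] == 0.0
        assert prev["c"] == 1.0

    def test_matches_per_cell_counting(self, rng):
        t = random_table(rng, 30, 40, max_count=4)
        for thr in (1, 2, 3):
            prev = prevalence(t, detection_threshold=thr)
            brute = [
                sum(1 for j in range(t.n_samples) if t.counts[i, j] >= thr) / t.n_samples
                for i in range(t.n_taxa)
            ]
            np.testing.assert_allclose(prev.to_numpy(), brute)

    @given(thr=st.integers(min_value=1, max_value=6))
    @settings(derandomize=True, deadline=None, max_examples=20)
    def test_monotone_nonincreasing_in_threshold(self, thr):
        t = random_table(np.random.default_rng(0), 15, 12, max_count=8)
        lo = prevalence(t, detection_threshold=thr)
        hi = prevalence(t, detection_threshold=thr + 1)
        assert (hi <= lo + 1e-15).all()
        assert ((lo >= 0) & (lo <= 1)).all()

    def test_empty_subset_rejected(self, toy_table):
        with pytest.raises(ValueError, match="empty"):
            prevalence(toy_table, [])


class TestRelativeAbundance:
    def test_columns_sum_to_one(self, rng):
        t = random_table(rng, 20, 15)
        rel = relative_abundance(t)
        np.testing.assert_allclose(rel.sum(axis=0), 1.0, atol=1e-12)
        expected = t.counts[:, :] / t.counts.sum(axis=0)
        np.testing.assert_allclose(rel.to_numpy(), expected[:, :rel.shape[1]], atol=1e-12)

    def test_zero_total_sample_dropped_with_warning(self, caplog):
        t = FeatureTable(["a", "b"], ["s1", "s2"], np.array([[2, 0], [2, 0]]))
        with caplog.at_level("WARNING"):
            rel = relative_abundance(t)
        assert list(rel.columns) == ["s1"]
        assert rel["s1"].tolist() == [0.5, 0.5]
        assert "s2" in caplog.text


class TestLineageFilter:
    def _ann(self, taxon, **ranks):
        lineage = {r: "Assigned" for r in
                   ("kingdom", "phylum", "class", "order", "family", "genus", "species")}
        lineage["kingdom"] = "Bacteria"
        lineage.update(ranks)
        return TaxonAnnotation(taxon, tuple(lineage[r] for r in
                                            ("kingdom", "phylum", "class", "order",
                                             "family", "genus", "species")))

    def test_rules_match_expected_taxa(self):
        anns = [
            self._ann("keep1"),
            self._ann("keep2", phylum="Firmicutes"),
            self._ann("cyano", phylum="p__Cyanobacteria"),
            self._ann("mito", family="f__mitochondria"),
            self._ann("chloro", **{"class": "Chloroplast"}),
            self._ann("unk", kingdom="Unassigned"),
            self._ann("keep3", genus="Lactobacillus"),
            self._ann("keep4"),
            self._ann("keep5", family="Comamonadaceae"),
            self._ann("keep6"),
        ]
        ids = [a.taxon_id for a in anns]
        t = FeatureTable(ids, ["s"], np.ones((10, 1), int))
        kept, removed = filter_taxa_by_lineage(t, anns)
        assert sorted(removed) == ["chloro", "cyano", "mito", "unk"]
        assert kept.n_taxa == 6

    def test_unannotated_taxon_errors_with_ids(self):
        t = FeatureTable(["x"], ["s"], np.ones((1, 1), int))
        with pytest.raises(ValidationError, match="x"):
            filter_taxa_by_lineage(t, [])


class TestAggregation:
    def _anns(self, genera):
        return [
            TaxonAnnotation(t, ("Bacteria", "P", "C", "O", "F", g, "unassigned"))
            for t, g in genera.items()
        ]

    def test_same_genus_counts_sum(self):
        t = FeatureTable(["a", "b"], ["s"], np.array([[3], [4]]))
        agg = aggregate_by_rank(t, self._anns({"a": "G1", "b": "G1"}), "genus")
        assert agg.to_dataframe().loc["G1", "s"] == 7

    def test_per_sample_totals_conserved(self, rng):
        t = random_table(rng, 25, 10)
        genera = {tid: f"G{i % 5}" for i, tid in enumerate(t.taxon_ids)}
        agg = aggregate_by_rank(t, self._anns(genera), "genus")
        np.testing.assert_array_equal(
            agg.counts.sum(axis=0), t.counts.sum(axis=0)
        )

    def test_unassigned_pooled(self):
        anns = [
            TaxonAnnotation("a", ("Bacteria", "P", "C", "O", "F", "g__", "s")),
            TaxonAnnotation("b", ("Bacteria", "P", "C", "O", "F", "unassigned", "s")),
        ]
        t = FeatureTable(["a", "b"], ["s"], np.array([[1], [2]]))
        agg = aggregate_by_rank(t, anns, "genus")
        assert agg.to_dataframe().loc["unassigned", "s"] == 3
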
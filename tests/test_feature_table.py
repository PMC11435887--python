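"""Feature-table model, I/O round-trips, filters, scaling, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmtkit.feature_table import (
    AsvTable,
    FeatureTableError,
    RelAbundTable,
    TaxonomyAssignment,
    aggregate_taxa,
    collapse_other,
    low_count_filter,
    low_variance_filter,
    read_asv_table,
    read_metadata,
    read_taxonomy,
    remove_rare_asvs,
    total_sum_scaling,
    write_asv_table,
    write_metadata,
    write_taxonomy,
)

from conftest import random_asv_table


class TestModel:
    def test_rejects_duplicate_ids(self):
        counts = pd.DataFrame([[1, 2]], index=["s1"], columns=["a", "a"])
        with pytest.raises(FeatureTableError, match="duplicate ASV"):
            AsvTable(counts)

    def test_rejects_negative_and_fractional_counts(self):
        with pytest.raises(FeatureTableError, match="negative count"):
            AsvTable(pd.DataFrame([[-1]], index=["s1"], columns=["a"]))
        with pytest.raises(FeatureTableError, match="non-integer"):
            AsvTable(pd.DataFrame([[2.5]], index=["s1"], columns=["a"]))

    def test_relabund_rows_must_sum_to_one(self):
        with pytest.raises(FeatureTableError, match="sum"):
            RelAbundTable(pd.DataFrame([[0.5, 0.4]], index=["s1"], columns=["a", "b"]))

    def test_taxonomy_label_falls_back_to_nearest_parent(self):
        tax = TaxonomyAssignment(
            ("Bacteria", "Firmicutes", "Clostridia", "Lachnospirales", "Lachnospiraceae", "", "")
        )
        assert tax.label("genus") == "unclassified Lachnospiraceae"
        assert tax.label("family") == "Lachnospiraceae"
        assert TaxonomyAssignment(("",) * 7).label("genus") == "unclassified"

    def test_taxonomy_needs_seven_ranks(self):
        with pytest.raises(FeatureTableError, match="7 rank"):
            TaxonomyAssignment(("Bacteria", "Firmicutes"))


class TestIO:
    def test_tsv_round_trip_small(self, small_table, tmp_path):
        path = tmp_path / "t.tsv"
        write_asv_table(small_table, path)
        back = read_asv_table(path)
        pd.testing.assert_frame_equal(back.counts, small_table.counts)

    def test_write_is_byte_stable(self, small_table, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_asv_table(small_table, p1)
        write_asv_table(small_table, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_table_round_trip(self, tmp_path):
        empty = AsvTable(pd.DataFrame(index=pd.Index([]), columns=pd.Index(["a1", "a2"])).fillna(0))
        path = tmp_path / "e.tsv"
        write_asv_table(empty, path)
        back = read_asv_table(path)
        assert back.n_samples == 0
        assert back.asv_ids == ["a1", "a2"]

    def test_large_random_round_trip(self, tmp_path):
        rng = np.random.default_rng(42)
        table = random_asv_table(rng, n_samples=1000, n_asvs=200, max_count=500)
        path = tmp_path / "big.tsv"
        write_asv_table(table, path)
        back = read_asv_table(path)
        assert (back.counts.to_numpy() == table.counts.to_numpy()).all()
        assert back.sample_ids == table.sample_ids
        assert back.asv_ids == table.asv_ids

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), n_samples=st.integers(1, 8), n_asvs=st.integers(1, 12))
    def test_round_trip_identity_property(self, seed, n_samples, n_asvs, tmp_path_factory):
        table = random_asv_table(np.random.default_rng(seed), n_samples, n_asvs)
        path = tmp_path_factory.mktemp("rt") / "t.tsv"
        write_asv_table(table, path)
        back = read_asv_table(path)
        pd.testing.assert_frame_equal(back.counts, table.counts)

    def test_duplicate_sample_column_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("asv_id\ts1\ts1\na1\t1\t2\n")
        with pytest.raises(FeatureTableError, match="duplicate sample column 's1'"):
            read_asv_table(path)

    def test_fractional_count_rejected_naming_cell(self, tmp_path):
        path = tmp_path / "frac.tsv"
        path.write_text("asv_id\ts1\ts2\na1\t1\t2.5\n")
        with pytest.raises(FeatureTableError, match=r"2\.5.*'a1'.*'s2'"):
            read_asv_table(path)

    def test_malformed_header_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("feature\ts1\na1\t1\n")
        with pytest.raises(FeatureTableError, match="malformed header"):
            read_asv_table(path)

    def test_biom_json_matches_tsv(self, small_table, tmp_path):
        import json

        doc = {
            "id": "t", "format": "Biological Observation Matrix 1.0.0",
            "type": "OTU table", "matrix_type": "sparse",
            "shape": [small_table.n_asvs, small_table.n_samples],
            "rows": [{"id": a, "metadata": None} for a in small_table.asv_ids],
            "columns": [{"id": s, "metadata": None} for s in small_table.sample_ids],
            "data": [
                [i, j, int(small_table.counts.iloc[j, i])]
                for i in range(small_table.n_asvs)
                for j in range(small_table.n_samples)
                if small_table.counts.iloc[j, i]
            ],
        }
        path = tmp_path / "t.biom"
        path.write_text(json.dumps(doc))
        back = read_asv_table(path, format="biom")
        pd.testing.assert_frame_equal(
            back.counts.loc[small_table.sample_ids, small_table.asv_ids], small_table.counts
        )

    def test_biom_hdf5_matches_tsv(self, small_table, tmp_path):
        import h5py
        from scipy import sparse

        mat = sparse.csr_matrix(small_table.counts.to_numpy().T)
        path = tmp_path / "t2.biom"
        with h5py.File(path, "w") as fh:
            fh.create_dataset("observation/ids", data=[a.encode() for a in small_table.asv_ids])
            fh.create_dataset("sample/ids", data=[s.encode() for s in small_table.sample_ids])
            fh.create_dataset("observation/matrix/data", data=mat.data.astype(float))
            fh.create_dataset("observation/matrix/indices", data=mat.indices)
            fh.create_dataset("observation/matrix/indptr", data=mat.indptr)
        back = read_asv_table(path, format="biom")
        pd.testing.assert_frame_equal(
            back.counts.loc[small_table.sample_ids, small_table.asv_ids], small_table.counts
        )

    def test_taxonomy_and_metadata_round_trip(self, lachno_taxonomy, tmp_path):
        tpath = tmp_path / "tax.tsv"
        write_taxonomy(lachno_taxonomy, tpath)
        back = read_taxonomy(tpath)
        assert back == lachno_taxonomy
        meta = pd.DataFrame(
            [{"sample_id": "s1", "dog_id": "F1", "group": "FMT", "visit": "screening"}]
        )
        from fmtkit.feature_table import SampleMetadata

        mpath = tmp_path / "meta.tsv"
        write_metadata(SampleMetadata(meta), mpath)
        assert read_metadata(mpath).sample_ids == ["s1"]


class TestFilters:
    def test_remove_rare_keeps_only_totals_above_cutoff(self):
        counts = pd.DataFrame(
            [[1, 2, 3, 1], [0, 0, 2, 1]], index=["s1", "s2"], columns=["a", "b", "c", "d"]
        )  # totals 1, 2, 5, 2
        out = remove_rare_asvs(AsvTable(counts), max_total=2)
        assert out.asv_ids == ["c"]
        assert out.sample_ids == ["s1", "s2"]

    def test_remove_rare_noop_when_all_above(self, small_table):
        out = remove_rare_asvs(small_table, max_total=1)  # totals 2, 4, 6
        assert out.asv_ids == small_table.asv_ids

    def test_remove_rare_empty_table(self):
        empty = AsvTable(pd.DataFrame(index=pd.Index([]), columns=pd.Index([]), dtype=int))
        assert remove_rare_asvs(empty).n_asvs == 0

    def test_low_count_filter_prevalence_rule(self):
        counts = pd.DataFrame(
            {"keep": [5, 5, 0, 0, 0], "drop": [3, 3, 3, 3, 3]},
            index=[f"s{i}" for i in range(5)],
        )
        out = low_count_filter(AsvTable(counts), min_count=4, min_prevalence=0.20)
        assert out.asv_ids == ["keep"]  # prevalence at >=4 is 0.40 vs 0.0

    def test_low_count_filter_boundary_inclusive(self):
        # exactly ceil(0.20 * 5) = 1 qualifying sample out of 5
        counts = pd.DataFrame({"edge": [4, 0, 0, 0, 0]}, index=[f"s{i}" for i in range(5)])
        out = low_count_filter(AsvTable(counts), min_count=4, min_prevalence=0.20)
        assert out.asv_ids == ["edge"]

    def test_low_variance_filter_drops_constant_feature(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.integers(1, 40, size=(6, 10)),
            index=[f"s{i}" for i in range(6)],
            columns=[f"a{j:02d}" for j in range(10)],
        )
        counts["a05"] = 7  # IQR 0
        out = low_variance_filter(AsvTable(counts), drop_fraction=0.10)
        assert "a05" not in out.asv_ids
        assert out.n_asvs == 9

    def test_low_variance_filter_floor_rule(self, small_table):
        out = low_variance_filter(small_table, drop_fraction=0.10)  # floor(0.3) = 0
        assert out.asv_ids == small_table.asv_ids
        assert low_variance_filter(small_table, drop_fraction=0.0).asv_ids == small_table.asv_ids

    def test_low_variance_tie_break_is_lexicographic(self):
        counts = pd.DataFrame(
            {"b": [1, 1, 1], "a": [2, 2, 2], "c": [1, 5, 9]}, index=["s1", "s2", "s3"]
        )
        out = low_variance_filter(AsvTable(counts), drop_fraction=1 / 3)
        assert "a" not in out.asv_ids  # a and b tie at IQR 0; 'a' sorts first
        assert set(out.asv_ids) == {"b", "c"}

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_count_filters_idempotent_and_preserve_retained_counts(self, seed):
        table = random_asv_table(np.random.default_rng(seed), 6, 15, max_count=8)
        for filt in (
            lambda t: remove_rare_asvs(t, 2),
            lambda t: low_count_filter(t, 4, 0.2),
        ):
            once = filt(table)
            twice = filt(once)
            pd.testing.assert_frame_equal(once.counts, twice.counts)
            # retained submatrix untouched
            pd.testing.assert_frame_equal(once.counts, table.counts.loc[:, once.asv_ids])

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_low_variance_filter_size_contract(self, seed):
        # a rank-based trim: exactly floor(drop_fraction * n) features removed,
        # retained counts untouched
        table = random_asv_table(np.random.default_rng(seed), 6, 15, max_count=8)
        out = low_variance_filter(table, 0.1)
        assert out.n_asvs == table.n_asvs - int(np.floor(0.1 * table.n_asvs))
        pd.testing.assert_frame_equal(out.counts, table.counts.loc[:, out.asv_ids])

    def test_remove_rare_zero_cutoff_identity_without_empty_columns(self):
        counts = pd.DataFrame([[1, 0], [0, 2]], index=["s1", "s2"], columns=["a", "b"])
        out = remove_rare_asvs(AsvTable(counts), max_total=0)
        assert out.asv_ids == ["a", "b"]


class TestScalingAndAggregation:
    def test_total_sum_scaling_hand_example(self, small_table):
        rel = total_sum_scaling(small_table)
        assert np.allclose(rel.proportions.loc["s1"], [0.5, 0.25, 0.25])
        assert np.allclose(rel.proportions.sum(axis=1), 1.0)

    def test_total_sum_scaling_excludes_empty_sample_with_warning(self):
        counts = pd.DataFrame([[1, 1], [0, 0]], index=["s1", "s2"], columns=["a", "b"])
        with pytest.warns(UserWarning, match="zero-total"):
            rel = total_sum_scaling(AsvTable(counts))
        assert rel.sample_ids == ["s1"]

    def test_total_sum_scaling_all_empty_is_error(self):
        counts = pd.DataFrame([[0, 0]], index=["s1"], columns=["a", "b"])
        with pytest.raises(FeatureTableError, match="zero total"):
            total_sum_scaling(AsvTable(counts))

    def test_aggregate_sums_shared_genus(self, small_table, lachno_taxonomy):
        small_table.taxonomy = lachno_taxonomy
        out = aggregate_taxa(small_table, "genus")
        # a1 + a2 are Blautia: s1 has 2+1=3, s2 has 0+3=3
        assert out.counts.loc["s1", "Blautia"] == 3
        assert out.counts.loc["s2", "Blautia"] == 3

    def test_aggregate_pools_unassigned_under_parent(self, small_table, lachno_taxonomy):
        small_table.taxonomy = lachno_taxonomy
        out = aggregate_taxa(small_table, "genus")
        assert "unclassified Lachnospiraceae" in out.asv_ids
        assert out.counts.loc["s2", "unclassified Lachnospiraceae"] == 5

    def test_aggregate_conserves_sample_totals(self, small_table, lachno_taxonomy):
        small_table.taxonomy = lachno_taxonomy
        out = aggregate_taxa(small_table, "species")
        assert (out.counts.sum(axis=1) == small_table.counts.sum(axis=1)).all()

    def test_aggregate_requires_taxonomy(self, small_table):
        with pytest.raises(FeatureTableError, match="taxonomy"):
            aggregate_taxa(small_table, "genus")

    def test_collapse_other_absorbs_minor_taxa(self):
        props = pd.DataFrame(
            {"big": [0.982, 0.991], "tiny": [0.009, 0.009], "mid": [0.009, 0.0]},
            index=["s1", "s2"],
        )
        rel = RelAbundTable(props)
        out = collapse_other(rel, min_mean_abundance=0.01)
        assert set(out.taxon_ids) == {"big", "Other"}
        assert np.allclose(out.proportions.sum(axis=1), 1.0, atol=1e-9)

    def test_collapse_other_noop_when_all_major(self):
        props = pd.DataFrame({"x": [0.6], "y": [0.4]}, index=["s1"])
        out = collapse_other(RelAbundTable(props), min_mean_abundance=0.01)
        assert "Other" not in out.taxon_ids
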
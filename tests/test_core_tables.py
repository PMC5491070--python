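"""Count-table model, I/O, filtering, rarefaction and summaries."""

import numpy as np
import pandas as pd
import pytest

from orofaecal.core_tables import (CountTable, SampleMetadata, TaxonomyTable,
                                   filter_nonbacterial, prevalence_filter,
                                   rarefy, shared_otu_summary,
                                   taxon_rank_proportions)
from conftest import make_taxonomy


class TestCountTable:
    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError, match="duplicate"):
            CountTable(("s1", "s1"), ("A",), np.array([[1], [2]]))
        with pytest.raises(ValueError, match="duplicate"):
            CountTable(("s1", "s2"), ("A", "A"), np.array([[1, 1], [2, 2]]))

    def test_rejects_negative_and_empty_samples(self):
        with pytest.raises(ValueError, match="non-negative"):
            CountTable(("s1",), ("A",), np.array([[-1]]))
        with pytest.raises(ValueError, match="zero total"):
            CountTable(("s1", "s2"), ("A",), np.array([[1], [0]]))

    def test_counts_are_immutable(self, tiny_table):
        with pytest.raises(ValueError):
            tiny_table.counts[0, 0] = 99

    def test_tsv_roundtrip(self, tiny_table, tmp_path):
        path = tmp_path / "counts.tsv"
        tiny_table.to_tsv(path)
        back = CountTable.from_tsv(path)
        assert back.sample_ids == tiny_table.sample_ids
        assert back.otu_ids == tiny_table.otu_ids
        np.testing.assert_array_equal(back.counts, tiny_table.counts)

    def test_biom_tsv_dialect_tolerated(self, tmp_path):
        path = tmp_path / "biom.tsv"
        path.write_text("# Constructed from biom file\n"
                        "#OTU ID\ts1\ts2\nA\t3\t1\nB\t0\t2\n")
        t = CountTable.from_tsv(path)
        assert t.otu_ids == ("A", "B") and t.sample_ids == ("s1", "s2")
        np.testing.assert_array_equal(t.counts, [[3, 0], [1, 2]])


class TestMetadata:
    def test_one_sample_per_region_per_individual(self):
        with pytest.raises(ValueError, match=">1 sample"):
            SampleMetadata(pd.DataFrame({
                "sample_id": ["a", "b"],
                "individual_id": ["i1", "i1"],
                "region": ["oral", "oral"]}))

    def test_region_labels_validated(self):
        with pytest.raises(ValueError, match="region"):
            SampleMetadata(pd.DataFrame({
                "sample_id": ["a"], "individual_id": ["i"],
                "region": ["gut"]}))


class TestFilterNonbacterial:
    def test_flagged_taxa_removed(self):
        t = CountTable(("s1",), ("A", "B", "C"), np.array([[5, 3, 2]]))
        tax = make_taxonomy("ABC", {"B": "chloroplast", "C": "nophylum"})
        out = filter_nonbacterial(t, tax)
        assert out.otu_ids == ("A",)

    def test_streptophyta_order_matched_case_insensitively(self):
        t = CountTable(("s1",), ("A", "B"), np.array([[5, 3]]))
        tax = make_taxonomy("AB", {"B": "streptophyta"})
        assert filter_nonbacterial(t, tax).otu_ids == ("A",)

    def test_all_bacterial_table_unchanged(self, tiny_table):
        tax = make_taxonomy(tiny_table.otu_ids)
        out = filter_nonbacterial(tiny_table, tax)
        np.testing.assert_array_equal(out.counts, tiny_table.counts)

    def test_missing_taxonomy_names_the_otu(self, tiny_table):
        tax = make_taxonomy(["A", "B", "C"])  # D missing
        with pytest.raises(KeyError, match="D"):
            filter_nonbacterial(tiny_table, tax)

    def test_flagged_read_fraction_on_random_table(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 30, size=(8, 50))
        counts[:, 0] += 1  # keep rows non-empty
        otus = [f"O{k}" for k in range(50)]
        t = CountTable([f"s{k}" for k in range(8)], otus, counts)
        flagged = {o: "chloroplast" for o in otus[40:]}
        out = filter_nonbacterial(t, make_taxonomy(otus, flagged))
        assert out.n_otus == 40
        flagged_reads = counts[:, 40:].sum()
        kept = np.isin(t.otu_ids, out.otu_ids)
        assert counts[:, kept].sum() == counts.sum() - flagged_reads

    def test_idempotent(self, small_dataset):
        once = filter_nonbacterial(small_dataset.table, small_dataset.taxonomy)
        twice = filter_nonbacterial(once, small_dataset.taxonomy)
        assert twice.otu_ids == once.otu_ids
        np.testing.assert_array_equal(twice.counts, once.counts)

    def test_emptied_samples_dropped_with_warning(self, caplog):
        t = CountTable(("s1", "s2"), ("A", "B"), np.array([[5, 0], [0, 3]]))
        tax = make_taxonomy("AB", {"B": "chloroplast"})
        with caplog.at_level("WARNING", logger="orofaecal.core_tables"):
            out = filter_nonbacterial(t, tax)
        assert out.sample_ids == ("s1",)
        assert any("s2" in r.message for r in caplog.records)


class TestPrevalenceFilter:
    @pytest.mark.parametrize("present_in,kept", [(4, False), (5, True)])
    def test_threshold_boundary(self, present_in, kept):
        counts = np.ones((6, 2), dtype=int)
        counts[present_in:, 1] = 0
        t = CountTable([f"s{k}" for k in range(6)], ("keep", "rare"), counts)
        out = prevalence_filter(t, 5)
        assert ("rare" in out.otu_ids) is kept

    def test_matches_bruteforce_recount(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 4, size=(10, 30))
        counts[:, 0] += 1
        t = CountTable([f"s{k}" for k in range(10)],
                       [f"O{k}" for k in range(30)], counts)
        out = prevalence_filter(t, 4)
        expected = [o for j, o in enumerate(t.otu_ids)
                    if np.count_nonzero(counts[:, j]) >= 4]
        assert list(out.otu_ids) == expected

    def test_min_samples_one_drops_only_allzero_columns(self):
        counts = np.array([[1, 0, 2], [3, 0, 0]])
        t = CountTable(("s1", "s2"), ("A", "B", "C"), counts)
        assert prevalence_filter(t, 1).otu_ids == ("A", "C")

    def test_threshold_above_sample_count_errors(self, tiny_table):
        with pytest.raises(ValueError, match="exceeds"):
            prevalence_filter(tiny_table, 4)


class TestRarefy:
    def test_full_depth_identity(self, tiny_table):
        depth = int(tiny_table.sample_sums().min())
        out = rarefy(tiny_table, depth, seed=1)
        i = np.argmin(tiny_table.sample_sums())
        np.testing.assert_array_equal(out.counts[i], tiny_table.counts[i])

    def test_row_sums_exact_and_zeros_preserved(self, small_dataset):
        t = small_dataset.table
        depth = int(t.sample_sums().min())
        out = rarefy(t, depth, seed=5)
        assert np.all(out.sample_sums() == depth)
        assert np.all(out.counts[t.counts == 0] == 0)
        assert np.all(out.counts <= t.counts)

    def test_deterministic_and_pure(self, tiny_table):
        before = tiny_table.counts.copy()
        a = rarefy(tiny_table, 7, seed=3)
        b = rarefy(tiny_table, 7, seed=3)
        np.testing.assert_array_equal(a.counts, b.counts)
        np.testing.assert_array_equal(tiny_table.counts, before)

    def test_depth_error_lists_offenders(self, tiny_table):
        with pytest.raises(ValueError, match="s3"):
            rarefy(tiny_table, 12, seed=0)

    def test_hypergeometric_expectation(self):
        """Mean rarefied count over many seeds matches depth * proportion."""
        counts = np.array([[40, 25, 10, 5]])
        t = CountTable(("s1",), ("A", "B", "C", "D"), counts)
        depth = 20
        draws = np.array([rarefy(t, depth, seed=s).counts[0]
                          for s in range(2000)], dtype=float)
        total = counts.sum()
        expected = depth * counts[0] / total
        # exact hypergeometric variance per OTU
        var = (depth * (counts[0] / total) * (1 - counts[0] / total)
               * (total - depth) / (total - 1))
        se = np.sqrt(var / draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0) - expected) < 3 * se + 1e-9)


class TestSummaries:
    def test_shared_otu_counts_by_hand(self):
        counts = np.array([[3, 2, 0], [1, 0, 4]])
        t = CountTable(("o1", "f1"), ("both", "oral_only", "faecal_only"),
                       counts)
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": ["o1", "f1"], "individual_id": ["i1", "i2"],
            "region": ["oral", "faecal"]}))
        s = shared_otu_summary(t, meta)
        assert (s.n_both, s.n_oral_only, s.n_faecal_only) == (1, 1, 1)
        assert sum(s.fractions.values()) == pytest.approx(1.0)

    def test_shared_otu_matches_set_oracle(self, small_dataset):
        t, meta = small_dataset.table, small_dataset.metadata
        s = shared_otu_summary(t, meta)
        region = meta.region_of(t.sample_ids)
        oral = {o for j, o in enumerate(t.otu_ids)
                if t.counts[region == "oral", j].sum() > 0}
        faecal = {o for j, o in enumerate(t.otu_ids)
                  if t.counts[region == "faecal", j].sum() > 0}
        assert s.n_both == len(oral & faecal)
        assert s.n_oral_only == len(oral - faecal)
        assert s.n_faecal_only == len(faecal - oral)

    def test_single_region_errors(self):
        t = CountTable(("o1",), ("A",), np.array([[2]]))
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": ["o1"], "individual_id": ["i1"], "region": ["oral"]}))
        with pytest.raises(ValueError, match="both regions"):
            shared_otu_summary(t, meta)

    def test_taxon_proportions_sum_to_one_and_match_groupby(self, small_dataset):
        t, tax = small_dataset.table, small_dataset.taxonomy
        prop = taxon_rank_proportions(t, tax, "phylum")
        np.testing.assert_allclose(prop.sum(axis=1), 1.0)
        # brute-force group-sum oracle on one sample
        labels = tax.df.loc[list(t.otu_ids), "phylum"].replace("", "Unassigned")
        row = t.counts[0] / t.counts[0].sum()
        for label in set(labels):
            manual = row[(labels == label).to_numpy()].sum()
            assert prop.iloc[0][label] == pytest.approx(manual)

    def test_two_phyla_split(self):
        t = CountTable(("s1",), ("A", "B"), np.array([[60, 40]]))
        tax = make_taxonomy("AB")
        tax2 = TaxonomyTable(tax.df.assign(
            phylum=["Firmicutes", "Actinobacteria"]))
        prop = taxon_rank_proportions(t, tax2, "phylum")
        assert prop.loc["s1", "Firmicutes"] == pytest.approx(0.6)
        assert prop.loc["s1", "Actinobacteria"] == pytest.approx(0.4)
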
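"""Abundance-table operations: aggregation, filters, rarefaction, export."""

import numpy as np
import pandas as pd
import pytest

from rrnpipe.classify_em import RANKS
from rrnpipe.tables_export import (AbundanceTable, aggregate_species,
                                   apply_crosstalk_filter, export_phyloseq_csv,
                                   prevalence_filter, rarefy,
                                   read_phyloseq_csv, replay_filters)


def make_table(counts, taxonomy_rows, samples=None):
    counts = pd.DataFrame(counts).T
    counts.index.name = "taxid"
    tax = pd.DataFrame(taxonomy_rows).T.reindex(columns=RANKS, fill_value="")
    return AbundanceTable(counts, tax,
                          samples if samples is not None else pd.DataFrame())


@pytest.fixture
def simple_table():
    counts = {
        101: {"s1": 50, "s2": 60, "s3": 70},
        102: {"s1": 30, "s2": 20, "s3": 10},
        103: {"s1": 20, "s2": 20, "s3": 20},
    }
    tax = {
        101: {"genus": "Escherichia", "species": "Escherichia coli"},
        102: {"genus": "Escherichia", "species": "Escherichia coli"},
        103: {"genus": "Listeria", "species": "Listeria monocytogenes"},
    }
    return make_table(counts, tax)


class TestAggregateSpecies:
    def test_same_species_rows_summed(self, simple_table):
        out = aggregate_species(simple_table)
        assert out.counts.loc["Escherichia coli", "s1"] == 80
        assert len(out.counts) == 2

    def test_blank_species_becomes_unclassified(self):
        t = make_table({1: {"s1": 5}}, {1: {"genus": "Bacillus", "species": ""}})
        out = aggregate_species(t)
        assert list(out.counts.index) == ["Bacillus Unclassified"]

    def test_blank_genus_removed(self):
        t = make_table(
            {1: {"s1": 5}, 2: {"s1": 7}},
            {1: {"genus": "", "species": "orphan"},
             2: {"genus": "Bacillus", "species": "Bacillus subtilis"}})
        out = aggregate_species(t)
        assert list(out.counts.index) == ["Bacillus subtilis"]

    def test_logged(self, simple_table):
        out = aggregate_species(simple_table)
        assert out.filter_log[-1]["op"] == "aggregate_species"


class TestCrosstalkFilter:
    def test_below_threshold_zeroed(self):
        # one taxon at 0.005% of its sample, threshold 0.0073%
        t = make_table({1: {"s1": 999_950}, 2: {"s1": 50}},
                       {1: {"genus": "A", "species": "a"},
                        2: {"genus": "B", "species": "b"}})
        out = apply_crosstalk_filter(t, 7.3e-5)
        assert 2 not in out.counts.index  # zeroed then dropped
        assert out.counts.loc[1, "s1"] == 999_950

    def test_zero_threshold_no_change(self, simple_table):
        out = apply_crosstalk_filter(simple_table, 0.0)
        pd.testing.assert_frame_equal(out.counts, simple_table.counts)

    def test_exact_threshold_retained(self):
        t = make_table({1: {"s1": 9_927}, 2: {"s1": 73}},
                       {1: {"genus": "A", "species": "a"},
                        2: {"genus": "B", "species": "b"}})
        # taxon 2 sits exactly at 0.73%: strict < removal keeps it
        out = apply_crosstalk_filter(t, 73 / 10_000)
        assert out.counts.loc[2, "s1"] == 73

    def test_per_sample_semantics(self):
        t = make_table({1: {"s1": 1, "s2": 500}, 2: {"s1": 999, "s2": 500}},
                       {1: {"genus": "A", "species": "a"},
                        2: {"genus": "B", "species": "b"}})
        out = apply_crosstalk_filter(t, 0.01)
        assert out.counts.loc[1, "s1"] == 0  # 0.1% in s1: zeroed
        assert out.counts.loc[1, "s2"] == 500  # 50% in s2: kept

    def test_monotone_in_threshold(self, simple_table):
        zeroed = []
        for thr in (0.0, 0.1, 0.2, 0.3):
            out = apply_crosstalk_filter(simple_table, thr)
            full = out.counts.reindex(simple_table.counts.index,
                                      fill_value=0)
            zeroed.append(frozenset(zip(*np.nonzero(full.values == 0))))
        for a, b in zip(zeroed, zeroed[1:]):
            assert a <= b


class TestPrevalenceFilter:
    @pytest.mark.parametrize("row,kept", [
        ([6, 6, 6, 0], True),     # >5 in exactly 3 samples
        ([5, 5, 5, 5], False),    # never strictly >5
        ([100, 100, 0, 0], False),  # only 2 qualifying samples
        ([6, 6, 5, 6], True),
    ])
    def test_rule(self, row, kept):
        counts = {1: dict(zip("abcd", row)), 2: dict(zip("abcd", [9] * 4))}
        t = make_table(counts, {1: {"genus": "G", "species": "g s"},
                                2: {"genus": "H", "species": "h s"}})
        out = prevalence_filter(t, min_reads=5, min_samples=3)
        assert (1 in out.counts.index) is kept


class TestRarefy:
    @pytest.fixture
    def deep_table(self):
        rng = np.random.default_rng(0)
        counts = {t: {s: int(c) for s, c in
                      zip("abc", rng.integers(100, 5000, 3))}
                  for t in range(1, 6)}
        tax = {t: {"genus": "G", "species": f"G s{t}"} for t in range(1, 6)}
        return make_table(counts, tax)

    def test_column_sums_equal_depth(self, deep_table):
        out = rarefy(deep_table, depth=500, seed=1)
        assert (out.counts.sum(axis=0) == 500).all()

    def test_shallow_sample_dropped(self):
        t = make_table({1: {"s1": 800, "s2": 5000}},
                       {1: {"genus": "G", "species": "g s"}})
        with pytest.warns(UserWarning, match="s1"):
            out = rarefy(t, depth=1900, seed=1)
        assert list(out.counts.columns) == ["s2"]
        assert out.counts["s2"].sum() == 1900

    def test_subsample_bounded_and_deterministic(self, deep_table):
        out1 = rarefy(deep_table, depth=400, seed=7)
        out2 = rarefy(deep_table, depth=400, seed=7)
        pd.testing.assert_frame_equal(out1.counts, out2.counts)
        assert (out1.counts.values <=
                deep_table.counts.loc[out1.counts.index].values).all()

    def test_preserves_proportions_in_expectation(self):
        """Mean rarefied proportion within 3 SE of the original (1,000 draws)."""
        col = np.array([600, 300, 100])
        t = make_table({i + 1: {"s": int(c)} for i, c in enumerate(col)},
                       {i + 1: {"genus": "G", "species": f"g{i}"}
                        for i in range(3)})
        depth, n_draws = 200, 1000
        draws = np.stack([rarefy(t, depth, seed=k).counts["s"].to_numpy()
                          for k in range(n_draws)])
        p = col / col.sum()
        mean_prop = draws.mean(axis=0) / depth
        # SE of the mean over draws, hypergeometric variance with fpc
        fpc = (col.sum() - depth) / (col.sum() - 1)
        se = np.sqrt(p * (1 - p) / depth * fpc / n_draws)
        assert (np.abs(mean_prop - p) <= 3 * se + 1e-12).all()


class TestExportAndReplay:
    def test_csv_shapes_and_roundtrip(self, simple_table, tmp_path):
        agg = aggregate_species(simple_table)
        paths = export_phyloseq_csv(agg, tmp_path)
        otu = pd.read_csv(paths["otu"], index_col=0)
        assert otu.shape == (2, 3)
        back = read_phyloseq_csv(tmp_path)
        assert np.allclose(back.counts.values, agg.counts.values)
        assert list(back.counts.index) == list(agg.counts.index)

    def test_empty_table_exports_headers(self, tmp_path):
        t = AbundanceTable(
            pd.DataFrame(index=pd.Index([], name="taxid")),
            pd.DataFrame(columns=list(RANKS)))
        paths = export_phyloseq_csv(t, tmp_path)
        assert paths["otu"].exists()

    def test_replay_reproduces_final_table(self, mock_pipeline_result):
        res = mock_pipeline_result
        replayed = replay_filters(res.raw_table, res.table.filter_log)
        pd.testing.assert_frame_equal(replayed.counts, res.table.counts)

    def test_filter_log_append_only(self, simple_table):
        t1 = aggregate_species(simple_table)
        t2 = prevalence_filter(t1, 5, 3)
        assert [e["op"] for e in t2.filter_log] == \
               [e["op"] for e in t1.filter_log] + ["prevalence_filter"]
        assert simple_table.filter_log == []
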
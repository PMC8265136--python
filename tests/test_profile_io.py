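"""Profile parsing, rank filtering, stratification splitting, renormalisation
and viral presence calling."""

import numpy as np
import pandas as pd
import pytest

from mgmwas import profile_io
from mgmwas.exceptions import DataError, FormatError
from mgmwas.profile_io import (
    AbundanceTable,
    DepthTable,
    TaxonLineage,
    aggregate_to_ranks,
    call_viral_presence,
    filter_by_rank,
    parse_stratification,
    renormalize,
    split_stratified,
)

from conftest import make_table


class TestLineage:
    def test_parse_and_terminal_rank(self):
        lin = TaxonLineage.parse("k__Bacteria|p__Firmicutes")
        assert lin.terminal_rank == "phylum"
        assert lin.terminal_name == "Firmicutes"
        assert str(lin) == "k__Bacteria|p__Firmicutes"

    @pytest.mark.parametrize(
        "bad", ["p__Firmicutes|k__Bacteria", "k__B|c__C", "x__Nope", "k__B|p__P|p__Q"]
    )
    def test_malformed_rank_order_rejected(self, bad):
        with pytest.raises(FormatError):
            TaxonLineage.parse(bad)


class TestReadWrite:
    def test_read_metaphlan_table(self, tmp_path):
        path = tmp_path / "taxa.tsv"
        path.write_text(
            "# merged abundance table\n"
            "ID\tS1\tS2\n"
            "k__Bacteria|p__Firmicutes\t10\t20\n"
            "k__Bacteria|p__Bacteroidetes\t90\t80\n"
        )
        table = profile_io.read_taxonomic_table(path, units="raw")
        assert table.feature_ranks().tolist() == ["phylum", "phylum"]
        assert table.data.loc["k__Bacteria|p__Firmicutes"].tolist() == [10, 20]
        # percent units are converted to fractions and flagged relative
        rel = profile_io.read_taxonomic_table(path, units="percent")
        assert rel.normalization == "relative"
        assert np.allclose(rel.data.sum(axis=0), 1.0)

    def test_duplicate_and_negative_rejected(self, tmp_path):
        dup = tmp_path / "dup.tsv"
        dup.write_text("ID\tS1\nk__B\t1\nk__B\t2\n")
        with pytest.raises(FormatError):
            profile_io.read_taxonomic_table(dup)
        neg = tmp_path / "neg.tsv"
        neg.write_text("ID\tS1\nk__B\t-1\n")
        with pytest.raises(FormatError):
            profile_io.read_taxonomic_table(neg)

    def test_round_trip_is_lossless(self, tmp_path):
        rng = np.random.default_rng(42)
        features = [f"k__B|p__P{i}" for i in range(5)]
        table = AbundanceTable(
            pd.DataFrame(rng.random((5, 3)), index=features, columns=["a", "b", "c"]),
            has_lineages=True,
        )
        path = tmp_path / "t.tsv"
        profile_io.write_taxonomic_table(table, path)
        back = profile_io.read_taxonomic_table(path, units="raw")
        pd.testing.assert_frame_equal(table.data, back.data)

    def test_gene_family_round_trip(self, tmp_path):
        ids = ["UniRef90_A", "UniRef90_A|g__G.s__Sp", "PWY-1: something"]
        table = AbundanceTable(
            pd.DataFrame([[1.0, 2.0], [0.5, 0.25], [3.0, 4.0]], index=ids, columns=["x", "y"])
        )
        path = tmp_path / "g.tsv"
        profile_io.write_gene_family_table(table, path)
        back = profile_io.read_gene_family_table(path)
        pd.testing.assert_frame_equal(table.data, back.data)

    def test_metadata_round_trip_and_validation(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "sample\tgroup\tachrab\tage\tgender\tbirth_mode\n"
            "MG1\tcase\t3.2\t6.5\tF\tVD\n"
            "HC1\tcontrol\t0.1\t7.0\tM\tCS\n"
        )
        meta = profile_io.read_metadata(path)
        assert meta.case_ids() == ["MG1"]
        bad = tmp_path / "bad.tsv"
        bad.write_text("sample\tgroup\nS1\tpatient\n")
        with pytest.raises(FormatError):
            profile_io.read_metadata(bad)


class TestRankOperations:
    @pytest.fixture
    def mixed(self):
        return make_table(
            {
                "k__B|p__P1": [1.0, 2.0],
                "k__B|p__P1|c__C|o__O|f__F|g__G": [3.0, 4.0],
                "k__B|p__P1|c__C|o__O|f__F|g__G|s__S1": [5.0, 6.0],
                "k__B|p__P1|c__C|o__O|f__F|g__G|s__S2": [1.0, 1.0],
            },
            has_lineages=True,
        )

    def test_filter_by_rank(self, mixed):
        sp = filter_by_rank(mixed, "species")
        assert all(f.split("|")[-1].startswith("s__") for f in sp.features)
        assert len(sp.features) == 2
        with pytest.raises(ValueError):
            filter_by_rank(mixed, "strain")

    def test_rank_filters_partition_features(self, mixed):
        seen = []
        for rank in profile_io.RANKS:
            seen.extend(filter_by_rank(mixed, rank).features)
        assert sorted(seen) == sorted(mixed.features)

    def test_aggregate_to_ranks_sums_children(self):
        table = make_table(
            {
                "k__B|p__P1|c__C1|o__O1|f__F1|g__G1|s__S1": [0.2, 0.5],
                "k__B|p__P1|c__C1|o__O1|f__F1|g__G1|s__S2": [0.3, 0.1],
                "k__B|p__P2|c__C2|o__O2|f__F2|g__G2|s__S3": [0.5, 0.4],
            },
            has_lineages=True,
            normalization="relative",
        )
        combined = aggregate_to_ranks(table)
        assert combined.data.loc["k__B|p__P1"].tolist() == [0.5, 0.6]
        genus = filter_by_rank(combined, "genus")
        assert np.allclose(genus.data.sum(axis=0), 1.0)


class TestStratification:
    def test_split_examples(self):
        table = make_table(
            {
                "PWY-6588: pyruvate fermentation to acetone": [1.0],
                "UniRef90_X|g__Prevotella.s__Prevotella_copri": [2.0],
                "UniRef90_X|unclassified": [3.0],
            }
        )
        unstrat, strat = split_stratified(table)
        assert unstrat.features == ["PWY-6588: pyruvate fermentation to acetone"]
        assert len(strat.features) == 2
        assert parse_stratification(strat.features[0]) == ("UniRef90_X", "Prevotella_copri")
        assert parse_stratification("UniRef90_X|unclassified")[1] == "unclassified"

    def test_empty_table(self):
        empty = AbundanceTable(pd.DataFrame(index=pd.Index([], dtype=object), columns=["S1"]).astype(float))
        unstrat, strat = split_stratified(empty)
        assert not unstrat.features and not strat.features


class TestRenormalize:
    def test_column_closure(self):
        table = make_table({"a": [2.0, 1.0], "b": [2.0, 3.0]})
        rel = renormalize(table)
        assert np.allclose(rel.data.sum(axis=0), 1.0)
        assert rel.data.iloc[:, 0].tolist() == [0.5, 0.5]
        pct = renormalize(table, "percent")
        assert np.allclose(pct.data.sum(axis=0), 100.0)

    def test_idempotent_and_permutation_independent(self):
        rng = np.random.default_rng(7)
        table = make_table({f"f{i}": rng.random(4).tolist() for i in range(6)})
        once = renormalize(table)
        twice = renormalize(once)
        pd.testing.assert_frame_equal(once.data, twice.data)
        perm = AbundanceTable(table.data.sample(frac=1, random_state=1))
        again = renormalize(perm)
        pd.testing.assert_frame_equal(once.data.sort_index(), again.data.sort_index())

    def test_zero_sum_sample_named_in_error(self):
        table = make_table({"a": [1.0, 0.0], "b": [1.0, 0.0]})
        with pytest.raises(DataError, match="S2"):
            renormalize(table)


class TestViralPresence:
    def test_threshold_is_strict(self):
        depths = DepthTable(
            pd.DataFrame(
                {
                    "sample": ["s1", "s2", "s3"],
                    "reference": ["adv_F"] * 3,
                    "mean_depth": [2.5, 2.0, 0.0],
                }
            )
        )
        calls = call_viral_presence(depths)
        assert calls == {("s1", "adv_F")}
        with pytest.raises(ValueError):
            call_viral_presence(depths, min_mean_depth=-1.0)
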
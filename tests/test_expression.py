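import numpy as np
import pandas as pd
import pytest

from tirscope.expression import (
    CountsTable,
    ExpressionError,
    assign_octiles,
    build_expression_table,
    combine_replicates,
    compute_ard,
    normalize_cpm,
    read_counts_table,
    replicate_spearman,
    select_representative_set,
    synthesis_rates,
    write_counts_table,
)


def make_table(counts: dict, assay="rna", columns=None):
    df = pd.DataFrame(counts).T if columns is None else pd.DataFrame(
        counts, index=columns
    ).T
    return CountsTable(assay, df)


class TestCombineReplicates:
    def test_sums_across_tables_and_columns(self):
        t1 = CountsTable("rna", pd.DataFrame({"r1": {"g": 2}}))
        t2 = CountsTable("rna", pd.DataFrame({"r2": {"g": 3}, "r3": {"g": 5}}))
        combined = combine_replicates([t1, t2])
        assert combined.counts.loc["g", "combined"] == 10

    def test_single_replicate_identity(self):
        t = CountsTable("ribo", pd.DataFrame({"r1": {"g": 7}}))
        assert combine_replicates([t]).counts.loc["g", "combined"] == 7

    def test_mismatches_rejected(self):
        t1 = CountsTable("rna", pd.DataFrame({"r1": {"g": 2}}))
        t2 = CountsTable("ribo", pd.DataFrame({"r1": {"g": 2}}))
        with pytest.raises(ExpressionError, match="assay"):
            combine_replicates([t1, t2])
        t3 = CountsTable("rna", pd.DataFrame({"r1": {"other": 2}}))
        with pytest.raises(ExpressionError, match="gene universe"):
            combine_replicates([t1, t3])


class TestRepresentativeSet:
    def test_genome_scale_top_third(self):
        """5138 genes at fraction 1/3 select exactly 1712."""
        n = 5138
        counts = pd.DataFrame({"r": np.arange(1, n + 1)},
                              index=[f"g{i:05d}" for i in range(n)])
        table = CountsTable("rna", counts)
        lengths = {f"g{i:05d}": 900 for i in range(n)}
        rep = select_representative_set(table, lengths, 1.0 / 3.0)
        assert len(rep) == 1712

    def test_ranking_is_by_density_not_raw_count(self):
        table = make_table({"a": [100], "b": [100], "c": [10]}, columns=["r"])
        lengths = {"a": 100, "b": 200, "c": 20}
        rep = select_representative_set(table, lengths, 1.0 / 3.0)
        assert rep == ["a"]  # density 1.0 beats 0.5 (b) and 0.5 (c)

    def test_tie_at_cut_broken_by_gene_id(self):
        table = make_table({"b": [10], "a": [10], "c": [1]}, columns=["r"])
        lengths = {"a": 10, "b": 10, "c": 10}
        rep = select_representative_set(table, lengths, 1.0 / 3.0)
        assert rep == ["a"]

    def test_zero_density_genes_never_selected(self):
        table = make_table({"a": [5], "b": [0], "c": [0]}, columns=["r"])
        lengths = {"a": 10, "b": 10, "c": 10}
        rep = select_representative_set(table, lengths, 1.0)
        assert rep == ["a"]


class TestCPM:
    def test_unit_scale(self):
        counts = pd.DataFrame({"r": {"a": 50, "b": 10**6 - 50}})
        table = CountsTable("rna", counts)
        cpm = normalize_cpm(table, ["a", "b"])
        assert cpm["a"] == pytest.approx(50.0)

    def test_scale_invariance_and_outside_gene_covered(self):
        counts = pd.DataFrame({"r": {"a": 10, "b": 30, "c": 5}})
        t1 = CountsTable("rna", counts)
        t2 = CountsTable("rna", counts * 2)
        rep = ["a", "b"]
        assert normalize_cpm(t1, rep).equals(normalize_cpm(t2, rep))
        assert normalize_cpm(t1, rep)["c"] == pytest.approx(5 * 1e6 / 40)

    def test_representative_cpm_sums_to_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame({"r": rng.integers(1, 1000, 100)},
                              index=[f"g{i}" for i in range(100)])
        table = CountsTable("rna", counts)
        rep = [f"g{i}" for i in range(0, 100, 3)]
        assert normalize_cpm(table, rep)[rep].sum() == pytest.approx(1e6, rel=1e-9)

    def test_zero_total_rejected(self):
        table = make_table({"a": [0]}, columns=["r"])
        with pytest.raises(ExpressionError):
            normalize_cpm(table, ["a"])


class TestARD:
    def test_hand_computed_ratios(self):
        rna = pd.Series({"a": 10.0, "b": 5.0, "c": 0.0, "d": 8.0, "e": 2.0, "f": 1.0})
        ribo = pd.Series({"a": 10.0, "b": 20.0, "c": 3.0, "d": 0.0, "e": 1.0, "f": 9.0})
        ard = compute_ard(rna, ribo)
        assert ard["a"] == pytest.approx(1.0)
        assert ard["b"] == pytest.approx(4.0)
        assert np.isnan(ard["c"])  # undefined, not infinite
        assert ard["d"] == pytest.approx(0.0)
        assert ard["f"] == pytest.approx(9.0)

    def test_invariant_to_common_scaling(self):
        rna = pd.Series({"a": 4.0, "b": 2.0})
        ribo = pd.Series({"a": 1.0, "b": 6.0})
        assert compute_ard(rna * 7, ribo * 7).equals(compute_ard(rna, ribo))


class TestOctiles:
    @pytest.mark.parametrize("n,size", [(1712, 214), (1440, 180), (1392, 174)])
    def test_standard_set_sizes_divide_evenly(self, n, size):
        ard = pd.Series(np.linspace(10, 1, n), index=[f"g{i:05d}" for i in range(n)])
        octiles = assign_octiles(ard, list(ard.index))
        assert octiles.value_counts().eq(size).all()
        assert len(octiles) == n

    def test_remainder_genes_unassigned(self):
        ard = pd.Series(np.arange(17, dtype=float), index=[f"g{i:02d}" for i in range(17)])
        octiles = assign_octiles(ard, list(ard.index))
        assert len(octiles) == 16  # one remainder gene dropped
        assert octiles.value_counts().eq(2).all()
        # the dropped gene is the lowest-ARD one
        assert "g00" not in octiles.index

    def test_octile_1_is_highest_ard_and_ranges_disjoint(self):
        rng = np.random.default_rng(1)
        ard = pd.Series(rng.lognormal(size=80), index=[f"g{i:02d}" for i in range(80)])
        octiles = assign_octiles(ard, list(ard.index))
        ranges = {
            o: (ard[octiles[octiles == o].index].min(),
                ard[octiles[octiles == o].index].max())
            for o in range(1, 9)
        }
        for o in range(1, 8):
            assert ranges[o][0] >= ranges[o + 1][1]

    def test_too_few_genes_rejected(self):
        ard = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ExpressionError):
            assign_octiles(ard, ["a", "b"])


class TestSynthesisRates:
    def test_proportional_to_coverage_per_length(self):
        table = make_table({"a": [100], "b": [100]}, assay="ribo", columns=["r"])
        rates = synthesis_rates(table, {"a": 100, "b": 200})
        assert rates["a"] / rates["b"] == pytest.approx(2.0)
        assert rates.sum() == pytest.approx(1e6)

    def test_single_gene_and_zero_count(self):
        table = make_table({"a": [5], "b": [0]}, assay="ribo", columns=["r"])
        rates = synthesis_rates(table, {"a": 10, "b": 10})
        assert rates["a"] == pytest.approx(1e6)
        assert rates["b"] == 0.0


class TestReplicateSpearman:
    def test_duplicate_replicate_is_perfectly_correlated(self):
        counts = pd.DataFrame({"r1": np.arange(10) + 1, "r2": np.arange(10) + 1})
        out = replicate_spearman(CountsTable("rna", counts))
        assert out.loc["r1", "r2"] == pytest.approx(1.0)

    def test_shuffled_counts_are_uncorrelated(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 10_000, 1000)
        counts = pd.DataFrame({"r1": base, "r2": rng.permutation(base)})
        out = replicate_spearman(CountsTable("rna", counts))
        assert abs(out.loc["r1", "r2"]) < 0.08  # ~3 sigma for n=1000

    def test_three_replicates_give_three_pairs(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(1, 100, (50, 3)), columns=list("abc"))
        out = replicate_spearman(CountsTable("rna", counts))
        upper = out.values[np.triu_indices(3, 1)]
        assert len(upper) == 3 and np.isfinite(upper).all()


class TestRoundTripAndPipelineTable:
    def test_counts_tsv_round_trip(self, tmp_path):
        counts = pd.DataFrame({"r1": {"a": 3, "b": 0}, "r2": {"a": 1, "b": 9}})
        table = CountsTable("rna", counts)
        p = tmp_path / "counts.tsv"
        write_counts_table(p, table)
        again = read_counts_table(p, "rna")
        pd.testing.assert_frame_equal(again.counts, table.counts,
                                      check_names=False)

    def test_full_table_recovers_planted_efficiency(self, small_bundle):
        from tirscope.stats_core import spearman

        _, bundle, rna, ribo = small_bundle
        table = build_expression_table([rna], [ribo], bundle.annotations,
                                       fraction=1.0 / 3.0)
        truth = bundle.ground_truth.frame()
        rep = table[table["representative"] & table["ard"].notna()]
        r = spearman(rep["ard"].values,
                     truth.loc[rep.index, "true_efficiency"].values)
        assert r > 0.85
        assert table["octile"].notna().sum() == (len(rep) // 8) * 8
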
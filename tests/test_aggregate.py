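import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import triadbalance as tb
from conftest import make_matrix
from oracles import brute_force_totals


class TestMeanTpmPerLocus:
    def test_mean_of_two_samples(self):
        m = make_matrix([("L1", "s1", 2.0), ("L1", "s2", 4.0)])
        assert tb.mean_tpm_per_locus(m) == {"L1": 3.0}

    def test_single_sample_is_identity(self):
        m = make_matrix([("L1", "s1", 7.5)])
        assert tb.mean_tpm_per_locus(m)["L1"] == 7.5

    def test_empty_selection_is_an_error(self):
        m = make_matrix([("L1", "s1", 1.0)])
        with pytest.raises(tb.AggregationError, match="no samples"):
            tb.mean_tpm_per_locus(m, {"tissue": "root"})

    def test_negative_tpm_rejected_at_construction(self):
        with pytest.raises(tb.AggregationError, match="negative"):
            make_matrix([("L1", "s1", -1.0)])

    def test_duplicate_cell_rejected_at_construction(self):
        with pytest.raises(tb.AggregationError, match="duplicate"):
            make_matrix([("L1", "s1", 1.0), ("L1", "s1", 2.0)])

    def test_missing_cell_is_an_error_unless_fill_requested(self):
        records = [("L1", "s1", 1.0), ("L1", "s2", 3.0), ("L2", "s1", 5.0)]
        with pytest.raises(tb.AggregationError, match="missing"):
            tb.mean_tpm_per_locus(make_matrix(records))
        means = tb.mean_tpm_per_locus(make_matrix(records, fill_missing=True))
        assert means == {"L1": 2.0, "L2": 2.5}

    def test_study_stratified_mean_weights_studies_equally(self):
        meta = pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3"],
                "study": ["st1", "st1", "st2"],
                "tissue": "leaf",
                "condition": "control",
            }
        ).set_index("sample_id")
        m = make_matrix([("L1", "s1", 0.0), ("L1", "s2", 2.0), ("L1", "s3", 10.0)], meta=meta)
        assert tb.mean_tpm_per_locus(m)["L1"] == pytest.approx(4.0)  # pooled
        assert tb.mean_tpm_per_locus(m, stratify_by_study=True)["L1"] == pytest.approx(5.5)

    def test_callable_filter(self):
        meta = pd.DataFrame(
            {
                "sample_id": ["s1", "s2"],
                "study": "st",
                "tissue": ["leaf", "spike"],
                "condition": "control",
            }
        ).set_index("sample_id")
        m = make_matrix([("L1", "s1", 1.0), ("L1", "s2", 9.0)], meta=meta)
        assert tb.mean_tpm_per_locus(m, lambda row: row["tissue"] == "spike") == {"L1": 9.0}


class TestSubgenomeTotals:
    def test_cpn60_two_locus_sum(self, table2_registry):
        """Total A expression of a two-copy gene is the sum of its two A loci."""
        means = {e.locus.raw_id: 0.0 for e in table2_registry.entries}
        means["TraesCS4A02G315500"] = 3.0
        means["TraesCS5A02G366800"] = 5.0
        totals = tb.subgenome_totals(means, table2_registry, "Cpn60")
        assert totals == (8.0, 0.0, 0.0)

    def test_single_locus_gene_is_identity(self, table2_registry):
        means = {e.locus.raw_id: 1.0 for e in table2_registry.entries}
        means["TraesCS7A02G341000"] = 2.5
        assert tb.subgenome_totals(means, table2_registry, "Bsd2") == (2.5, 1.0, 1.0)

    def test_override_locus_counts_toward_assigned_subgenome(self, table2_registry):
        means = {e.locus.raw_id: 0.0 for e in table2_registry.entries}
        means["TraesCSU02G129700"] = 4.0  # Raf2 unplaced locus, assigned to D
        assert tb.subgenome_totals(means, table2_registry, "Raf2") == (0.0, 0.0, 4.0)

    def test_all_zero_gives_zero_totals(self, table2_registry):
        means = {e.locus.raw_id: 0.0 for e in table2_registry.entries}
        assert tb.subgenome_totals(means, table2_registry, "Rca1") == (0.0, 0.0, 0.0)

    def test_missing_locus_error_lists_ids(self, table2_registry):
        with pytest.raises(tb.AggregationError, match="TraesCS4A02G315500"):
            tb.subgenome_totals({}, table2_registry, "Cpn60")


class TestFractionsAndLog2:
    @pytest.mark.parametrize(
        "totals,expected",
        [
            ((10, 10, 10), (1 / 3, 1 / 3, 1 / 3)),
            ((0, 5, 5), (0.0, 0.5, 0.5)),
            ((22, 23, 55), (0.22, 0.23, 0.55)),
        ],
    )
    def test_examples(self, totals, expected):
        assert tb.relative_fractions(totals) == pytest.approx(expected, abs=1e-12)

    def test_zero_total_is_an_error(self):
        with pytest.raises(tb.AggregationError, match="undefined"):
            tb.relative_fractions((0, 0, 0))

    def test_negative_total_is_an_error(self):
        with pytest.raises(tb.AggregationError):
            tb.relative_fractions((-1, 2, 3))

    @settings(derandomize=True, max_examples=300)
    @given(
        st.tuples(
            st.floats(0, 1e6, allow_nan=False),
            st.floats(0, 1e6, allow_nan=False),
            st.floats(0, 1e6, allow_nan=False),
        ).filter(lambda t: sum(t) > 0)
    )
    def test_fractions_sum_to_one(self, totals):
        assert sum(tb.relative_fractions(totals)) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("totals,expected", [((1, 1, 2), 2.0), ((1024, 0, 0), 10.0)])
    def test_log2_examples(self, totals, expected):
        assert tb.log2_total(totals) == expected

    def test_log2_zero_total_is_an_error(self):
        with pytest.raises(tb.AggregationError):
            tb.log2_total((0, 0, 0))


def _random_small_dataset(rng):
    n_genes = rng.integers(1, 4)
    genes = tuple(
        tb.GeneSpec(
            f"G{i}",
            loci_per_subgenome=tuple(rng.integers(1, 3, size=3)),
            true_fractions=tuple(rng.dirichlet([2, 2, 2])),
            base_total_tpm=float(rng.uniform(1, 200)),
        )
        for i in range(n_genes)
    )
    spec = tb.SimulationSpec(
        genes=genes, n_samples=int(rng.integers(1, 6)), noise_cv=0.4, seed=int(rng.integers(2**31))
    )
    return spec


class TestAnalyzeGeneSet:
    def test_totals_match_brute_force_double_loop(self, rng):
        """Pipeline totals equal an independent record-by-record recomputation."""
        for _ in range(10):
            spec = _random_small_dataset(rng)
            registry_df, matrix, _ = tb.simulate_dataset(spec)
            registry = tb.load_registry(registry_df)
            results, _ = tb.analyze_gene_set(matrix, registry, [tb.Context("leaf", "control")])
            locus_sg = {
                e.locus.raw_id: e.effective_subgenome
                for e in registry.entries
            }
            records = list(matrix.values.itertuples(index=False, name=None))
            samples = set(matrix.samples.index)
            for r in results:
                gene_loci = {
                    l: sg for l, sg in locus_sg.items()
                    if l in {e.locus.raw_id for e in registry.entries if e.gene_name == r.gene_name}
                }
                expected = brute_force_totals(records, gene_loci, samples)
                assert r.totals == pytest.approx(expected, rel=1e-12)

    def test_linearity_under_tpm_rescaling(self, rng):
        spec = _random_small_dataset(rng)
        registry_df, matrix, _ = tb.simulate_dataset(spec)
        registry = tb.load_registry(registry_df)
        scaled = tb.ExpressionMatrix(
            values=matrix.values.assign(tpm=matrix.values["tpm"] * 7.0),
            samples=matrix.samples,
        )
        ctx = [tb.Context("leaf", "control")]
        base, _ = tb.analyze_gene_set(matrix, registry, ctx)
        big, _ = tb.analyze_gene_set(scaled, registry, ctx)
        for r0, r7 in zip(base, big):
            assert r7.totals == pytest.approx(tuple(7.0 * t for t in r0.totals), rel=1e-12)
            assert r7.fractions == pytest.approx(r0.fractions, abs=1e-12)

    def test_subgenome_relabelling_swaps_fractions(self):
        """Swapping the A and B assignments of every locus swaps fA and fB."""
        table = pd.DataFrame(
            {
                "gene_name": ["G"] * 3,
                "gene_id": ["TraesCS1A02G000100", "TraesCS1B02G000200", "TraesCS1D02G000300"],
            }
        )
        reg = tb.load_registry(table)
        swapped = tb.load_registry(
            table,
            overrides={"TraesCS1A02G000100": "B", "TraesCS1B02G000200": "A"},
        )
        m = make_matrix(
            [("TraesCS1A02G000100", "s1", 10.0),
             ("TraesCS1B02G000200", "s1", 30.0),
             ("TraesCS1D02G000300", "s1", 60.0)]
        )
        ctx = [tb.Context("leaf", "control")]
        (r,), _ = tb.analyze_gene_set(m, reg, ctx)
        (rs,), _ = tb.analyze_gene_set(m, swapped, ctx)
        assert (rs.frac_a, rs.frac_b, rs.frac_d) == (r.frac_b, r.frac_a, r.frac_d)

    def test_zero_total_pairs_reported_not_dropped_silently(self, table2_registry):
        records = [(e.locus.raw_id, "s1", 0.0) for e in table2_registry.entries]
        records = [
            (l, s, 1.0) if l.startswith("TraesCS7A02G341") else (l, s, t)
            for l, s, t in records
        ]  # only Bsd2-A expressed
        m = make_matrix(records)
        results, dropped = tb.analyze_gene_set(m, table2_registry, [tb.Context("leaf", "control")])
        assert [r.gene_name for r in results] == ["Bsd2"]
        assert ("Rca1", ("leaf", "control")) in dropped
        assert len(results) + len(dropped) == 11

    def test_one_gene_one_context_singleton(self, mixed_category_spec):
        registry_df, matrix, _ = tb.simulate_dataset(mixed_category_spec)
        registry = tb.load_registry(registry_df)
        results, dropped = tb.analyze_gene_set(
            matrix, registry, [tb.Context("leaf", "control")], genes=["GeneBal"]
        )
        assert len(results) == 1 and not dropped
        assert results[0].n_samples == mixed_category_spec.n_samples
        assert results[0].log2_total == pytest.approx(math.log2(60.0))
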
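"""Unit and property tests for the enrichment statistic and its inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmea import (
    EnrichmentParams,
    MOACatalog,
    NullDistribution,
    RankedDrugList,
    ValidationError,
)
from dmea.core import (
    catalog_from_annotations,
    drug_sea,
    enrichment_score,
    fdr_adjust,
    null_distribution,
    prepare,
    significance,
)

from conftest import brute_force_es


class TestEnrichmentScore:
    @pytest.mark.parametrize(
        "members, expected_es",
        [({"A", "B"}, 1.0), ({"E", "F"}, -1.0), ({"A", "D"}, 0.75)],
    )
    def test_hand_computed_values(self, toy_list, members, expected_es):
        es, running, edge = enrichment_score(toy_list, members)
        assert es == expected_es
        assert len(running) == len(toy_list)
        assert set(edge) <= members

    def test_leading_edge_sides(self, toy_list):
        _, _, edge_pos = enrichment_score(toy_list, {"A", "B"})
        assert edge_pos == ("A", "B")  # members at/before the maximum
        _, _, edge_neg = enrichment_score(toy_list, {"E", "F"})
        assert edge_neg == ("E", "F")  # members at/after the minimum

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(4, 21))
            nh = int(rng.integers(1, min(8, n - 1) + 1))
            ranks = rng.normal(0, 1, n)
            ranks[ranks == 0] = 0.5
            drugs = tuple(f"d{i}" for i in range(n))
            members = set(rng.choice(drugs, nh, replace=False))
            rlist = RankedDrugList(drugs, ranks).sort_descending()
            es, _, _ = enrichment_score(rlist, members)
            oracle = brute_force_es(drugs, ranks, members)
            # the two implementations sum in different orders, so agreement
            # is to within accumulated rounding (~1e-15), far below any
            # reported precision
            assert es == pytest.approx(oracle, abs=1e-12)
            assert np.sign(es) == np.sign(oracle)

    def test_degenerate_sets_rejected(self, toy_list):
        with pytest.raises(ValidationError):
            enrichment_score(toy_list, set())
        with pytest.raises(ValidationError):
            enrichment_score(toy_list, set(toy_list.drugs))
        with pytest.raises(ValidationError):
            enrichment_score(toy_list, {"A", "not_in_list"})

    @given(
        ranks=st.lists(
            st.floats(-10, 10).filter(lambda x: abs(x) > 1e-6),
            min_size=4,
            max_size=15,
            unique=True,
        ),
        data=st.data(),
        alpha=st.sampled_from([0.0, 0.5, 1.0, 2.0]),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_antisymmetric(self, ranks, data, alpha):
        """|ES| <= 1 always, and negating every rank negates the ES."""
        drugs = tuple(f"d{i}" for i in range(len(ranks)))
        nh = data.draw(st.integers(1, len(ranks) - 1))
        members = set(drugs[:nh])
        arr = np.array(ranks)
        es, running, _ = enrichment_score(
            RankedDrugList(drugs, arr).sort_descending(), members, alpha
        )
        es_neg, _, _ = enrichment_score(
            RankedDrugList(drugs, -arr).sort_descending(), members, alpha
        )
        assert abs(es) <= 1.0 + 1e-12
        assert abs(es_neg) == pytest.approx(abs(es), abs=1e-9)
        # the sign flips whenever the extremum is unambiguous (an exact
        # magnitude tie between the max and min may resolve either way)
        if abs(running.max() + running.min()) > 1e-9:
            assert es_neg == pytest.approx(-es, abs=1e-9)

    def test_top_block_gives_plus_one(self):
        drugs = tuple(f"d{i}" for i in range(10))
        ranks = np.linspace(5, 0.5, 10)
        rlist = RankedDrugList(drugs, ranks).sort_descending()
        es, _, _ = enrichment_score(rlist, set(drugs[:3]))
        assert es == pytest.approx(1.0)


class TestPrepare:
    def test_small_sets_removed_and_reported(self, toy_list):
        catalog = MOACatalog(
            {
                "big": frozenset({"A", "B", "C"}),
                "ok": frozenset({"D", "E"}),
                "small": frozenset({"F"}),
            }
        )
        params = EnrichmentParams(min_per_set=2, n_permutations=10)
        _, kept, report = prepare(toy_list, catalog, params)
        assert set(kept.sets) == {"big", "ok"}
        assert report.removed_sets == {"small": 1}

    def test_zero_rank_names_drug(self, small_catalog):
        rlist = RankedDrugList(("A", "B", "C", "D", "E", "F"),
                               np.array([1.0, 0.0, 2.0, -1.0, -2.0, 1.5]))
        with pytest.raises(ValidationError, match="'B'"):
            prepare(rlist, small_catalog, EnrichmentParams(min_per_set=2))

    def test_unannotated_drugs_kept_as_background(self, toy_list):
        catalog = MOACatalog({"a": frozenset({"A", "B"}), "b": frozenset({"E", "F"})})
        params = EnrichmentParams(min_per_set=2, n_permutations=10)
        prepared, _, report = prepare(toy_list, catalog, params)
        assert set(report.unannotated_drugs) == {"C", "D"}
        assert set(prepared.drugs) == set(toy_list.drugs)

    def test_fewer_than_two_sets_is_error(self, toy_list):
        catalog = MOACatalog({"only": frozenset({"A", "B"})})
        with pytest.raises(ValidationError, match="two MOAs"):
            prepare(toy_list, catalog, EnrichmentParams(min_per_set=2))

    def test_sets_intersected_before_min_size_test(self, toy_list):
        # 6 nominal members but only 2 ranked: fails min_per_set=3
        catalog = MOACatalog(
            {
                "phantom": frozenset({"A", "B", "x1", "x2", "x3", "x4"}),
                "real1": frozenset({"A", "B", "C"}),
                "real2": frozenset({"D", "E", "F"}),
            }
        )
        params = EnrichmentParams(min_per_set=3, n_permutations=10)
        _, kept, report = prepare(toy_list, catalog, params)
        assert "phantom" in report.removed_sets
        assert report.removed_sets["phantom"] == 2

    def test_sort_is_deterministic_on_rank_ties(self):
        rlist = RankedDrugList(("b", "a", "c"), np.array([1.0, 1.0, 2.0]))
        assert rlist.sort_descending().drugs == ("c", "a", "b")

    def test_catalog_from_annotations(self):
        rlist = RankedDrugList(
            ("d1", "d2", "d3"),
            np.array([1.0, 2.0, -1.0]),
            annotations=(("EGFRi",), ("EGFRi", "MEKi"), ()),
        )
        catalog = catalog_from_annotations(rlist)
        assert catalog.sets == {
            "EGFRi": frozenset({"d1", "d2"}),
            "MEKi": frozenset({"d2"}),
        }


class TestSignificance:
    def test_count_based_p(self):
        null = NullDistribution(np.array([0.9, 0.7, 0.6, -0.5]), np.zeros(4))
        p, nes = significance(0.8, null)
        assert p == pytest.approx(1 / 3)
        assert nes == pytest.approx(0.8 / ((0.9 + 0.7 + 0.6) / 3))

    def test_nes_is_one_when_es_equals_null_mean(self):
        null = NullDistribution(np.array([0.8, 0.8, -0.1]), np.zeros(3))
        _, nes = significance(0.8, null)
        assert nes == pytest.approx(1.0)

    def test_p_floor_and_empty_same_sign(self):
        null = NullDistribution(np.array([0.1, 0.2, 0.3, 0.4]), np.zeros(4))
        p, nes = significance(-0.5, null)
        assert p == 0.25  # 1/n_permutations
        assert np.isnan(nes)

    def test_negative_es_mirrors_positive(self):
        null_pos = NullDistribution(np.array([0.9, 0.7, 0.6, -0.5]), np.zeros(4))
        null_neg = NullDistribution(-null_pos.es_null, np.zeros(4))
        p_pos, nes_pos = significance(0.8, null_pos)
        p_neg, nes_neg = significance(-0.8, null_neg)
        assert p_neg == p_pos
        assert nes_neg == pytest.approx(-nes_pos)

    def test_zero_es_degenerate(self):
        null = NullDistribution(np.array([0.5, -0.5]), np.zeros(2))
        assert significance(0.0, null) == (1.0, 0.0)


class TestFdrAdjust:
    def test_count_based_oracle(self):
        q = fdr_adjust({"a": 2.0, "b": 1.5}, np.array([2.2, 1.0, 0.5, 1.6]))
        assert q["a"] == pytest.approx(0.5)
        assert q["b"] == pytest.approx(0.5)

    def test_extreme_observation_gets_zero(self):
        q = fdr_adjust({"a": 3.0}, np.array([1.0, 2.0, -1.5]))
        assert q["a"] == 0.0

    def test_clamped_to_unit_interval(self):
        q = fdr_adjust({"a": 0.1, "b": 5.0}, np.array([1.0, 2.0, 3.0]))
        assert 0.0 <= q["a"] <= 1.0

    def test_nan_propagates(self):
        q = fdr_adjust({"a": float("nan"), "b": 1.0}, np.array([0.5, -0.5]))
        assert np.isnan(q["a"]) and np.isfinite(q["b"])

    def test_empty_pool_is_error(self):
        with pytest.raises(ValidationError):
            fdr_adjust({"a": 1.0}, np.array([]))


class TestNullDistribution:
    def test_length_and_determinism(self, toy_list, fast_params):
        null1 = null_distribution(toy_list, 2, fast_params, "key")
        null2 = null_distribution(toy_list, 2, fast_params, "key")
        other = null_distribution(toy_list, 2, fast_params, "other")
        assert len(null1.es_null) == fast_params.n_permutations
        np.testing.assert_array_equal(null1.es_null, null2.es_null)
        assert not np.array_equal(null1.es_null, other.es_null)

    def test_nes_null_normalization(self, toy_list, fast_params):
        null = null_distribution(toy_list, 2, fast_params, "k")
        pos = null.es_null > 0
        if pos.any():
            expect = null.es_null[pos] / abs(null.es_null[pos].mean())
            np.testing.assert_allclose(null.nes_null[pos], expect)
            assert np.isclose(null.nes_null[pos].mean(), 1.0)

    def test_set_size_bounds(self, toy_list, fast_params):
        with pytest.raises(ValidationError):
            null_distribution(toy_list, len(toy_list), fast_params, "k")
        with pytest.raises(ValidationError):
            null_distribution(toy_list, 0, fast_params, "k")


class TestDrugSea:
    def test_one_result_per_surviving_set(self, toy_list, small_catalog, fast_params):
        outcome = drug_sea(toy_list, small_catalog, fast_params)
        assert len(outcome.results) == 3
        assert all(np.isfinite(r.es) for r in outcome.results)

    def test_constructed_extreme_instance(self):
        """A 6-drug MOA occupying the strongly positive top of a 40-drug list
        must attain the top NES with p at the permutation floor."""
        rng = np.random.default_rng(5)
        n = 40
        drugs = tuple(f"d{i:02d}" for i in range(n))
        ranks = np.concatenate([np.linspace(8, 6, 6), rng.normal(0, 0.5, n - 6)])
        ranks[ranks == 0] = 0.1
        catalog = MOACatalog(
            {
                "planted": frozenset(drugs[:6]),
                "background1": frozenset(drugs[10:20]),
                "background2": frozenset(drugs[20:30]),
            }
        )
        params = EnrichmentParams(n_permutations=200, seed=1)
        outcome = drug_sea(RankedDrugList(drugs, ranks), catalog, params)
        top = outcome.results[0]
        assert top.moa == "planted"
        assert top.p_value == 1 / 200
        assert top.es == pytest.approx(brute_force_es(drugs, ranks, set(drugs[:6])))

    def test_significance_flag_uses_both_thresholds(self, toy_list, small_catalog):
        params = EnrichmentParams(
            n_permutations=100, min_per_set=2, p_threshold=1e-9, fdr_threshold=1e-9, seed=0
        )
        outcome = drug_sea(toy_list, small_catalog, params)
        assert not any(r.significant for r in outcome.results)

    def test_results_sorted_by_nes_descending(self, toy_list, small_catalog, fast_params):
        outcome = drug_sea(toy_list, small_catalog, fast_params)
        nes = [r.nes for r in outcome.results if np.isfinite(r.nes)]
        assert nes == sorted(nes, reverse=True)

    def test_deterministic_given_seed(self, toy_list, small_catalog, fast_params):
        a = drug_sea(toy_list, small_catalog, fast_params).to_frame()
        b = drug_sea(toy_list, small_catalog, fast_params).to_frame()
        assert a.equals(b)
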
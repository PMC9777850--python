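"""Hypergeometric enrichment and BH-FDR against exhaustive oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from _oracles import bh_step_up, hypergeom_upper_tail
from yakcnv.enrichment import TermMap, bh_adjust, enrich, hypergeom_test


class TestHypergeomTest:
    def test_zero_hits_is_certain(self):
        assert hypergeom_test(0, 5, 3, 20) == 1.0

    def test_term_covering_population_is_certain(self):
        assert hypergeom_test(2, 10, 2, 10) == pytest.approx(1.0)

    def test_exact_small_case(self):
        # drawing both of the 2 annotated genes in a study of 2 from 10
        assert hypergeom_test(2, 2, 2, 10) == pytest.approx(1 / 45)

    def test_matches_enumeration_for_all_small_configurations(self):
        """Agree with brute-force summation for every valid (k,K,n) at N<=20."""
        for N in (7, 12, 20):
            for K, n in itertools.product(range(N + 1), repeat=2):
                for k in range(max(0, K + n - N), min(K, n) + 1):
                    assert hypergeom_test(k, K, n, N) == pytest.approx(
                        hypergeom_upper_tail(k, K, n, N), rel=1e-9, abs=1e-12
                    )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_test(5, 3, 10, 20)  # k > K


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]).tolist() == [0.37]

    def test_hand_computed_vector(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.9]), [0.03, 0.03, 0.9]
        )

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_matches_definition_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            p = rng.random(rng.integers(1, 30))
            np.testing.assert_allclose(bh_adjust(p), bh_step_up(p), rtol=1e-12)

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(4)
        p = rng.random(15)
        perm = rng.permutation(15)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestEnrich:
    @pytest.fixture
    def population(self):
        return {f"g{i}" for i in range(50)}

    def test_empty_study_set_no_rows(self, population):
        tm = TermMap(terms={"T1": {"g1", "g2"}}, meta={"T1": ("t", "biological process")})
        assert enrich(set(), tm, population) == []

    def test_planted_enrichment_flagged(self, population):
        """A term exactly covering a small study set is significant at 0.05."""
        study = {"g1", "g2", "g3", "g4"}
        tm = TermMap(
            terms={"HIT": set(study), "BG": {f"g{i}" for i in range(20, 45)}},
            meta={"HIT": ("hit", "biological process"), "BG": ("bg", "molecular function")},
        )
        rows = enrich(study, tm, population)
        byid = {r.term_id: r for r in rows}
        assert byid["HIT"].adjusted_p <= 0.05
        assert byid["HIT"].k == 4 and byid["HIT"].K == 4

    def test_study_outside_population_rejected(self, population):
        tm = TermMap(terms={}, meta={})
        with pytest.raises(ValueError, match="outside the population"):
            enrich({"nope"}, tm, population)

    def test_rows_sorted_and_adjusted_at_least_raw(self, population):
        rng = np.random.default_rng(6)
        terms = {
            f"T{i}": set(rng.choice(sorted(population), size=8, replace=False))
            for i in range(12)
        }
        tm = TermMap(terms=terms, meta={t: (t, "biological process") for t in terms})
        study = set(rng.choice(sorted(population), size=10, replace=False))
        rows = enrich(study, tm, population)
        assert all(a.adjusted_p <= b.adjusted_p for a, b in zip(rows, rows[1:]))
        assert all(r.adjusted_p >= r.p_value for r in rows)

    def test_null_significant_fraction_bounded_by_alpha(self, population):
        """Random study sets: FDR-significant calls occur at rate <= alpha + MC error."""
        rng = np.random.default_rng(11)
        pop = sorted(population)
        terms = {
            f"T{i}": set(rng.choice(pop, size=10, replace=False)) for i in range(15)
        }
        tm = TermMap(terms=terms, meta={t: (t, "biological process") for t in terms})
        n_tests = n_sig = 0
        for _ in range(300):
            study = set(rng.choice(pop, size=8, replace=False))
            rows = enrich(study, tm, population, alpha=0.05)
            n_tests += 1
            n_sig += any(r.adjusted_p <= 0.05 for r in rows)
        # BH controls FDR per family; across null families the hit rate stays small
        assert n_sig / n_tests <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_tests)


class TestTermMapIO:
    def test_gmt_round(self, tmp_path):
        p = tmp_path / "t.gmt"
        p.write_text("T1\tdesc\tg1\tg2\nT2\tdesc2\tg3\n")
        tm = TermMap.from_gmt(p)
        assert tm.terms == {"T1": {"g1", "g2"}, "T2": {"g3"}}

    def test_two_column_tsv(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("T1\tg1\nT1\tg2\nT2\tg9\n")
        tm = TermMap.from_tsv(p)
        assert tm.terms == {"T1": {"g1", "g2"}, "T2": {"g9"}}

    def test_malformed_tsv_line_located(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("T1\tg1\nT1 g2 extra\n")
        with pytest.raises(ValueError, match="line 2"):
            TermMap.from_tsv(p)
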
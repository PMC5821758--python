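"""Fisher right-tail tests, BH correction and the module enrichment
analyses, verified against brute-force hypergeometric oracles."""
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cadnet.annotations import ATC_GROUPS, AnnotationBundle, DRUG_COLUMNS
from cadnet.enrichment import (
    atc_enrichment,
    benjamini_hochberg,
    drug_enrichment,
    fisher_right_tail,
    go_enrichment,
    main_go_term,
)


# -- oracles ---------------------------------------------------------------

def hypergeom_upper_tail(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) by direct summation of the hypergeometric pmf."""
    n_total, n_set, n_draw = a + b + c + d, a + c, a + b
    denom = comb(n_total, n_draw)
    total = 0
    for k in range(a, min(n_set, n_draw) + 1):
        total += comb(n_set, k) * comb(n_total - n_set, n_draw - k)
    return total / denom


def bh_step_up(p: np.ndarray) -> np.ndarray:
    """Independent BH implementation: q_i = min_{p_(j) >= p_(i)} p_(j)*m/j."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0, 1)
    return q


class TestFisherRightTail:
    def test_worked_overlap_example(self):
        # overlap 5 of a module of 10 and a set of 10 in a universe of 100
        odds, p = fisher_right_tail(5, 5, 5, 85)
        expected = sum(
            comb(10, k) * comb(90, 10 - k) for k in range(5, 11)
        ) / comb(100, 10)
        assert p == pytest.approx(expected, rel=1e-12)
        assert odds == pytest.approx(5 * 85 / (5 * 5))

    def test_zero_overlap_full_tail(self):
        _, p = fisher_right_tail(0, 10, 10, 80)
        assert p == pytest.approx(1.0)

    def test_module_equal_universe_degenerate(self):
        _, p = fisher_right_tail(10, 0, 0, 0)
        assert p == pytest.approx(1.0)

    def test_all_zero_table(self):
        odds, p = fisher_right_tail(0, 0, 0, 0)
        assert (odds, p) == (1.0, 1.0)

    def test_infinite_odds_when_off_diagonal_empty(self):
        odds, _ = fisher_right_tail(5, 0, 0, 5)
        assert odds == float("inf")

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_right_tail(-1, 1, 1, 1)

    @given(
        st.tuples(
            st.integers(0, 50), st.integers(0, 50),
            st.integers(0, 50), st.integers(0, 50),
        ).filter(lambda t: sum(t) > 0)
    )
    def test_matches_brute_force_sum(self, table):
        a, b, c, d = table
        _, p = fisher_right_tail(a, b, c, d)
        assert p == pytest.approx(hypergeom_upper_tail(a, b, c, d), rel=1e-12)


class TestBenjaminiHochberg:
    def test_linear_p_sequence(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert benjamini_hochberg([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert np.allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_empty_input(self):
        assert benjamini_hochberg([]).size == 0

    def test_q_at_least_p_and_order_preserved(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        q = benjamini_hochberg(p)
        assert (q >= p - 1e-15).all()
        # order-preserving: smaller p never gets a larger q
        idx = np.argsort(p)
        assert (np.diff(q[idx]) >= -1e-15).all()

    def test_matches_independent_step_up_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(benjamini_hochberg(p), bh_step_up(p), atol=1e-12)


class TestGoEnrichment:
    def universe(self):
        return {f"u{i}" for i in range(50)}

    def test_module_matching_a_rare_term_is_the_main_term(self):
        universe = self.universe()
        module = {"u0", "u1", "u2"}
        go = {"GO:rare": set(module), "GO:common": set(universe)}
        results = go_enrichment(module, go, universe)
        main = main_go_term(results)
        assert main.unit == "GO:rare"
        assert main.q_value <= min(r.q_value for r in results)

    def test_empty_bundle_gives_empty_results(self):
        assert go_enrichment({"u0"}, {}, self.universe()) == []

    def test_missing_module_gene_added_to_universe(self):
        results = go_enrichment({"zzz"}, {"GO:x": {"zzz"}}, {"u0"})
        (res,) = results
        assert sum(res.table) == 2  # universe grew to include zzz

    def test_shuffled_annotations_p_values_stochastically_uniform_or_larger(self):
        """Null annotations: right-tail p-values are >= uniform in
        distribution (the discrete test is conservative)."""
        rng = np.random.default_rng(7)
        universe = sorted(self.universe())
        ps = []
        for _ in range(300):
            module = set(rng.choice(universe, size=8, replace=False))
            term = set(rng.choice(universe, size=10, replace=False))
            _, p = fisher_right_tail(
                len(module & term), len(module - term),
                len(term - module), 50 - len(module | term),
            )
            ps.append(p)
        ps = np.sort(ps)
        ecdf = np.arange(1, len(ps) + 1) / len(ps)
        # conservative: ECDF at p never exceeds p by more than MC noise
        assert (ecdf - ps <= 3 * np.sqrt(0.25 / len(ps))).all()


def make_bundle(drug_rows):
    return AnnotationBundle(pd.DataFrame(drug_rows, columns=DRUG_COLUMNS))


class TestDrugEnrichment:
    def test_strongly_targeted_module_is_enriched(self):
        universe = {f"u{i}" for i in range(1000)}
        targets = sorted(universe)[:100]
        rows = [(g, f"D{i}", False, "L") for i, g in enumerate(targets)]
        bundle = make_bundle(rows)
        module = set(targets[:9]) | {"u999"}
        overall, _ = drug_enrichment(module, bundle, universe)
        assert overall.table[0] == 9
        assert overall.p_value == pytest.approx(
            hypergeom_upper_tail(9, 1, 91, 899), rel=1e-9
        )

    def test_cardiometabolic_contrast_within_targeted_subuniverse(self):
        universe = {f"u{i}" for i in range(40)}
        cm = [f"u{i}" for i in range(5)]
        other = [f"u{i}" for i in range(5, 20)]
        rows = [(g, "Dc", True, "C") for g in cm]
        rows += [(g, "Do", False, "L") for g in other]
        bundle = make_bundle(rows)
        module = set(cm[:4]) | {other[0]}
        _, cardio = drug_enrichment(module, bundle, universe)
        assert cardio.table == (4, 1, 1, 14)
        assert cardio.p_value == pytest.approx(
            hypergeom_upper_tail(4, 1, 1, 14), rel=1e-9
        )
        # sub-universe consistency: counts never exceed the drug-target counts
        assert sum(cardio.table) == 20

    def test_module_without_targeted_members_gives_p_one(self):
        bundle = make_bundle([("u0", "D", True, "C")])
        _, cardio = drug_enrichment({"zz"}, bundle, {"u0", "zz"})
        assert cardio.p_value == 1.0 and cardio.table == (0, 0, 0, 0)

    def test_no_cardiometabolic_drugs_gives_p_one_everywhere(self):
        bundle = make_bundle([("u0", "D", False, "L"), ("u1", "E", False, "N")])
        _, cardio = drug_enrichment({"u0", "u1"}, bundle, {"u0", "u1", "u2"})
        assert cardio.p_value == pytest.approx(1.0)


class TestAtcEnrichment:
    def test_gene_targeted_in_two_groups_counted_in_both(self):
        rows = [("u0", "D1", False, "C"), ("u0", "D2", False, "B"),
                ("u1", "D3", False, "L")]
        bundle = make_bundle(rows)
        sets = bundle.atc_sets()
        assert "u0" in sets["C"] and "u0" in sets["B"]

    def test_drug_without_atc_code_excluded(self):
        rows = [("u0", "D1", False, ""), ("u1", "D2", False, "L")]
        bundle = make_bundle(rows)
        sets = bundle.atc_sets()
        assert all("u0" not in s for s in sets.values())

    def test_group_specific_enrichment_flagged(self):
        targets = [f"u{i}" for i in range(20)]
        rows = [(g, f"DL{i}", False, "L") for i, g in enumerate(targets[:4])]
        rows += [(g, f"DN{i}", False, "N") for i, g in enumerate(targets[4:])]
        bundle = make_bundle(rows)
        module = set(targets[:4])
        table = atc_enrichment(module, bundle).set_index("atc_code")
        assert bool(table.loc["L", "significant"])
        assert not bool(table.loc["N", "significant"])
        assert set(table.index) == set(ATC_GROUPS)
        # spot-check one p against the oracle
        row = table.loc["L"]
        assert row["p_value"] == pytest.approx(
            hypergeom_upper_tail(4, 0, 0, 16), rel=1e-9
        )
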
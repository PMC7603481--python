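"""Dyadic states, period sociomatrices and half-weight indices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cobreed.association import (
    DyadState,
    Sociomatrix,
    build_period_sociomatrix,
    dyad_year_state,
    export_edges,
    half_weight_index,
    validate_resightings,
)
from cobreed.errors import DataError, InvalidDyadError
from tests.conftest import make_records


class TestDyadYearState:
    def test_same_patch_is_together(self):
        rec = make_records([("i", 2004, "P7"), ("j", 2004, "P7")])
        assert dyad_year_state(rec, "i", "j", 2004) is DyadState.TOGETHER

    def test_different_patches_is_apart(self):
        rec = make_records([("i", 2004, "P7"), ("j", 2004, "P9")])
        assert dyad_year_state(rec, "i", "j", 2004) is DyadState.APART

    def test_unseen_member_is_missing(self):
        rec = make_records([("i", 2004, "P7"), ("j", 2005, "P7")])
        assert dyad_year_state(rec, "i", "j", 2004) is DyadState.MISSING

    def test_self_dyad_rejected(self):
        rec = make_records([("i", 2004, "P7")])
        with pytest.raises(InvalidDyadError):
            dyad_year_state(rec, "i", "i", 2004)


class TestPeriodPrecedence:
    """Period state = together if ever together, else apart if ever both
    seen apart, else missing."""

    @pytest.mark.parametrize(
        "yearly,expected",
        [
            # (patch_i, patch_j) per year; None = unseen
            ([("P1", "P2"), ("P3", "P3"), (None, "P4")], DyadState.TOGETHER),
            ([(None, None), (None, "P1")], DyadState.MISSING),
            ([("P1", "P2"), ("P3", None)], DyadState.APART),
            ([(None, "P1"), ("P2", None)], DyadState.MISSING),
        ],
    )
    def test_precedence(self, yearly, expected):
        rows = []
        for k, (pi, pj) in enumerate(yearly):
            if pi is not None:
                rows.append(("i", 2000 + k, pi))
            if pj is not None:
                rows.append(("j", 2000 + k, pj))
        soc = build_period_sociomatrix(
            make_records(rows), range(2000, 2000 + len(yearly)),
            individuals=["i", "j"],
        )
        assert DyadState(soc.state[0, 1]) is expected

    def test_row_order_invariance(self, records_small, rng):
        base = build_period_sociomatrix(records_small, range(2002, 2005))
        for _ in range(10):
            shuffled = records_small.sample(frac=1, random_state=int(rng.integers(1 << 31)))
            other = build_period_sociomatrix(shuffled, range(2002, 2005))
            assert other.individuals == base.individuals
            np.testing.assert_array_equal(other.state, base.state)

    def test_union_of_periods_is_precedence_merge(self, rng):
        """Building over years A∪B equals merging the A and B matrices under
        the together > apart > missing lattice."""
        from cobreed.simulate import SimulationConfig, simulate_colony

        rec, _ = simulate_colony(
            SimulationConfig(n_individuals=25, years=(2000, 2007), seed=11)
        )
        ids = sorted(rec["individual_id"].unique())
        ya, yb = list(range(2000, 2004)), list(range(2004, 2008))
        sa = build_period_sociomatrix(rec, ya, individuals=ids)
        sb = build_period_sociomatrix(rec, yb, individuals=ids)
        s_all = build_period_sociomatrix(rec, ya + yb, individuals=ids)
        merged = np.where(
            (sa.state == 1) | (sb.state == 1),
            1,
            np.where((sa.state == 0) | (sb.state == 0), 0, -1),
        )
        np.fill_diagonal(merged, -1)
        np.testing.assert_array_equal(s_all.state, merged)

    def test_symmetry_and_missing_diagonal(self, records_small):
        soc = build_period_sociomatrix(records_small, range(2002, 2005))
        np.testing.assert_array_equal(soc.state, soc.state.T)
        assert (np.diag(soc.state) == int(DyadState.MISSING)).all()

    def test_duplicate_individual_year_rejected(self):
        rec = make_records([("i", 2004, "P7"), ("i", 2004, "P9")])
        with pytest.raises(DataError):
            build_period_sociomatrix(rec, [2004])

    def test_lenient_validation_keeps_first(self):
        rec = make_records([("i", 2004, "P7"), ("i", 2004, "P9"), ("j", 2004, "P7")])
        with pytest.warns(UserWarning):
            clean = validate_resightings(rec, strict=False)
        assert len(clean) == 2
        assert dyad_year_state(clean, "i", "j", 2004) is DyadState.TOGETHER

    def test_triplet_round_trip(self, records_small, tmp_path):
        soc = build_period_sociomatrix(records_small, range(2002, 2005))
        path = tmp_path / "soc.csv"
        soc.to_triplets(path)
        back = Sociomatrix.from_triplets(path)
        assert back.individuals == soc.individuals
        np.testing.assert_array_equal(back.state, soc.state)


def brute_force_hwi(records, years, i, j):
    """Independent per-dyad HWI: count occasion types year by year."""
    x = yab = ya = yb = 0
    for year in years:
        sub = records[records["year"] == year]
        pi = sub.loc[sub["individual_id"] == i, "patch_id"]
        pj = sub.loc[sub["individual_id"] == j, "patch_id"]
        if not pi.empty and not pj.empty:
            if pi.iloc[0] == pj.iloc[0]:
                x += 1
            else:
                yab += 1
        elif not pi.empty:
            ya += 1
        elif not pj.empty:
            yb += 1
    denom = x + yab + 0.5 * (ya + yb)
    return x / denom if denom > 0 else None


class TestHalfWeightIndex:
    def test_worked_example(self):
        # x=3 together, y_ab=1 apart, y_a=2 only-i years: 3/(3+1+1) = 0.6
        rows = [
            ("i", 2000, "A"), ("j", 2000, "A"),
            ("i", 2001, "B"), ("j", 2001, "B"),
            ("i", 2002, "C"), ("j", 2002, "C"),
            ("i", 2003, "D"), ("j", 2003, "E"),
            ("i", 2004, "F"),
            ("i", 2005, "G"),
        ]
        hwi = half_weight_index(make_records(rows), range(2000, 2006))
        k_i, k_j = hwi.individuals.index("i"), hwi.individuals.index("j")
        assert hwi.hwi[k_i, k_j] == pytest.approx(0.6)

    def test_always_together_is_one(self):
        rows = [(ind, y, f"P{y}") for y in range(4) for ind in ("i", "j")]
        hwi = half_weight_index(make_records(rows), range(4))
        assert hwi.hwi[0, 1] == pytest.approx(1.0)

    def test_never_together_is_zero(self):
        rows = []
        for y in range(5):
            rows += [("i", y, f"A{y}"), ("j", y, f"B{y}")]
        hwi = half_weight_index(make_records(rows), range(5))
        assert hwi.hwi[0, 1] == 0.0

    def test_unsampled_dyad_is_undefined(self):
        rec = make_records([("i", 2000, "A"), ("j", 2001, "B")])
        hwi = half_weight_index(rec, [2005], individuals=["i", "j"])
        assert np.isnan(hwi.hwi[0, 1])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_exhaustive_per_dyad_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        n_ind, n_years, n_patches = 8, 6, 3
        rows = []
        for i in range(n_ind):
            for y in range(n_years):
                if rng.random() < 0.6:
                    rows.append((f"i{i}", y, f"P{y}_{rng.integers(n_patches)}"))
        if not rows:
            return
        rec = make_records(rows)
        years = list(range(n_years))
        hwi = half_weight_index(rec, years)
        for a in range(hwi.n):
            for b in range(a + 1, hwi.n):
                expect = brute_force_hwi(rec, years, hwi.individuals[a], hwi.individuals[b])
                got = hwi.hwi[a, b]
                if expect is None:
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expect, abs=1e-12)


class TestExportEdges:
    def test_single_together_dyad_gives_one_edge(self):
        rec = make_records([("i", 2000, "A"), ("j", 2000, "A"), ("k", 2000, "B")])
        soc = build_period_sociomatrix(rec, [2000])
        edges = export_edges(soc)
        assert len(edges) == 1
        assert {edges.iloc[0]["source"], edges.iloc[0]["target"]} == {"i", "j"}

    def test_min_weight_one_keeps_only_never_apart_pairs(self):
        rows = [
            ("i", 2000, "A"), ("j", 2000, "A"),      # together always
            ("i", 2001, "B"), ("j", 2001, "B"),
            ("k", 2000, "A"), ("k", 2001, "C"),      # with i: together then apart
        ]
        hwi = half_weight_index(make_records(rows), [2000, 2001])
        edges = export_edges(hwi, min_weight=1.0)
        pairs = {frozenset((r.source, r.target)) for r in edges.itertuples()}
        assert pairs == {frozenset(("i", "j"))}

    def test_empty_matrix_gives_empty_edge_list(self):
        soc = Sociomatrix(individuals=[], state=np.zeros((0, 0), dtype=np.int8), years=())
        assert export_edges(soc).empty

    def test_graphml_round_trip(self, tmp_path, records_small):
        import networkx as nx

        from cobreed.association import write_edges_graphml

        soc = build_period_sociomatrix(records_small, range(2002, 2005))
        edges = export_edges(soc)
        path = tmp_path / "net.graphml"
        write_edges_graphml(edges, path)
        g = nx.read_graphml(path)
        assert g.number_of_edges() == len(edges)
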
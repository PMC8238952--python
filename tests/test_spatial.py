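"""Neighbor graph, pair enrichment, niches, composition, contacts."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from nichemap.spatial import (
    build_neighbor_graph,
    contact_fraction,
    define_niches,
    niche_composition,
    pair_enrichment,
    reproducible_enrichments,
)


def brute_force_edges(pts, radius=20.0):
    return {
        (i, j)
        for i, j in combinations(range(len(pts)), 2)
        if np.linalg.norm(np.asarray(pts[i]) - np.asarray(pts[j])) < radius
    }


def brute_force_enrichment(pts, types, radius=20.0, include_self=True):
    """Direct probability computation over all pairs, for small scenes."""
    edges = brute_force_edges(pts, radius)
    types = np.asarray(types)
    if not include_self:
        edges = {(i, j) for i, j in edges if types[i] != types[j]}
    names = sorted(set(types))
    fr = {t: (types == t).mean() for t in names}
    total = len(edges)
    self_mass = sum(f * f for f in fr.values())
    out = {}
    for a, b in set(combinations(list(names), 2)) | {(t, t) for t in names}:
        a, b = sorted((a, b))
        if not include_self and a == b:
            continue
        obs = sum(
            1 for i, j in edges if {types[i], types[j]} == ({a} if a == b else {a, b})
        )
        p_exp = fr[a] ** 2 if a == b else 2 * fr[a] * fr[b]
        if not include_self:
            p_exp /= 1 - self_mass
        out[(a, b)] = (obs, p_exp, np.log2(obs / total / p_exp) if obs else -np.inf)
    return out, total


class TestNeighborGraph:
    def test_strict_radius_boundary(self):
        pts = np.array([[0.0, 0.0], [19.9, 0.0]])
        assert len(build_neighbor_graph(pts)) == 1
        pts2 = np.array([[0.0, 0.0], [20.0, 0.0]])
        assert len(build_neighbor_graph(pts2)) == 0

    def test_collinear_three_cells(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 0.0]])
        g = build_neighbor_graph(pts)
        assert len(g) == 2
        assert set(map(tuple, g[["i", "j"]].to_numpy())) == {(0, 1), (1, 2)}

    def test_matches_brute_force_on_random_scene(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 100, size=(50, 2))
        g = build_neighbor_graph(pts)
        assert set(map(tuple, g[["i", "j"]].to_numpy())) == brute_force_edges(pts)


class TestPairEnrichment:
    def test_collinear_aba_worked_example(self):
        # A(0), B(10), A(20): both edges are A-B; f_A=2/3, f_B=1/3
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 0.0]])
        g = build_neighbor_graph(pts)
        tab = pair_enrichment(g, ["A", "B", "A"])
        row = tab.loc[("A", "B")]
        assert row.observed_pairs == 2
        assert row.expected_probability == pytest.approx(4 / 9)
        assert row.log2_enrichment == pytest.approx(np.log2(9 / 4))

    @pytest.mark.parametrize("include_self", [True, False])
    def test_matches_brute_force_oracle(self, include_self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 120, size=(50, 2))
        types = rng.choice(["A", "B", "C"], size=50)
        g = build_neighbor_graph(pts)
        tab = pair_enrichment(g, types, include_self_pairs=include_self)
        oracle, total = brute_force_enrichment(pts, types, include_self=include_self)
        assert tab["observed_pairs"].sum() == total
        for (a, b), (obs, p_exp, log2e) in oracle.items():
            row = tab.loc[(a, b)]
            assert row.observed_pairs == obs
            assert row.expected_probability == pytest.approx(p_exp)
            if np.isfinite(log2e):
                assert row.log2_enrichment == pytest.approx(log2e)

    def test_expected_probabilities_sum_to_one(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 150, size=(200, 2))
        types = rng.choice(list("ABCD"), size=200, p=[0.4, 0.3, 0.2, 0.1])
        g = build_neighbor_graph(pts)
        for include_self in (True, False):
            tab = pair_enrichment(g, types, include_self_pairs=include_self)
            assert tab["expected_probability"].sum() == pytest.approx(1.0)
            if not include_self:
                assert all(a != b for a, b in tab.index)

    def test_zero_cell_type_reported_undefined(self):
        pts = np.array([[0.0, 0.0], [5.0, 0.0]])
        g = build_neighbor_graph(pts)
        tab = pair_enrichment(g, ["A", "A"], type_names=["A", "B"])
        assert np.isnan(tab.loc[("A", "B"), "log2_enrichment"])
        assert ("B", "B") in tab.index

    def test_empty_graph_no_crash(self):
        tab = pair_enrichment(build_neighbor_graph(np.zeros((0, 2))), np.array(["A"])[:0],
                              type_names=["A"])
        assert np.isnan(tab.loc[("A", "A"), "chi2_p"])


class TestReproducibility:
    def _table(self, log2e, p):
        return pd.DataFrame(
            {"log2_enrichment": [log2e], "fdr_q": [p]},
            index=pd.MultiIndex.from_tuples([("A", "B")]),
        )

    def test_three_of_four_flagged(self):
        tables = [self._table(1.0, 0.001)] * 3 + [self._table(-0.5, 0.9)]
        assert reproducible_enrichments(tables).loc[("A", "B")]

    def test_two_of_four_not_flagged(self):
        tables = [self._table(1.0, 0.001)] * 2 + [self._table(1.0, 0.5)] * 2
        assert not reproducible_enrichments(tables).loc[("A", "B")]

    def test_weak_p_everywhere_not_flagged(self):
        tables = [self._table(1.0, 0.02)] * 4
        assert not reproducible_enrichments(tables).loc[("A", "B")]

    def test_too_few_tables_rejected(self):
        with pytest.raises(ValueError):
            reproducible_enrichments([self._table(1.0, 0.001)] * 2)


class TestNiches:
    def test_radius_membership(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [25.0, 0.0]])
        flags = pd.Series([True, False, False])
        niches = define_niches(flags, pts)
        assert niches["members"][0] == [1]
        assert niches["niche_cells"] == [1]
        assert niches["non_niche_cells"] == [2]

    def test_isolated_hsc_has_empty_niche(self):
        pts = np.array([[0.0, 0.0], [100.0, 100.0]])
        niches = define_niches(pd.Series([True, False]), pts)
        assert niches["members"][0] == []

    def test_close_hscs_are_mutual_members(self):
        pts = np.array([[0.0, 0.0], [5.0, 0.0]])
        niches = define_niches(pd.Series([True, True]), pts)
        assert niches["members"][0] == [1] and niches["members"][1] == [0]
        assert niches["non_niche_cells"] == []

    def test_cell_order_invariance(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 80, size=(60, 2))
        flags = pd.Series(np.arange(60) < 4)
        base = define_niches(flags, pts)
        perm = rng.permutation(60)
        permuted = define_niches(
            pd.Series(flags.to_numpy()[perm], index=perm), pts[perm]
        )
        for h, members in base["members"].items():
            assert sorted(permuted["members"][h]) == sorted(members)


class TestNicheComposition:
    def test_reproduces_published_tables(self):
        # build type vectors realizing the printed niche/overall counts
        types = pd.Series(["EC"] * 5876 + ["other"] * 106516)
        niche = list(range(21)) + list(range(5876, 5876 + 233))
        comp = niche_composition(niche, types)
        assert round(comp.loc["EC", "chi2_p"], 3) == 0.042
        types_ko = pd.Series(["EC"] * 12309 + ["other"] * 125319)
        niche_ko = list(range(153)) + list(range(12309, 12309 + 397))
        comp_ko = niche_composition(niche_ko, types_ko)
        assert comp_ko.loc["EC", "chi2_p"] < 0.001

    def test_identical_proportions_near_zero_statistic(self):
        types = pd.Series(["A"] * 50 + ["B"] * 50)
        niche = list(range(10)) + list(range(50, 60))  # same 50/50 mix
        comp = niche_composition(niche, types)
        assert comp["chi2_p"].min() > 0.5

    def test_empty_niche_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            niche_composition([], pd.Series(["A"]))


class TestContactFraction:
    def test_touching_and_separated_labels(self):
        mask = np.zeros((40, 40), dtype=np.int32)
        mask[5:15, 5:15] = 1
        mask[5:15, 15:25] = 2  # shares a boundary with 1
        mask[30:35, 30:35] = 3  # far away
        assert contact_fraction(mask, [1], [2]) == 1.0
        assert contact_fraction(mask, [1], [3]) == 0.0
        assert contact_fraction(mask, [1, 3], [2]) == 0.5

    def test_one_pixel_gap_not_touching(self):
        mask = np.zeros((20, 20), dtype=np.int32)
        mask[2:8, 2:8] = 1
        mask[2:8, 10:16] = 2  # 2-px background gap
        assert contact_fraction(mask, [1], [2]) == 0.0

    def test_diagonal_contact_counts(self):
        mask = np.zeros((10, 10), dtype=np.int32)
        mask[0:5, 0:5] = 1
        mask[5:10, 5:10] = 2  # touch only at the corner
        assert contact_fraction(mask, [1], [2]) == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            contact_fraction(np.ones((5, 5), dtype=np.int32), [], [1])
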
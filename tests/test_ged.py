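"""Graph edit distance: cost model, exact solver, evolutionary heuristic."""

import itertools

import numpy as np
import pytest

from ecoged.foodweb import FoodWeb
from ecoged.ged import (
    CostScheme,
    NodeMapping,
    SearchParams,
    evolutionary_ged,
    exact_ged,
    identity_ged,
    mapping_cost,
    normalize_score,
    pair_state,
)
from .conftest import random_web


# ---------------------------------------------------------------------------
# independent oracle: recompute a mapping's cost from first principles using
# explicit link-set bookkeeping (no adjacency matrices), and exact GED by a
# separately coded enumeration over it
# ---------------------------------------------------------------------------

def naive_mapping_cost(g1, g2, pairs, costs):
    """pairs: dict u -> u' over a subset of V1, injective into V2."""
    deleted = g1.nodes - set(pairs)
    inserted = g2.nodes - set(pairs.values())
    total = costs.node * (len(deleted) + len(inserted))
    total += costs.link * sum(1 for u, v in g1.links if u in deleted or v in deleted)
    total += costs.link * sum(1 for u, v in g2.links if u in inserted or v in inserted)
    flip = min(costs.flip, 2 * costs.link)
    mapped = sorted(pairs)
    for u in mapped:
        if (((u, u) in g1.links) != ((pairs[u], pairs[u]) in g2.links)):
            total += costs.link
    for u, v in itertools.combinations(mapped, 2):
        s1 = (((u, v) in g1.links), ((v, u) in g1.links))
        s2 = (((pairs[u], pairs[v]) in g2.links), ((pairs[v], pairs[u]) in g2.links))
        if s1 == s2:
            continue
        if s1 == s2[::-1] and s1[0] != s1[1]:
            total += flip
        else:
            total += costs.link * (int(s1[0] != s2[0]) + int(s1[1] != s2[1]))
    return total


def naive_exact_ged(g1, g2, costs):
    best = np.inf
    v1, v2 = sorted(g1.nodes), sorted(g2.nodes)
    for k in range(min(len(v1), len(v2)) + 1):
        for sub1 in itertools.combinations(v1, k):
            for sub2 in itertools.permutations(v2, k):
                best = min(best, naive_mapping_cost(g1, g2, dict(zip(sub1, sub2)), costs))
    return best


class TestPairState:
    G = FoodWeb("g", {"a", "b", "c"}, {("a", "b"), ("b", "a"), ("b", "c")})

    @pytest.mark.parametrize("u, v, expected", [
        ("b", "c", "forward"),
        ("c", "b", "backward"),
        ("a", "b", "both"),
        ("a", "c", "none"),
    ])
    def test_classification(self, u, v, expected):
        assert pair_state(self.G, u, v) == expected

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError):
            pair_state(self.G, "a", "a")


class TestMappingCost:
    def test_identity_on_identical_webs_is_free(self, rng):
        web = random_web("w", 8, 0.3, rng)
        m = NodeMapping.build({n: n for n in web.nodes})
        assert mapping_cost(web, web, m, CostScheme(0.9, 0.7, 0.3)) == 0.0

    def test_pure_reversal_takes_cheaper_route(self):
        g1 = FoodWeb("g1", {"a", "b"}, {("a", "b")})
        g2 = FoodWeb("g2", {"a", "b"}, {("b", "a")})
        m = NodeMapping.build({"a": "a", "b": "b"})
        # flip costlier than delete+insert: route through two link edits
        assert mapping_cost(g1, g2, m, CostScheme(0.75, 0.5, 0.25)) == pytest.approx(0.5)
        # flip cheaper: flip wins
        assert mapping_cost(g1, g2, m, CostScheme(0.25, 0.5, 1.0)) == pytest.approx(0.25)

    def test_deleted_node_carries_incident_links(self):
        # node x with total degree 3 left unmatched: node edit + 3 link edits
        g1 = FoodWeb("g1", {"x", "p", "q", "r"}, {("x", "p"), ("q", "x"), ("x", "r")})
        g2 = FoodWeb("g2", {"p", "q", "r"})
        m = NodeMapping.build({"p": "p", "q": "q", "r": "r"}, deleted={"x"})
        assert mapping_cost(g1, g2, m, CostScheme(0.75, 0.5, 0.25)) == pytest.approx(0.5 + 3 * 0.25)

    def test_invalid_mapping_rejected(self, tiny_pair):
        g1, g2 = tiny_pair
        m = NodeMapping.build({"a": "b"}, deleted={"b"}, inserted=g2.nodes - {"b"})
        with pytest.raises(ValueError):
            mapping_cost(g1, g2, m, CostScheme(1, 1, 1))

    def test_agrees_with_naive_oracle_on_random_mappings(self, rng):
        for _ in range(50):
            g1 = random_web("g1", int(rng.integers(1, 7)), 0.35, rng)
            g2 = random_web("g2", int(rng.integers(1, 7)), 0.35, rng)
            v1, v2 = sorted(g1.nodes), sorted(g2.nodes)
            k = int(rng.integers(0, min(len(v1), len(v2)) + 1))
            pairs = dict(zip(rng.permutation(v1)[:k], rng.permutation(v2)[:k]))
            costs = CostScheme(*rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=3))
            m = NodeMapping.build(pairs, g1.nodes - set(pairs), g2.nodes - set(pairs.values()))
            assert mapping_cost(g1, g2, m, costs) == pytest.approx(
                naive_mapping_cost(g1, g2, pairs, costs))


class TestExactGED:
    def test_empty_pair(self):
        assert exact_ged(FoodWeb("a"), FoodWeb("b"), CostScheme(1, 1, 1)).raw_cost == 0.0

    def test_single_forced_deletion(self):
        res = exact_ged(FoodWeb("a", {"x"}), FoodWeb("b"), CostScheme(0.25, 0.75, 0.25))
        assert res.raw_cost == pytest.approx(0.75)
        assert res.exact

    def test_cap_exceeded(self, rng):
        big = random_web("big", 8, 0.2, rng)
        with pytest.raises(ValueError, match="evolutionary"):
            exact_ged(big, big, CostScheme(1, 1, 1))

    def test_matches_independent_enumeration(self, rng):
        for _ in range(15):
            g1 = random_web("g1", 4, 0.35, rng)
            g2 = random_web("g2", 4, 0.35, rng)
            costs = CostScheme(0.25, 0.25, 0.25)  # mid-grid scenario
            assert exact_ged(g1, g2, costs).raw_cost == pytest.approx(naive_exact_ged(g1, g2, costs))

    def test_symmetry_under_shared_add_delete_costs(self, rng):
        for _ in range(15):
            g1 = random_web("g1", int(rng.integers(1, 5)), 0.3, rng)
            g2 = random_web("g2", int(rng.integers(1, 5)), 0.3, rng)
            costs = CostScheme(0.75, 0.5, 0.25)
            assert exact_ged(g1, g2, costs).raw_cost == pytest.approx(
                exact_ged(g2, g1, costs).raw_cost)


class TestIdentityGED:
    def test_identical_webs(self, rng):
        web = random_web("w", 10, 0.2, rng)
        assert identity_ged(web, web, CostScheme(0.75, 0.5, 0.25)).raw_cost == 0.0

    def test_disjoint_node_sets_cost_everything(self):
        g1 = FoodWeb("g1", {"a", "b"}, {("a", "b")})
        g2 = FoodWeb("g2", {"c", "d"}, {("c", "d")})
        res = identity_ged(g1, g2, CostScheme(0.75, 0.5, 0.25))
        assert res.raw_cost == pytest.approx(0.5 * 4 + 0.25 * 2)
        assert res.score == pytest.approx(1.0)

    def test_single_reversal(self):
        g1 = FoodWeb("g1", {"a", "b"}, {("a", "b")})
        g2 = FoodWeb("g2", {"a", "b"}, {("b", "a")})
        assert identity_ged(g1, g2, CostScheme(0.25, 0.5, 1.0)).raw_cost == pytest.approx(0.25)


class TestNormalizeScore:
    def test_zero_cost(self, tiny_pair):
        g1, g2 = tiny_pair
        assert normalize_score(0.0, g1, g2, CostScheme(1, 1, 1)) == 0.0

    def test_total_replacement_is_one(self, rng):
        g1 = random_web("g1", 5, 0.3, rng)
        g2 = random_web("g2", 5, 0.3, rng)
        costs = CostScheme(0.75, 0.5, 0.25)
        c_max = 0.5 * (g1.n_nodes + g2.n_nodes) + 0.25 * (g1.n_links + g2.n_links)
        assert normalize_score(c_max, g1, g2, costs) == pytest.approx(1.0)

    def test_hand_computed_ratio(self):
        # zero node cost (scenario with free species edits): only links count
        g1 = FoodWeb("g1", {"a", "b", "c"}, {("a", "b"), ("b", "c")})
        g2 = FoodWeb("g2", {"a", "b", "c"}, {("a", "b")})
        costs = CostScheme(0.25, 0.0, 0.25)
        assert normalize_score(0.25, g1, g2, costs) == pytest.approx(0.25 / (0.25 * 3))

    def test_degenerate_zero_denominator(self):
        assert normalize_score(0.0, FoodWeb("a"), FoodWeb("b"), CostScheme(1, 0, 0)) == 0.0

    def test_negative_cost_rejected(self, tiny_pair):
        with pytest.raises(ValueError):
            normalize_score(-0.1, *tiny_pair, CostScheme(1, 1, 1))


class TestEvolutionaryGED:
    def test_identity_seed_finds_zero_on_identical_webs(self, rng):
        web = random_web("w", 10, 0.2, rng)
        res = evolutionary_ged(web, web, CostScheme(0.75, 0.5, 0.25),
                               SearchParams(seed=1, stall_limit=50))
        assert res.raw_cost == 0.0
        assert not res.exact

    def test_never_exceeds_total_replacement(self, rng):
        for k in range(10):
            g1 = random_web("g1", int(rng.integers(0, 9)), 0.3, rng)
            g2 = random_web("g2", int(rng.integers(0, 9)), 0.3, rng)
            costs = CostScheme(0.25, 1.0, 0.5)
            res = evolutionary_ged(g1, g2, costs, SearchParams(seed=k, stall_limit=50))
            bound = 1.0 * (g1.n_nodes + g2.n_nodes) + 0.5 * (g1.n_links + g2.n_links)
            assert res.raw_cost <= bound + 1e-9
            assert 0.0 <= res.score <= 1.0

    def test_deterministic_given_seed(self, rng):
        g1 = random_web("g1", 7, 0.3, rng)
        g2 = random_web("g2", 7, 0.3, rng)
        params = SearchParams(seed=99, stall_limit=100)
        r1 = evolutionary_ged(g1, g2, CostScheme(0.75, 0.5, 0.25), params)
        r2 = evolutionary_ged(g1, g2, CostScheme(0.75, 0.5, 0.25), params)
        assert r1.raw_cost == r2.raw_cost and r1.mapping == r2.mapping

    def test_matches_exact_on_tiny_instances(self, rng):
        hits = 0
        for k in range(30):
            g1 = random_web("g1", int(rng.integers(2, 6)), 0.3, rng)
            g2 = random_web("g2", int(rng.integers(2, 6)), 0.3, rng)
            costs = CostScheme(0.25, 0.25, 0.25)
            ex = exact_ged(g1, g2, costs)
            ev = evolutionary_ged(g1, g2, costs, SearchParams(seed=k, restarts=3))
            assert ev.raw_cost >= ex.raw_cost - 1e-9  # never below the optimum
            hits += abs(ev.raw_cost - ex.raw_cost) < 1e-9
        assert hits >= 28


def test_cost_scheme_rejects_negative_costs():
    with pytest.raises(ValueError):
        CostScheme(-0.1, 1, 1)
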
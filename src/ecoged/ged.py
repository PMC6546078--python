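"""Error-tolerant graph matching between directed food webs.

The graph edit distance (GED) between two webs is the minimum total cost of
an edit path — a sequence of node insertions/deletions, link
insertions/deletions, and link reversals ("flips", which exchange consumer
and resource roles) — transforming one web into the other.  Each candidate
node correspondence induces a cheapest edit path whose cost is computed in
closed form; GED is the minimum over correspondences.  Three solvers are
provided:

* :func:`exact_ged` — exhaustive enumeration of injective partial
  correspondences, feasible for webs of up to ~6 nodes; the ground truth
  the heuristic is validated against.
* :func:`evolutionary_ged` — a steady-state evolutionary search over
  complete correspondences (smaller web padded with null partners), in the
  style of the GEDEVO network aligner: label-free, topology-driven, with
  the taxon-identity correspondence optionally injected into the initial
  population so shared-composition signal is never missed.
* :func:`identity_ged` — the single correspondence pairing equal taxon
  codes; no search.

Raw costs normalise to a [0, 1] dissimilarity score by dividing by the
delete-everything/insert-everything cost, so 0 is identity and 1 is total
replacement.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .foodweb import FoodWeb

__all__ = [
    "CostScheme",
    "NodeMapping",
    "GEDResult",
    "SearchParams",
    "pair_state",
    "mapping_cost",
    "exact_ged",
    "evolutionary_ged",
    "identity_ged",
    "normalize_score",
]


@dataclass(frozen=True)
class CostScheme:
    """Edit costs for one scenario.

    ``flip`` prices reversing a link's direction, ``node`` prices deleting
    or adding a taxon, ``link`` prices deleting or adding an interaction.
    Deletion and addition of the same element class share one price, which
    makes GED symmetric in its arguments.
    """

    flip: float
    node: float
    link: float
    scenario_id: int | None = None

    def __post_init__(self) -> None:
        if self.flip < 0 or self.node < 0 or self.link < 0:
            raise ValueError("edit costs must be nonnegative")

    @property
    def flip_effective(self) -> float:
        # delete+insert is always an admissible alternative route to a flip,
        # so the effective reversal price is capped at 2*link
        return min(self.flip, 2.0 * self.link)


@dataclass(frozen=True)
class NodeMapping:
    """An injective partial correspondence V1 → V2 encoding one edit path.

    Unmatched V1 nodes are deleted, unmatched V2 nodes inserted.
    """

    pairs: tuple[tuple[str, str], ...]
    deleted: frozenset[str]
    inserted: frozenset[str]

    @classmethod
    def build(cls, pairs, deleted=(), inserted=()) -> "NodeMapping":
        return cls(tuple(sorted(dict(pairs).items())), frozenset(deleted), frozenset(inserted))

    def validate(self, g1: FoodWeb, g2: FoodWeb) -> None:
        sources = [u for u, _ in self.pairs]
        targets = [v for _, v in self.pairs]
        if len(set(sources)) != len(sources) or len(set(targets)) != len(targets):
            raise ValueError("mapping is not injective")
        if set(sources) | self.deleted != g1.nodes or set(sources) & self.deleted:
            raise ValueError("pairs and deleted must partition V1")
        if set(targets) | self.inserted != g2.nodes or set(targets) & self.inserted:
            raise ValueError("image and inserted must partition V2")


@dataclass(frozen=True)
class GEDResult:
    raw_cost: float
    score: float
    mapping: NodeMapping
    evaluations: int
    seed: int | None
    exact: bool


@dataclass(frozen=True)
class SearchParams:
    """Evolutionary-search knobs.

    ``stall_limit`` iterations without improvement terminate a run (the
    aligner's stopping rule); ``max_iterations`` is a hard cap.
    """

    population_size: int = 128
    mutation_rate: float = 0.05
    elite_fraction: float = 0.1
    stall_limit: int = 1000
    max_iterations: int = 50_000
    seed: int = 0
    restarts: int = 1
    seed_with_identity: bool = True

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be a probability")
        if self.stall_limit < 1:
            raise ValueError("stall_limit must be >= 1")


def pair_state(g: FoodWeb, u: str, v: str) -> str:
    """Classify the unordered pair {u, v} by link presence: none/forward/backward/both."""
    if u == v:
        raise ValueError("pair_state is undefined for u == v (self-loops are handled separately)")
    if u not in g.nodes or v not in g.nodes:
        raise ValueError("both nodes must belong to the web")
    fwd = (u, v) in g.links
    bwd = (v, u) in g.links
    if fwd and bwd:
        return "both"
    if fwd:
        return "forward"
    if bwd:
        return "backward"
    return "none"


class _Problem:
    """Adjacency-matrix view of a web pair for fast correspondence costing."""

    def __init__(self, g1: FoodWeb, g2: FoodWeb, costs: CostScheme):
        self.nodes1 = g1.sorted_nodes()
        self.nodes2 = g2.sorted_nodes()
        self.n1, self.n2 = len(self.nodes1), len(self.nodes2)
        self.idx1 = {c: i for i, c in enumerate(self.nodes1)}
        self.idx2 = {c: i for i, c in enumerate(self.nodes2)}
        self.A1 = np.zeros((self.n1, self.n1), dtype=bool)
        self.A2 = np.zeros((self.n2, self.n2), dtype=bool)
        for u, v in g1.links:
            self.A1[self.idx1[u], self.idx1[v]] = True
        for u, v in g2.links:
            self.A2[self.idx2[u], self.idx2[v]] = True
        self.E1 = int(self.A1.sum())
        self.E2 = int(self.A2.sum())
        self.costs = costs

    def cost(self, i1: np.ndarray, i2: np.ndarray) -> float:
        """Edit cost induced by the correspondence nodes1[i1[k]] ↦ nodes2[i2[k]]."""
        c = self.costs
        k = len(i1)
        total = c.node * ((self.n1 - k) + (self.n2 - k))
        if k == 0:
            return total + c.link * (self.E1 + self.E2)
        B1 = self.A1[np.ix_(i1, i1)]
        B2 = self.A2[np.ix_(i2, i2)]
        # links with an endpoint outside the matched set go with that endpoint
        total += c.link * (self.E1 - int(B1.sum()) + self.E2 - int(B2.sum()))
        X = B1 ^ B2
        diag_mismatch = int(np.diag(X).sum())          # self-loop presence differs
        off_mismatch = int(X.sum()) - diag_mismatch     # per-direction mismatches
        # pure reversals: both directions differ and g1 holds exactly one of them
        R = X & X.T & (B1 ^ B1.T)
        n_rev = int(R.sum()) // 2
        total += c.link * (off_mismatch - 2 * n_rev + diag_mismatch)
        total += n_rev * c.flip_effective
        return total

    def to_mapping(self, i1: np.ndarray, i2: np.ndarray) -> NodeMapping:
        pairs = {self.nodes1[a]: self.nodes2[b] for a, b in zip(i1, i2)}
        deleted = set(self.nodes1) - set(pairs)
        inserted = set(self.nodes2) - set(pairs.values())
        return NodeMapping.build(pairs, deleted, inserted)


def mapping_cost(g1: FoodWeb, g2: FoodWeb, m: NodeMapping, costs: CostScheme) -> float:
    """Total edit cost induced by a node correspondence.

    Node term: one node price per deleted/inserted taxon.  Link term, with
    no double counting: each link incident to a deleted or inserted node
    costs one link edit; between mapped pairs, the pair states are compared
    (each direction mismatch is one link edit, a pure reversal is priced
    ``min(flip, 2·link)``); a self-loop presence mismatch on a mapped node
    is one link edit.
    """
    m.validate(g1, g2)
    prob = _Problem(g1, g2, costs)
    i1 = np.array([prob.idx1[u] for u, _ in m.pairs], dtype=np.intp)
    i2 = np.array([prob.idx2[v] for _, v in m.pairs], dtype=np.intp)
    return float(prob.cost(i1, i2))


def normalize_score(raw_cost: float, g1: FoodWeb, g2: FoodWeb, costs: CostScheme) -> float:
    """Normalise a raw edit cost to [0, 1] by the total-replacement cost.

    The denominator ``C_max = node·(|V1|+|V2|) + link·(|E1|+|E2|)`` is the
    cost of deleting web 1 entirely and inserting web 2 entirely — an edit
    path that always exists — so identity maps to 0 and total replacement
    to 1.  Degenerate ``C_max = 0`` (e.g. zero costs) maps to 0.
    """
    if raw_cost < 0:
        raise ValueError("raw_cost must be nonnegative")
    c_max = costs.node * (g1.n_nodes + g2.n_nodes) + costs.link * (g1.n_links + g2.n_links)
    if c_max == 0:
        return 0.0
    return float(min(1.0, max(0.0, raw_cost / c_max)))


def exact_ged(g1: FoodWeb, g2: FoodWeb, costs: CostScheme, size_cap: int = 6) -> GEDResult:
    """Exact GED by exhaustive enumeration of injective partial correspondences.

    Feasible only for tiny webs (default cap 6 nodes per side); ties broken
    by enumeration order (ascending correspondence size, lexicographic node
    order) for determinism.
    """
    if g1.n_nodes > size_cap or g2.n_nodes > size_cap:
        raise ValueError(
            f"exact solver capped at {size_cap} nodes per web "
            f"({g1.n_nodes}, {g2.n_nodes} given); use evolutionary_ged"
        )
    prob = _Problem(g1, g2, costs)
    best_cost = np.inf
    best: tuple[np.ndarray, np.ndarray] | None = None
    evals = 0
    all1 = range(prob.n1)
    all2 = range(prob.n2)
    for k in range(min(prob.n1, prob.n2) + 1):
        for sub1 in itertools.combinations(all1, k):
            a1 = np.array(sub1, dtype=np.intp)
            for sub2 in itertools.combinations(all2, k):
                for perm in itertools.permutations(sub2):
                    a2 = np.array(perm, dtype=np.intp)
                    c = prob.cost(a1, a2)
                    evals += 1
                    if c < best_cost:
                        best_cost = c
                        best = (a1, a2)
    assert best is not None
    mapping = prob.to_mapping(*best)
    return GEDResult(
        raw_cost=float(best_cost),
        score=normalize_score(float(best_cost), g1, g2, costs),
        mapping=mapping,
        evaluations=evals,
        seed=None,
        exact=True,
    )


def identity_ged(g1: FoodWeb, g2: FoodWeb, costs: CostScheme) -> GEDResult:
    """Cost of the single correspondence pairing equal taxon codes (no search)."""
    prob = _Problem(g1, g2, costs)
    shared = sorted(g1.nodes & g2.nodes)
    i1 = np.array([prob.idx1[c] for c in shared], dtype=np.intp)
    i2 = np.array([prob.idx2[c] for c in shared], dtype=np.intp)
    raw = float(prob.cost(i1, i2))
    return GEDResult(
        raw_cost=raw,
        score=normalize_score(raw, g1, g2, costs),
        mapping=prob.to_mapping(i1, i2),
        evaluations=1,
        seed=None,
        exact=False,
    )


def _genome_arrays(perm: np.ndarray, n1: int, n2: int) -> tuple[np.ndarray, np.ndarray]:
    """Decode a padded permutation into matched index arrays.

    Genome: a permutation of 0..n1+n2-1.  Position i < n1 is real node i of
    web 1; value j < n2 is real node j of web 2; anything else is a null
    partner (deletion/insertion).
    """
    head = perm[:n1]
    mask = head < n2
    i1 = np.nonzero(mask)[0]
    return i1.astype(np.intp), head[mask].astype(np.intp)


def _eval_genome(prob: _Problem, perm: np.ndarray) -> float:
    return prob.cost(*_genome_arrays(perm, prob.n1, prob.n2))


def _identity_genome(prob: _Problem, rng: np.random.Generator) -> np.ndarray:
    n1, n2 = prob.n1, prob.n2
    N = n1 + n2
    perm = np.full(N, -1, dtype=np.intp)
    used = np.zeros(N, dtype=bool)
    for code, i in prob.idx1.items():
        j = prob.idx2.get(code)
        if j is not None:
            perm[i] = j
            used[j] = True
    free = np.nonzero(~used)[0]
    rng.shuffle(free)
    perm[perm < 0] = free[: int((perm < 0).sum())]
    return perm


def _delete_all_genome(prob: _Problem) -> np.ndarray:
    n1, n2 = prob.n1, prob.n2
    # every real node of web 1 gets a null partner; nulls absorb web 2
    return np.concatenate([np.arange(n2, n2 + n1), np.arange(n2)]).astype(np.intp)


def _evolve_once(prob: _Problem, params: SearchParams, rng: np.random.Generator) -> tuple[float, np.ndarray, int]:
    n1, n2 = prob.n1, prob.n2
    N = n1 + n2
    P = params.population_size
    genomes = [rng.permutation(N).astype(np.intp) for _ in range(P)]
    genomes[0] = _delete_all_genome(prob)
    if params.seed_with_identity:
        genomes[1 % P] = _identity_genome(prob, rng)
    fitness = np.array([_eval_genome(prob, g) for g in genomes])
    evals = P
    order = np.argsort(fitness, kind="stable")
    n_elite = max(1, int(round(params.elite_fraction * P)))
    best_cost = float(fitness[order[0]])
    best = genomes[order[0]].copy()
    stall = 0
    it = 0
    while stall < params.stall_limit and it < params.max_iterations:
        it += 1
        # elitist parent selection: one parent from the current elite ranks
        p1 = genomes[order[rng.integers(n_elite)]]
        p2 = genomes[rng.integers(P)]
        child = p1.copy()
        pos = {int(v): i for i, v in enumerate(child)}
        # assignment crossover: graft parent-2 pairings position by position,
        # repairing the permutation with swaps
        for i in np.nonzero(rng.random(n1) < 0.5)[0]:
            want = int(p2[i])
            if child[i] != want:
                j = pos[want]
                pos[int(child[i])] = j
                pos[want] = int(i)
                child[j] = child[i]
                child[i] = want
        # swap mutation
        for i in np.nonzero(rng.random(N) < params.mutation_rate)[0]:
            j = int(rng.integers(N))
            child[i], child[j] = child[j], child[i]
        c = _eval_genome(prob, child)
        evals += 1
        worst = order[-1]
        if c < fitness[worst]:
            genomes[worst] = child
            fitness[worst] = c
            order = np.argsort(fitness, kind="stable")
        if c < best_cost - 1e-12:
            best_cost = float(c)
            best = child.copy()
            stall = 0
        else:
            stall += 1
    return best_cost, best, evals


def evolutionary_ged(g1: FoodWeb, g2: FoodWeb, costs: CostScheme, params: SearchParams | None = None) -> GEDResult:
    """Approximate GED by steady-state evolutionary search.

    Complete correspondences (each web padded with null partners for the
    other's nodes) are encoded as permutations and evolved by elitist
    parent selection, assignment crossover, and swap mutation, with
    replace-worst survivor selection.  A run stops after ``stall_limit``
    offspring without improvement; ``restarts`` independent runs are pooled.
    The delete-all/insert-all correspondence is always in the initial
    population, so the result never exceeds the total-replacement cost.
    Deterministic given ``params.seed``.
    """
    if params is None:
        params = SearchParams()
    prob = _Problem(g1, g2, costs)
    master = np.random.SeedSequence(params.seed)
    best_cost = np.inf
    best_perm: np.ndarray | None = None
    total_evals = 0
    for child_seq in master.spawn(max(1, params.restarts)):
        rng = np.random.default_rng(child_seq)
        cost, perm, evals = _evolve_once(prob, params, rng)
        total_evals += evals
        if cost < best_cost:
            best_cost, best_perm = cost, perm
    assert best_perm is not None
    mapping = prob.to_mapping(*_genome_arrays(best_perm, prob.n1, prob.n2))
    return GEDResult(
        raw_cost=float(best_cost),
        score=normalize_score(float(best_cost), g1, g2, costs),
        mapping=mapping,
        evaluations=total_evals,
        seed=params.seed,
        exact=False,
    )
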
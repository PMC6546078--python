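# ecoged

Community similarity for directed food webs, measured jointly on species
composition and trophic interactions.

Ecologists usually compare communities by who is there (compositional
similarity, e.g. the Jaccard index) and, more rarely, by who eats whom
(interaction similarity).  `ecoged` treats each community as a directed
consumer–resource network g = (V, E) and measures the distance between two
communities as a **graph edit distance (GED)**: the minimum total cost of an
edit path λ — node insertions/deletions, link insertions/deletions, and link
reversals ("flips", which invert the direction of energy flow) — that
transforms one web into the other,

```
GED(g1, g2) = min_λ C(λ),   C(λ) = Σ c(e_i),
```

normalised to [0, 1] by the delete-everything/insert-everything cost so that
0 is identity and 1 is total replacement.  Because each edit class carries
its own cost, a researcher can price species turnover, interaction rewiring
and role reversal independently; a grid of 49 published cost scenarios is
built in.  The package then quantifies how much information the GED-based
similarity shares with

* compositional similarity, 1 − Jaccard where Jaccard = (a+b)/(a+b+c), and
* the interaction β-diversity partition B_WN (whole-network link
  dissimilarity), B_OS (dissimilarity among links of shared species) and
  B_ST = B_WN − B_OS (turnover component),

using the **max-normalised adjusted mutual information**

```
AMI = (I(U,V) − E{I(U,V)}) / (max{H(U), H(V)} − E{I(U,V)})
```

between equal-frequency-discretized similarity vectors, with the expected
mutual information computed exactly under the hypergeometric (permutation)
model.  AMI ≈ 0 means the two indices carry unrelated information; 1 means
they are informationally identical.

Exact GED is NP-hard, so beyond ~6 nodes per web an evolutionary search over
node correspondences approximates it (steady-state, elitist, terminated
after a configurable number of offspring without improvement); an exhaustive
exact solver validates the heuristic on small webs.

A synthetic community generator — niche-model metaweb, gradient-driven local
assembly, and a rewiring knob ρ that decouples interactions from
co-occurrence while preserving link counts — provides study-scale data (16
webs, 48–113 taxa, 110–832 links each by default) for every stage.

## Worked example

```python
from ecoged import (CostScheme, exact_ged, jaccard_similarity,
                    partition, read_edgelist)

g1 = read_edgelist(
    "source,target\nalgae,mayfly\nmayfly,trout\nalgae,caddisfly\ncaddisfly,trout\n",
    "stream_a")
g2 = read_edgelist(
    "source,target\nalgae,mayfly\nmayfly,trout\ntrout,eel\n",
    "stream_b")

costs = CostScheme(flip=0.75, node=0.5, link=0.25)   # scenario 36
res = exact_ged(g1, g2, costs)
print(res.raw_cost, round(res.score, 4))             # 0.75 0.1304
print(jaccard_similarity(g1, g2))                    # 0.6
p = partition(g1, g2)
print(round(p.b_wn, 4), p.b_os, round(p.b_st, 4))    # 0.4286 0.0 0.4286
```

The optimal correspondence pairs the three shared taxa with themselves and,
because the search is topology-driven, maps caddisfly onto eel; the three
mismatched links then cost 3 × 0.25 = 0.75, a score of
0.75 / C_max = 0.75 / 5.75 ≈ 0.13.  The webs are structurally close even
though they share only 3 of 5 taxa (1 − Jaccard = 0.6).  The β-partition
attributes all interaction dissimilarity (B_WN ≈ 0.43) to species turnover
(B_ST = B_WN, B_OS = 0): on their shared taxa the two webs feed
identically.

From a shell, the same comparison is `ecoged compare --web1 a.csv --web2
b.csv --flip 0.75 --node 0.5 --link 0.25 --mode exact`; `ecoged sweep`,
`ecoged simulate` and `ecoged experiment` drive the full scenario grid,
the synthetic generator and the decoupling experiment.

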
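# wrcf

Topological analysis of weighted functional networks: **w**eight **r**ank
**c**lique **f**iltration, persistent homology with representative cycles,
and homological scaffolds.

## The problem

Functional connectivity studies (resting-state fMRI and similar) produce
dense, weighted, signed networks — typically partial-correlation matrices
between brain regions. Thresholding such a network discards the weak
links, yet mesoscopic structure often lives precisely in the *relation*
between strong and weak links: a cycle of regions whose mutual
connections are strong, surrounding a "hole" of comparatively weak
internal connectivity, is invisible to any single threshold.

`wrcf` analyses the whole weight fabric at once. Edge weights are sorted
in descending order and their dense ranks ω = 1, 2, … index a nested
family of binary graphs G_ω and their clique (flag) complexes K_ω, in
which every (k+1)-clique is a filled k-simplex. Persistent homology of
the filtration {K_ω} tracks each 1-dimensional cycle (hole) g from the
step β_g where its boundary closes to the step δ_g where triangles fill
it; the persistence π_g = δ_g − β_g measures how much heavier a hole's
boundary is than the links that eventually close it.

Because a persistence diagram forgets *which* edges carry the holes, the
package also builds the two **homological scaffolds** over the H₁
generators g_i with representative cycles and persistences π_i:

- persistence scaffold: W^p_e = Σ_i π_{g_i} · 1[e ∈ g_i]
- frequency scaffold: W^f_e = Σ_i 1[e ∈ g_i]

Both share one edge set (the union of all representative cycles). An edge
that is heavy in W^p but ordinary in W^f belongs to a few unusually
stable cycles — a locally strong bridge. Representatives are a basis
choice, so scaffolds are summaries rather than topological invariants;
`triangle_audit` quantifies the ambiguity.

For two experimental conditions, `wrcf` pools the per-subject diagrams of
each group, compares persistence, birth and scaffold-weight distributions
with two-sample Kolmogorov–Smirnov tests, fits W^p against W^f per edge
by OLS and tests slope equality, and reports community structure
(Louvain) plus cross-community edge counts of the thresholded scaffolds.

## Worked example

The canonical toy case: a square a–b–c–d whose boundary edges are strong
(0.9, 0.8, 0.7, 0.6) plus a weak diagonal (a, c) = 0.1 that closes the
hole by creating the triangles (a, b, c) and (a, c, d).

```python
from wrcf import (WeightedNetwork, rank_filtration, persistent_homology,
                  persistence_scaffold)

net = WeightedNetwork()
for u, v, w in [("a","b",0.9), ("b","c",0.8), ("c","d",0.7),
                ("a","d",0.6), ("a","c",0.1)]:
    net.add_edge(u, v, w)

filt = rank_filtration(net)                   # 5 distinct weights -> 5 steps
gens = [g for g in persistent_homology(filt, max_dim=1)
        if g.dimension == 1 and not g.zero_persistence]
for g in gens:
    print(f"H1 bar: birth step {g.birth_step} (w={g.birth_weight}), "
          f"death step {g.death_step} (w={g.death_weight}), persistence {g.persistence}")
sp = persistence_scaffold(gens, nodes=net.nodes)
print("persistence scaffold:", sp.weights())
```

prints

```
H1 bar: birth step 4 (w=0.6), death step 5 (w=0.1), persistence 1
persistence scaffold: {('a', 'b'): 1.0, ('a', 'd'): 1.0, ('b', 'c'): 1.0, ('c', 'd'): 1.0}
```

The hole is born at step 4 — the rank of the lightest boundary edge,
when the cycle is complete — and dies at step 5 when the diagonal enters
and fills it; its four boundary edges each inherit scaffold weight
π = 1. The diagonal is not part of any representative, so it is absent
from the scaffold.

## Command line

```bash
wrcf simulate -o sim --law peaked_plus_heavy_tail --subjects 8 --seed 1
wrcf net timeseries.csv -o pc.csv --drop CSF --drop WM     # partial correlations
wrcf ph pc.csv -o out/                                     # diagrams + scaffolds
wrcf compare --group-a a1.csv --group-b b1.csv -o cmp/ -f edgelist_csv
```

`net` builds signed partial-correlation matrices from regional time
series via the joint precision matrix (nuisance regressors are columns
prefixed `nuis_`), then optionally discards non-neural rows/columns
without recomputing. `compare` writes pooled density tables, the KS
battery, per-edge frequency-vs-persistence scatter and fits, community
partitions and a JSON comparison report.

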
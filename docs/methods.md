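# Methods

## Filtration model

The analysis substrate is an undirected, signed, weighted graph with a
stable node order (declaration order of the input file; every internal
index is a 0-based position in that order). The filtration is indexed by
the *dense descending rank* of the edge weights: all edges of equal
weight enter at the same step, so the number of steps equals the number
of distinct weights and each step corresponds to one threshold ω. At
each step the binary graph of the edges seen so far is promoted to its
clique (flag) complex: a k-simplex is present exactly when its k+1
vertices are pairwise connected. Vertices all enter at step 0 — only
edge-weight structure, not node arrival order, matters for cycles.

Three ranking modes handle signed weights. `signed` (default) ranks on
the signed value, so negative partial correlations enter last;
`absolute` ranks on |w|; `positive` discards non-positive edges
entirely. The convention for signed matrices is genuinely open — a
descending sweep can either treat a strong negative coupling as a strong
or as a late edge — so all three are implemented and the choice is an
explicit parameter rather than a baked-in assumption.

The clique-enumeration cap defaults to 3 (triangles), which is exact for
H₀ and H₁: a 1-cycle can only be filled by 2-simplices. Requesting
homology in dimension k sets the cap to k + 2.

## Persistence computation

Homology is computed over GF(2) by the standard column reduction of the
boundary matrix in simplex-stream order (appearance step, then
dimension, then lexicographic vertex tuple — a total order in which
faces always precede cofaces, deterministic for a given input file).
Columns are arbitrary-precision integers used as bitsets; column
addition is XOR, the pivot is the highest set bit.

Alongside R we track V with D = R·V. When the column of a d-simplex σ
reduces to zero, σ creates a d-cycle and the V column at that moment is
a concrete cycle through σ: this is the **representative, frozen at
birth**, with no later shortening or re-basing. This mirrors the
original use of the raw cycles returned by the reduction and is the
reason scaffolds are not topological invariants; the alternative
(minimal cycle representatives) is explicitly out of scope. When a later
column retains σ as its pivot, the class dies at that column's
appearance step; creators never used as pivots are essential.

Conventions:

- **Essential deaths.** For scaffold arithmetic every generator needs a
  finite persistence, so essential classes get the sentinel death
  `last step + 1`. In weight units the analogue is
  `last threshold − mean threshold gap` (1.0 when the filtration has a
  single step). The `essential` flag is preserved everywhere.
- **Tie steps.** Equal weights can create and fill a cycle at the same
  step (e.g. a triangle entering whole). Such pairs have π = 0, are
  recorded, flagged `zero_persistence`, and are excluded from scaffolds
  by default: they contribute nothing to the persistence scaffold but
  would inflate the frequency scaffold, and the two must keep one edge
  set. A flag re-includes them.
- **Units.** Births/deaths are carried both as rank steps and as the
  corresponding threshold weights; persistence can be measured in either
  (`units={"rank","weight"}`). Downstream statistics take the same flag.

Betti numbers are available independently of the pairing as
b_k = n_k − rank ∂_k − rank ∂_{k+1} over GF(2); the test suite uses a
separate dense-elimination implementation of the same quantity as an
oracle against the reduction.

## Scaffolds

Persistence scaffold `W_p(e) = Σ_i π_i · 1[e ∈ g_i]`; frequency scaffold
`W_f(e) = Σ_i 1[e ∈ g_i]`, over the chosen generator set. Group-level
scaffolds aggregate all subjects' generators into one list, which
commutes with summing per-subject scaffolds (tested). Because
representatives store vertex *positions*, aggregation across subjects
first remaps every generator onto a shared node universe
(`homology.remap_generators`).

The `triangle_audit` flags a generator when an edge entering during its
lifetime (β, δ], with both endpoints on the representative, closes a
triangle with two representative edges — the situation in which
persistence mass may be misattributed to the two older edges. Counting
is per generator (a generator is flagged if any such edge exists); the
report gives per-generator flags and the unflagged fraction.

## Partial-correlation networks

Regions and nuisance regressors are conditioned jointly: with C the
sample covariance of all columns and P = C⁻¹,
ρ_ij = −P_ij / √(P_ii P_jj) restricted to region rows/columns, diagonal
set to exactly 1 (the filtration ignores self-loops). Joint conditioning
is mathematically equivalent to pre-regressing the nuisance series and
keeps one linear-algebra path that is testable against a pairwise
residualization oracle (agreement to 1e-8 on full-rank inputs).

A rank-deficient covariance raises an error naming the collinear
columns (via the near-null eigenvectors); there is no silent ridging. An
explicit shrinkage parameter s mixes C with its diagonal,
C ← (1−s)C + s·diag C, default 0, for users who want regularization on
short panels. Dropping non-neural rows/columns afterwards deliberately
retains the conditioning on the dropped series.

## Group comparison

Per-subject H₁ diagrams are pooled with every generator as one
observation (a per-subject-mean alternative can be built from the same
`GroupSummary`). Densities are histogram estimates; log-densities report
empty bins as missing, never −∞; scaffold-weight histograms use
log₁₀-spaced bins (default 30). The KS test is the two-sample statistic
with the asymptotic p-value (`scipy.stats.ks_2samp(method="asymp")`);
the exact small-sample computation was considered and not used because
pooled samples here are hundreds to thousands of points. The
frequency-vs-persistence relation is summarized by OLS of W_p on W_f
across edges (errors-in-variables alternatives are out of scope); slope
equality between conditions is tested by
t = (b₁ − b₂)/√(se₁² + se₂²) with df = n₁ + n₂ − 4. Constant-frequency
scaffolds make the slope undefined and are flagged degenerate rather
than fitted. Communities come from Louvain modularity maximization
(networkx implementation) at a configurable resolution (default 1) with
a fixed, reported seed (default 0); labels are canonicalized by
descending community size. Cross-condition edge reports threshold both
scaffolds at w_min and count surviving, shared, and between-community
edges of the non-reference scaffold under the reference partition.

## Synthetic data

`planted_network` builds a cycle c₀…c_{L−1} with distinct boundary
weights from a high range and, in the `closing_chord` pattern, a
triangulation fan from c₀ ((c₀,c₂)…(c₀,c_{L−2})) with weights from a
strictly lower range, entering in descending order. Each fan chord is
filled instantly by a triangle with already-present edges (a
zero-persistence tie pair at its own step), so the planted class
survives exactly from the lightest boundary edge to the lightest fan
chord — the planted (β, δ) is exact, not probabilistic. Background nodes
form a random graph in the band strictly between the two ranges and
attach to the cycle through one bridge only; a bridge is a cut edge and
cannot create cycles through planted nodes. This guard is what turns
plant-and-recover assertions into equalities.

`group_ensemble` chains such modules (cycle lengths 4–6, subjects of 60
nodes by default — small enough that the full suite runs in seconds)
with bridge edges, drawing each module's weight-unit persistence from
one of two laws:

- `broad_uniform`: π ~ U(0.08, 0.35). Moderately long-lived cycles over
  a limited band; no extreme values.
- `peaked_plus_heavy_tail`: with probability 0.75, π ~ 0.01 +
  Exp(0.04) (transient cycles); with probability 0.25 a truncated
  Pareto(x_m = 0.25, α = 1.2, upper 0.9), sampled by inverse CDF so the
  truncation leaves no boundary atom.

The Pareto support starts above the broad law's maximum, so the top of
the pooled persistence-scaffold weight distribution is carried by the
heavy-tail condition alone: a small population of unusually stable
cycles against a background of transient ones, which is the qualitative
two-condition signature the comparison machinery must detect (broader
persistence-scaffold tail, indistinguishable frequency-scaffold
weights — every planted cycle passes through each of its edges exactly
once in either condition). The module construction realizes each drawn π
exactly (lightest boundary edge at b, lightest chord at b − π), verified
by comparing generation logs with computed persistence.

What the generator does *not* emulate: dense all-to-all connectivity
(real partial-correlation matrices are complete graphs; synthetic
subjects are sparse modular networks), signed edges, inter-subject
registration noise, and hemodynamic autocorrelation. Passing tests
therefore demonstrate correctness of the machinery and detectability of
planted contrasts at desk scale, not effect sizes on clinical data.

`gaussian_panel` draws time series from N(0, P⁻¹) for a given positive
definite precision matrix P (Cholesky sampling), optionally adding
independent nuisance components with random loadings; the ground truth
−P_ij/√(P_ii P_jj) is available in closed form.

## Numerical choices and limitations

- Matrix input symmetry tolerance 1e-8; CSV floats always written with
  12 significant digits, so repeated runs are byte-identical.
- The reduction is exact integer arithmetic; there are no numerical
  tolerances inside the homology computation. Determinism is
  bit-for-bit for a fixed input file.
- Problem sizes: the bitset reduction is designed for the sparse,
  moderate networks of the test battery and for dense matrices up to a
  few hundred nodes; complexity grows with the number of triangles, so
  dense 1000+-node matrices would need a compiled reduction.
- KS p-values are asymptotic; for pooled samples below ~50 points they
  are approximate.
- Louvain is stochastic; results are reproducible only through the
  recorded seed, and community labels are comparable across runs only
  after the canonical size ordering.
- The acceptance script (`scripts/acceptance.py`) reports only
  quantities it computes at run time; see the README for the list.
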
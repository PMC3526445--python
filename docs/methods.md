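# Methods

## Problem setting and representations

Genes are 1-based integers; an extremity is a (gene, end) pair ordered with
tails before heads, written `1t`/`1h`.  A genome is a validated matching on
the 2n extremities (`kmcp.genomes.Genome`); mixtures are adjacency multisets
(`PartialMultiGenome`).  Graph work (augmented genome graphs, breakpoint
graphs, mixture genome graphs) uses `networkx` multigraphs; a component is a
cycle exactly when it has as many edges as vertices.  All adjacency sets are
iterated and written in a canonical sorted order, so every operation and
every file the package writes is byte-reproducible.

## DCJ distance and its conventions

`dcj_distance` implements n − c − p/2 on the two-genome breakpoint graph.
Two conventions matter and are deliberate:

* **p counts paths with an odd number of vertices**, not odd edges, and an
  isolated extremity is a 1-vertex (odd) path.  This makes d(G, G) = 0 for
  genomes with telomeres (each telomere pair contributes two odd singletons).
* The arbiter for this reading is behavioral, not textual: `dcj_bfs_distance`
  searches the actual DCJ move graph (`dcj_neighbors`: the two rejoins of two
  adjacencies, adjacency–telomere exchanges, splits, joins) and the formula
  agrees with it exhaustively for n ≤ 2 and on hundreds of seeded pairs at
  n = 3.  Any discrepancy would surface as a test failure rather than being
  patched around.

## Single-genome completion

*Unrestricted.*  Close every breakpoint-graph path whose two terminal edges
are reference adjacencies; leave everything else open.  Joining other path
ends can only merge paths without creating cycles — and joining two odd-vertex
paths would *increase* the distance under the parity convention above — so
non-closable paths are left untouched.  Certified against the minimum over
all matching extensions on 100 seeded instances (n ≤ 4).

*Circular uni-chromosomal.*  The free-extremities graph R(G, A) has the free
extremities of G as vertices, a blue edge per breakpoint-graph path
(endpoints; adding that adjacency closes a breakpoint cycle) and a red edge
per augmented-graph path (endpoints; adding it closes a chromosome).  With a
circular reference, both edge sets are restrictions of perfect matchings, so
|blue| = |red| = |free|/2 and every component is an even alternating cycle —
asserted invariants, not assumptions.  The greedy solver first merges cycles
of R (cross-cycle pairs), then consumes blue edges, then adds the last
excluded edge; the blue-update capacity N_b − c + 1 is cross-checked by an
exhaustive search over *all* legal update sequences.  Where the procedure
says only "select two vertices", ties are broken by the lexicographically
smallest eligible pair — any optimal choice works, so determinism is free.
A partial genome that is already circular uni-chromosomal is returned
unchanged rather than rejected.

*Linear uni-chromosomal.*  The linear reference's two telomeres define its
excluded edge e; adding e gives a circular reference, the circular solver
runs, and one adjacency is removed: an **added** adjacency sharing e's
breakpoint cycle when θ(e) = 1, otherwise the smallest added adjacency.
Restricting removal to added adjacencies (the smallest, for determinism)
keeps the output a superset of the input, which "remove an arbitrary edge"
would not guarantee.  θ(e) is 2 iff e lies on a cycle of B(G, A_c), and the
identity ĉ_c = ĉ_ℓ + θ(e) is verified with both sides computed by exhaustive
completion enumeration.

## Mixtures

A mixture has an unrestricted k-completion iff its genome graph is
k-edge-colorable.  `chromatic_index_at_most` is an exact backtracking search
(largest-degree-first edge order, color-symmetry breaking) guarded at 32
edges; outside the guard the Δ lower bound may still answer "no", and
otherwise the result is an explicit *undecided* — a heuristic coloring is
never reported as a negative.  The exhaustive k-MCP solver enumerates
distinct partitions into ≤ k matchings, all condition-satisfying completions
of each class (every matching over the class's free extremities, filtered),
and all labeled mixture trees via Prüfer sequences ((k+1)^(k−1) trees; for
k = 2: one branch tree and the two path orientations).  Unordered color
classes with all labeled trees cover every assignment of classes to tree
positions exactly once.  Default guards are n ≤ 3, k ≤ 3; the guard is a
parameter because the hardness gadgets (n = 14) are cheap special cases —
their mixture graphs are disjoint even cycles, so each 2-coloring's classes
are perfect matchings with nothing left to complete.

### Validity domain of the circular/unrestricted equivalence

Restricting completions to all-circular genomes does not change the optimal
tree value **when the reference is circular**: every tree-edge distance is
then n − c, and an unrestricted optimum can be circularized by closing each
even-vertex path of each pairwise breakpoint graph into its own cycle and
each pair of odd-vertex paths into a shared cycle, never losing cycles.  For
a reference with telomeres the equivalence fails, and the package computes a
minimal counterexample (kept as a test): n = 1, empty mixture, empty linear
reference — the unrestricted optimum is 0, but the only circular completion
{{1h,1t}} is at distance 1, because circularization destroys the odd-path
credit p/2 against a non-circular reference.  The equality test therefore
draws circular references; the counterexample test documents the boundary.

## Hardness gadgets

`expand_clause` emits the seven sign-pattern conjunctions of a 3-clause (all
eight minus the all-negated one); exhaustive evaluation confirms at most one
is satisfied per assignment, exactly one iff the clause holds, and that
optima transfer clause-by-clause.  `build_gadget` adds 3m+1 fresh
single-variable padding conjunctions, then builds one cycle per variable of
length max(4t, 4) (t = the variable's literal occurrences in 3-literal
conjunctions), with alternating true/false perfect matchings.  Each literal
occurrence is hosted in its own block of four consecutive cycle vertices
(true-matching edge for a positive literal, false-matching edge for a
negative one), so no variable-cycle edge touches conjunction edges of two
different conjunction-cycles; the three host edges plus three conjunction
edges form the length-6 conjunction-cycle.  Gadget vertices are fresh
extremities, two per new gene, keeping the mixture and the reference ordinary
genome-world objects.

The padding count deserves a note: 3m+1 untouched cycles against 3m reference
edges does **not** satisfy the ℓ' > 2ℓ hypothesis under which path-tree
optimality is proved in general.  The construction is kept as specified, and
path-tree optimality is *verified computationally* on the tiny gadgets the
exact solver can handle (there, the best path value 21 − c(A,G₁) beats every
branch value), plus separately on instances that do satisfy ℓ' > 2ℓ.
Witness recovery (`recover_assignment`) reads each real variable from the
matching its cycle kept in the reference-adjacent genome; padding variables
are unconstrained by the geometry (their cycles carry no conjunction edges),
so the back-mapping fixes them to true, their trivially optimal value.

## Synthetic data

`simulate_mixture` emulates the motivating measurement process: a reference
genome with a configurable chromosome spec, one genome per mixture-tree edge
obtained by uniformly random DCJ moves from its parent, independent
per-adjacency Bernoulli masking, and pooling into an unattributed multiset
(ground truth returned separately).  Defaults — 30 genes, two linear
chromosomes, two genomes on a path, 5 moves per edge, 20% masking — are the
package's choice of a modest tumor-like scenario; tests use smaller sizes.
What the simulator does *not* model: false-positive adjacencies, copy-number
events, duplicated genes, read-level effects, or biased dropout — so passing
tests certify algorithmic correctness on the clean adjacency model, not
robustness to measurement error.  Scramble moves are not constrained to
preserve the root's chromosome structure (the flags describe the generated
root only).  All randomness flows from the single config seed; identical
configs reproduce instances byte-for-byte.

## Numerical and scale choices

Everything here is exact integer combinatorics; there are no tolerances.
Guards keep exhaustive components honest about their reach: BFS distance
n ≤ 4, completion enumeration ≤ 10 free extremities (2n for the k-MCP inner
loop), coloring search ≤ 32 edges, tree enumeration k ≤ 4.  Test sweeps use
n ≤ 4 genomes, 100-instance solver-vs-oracle samples, 200 DCJ/BFS pairs at
n = 3, and 50 mixtures for the circular/unrestricted equality — sizes at
which the exhaustive oracles enumerate complete solution spaces.  Known
limitations: no weighted or error-tolerant adjacencies, no approximation
algorithms for k ≥ 2 (the problem is NP-complete there; only the exhaustive
solver is provided), and completability is defined only for the condition
sets the solvers support.
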
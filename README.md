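# kmcp — reconstructing genome mixtures from partial adjacencies

Tumor sequencing reads come from a mixture of cells, so the novel adjacencies
(breakpoints) created by somatic rearrangements are measured **without knowing
which genome in the mixture each one belongs to**, and coverage limits mean
**not every adjacency is measured at all**.  `kmcp` is a toolkit for the
*k-minimum completion problem*: given such an incomplete, unattributed
multiset of adjacencies and a reference genome, reconstruct the k genomes in
the mixture — and a tree relating them to the reference — at minimum total
rearrangement distance.

## The model

A genome on n genes is a matching on the 2n gene extremities
(head g<sub>h</sub>, tail g<sub>t</sub>); unmatched extremities are telomeres.
Adding each gene's internal edge {g<sub>t</sub>, g<sub>h</sub>} gives the
augmented genome graph, whose cycle components are circular chromosomes and
path components linear ones.  For genomes G₁, G₂, the breakpoint graph
B(G₁,G₂) carries both matchings, and the double-cut-and-join distance is

&nbsp;&nbsp;&nbsp;&nbsp;d<sub>DCJ</sub>(G₁,G₂) = n − c − p/2,

with c the cycle components and p the path components with an odd number of
vertices (isolated extremities count).  A *partial genome* is a matching
missing some adjacencies; a *partial multi-genome* (mixture) is an adjacency
multiset with unknown attribution; a *k-completion* splits and extends it
into k genomes; the objective sums pairwise distances along a *mixture tree*
rooted at the reference.

What the package provides:

* **Exact linear-time solvers for k = 1** — unrestricted completion (close
  every breakpoint-graph path flanked by reference adjacencies), circular
  uni-chromosomal completion (greedy over the bicolored *free-extremities
  graph*, whose blue-update capacity is N_b − c + 1), and linear
  uni-chromosomal completion (via the circular solver and the correction term
  θ(e) ∈ {1, 2}).
* **k-completion existence test** — a mixture has an unrestricted
  k-completion iff its genome graph is k-edge-colorable; decided exactly by
  backtracking on small instances, by the Δ bound otherwise, with an explicit
  "undecided" outcome beyond the guard.
* **Exhaustive exact k-MCP** on tiny instances (all colorings × completions ×
  labeled trees), used as the optimization oracle.
* **Hardness gadget constructors** — the MAX 3-SAT → MAX 3-AND clause
  expansion and the MAX 3-AND → 2-MCP graphical representation
  (variable-cycles with true/false matchings, length-6 conjunction-cycles,
  3m+1 padding), with score/assignment bookkeeping to audit the reduction end
  to end.
* **A seeded simulator** for synthetic mixtures with ground truth, plus
  breakpoint-graph/DCJ machinery, a BFS move-count oracle, and plain-text I/O
  (adjacency format and GRIMM-style signed permutations).

## Worked example

A 5-gene genome with adjacency set {1h,3h}, {5t,2t}, {2h,4t}, {4h,5h}:

```sh
$ kmcp chromosomes fig.txt --json
```

reports two chromosomes — genes {1,3} linear, genes {2,4,5} circular — and
telomeres `1t`, `3t`.

Completing the partial genome G = {{1h,2t}} on 3 genes to a single circular
chromosome against the circular reference A = {{1h,2t},{2h,3t},{3h,1t}}:

```sh
$ kmcp complete1 partial.txt ref.txt --condition circular
genes 3
1t 3h
1h 2t
2h 3t
condition=circular  added_adjacencies=2  breakpoint_cycles=3  dcj_distance=0
```

The solver adds {1t,3h} and {2h,3t}, recovering the reference itself: the
breakpoint graph reaches the maximum of 3 cycles, so the DCJ distance is 0.
Exhaustive enumeration of all circular uni-chromosomal completions confirms 3
is optimal.  Removing one reference adjacency e and asking for a *linear*
completion costs exactly θ(e): 1 when e lies on a breakpoint-graph path
(best linear completion has 2 cycles), 2 when it lies on a cycle (1 cycle).

Other subcommands: `kmcp dcj-dist` (with `--oracle` BFS cross-check),
`kmcp kcheck -k` (completable / not completable / undecided), `kmcp
brute-kmcp -k` (exact tiny-instance k-MCP; exit status 3 means "no valid
solution"), `kmcp reduce-3and` (gadget files + JSON cycle map), and `kmcp
simulate` (seeded synthetic instances with ground truth).

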
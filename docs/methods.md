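# Methods

## Graph model and coordinates

The reference `R` is a chain of `|R|+1` coordinate vertices `v_0 .. v_|R|`
whose edges spell `R`; this chain is the coordinate axis.  All coordinates in
the package are 0-based; VCF's 1-based, anchor-based representation is
converted at the I/O boundary only.  A SNP at coordinate `c` is an extra
labeled edge `v_c → v_{c+1}`; a deletion of span `s` is an ε-labeled edge
`v_c → v_{c+s}`; an insertion is a labeled chain leaving and re-entering
`v_c`.  The variants sharing a coordinate form one *locus* (the vertex's
out-degree minus one counts its alleles), and selection is all-or-nothing per
locus: once one allele at a coordinate is dropped, overlapping paths already
pay an error there, so an optimal solution never retains the rest.  When a
locus is dropped, the vertex's single outgoing label is the reference base.
Reference `N`s are ordinary characters that mismatch everything but `N`.
Two deletions with identical (coordinate, span) are deduplicated into one
edge, as are identical SNP or insertion alleles.

### Path admissibility

A path spells the concatenation of its non-ε labels; a path with α labeled
edges spells an α-long string.  Recombinant paths (combinations of variants
never co-observed in a haplotype) are deliberately included — the framework
preserves every path of the complete graph, not only haplotype walks.  Two
admissibility rules bound insertion traversals: a vertex may be visited at
most twice, and a path may enter an insertion chain at most once per host
coordinate, a path starting mid-chain counting as that one traversal.  The
second rule is the operative content of the first (a single completed
traversal visits the host vertex twice, blocking a second full loop), but it
is needed explicitly because a *partial* second entry that ends inside the
chain also collects the insertion's characters twice while respecting the
vertex rule — and such a path can exceed the per-locus penalty bound below,
which would void every safety guarantee in the package.

## Compatibility

A reduced graph `G'` is (α, δ)-compatible when every α-long string of `G`
maps from its corresponding start vertex in `G'` within δ differences.  For
SNP-only graphs the metric is positionwise Hamming distance over same-start,
same-length paths.  With indels it is semi-global edit distance: the whole
string must be consumed, the path end is free — the more permissive reading,
and the one matching how aligners anchor a read at a position.  A path that
started inside a dropped insertion is re-anchored at the insertion's host
coordinate vertex.

## SNP-only selection (exact)

Any α-long segment containing more than δ removed loci breaks compatibility
(the recombinant path taking every dropped alternative allele mismatches at
each of them), and conversely every segment's removed loci fit inside the
window `(p − α, p]` of its rightmost removed locus `p` — so feasibility is
exactly: at most δ removed loci in every window anchored at a variant
coordinate.

* `greedy_s` sweeps start events `max(0, p_i − α + 1)` and end events `p_i`
  (start before end on ties), removing a locus whenever fewer than δ removed
  loci are active.  Optimal for the fewest-retained-loci objective by an
  exchange argument, O(n) after sorting.
* `lp_s` maximizes removed variants `Cᵀx`, `C_i` = allele count, subject to
  `Ax ≤ δ`, `0 ≤ x ≤ 1`.  Rows of `A` cover the contiguous index range of
  each window, so `A` is an interval matrix and the LP (HiGHS) has an
  integral optimal vertex.  Values are accepted as integral within 1e-6
  (solver float noise only), rounded, and re-checked against the
  constraints; a fractional or infeasible point falls back to an exact ILP
  and is flagged — with an interval matrix this path should never trigger.

α larger than `|R|` behaves identically to α = `|R|`: windows already cover
every locus, and no α-long path exists to constrain further.

## Indel-aware selection (safe heuristics)

With deletion edges, an α-path can span more than α backbone positions, so
fixed-width windows are replaced by reachability windows.  `f(v, x)` — the
leftmost vertex from which `v` is reachable using fewer than `x` labeled
edges — obeys

    f(v_i, x) = min( i, f(v_{i-1}, x-1), f(v_j, x) for each deletion j → i )

since SNPs and insertions never move a path leftward along the axis.  The
window of locus `p` is `[f(v_p, α), p]`.  The vector `f(v_i, 1..α)` is
advanced left to right in O(α · (|R| + y)) time for `y` deletions; between
deletion endpoints and loci it has the closed form `max(0, i − x + 1)`, so
the implementation advances analytically between those event positions and
handles ~1 Mbp references in milliseconds.  Window starts are *not*
monotone in the locus coordinate: a deletion target's window can reach far
left of its neighbours'.  An independent 0-1 BFS over the reversed
deletion-only graph re-derives every window start in the tests.

Dropping a locus costs any single admissible path at most

    penalty = Δdel + Δins                    (both indel types present)
            = Δins (+1 with a coexisting SNP) (insertions only)
            = Δdel                            (deletions, with or without SNPs)
            = 1                               (SNPs only)

where Δins/Δdel are the longest insertion/deletion at the locus.  The mixed
insertion+SNP bound adds 1 because a path may traverse the insertion and
then a SNP edge.  If every window's removed-penalty sum stays ≤ δ the
reduction is edit-compatible: all dropped loci an α-path crosses lie inside
the window of the rightmost one (the path reaches it within α labeled
edges), so the path's total edit cost is bounded by that window's sum.

* `greedy_i` scans loci left to right and removes a locus only if *every*
  window containing its coordinate — windows of later loci reach left —
  keeps its accumulated sum within δ.  This is deliberately conservative:
  checking only the locus's own window is also safe by the argument above,
  but the resulting removal set can violate other windows' sums and hence
  need not be a feasible point of the ILP below, which would break the
  dominance guarantee.  The constraint scan uses an inverted index
  (position → containing windows) with running sums.
* `ilp_iv` / `ilp_ip` maximize `Σ C_i x_i` (`C_i` = allele count / 1) under
  `Σ_{j ∈ window_i} penalty_j x_j ≤ δ`, binary `x`, solved with HiGHS under
  a configurable time limit (default 60 s).  On timeout the best feasible
  incumbent is returned and flagged; with none, the greedy solution is
  returned and flagged.  Because the greedy output is feasible for the same
  constraints, the ILP objective is never worse.  Solver tie-breaking among
  equally optimal sets is version-dependent, so tests compare objective
  values, not set identity.

Since penalties are upper bounds, window feasibility is sufficient but not
necessary for edit-compatibility; no polynomial-time optimal algorithm is
known for the indel problems, and none is attempted.

## Verification oracle

`enumerate_alpha_paths` performs DFS from every coordinate and chain vertex
under the admissibility rules, with an explicit path cap that errors rather
than truncates.  `min_distance_from_vertex` runs Dijkstra over
(vertex, string-offset) states — ε edges cost 0; a labeled edge costs 0/1 as
it matches/mismatches the next character; the edit metric adds
skip-a-string-character and skip-a-path-character moves at cost 1.  The
target graph side of this DP does not re-impose the visit rules (tracking
them would blow up the state space); this can only make mapping easier,
i.e. the verifier is exact for violations it reports and marginally
permissive about near-budget passes through insertion cycles.
`brute_force_select` tries all 2ⁿ locus subsets, feasibility-checked either
against the window system (vectorized, exact for SNP-only graphs) or by full
path verification (tiny n), and is the optimality reference in the tests.

## Synthetic data

Generation is deterministic given the seed (numpy PCG64).  Defaults emulate
the human call sets the selection regimes are aimed at: SNP loci at one per
39 bp with ~0.3% multi-allelic, short indels (geometric lengths truncated to
1–50 bp) at about one per kilobase, and SV regimes of ≥50 bp indels with
log-uniform lengths up to 5 kbp, placed without mutual overlap so window and
penalty semantics stay unambiguous (overlap can be enabled by flag).  Bases
are i.i.d. uniform; real genomes have repeat structure and clustered
variants, so passing tests say nothing about mapping behaviour in repeats —
they certify the combinatorial guarantees (feasibility, optimality,
dominance, safety), which are sequence-independent.  Linkage and phasing are
not simulated because the framework deliberately preserves recombinant
paths.

## Problem sizes in tests

Exhaustive oracles bound the test scales: brute force at ≤ 14 loci,
path enumeration at α ≤ ~8 on ~30–60 bp references (hundreds of instances),
window/BFS cross-checks at |R| ≤ 200, α ≤ 20, and the SV-floor check on a
200 kbp / 30-SV catalogue; the acceptance script uses 1 Mbp and 500 SVs.
These sizes keep every guarantee independently verified while the full suite
runs in seconds.

## Known limitations

* Haplotype-aware selection (preserving only observed-haplotype paths) is
  out of scope; those problems are NP-hard even at δ = 1.
* No allele-frequency weighting; every variant counts equally.
* Only SNPs, insertions and deletions — no inversions, duplications or
  complex rearrangements (symbolic `<INV>` etc. records are counted and
  skipped at parse time).
* Genotype/sample columns are ignored; selection is haplotype-agnostic.
* The exhaustive verifier is exponential in local variant density and is a
  development/validation tool, not a production checker for full
  chromosomes.
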
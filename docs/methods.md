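# Methods

## Model

`pgentropy` treats a protein graph as a simple undirected graph
G = (V, E) on vertices 1..n, optionally equipped with a *geometry*: the
full symmetric table of pairwise Euclidean distances between the
vertices' representative coordinates (Å for proteins). Hop distance
d(u, v) (shortest-path length) and geometric distance are kept strictly
separate; the entropy formulas see only topology, while the
edge-adjustment rule ranks candidate edges by geometry.

### Entropies

*Classic entropy* I(G) is the Shannon entropy (base 2, reported in bits)
of the degree distribution pᵢ = deg(vᵢ)/Σdeg. It is undefined on an
edgeless graph; isolated vertices in otherwise non-trivial graphs
contribute 0·log 0 = 0.

*Extended entropy* I′(G) is the Shannon entropy of the distribution
qᵢ ∝ f(vᵢ), where the impact score sums the k-sphere sizes
|N_k(u)| = |{v : d(u,v) = k}| weighted by 1/(n − k + 1). The weight is
largest at k = 1 (denominator n) and shrinks toward distance
eccentricity(u) (denominator approaches 2), so *far* spheres weigh
*more* per vertex. The formula is implemented exactly as stated; the
resulting behavior — path below star below clique/cycle at four
vertices — is the ordering the measure is designed to produce. For a
connected graph Σ_k |N_k(u)| = n − 1 and q is a proper distribution, so
0 < I′(G) ≤ log₂ n with equality iff q is uniform (all
vertex-transitive graphs attain it).

I′ is undefined on disconnected graphs. The package raises a typed
`DisconnectedGraphError` carrying the label `NaC` ("not a connected
graph") rather than returning a sentinel number — 0 is a legal entropy
value, so report writers print the literal string instead.

Known discrepancies in the published worked examples, kept out of the
test targets because they contradict the formulas as stated: the path
value printed as 1.894 (direct evaluation gives 1.9877) and the
five-vertex example printed as 2.4835, which exceeds log₂ 5 ≈ 2.322 and
cannot arise from any normalized distribution (direct evaluation:
2.3162). The per-vertex probability 0.2214 printed for the same example
*is* consistent and is asserted. The star's classic entropy is exactly
1.79248, printed (misrounded) as 1.793; printed-precision comparisons
therefore allow one ulp of the last printed digit.

### Edge adjustment

`evaluate` computes the triple x = I′(G), y = I′(G − e_long),
z = I′(G + e_short), where e_long is the geometrically longest existing
edge and e_short the geometrically shortest absent pair. Equal lengths
are broken by sorting candidates on (length, min endpoint, max
endpoint), which makes every decision deterministic across platforms.

Classification follows the four published cases, with two boundary
policies decided here:

* **Case 1 is terminal and takes priority.** If removing e_long
  disconnects the graph, the decision is case 1 (y = NaC, action
  stop-disconnected) even when z > x; the source material treats the
  disconnection case as a stopping condition and we do not reorder it.
* **Complete graphs have no z.** The NaN sentinel marks the missing
  addition candidate and the decision falls back to x vs y: x > y is
  case 3 (stable), y > x case 4 (remove).
* **Orderings outside the four cases** (z > y > x, y > z > x, exact
  ties) are labeled `uncovered` with action none — the rule as published
  does not cover them, and we do not guess intent.

`iterate` applies the recommended action repeatedly, stopping at case 1,
case 3, `uncovered`, or a step cap. When every applied step was case 2
or case 4, the final I′ is at least the initial I′ by construction
(each such step strictly increases it); this is property-tested.

`sweep` implements the ±ke protocol. Removal candidates are the graph's
edges ranked once by descending length; addition candidates are its
non-edges ranked once by ascending length, both from the offset-0 graph,
and applied cumulatively. Ranking once (rather than re-ranking after
each step) matches the "k longest / k shortest" phrasing and makes each
column independent of the path taken. A row whose graph is disconnected
reports NaC (its density is still well-defined and increases with the
offset; the report writer prints "-" under NaC to mirror the published
layout); a row with no remaining candidate reports NaN and carries the
exhausted graph's density, which is how a complete graph shows NaN with
density 1.000 in its +ke columns.

### Spectra

The Laplacian is L = D − A with integer entries. Eigenvalues come from
the symmetric eigensolver (`numpy.linalg.eigvalsh`), are sorted
*descending*, and values within 1e−8 of zero are clipped to zero; the
zero-multiplicity then counts connected components. To compare spectra
of different orders the shorter vector is padded with trailing zeros —
padding descending spectra at the tail keeps the structural zero
eigenvalues aligned, whereas ascending padding would shift them. The
comparison statistic is the Euclidean distance of the padded vectors: a
genuine metric on padded vectors (property-tested for symmetry, zero
diagonal and the triangle inequality). We call it a distance and never
normalize it to [0, 1].

One published value deserves a note. For the five-vertex example graph
the published spectrum [4, 4, 1, 1, 0] is the integer rounding of the
true eigenvalues (4.3028, 3.6180, 1.3820, 0.6972, 0): rounding
reproduces the printed vector exactly, and the printed distance 1.414 =
√2 is exactly the distance from [4, 4, 2, 0, 0] to the *rounded* vector.
No simple graph attains [4, 4, 1, 1, 0] — by the matrix-tree theorem its
spanning-tree count would be 4·4·1·1/5 = 16/5, not an integer. The
package reports the true spectrum (and hence distance 1.0515 for that
pair); the padding rule itself is additionally unit-tested on the
printed vectors, where it yields 1.414. One acceptance test asserts the
printed vector literally and is expected to fail; it is kept as
documentation of the discrepancy rather than silenced.

### P-graph construction

Vertices are maximal runs of the three-state secondary-structure classes
(G/H/I → H, T/E/B → T, C → C; blank and S, which the three-class table
omits, fall to coil, the catch-all of standard 3-state reductions; any
other code is an error). Each segment is represented by the arithmetic
centroid of its residues' Cα coordinates — the simplest convention
consistent with measuring distances "between" elements, chosen because
the original construction is not published. The AVG threshold is the
mean Euclidean distance over *all* unordered vertex pairs (the threshold
must exist before any edge does), and the edge rule is inclusive:
distance ≤ AVG. Multimeric structures build one joint graph over all
supplied chains by default; `per_chain=True` splits them. A disconnected
result is legal and reported, not rejected.

Inputs: a plain residue TSV (chain, resnum, DSSP code, x, y, z), a real
DSSP output file (fixed-column parse of resnum/chain/SS/Cα columns), or
Cα coordinates pulled from a PDB file via Biopython.

## Synthetic data

`fixtures.random_geometric(n, multiplier, seed)` draws n points
uniformly in the unit cube and applies the distance-threshold rule at
`multiplier ×` the mean pairwise distance, so multiplier 1.0 emulates
the AVG rule on a structureless point cloud. This captures what the
adjustment and sweep machinery needs — geometric edge lengths correlated
with topology, densities near 0.5, occasional bridges and disconnected
outcomes — but none of the things that make real protein graphs special:
chain connectivity along the backbone, segregated H/T/C vertex classes,
anisotropic element packing, or the size range of real domains (tens of
vertices). Passing property tests on these graphs therefore validates
the *algorithms* (normalization, case trichotomy, density arithmetic,
metric axioms), not any biological claim about protein stability.

`fixtures.all_connected_graphs(n)` enumerates all connected labeled
graphs (guarded at n ≤ 6; 26,704 graphs at n = 6) as the substrate for
exhaustive oracle checks: the packaged entropy implementation is
compared against a literal brute force that recomputes all-pairs
distances by boolean matrix powers and sums the formulas term by term,
to 1e−12.

## Numerical and testing choices

* Logarithms are base 2 throughout; entropies are bits.
* Eigenvalue zero-tolerance 1e−8; oracle-equivalence tolerance 1e−12;
  paper-printed values compared at one ulp of their last printed digit.
* Problem sizes: the exhaustive oracle sweep covers every connected
  graph with n ≤ 6 (~5 s); distribution normalization and entropy
  bounds are checked on 1,000 seeded random geometric graphs at n = 8;
  the adjustment trichotomy on 400 seeds at n = 6; the non-monotone
  entropy-versus-density exhibit is the n = 7, seed 0 random geometric
  graph, frozen after inspection of its sweep.
* The table verdict "=" (not bad) uses equality after rounding to the
  report precision *or* a relative difference ≤ 0.5% — calibrated once
  so that a published pair differing by 0.02 at magnitude 19.3 counts as
  a tie, since the original never defines "not bad".
* Reports print entropies, densities and distances at 3 decimals.

## Limitations

* The edge-adjustment rule moves one edge at a time; it is a local
  criterion, not a global optimizer of I′ over graphs of fixed order.
* Entropy formulas ignore edge weights and labels; chemical edge
  attributes are out of scope.
* Cospectral non-isomorphic graphs exist, so a spectral distance of zero
  does not certify isomorphism.
* The original ten-structure experiment is not reproducible from the
  published record (the exact graph construction and vertex sets are
  unpublished); the package substitutes exhaustive and property-based
  validation at desk scale.
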
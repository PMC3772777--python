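# Methods

## The System Difference measure

`sdnet` analyzes directed, self-loop-free networks stored as adjacency
matrices **A** with rows as outputs and columns as inputs (`A[i,j] = 1`
is the edge i→j). Its central quantity, System Difference (SD), measures
node specialization: for every unordered pair of nodes it counts the
non-overlap (symmetric-difference size) of their successor sets and of
their predecessor sets, sums both, and divides by the n(n−1)/2 pairs,

    SD = [ Σ_{a<b} |Out(a) Δ Out(b)| + Σ_{a<b} |In(a) Δ In(b)| ] / (n(n−1)/2).

Rearranging the pairwise comparisons column by column shows the same
quantity is a quadratic functional of the degree sequence,

    SD = Σ_t [ in(t)(n − in(t)) + out(t)(n − out(t)) ] / (n(n−1)/2),

so SD depends on the graph only through its in-/out-degree distribution.
It is zero exactly for the edgeless graph, maximal (n²/(n−1)) when every
degree equals n/2, and invariant under node relabeling, edge-direction
reversal, and any positive reweighting of edges (weighted matrices are
binarized first). Both forms are implemented; numerators are accumulated
in exact integer arithmetic and divided only at the end, so the two
routes agree bit-for-bit — this equivalence is a standing test, not an
assumption. Per-node contributions (`sd_node`) are reported
unnormalized, matching the single-node decomposition; a normalized
variant is a flag.

Average Connectedness (AC) is the mean of the transitive reachability
matrix, AC = ΣR / n². The diagonal convention is that `R[i,i] = 1` only
when node i lies on a directed cycle (paths of length ≥ 1). This makes
AC = 1 exactly for strongly connected graphs and AC = 0 for the empty
graph; the alternative all-zero diagonal is available via
`reachability_matrix(..., cycle_diagonal=False)`.

## Random network populations

Three generation schemes cover the experiments, all producing directed,
self-loop-free matrices:

* **bernoulli** — each off-diagonal cell gets weight 0.5 with
  probability p (default 0.5). Used for the AC/SD development sweep.
* **fixed_column** — one column fill c ~ U{1..n−1} per matrix; each
  column receives exactly c entries of weight k/c (k = 0.5). Columns
  then sum to k, so the matrix is simultaneously binary-patterned and
  column-normalized (C = A) — the population used for all Φ work, since
  stationarity of the linear dynamics needs column sums below one.
* **uniform_density** — a density target u ~ U(0,1) is drawn and
  distinct off-diagonal cells are added in random order until the
  density reaches or just exceeds u (without replacement, which
  guarantees termination). Used for the 50- and 100-node substructure
  sweeps.

Populations are rejection-filtered: candidates that are not weakly
connected, or that are isomorphic to any earlier accept of the same run,
are discarded and redrawn. Isomorph rejection uses canonical-form
hashing (BLISS canonical labeling), with VF2 as the exact pairwise
check elsewhere. Each sampling run is a pure function of its
configuration and seed.

Population composition is not an implementation detail. The
isomorph-rejected fixed-column ensemble at its full scale
(24,000 accepts per size) strongly depletes the extreme-density column
fills, because few isomorphism classes exist there — at n = 8 there are
only ~210 weakly connected classes at c = 1, ~280 at c = 6 and exactly
one at c = 7 — and the SD–Φ correlation depends visibly on that
depletion. The Φ experiments therefore generate the population at full
scale (filtering costs seconds) and run the expensive Φ measurement on
a seeded uniform subsample; scaling down the *accept count* instead
changes the ensemble and inflates the correlation by about 0.1.

## Graph metrics

Cliques are found on the OR-symmetrized undirected graph (an edge in
either direction makes an undirected edge) with Bron–Kerbosch maximal
clique enumeration; omega is the largest maximal clique size. Average
path length is the mean directed geodesic over ordered pairs with a
path; unreachable pairs are excluded (the populations are weakly but
not necessarily strongly connected), and a strict mode raises instead.
Motif censuses classify induced 3- or 4-node subgraphs, counting only
weakly connected classes — 13 classes at size 3, 199 at size 4 — with
class identity given by the graph library's isomorphism-class numbering;
an exhaustive enumerator (`enumerate_motif_classes`) rebuilds the class
lists from all labeled digraphs and is cross-checked against the
library's tables in the tests. Size-3 motif classes group by edge count
into four density groups: {2,4}→1, {3}→2, {5}→3, {6}→4.

## The 2003 integrated-information measure

A system of n units with normalized connection matrix CON evolves by
the row-vector recursion F = F·CON + Ĉ∗R̂ with unit-variance white
noise R̂ and per-unit noise magnitudes Ĉ. The stationary covariance is
computed, by default, with the historical analytical shortcut of the
original reference implementation,

    Q = (I − CON)⁻¹,   COV = Qᵀ · diag(Ĉ²) · Q,

which treats the recursion as a simultaneous equation. This derivation
is known to be erroneous — the true stationary covariance solves the
discrete Lyapunov equation Σ = CONᵀ Σ CON + diag(Ĉ²) — but the
correlation analyses this package replicates were produced with the
shortcut, so
`mode="reference"` is the default and `mode="corrected"` (Lyapunov, via
`scipy.linalg.solve_discrete_lyapunov`) is provided for sensitivity
analysis. The two modes differ even for a two-node chain: the shortcut
predicts instantaneous cross-correlation across a single edge where the
temporal dynamics produce none (a standing test documents this), and
the corrected mode lowers the SD–Φ correlation.

Effective information from part A to part B of a subset is the Gaussian
mutual information MI(A:B) after assigning perturbation noise c_p = 1
to A and intrinsic noise c_i = 1e−5 to B and recomputing the stationary
covariance of the subset (taken in isolation, i.e. the connection
submatrix). EI(A↔B) = EI(A→B) + EI(B→A). The minimum information
bipartition of a subset minimizes EI(A↔B) / min{Hmax(A), Hmax(B)} with
Hmax(A) = |A|·½ln(2πe·c_p²); Φ of the subset is the unnormalized EI at
that cut, and the system's Φ is the maximum over all subsets of size
≥ 2. Ties among bipartitions break toward the lexicographically
smallest part containing the subset's first node, making results
deterministic.

Numerics: with c_i = 1e−5 the covariances have condition numbers near
(c_p/c_i)² = 1e10, so all determinants are taken in log space
(`slogdet`) and agreement between independent computational routes
bottoms out near 1e−6 relative — the tolerance the dual-route tests
use. The subset scan costs on the order of 3ⁿ bipartition evaluations;
it is vectorized by batching all bipartitions of a subset into one
covariance tensor (the full-set log-determinant has the closed form
2·log|det Q| + Σ log c²), and systems above a configurable cap
(default 12 nodes) are refused with a cost estimate rather than
approximated.

## The lag-based measure (Φ Empirical)

The same connection matrices drive a first-order autoregression
X_t = X_{t−1}·A₁ + E_t with identity noise covariance (order fixed at
one). The stationary covariance S solves the Lyapunov equation — here
correctly, as the measure's definition prescribes — and the lag-τ
cross-covariance is S·A₁^τ. Effective information across a whole-system
bipartition {M₁, M₂} at lag τ compares the temporal information of the
whole with that of the parts,

    EI = ½log[det S / det cov(X_{t−τ}|X_t)]
         − Σ_k ½log[det S_k / det cov(M^k_{t−τ}|M^k_t)],

with each conditional covariance a Schur complement of the
corresponding past/present joint. The MIB minimizes EI/K with
K = ½log min_k[(2πe)^{|M_k|} det S_k]; Φ is the unnormalized EI at the
MIB, computed for τ ∈ {1,2,3,4} and summed across lags. Everything is
in nats. The analytic route is validated against estimates from
simulated time series (sample covariances plugged into the same
formulas) within Monte-Carlo error.

## Experiments and fits

Each experiment family is a pure function of (configuration, seed) and
emits a tidy records table plus fit summaries. Regression conventions:
`FitResult.r` is the Pearson correlation between observed and fitted
values (signed, equal to the x–y correlation for a simple linear fit)
and `r_squared` is 1 − SS_res/SS_tot; both are always reported because
correlation tables in the literature do not always say which statistic
they print. For the SD–Φ series specifically, the variance-explained
reading is adopted for the headline values: under it the
full-population results at 8 and 9 nodes match the reference series
(0.667, 0.804) closely at both sizes, while the Pearson reading
matches at neither. The exponential
fit of AC on SD uses y = a·e^{bx} with a log-linear start refined by
least squares; a zero-variance response is flagged as NaN rather than
fitted. The skewed SD-vs-path-length trend is summarized by binned
means (bin width 0.1) with the argmax bin center reported, since a
single quadratic cannot represent the skew.

Default scales are sized for a single workstation core: Φ at 8 nodes on
2,000 of 24,000 networks and at 9 nodes on ~800, the AC/SD sweep at 500
networks per size, substructure sweeps at 1,000 networks. Full-scale
measurement (Φ on all 24,000) is a parameter, not a different code
path.

## What the synthetic populations do and do not show

All experiments run on randomly generated matrices, as in the original
design — there is no empirical connectome here. The populations probe
how SD relates to other structural and informational measures across
the space of random weakly connected digraphs; they do not establish
anything about specific biological networks, and conclusions about
small-world architectures are interpretive. Passing tests certify the
mathematical relationships (form equivalence, metric trends, measure
correlations) on these ensembles only.

## Known limitations

* The 2003 Φ subset search is exponential; sizes above the cap are
  refused, so the large-n end of the SD–Φ correlation series (10–13
  nodes) is out of desk-scale scope.
* The reference covariance mode reproduces a historically erroneous
  derivation on purpose; its Φ values should not be used as a correct
  integrated-information measure.
* No worked per-network Φ reference value was available to pin the
  covariance formula bit-exactly, so it is validated by closed-form
  two-node algebra and simulation cross-checks instead.
* Motif censuses are limited to sizes 3 and 4; weighted generalizations
  of SD are intentionally absent (undefined for the measure).

## A note on AC saturation

AC is informative only while reachability still varies. For dense
Bernoulli populations (p = 0.5) the probability of strong connectivity
grows quickly with n: by seven nodes roughly four of five weakly
connected samples have AC exactly 1, and the exponential fit of AC on
SD explains only about 38% of SD variance (about 80% at four nodes,
declining monotonically in between — the acceptance suite computes
these numbers). Any binary transitive-closure variant of AC (either
diagonal convention, any normalization) saturates the same way, so
population-level AC–SD association at this density should be expected
only for small systems or for populations that span a wide density
range.
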
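# Methods

## Generative model

A network on *n* nodes with total link weight *m* is modelled as the
superposition of *c* link communities. Community *z* carries two kinds
of parameters:

* ω_z ≥ 0 — the community *size*, defined as twice the expected link
  weight the community generates, so that Σ_z ω_z = 2m at a perfect fit;
* φ_iz ≥ 0 — the probability that community *z* picks node *i* when it
  places a link endpoint, with Σ_i φ_iz = 1 per community.

A link is generated by choosing a community with probability
ω_z / Σ ω, then drawing both endpoints independently from φ_·z. The
expected link count between the ordered pair (i, j) contributed by
community *z* is ω_z φ_iz φ_jz; summing over communities gives the
expected adjacency Â = X Xᵀ with X_iz = √ω_z · φ_iz. Multi-edges and
self-loops are allowed. We adopt the random-multigraph diagonal
convention A_ii = 2 × (self-loop weight), which makes Σ_ij A_ij = 2m an
identity and keeps the ordered-pair expectation ω_z φ_iz φ_jz free of
factor-2 corrections.

Given fitted parameters, the posterior fraction by which an observed
edge (i, j) belongs to community *z* is

    R_ij^z = ω_z φ_iz φ_jz / Σ_y ω_y φ_iy φ_jy ,

and the hard link partition takes the argmax (ties to the lowest
community index). An edge with zero probability under the model — which
can occur on subnetworks during recursive bipartition — receives the
uniform vector 1/c with a warning rather than an error, keeping the
driver robust. Overlapping node memberships follow from the link
partition: node *i* belongs to community *z* when the weight of its
incident links assigned to *z* exceeds a threshold fraction of its
degree. The threshold defaults to 0 (any incident link suffices); it is
exposed because any positive choice trades recall of overlapping nodes
for precision.

## Parameter fitting

Fitting minimizes, over nonnegative n×c factors X,

    O(X) = ‖A − XXᵀ‖²_F + λ (1ᵀXXᵀ1 − 2m)² ,

where 1ᵀXXᵀ1 = Σ_z (Σ_i X_iz)² is the model's total size, so the
penalty encodes the constraint Σ_z ω_z = 2m softly. The parameters are
read off the optimum as ω_z = (Σ_i X_iz)² and φ_·z = X_·z / Σ_i X_iz;
columns whose sum falls below 1e−8 are dropped as empty communities.

### Multiplicative update

Writing s = Xᵀ1 for the vector of column sums, the gradient of O splits
into a nonnegative attraction part A X + 2mλ·1sᵀ and a nonnegative
repulsion part X(XᵀX) + λ(sᵀs)·1sᵀ. The update multiplies each entry by
the ratio of the two raised to an exponent η:

    X ← X ∘ ( (A X + 2mλ 1sᵀ) / (X XᵀX + λ (sᵀs) 1sᵀ) )^η .

η = 1/4 (the default) is the exact minimizer of the standard auxiliary
function for this objective — a Jensen/AM–GM majorizer of the quartic
terms combined with the logarithmic minorizer of the quadratic terms —
so the objective is provably non-increasing at every step and is
stationary exactly at KKT points of O on the nonnegative orthant.
η = 1 gives the bare fixed-point form of the KKT conditions, which
shares the same fixed points but can overshoot; the exponent is exposed
for experimentation. One update costs O(mc + nc²): the sparse product
A X dominates for sparse networks, the Gram-matrix terms for dense
factors.

Numerical guards: denominator entries are floored at 1e−12, and updated
entries of X are floored at 1e−12 so that zeros are never absorbing
during the search; the returned factor zeroes entries below 1e−8.

### Two-phase schedule, restarts, convergence

Optimization runs in two phases: λ = 0 from a random start until
convergence, then λ = 1000 (default, configurable) from the phase-1
factor. The unpenalized phase finds a good factorization shape without
fighting the size constraint; the penalized phase then makes
Σ_z ω_z ≈ 2m to well under 1% in practice. Initial factors have i.i.d.
uniform (0, 1] entries rescaled by √(2m / 1ᵀXXᵀ1), so the size
constraint holds exactly at the start.

The objective is non-convex, so `fit` makes 10 random restarts by
default (each seeded from `(seed, restart_index)` via numpy's seed
sequences) and keeps the strictly lowest final objective, earlier
restarts winning ties. Each phase stops when the relative objective
change drops below `tol` = 1e−6 or after `max_iter` = 500 iterations;
non-convergence is reported in the result, not raised.

## Partition density and NMFIB

A community with link weight m_z touching n_z nodes has link density

    D_z = (m_z − (n_z − 1)) / (n_z(n_z−1)/2 − (n_z − 1)) ,

m_z normalized between tree (0) and clique (1); communities touching
fewer than three nodes score 0 by convention, and weighted or multigraph
communities denser than a simple clique report their raw value above 1
with a warning. The partition density is D = Σ_z (m_z / m) D_z, and the
change under splitting one community r into r₁, r₂ is

    ΔD = (m₁D₁ + m₂D₂ − m_r D_r) / m ,

which depends only on the community being split — so the acceptance
decisions of a recursive bipartition do not depend on traversal order.

NMFIB starts from all links in one community and recursively: isolates a
community's links as a compact subnetwork, fits the model with c = 2,
hard-assigns the links, and accepts the split iff both sides are
non-empty and ΔD > 0 strictly (ΔD = 0 stops the recursion; "no
improvement" is read strictly). Communities with fewer than 2 links are
never split. Recursion is depth-first; child fits use a seed derived by
hashing the parent seed with the child's link set, so runs are exactly
reproducible while children explore independent starts. The final
communities are the tree's leaves, numbered in depth-first order.

## Synthetic benchmark

The generator plants two overlapping link communities on *n* nodes:
*x* exclusive to community 1, *y* exclusive to community 2, *z* shared,
all with the same expected degree ⟨k⟩, shared nodes splitting theirs
equally. The degree-balance equations under the model give

    ω₁ = ⟨k⟩(x + z/2),   φ_i1 = ⟨k⟩/ω₁  (exclusive),  ⟨k⟩/(2ω₁)  (shared),

symmetrically for community 2, so every node's expected degree is
exactly ⟨k⟩ and the expected link total is n⟨k⟩/2. Networks are sampled
from the generative law itself: a Poisson-distributed number of links
with mean Σω/2 (a `fixed_m` mode conditions on the rounded mean for
reproducible fixtures), each picking a community and then endpoints.

Three experiment designs vary ⟨k⟩, the x:y ratio (grid over x/(x+y)
with x+y fixed; defaults 0.5–0.9), and the overlap z. The detector is
the c = 2 fit with the true community count supplied, as in the
benchmark's design. Accuracy is scored by FVCC — the fraction of nodes
whose *entire* predicted membership set equals the planted set, after
matching predicted to planted labels by optimal assignment on the
node-overlap confusion matrix — and by the Jaccard index |S∩V|/|S∪V|
between true (S) and predicted (V) overlapping-node sets. A
guess-the-modal-set chance baseline for FVCC is reported alongside.

What the generator does *not* emulate: degree heterogeneity, weighted
real-world edges, more than two planted communities (the multi-block
recovery property is tested separately through the model's own sampler),
and any correlation structure beyond the block pattern. Passing
benchmark tests therefore demonstrates recovery under the model's own
assumptions, not robustness to real-data deviations from them.

### Problem sizes used in the test suite

The shipped tests run the benchmark at n = 500 with overlap 25 and 5
replicates per grid point (the classic design uses n = 10000, overlap
500 and 50 replicates; both are available through the same interface).
At this scale the expected-degree sweep {2, 6, 10, 16} reproduces the
qualitative behaviour — accuracy rising steeply with ⟨k⟩ and exceeding
0.9 on both metrics at ⟨k⟩ = 16 — in a few seconds. n = 500 with 475
exclusive nodes cannot split exactly evenly, so x = 238, y = 237.

## Design choices and limitations

* **Hard-assignment ties** go to the lowest community index; restart
  ties to the earliest restart — both arbitrary but deterministic.
* **FVCC with surplus predicted labels**: labels left unmatched by the
  optimal assignment mark their nodes incorrect.
* **Weighted networks** reuse the unweighted formulas with m_z as total
  link weight; density values above 1 are then possible and flagged.
* The optimizer finds local minima only; pathological instances can
  need more restarts. NMFIB inherits this per split, and greedy
  acceptance cannot undo an early bad split.
* The two-phase penalty schedule enforces Σω = 2m only softly;
  residual constraint violation is typically below 1% at λ = 1000 and
  is reported in `summary()`.
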
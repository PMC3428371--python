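# Methods

## Problem setting

All solvers operate on polytopes in inequality form, P = {x ∈ ℝⁿ : Ax ≤ b}
with k constraint rows, and address two problems:

* **Linear programming** — min cᵀx over P;
* **Polytope projection** — min ‖x − z‖² over P, the Euclidean projection
  of a target z onto P (a quadratic program with identity Hessian).

Both solvers require a feasible starting point and do not perform a
feasibility phase (no big-M or two-phase bootstrap); the benchmark
generator guarantees the origin is feasible, and the protein-inference
compiler supplies an explicit feasible start.

## Conic sampling

The LP solver alternates two phases.

**Descent to fixation.** From a feasible x it repeatedly takes the
direction d = −proj⊥(c), the negated objective projected orthogonal to the
rows accumulated in the active basis, and moves to the first blocking
constraint (ratio test t* = minᵢ (bᵢ − aᵢᵀx)/(aᵢᵀd) over rows with
aᵢᵀd > ε). The blocking row joins the basis. Each accepted row has a
positive inner product with a direction orthogonal to the current span, so
it is linearly independent of the span and the basis rank strictly grows:
at most n insertions occur before the projected objective vanishes
("fixation"). The objective never increases during descent.

**Ray sampling at fixation.** The active rows A_S carve the polyhedral cone
of feasible directions {d : A_S d ≤ 0}. Its spanning rays are computed in
closed form as the negated rows of (A_S A_Sᵀ)⁻¹A_S — ray i satisfies
aⱼᵀrᵢ = −δᵢⱼ, i.e. it releases constraint i while staying on the others;
this equals projecting each inward normal orthogonal to the other rows. A
direction is sampled as d = Σᵢ λᵢ rᵢ with λᵢ i.i.d. Uniform(0, 1] **over
the improving rays only** (rays with cᵀrᵢ < −ε‖c‖; non-improving rays get
weight zero). This guarantees cᵀd < 0 in a single draw while preserving
random mixing over the improving cone. The sampled ray is followed through
the interior to the next blocking constraint, the basis is rebuilt from
scratch around that constraint (full rebuild is chosen over incremental
row removal: it costs up to a factor n per fixation but resets accumulated
round-off each iteration), and descent resumes. When no spanning ray
improves, the vertex is optimal.

When fewer than n rows are active at fixation (a face, not a vertex), a
random unit vector from the orthogonal complement of the active span is
mixed into d. The projected objective vanished there, so the complement
direction has zero objective slope — improvement still comes from the rays
— but the move can leave the face's affine hull, preserving the sampling
interpretation on degenerate faces.

**Certificates and anticycling.** Optimality is never declared from the
sampled cone alone. At any candidate optimum the solver solves the
nonnegative least-squares problem

    min_{λ ≥ 0} ‖A_Tᵀ λ + c‖        (T = all rows tight at x)

with scipy's NNLS. By the Farkas alternative exactly one of two things
happens: the residual is (numerically) zero, giving the certificate
−c = A_Tᵀλ, λ ≥ 0 that is stored on the result; or the residual vector r
yields the direction d = −r which satisfies A_T d ≤ 0 (NNLS first-order
conditions) and cᵀd = −‖r‖² < 0 — a strictly improving feasible direction
with a guaranteed nonzero step, since no tight row blocks it. This second
branch is the anticycling fallback: at degenerate vertices a sampled ray
can be blocked at step length zero by a tight row outside the basis; after
25 fruitless resamples the solver takes the certified direction instead.
The fallback plays the role of a Bland-style deterministic escape — it
guarantees strict objective decrease from any suboptimal point — while
reusing the certificate computation that must happen anyway. Termination
follows because fixation vertices have strictly decreasing objective and
the polytope has finitely many faces; `max_fixations` (default 10·(n+k),
far above observed behavior) guards against floating-point pathologies.

Ties in the ratio test break toward the smallest row index
(lexicographic), and unboundedness is detected whenever an improving
direction meets no blocking row.

## Projection variant

Two changes adapt the solver to the projection QP. First, the fixed
objective c is replaced by the local gradient g = x − z, recomputed after
every move. Second, a move along d stops at t_q = ((z − x)ᵀd)/(dᵀd) — the
exact 1-D minimizer of the squared distance — whenever t_q precedes the
constraint step; no constraint is added then. Because the Hessian is the
identity and the line search exact, an interior stop zeroes the projected
gradient immediately, so each descent phase still performs at most n
insertions. Unboundedness cannot occur (t_q is always finite).

At fixation the point is automatically the projection of z onto the affine
span of the active rows (the projected gradient vanished while all basis
rows are tight), so the classical "equality-constrained projection is
feasible" halting test is subsumed by the KKT check performed there: NNLS
over the tight rows with target z − x either certifies z − x = A_Tᵀμ,
μ ≥ 0 (the stationarity + dual feasibility half of the KKT conditions;
complementary slackness holds because only tight rows enter) or returns a
strictly descending feasible direction as in the LP case. The optimum is
unique, hence seed-independent; only the trajectory varies.

## Baselines

**Tableau simplex** (steepest-edge and random-edge pivot rules) solves the
slack form of min cᵀx, A'x ≤ b', x ≥ 0 with the slack variables as the
initial basis, valid because the benchmark polytopes contain the origin.
Explicit −xⱼ ≤ 0 rows are dropped from the tableau (slack form already
implies them); the solver refuses problems where nonnegativity is not
implied for every variable. Steepest edge uses the textbook ratio
c̄ⱼ/√(1 + ‖dⱼ‖²) on the current tableau columns rather than
reference-framework updates — the didactic variant appropriate for a
shared-codebase comparison. Random edge picks uniformly among improving
columns. After 30 pivots without objective improvement both rules switch
to Bland's smallest-index rule, which guarantees termination on degenerate
problems; leaving-row ties always break toward the smallest basis variable
index.

**Primal affine scaling** iterates from a strictly interior point with
slacks v = b − Ax > 0: the direction solves (Aᵀ diag(v)⁻² A) d = −c — the
steepest feasible descent in the metric that gives every nearby constraint
equal slack — and the step is β times the distance to the nearest
constraint. Defaults β = 0.9, stopping tolerance τ = 1e-9 on the relative
objective improvement, max 10 000 iterations. The raw direction shrinks
quadratically as iterates approach the boundary, so it is renormalized
each iteration and the stationarity exit uses a near-machine threshold;
without this the solver would stop at distance ~√ε from the optimum
instead of ~ε. The result is an approximate interior optimum: no crossover
to a vertex is performed. When the protocol starts "from 0" (a boundary
point of the nonnegativity rows), `interior_start` first steps halfway to
the nearest constraint along the averaged inward normal of the tight rows.

## Numerical policy

One global tolerance ε = 1e-9 (`conicopt.config.EPS`) governs every
zero/feasibility/dependence comparison, scaled by the magnitude of the
quantities involved (e.g. row feasibility uses ε·(1+|bᵢ|), dependence
rejection ‖residual‖ ≤ ε‖v‖). Certificate residuals use the looser
1e-6·(1+‖target‖) (`CERT_TOL`), reflecting accumulated error over a full
trajectory. Orthogonal bases store unit rows and re-orthogonalize each
inserted vector twice ("twice is enough"), keeping pairwise dot products
at working precision even for nearly dependent inputs. A single sparse
representation (CSR for A, dense vectors in the kernels) is used
throughout; the problem sizes here never make a dual sparse-dense layout
worthwhile.

## Random instances and what they do (not) show

`gen_random_lp` draws A and c uniformly from (−1, 1), zeroes a requested
fraction of A's entries (redrawing all-zero rows), draws b uniformly from
(0.1, 1.1) so the origin is strictly feasible, and appends −xⱼ ≤ 0 rows
for every variable (flagged for the simplex baseline to skip). c is not
sparsified by default. These uniform-box instances have no correlated or
near-parallel constraints and no structured degeneracy; passing on them
shows correctness and the qualitative scaling of the methods, not
performance on industrially structured LPs. Degeneracy is exercised
separately by duplicating every constraint row, which makes every vertex
degenerate.

The synthetic peptide-protein graphs attach each peptide to
1 + Poisson(mean_degree − 1) proteins and score peptides touching a
"present" protein (30% of proteins by default) from Beta(8, 2), background
peptides from Beta(2, 8). This reproduces the bipartite sharing structure
and the bimodal score mixture of a search-engine output, but not homology
clusters, degenerate peptide groups spanning many proteins, or decoy
structure — conclusions about those require real spectra.

## Reference oracles

The LP oracle enumerates all (k choose n) row subsets, solves each square
system and takes the best feasible vertex; unboundedness is decided first
by a box-bounded recession-ray feasibility LP (Ad ≤ 0, cᵀd ≤ −1)
delegated to scipy's HiGHS-backed `linprog`. The projection oracle
enumerates candidate active sets up to size n and projects z onto each
affine subspace via the Gram system. Both refuse instances beyond an
enumeration cap; they are deliberately independent of every solver in the
package.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run: 200 LPs with n ∈ {2..6},
k ∈ {4..12}, sparsity ∈ {0, 0.5}, three seeds each, against the vertex
oracle; 30 LPs with n = 20, k = 200, 95% sparsity across all four methods;
50 duplicated-row degeneracy instances; 100 projection instances with
n ≤ 5, k ≤ 10 against the active-set oracle plus 100 idempotence /
nonexpansiveness pairs; 20 synthetic inference graphs with 100 proteins ×
300 peptides (mean degree 2) audited by KKT residual, with 10-protein
variants checked against the oracle; and a benchmark grid at n = 50, 95%
sparsity, k ∈ {128, 512, 2048} with two replicates. These sizes keep the
whole suite in the minutes range on one core while covering every code
path; all of them are plain parameters that scale up freely.

## Known limitations

* No feasibility phase: an infeasible start is reported, not repaired.
* The simplex baseline only accepts problems whose nonnegativity is
  expressible in slack form; it is a benchmark companion, not a general
  LP solver.
* Affine scaling returns an interior approximation (relative tolerance τ),
  so comparisons against it use a looser 1e-4 band.
* The ray-sampling distribution fixes uniform weights on improving rays;
  the optimum is distribution-independent, but iteration counts under
  other sampling rules may differ.
* General convex QPs (non-identity Hessians) are out of scope; only
  projections onto polytopes are supported.
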
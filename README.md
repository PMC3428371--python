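# conicopt

Randomized **conic sampling** solvers for linear programming and for
projecting a point onto a polytope, with tableau-simplex and primal
affine-scaling baselines, a random-LP benchmark harness, and a
computational-proteomics application that scores proteins from peptide
evidence.

## The algorithm

For an LP `min cᵀx  s.t.  Ax ≤ b` starting from a feasible point, the
solver descends through the interior along `−c` projected orthogonal to
each constraint row it encounters, accumulating an independent active
basis until the projected objective vanishes (a *fixation*, reached after
at most `n` insertions). The active rows `A_S` then define a polyhedral
cone of feasible directions whose spanning rays are the negated rows of
`(A_S A_Sᵀ)⁻¹A_S`; a random conic combination of the *improving* rays
(those with `cᵀr < 0`) is followed back through the interior to a distant,
strictly better vertex, and descent resumes. If no spanning ray improves,
the vertex is optimal; optimality is always confirmed by a Farkas
certificate `−c = A_Tᵀλ, λ ≥ 0` over the tight rows (the same computation
doubles as a deterministic anticycling escape at degenerate vertices).
Because a sampled jump lands on a random *superior* vertex rather than an
adjacent one, highly constrained sparse polytopes are traversed in very
few fixations — the regime where this method shines against simplex
pivoting.

The projection variant solves `min ‖x − z‖²  s.t.  Ax ≤ b` by replacing
`c` with the local gradient `g = x − z` (refreshed after every move) and
stopping a move early at the exact 1-D minimizer along the ray whenever
that point is interior. Termination yields the unique nearest point with a
KKT certificate `z − x* = A_Tᵀμ, μ ≥ 0`.

**Protein inference.** Peptides observed in a shotgun mass-spectrometry
experiment map to proteins through a bipartite graph with per-peptide
scores `q_e ∈ [0, 1]`. Eliminating peptide variables by substitution gives
the quadratic program

    minimize ‖ρ‖²   s.t.   Σ_r w_r ρ_r ≥ γ,   ρ ≥ 0

with `w_r = Σ_{e ∼ r} q_e` and `γ` a fraction (default 0.9) of the total
peptide score mass — a projection of the zero vector onto a polytope with
`n + 1` constraints. The L2 objective enforces economy: proteins without
evidence score exactly zero, and shared peptides split their support.

## Worked example

Two proteins share a peptide: R1 carries peptides e1 (q=0.9) and e2
(q=0.8); R2 carries e2 and e3 (q=0.5). Then `w = (1.7, 1.3)`,
`γ = 0.9 × 2.2 = 1.98`, and the projection has the closed form
`ρ* = (γ/‖w‖²)·w`:

```python
>>> from conicopt import PeptideProteinGraph, infer_proteins
>>> G = PeptideProteinGraph(
...     ["R1", "R2"], ["e1", "e2", "e3"],
...     {("R1", "e1"), ("R1", "e2"), ("R2", "e2"), ("R2", "e3")},
...     {"e1": 0.9, "e2": 0.8, "e3": 0.5})
>>> table, result = infer_proteins(G, gamma_fraction=0.9, seed=0)
>>> print(table)
  protein_id     score  rank
0         R1  0.734934     1
1         R2  0.562009     2
>>> result.certificate.residual  # KKT residual of the optimum
1.942097114741681e-15
```

R1 outranks R2 because it carries more peptide evidence (1.7 vs 1.3); the
scores are exactly `(1.98/4.58)·(1.7, 1.3)`, the KKT solution with only
the evidence row active.

The same solvers run from the command line:

```sh
conicopt gen-lp --n 50 --k 2048 --sparsity 0.95 --seed 1 --out lp.json
conicopt solve-lp --in lp.json --method conic --seed 1 --out sol.json
conicopt gen-proteomics --proteins 100 --peptides 300 --seed 7 --out-prefix g
conicopt infer --edges g.edges.tsv --scores g.scores.tsv --out proteins.tsv
```

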
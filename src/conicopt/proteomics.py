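"""Protein inference as a projection of the origin onto a polytope.

In shotgun proteomics, observed peptides map to one or more candidate
proteins, and shared peptides make naive per-protein aggregation
overcount.  A parsimony-flavored relaxation scores proteins by solving

    minimize   ||rho||^2
    subject to sum_r w_r * rho_r >= gamma,   rho >= 0

where ``rho_r`` is the score of protein ``r``, ``w_r`` is the protein's
aggregated peptide evidence (the sum of the scores ``q_e`` of its adjacent
peptides in the bipartite graph), and ``gamma`` is a fraction of the total
observed peptide score mass that must be "explained".  Minimizing the
L2-norm enforces economy in the protein set — proteins without evidence are
driven exactly to zero — while shared peptides split their support among
the proteins that contain them.

The program arises by substituting each peptide variable with the sum of
its adjacent proteins in the evidence constraint, leaving ``n`` protein
variables, ``n`` nonnegativity rows, and one evidence row (``n + 1``
constraints in total).  It is solved as a projection of the zero vector
onto that polytope with :func:`conicopt.projection.project_onto_polytope`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import EPS
from .problems import ProjectionProblem, SolveResult
from .projection import project_onto_polytope


class GraphValidationError(ValueError):
    """The peptide-protein graph violates an invariant."""


@dataclass
class PeptideProteinGraph:
    """Bipartite protein-peptide graph with per-peptide scores in [0, 1]."""

    proteins: list[str]
    peptides: list[str]
    edges: set[tuple[str, str]]  # (protein, peptide)
    scores: dict[str, float]

    def __post_init__(self) -> None:
        prot = set(self.proteins)
        pep = set(self.peptides)
        if len(prot) != len(self.proteins) or len(pep) != len(self.peptides):
            raise GraphValidationError("duplicate protein or peptide ids")
        for r, e in self.edges:
            if r not in prot or e not in pep:
                raise GraphValidationError(f"edge ({r!r}, {e!r}) references unknown node")
        degree = {e: 0 for e in self.peptides}
        for _, e in self.edges:
            degree[e] += 1
        isolated = [e for e, d in degree.items() if d == 0]
        if isolated:
            raise GraphValidationError(f"peptides with no protein: {isolated}")
        for e in self.peptides:
            q = self.scores.get(e)
            if q is None:
                raise GraphValidationError(f"peptide {e!r} has no score")
            if not 0.0 <= q <= 1.0:
                raise GraphValidationError(f"score of {e!r} outside [0, 1]: {q}")

    def protein_evidence(self) -> np.ndarray:
        """``w_r = sum of q_e over peptides adjacent to protein r``."""
        idx = {r: i for i, r in enumerate(self.proteins)}
        w = np.zeros(len(self.proteins))
        for r, e in self.edges:
            w[idx[r]] += self.scores[e]
        return w

    def total_peptide_score(self) -> float:
        return float(sum(self.scores[e] for e in self.peptides))


@dataclass
class ProteinInferenceQP:
    """Compiled inference program: project 0 onto the evidence polytope."""

    problem: ProjectionProblem
    proteins: list[str]
    w: np.ndarray
    gamma: float


def build_qp(G: PeptideProteinGraph, gamma_fraction: float = 0.9,
             ) -> ProteinInferenceQP:
    """Compile the graph into the ``n + 1``-constraint projection program.

    Peptide variables are eliminated by substitution (each equals the sum of
    its adjacent proteins), so the polytope has one aggregated evidence row
    ``-w @ rho <= -gamma`` plus ``n`` nonnegativity rows, with
    ``gamma = gamma_fraction * sum_e q_e``.
    """
    if not 0.0 < gamma_fraction < 1.0:
        raise GraphValidationError("gamma_fraction must lie in (0, 1)")
    n = len(G.proteins)
    w = G.protein_evidence()
    gamma = gamma_fraction * G.total_peptide_score()
    A = sp.vstack([sp.csr_matrix(-w[None, :]), -sp.identity(n, format="csr")])
    b = np.concatenate([[-gamma], np.zeros(n)])
    if np.all(np.abs(w) <= EPS):
        # zero evidence: the evidence row is vacuous (gamma == 0); keep the
        # polytope well formed by replacing it with a redundant row
        A = sp.vstack([sp.csr_matrix(-np.ones((1, n))),
                       -sp.identity(n, format="csr")])
        b = np.concatenate([[0.0], np.zeros(n)])
    problem = ProjectionProblem(A.tocsr(), b, np.zeros(n))
    return ProteinInferenceQP(problem, list(G.proteins), w, float(gamma))


def initial_feasible_point(qp: ProteinInferenceQP) -> np.ndarray:
    """All-ones protein vector, scaled up if the evidence row needs it.

    Feasible by construction: the aggregated weights satisfy
    ``sum_r w_r = sum_e q_e * degree(e) >= sum_e q_e > gamma``; when the
    margin is thin the vector is scaled so the evidence row holds with a
    factor-two margin.
    """
    n = len(qp.proteins)
    x = np.ones(n)
    total = float(qp.w @ x)
    if qp.gamma > 0.0 and total < 2.0 * qp.gamma:
        x *= 2.0 * qp.gamma / total
    return x


def infer_proteins(G: PeptideProteinGraph, gamma_fraction: float = 0.9,
                   seed: int | np.random.Generator = 0,
                   ) -> tuple[pd.DataFrame, SolveResult]:
    """Score and rank proteins by solving the inference projection.

    Returns a table with columns ``protein_id``, ``score``, ``rank`` sorted
    by descending score (ties broken by protein id for a stable order), and
    the underlying :class:`SolveResult` with the KKT certificate.
    """
    qp = build_qp(G, gamma_fraction)
    x0 = initial_feasible_point(qp)
    res = project_onto_polytope(qp.problem, x0=x0, seed=seed)
    scores = np.where(np.abs(res.x) <= EPS, 0.0, res.x)
    table = pd.DataFrame({"protein_id": qp.proteins, "score": scores})
    table = table.sort_values(["score", "protein_id"],
                              ascending=[False, True], kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    return table.reset_index(drop=True), res


# ---------------------------------------------------------------------------
# synthetic graphs
# ---------------------------------------------------------------------------

def gen_synthetic_graph(n_proteins: int, n_peptides: int,
                        mean_degree: float = 2.0,
                        present_fraction: float = 0.3,
                        seed: int = 0) -> PeptideProteinGraph:
    """Synthetic stand-in for a mass-spectrometry peptide-protein graph.

    Each peptide attaches to ``1 + Poisson(mean_degree - 1)`` distinct
    proteins (capped at ``n_proteins``), so shared peptides appear at the
    requested rate.  A ``present_fraction`` of proteins is marked as truly
    present; peptides touching at least one present protein draw their score
    from Beta(8, 2) (high-confidence observations), the rest from Beta(2, 8)
    (background matches).  Deterministic in ``seed``.
    """
    if n_proteins < 1 or n_peptides < 1:
        raise GraphValidationError("need at least one protein and one peptide")
    if mean_degree < 1.0:
        raise GraphValidationError("mean_degree must be >= 1")
    if not 0.0 <= present_fraction <= 1.0:
        raise GraphValidationError("present_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    proteins = [f"P{i:05d}" for i in range(n_proteins)]
    peptides = [f"e{i:06d}" for i in range(n_peptides)]
    n_present = int(round(present_fraction * n_proteins))
    present = set(rng.choice(n_proteins, size=n_present, replace=False).tolist())

    edges: set[tuple[str, str]] = set()
    scores: dict[str, float] = {}
    for j, pep in enumerate(peptides):
        deg = min(1 + rng.poisson(mean_degree - 1.0), n_proteins)
        attached = rng.choice(n_proteins, size=deg, replace=False)
        for i in attached:
            edges.add((proteins[i], pep))
        signal = any(int(i) in present for i in attached)
        a, b = (8.0, 2.0) if signal else (2.0, 8.0)
        scores[pep] = float(rng.beta(a, b))
    return PeptideProteinGraph(proteins, peptides, edges, scores)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def write_graph(G: PeptideProteinGraph, edges_path: str | Path,
                scores_path: str | Path) -> None:
    edges = pd.DataFrame(sorted(G.edges), columns=["protein_id", "peptide_id"])
    edges.to_csv(edges_path, sep="\t", index=False)
    scores = pd.DataFrame(
        {"peptide_id": G.peptides,
         "score": [G.scores[e] for e in G.peptides]})
    scores.to_csv(scores_path, sep="\t", index=False)


def read_graph(edges_path: str | Path,
               scores_path: str | Path) -> PeptideProteinGraph:
    edges_df = pd.read_csv(edges_path, sep="\t")
    scores_df = pd.read_csv(scores_path, sep="\t")
    for col in ("protein_id", "peptide_id"):
        if col not in edges_df.columns:
            raise GraphValidationError(f"edges file missing column {col!r}")
    for col in ("peptide_id", "score"):
        if col not in scores_df.columns:
            raise GraphValidationError(f"scores file missing column {col!r}")
    proteins = sorted(edges_df["protein_id"].astype(str).unique())
    peptides = list(scores_df["peptide_id"].astype(str))
    edges = {(str(r), str(e))
             for r, e in zip(edges_df["protein_id"], edges_df["peptide_id"])}
    scores = dict(zip(scores_df["peptide_id"].astype(str),
                      scores_df["score"].astype(float)))
    return PeptideProteinGraph(proteins, peptides, edges, scores)


def write_scores(table: pd.DataFrame, path: str | Path) -> None:
    table[["protein_id", "score", "rank"]].to_csv(path, sep="\t", index=False)
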
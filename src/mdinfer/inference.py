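"""Two-sided label propagation over the heterogeneous graph.

The prediction score of an unknown miRNA-disease pair accumulates evidence
along length-three paths miRNA ~ miRNA - disease ~ disease: the one-step
score is the triple product ``SM @ A @ SD``.  Iterating this propagation
with a decay factor ``alpha`` and re-injecting the known associations,

    P(t+1) = alpha * SM @ P(t) @ SD + (1 - alpha) * A,

converges to a unique fixed point once both similarity matrices are
symmetrically normalized (dividing each entry by the geometric mean of its
row sums bounds the spectral radius by 1, making the update a contraction
for alpha < 1).  Iteration stops when the elementwise L1 change drops below
``tol`` (default 1e-6).

``closed_form_fixed_point`` solves the fixed-point linear system exactly by
flattening it with a Kronecker product; it is the independent oracle the
iterative solver is tested against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .graph_data import (
    AssociationMatrix,
    PartialSimilarity,
    SimilarityMatrix,
    ValidationError,
)
from .similarity import KernelConfig, integrate_similarity, interaction_kernels

logger = logging.getLogger(__name__)


@dataclass
class PropagationConfig:
    """Fixed-point iteration parameters.

    alpha : decay factor in [0, 1); weight of propagated evidence versus the
        re-injected known associations, analogous to a restart probability.
        Default 0.4, following heterogeneous-graph inference precedent.
    tol : L1 convergence cutoff on the change between iterates (default 1e-6).
    max_iter : iteration cap; exceeding it returns converged=False with a
        logged warning rather than raising.
    """

    alpha: float = 0.4
    tol: float = 1e-6
    max_iter: int = 10000

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValidationError(f"alpha must lie in [0, 1), got {self.alpha}")
        if self.tol <= 0:
            raise ValidationError("tol must be positive")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be at least 1")


@dataclass
class ScoreMatrix:
    """Real-valued miRNA x disease prediction matrix with convergence info."""

    mirna_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray
    iterations: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def validate(self) -> None:
        if self.values.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ValidationError("score shape does not match identifiers")
        if not np.isfinite(self.values).all():
            raise ValidationError("scores must be finite")


def normalize(sim: SimilarityMatrix) -> SimilarityMatrix:
    """Symmetric row-sum normalization: S'(i,j) = S(i,j)/sqrt(r_i * r_j).

    With ``r_i`` the i-th row sum.  Preserves symmetry and bounds the
    spectral radius by 1 (the normalized matrix is similar to the row
    stochastic D^-1 S), which makes the propagation a contraction.
    """
    rowsums = sim.values.sum(axis=1)
    if (rowsums <= 0).any():
        raise ValidationError("normalization requires strictly positive row sums")
    scale = 1.0 / np.sqrt(rowsums)
    return SimilarityMatrix(
        list(sim.ids), sim.values * np.outer(scale, scale)
    )


def one_step_scores(
    sm: SimilarityMatrix, assoc: AssociationMatrix, sd: SimilarityMatrix
) -> ScoreMatrix:
    """Length-three path score: P = SM @ A @ SD.

    Entry (m, d) sums, over all known associations (m(i), d(j)), the product
    of miRNA similarity SM(m(i), m) and disease similarity SD(d(j), d).
    """
    _check_shapes(sm, assoc, sd)
    values = sm.values @ assoc.values @ sd.values
    return ScoreMatrix(list(assoc.mirna_ids), list(assoc.disease_ids), values)


def propagate(
    smn: SimilarityMatrix,
    sdn: SimilarityMatrix,
    assoc: AssociationMatrix,
    cfg: PropagationConfig | None = None,
) -> ScoreMatrix:
    """Iterate the propagation to its fixed point.

    Starting from P(0) = A (the fixed point is initialization-independent
    since the update is a contraction for alpha < 1), apply

        P(t+1) = alpha * SMn @ P(t) @ SDn + (1 - alpha) * A

    until the elementwise L1 change is below ``cfg.tol``.
    """
    cfg = cfg or PropagationConfig()
    _check_shapes(smn, assoc, sdn)
    a = assoc.values
    prior = (1.0 - cfg.alpha) * a
    p = a.copy()
    converged = False
    iterations = 0
    for iterations in range(1, cfg.max_iter + 1):
        p_next = cfg.alpha * (smn.values @ p @ sdn.values) + prior
        delta = np.abs(p_next - p).sum()
        p = p_next
        if delta < cfg.tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "propagation did not converge within %d iterations (alpha=%g)",
            cfg.max_iter,
            cfg.alpha,
        )
    return ScoreMatrix(
        list(assoc.mirna_ids),
        list(assoc.disease_ids),
        p,
        iterations=iterations,
        converged=converged,
    )


def closed_form_fixed_point(
    smn: SimilarityMatrix,
    sdn: SimilarityMatrix,
    assoc: AssociationMatrix,
    alpha: float,
) -> ScoreMatrix:
    """Solve P - alpha * SMn @ P @ SDn = (1 - alpha) * A exactly.

    Flattens the matrix equation with a Kronecker product into a dense
    linear system; the solution is unique because the propagation operator's
    spectral radius is at most alpha < 1.  Intended as a test oracle for
    small problems (a few thousand unknowns).
    """
    if not 0.0 <= alpha < 1.0:
        raise ValidationError(f"alpha must lie in [0, 1), got {alpha}")
    _check_shapes(smn, assoc, sdn)
    nm, nd = assoc.values.shape
    # vec(SM P SD) = (SD^T kron SM) vec(P) with column-major vec
    op = np.eye(nm * nd) - alpha * np.kron(sdn.values.T, smn.values)
    rhs = (1.0 - alpha) * assoc.values.flatten(order="F")
    p = scipy.linalg.solve(op, rhs).reshape((nm, nd), order="F")
    return ScoreMatrix(list(assoc.mirna_ids), list(assoc.disease_ids), p)


def predict_scores(
    assoc: AssociationMatrix,
    fs: PartialSimilarity,
    ss: PartialSimilarity,
    ker_cfg: KernelConfig | None = None,
    prop_cfg: PropagationConfig | None = None,
    *,
    bandwidth_fallback: bool = True,
) -> ScoreMatrix:
    """Full scoring pipeline from an association matrix and similarity data.

    Computes the GIP kernels from ``assoc``, integrates them with the
    functional (miRNA) and semantic (disease) partial similarities,
    normalizes both networks, and propagates to the fixed point.
    """
    km, kd = interaction_kernels(
        assoc, ker_cfg, bandwidth_fallback=bandwidth_fallback
    )
    smn = normalize(integrate_similarity(km, fs))
    sdn = normalize(integrate_similarity(kd, ss))
    return propagate(smn, sdn, assoc, prop_cfg)


def _check_shapes(
    sm: SimilarityMatrix, assoc: AssociationMatrix, sd: SimilarityMatrix
) -> None:
    nm, nd = assoc.values.shape
    if sm.values.shape != (nm, nm):
        raise ValidationError(
            f"miRNA similarity shape {sm.values.shape} does not match nm={nm}"
        )
    if sd.values.shape != (nd, nd):
        raise ValidationError(
            f"disease similarity shape {sd.values.shape} does not match nd={nd}"
        )
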
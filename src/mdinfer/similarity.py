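"""Disease semantic similarity, Gaussian interaction-profile kernels, and
their integration into the two similarity networks of the heterogeneous graph.

Three similarity notions feed the propagation:

* **Semantic similarity (SS)** between diseases, from their MeSH ancestor
  DAGs.  Each node in a disease's DAG contributes a semantic value that
  decays by a factor ``delta`` per edge away from the disease itself
  (taking the max over descendants when several paths exist); two diseases
  are similar in proportion to the contribution mass of their shared
  ancestor terms.
* **Gaussian interaction-profile (GIP) kernel similarity** for both
  diseases (KD) and miRNAs (KM): a Gaussian kernel on the binary rows /
  columns of the association matrix, with bandwidth normalized by the mean
  squared profile norm so the kernel scale adapts to association density.
* **Functional similarity (FS)** for miRNAs, consumed as precomputed data.

Integration averages the kernel with FS / SS where the latter is observed
and falls back to the pure kernel otherwise; this fallback is what lets the
model score diseases and miRNAs that have no curated similarity entries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .graph_data import (
    AssociationMatrix,
    DiseaseDAG,
    PartialSimilarity,
    SimilarityMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)


class BandwidthUndefinedError(ValueError):
    """Raised when every interaction profile is all-zero, so the
    density-normalized kernel bandwidth would divide by zero."""


@dataclass
class SemanticConfig:
    """Configuration of the DAG-based semantic similarity.

    delta : semantic contribution factor in (0, 1); per-edge decay of a
        node's contribution as it moves away from the DAG root.  Default 0.5,
        the convention of the functional-similarity literature this score
        family follows.
    """

    delta: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.delta < 1.0:
            raise ValidationError(f"delta must lie in (0, 1), got {self.delta}")


@dataclass
class KernelConfig:
    """Raw GIP bandwidths before density normalization.

    Both default to 1, the standard choice in the interaction-profile kernel
    literature; the effective bandwidth is the raw value divided by the mean
    squared interaction-profile norm.
    """

    gamma_prime_d: float = 1.0
    gamma_prime_m: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma_prime_d <= 0 or self.gamma_prime_m <= 0:
            raise ValidationError("kernel bandwidths must be strictly positive")


# ---------------------------------------------------------------------------
# Disease semantic similarity
# ---------------------------------------------------------------------------


def _ancestor_chain(number: str) -> list[str]:
    """Dotted prefixes of a tree number, most specific first.

    ``C04.557.337 -> [C04.557.337, C04.557, C04]``.
    """
    parts = number.split(".")
    return [".".join(parts[: k + 1]) for k in range(len(parts) - 1, -1, -1)]


def build_dag(
    term: str,
    tree_index: dict[str, str],
    term_numbers: dict[str, set[str]],
) -> DiseaseDAG:
    """Build the ancestor DAG of ``term`` from its MeSH tree numbers.

    Nodes are ``term`` plus every term owning a proper dotted prefix of any
    of its tree numbers; edges run parent -> child between nearest indexed
    terms (prefixes owned by no term are skipped over).  Several tree
    numbers yield a single DAG containing the union of the ancestor paths.
    """
    numbers = term_numbers.get(term)
    if not numbers:
        raise ValidationError(f"term {term!r} has no tree numbers")
    nodes = {term}
    edges: set[tuple[str, str]] = set()
    for number in numbers:
        child_term = term
        for prefix in _ancestor_chain(number)[1:]:
            parent_term = tree_index.get(prefix)
            if parent_term is None:
                continue
            if parent_term != child_term:
                nodes.add(parent_term)
                edges.add((parent_term, child_term))
                child_term = parent_term
    return DiseaseDAG(root=term, nodes=nodes, edges=edges)


def semantic_contributions(
    dag: DiseaseDAG, cfg: SemanticConfig | None = None
) -> dict[str, float]:
    """Per-node semantic contribution DD within ``dag``.

    The root (the disease itself) contributes 1; every ancestor contributes
    ``delta`` times the largest contribution among its children in the DAG,
    so the contribution decays with distance from the disease.
    """
    cfg = cfg or SemanticConfig()
    dd: dict[str, float] = {}

    def value(node: str) -> float:
        if node in dd:
            return dd[node]
        if node == dag.root:
            dd[node] = 1.0
        else:
            dd[node] = max(cfg.delta * value(c) for c in dag.children(node))
        return dd[node]

    for node in dag.nodes:
        value(node)
    return dd


def semantic_value(dd: dict[str, float]) -> float:
    """Semantic value DV of a disease: the sum of its nodes' contributions."""
    if not dd:
        raise ValidationError("empty contribution mapping")
    return float(sum(dd.values()))


def semantic_similarity(
    dag_i: DiseaseDAG, dag_j: DiseaseDAG, cfg: SemanticConfig | None = None
) -> float:
    """Semantic similarity of two diseases from their ancestor DAGs.

    The shared terms' contributions (evaluated within each disease's own
    DAG) are summed and scaled by the two semantic values:

        SS(i, j) = sum_{t in T(i) & T(j)} (DD_i(t) + DD_j(t)) / (DV(i) + DV(j))
    """
    cfg = cfg or SemanticConfig()
    dd_i = semantic_contributions(dag_i, cfg)
    dd_j = semantic_contributions(dag_j, cfg)
    shared = dag_i.nodes & dag_j.nodes
    num = sum(dd_i[t] + dd_j[t] for t in shared)
    return float(num / (semantic_value(dd_i) + semantic_value(dd_j)))


def semantic_similarity_matrix(
    disease_ids: list[str],
    tree_index: dict[str, str],
    term_numbers: dict[str, set[str]],
    cfg: SemanticConfig | None = None,
) -> PartialSimilarity:
    """Pairwise semantic similarity over ``disease_ids`` as a partial matrix.

    Pairs are observed iff both diseases carry MeSH tree numbers; diseases
    absent from the MeSH table stay unobserved and later take the pure
    GIP-kernel branch of the integration.
    """
    cfg = cfg or SemanticConfig()
    n = len(disease_ids)
    dags = {
        d: build_dag(d, tree_index, term_numbers)
        for d in disease_ids
        if term_numbers.get(d)
    }
    missing = [d for d in disease_ids if d not in dags]
    if missing:
        logger.warning(
            "%d of %d diseases have no MeSH tree numbers; their semantic "
            "similarity is unobserved",
            len(missing),
            n,
        )
    values = np.zeros((n, n))
    observed = np.zeros((n, n), dtype=bool)
    for i, a in enumerate(disease_ids):
        if a not in dags:
            continue
        for j in range(i, n):
            b = disease_ids[j]
            if b not in dags:
                continue
            s = 1.0 if i == j else semantic_similarity(dags[a], dags[b], cfg)
            values[i, j] = values[j, i] = s
            observed[i, j] = observed[j, i] = True
    np.fill_diagonal(values, 1.0)
    np.fill_diagonal(observed, True)
    return PartialSimilarity(list(disease_ids), values, observed)


# ---------------------------------------------------------------------------
# Gaussian interaction-profile kernels
# ---------------------------------------------------------------------------


def gip_bandwidth(profiles: np.ndarray, gamma_prime: float) -> float:
    """Density-normalized kernel bandwidth.

    gamma = gamma' / mean_u ||IP(u)||^2, so denser association matrices get
    flatter kernels.  Raises :class:`BandwidthUndefinedError` when every
    profile is all-zero; callers may fall back to gamma = gamma'.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] == 0:
        raise ValidationError("profiles must be a nonempty 2-d array")
    mean_sq = float((profiles**2).sum(axis=1).mean())
    if mean_sq == 0.0:
        raise BandwidthUndefinedError(
            "all interaction profiles are zero; bandwidth is undefined"
        )
    return gamma_prime / mean_sq


def gip_kernel(
    profiles: np.ndarray, gamma: float, ids: list[str] | None = None
) -> SimilarityMatrix:
    """Gaussian kernel on interaction profiles.

    K(u, v) = exp(-gamma * ||IP(u) - IP(v)||^2); symmetric, unit diagonal,
    entries in (0, 1].
    """
    profiles = np.asarray(profiles, dtype=float)
    if gamma <= 0:
        raise ValidationError("gamma must be strictly positive")
    sq = squareform(pdist(profiles, metric="sqeuclidean"))
    values = np.exp(-gamma * sq)
    if ids is None:
        ids = [str(i) for i in range(profiles.shape[0])]
    return SimilarityMatrix(list(ids), values)


def interaction_kernels(
    assoc: AssociationMatrix,
    cfg: KernelConfig | None = None,
    *,
    bandwidth_fallback: bool = False,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """GIP kernel similarity matrices (KM for miRNAs, KD for diseases).

    With ``bandwidth_fallback`` the degenerate all-zero-profile case uses
    gamma = gamma' (logged) instead of raising; leave-one-out folds on tiny
    matrices need this to stay well-defined.
    """
    cfg = cfg or KernelConfig()

    def bandwidth(profiles: np.ndarray, gamma_prime: float) -> float:
        try:
            return gip_bandwidth(profiles, gamma_prime)
        except BandwidthUndefinedError:
            if not bandwidth_fallback:
                raise
            logger.warning(
                "all-zero interaction profiles; falling back to gamma = %g",
                gamma_prime,
            )
            return gamma_prime

    gamma_m = bandwidth(assoc.values, cfg.gamma_prime_m)
    gamma_d = bandwidth(assoc.values.T, cfg.gamma_prime_d)
    km = gip_kernel(assoc.values, gamma_m, assoc.mirna_ids)
    kd = gip_kernel(assoc.values.T, gamma_d, assoc.disease_ids)
    return km, kd


# ---------------------------------------------------------------------------
# Integrated similarity
# ---------------------------------------------------------------------------


def integrate_similarity(
    kernel: SimilarityMatrix, partial: PartialSimilarity
) -> SimilarityMatrix:
    """Blend a GIP kernel with partially observed similarity scores.

    Observed pairs take the average of kernel and score; unobserved pairs
    keep the kernel alone.  This is the integrated miRNA similarity SM
    (kernel KM + functional similarity FS) and the integrated disease
    similarity SD (kernel KD + semantic similarity SS).
    """
    if list(kernel.ids) != list(partial.ids):
        raise ValidationError("kernel and partial similarity ids differ")
    values = np.where(
        partial.observed, (kernel.values + partial.values) / 2.0, kernel.values
    )
    return SimilarityMatrix(list(kernel.ids), values)
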
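"""Domain types and TSV readers/writers for the miRNA-disease graph.

The central object is the binary adjacency matrix ``A`` of experimentally
confirmed miRNA-disease associations: rows are miRNAs, columns are diseases,
and ``A[i, j] = 1`` iff miRNA ``i`` is known to be associated with disease
``j``.  Row ``i`` of ``A`` is the *interaction profile* of miRNA ``i`` and
column ``j`` the interaction profile of disease ``j``; the Gaussian kernels
in :mod:`mdinfer.similarity` are built on these profiles.

All external tables are plain TSV, UTF-8, no quoting; lines starting with
``#`` are comments.  Identifier order is first appearance in the association
file, and similarity tables are aligned to it.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

_TREE_NUMBER_RE = re.compile(r"^[A-Z]\d{2}(\.\d+)*$")


class ParseError(ValueError):
    """A malformed input table (bad row, empty file, bad tree number)."""


class ValidationError(ValueError):
    """Data that parses but violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class AssociationMatrix:
    """Binary miRNA x disease adjacency matrix with identifier labels.

    Attributes
    ----------
    mirna_ids : list of str
        Row labels, ordered, no duplicates (length ``nm``).
    disease_ids : list of str
        Column labels, ordered, no duplicates (length ``nd``).
    values : ndarray of shape (nm, nd)
        Entries in {0, 1}; ``values[i, j] = 1`` iff miRNA ``i`` is
        associated with disease ``j``.
    """

    mirna_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def nm(self) -> int:
        return len(self.mirna_ids)

    @property
    def nd(self) -> int:
        return len(self.disease_ids)

    @property
    def density(self) -> float:
        return float(self.values.sum()) / (self.nm * self.nd)

    def mirna_profile(self, i: int) -> np.ndarray:
        """Interaction profile IP(m(i)): row i of A."""
        return self.values[i, :]

    def disease_profile(self, j: int) -> np.ndarray:
        """Interaction profile IP(d(j)): column j of A."""
        return self.values[:, j]

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            list(self.mirna_ids), list(self.disease_ids), self.values.copy()
        )

    def validate(self) -> None:
        if len(set(self.mirna_ids)) != self.nm:
            raise ValidationError("duplicate miRNA identifiers")
        if len(set(self.disease_ids)) != self.nd:
            raise ValidationError("duplicate disease identifiers")
        if self.values.shape != (self.nm, self.nd):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"identifier counts ({self.nm}, {self.nd})"
            )
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValidationError("association entries must be binary")


@dataclass
class DiseaseDAG:
    """A disease term together with all its MeSH ancestors.

    ``nodes`` is the term set T(D) (the disease plus every ancestor term),
    ``edges`` the directed parent -> child pairs E(D).  The graph is acyclic
    and every non-root node reaches the root along directed edges (the root
    being the most specific term, D itself).
    """

    root: str
    nodes: set[str]
    edges: set[tuple[str, str]]

    def children(self, term: str) -> set[str]:
        """Direct descendants of ``term`` within this DAG (more specific terms)."""
        return {c for p, c in self.edges if p == term}

    def validate(self) -> None:
        if self.root not in self.nodes:
            raise ValidationError("DAG root missing from node set")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError("disease DAG contains a cycle")
        for n in self.nodes:
            if n != self.root and not nx.has_path(g, n, self.root):
                raise ValidationError(f"node {n!r} has no path to the root")


@dataclass
class PartialSimilarity:
    """Symmetric similarity scores known only for a subset of pairs.

    Holds the miRNA functional similarity matrix FS (whose published scores
    do not cover all miRNA pairs) and the disease semantic similarity matrix
    SS when some diseases lack MeSH annotations.  ``observed[i, j]`` marks
    pairs with a known score; unobserved pairs fall back to the Gaussian
    interaction-profile kernel during integration.
    """

    ids: list[str]
    values: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)

    def validate(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n) or self.observed.shape != (n, n):
            raise ValidationError("similarity shape does not match identifiers")
        if not np.array_equal(self.observed, self.observed.T):
            raise ValidationError("observation mask must be symmetric")
        if not np.allclose(
            self.values[self.observed], self.values.T[self.observed]
        ):
            raise ValidationError("observed values must be symmetric")
        if not self.observed.diagonal().all():
            raise ValidationError("diagonal must be observed")
        if not np.allclose(self.values.diagonal(), 1.0):
            raise ValidationError("diagonal must equal 1")
        obs = self.values[self.observed]
        if obs.size and (obs.min() < 0 or obs.max() > 1):
            raise ValidationError("observed scores must lie in [0, 1]")


@dataclass
class SimilarityMatrix:
    """Square symmetric nonnegative score matrix over one node set.

    Used for the Gaussian kernels KD and KM, the integrated similarities
    SM and SD, and their normalized forms.
    """

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def validate(self, *, unit_diagonal: bool = True) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError("similarity shape does not match identifiers")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("similarity matrix must be symmetric")
        if self.values.min() < 0:
            raise ValidationError("similarity entries must be nonnegative")
        if unit_diagonal and not np.allclose(self.values.diagonal(), 1.0):
            raise ValidationError("diagonal must equal 1")


@dataclass
class RankRecord:
    """One held-out association's rank within its LOOCV candidate set.

    ``rank`` is the average rank of the held-out pair's score among itself
    plus its ``n_candidates`` competing unknown pairs (descending score,
    ties averaged), so ``1 <= rank <= n_candidates + 1``.
    """

    mirna_id: str
    disease_id: str
    score: float
    rank: float
    n_candidates: int
    mode: str

    def validate(self) -> None:
        if not 1.0 <= self.rank <= self.n_candidates + 1:
            raise ValidationError(
                f"rank {self.rank} outside [1, {self.n_candidates + 1}]"
            )
        if self.mode not in ("global", "local"):
            raise ValidationError(f"unknown LOOCV mode {self.mode!r}")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, tab-split fields), skipping comments/blanks."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_associations(path: str | Path) -> AssociationMatrix:
    """Read a two-column (miRNA, disease) edge list into an adjacency matrix.

    Identifiers are ordered by first appearance; duplicate pairs collapse to
    a single entry with a logged warning.
    """
    mirna_order: dict[str, int] = {}
    disease_order: dict[str, int] = {}
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dupes = 0
    for lineno, fields in _data_lines(path):
        if len(fields) != 2:
            raise ParseError(
                f"{path}:{lineno}: expected 2 tab-separated columns, "
                f"got {len(fields)}"
            )
        m, d = (f.strip() for f in fields)
        if not m or not d:
            raise ParseError(f"{path}:{lineno}: empty identifier")
        if (m, d) in seen:
            n_dupes += 1
            continue
        seen.add((m, d))
        mirna_order.setdefault(m, len(mirna_order))
        disease_order.setdefault(d, len(disease_order))
        pairs.append((m, d))
    if not pairs:
        raise ParseError(f"{path}: no association rows found")
    if n_dupes:
        logger.warning("%s: collapsed %d duplicate association rows", path, n_dupes)
    values = np.zeros((len(mirna_order), len(disease_order)))
    for m, d in pairs:
        values[mirna_order[m], disease_order[d]] = 1.0
    return AssociationMatrix(list(mirna_order), list(disease_order), values)


def read_functional_similarity(
    path: str | Path, mirna_ids: list[str]
) -> PartialSimilarity:
    """Read a three-column (miRNA, miRNA, score) table aligned to ``mirna_ids``.

    Scores must lie in [0, 1]; each unordered pair may appear once (or twice
    with the same score).  Pairs absent from the file are unobserved; the
    diagonal is forced observed with value 1.  Rows naming miRNAs outside
    ``mirna_ids`` are ignored with a logged count.
    """
    index = {m: i for i, m in enumerate(mirna_ids)}
    n = len(mirna_ids)
    values = np.zeros((n, n))
    observed = np.zeros((n, n), dtype=bool)
    n_ignored = 0
    for lineno, fields in _data_lines(path):
        if len(fields) != 3:
            raise ParseError(
                f"{path}:{lineno}: expected 3 tab-separated columns, "
                f"got {len(fields)}"
            )
        a, b, raw_score = (f.strip() for f in fields)
        try:
            score = float(raw_score)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric score {raw_score!r}")
        if not 0.0 <= score <= 1.0:
            raise ValidationError(
                f"{path}:{lineno}: score {score} outside [0, 1]"
            )
        if a not in index or b not in index:
            n_ignored += 1
            continue
        i, j = index[a], index[b]
        if observed[i, j] and values[i, j] != score:
            raise ValidationError(
                f"{path}:{lineno}: conflicting scores for pair "
                f"({a}, {b}): {values[i, j]} vs {score}"
            )
        values[i, j] = values[j, i] = score
        observed[i, j] = observed[j, i] = True
    if n_ignored:
        logger.warning(
            "%s: ignored %d rows naming miRNAs outside the association set",
            path,
            n_ignored,
        )
    np.fill_diagonal(values, 1.0)
    np.fill_diagonal(observed, True)
    return PartialSimilarity(list(mirna_ids), values, observed)


def read_mesh_tree_numbers(
    path: str | Path,
) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read a two-column (disease term, dotted tree number) table.

    A term may carry several tree numbers (MeSH descriptors often do), but a
    tree number locates exactly one term.  Returns the term -> tree-number-set
    mapping and the inverse (injective) tree-number -> term index.
    """
    term_numbers: dict[str, set[str]] = {}
    tree_index: dict[str, str] = {}
    any_rows = False
    for lineno, fields in _data_lines(path):
        if len(fields) != 2:
            raise ParseError(
                f"{path}:{lineno}: expected 2 tab-separated columns, "
                f"got {len(fields)}"
            )
        term, number = (f.strip() for f in fields)
        if not _TREE_NUMBER_RE.match(number):
            raise ParseError(
                f"{path}:{lineno}: malformed tree number {number!r}"
            )
        owner = tree_index.get(number)
        if owner is not None and owner != term:
            raise ValidationError(
                f"{path}:{lineno}: tree number {number} already assigned "
                f"to {owner!r}"
            )
        tree_index[number] = term
        term_numbers.setdefault(term, set()).add(number)
        any_rows = True
    if not any_rows:
        raise ParseError(f"{path}: no tree-number rows found")
    return term_numbers, tree_index


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_associations(assoc: AssociationMatrix, path: str | Path) -> None:
    """Write the known associations back out as a two-column edge list."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, m in enumerate(assoc.mirna_ids):
            for j, d in enumerate(assoc.disease_ids):
                if assoc.values[i, j]:
                    fh.write(f"{m}\t{d}\n")


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    """Write a square similarity matrix as TSV with id header row/column."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t" + "\t".join(sim.ids) + "\n")
        for i, a in enumerate(sim.ids):
            row = "\t".join(format(v, ".10g") for v in sim.values[i])
            fh.write(f"{a}\t{row}\n")


def write_predictions(
    scores: "np.ndarray | object", known: AssociationMatrix, path: str | Path
) -> None:
    """Write ranked candidate predictions, one block per disease.

    Columns: disease, miRNA, score, within-disease rank.  Pairs already known
    (``known[i, j] = 1``) are excluded; within a disease, rows are sorted by
    descending score with ties broken by miRNA identifier.
    """
    values = getattr(scores, "values", scores)
    score_mirnas = getattr(scores, "mirna_ids", known.mirna_ids)
    score_diseases = getattr(scores, "disease_ids", known.disease_ids)
    values = np.asarray(values, dtype=float)
    if (
        values.shape != known.values.shape
        or list(score_mirnas) != list(known.mirna_ids)
        or list(score_diseases) != list(known.disease_ids)
    ):
        raise ValidationError("score and association matrices do not agree")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("disease\tmiRNA\tscore\trank\n")
        for j, d in enumerate(known.disease_ids):
            rows = [
                (-values[i, j], known.mirna_ids[i], values[i, j])
                for i in range(known.nm)
                if not known.values[i, j]
            ]
            rows.sort()
            for rank, (_, m, s) in enumerate(rows, start=1):
                fh.write(f"{d}\t{m}\t{s:.10g}\t{rank}\n")
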
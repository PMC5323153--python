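"""Leave-one-out cross-validation and rank-based ROC/AUC.

Each known association is held out in turn: its entry of the adjacency
matrix is zeroed, every quantity that depends on the matrix (GIP kernels,
integrated similarities, normalization, propagation) is recomputed on the
training matrix, and the held-out pair's score is ranked among candidate
pairs that the training matrix considers unknown.

Two candidate conventions are supported:

* **global** — the held-out pair competes with every miRNA-disease pair
  lacking a known association in the training matrix;
* **local** — it competes only with the miRNAs not known to associate with
  the held-out disease.

Ranks are converted to per-fold percentiles; the ROC curve plots, at each
percentile threshold, the fraction of held-out associations ranked within
that percentile (sensitivity) against the expected fraction of candidate
negatives ranked above the threshold (1 - specificity).  The trapezoidal
AUC of this curve equals the Mann-Whitney statistic: the probability that
a held-out association outranks a random candidate negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

from .graph_data import (
    AssociationMatrix,
    PartialSimilarity,
    RankRecord,
    ValidationError,
)
from .inference import PropagationConfig, ScoreMatrix, normalize, predict_scores, propagate
from .similarity import KernelConfig, integrate_similarity, interaction_kernels

logger = logging.getLogger(__name__)

Scorer = Callable[[AssociationMatrix], ScoreMatrix]


@dataclass
class ROCCurve:
    """Ordered (FPR, TPR) points from (0, 0) to (1, 1) plus their AUC."""

    points: list[tuple[float, float]]
    auc: float

    def validate(self) -> None:
        fpr = [p[0] for p in self.points]
        tpr = [p[1] for p in self.points]
        if self.points[0] != (0.0, 0.0) or self.points[-1] != (1.0, 1.0):
            raise ValidationError("ROC curve must run from (0,0) to (1,1)")
        if any(b < a for a, b in zip(fpr, fpr[1:])) or any(
            b < a for a, b in zip(tpr, tpr[1:])
        ):
            raise ValidationError("ROC curve must be nondecreasing")
        if not 0.0 <= self.auc <= 1.0:
            raise ValidationError("AUC must lie in [0, 1]")


def _rank_of(test_score: float, competitor_scores: np.ndarray) -> float:
    """Average rank of the test score among itself plus competitors
    (descending score; ties averaged)."""
    scores = np.concatenate(([test_score], competitor_scores))
    return float(rankdata(-scores, method="average")[0])


def loocv(
    assoc: AssociationMatrix,
    fs: PartialSimilarity,
    ss: PartialSimilarity,
    mode: str = "global",
    ker_cfg: KernelConfig | None = None,
    prop_cfg: PropagationConfig | None = None,
    *,
    scorer: Scorer | None = None,
    reuse_kernels: bool = False,
) -> list[RankRecord]:
    """Leave-one-out cross-validation over the known associations.

    For each known pair (m, d): zero A(m, d), rescore every pair on the
    training matrix, and rank the held-out pair (descending score, average
    rank on ties) among the candidates of the chosen ``mode``.  The input
    matrix is restored after every fold.

    Parameters
    ----------
    mode : "global" or "local"
        Candidate convention (see module docstring).
    scorer : optional
        Replaces the default full pipeline with any callable mapping a
        training AssociationMatrix to a ScoreMatrix; used to decouple the
        evaluation protocol from the scoring model in tests.
    reuse_kernels : bool
        Compute GIP kernels and normalized similarities once from the full
        matrix instead of per fold.  Cheaper but leaks the held-out edge
        into the similarity side; exploration only.
    """
    if mode not in ("global", "local"):
        raise ValidationError(f"mode must be 'global' or 'local', got {mode!r}")
    known = np.argwhere(assoc.values == 1.0)
    if len(known) < 2:
        raise ValidationError("LOOCV needs at least two known associations")

    if scorer is None:
        if reuse_kernels:
            km, kd = interaction_kernels(assoc, ker_cfg, bandwidth_fallback=True)
            smn = normalize(integrate_similarity(km, fs))
            sdn = normalize(integrate_similarity(kd, ss))

            def scorer(train: AssociationMatrix) -> ScoreMatrix:
                return propagate(smn, sdn, train, prop_cfg)

        else:

            def scorer(train: AssociationMatrix) -> ScoreMatrix:
                return predict_scores(
                    train, fs, ss, ker_cfg, prop_cfg, bandwidth_fallback=True
                )

    records: list[RankRecord] = []
    train = assoc.copy()
    for i, j in known:
        train.values[i, j] = 0.0
        scores = scorer(train).values
        test_score = float(scores[i, j])
        if mode == "global":
            candidate_mask = train.values == 0.0
            candidate_mask[i, j] = False
            competitors = scores[candidate_mask]
        else:
            candidate_mask = train.values[:, j] == 0.0
            candidate_mask[i] = False
            competitors = scores[candidate_mask, j]
        records.append(
            RankRecord(
                mirna_id=assoc.mirna_ids[i],
                disease_id=assoc.disease_ids[j],
                score=test_score,
                rank=_rank_of(test_score, competitors),
                n_candidates=int(competitors.size),
                mode=mode,
            )
        )
        train.values[i, j] = 1.0
    return records


def roc_points(records: Sequence[RankRecord]) -> ROCCurve:
    """ROC curve over rank percentiles of LOOCV folds.

    Each record's rank percentile ``u = (rank - 1) / n_candidates`` is the
    fraction of its candidate negatives scoring above it.  Sweeping a
    percentile threshold theta, TPR(theta) is the fraction of records with
    u <= theta and FPR(theta) = theta (the expected fraction of negatives
    above the threshold).  The trapezoidal area under the resulting step
    curve equals the mean Mann-Whitney statistic
    mean_r (n_candidates + 1 - rank) / n_candidates.
    """
    if not records:
        raise ValidationError("cannot build a ROC curve from zero records")
    u = np.sort(
        [(r.rank - 1.0) / r.n_candidates for r in records if r.n_candidates > 0]
    )
    if u.size == 0:
        raise ValidationError("all records have empty candidate sets")
    n = u.size
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    for theta in np.unique(u):
        below = float(np.searchsorted(u, theta, side="left")) / n
        at = float(np.searchsorted(u, theta, side="right")) / n
        if points[-1] != (float(theta), below):
            points.append((float(theta), below))
        points.append((float(theta), at))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    curve = ROCCurve(points=points, auc=0.0)
    curve.auc = auc(curve)
    return curve


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the stored ROC points."""
    fpr = np.array([p[0] for p in curve.points])
    tpr = np.array([p[1] for p in curve.points])
    return float(np.trapezoid(tpr, fpr))


def mean_rank_auc(records: Sequence[RankRecord]) -> float:
    """Mann-Whitney AUC directly from the rank records.

    The per-fold probability that the held-out association outranks a
    random candidate negative is (n_candidates + 1 - rank) / n_candidates;
    the AUC is its mean over folds.  Agrees with the trapezoidal area of
    :func:`roc_points`.
    """
    if not records:
        raise ValidationError("no records")
    vals = [
        (r.n_candidates + 1.0 - r.rank) / r.n_candidates
        for r in records
        if r.n_candidates > 0
    ]
    if not vals:
        raise ValidationError("all records have empty candidate sets")
    return float(np.mean(vals))


def write_rank_records(records: Sequence[RankRecord], path: str) -> None:
    """Write per-fold ranks as TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("miRNA\tdisease\tscore\trank\tn_candidates\tmode\n")
        for r in records:
            fh.write(
                f"{r.mirna_id}\t{r.disease_id}\t{r.score:.10g}\t"
                f"{r.rank:g}\t{r.n_candidates}\t{r.mode}\n"
            )


def write_roc(curve: ROCCurve, path: str) -> None:
    """Write the ROC points as TSV (FPR, TPR columns)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("FPR\tTPR\n")
        for fpr, tpr in curve.points:
            fh.write(f"{fpr:.10g}\t{tpr:.10g}\n")
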
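# Methods

## Model

`mdinfer` scores unknown miRNA–disease pairs by propagating known
associations over a heterogeneous graph whose two node layers (miRNAs,
diseases) are each equipped with an integrated similarity network.

**One propagation step** is the length-three path sum
`P(m, d) = Σ_i Σ_j SM(m(i), m) · A(m(i), d(j)) · SD(d(j), d)`, i.e. the
triple matrix product `SM · A · SD`: evidence flows from a known
association `(m(i), d(j))` to the pair `(m, d)` in proportion to how
similar `m` is to `m(i)` and `d` to `d(j)`. Iterating with a decay factor
and re-injecting the prior,

    P(t+1) = alpha * SM @ P(t) @ SD + (1 - alpha) * A,

accumulates paths of every length with geometrically decaying weight.
Unlike a restart random walk seeded only by a disease's known miRNAs, the
update is driven by the full similarity structure, so diseases (or miRNAs)
with *no* known associations still receive informative scores through the
similarity side; this is the model's main practical advantage.

**Normalisation and convergence.** Both similarity matrices are
symmetrically normalised, `S'(i, j) = S(i, j) / sqrt(r_i r_j)` with `r_i`
the row sums. `S'` is similar to the row-stochastic `D^-1 S`, so its
spectral radius is at most 1 and the two-sided update is a contraction
with factor at most `alpha < 1`; the fixed point exists, is unique, and is
independent of the initial iterate. We start from `P(0) = A` (exact at
`alpha = 0`, and empirically the fastest start) and stop when the
elementwise L1 change falls below `tol`. The fixed point also equals the
Neumann series `(1 - alpha) Σ_k alpha^k S_M^k A S_D^k`, which the tests
assert numerically, and `closed_form_fixed_point` solves the equivalent
linear system `(I - alpha · SD' ⊗ SM') vec(P) = (1 - alpha) vec(A)`
exactly as an independent oracle (practical up to a few thousand
unknowns).

## Similarity inputs

**Disease semantic similarity** uses MeSH Category-C tree numbers only (a
flat two-column table; no MeSH XML). A disease's DAG contains the disease
plus every term owning a proper dotted prefix of any of its tree numbers;
prefixes owned by no term are skipped, connecting the nearest indexed
ancestor, and a term's several tree numbers merge into one DAG so shared
ancestors are counted once. Contributions decay by `delta` per edge away
from the disease, taking the max over a node's children when several paths
exist. Association-file diseases are matched to MeSH terms by exact string
equality; unmatched diseases are simply unobserved on the semantic side.

**GIP kernels** adapt their bandwidth to association density:
`gamma = gamma' / mean ||IP||^2`, so a denser matrix flattens the kernel.
When every profile is all-zero the bandwidth is undefined;
`gip_bandwidth` raises, and pipeline-level callers (notably LOOCV folds)
fall back to `gamma = gamma'` with a logged warning rather than inventing
similarity.

**Integration** averages kernel and curated similarity where the curated
score exists and uses the kernel alone otherwise. On the disease side the
integrand is the disease kernel KD throughout; the miRNA kernel has the
wrong dimensions in that role.

## Parameters

| name | meaning | default | why |
|---|---|---|---|
| `delta` | semantic contribution decay per DAG edge, in (0, 1) | 0.5 | convention of the DAG-based similarity literature this score family follows |
| `gamma_prime_m`, `gamma_prime_d` | raw GIP bandwidths (> 0), divided by mean squared profile norm | 1.0 | standard choice in the interaction-profile kernel literature |
| `alpha` | propagation decay / restart weight, in [0, 1) | 0.4 | open parameter of the model; 0.4 follows heterogeneous-graph inference precedent. Scores are monotone in evidence for any valid value |
| `tol` | L1 convergence cutoff | 1e-6 | small enough that the fixed-point residual is below ranking resolution |
| `max_iter` | iteration cap | 10000 | never reached for alpha <= 0.9 on normalised inputs; exhaustion returns `converged=False` with a warning instead of raising |

## Evaluation protocol

Leave-one-out cross-validation holds out each known association in turn,
zeroes its entry, and recomputes *everything downstream of A* — GIP
kernels, integrated similarities, normalisation, propagation — on the
training matrix, so the held-out edge cannot leak through the similarity
side. (A `reuse_kernels` switch computes the kernels once from the full
matrix; it is cheaper and clearly labelled as the leaky variant, for
exploration only.) Semantic and functional similarity do not depend on A
and are computed once outside the folds.

The held-out pair is ranked by descending score, ties receiving the
average rank, among its candidates: in **global** mode all pairs unknown
in the training matrix, in **local** mode the miRNAs unknown for the
held-out disease. `n_candidates` counts the *competing* candidates, so
`1 <= rank <= n_candidates + 1`.

The ROC curve sweeps rank-percentile thresholds
`u = (rank - 1) / n_candidates` (the fraction of a fold's negatives that
outscore the positive): TPR(θ) is the fraction of folds with `u <= θ` and
FPR(θ) = θ, the expected fraction of negatives above the threshold.
Percentiles make global and local folds comparable despite very different
candidate-set sizes. The trapezoidal area under this curve equals the
Mann–Whitney mean `avg (n_candidates + 1 - rank) / n_candidates` — the
probability that a held-out association outranks a random candidate
negative — exactly, including under ties (average ranks keep the
statistic unbiased); `mean_rank_auc` computes it directly and the tests
assert the equality. A constant scorer yields AUC exactly 0.5, a perfect
scorer exactly 1.

## Synthetic benchmark

`simulate_block_dataset` plants the assumption the model exploits —
functionally similar miRNAs associate with similar diseases — as a block
model: round-robin group assignment (balanced, reproducible), associations
with probability `p_in` within a matched group and `p_out` otherwise,
similarities drawn around `s_in` / `s_out` with truncated-Gaussian noise
(clipped to [0, 1], symmetrised, unit diagonal), and an `fs_coverage`
fraction of miRNA pairs observed. `simulate_dag_forest` grows one random
dotted-tree per group so same-group diseases share MeSH-style ancestors
and cross-group diseases share none (semantic similarity exactly zero
across groups). Defaults — 60 miRNAs, 40 diseases, 4 groups, `p_in=0.3`,
`p_out=0.02` (overall density ≈ 0.09), `s_in=0.8`, `s_out=0.1`, noise sd
0.05, 70% coverage — give a moderately sparse benchmark with clear but
noisy signal.

What the generator does *not* emulate: the heavy-tailed degree
distribution of curated association databases, the score distribution of
published functional-similarity tables, correlated annotation errors, or
literature bias toward well-studied miRNAs. Passing the synthetic
benchmark therefore shows the pipeline recovers planted homophily signal
end-to-end; it does not certify accuracy on any particular curated
dataset, and per-dataset AUCs will differ.

## Numerical choices and degenerate inputs

* Convergence is measured by the elementwise L1 norm of the iterate
  difference; the returned fixed point satisfies the stationarity equation
  to below `tol`.
* Dense float64 matrices throughout: at curated-database scale (hundreds
  by hundreds) the dense triple product is trivially fast, and the
  propagation update is dense anyway.
* Ranking ties take the average rank (unbiased Mann–Whitney AUC);
  within-disease prediction output breaks score ties by miRNA identifier
  for deterministic files.
* Duplicate association rows collapse to one entry with a warning
  (curated exports contain duplicates); conflicting duplicate functional
  similarity scores are an error.
* An all-zero association matrix makes the GIP bandwidth undefined: error
  at the primitive level, logged `gamma = gamma'` fallback at pipeline
  level.
* LOOCV restores the held-out entry even if a fold raises, leaving the
  input matrix bit-identical.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run the full LOOCV (one
pipeline recomputation per fold, ~200 folds) on the default 60 x 40
benchmark, and verify the solvers on batches of random instances up to
10 x 10 — sizes at which the closed-form oracle is exact and the whole
suite completes in seconds while exercising every code path at realistic
density.

## Known limitations

* Exact string matching between association-file disease names and MeSH
  terms; no synonym resolution.
* The decay factor `alpha` is not identified by the model itself; the
  default is a convention, and sensitivity to it should be checked per
  dataset.
* Scores are biased toward miRNAs with many recorded associations (their
  profiles carry more mass through the kernel).
* No sparse or GPU execution path; problems far beyond curated-database
  scale would need one.
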
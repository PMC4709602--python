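# Methods

## Model

`hetwalk` scores candidate binding proteins for a query lncRNA with a
random walk with restart (RWR) on a heterogeneous two-layer network. The
working assumption is guilt by association across layers: lncRNAs with
similar expression profiles tend to share protein partners, and proteins
that interact with each other tend to bind the same lncRNAs. The walk turns
both assumptions into a single diffusion process whose stationary
distribution concentrates on proteins that are close — through any mixture
of expression-similarity edges, PPI edges and known interactions — to the
query and its known partners.

### Network layers

**lncRNA layer.** For expression profiles X, Y over K tissues/cell types,
the edge weight is the absolute Pearson correlation
SL(i,j) = |cov(X,Y)/(σ_X σ_Y)|. The absolute value is deliberate: a
strongly anti-correlated pair is treated as functionally related. Any
strictly positive similarity yields an edge; there is no extra threshold.
The diagonal is zero — self-loops would inflate the restart mass a node
keeps and distort the ranking. Zero-variance profiles have no defined
correlation; such lncRNAs get similarity 0 to every other node (with a
warning) rather than an imputed value. lncRNAs that appear in the
interaction table but have no expression profile keep an all-zero
similarity row: they can still be queried, but mass leaves them only
through their known partners.

**Protein layer.** The weighted PPI score matrix SP is normalised
symmetrically, SP′(i,j) = SP(i,j)/√(M(i,i)·M(j,j)) with M(j,j) = Σ_i SP(j,i).
The square-root form is the standard symmetric normalisation: it keeps SP′
symmetric, bounded by 1, and for an unweighted graph reduces to
1/√(d_i d_j). Normalising by the raw product M(i,i)M(j,j) instead would
shrink scores quadratically with degree and break the bound; we use the
square root. Proteins with zero total score keep all-zero rows.

### Transition matrix

With m proteins (indices 0..m−1) and n lncRNAs (indices m..m+n−1),

    W = [ W_P   W_PL ]
        [ W_LP  W_L  ]

Protein row i: if protein i has no known lncRNA partner, W_P(i,·) is the
row-normalised SP′ row (mass 1 stays in the layer). If it has partners, the
intra-layer part is scaled by 1−γ and W_PL(i,·) distributes γ uniformly
over its partner lncRNAs. lncRNA rows are built the same way from SL and
the transposed interaction matrix: the cross mass of lncRNA j is divided by
its number of partner proteins, which is the only reading that keeps the
row stochastic. Two degenerate cases are resolved explicitly:

- a node with cross partners but no intra-layer neighbour sends its entire
  unit mass across (γ is effectively 1 for that row) — otherwise the row
  would sum to γ < 1 and leak mass;
- a fully isolated node keeps an all-zero row. The restart term still
  injects mass into it; it simply emits nothing. This is the
  minimal-assumption alternative to adding a self-loop.

Every row therefore sums to exactly 1 or exactly 0, which the test suite
asserts to 10⁻¹² on randomly generated networks.

### Walk and ranking

The initial vector for query lncRNA j puts mass β on j and 1−β spread
equally over its known partner proteins; if the query has no known partner
the whole unit mass sits on the query (the vector always sums to 1, so
results for seedless queries remain comparable). The iteration

    Y_{t+1} = (1−δ) Wᵀ Y_t + δ Y₀

is run until the **L1** change between successive vectors falls below the
tolerance. L1 is the natural norm for probability mass; the iteration map
is a contraction with factor 1−δ, so for the defaults (δ = 0.3,
tol = 10⁻¹⁰) convergence needs at most ⌈log tol / log(1−δ)⌉ ≈ 65
iterations, far below the max_iter cap of 10,000. Failure to converge is
reported via a flag, not an exception. Candidates (proteins with no known
interaction with the query) are ranked by their raw entries in the protein
partition of Y∞ — the constant (1−β) factor is not divided out because it
cannot change ranks. Ties break lexicographically on protein id so output
is deterministic.

## Parameters

| name | meaning | default | rationale |
|---|---|---|---|
| δ (delta) | restart probability per step | 0.3 | standard RWR setting; the result is known to be insensitive to it |
| β (beta) | initial mass on the lncRNA layer | 0.5 | weights the two layers equally |
| γ (gamma) | cross-layer jump probability | 0.5 | intra- and inter-layer evidence weighted equally |
| tol | L1 convergence tolerance | 10⁻¹⁰ | well below any score difference that could affect a rank |
| max_iter | iteration cap | 10,000 | ~150× the contraction bound at the defaults |

All three probabilities are validated against their open-interval bounds
(δ additionally admits 1.0, which collapses the walk to Y₀).

## Evaluation

Leave-one-out cross-validation hides each known interaction in turn. Only
lncRNAs with ≥ 2 known partners contribute trials, so every trial keeps at
least one seed protein. For each trial the hidden pair is removed from the
interaction matrix *before* the transition matrix and the initial vector
are built (the hidden protein may stay a seed for other lncRNAs); the
hidden protein joins the candidate set and is scored like any other.

- **ROC/AUC**: (score, label) pairs are pooled across trials into one curve
  (AUC by trapezoidal integration, which equals the normalised
  Mann–Whitney statistic; asserted to 10⁻¹⁰ in tests). Caveat: scores are
  strictly comparable only within a trial; pooling follows the standard
  single-curve presentation of link-prediction studies.
- **Operating points**: sensitivity, accuracy, precision and MCC at the
  threshold whose specificity is the closest achievable value ≥ the
  requested level (defaults 0.99, 0.95, 0.90). A threshold above the top
  score (zero positive predictions, specificity 1) is included and flagged;
  any zero denominator in a metric yields 0 for that metric.
- **precision@k / recall@k**: pooled over trials — precision@k is the
  fraction of the k·(number of trials) top slots occupied by hidden
  partners, recall@k the fraction of hidden partners ranked ≤ k.
- **Fold enrichment**: mean over trials of N/(2n), where N is the
  candidate-set size and n the hidden partner's rank; 1 is the random
  expectation, N/2 the maximum.
- **Percentile retrieval**: trials whose hidden rank ≤ ⌈qN/100⌉; the
  ceiling keeps the top-q% bucket non-empty for small N.
- **Randomized baseline**: the cross-validation is repeated with each
  query's interaction column rewired to a uniformly random protein set of
  the same size (excluding the hidden protein), and both the transition
  matrix and the restart vector are built from the rewired column. An
  alternative in which only the restart seeds are randomized while the true
  interactions stay in W was measured and rejected: the surviving network
  signal keeps its AUC near 0.71 on the default scenario, which defeats the
  purpose of a chance-level reference, whereas full rewiring gives ≈ 0.58
  (the residue above 0.5 comes from the expression layer, which is not
  randomized). One integer seed makes the baseline bit-reproducible.
- **PPI-only baseline**: plain RWR on the normalised PPI layer, restarting
  uniformly on the query's training partners — the single-layer comparison
  method.

## Synthetic data

The generator plants exactly the structure the walk assumes. lncRNAs and
proteins are assigned round-robin to groups. Expression profiles are a
shared per-group latent profile plus i.i.d. Gaussian noise; the noise SD is
solved from the target within-group correlation ρ via ρ = 1/(1+σ²)
(default ρ = 0.8). PPI edges are dense and high-scoring within groups
(density 0.8, scores U(0.6, 1.0)) and sparse/weak between groups (density
0.05, scores U(0.1, 0.4)), giving the normalisation realistically
heterogeneous degrees. Each lncRNA draws 1 + Poisson(3.37) partners — mean
4.37, matching the average partner count of curated human interaction sets
— inside its own group except with probability `noise_rate` (default 0.1)
per partner. Default sizes (60 lncRNAs, 40 proteins, 24 conditions, 4
groups, seed 1) keep a full cross-validation plus a 100-repetition
randomized baseline under a minute on one CPU.

What the generator does **not** emulate: the heavy-tailed degree
distributions of real interaction databases, the evidence-channel semantics
of real PPI scores, expression measurement noise structure (batch effects,
zero inflation), and identifier-mapping noise. Passing tests therefore
demonstrate correctness of the algorithm and internal consistency of the
evaluation, not performance on any real database snapshot.

## Numerical and design choices

- Node order is the lexicographic sort of identifiers, fixed at registry
  construction, so every matrix index is reproducible across runs.
- Duplicate weighted PPI records keep the maximum score (conservative for
  an evidence score); duplicate interaction pairs collapse silently with a
  count; expression rows with missing cells are dropped, not imputed.
- Matrices are dense numpy arrays: at evaluation scale (hundreds to ~1,200
  nodes) dense mat-vecs beat sparse overhead, and the full LOOCV on the
  default scenario runs in well under a second per hundred trials.
- The closed-form fixed point δ(Id − (1−δ)Wᵀ)⁻¹Y₀ is used in the test
  suite as an independent oracle for the iterative solver, never as the
  implementation.

## Limitations

- Scores are propagated probabilities, not calibrated interaction
  probabilities; compare them within a query, not across queries.
- lncRNAs without expression profiles lose the similarity layer entirely;
  their predictions rely on known partners alone.
- The pooled ROC treats cross-trial scores as comparable (see caveat
  above); per-query evaluation is available through the per-trial records.
- Very sparse interaction sets (many single-partner lncRNAs) leave few
  usable cross-validation trials, and network-based propagation is known to
  be biased toward high-degree proteins.
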
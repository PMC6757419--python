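# Methods

## The prediction problem

Given a binary miRNA–disease association matrix `A` (rows = `nm` miRNAs,
columns = `nd` diseases), the task is to score every unobserved pair by how
likely it is to be a true but undiscovered association. The guiding
assumption is the standard one in this literature: functionally similar
miRNAs tend to associate with phenotypically similar diseases. The package
scores pairs by a similarity-weighted, popularity-damped two-step diffusion
over the bipartite association graph, run in both directions and averaged.

## Similarity construction

**Disease semantic similarity.** Every disease `S` is represented by the DAG
of its ancestor terms (MeSH-style child→parent edges). Two contribution
models are computed:

* *Model 1 (depth decay).* The disease's own term contributes 1; any other
  term contributes `Δ` times the largest contribution among its children in
  the DAG, i.e. `Δ^depth` along the shortest ancestor path. `Δ` defaults to
  0.5, the convention of the MISIM lineage these models descend from;
  exposed as `SemanticParams.delta` (valid range (0, 1]).
* *Model 2 (information content).* A term contributes
  `−log(n_DAGs_containing_term / n_diseases)`, identically in every DAG, so
  ubiquitous terms contribute nothing and rare terms most. The log base is
  natural; since a base change rescales all contributions by one common
  factor, the similarity ratio is base-invariant (unit-tested).

For either model the similarity of diseases `A` and `B` is the summed
contribution of their shared terms divided by the sum of their total
semantic values; the default (`model="combined"`) is the elementwise mean of
the two models. Self-similarity is defined as 1, including the degenerate
model-2 case where a disease's entire DAG is ubiquitous (zero semantic
value); off-diagonal pairs with a zero denominator get similarity 0 with a
warning.

**Gaussian interaction-profile (GIP) kernels.** Disease profiles are the
columns of `A`, miRNA profiles the rows;
`K(x, y) = exp(−γ · ||x − y||²)` with `γ = γ' / mean(||profile||²)` and raw
bandwidth `γ' = 1` on both axes. Dividing by the mean squared profile norm
is the normalisation of the GIP-kernel literature this method builds on;
`KernelParams(bandwidth_form="multiply")` switches to multiplying for
comparison. An all-zero association matrix has no profiles and is rejected.

**Integration.** The integrated miRNA similarity `MS` uses the curated
functional-similarity matrix wherever both miRNAs are covered by it and the
miRNA GIP kernel elsewhere; the integrated disease similarity `DS` likewise
prefers the combined semantic similarity over the disease GIP kernel.
Coverage is per-pair: a pair has curated similarity iff both identifiers
appear in the curated input.

## The projection

**Transfer weights.** Each bipartite edge carries a weight in each
direction:

    wr(m_j, d_i) = Σ_k MS(m_j, m_k) · A(m_k, d_i) / Σ_k MS(m_j, m_k)
    wd(m_j, d_i) = Σ_k DS(d_i, d_k) · A(m_j, d_k) / Σ_k DS(d_i, d_k)

Self-similarity terms are included in both sums. With identity similarity
the weights collapse to the raw adjacency; with all-ones similarity they
collapse to degree fractions (both cases are pinned by tests).

**Initial information.** The resource placed on a known edge is damped by
the popularity of the receiving side: `S_ini = A · k^β`, with `k` the
disease degree in the disease-based network and the miRNA degree in its
mirror. `β` defaults to −0.1 and is restricted to (−1, 0]; `β = 0` is the
undamped limit. Entries with `A = 0` carry no resource; `0^β` never arises
with `A = 1`.

**Two-step diffusion.** Resource flows miRNA→disease→miRNA with weights
`wr`, normalised by the weighted degrees `d(m_k) = Σ_i wr(m_k, d_i)` and
`d(d_i) = Σ_j wr(m_j, d_i)`. The composition is the propagation matrix

    P(m_j, m_k) = (1/d(m_k)) Σ_i wr(m_j, d_i) wr(m_k, d_i) / d(d_i)

whose columns sum to one (total resource is conserved; verified to 1e-10 on
random instances), and `S_M = P · S_ini`. The miRNA-based direction is the
exact mirror — `wd` in both steps, miRNA-side damping, the `nd × nd`
analogue of `P` — implemented by the same code path parameterised by
direction, and yields `S_D`. The final score is `S_fin = (S_M + S_D)/2`.

**Isolated nodes.** A node with zero weighted degree has no diffusion path;
the projection fails fast with an error listing the offending identifiers
rather than silently returning zeros. `drop_isolated` (library) and
`--drop-isolated` (CLI) remove such nodes beforehand. Masking the only
association of a degree-1 node during cross-validation zeroes its `wr`
column or `wd` row exactly, so such folds fail and are reported (see below).

All computation is dense double precision: at the intended scale (hundreds
to a few thousand nodes) dense linear algebra is both simplest and fastest.

## Evaluation

**AUC.** The rank-sum (Mann–Whitney) formulation with tied scores counted
half — the probability that a random positive outscores a random negative —
with the ROC curve produced by threshold sweeping. An exhaustive
pair-counting oracle in the test suite checks the implementation on random
score sets with ties.

**LOOCV.** Each known association is zeroed in turn; by default every
A-dependent stage (GIP kernels, integrated similarities, transfer weights,
initial information) is recomputed from the masked matrix, which is the
leak-free protocol. `RecomputeFlags` freeze any stage to the full-matrix
version to probe leakage; freezing everything provably returns the
full-matrix score for every fold, and the suite asserts the resulting AUC
inflation. Each held-out positive is compared against all pairs never
observed in the full matrix, scored within its own fold; the global AUC is
the mean of the per-positive Mann–Whitney fractions. Folds that isolate a
node are recorded with a missing score, excluded from the AUC, and warned
about — never silently dropped.

**Repeated k-fold.** Per repetition the known pairs are shuffled and split
into k groups whose sizes differ by at most one; each group is held out in
turn and the repetition's AUC is pooled as above. The summary is the mean ±
sd over repetitions. All randomness derives from one user seed through
`numpy.random.SeedSequence.spawn`, one child stream per repetition, so runs
are bit-reproducible and repetitions independent. With `k` equal to the
number of associations and one repetition the protocol reduces exactly to
LOOCV (tested).

**β sweep.** The chosen CV protocol is rerun per β over a grid (default
−0.9 … 0 in steps of 0.1); the AUC varies little across the range on the
synthetic benchmark, matching the known insensitivity of this method family
to the damping exponent.

**Baseline.** `degree_product_scores` (score = `k_m · k_d` of the fold's
matrix) is the popularity-only baseline; on planted-structure data the
projection must and does beat it on identical folds.

## Synthetic data

The generator plants exactly the structure the method assumes: miRNAs and
diseases are assigned round-robin to `n_blocks` communities; associations
are Bernoulli(`p_within`) inside a community and Bernoulli(`p_between`)
across; the functional-similarity matrix is
`clamp(fs_signal · same_block + (1 − fs_signal) · noise)` over a random
`fs_coverage` fraction of miRNAs (partial coverage keeps the kernel
fallback of the integration step exercised); disease DAGs are ancestor
chains drawn mostly from per-community term pools under a shared universal
root, so same-community diseases share more ancestors. The matrix is
resampled (bounded retries) until no node is isolated. One seed drives
independent named sub-streams for the three artifacts.

Defaults — 60 miRNAs × 40 diseases, two communities, `p_within = 0.6`,
`p_between = 0.02`, `fs_signal = 0.8`, `fs_coverage = 0.85`,
`dag_depth = 4` — define the benchmark used throughout the tests and the
acceptance script: large enough that LOOCV AUC comfortably separates
planted structure (≈ 0.84) from the chance band, small enough that a full
LOOCV runs in about a second. The structureless control uses one block with
uniform density 0.15 and uninformative similarity. `dag_depth = 4` reflects
typical MeSH disease-term depths; `fs_signal = 0.8` makes the curated
similarity informative but noisy.

What the generator does **not** emulate: the heavy-tailed degree
distribution of real curated association databases, correlations between
miRNA family structure and disease ontology beyond block co-membership, and
biased/incomplete curation. Passing tests therefore demonstrate
correctness of the algorithm and its evaluation harness and recovery of
planted community signal — not the AUC the method attains on any real
database. Real curated inputs in the documented file dialects can be run
through the same CLI unchanged.

## Numerical choices and edge cases

* Similarity matrices are validated symmetric within 1e-12 (readers
  average asymmetries up to 1e-8 and reject worse), entries in [0, 1].
* Kernel matrices are explicitly symmetrised and their diagonal pinned to 1
  to remove floating-point asymmetry from the distance computation.
* Propagation output is clipped at 0 to guard against tiny negative
  round-off; scores are validated finite and nonnegative.
* Ranking ties break lexicographically on miRNA identifier, making ranked
  outputs platform-independent.
* The association writer emits label-directive comments so that
  write→read round-trips preserve label order and isolated nodes exactly;
  plain two-column edge lists load with first-appearance label order.

## Known limitations

* The method cannot score nodes with no known association (a property of
  the projection itself); they must be dropped first.
* LOOCV recomputes the pipeline per fold; at tens of thousands of
  associations, repeated fivefold CV is the practical protocol.
* Model-2 semantic similarity degenerates to 0 for disease pairs whose
  shared vocabulary is ubiquitous; the combined model softens but does not
  remove this.
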
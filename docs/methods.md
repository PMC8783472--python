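# Methods

This note records the models implemented in `sczeros`, the numerical
choices behind them, and what the synthetic experiments do and do not
show. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Count models and model selection

A gene's counts across cells of one type are modeled by one of four
families: Poisson(λ), zero-inflated Poisson ZIP(λ, p), negative binomial
NB(μ, ψ) in the size parameterization (Var = μ + μ²/ψ), and ZINB(μ, ψ, p).
The zero-inflated families mix a point mass p at zero with the base
distribution at weight 1 − p. The families are nested: p → 0 collapses
ZIP→Poisson and ZINB→NB; ψ → ∞ collapses NB→Poisson and ZINB→ZIP. We keep
ψ = +∞ as an explicit sentinel: a reported NB/ZINB fit with ψ = +∞ *is*
the Poisson/ZIP limit, which avoids ridge non-identifiability near the
boundary (any ψ ≥ 10⁶ is reported as +∞).

**Fitting.** Poisson: λ̂ = x̄ in closed form. NB: μ̂ = x̄ for every ψ, so ψ
is found by bounded 1-D maximization of the profile likelihood on log ψ ∈
[log 10⁻⁴, log 10⁶] (Brent, xatol 10⁻⁶). ZIP: EM over the latent
zero-origin indicator with closed-form M-steps for p and λ (tolerance
10⁻⁸ on the log-likelihood, 500 iterations). ZINB: before any iteration
we evaluate the score of the likelihood in p at the boundary p = 0 of the
NB maximum — it is n₀/f(0) − n, so when the observed zero fraction does
not exceed the NB fit's zero probability, the NB fit already is the ZINB
maximum and is returned directly. Otherwise 30 EM warm-up iterations (p
and μ closed-form, ψ by a coarse profile search) are followed by an
L-BFGS-B polish on (log μ, log ψ, logit p); EM alone crawls along the
weakly identified ψ/p ridge. The fit is finally floored at the NB (p = 0)
and ZIP (ψ = ∞) boundary fits, so the nesting inequalities between
maximized log-likelihoods hold by construction up to optimizer tolerance.
p is confined to [0, 0.999] so the likelihood stays finite. All-zero
genes are the point mass at zero for every family (mean 0, log-likelihood
0) and are never tested.

**Selection.** The chain tests Poisson vs NB first (dispersion), then the
winner against its zero-inflated extension, both at α = 0.05. Because the
null value lies on the boundary of the parameter space, the test
statistic Λ = 2Δloglik is referred to the mixture ½χ²₀ + ½χ²₁ rather than
χ²₁ (Λ = 0 gives p = 1). A consequence worth knowing: strongly
overdispersed ZIP data leave the chain at stage 1, so they are reported
as ZINB with a very large ψ̂ — the same distribution on the ZINB boundary.
Genes with a single distinct value skip the dispersion test (p-value 1).

## Telegraph model of biological zeros

The two-state promoter model has four reaction channels: activation at
k_a (when inactive), inactivation at k_i (when active), synthesis at s_m
(when active), degradation at m·δ at copy number m. Time units are
arbitrary; δ = 1 is the documented normalization. `simulate_telegraph` is
an exact Gillespie simulation; the inner loop is compiled with numba
because the interesting regimes produce 10⁶–10⁷ events. Occupancy
statistics weight each copy-number state by its holding time and discard
the first 10% of the run as burn-in; the simulation starts inactive at 0
copies (active when k_i = 0, the always-active limit, so the birth–death
stationary regime is entered immediately).

The stationary law is computed from the Beta-Poisson representation: copy
number is Poisson with intensity (s_m/δ)·U, U ~ Beta(k_a/δ, k_i/δ). The
mixture integral is evaluated with 128-node Gauss–Jacobi quadrature
(chosen over confluent-hypergeometric evaluation for robustness at
extreme rate ratios), and the support is extended until the truncated
tail mass is below 10⁻⁸. Limits are handled explicitly: k_i = 0 gives
Poisson(s_m/δ); k_a = 0 or s_m = 0 gives the point mass at zero.

## Masking schemes

All schemes mask exactly round-half-up(q·nnz) non-zero entries in total
(at least 1 when q > 0), never touch zero entries, and never modify the
input. Matrix-wide schemes pick that many positions directly — uniformly
at random, or the smallest values with seeded tie-breaking at the cut.
Per-gene schemes first apportion the total across genes by largest
remainder: gene g receives floor(q_g·nnz_g) plus at most one unit, extras
going to the largest fractional parts. Each gene's masked count is
therefore the floor or ceiling of its real-valued target while the grand
total stays exact; independent per-gene rounding would bias the overall
proportion upward (every gene with odd nnz_g rounds 0.5 up at q = 0.5).

Gene-specific proportions use q_g ∝ exp(−μ_g/μ̄), with μ_g the mean of the
gene's non-zero counts and μ̄ the mean over all non-zero entries, clipped
to [0, 0.99]; the proportionality constant is calibrated by bisection so
the apportioned total matches round(q·nnz). The shape encodes the
empirical regularity that lowly expressed genes lose a larger share of
their counts to technical zeros. These per-scheme semantics are this
package's reconstruction from the schemes' names and documented
properties; they are exact contracts here, not a claim about any external
implementation.

## Synthetic data and DE ground truth

`sample_reference_panel` draws per-gene, per-type count models: means are
lognormal(0, 1.5) per type (heavy-tailed, independent across types so
types genuinely differ); the family (NB with probability 0.7, else
Poisson) and dispersion (lognormal with median 1, log-sd 1) are drawn
once per gene and shared across types, mirroring real data where
dispersion is largely a gene/technology property — and guaranteeing that
after mean-averaging, non-DE genes are *identically distributed* across
types, which every downstream null test presupposes. The `umi-like`
preset has no zero-inflation components; `smartseq2-like` gives roughly
half the genes p ~ U(0.05, 0.5), reflecting the qualitative contrast
between full-length and UMI protocols.

DE ground truth ranks genes by |mean_A − mean_B| of the model mean
parameters on the count scale (ties broken by gene id, ascending,
deterministic); the top n_de genes keep their models and all others get
the average mean in both types with dispersions kept. Generation draws
each gene independently from its marginal; the optional Gaussian copula
couples only the top_k highest-mean genes (default 100) per population —
a deliberately scoped-down correlation model: coupling every gene is
quadratic in gene count and unnecessary for desk-scale experiments. The
copula is estimated by the distributional transform (uniform jitter over
each count's CDF gap, probit, empirical correlation, projection to the
nearest correlation matrix by eigenvalue clipping).

What the generator does *not* emulate: batch effects, cell trajectories,
library-size variation between cells of a type beyond what the count
models imply, and genome-scale gene-gene correlation. Tests passing on
these synthetics demonstrate the pipeline's statistical correctness under
its stated model, not performance on any particular real dataset.

## Downstream analyses

Cells with zero total counts (possible after heavy masking) are dropped
with a logged warning before log-normalization (log(1 + 10⁴·count/total)).
The clustering pipeline selects the 2000 most variable genes, takes PCA
scores (default 50 PCs, 30 in the desk-scale benchmark config), builds a
shared-nearest-neighbor graph over all cell pairs (Jaccard overlap of
k-NN sets, k = 20 default, pruned below 1/15 — the toolkit-standard
sparsification), and partitions it with seeded Leiden at resolution 0.8.
Cells are processed in a canonical sort order so the partition is
invariant to input permutation. The 2-D embedding for silhouette scoring
is UMAP on the PC scores with a fixed random state; silhouette is
computed in that 2-D space, with singleton-label points contributing 0.

The count-model LRT for DE selects a family on the pooled counts of both
groups, then compares the pooled fit (null) with per-group fits
(alternative) against χ² with df equal to the family's free-parameter
count. The selection step is treated as fixed — no post-selection
correction — which is standard practice and is validated empirically by
the type-I-error and FDR tests rather than by theory. The
detection-proportion test on binarized counts is a pooled-variance
two-sample z-test with Fisher's exact test as fallback whenever an
expected 2×2 cell count is below 5. Untestable genes (no counts, or no
detections) carry NA p-values and are excluded from the BH multiplicity
count m.

## Benchmark and reproducibility

`run_benchmark` crosses masking schemes × proportions × input types ×
analyses × replicates, always including the unmasked baseline, and writes
tidy records. One master seed drives everything; per-condition streams
are derived by hashing the condition tuple (sha256, stable across
processes), so any single condition can be re-run in isolation and two
runs of the same config are bit-identical. Desk-scale defaults — 300
genes, 150 cells per type, n_de = n_genes/5 — keep a full grid affordable
on one CPU; they are the package's chosen study size, and all headline
properties (exact masking counts, FDR control, monotone F1 degradation
under random masking, ARI robustness at moderate masking) are asserted at
this scale in `tests/test_acceptance.py`.

Known limitations: the family-selection chain cannot return ZIP for
overdispersed data (see above); the copula covers only the top-expressed
gene subset; the per-gene-specific proportion calibration is exact up to
the granularity of per-gene rounding steps (within ~1 entry in practice);
and UMAP determinism holds per environment (fixed seeds), not bit-for-bit
across library versions.
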
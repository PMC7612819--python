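# Methods

`devimmune` implements the statistical core of a cross-tissue,
cross-gestation single-cell analysis: testing where in a latent cell-state
space cell abundance changes with gestational age or differs between
organs, finding the genes that mark those shifting states, separating
biological organ-specific expression from tissue-processing artifacts,
quantifying immune-receptor repertoire biases, factorizing spatial
cell-type maps into colocalization microenvironments, and transferring
labels between embedded datasets. Every procedure is exercised end-to-end
on synthetic data whose generating parameters are recorded, so recovery
can be scored without external downloads.

## Neighborhood differential abundance

Cells are represented by a low-dimensional embedding (in practice a
batch-corrected latent space; the generator draws per-type Gaussians). A
KNN graph (Euclidean, k = 30 for gestational tests, k = 100 for
cross-organ tests) is symmetrized by union. Index cells are sampled at
proportion 0.05–0.1 of all cells, refined to the member of their closed
neighborhood nearest the neighborhood's componentwise median position,
and deduplicated; each index cell plus its graph neighbors forms a
*neighborhood*, the unit of testing. Neighborhoods are labeled by
majority vote: the modal member cell-type label when it is unique and
covers at least 50% of members, otherwise "Mixed". A plurality below 50%
is Mixed because such neighborhoods straddle annotation boundaries; an
exact 50% unique mode is still labeled (only a *minority* mode is
disqualifying).

Counts of member cells per sample are modeled per neighborhood with a
negative-binomial log-linear GLM. The offset is the log total cell count
of the sample over all neighborhoods, which makes the test compositional:
only relative abundance trends are estimable, and a trend shared by every
neighborhood is absorbed by the offset. Gestational age enters as an
ordinal age-bin index (bins of 2 pcw anchored at the dataset minimum;
organs spanning fewer than 3 consecutive bins are excluded), giving one
log fold change per bin; a categorical last-versus-first coding is
available behind a flag. Organ tests use an organ-versus-rest indicator.
Confounders (the FACS correction factor, library protocol) are
dummy-coded; constant columns are dropped, so an unsorted dataset is
identical to omitting the FACS covariate.

Estimation is a vectorized IRLS shared across neighborhoods: a Poisson
pilot fit, a method-of-moments dispersion per neighborhood from
Var = mu + alpha mu^2, shrinkage of raw dispersions toward a lowess
mean–dispersion trend weighted prior_df/(prior_df + df) with prior_df =
10, an NB refit at the shrunk dispersions, and quasi-likelihood
inference: the model covariance is scaled by the Pearson dispersion and
coefficients are referred to a t distribution on the residual degrees of
freedom. With ~12–24 samples this small-sample t is deliberately
conservative; under the generator's null the realized false-discovery
proportion at spatial FDR 10% averages ~0.10 over 20 simulations
(reported by the test suite and `scripts/acceptance.py`).

Multiplicity over neighborhoods is controlled with weighted
Benjamini–Hochberg, weight w_i = 1 / (kth-NN distance of the index
cell): dense regions carry many overlapping neighborhoods, and
density-proportional weights keep that redundancy from consuming the FDR
budget. After sorting by p-value, q_i = min over j >= i of
p_(j) * sum(w) / cumsum(w)_j, clipped to [0, 1]. With constant weights
this reduces exactly to standard BH (verified element-wise against
statsmodels).

### FACS correction

Samples sorted into CD45+/CD45− fractions over- or under-represent
immune cells. Each sorted fraction with measured live-cell share pi
contributes ln(pi) as a per-sample covariate (unsorted samples 0), so
the count model can absorb the enrichment; the exact functional form is
isolated in one function and can be swapped. The generator simulates
sorting by routing immune/non-immune cells to fractions with 98% purity
and records the realized shares.

## Marker discovery

For a cell type with significant early- (logFC < 0) or late- (logFC > 0)
neighborhoods at spatial FDR < 0.1, marker genes are found by testing
the type's cells inside those neighborhoods against the type's cells in
all other neighborhoods. A cell in both goes to the significant set,
keeping the two samples disjoint. The test is the overestimated-variance
t statistic t = (m_A − m_B) / sqrt(v_A/n_A + v_B/n_A) — both variance
terms divided by the tested group's size, a conservative variant that
equals standard Welch when group sizes match — with BH FDR. Markers are
then filtered: expressed fraction over tested cells <= 70% (housekeeping
exclusion), logFC > 1 natural-log units on the normalized-log scale, FDR
< 0.1%. The expressed-fraction filter is applied after testing, before
reporting. Gene-set activation scores subtract the mean of control genes
sampled from 25 equal-frequency expression bins (50 controls per set
gene), seeded for determinism.

## Pseudobulk interaction model

Raw counts are summed per (sample, cell type) into pseudobulks (>= 20
cells; the threshold matches the >= 20-cell gating used elsewhere in the
pipeline). Gene counts follow an NB GLM with donor fixed effects and the
log library size as offset. The organ effect is parametrized as two
columns — target organ in *other* cell types, and target organ in the
*target* cell type — spanning the same space as the classic main-effect +
interaction coding. The tested coefficient is therefore directly the
organ log fold change experienced by the target cell type. This choice
is deliberate: a processing artifact (e.g., dissociation stress in one
organ's samples) raises expression in *all* cell types, so it appears in
the per-cell-type organ logFC of target and control cell types alike —
which is what the control filter compares — whereas in a pure
interaction contrast it would cancel and the filter would have nothing
to catch. The classic interaction coefficient (target minus other) is
also reported. A gene is flagged "technical" when any control-cell-type
fit shows a same-sign logFC of magnitude >= 0.5 at FDR < 0.1 (defaults,
configurable).

## Repertoire statistics

Cycling fractions (raw marker count > 0, reported only for groups with
>= 10 cells) and chain features (junction length, NP-insertion lengths,
mutation frequency) are compared between groups with logistic/linear
regressions controlling for donor and organ as fixed effects; NP
features use only records flagged as high-quality D-segment mappings
(the flag is taken as input; the upstream caller's criterion is not
reproduced). Mutation frequency is the fraction of mismatching
non-gap positions between the aligned observed and germline sequences.
Segment usage is tested per segment as used/not-used: logistic
regression with BH adjustment across segments of a class (>= 5 total
uses required; a ridge-penalized IRLS fallback supplies a finite,
flagged odds ratio under separation), or a Pearson chi-squared test
without continuity correction. Per-sample usage-proportion vectors
(each segment family renormalized to sum 1) from samples with >= 20
cells are summarized by PCA; per-cell-type centroids carry 80% Gaussian
ellipses with squared radii scaled by the chi-squared(2 df) 0.80
quantile (3.219).

## Spatial microenvironments

Spot × cell-type abundance matrices (e.g., deconvolution output) are
first cleaned: a cell type is dropped only if its 99%-quantile abundance
is below 0.15 in *every* slide. NMF with d = 10 factors
(nonnegative-double-SVD initialization, coordinate descent; deterministic
under the seed) yields spot weights W and loadings H. Each cell type's
loadings are normalized across factors (H_norm columns sum to 1), read
as "what fraction of this cell type's signal sits in this
microenvironment"; a cell type belongs to a factor when that fraction is
strictly over 0.2, and factor subsets can be selected by requiring a
cell-type group's summed fractions to exceed 0.8. Spots carry a factor
when their weight is strictly above the factor's 90% quantile within the
slide. All three boundaries are strict. The within-factor normalization
of H is available behind a flag of the membership call (pass H rows
renormalized); across-factor fractions are the default because
membership should reflect where a cell type concentrates, not the
factor's internal composition.

The generator plants factors as Gaussian bumps on a square spot grid
(compact tissue zones), with centers spread by best-candidate sampling
so that planted zones are spatially distinct — as real tissue
compartments are, and as identifiability of the planted factors
requires — loading on small, mostly disjoint cell-type sets, plus
half-normal noise at 10% of mean signal; recovery is scored by
Hungarian-matched cosine similarity of loadings, exact membership-set
equality, and the fraction of assigned spots inside the planted bump
support (true weight > 10% of maximum).

## Label transfer and NMI

Query cells are classified from their k = 30 nearest reference cells in
the shared embedding with Gaussian weights exp(−d²/(2σ²)), σ = the
query's kth-neighbor distance (adaptive bandwidth; a fixed global
bandwidth would over-smooth dense regions). Normalized per-label weight
sums are the similarity scores; argmax is the prediction. Labeling
agreement uses NMI normalized by the arithmetic mean of entropies
(geometric available); single-class labelings return 0 with a warning
(the 0/0 case), and the argument order is canonicalized internally so
the score is bit-exactly symmetric.

## Synthetic data: what it does and does not emulate

The cell-table generator reproduces the statistical structure the
methods rely on: multi-donor multi-organ design, age-dependent
composition (log-linear per-type slopes, normalized), NB gene counts
(Gamma–Poisson, shared dispersion 0.3, mean depth 5000 over a 2,000-gene
panel), planted marker blocks, well-separated per-type Gaussian
embedding clusters, late-stage transcriptional states (60% penetrance
above 12 pcw, displaced 3 latent units — stage states occupy their own
embedding region, which is what neighborhood DA exploits), organ
enrichment, and CD45-sort thinning with recorded shares. It does not
simulate reads, UMIs, ambient RNA, doublets, batch effects in the
embedding, or realistic gene–gene correlation; passing tests demonstrate
that the estimators recover what they model, not robustness to
artifacts the generator omits. Counts are stored dense (int32): at this
panel size and depth, density is ~60% and sparse storage would cost
memory and time.

Repertoire tables are AIRR-style with planted multiplicative segment
odds (multiplying one segment's multinomial weight by c multiplies its
binary usage odds by exactly c), Gaussian junction-length shifts,
Poisson NP insertions, binomial per-site mutations on a shared germline,
and Bernoulli cycling. Segment base usage is Dirichlet-drawn by default;
simulation studies of interval coverage instead fix it to uniform, so
replicates share one data-generating process and differ only in
sampling noise. Spatial matrices are W·H plus half-normal noise as
above.

## Problem sizes and numerical choices

Simulated studies use ~12–24 samples and 15k–40k cells — large enough
for the asymptotics the tests rely on while keeping a full run of the
suite and the reproduction script inexpensive. Dispersions are clipped
to [1e-8, 100]; IRLS runs at most 60 iterations to tolerance 1e-8 with a
1e-10 ridge on the normal equations; all-zero neighborhoods/genes are
dropped from testing and reported as NaN rather than pseudocounted.
Exact ties: KNN distance ties break by cell index; label ties are
"Mixed"; boundary values at the microenvironment thresholds are
excluded (strict inequalities). Known limitations: the quasi-likelihood
t-test is conservative at very small sample counts; Wald CIs for
logistic odds ratios undercover slightly below ~100 events; NMF recovery
degrades when planted member sets overlap heavily; and the count
duplication invariance of the DA model is exact only in the Poisson
limit (the NB refit changes estimates at the 1e-2 level).
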
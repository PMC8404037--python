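# Methods

## The model

`taxafuse` treats downstream microbiome analysis as four composable
transforms. The statistical object moving through the pipeline changes at
each stage, and each stage is designed around one pathology of taxon
abundance tables.

### Stage 1 — Takagi–Sugeno rule inference (sparsity, effect size)

The label-augmented matrix (samples × features, plus a numeric label column
coded 1..K in lexicographic label order) is fuzzified per column:
`num_labels` Gaussian terms, means equally spaced over the observed
[min, max], common width σ = spacing/(2√(2 ln 2)) so adjacent terms cross at
membership 0.5. Constant columns get a single degenerate term.

Rules are generated one-per-sample (Wang–Mendel): the antecedent is the
argmax-membership term per variable (ties take the lower index, so the map is
deterministic); the rule degree is the product of the generating sample's
memberships; duplicate antecedents keep the highest-degree candidate, so the
rule count never exceeds the sample count and duplicated samples strictly
reduce it. Consequents are first-order linear functions fitted by the hybrid
scheme: a global linear least-squares solve for all consequent coefficients
on rule-normalised firing strengths, alternated with one analytic
gradient-descent step on the Gaussian means and widths. Because the
least-squares pass is optimal for the current premises, the training SSE
immediately after each pass never exceeds the SSE immediately before it; both
trajectories are recorded on the model. When the consequent system is wider
than the sample count the solver returns the minimum-norm solution (the
ridge-limit) and logs a warning.

The integer rendering of the rule base — term indices per rule, the output
variable's term index as the final "effective label" column — is the
*inferred matrix* handed downstream, together with its auto-scaled copy
(columns centred to mean 0, sample SD 1; constant columns map to zeros).
Correlation preservation is quantified as the elementwise
|ρ_before − ρ_after| of the two Pearson matrices; constant columns contribute
zero correlations.

### Stage 2 — DBSCAN over feature columns (collinearity)

Points are the *columns* of the auto-scaled inferred matrix, distance is
Euclidean. With minpts = 2 every non-isolated point is core, so DBSCAN's
output equals the connected components of the eps-neighbourhood graph;
isolated columns are noise and pass through unchanged. Clusters are collapsed
to Σᵢ ℓᵢ xᵢ with ℓ the unit-norm leading eigenvector of the cluster's column
covariance (centred, not re-standardised — the columns are already
auto-scaled), sign-fixed so the largest-magnitude loading is positive;
zero-variance clusters fall back to uniform 1/√k loadings.

Epsilon is selected by an ascending grid search from 1 to the maximum entry
of the *integer* matrix in steps of 0.5. At each eps the collapsed design
(intercept + collapsed columns) is checked for aliased columns by sequential
orthogonalisation with threshold 1e-7 × the largest column norm — the exact
mechanism by which a GLM reports unestimable (NA) coefficients; a multinomial
logistic fit of the effective labels on the accepted design is recorded for
diagnostics. The first eps with no aliased columns wins; if none qualifies
the final grid value is returned with a warning.

**Behaviour worth knowing.** Distances between auto-scaled columns scale as
√(2(n_rules−1)(1−r)) for column correlation r, while the grid tops out at
`num_labels`. When the rule matrix is tall (rules ≫ features) the design is
usually full rank at eps = 1, so the search stops after merging only
near-exact duplicates; moderately correlated blocks (r ≈ 0.9) sit at
distances the grid never reaches. Escalation beyond eps = 1 happens when
coarse fuzzy binning makes one block member an *exact* linear combination of
its mates — frequent in very sparse data, where columns differ from constant
only on a few shared rows. The stage is therefore a collinearity *remover*
(it restores estimability with the smallest possible intervention), not a
correlation-block *detector*; on nearly-square rule matrices the two
coincide. This is the main reason the end-to-end block-recovery rate reported
by `scripts/acceptance.py` is low at the default problem size, and we regard
it as a property of the published selection rule rather than a defect to
patch around.

### Stage 3 — adaptive LASSO (scores)

Cluster scores solve

    argmin_β ‖y − Σⱼ xⱼβⱼ‖² + λ Σⱼ wⱼ|βⱼ|

with y the (auto-scaled) effective label treated as continuous regardless of
K — squared-error loss as written, no ½ factor, so the orthonormal-design
solution is the soft threshold S(xⱼᵀy, λwⱼ/2). The solver uses the rescaling
trick (x̃ⱼ = xⱼ/wⱼ, plain LASSO, β̂ⱼ = β̃ⱼ/wⱼ) with X and y de-meaned (the
intercept-equivalent fit; `center=False` solves the bare objective). λ is the
minimum-cross-validated-error value over a seeded k-fold split (k = 10
default), followed by a tight refit so the returned solution satisfies the
stationarity conditions to ~1e-12.

The penalty multipliers used by the pipeline are wⱼ = 1/max(|β̂ⱼ^pilot|, 1e-6),
the reciprocal magnitudes of an unpenalised linear-link pilot GLM
(tiny-ridge-stabilised when the design is wide or singular). This is the
oracle weighting that gives the adaptive LASSO its consistent-selection
property: strong pilot evidence ⇒ light penalty. The weight floor keeps the
rescaling finite when pilot coefficients vanish. Feature scores are cluster
score × first-PC loading (singletons carry loading 1); distribution summaries
use moment estimators — skewness g₁ = m₃/m₂^1.5 and *non-excess* kurtosis
m₄/m₂² — chosen because prioritisation cares about heavy single-sided tails
and the non-excess convention keeps reported kurtosis positive and
comparable across runs.

### Stage 4 — network fusion

Name conversion: `x__Name` features drop the rank prefix and any trailing
qualifier after the first clade token (`f__Myxococcales.0319.6G20` and
`s__Myxococcales.sp` both → `Myxococcales`); OTU ids resolve to the deepest
classified rank of a mothur-style lineage, ascending past `unclassified`
levels (`Otu00002` with genus unclassified → `Enterobacteriaceae`). Species
epithets without their genus are left as-is by default; a user-supplied
synonym map overrides individual conversions.

Enrichment results are consumed as a flat CSV (study id, disease, semicolon-
joined members) — the file a user exports from a taxon-set-enrichment web
tool — filtered by case-insensitive substring match on the disease field.
Node size = number of retained studies containing the microbe; edge weight =
number containing both endpoints; the adjacency matrix carries occurrences on
the diagonal and co-occurrences off it, so weight(u,v) ≤ min(size(u),
size(v)) for enrichment edges by construction. A cluster is valid iff ≥1
member's converted name is already a node; valid clusters add their missing
names as size-1 `origin="infused"` nodes and pairwise `origin="cluster"`
edges (weight 1, a presence marker distinct from co-occurrence counts;
existing enrichment edges keep their weight and gain a `cluster=True` flag,
standing in for the red edges of the usual rendering). Infusion is
idempotent. Node score = mean of member feature scores; nodes with no scored
members are flagged `unscored`. Graphs export to GraphML/GML and round-trip
losslessly.

## Synthetic study conditions

The generator emulates the three target pathologies with a zero-inflated
log-normal/Poisson model: per-feature latent Gaussians, correlated within
designated blocks via a shared factor (latent r = √ρ·z_block + √(1−ρ)·ε);
counts ~ Poisson(exp(μⱼ + s·latent)) with per-feature baselines
μⱼ ~ U(log 5, log 50) and dispersion s = 2 (abundances spanning orders of
magnitude, the usual heavy right skew); structural zeros at rate 0.7 — the
zero fraction typical of 16S OTU tables. Structural zeros are *shared within
a block* (one per-sample detection mask per block): the collinear blocks
stand for the same organism tallied at several taxonomic ranks, and an
undetected organism zeroes all its rank-level features at once; unblocked
features zero independently. The designated signal block receives per-class
latent shifts (−0.6, 0, +0.6 for three balanced classes — roughly a 10-fold
rate difference between extreme classes before zero-inflation, which the
coarse 7-term fuzzification then heavily attenuates: genuinely small
*observable* effects). Defaults: 200 samples × 60 features, 3 classes, three
blocks of 6 at ρ = 0.95. Everything is reproducible bit-for-bit from
(spec, seed), and ground truth (block membership, signal features, latents)
is returned for recovery tests.

What the generator does **not** model: compositional closure (no total-sum
constraint), phylogenetic signal beyond the block structure, sample-specific
library sizes, and overdispersion beyond the log-normal mixing. Passing
recovery tests therefore says the pipeline finds planted *correlation and
label structure under sparsity*; it says nothing about compositional
artefacts in real data.

## Defaults and numerical choices

| parameter | default | why |
|---|---|---|
| `num_labels` | 7 | granularity of the fuzzy discretisation; the conventional default of the rule-learning implementations this stage follows |
| `max_iter`, `step_size` | 10, 0.01 | hybrid-learning passes and premise learning rate; same convention |
| `minpts` | 2 | makes DBSCAN the eps-graph connected components — the minimal notion of "these columns travel together" |
| eps grid | 1 … max term index, step 0.5 | the published selection rule; overridable (`grid_start/stop/step`) |
| aliasing tol | 1e-7 | relative rank threshold matching double-precision GLM behaviour |
| `k_folds` | 10 | CV for λ at the minimum-CV-error rule (not 1-SE) |
| weight floor | 1e-6 | keeps 1/w finite for vanishing pilot coefficients |
| RF pre-filter | top 100, 500 trees | impurity importances; fitted on name-canonical column order so selection is permutation-invariant |

Tie-breaks are deterministic everywhere (lower term index at membership ties,
first maximum in argmax, stable sorts for importance ranking). Randomness
enters only through data generation, the random forest, and CV fold
assignment — all seeded through the pipeline config.

Problem sizes used by the test suite and the acceptance script (full runs at
200 × 60, oracle checks at n ≤ 60, 10-seed recovery studies) were chosen so a
complete verification pass stays comfortably within a coffee break on one
CPU; they match the generator defaults above rather than down-scaling them.

## Known limitations

- The eps selection rule restores design estimability; it does not guarantee
  that moderately-correlated blocks are gathered (see Stage 2 above). Users
  who want correlation-block clustering at tall rule matrices should pass an
  explicit `grid_start` above 1 or override the grid.
- The effective label is regressed as a continuous response even for
  multi-class outcomes; with many classes the term-index coding imposes an
  artificial ordering.
- Name conversion of species-rank mixed-level features without a genus
  prefix is inherently ambiguous; the synonym map is the escape hatch.
- The fuzzy discretisation is lossy by design: very large fold changes can
  vanish when one extreme sample stretches a column's range. That is the
  price of the sparsity-robust integer representation, and the correlation-
  preservation metric is the guardrail to watch.
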
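# Methods

This note documents the models, algorithms, defaults and design choices
behind `ecoweb`, and what the synthetic-data tests do and do not establish
about real data.

## Network representation

All networks are binary. Mutualistic webs are bipartite incidence matrices
(plants × animals); any positive interaction weight on disk is truncated to
presence, because the analysis targets binary architecture only. All-zero
rows and columns are dropped on read (with a warning) rather than erroring:
NODF's pairwise-overlap terms and the degree-based null model are undefined
for degree-0 species, and dropping matches common practice for incidence
matrices. Food webs are directed unipartite graphs (resource → consumer)
that may contain mutual (A↔B) edges; for NODF a food web is viewed as a
resource × consumer bipartite matrix in which a species with both prey and
predators appears as a row and as a column. Species with no trophic links
at all are dropped and logged — source compilations rarely state how such
records should be treated, and a zero-degree node is uninformative for
every metric used here.

## NODF

For a pair of rows (or columns) (u, v) with fill(u) > fill(v) the pair
contributes 100 · |ones(u) ∩ ones(v)| / fill(v); tied fills contribute 0
(the decreasing-fill rule). NODF is the mean over all row pairs plus all
column pairs, hence lies in [0, 100], is invariant under row/column
permutations, and equals the same value on the transpose. The
implementation uses the Gram matrix of the incidence matrix for overlaps;
tests verify it against a wholly independent double-loop oracle.

## Modularity and simulated annealing

Both modularity forms reduce to Q = Σ_m [e_m/L − s_m t_m / L²] over modules
m, with e_m the within-module links and (s_m, t_m) the module sums of
(plant degree, animal degree) in the bipartite (Barber) case or (out-degree,
in-degree) in the directed (Leicht–Newman) case. The directed in/out null
term is the standard directed generalization; the single-module partition
scores exactly 0 in both forms, so the maximized value is never negative.

`maximize_modularity` runs simulated annealing over partitions with three
move types — single-node reassignment (90% of proposals, occasionally to a
fresh module), merging two modules (5%), and splitting one module (5%) —
using O(degree) incremental score updates. Defaults: the starting
temperature is set adaptively so the bulk of early proposals accept
(median initial |ΔQ| / ln(1/0.8)); geometric cooling with factor 0.9 down
to 10⁻³ of the starting temperature; 4·n² proposals per level; 3 random
restarts with the best partition ever visited returned. This schedule was
chosen for throughput in the 500-replicate null ensembles, where annealing
runs once per replicate; its quality is enforced by a test requiring the
exhaustive Bell-enumeration optimum on 8-node networks in ≥ 95/100 seeded
runs (it currently attains 100/100). For the tiny fixtures used in
ensemble-calibration tests a lighter documented schedule (1 restart,
cooling 0.85) is adequate and is verified against the same oracle class.
All stochastic routines take an explicit seed; there is no hidden global
random state.

## Null models and Z-scores

Directed webs: edge switching in two separate pools. A proposed swap of
one-way edges A→B, C→D yields A→D, C→B and is applied only if it creates no
self-edge, no duplicate edge, and no incidental mutual pair (the new edge
must not land opposite an existing edge); mutual pairs swap analogously
with all four directed slots checked. This preserves each node's
(one-way-in, one-way-out, mutual) triple exactly — asserted in every test
run. The default target is 10 accepted swaps per edge with a budget of 100
attempts per targeted swap; networks with no legal swap (e.g. a directed
3-cycle) are returned unchanged.

Bipartite webs: each cell is drawn independently with
p_ij = min(1, k_i d_j / L) (probability proportional to the product of the
observed degrees). The classical averaged-fill variant
p_ij = (k_i/C + d_j/R)/2 is available via `variant="fill_average"`. Draws
are rejected until no row or column is empty (cap 1000, then error) so the
metrics stay defined. Two consequences are documented rather than hidden:
the min-capping makes expected degrees of highly connected species slightly
lower than observed, and the no-empty-row conditioning inflates the
realized degree of degree-1 species on small matrices. The unconditioned
draw (`require_filled=False`) is exposed for expectation checks.

Z = (X_real − X_null)/SD_null with mean and SD over (by default) 500 null
replicates; a zero-SD ensemble raises a degenerate-null error naming the
metric. For modularity each null replicate re-runs annealing with its own
child seed from one seed sequence; the same default schedule is reused
across replicates.

## Climate-change velocity

Velocity at a site = |current − LGM| at the site's grid cell divided by the
local slope of the *current* surface, where the slope is the magnitude of
the central-difference gradient over the four rook neighbors, with
east–west spacing scaled by cos(latitude) on a spherical Earth of radius
6371 km. Slope is computed in variable units per km; because every
covariate is standardized before regression, only the log-velocity's shape
matters, not its absolute scale. Zero-slope or edge cells yield a
flagged-undefined velocity (no invented floor value); downstream code drops
such sites with a logged count. Log transforms use ln(v + ε) with
ε = 10⁻⁶ × the smallest positive value, guarding genuine zeros while
leaving positive values essentially untouched. Rasters are plain-text ESRI
ASCII grids.

## Regression suite

The design standardizes the response and all predictors to mean 0, SD 1, so
estimates are comparable standardized coefficients. Species richness
(n_species) is a fixed term in every candidate model — richness must be
controlled for to see architecture beyond size — so its importance is 1 by
construction. AICc uses the Gaussian profile likelihood with
k = mean parameters + 1 (error variance): AICc = AIC + 2k(k+1)/(n−k−1).
All 2^8 subsets of the remaining predictors are fitted; Akaike weights
w_i ∝ exp(−Δ_i/2) give per-variable importances (sum of weights of models
containing the variable) and conditional model averaging over the smallest
top-ranked set with cumulative weight ≥ 0.95 (full-model averaging with
zero substitution is available behind a flag). Averaged standard errors use
the weighted unconditional-variance formula; averaged p-values use a normal
approximation. Significance is declared at p < 0.05.

The residual Moran's test uses I = (n/S₀)·e'We/e'e and the Cliff–Ord
normal-theory moments with M = I − X(X'X)⁻¹X' and A = M·W_sym·M:
E[I] = (n/S₀)tr(A)/(n−k), E[I²] = (n/S₀)²[tr(A)² + 2tr(A²)]/((n−k)(n−k+2)),
two-sided normal p. This is a moment-based approximation rather than the
exact ratio-of-quadratic-forms distribution; a 999-permutation p-value is
available as a cross-check, and the approximation's type-I error is tested
to sit in [0.03, 0.07] at α = 0.05. Spatial weights default to k = 6
nearest neighbors by great-circle distance, row-standardized — connectivity
rules are rarely reported in this literature, so the choice is prominent
and configurable.

SEVM: eigenvectors of the doubly centered symmetrized weights
(I − 11'/n) W (I − 11'/n), sorted by descending eigenvalue; only
positive-eigenvalue vectors (positive-autocorrelation patterns) are filter
candidates, the standard convention. Greedy forward selection adds the
candidate that most reduces the absolute standardized residual Moran
statistic of the full model, stopping when the Moran p-value exceeds α or
no candidate improves; the selected filter is then held fixed through the
SEVM subset enumeration and averaging. By construction the selected filter
never increases the full model's |standardized Moran|.

The least-squares internals are implemented directly with numpy/scipy
linear algebra for throughput (all-subsets enumeration inside simulation
studies requires ~10⁵ fits); the unit tests cross-check coefficients,
standard errors, p-values, R² and log-likelihood against statsmodels.

## Synthetic data: what it emulates and what it does not

Networks: a rank-decay generator (cell probability ∝ exp(−bias·(row rank +
column rank)), rescaled by bisection so expected fill equals the requested
connectance) gives analytic control of nestedness; at extreme bias a sparse
perfect staircase cannot give every specialist a link, so degree-0 species
are dropped exactly as the file readers do. A planted-partition generator
controls modular structure, and a directed generator controls connectance
and the mutual-edge fraction (pair probability 2c/(1+μ) with μ the mutual
share of connected pairs).

Site tables: coordinates uniform on a 40° × 40° window; each predictor is a
unit-variance mix (default half/half) of a Gaussian-process field with
exponential covariance (default range 1100 km, roughly a quarter of the
domain) and white noise; the response is Σβ·x plus an error split between
a spatial GP and white noise, with total error variance topping the
response variance up to ≈1 so that the generating betas are recovered
directly on the standardized scale. Default study conditions for the
recovery experiments: n = 100 sites, standardized effects 0.7 (richness)
and 0.3 (one climate variable), all other effects 0.

These generators reproduce the statistical structure the regression stage
assumes — linear effects, stationary isotropic spatial error — not the
taxonomic composition, sampling heterogeneity, or geographic clustering of
real compiled network datasets. Passing tests therefore demonstrate that
the machinery is correct and calibrated under its own assumptions, not that
those assumptions hold for any particular empirical compilation; coefficient
estimates from real data inherit all the usual caveats (missing links,
uneven sampling effort, non-stationary spatial processes).

## Numerical details and degenerate inputs

- Annealing recomputes the final score from scratch to wash out incremental
  floating-point drift; ties in module labels are normalized to
  first-appearance order.
- Modularity of networks with a single feasible partition, and metric
  computation on matrices with fewer than 2 rows and 2 columns, raise
  informative errors.
- The design table requires ≥ 10 more rows than predictors; zero-variance
  columns are named in the error.
- Problem sizes in tests (8-node exhaustive enumeration, 100-replicate
  simulation studies, 500-replicate null ensembles on ≤ 10-node fixtures)
  were chosen so that the full suite runs comfortably on one CPU while
  keeping Monte-Carlo error well inside the asserted bands.

## Known limitations

No weighted metrics or overlapping communities; no fixed-fill bipartite
swap null; no reprojection or multi-model LGM ensembles for velocity; no
phylogenetic correction; no SAR/CAR alternatives to SEVM. Mainland/island
subsetting reuses the identical pipeline on row subsets rather than a
separate code path.
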
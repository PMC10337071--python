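# Methods

This note records the models, numerical choices, and design decisions
behind phyllonet, and what the synthetic-data tests do and do not
demonstrate about real data.

## Synthetic community generator

The generator emulates the statistical structure the downstream analysis
assumes, at the scale of the study it mirrors: 27 samples per
species × compartment, 80 ASVs, reads rarefied to 12,412 per sample.

**Latent model.** Log-abundances follow a Gaussian latent-factor model.
Each of 4 modules (default sizes 24/10/6/5) has a per-sample factor
f ~ N(0,1); member i's latent value is uᵢ·√ρ·f + σ·ε with
ρ = `within_module_rho` (default 0.8), σ = `noise_sd` (default 0.3), and a
per-member loading jitter uᵢ ~ U(0.35, 1). The jitter makes strong loaders
intra-module hubs and weak loaders peripheral, giving the degree
heterogeneity (centralization above random, heavy-ish degree tail) that
real co-occurrence networks display; homogeneous blocks would produce
flatter-than-random degree distributions. The skewed module sizes serve
the same purpose at the whole-network level.

**Environmental coupling.** Three designated ASV pairs load on a shared
environmental factor exactly as module members load on module factors.
These are the planted "environmentally driven" links.

**Dispersal limitation.** Eight ASVs share a linear spatial gradient of
log-abundance with slope `distance_decay_rate` (default 3) in a random
direction over the unit square, plus low noise (0.25 σ). Pairwise
single-taxon Bray–Curtis between samples then grows with geographic
distance, which is what the per-node Mantel test detects. A radial
decay from a single focal point was considered and rejected: Bray–Curtis
under a focal gradient tracks |dₐ − d_b| (difference of distances to the
focal point), not the inter-sample distance, which caps the achievable
Mantel r near 0.4 — below the r ≥ 0.6 definition of strong dispersal
limitation the attribution uses. The dispersal class is deliberately
low-noise so that the planted ASVs meet that definition by construction;
even so, the Pearson-Mantel correlation of a one-dimensional gradient has
a geometric ceiling near 0.65, and for some random gradient directions a
draw's ceiling falls just below 0.6. Attribution tests therefore assert
precision of the labels rather than full recall of planted dispersal
links.

**Read-count layer.** Expected relative abundances are a softmax of
base + latent values; counts are drawn multinomially at twice the
rarefaction depth and subsampled without replacement (multivariate
hypergeometric) to exactly the depth, so every sample sums to 12,412.
Structured ASVs (modules, env pairs, dispersal) receive a small share of
the total read mass (log-base −2.0/−1.0 versus +0.5 for background taxa).
This keeps compositional closure from coupling unrelated taxa: when
structured taxa carry a large mass share, their coherent swings move the
rarefaction denominator and induce spurious cross-module correlations
(within-module edge fraction dropped from ~0.87 to ~0.48 in an early
design without this separation). Module members are consequently
high-prevalence (≥ 70% by construction at default settings), which is
also what keeps Spearman estimates stable at n = 27.

**Saponins.** Each of the 8 saponins (Rb1, Rb2, Rc, Rd, Re, Rg1, F1, R1)
is base·exp(β·Σ f_PRM + γ·env₁ + σ·ε) with β = `prm_effect_size`
(default 0.8) and γ = 0.2 — positive, strictly monotone in the planted
PRM factors, so total content (the row sum used downstream) carries the
signal the screening, PRM rule, and SEM must recover.

**What the generator does not emulate:** taxon-specific sequencing
biases, over-dispersion beyond multinomial sampling, chimeras or
read-level artifacts, phylogenetic signal in abundances, temporal
structure, and realistic environmental covariance (factors are
independent N(0,1)). Passing recovery tests therefore shows the pipeline
is correct and well-calibrated under its own assumptions — not that those
assumptions hold for any particular real community.

## RMT threshold selection

The FDR-masked (q ≤ 0.05) Spearman matrix is hard-thresholded over a grid
(0.30–0.99, step 0.01). At each cutoff, nodes retaining at least one
off-diagonal entry are kept, the matrix is eigendecomposed, degenerate
eigenvalues (spacing < 1e-8, artifacts of masking) are dropped, and the
spectrum is unfolded with a cubic least-squares spline fitted to the
empirical cumulative spectral function (10 coefficients; interior knots at
quantiles). Spacings are normalized to unit mean and their histogram is
chi-square-compared against Poisson exp(−s) and the Wigner surmise
(πs/2)·exp(−πs²/4) over bins on [0, 3] — 40 bins when spacings are
plentiful, shrunk to ≥ 8 (n/4) for short spectra so expected counts stay
O(1). The transition point is the smallest cutoff where the Poisson
statistic beats the GOE statistic *and* a chi-square test does not reject
Poisson (α = 0.05); thresholds with fewer than 10 spacings are unusable.

Two caveats are worth recording. First, the unfolding/fit protocol of the
original RMT-thresholding software is not published in detail; the spline
and binning defaults here are this package's own, stated and test-covered.
Second, the GOE→Poisson reference presumes the thresholded matrix
decomposes into *several* independent blocks. A matrix with exactly two
sampled blocks retains GOE-like level repulsion inside each block bulk,
and a two-fold GOE superposition is measurably non-Poisson; planted-block
test fixtures therefore use five blocks, which is also the regime real
modular networks occupy.

## Topology, ensembles, robustness

All metrics use the unsigned, unweighted simple graph (signs are stored as
edge attributes but do not enter topology). avgL averages shortest-path
lengths over connected pairs only; global efficiency counts unreachable
pairs as zero contribution — the two deliberately disagree on disconnected
graphs. Degree centralization is Freeman's Σ(k_max − kᵢ)/((N−1)(N−2));
N < 3 returns 0 with a warning. Natural connectivity is computed via
logsumexp of the adjacency eigenvalues for numerical stability; an
edgeless graph scores 0. Erdős–Rényi comparisons use G(n, m) with the
observed node and edge counts, 100 replicates, and the |obs − mean| >
1.96·SD significance rule. zᵢ uses the population SD of within-module
degrees (zᵢ = 0 when the module is degree-degenerate); Pᵢ = 1 − Σ
(κ_is/kᵢ)². Node roles: kinless hub (z > 2.5, P > 0.62), provincial hub
(z > 2.5, P ≤ 0.62), connector (z ≤ 2.5, P > 0.62), else peripheral;
kinless ∪ provincial are "hub nodes".

The degree-tail fit fixes x_min at the median degree (the analysis
convention; an x_min search à la Clauset would be the alternative) and
maximizes the discrete power-law likelihood with the Hurwitz zeta
normalization over α ∈ (1.01, 8). The KS distance is evaluated at the
integer support points against the fitted discrete CDF (left limits use
F(x−1)); the p-value uses the one-sample KS distribution without a
parametric bootstrap, which is conservative in the direction that matters
for declaring a tail power-law-consistent. Tails passing KS (P > 0.05)
are "weak" scale-free if they cover > 50 nodes, "weakest" otherwise.

## Link attribution (LTED)

The environment test is an operationalization (the procedure is cited
without formulas in the literature this follows): an edge is
environment-attributable if some factor correlates significantly with
both endpoints (BH q ≤ 0.05 over the full node × factor family) and the
endpoints' partial Spearman correlation controlling that factor falls
below the network threshold. Factors are tested one at a time (any-factor
rule) rather than jointly; the module boundary isolates this choice so it
can be swapped. Single-taxon Bray–Curtis reduces to |xₐ − x_b|/(xₐ + x_b)
with double zeros contributing 0. The Mantel test is one-sided (greater),
999 permutations by default, seeded and deterministic. Edges qualifying
for both tests are "env&disp"; the remainder are potential biotic
interactions. Labels are exhaustive and exclusive, so proportions sum
to 1.

## Modules, eigengenes, saponin PCA, ML

Fast-greedy (Clauset–Newman–Moore) modularity maximization on the
unweighted graph; modules are renumbered by decreasing size with ties
broken by smallest member id, making partitions deterministic. Eigengenes
are computed for modules with ≥ 5 members as PC1 of the z-scored member
relative-abundance submatrix, sign-oriented so the eigengene correlates
non-negatively with the members' mean standardized profile (the WGCNA
convention; the choice is arbitrary but must be fixed for screening signs
to be meaningful). Constant member profiles are dropped with a warning.

Saponin PCA is centered but *unscaled* (covariance PCA): contents are
absolute quantifications on one mg/g scale, so variance weighting is
informative rather than an artifact of units. Centering is standard PCA
practice and assumed. The collinearity filter greedily removes, from the
worst-offending pair (Spearman ρ² > 0.6), the variable with the larger
mean |ρ| to all others, until no pair exceeds the cut.

The ML check uses KNN regression (k = 7) and random forest (500 trees) —
the learners named by the analysis, with hyperparameters this package's
own documented defaults — under a shared five-fold split (plain random,
seeded) so the four feature sets are compared on identical folds. Scores
are MSE and Spearman ρ on pooled out-of-fold predictions. Growth year is
not a covariate anywhere in the pipeline.

## PRM rule, NST, SEM

The PRM rule reads "half of the members" inclusively: a module is a PRM
when n_sig_positive ≥ n_members/2, with member significance taken as BH
FDR < 0.05 (FDR rather than raw P, consistent with the rest of the
screening) across all members of all candidate modules.

NST here is a stochasticity ratio over Ruzicka (abundance-Jaccard)
dissimilarities. The null preserves each sample's richness, draws taxa
proportionally to occupancy frequency, and permutes the sample's observed
abundance values onto the drawn taxa (1000 randomizations by default).
Per sample pair, the ratio is E_C/C when the pair is more similar than the
null expectation and E_D/D when less similar; fully random assembly scores
1, strong selection approaches 0, and the pairwise mean is clamped to
[0, 1]. The published NST family spans several null models and
dissimilarities; this pinned combination is one defensible member of that
family, chosen for determinism and speed, and is swappable behind the
function interface. Note that "identical communities → NST ≈ 0" holds for
realistically uneven (e.g. lognormal) abundance profiles; for near-even
profiles the null cannot make permuted samples much more dissimilar than
observed, and the floor rises.

The SEM is observed-variable path analysis (the prior model has no latent
constructs): a recursive system η = Bη + Γξ + ζ with free exogenous
covariances and diagonal residuals, fitted by minimizing
F = ln|Σ(θ)| + tr(SΣ⁻¹) − ln|S| − p (BFGS from OLS starting values;
non-PD candidates rejected with a large penalty). χ² = (n−1)F_min with
df = p(p+1)/2 − free parameters; CFI against the diagonal independence
baseline; RMSEA = √(max(χ²−df,0)/(df(n−1))). Standard errors come from
the numerical Hessian of F, acov = (2/(n−1))H⁻¹. Inputs are z-scored by
default so estimates are standardized effects. Tests cross-check the
optimum against an independent optimizer (Nelder–Mead from remote starts)
to 1e-4.

## Enrichment and taxonomy

Order enrichment is the one-sided hypergeometric upper tail
P(X ≥ k) with population = network ASVs of known order, successes = the
order's members, draws = PRT — identical to one-sided Fisher's exact on
the 2×2 table (asserted in tests). BH correction runs across orders only;
orders with < 2 network members are reported but skipped as powerless.
The taxonomy tree is rank-layered (kingdom→genus, ASV tips), emitted as
newick; rank conflicts (one genus under two families) are hard errors.

## Pipeline, seeding, problem sizes

The pipeline simulates two compartments (LE/LP) over shared plants,
environment, and coordinates; saponins are driven by the planted PRM
factors of both. Stages communicate only through written files, so any
stage can be re-run from disk. Per-stage seeds derive from the master
seed by CRC32 of the stage name through numpy's SeedSequence; identical
config + seed reproduces byte-identical outputs (hashed in
`run_manifest.json`).

Default problem sizes are the study scale (27 samples); recovery-style
assertions that depend on correlation significance use 100–200 samples to
keep stochastic test outcomes stable, and the test suite's NST checks use
100–200 randomizations — both documented here as the package's chosen
test scales. A full default `run-all` takes well under a minute on one
core; the test suite a few minutes.

## Known limitations

- The RMT unfolding/binning protocol is a stated default, not a
  reimplementation of any specific prior software.
- LTED conditions on one factor at a time; jointly confounded links
  (explained only by a factor combination) are not attributed.
- NST is one pinned member of a family of estimators; absolute values are
  not comparable across null-model choices, only contrasts computed with
  the same settings.
- The SEM is limited to observed variables and recursive path structures;
  no latent constructs, grouping, or non-recursive loops.
- Compositionality is handled by design in the generator (mass-share
  separation), not by a compositional correlation method (SparCC-style
  inference is out of scope); on real data, strongly dominant taxa can
  still induce closure artifacts in Spearman networks.
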
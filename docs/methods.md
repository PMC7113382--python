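# Methods

`waveconn` implements a resting-state functional-connectivity analysis in
which per-subject ROI time series are decomposed into dyadic frequency bands,
band-limited correlation networks are binarized at a fixed connection
density, and network efficiency is compared across groups and used as a
mediator between group membership and cognitive outcomes. This note records
the model choices, defaults, numerical conventions and known limitations.

## Wavelet band decomposition

Time series are decomposed with the maximal-overlap discrete wavelet
transform (MODWT), the undecimated pyramid algorithm with circular boundary
treatment. Filters are the Daubechies least-asymmetric length-8 pair
("LA(8)"): the scaling coefficients are taken from PyWavelets' `sym4`
(identical, element for element, to the standard published LA(8) scaling
filter) and the wavelet filter is derived through the quadrature-mirror
relation h_l = (-1)^l g_{L-1-l}, both rescaled by 1/sqrt(2) as the MODWT
requires. This pins one orthonormal convention; perfect reconstruction and
the energy partition hold to ~1e-12 and are asserted in tests.

Level *j* covers the band (f_N / 2^j, f_N / 2^(j-1)] with f_N = 1/(2 TR).
Defaults: 6 levels, level of interest 4, TR = 0.72 s, giving the
0.043–0.087 Hz band conventionally analyzed in resting-state work. The
first L_j − 1 = (2^j − 1)(L − 1) coefficients of each level are affected by
the circular boundary; they are retained by default (`drop_boundary=False`)
because exclusion is not part of the reference protocol, but a flag removes
them for sensitivity analysis. Confound regression (ordinary least-squares
residualization against an intercept plus the confound columns) runs
*before* decomposition when a confound table is supplied.

## Connectivity graphs

Pearson correlations of the level-of-interest coefficient series form each
subject's R × R matrix. Binarization keeps a fixed *number of edges* —
`round_half_up(density · R(R−1)/2)`, e.g. 1,736 edges for 264 regions at 5% —
so the edge count is identical across subjects while the correlation
threshold attained varies per matrix. Ranking is by signed r by default
(strongest positive correlations; an `absolute` mode ranks |r|, since the
treatment of negative correlations is a genuinely open choice in this
design). Ties at the cutoff are broken lexicographically by (i, j), making
the edge set deterministic for any input.

## Efficiency

Global efficiency is the Latora–Marchiori average of inverse shortest-path
lengths over ordered node pairs, with 1/∞ ≡ 0 for disconnected pairs (no
largest-component restriction). Nodal efficiency is the inner average for a
single node; E equals the mean of nodal efficiencies. Subnetwork efficiency
E_s evaluates the same formula on one named network's node subset. Two path
conventions are implemented:

* **induced** (default): distances within the induced subgraph — information
  exchange strictly inside the subnetwork, not routed through the rest of
  the brain;
* **restricted**: whole-graph distances with member endpoints only.

Induced-mode E_s is never larger than restricted-mode E_s; both are checked
against a literal evaluation of the definition over an independently coded
Floyd–Warshall oracle. Shortest paths in the implementation come from
`scipy.sparse.csgraph` (unweighted BFS).

## Group inference

Efficiency variables (E and each E_s) are compared with the two-sided
independent-samples Student's t-test (pooled variance; Welch behind a flag),
cognitive scores with the Kruskal–Wallis rank test, and 2×2 demographic
tables with the Pearson chi-square (Yates continuity correction on by
default, the small-sample convention; with it, the male/female table
24/6 vs 16/11 gives χ² = 2.01, p = 0.156). Benjamini–Hochberg adjustment is
applied *within* each family — efficiency comparisons form one family,
cognitive comparisons another — matching how such results are usually
reported. Kruskal–Wallis is used as named even for two groups (where it is
equivalent to a Mann–Whitney test up to the chi-square reference).

## Path models and mediation

Models are recursive (acyclic) systems of linear structural equations among
observed variables with uncorrelated disturbances. For this class the
normal-theory likelihood factorizes equation by equation, so the
maximum-likelihood solution is closed-form: path coefficients are the OLS
regressions of each endogenous variable on its parents (computed from the
ddof-1 sample covariance S), residual variances are the conditional
variances, and the exogenous covariance block is free. The discrepancy
F_ML = ln|Σ(θ)| − ln|S| + tr(S Σ⁻¹) − p is evaluated analytically at that
optimum; χ² = (n−1) F_ML. Model df is p(p+1)/2 minus free parameters
(edges + endogenous residual variances + exogenous (co)variances). CFI is
computed against the independence baseline as
1 − max(χ²−df, 0)/max(χ²_b−df_b, χ²−df, 0); RMSEA is
sqrt(max(χ²−df, 0)/(df (n−1))), zero for saturated models. Standardized
coefficients use model-implied variances; per-path p-values are the OLS
t-tests of the corresponding equations. Because the fit is closed-form there
is no iterative optimization and no non-convergence failure mode.

Nuisance covariates (sex, age, other-substance use) are regressed out of the
dependent and mediating variables *before* fitting; the residuals enter the
model, and group membership enters as a 0/1 indicator.

Trimming is backward elimination only: repeatedly drop the single least
significant path with p > α (ties broken by edge order) and refit, until all
remaining paths are significant. Removing every path into a variable
re-classifies it as exogenous, which frees its covariances; df therefore
never decreases but need not rise by exactly one in that corner case.
Modification indexes for *adding* paths are out of scope.

Indirect effects are products of coefficients along a chain, with
nonparametric case-resampling bootstrap and percentile 95% CIs (percentile
rather than BCa by default; the variant is configurable in principle but
percentile is what the implementation ships). Replicates with degenerate
resampled covariance are dropped and counted; more than 5% failures aborts.
Results are bit-reproducible under (seed, n_boot); `n_boot=1` degenerates to
a zero-width interval by construction.

## Synthetic cohort generator

The generator emulates a two-group case-control study: IC
("inhalant-consuming", coded 1) versus HC (controls, coded 0), default
sample sizes (30, 27), 264 regions with named networks DMN/SN/FPN of sizes
58/18/25 (configurable — the true per-network counts of the reference atlas
partition are not pinned down here), T = 500 timepoints at TR = 0.72 s.

**Connectivity.** Signals are multivariate-normal draws from a block
covariance: `rho_within[group][network]` inside each named network,
`rho_between` elsewhere (defaults: HC 0.6 everywhere; IC 0.35 in DMN and
0.45 in SN/FPN, so the DMN is the most affected; background 0.1). The draws
are shaped in the frequency domain with a two-level zero-phase gain that
places 30% of total power in the level-4 band — about six times the
spectral density of the broadband remainder, so the periodogram peak lies in
the band — with the rest spread across the spectrum. Concentrating much more
power in a band spanning 1/16 of the spectrum would make the signal
unrealistically narrowband and inflate the sampling variability of
correlation estimates well beyond the 1/sqrt(T) white-noise scale. Because
every region passes through the same filter, the planted cross-regional
correlations are preserved exactly in expectation.

**Cognition.** Scores follow `score = c·group + b·eff + ε`, where `eff` is a
*latent* efficiency construct `a·group + ε_eff` (noise SD 0.97, so the
construct is approximately unit-variance with the default a = −0.5). Using
the planted construct rather than the downstream-measured efficiency keeps
the ground truth exact (indirect effect = a·b); full-pipeline mediation on
measured efficiency is still exercised but is expected to show attenuation.
All scores must share one `a` (one mediator construct); b and c vary per
score. Defaults give working memory and card sorting direct-only paths
(c = −0.53, −0.58), and the inhibition/planning scores mediated-only paths
(b = 0.4, c = 0).

**Demographics.** Sex (IC 80% / HC 59% male), age ~ N(15, 1.35) clipped to
12–17, and an "other substance use, months" covariate drawn from a gamma
distribution *independently of group*. That independence is deliberate: these
are nuisance-only variables with no planted effect, and if the covariate
tracked group membership, residualizing the mediator and outcomes on it
would absorb the planted group effect and make mediation recovery impossible
by construction — a property of the estimand, not a bug of the estimator.

**What the generator does not emulate.** No volumetric data, head motion,
physiological noise spectra, 1/f structure, or spatial autocorrelation;
region "coordinates" are a synthetic grid. Passing tests therefore show the
*pipeline* recovers what was planted under clean band-limited Gaussian
conditions, not that real acquisitions are free of confounds.

**An emergent caveat worth knowing.** Fixed-density thresholding couples the
networks: every subject has the same edge budget, so edges that a weakened
IC DMN loses are reallocated to the rest of that subject's graph. In
strongly segregated default cohorts this *raises* consumers' whole-graph
efficiency (their extra between-block edges reconnect otherwise isolated
regions) and can mask or even invert deficits in the other named networks.
The planted DMN deficit itself is recovered with very large effect sizes.
This is a real property of fixed-edge-count binarization, not a simulation
artifact, and it is why the generator does not attempt to reproduce the
reference study's *global*-efficiency ordering.

## Problem sizes and runtime choices

Validation suites run at deliberately chosen scales: transform identities on
50 random signals of T = 512; efficiency oracles on 100 random graphs with
n ≤ 30; mediation recovery at n = 2000 over 20 seeds and bootstrap coverage
over 300 replicates at n = 200 with 1,000 resamples; end-to-end type-I/power
runs on 50 cohorts of 30 + 30 subjects with 60 regions and T = 500 (region
count reduced from 264 to keep repeated-cohort simulation cheap; the planted
effect and test statistics do not depend on the OTHER-region padding). The
acceptance script runs the full default study (57 subjects × 264 regions ×
T = 500) once.

## Known limitations

* Path models cover observed variables only: no latent factors, mean
  structure, missing-data FIML, or multi-group constraints.
* The decimated DWT, wavelet coherence, and weighted-graph metrics are out
  of scope; efficiency is the only graph statistic.
* BH-FDR assumes the usual positive-dependence conditions; efficiency
  measures from one graph per subject are correlated across networks.
* Bootstrap CIs are percentile; BCa would shift coverage slightly for
  skewed indirect-effect distributions.
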
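# Methods

`netcog` implements an analysis chain that links individual differences
in structural brain connectivity to a latent general cognitive factor
(g) across several cohorts. This note records the models, the defaults
and the numerical choices, and what the synthetic data do and do not
establish.

## Data model

Networks are 85×85 symmetric nonnegative matrices over a fixed
parcellation: 68 Desikan-Killiany cortical regions, 16 subcortical
structures and the brainstem, in a frozen order (34 left cortical, 34
right cortical, 8+8 subcortical, brainstem last). Three weightings are
analysed in parallel: streamline count (SC, tractography connection
count), fractional anisotropy (FA ∈ [0,1], fibre coherence) and mean
diffusivity (MD, 10⁻³ mm²/s, higher = less intact tissue). A fourth,
streamline density (SD = SC_ij / (vol_i + vol_j)), corrects SC for
endpoint grey matter volume; summing the two endpoint volumes is the
common convention and is the one implemented. FA/MD values are sampled
along streamlines, so any edge with zero streamlines carries zero FA/MD
by construction — the loaders enforce this coupling. All indices are
0-based; edge vectors use the canonical (i asc, j asc) order of the
3570 unordered pairs.

## Reference-network construction

Cohorts scanned on different hardware differ in network density, which
confounds density-sensitive graph metrics. The remedy is two-step:

1. **Consistency thresholding** per cohort: rank edges by the
   coefficient of variation (CV = sd/mean) of SC weight across
   participants and keep the K = round(density · 3570) lowest-CV edges
   (at the default density 0.30, K = 1071 exactly). CV includes
   participants with zero weight; excluding them would make rarely
   reconstructed edges look spuriously consistent (a zeros-excluded
   variant exists for sensitivity analyses). Ties break by higher mean
   weight, then lexicographic (i, j), making the mask deterministic.
2. **Intersection** of the per-cohort masks; only edges retained in
   every cohort survive. The single intersected mask is applied to SC,
   FA and MD alike.

Consistency is computed on SC only — the convention of the consistency-
thresholding literature — and the mask provenance records input sizes
and pairwise overlap counts.

## Graph metrics

Per participant and weighting, on the masked network:

- **Mean edge weight**: mean over the mask's edge set, zeros included
  (an absent connection is evidence, not missing data).
- **Global efficiency**: E = (1/(n(n−1))) Σ_{i≠j} 1/d_ij with lengths
  l = 1/w and Dijkstra shortest paths; unreachable pairs contribute 0.
- **Mean clustering** (Onnela): C_i = Σ_{j,h}(ŵ_ij ŵ_ih ŵ_jh)^{1/3} /
  (k_i(k_i−1)) on max-normalized weights ŵ = W/max(W), k_i the binary
  degree; C_i = 0 for k_i < 2.
- **Local efficiency** (nodal): E_loc,i = Σ_{j≠h∈N(i)}
  (ŵ_ij ŵ_ih / d_jh(N_i))^{1/3} / (k_i(k_i−1)), where d_jh(N_i) is the
  shortest path between neighbours j,h using only paths inside N(i),
  again on max-normalized weights. Several descendants of the weighted
  local-efficiency formula coexist in the literature; this variant is
  the one oracle-tested here (Floyd–Warshall + exhaustive triples on
  small graphs, agreement to 1e-10).

The weight-to-length map is l = 1/w for every weighting, **including
MD**: MD networks are analysed on raw weights, and their metrics then
correlate negatively with g, as expected for a marker of less intact
tissue. Max-normalization makes clustering and local efficiency
invariant to uniform rescaling; global efficiency uses raw weights.

## Latent g

One-factor CFA: x_j = μ_j + λ_j g + ε_j, Var(g) = 1 (all loadings
free), diagonal Θ plus optional free residual covariances between named
test pairs (method variance within cognitive domains). Estimation is
casewise FIML over missingness patterns (no case dropped), L-BFGS-B on
the free parameters, convergence by relative loglik change < 1e-12 /
gradient tolerance 1e-7, max 500 iterations; first loading constrained
positive by sign convention. The saturated model is estimated by EM for
the unstructured multivariate normal under missingness; the
independence baseline has a closed-form FIML solution (the likelihood
factorizes per variable). CFI/TLI/RMSEA follow the likelihood-ratio
statistic T = 2(ll_sat − ll_model); SRMR is computed on listwise-
complete sample correlations against the implied correlations (a
documented approximation when data are missing). Factor scores are
regression-method scores over each participant's observed pattern,
standardized over the sample; participants with no observed tests get a
missing score.

## Associations

The primary estimator is a one-step MIMIC-style SEM: the measurement
model above plus a structural regression of g on the standardized
metric, standardized age, sex (0/1) and site dummies (first site
reference; dropped for single-site cohorts). The latent residual
variance is fixed to 1; reported coefficients are fully standardized
(β = γ·sd(x)/sd(g) with sd(g)² = γᵀS_xγ + 1), with SEs from the
numerically differentiated observed information. Wald 95% CIs and
two-sided normal p-values.

A two-stage estimator (factor scores, then OLS with the same design) is
the fast path for the large metric batches (85 nodes × 3 weightings,
hundreds of edges). Naive factor-score regression attenuates every
coefficient by the score reliability, so the two-stage estimates are
disattenuated Croon-style by √(mean_o λ_oᵀΣ_o⁻¹λ_o); after the
correction the two estimators agree to well within ±0.02 on synthetic
data at n ≥ 2000. Age-moderation models add an age_z × metric_z term
and report it per SD of age; cohorts with age SD < 2 years cannot
support an interaction and are flagged skipped rather than fitted.

## Meta-analysis and FDR

Cohort βs are pooled under β_i ~ N(μ, v_i + τ²) with τ² by iterative
REML (Fisher scoring on the restricted likelihood, floor at 0, tol
1e-10, max 100 iterations); on non-convergence the DerSimonian–Laird
moment estimator is used and flagged in the output — with k = 3 studies
REML is fragile and a silent fallback would be misleading. Identical
inputs return τ² = 0 exactly. Pooled weights 1/(v_i+τ²) make β_meta a
convex combination of the inputs. BH-FDR (statsmodels step-up,
q-values as cumulative-minimum adjusted p) is applied within each
family, one family per weighting × scale (e.g. the 85 SC nodes);
joint-versus-separate family boundaries are configurable, separate is
the default.

## Prediction and reporting

Composite scores are Σ_k β_k z(edge_k) over the masked edges with meta-
analytic βs as weights. Edges are standardized within the evaluated
sample by default; a train-moments mode gives strict out-of-sample
semantics. The largest cohort is split in half: the first half enters
association and meta-analysis, the second is touched only at scoring
time, and the train-vs-hold-out correlation gap measures replicability.
Edge classification is exhaustive and exclusive (brainstem-involved /
intra-left / intra-right / inter-hemispheric; intra- vs inter-lobe with
a sorted lobe-pair label); percentages are reported to one decimal,
round-half-even. Cross-cohort agreement and hemispheric symmetry are
Pearson correlations over aligned coefficient vectors (the 42 bilateral
homologue pairs for symmetry; the brainstem is excluded as unpaired).
External regional maps (e.g. cortical morphometry effect maps) are
matched by region name over the 68 cortical nodes.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
at desk scale: three cohorts — large/wide-age/4-site (n = 2000),
small/wide-age/2-site (n = 500), small/narrow-age/1-site (n = 400) —
with density targets 0.35/0.32/0.30 and distinct weight scales
(scanner effects as per-site log-weight shifts, SD 0.05). A shared
group-level template with distance-dependent scores determines edge-
presence probabilities (calibrated by bisection to the cohort density
target) and log-normal base weights; per-participant SC is Bernoulli
presence × jittered log-normal weight (edge jitter SD 0.40), rounded to
integer counts. The g coupling enters as a global log-weight multiplier
with SD 0.15 carrying β_global·g (default 0.20) plus an optional
age_z·g moderation term, and 60 short-range edges carry edge-specific
effects (β ∈ [0.05, 0.20]). FA/MD get per-edge bases, g couplings of
0.13/−0.08 (scaled into between-subject shifts of SD 0.020/0.030),
age slopes −0.015/+0.030 per SD age, and clipping to [0.2, 0.7] /
[0.6, 1.2]·10⁻³. Test scores are λ_j g + ε with loadings
(0.28, 0.45, 0.55, 0.65, 0.73), one true residual covariance (0.10
between the first two tests), 10% MCAR missingness; g correlates −0.20
with age. TBV is constructed to correlate 0.80 with total SC (CV 8%),
and node volumes scale with TBV.

What passing tests show: the pipeline recovers known effects, controls
error rates, and is deterministic. What they do not show: realism of
tractography noise, anatomical geometry beyond a mirrored random
template, non-MCAR missingness, or the effect sizes of any real cohort
— cohort-level coefficients from restricted-access imaging data are
not reproducible at desk scale and are not claimed.

## Numerical and engineering choices

- All randomness flows from one root seed; each cohort uses
  `default_rng([seed, 1000 + cohort_index])`, so runs are bit-identical
  under a fixed seed and cohorts are independent streams.
- Matrices are symmetrized from the upper triangle after an asymmetry
  check at 1e-9 absolute; dense text I/O uses %.17g for exact
  round-trips; pipeline CSVs use 10 significant digits.
- The default pipeline runs the generator at 0.25 of the study-size
  defaults (500/125/100) so the full chain, run twice for the
  determinism check, completes in minutes; precision-sensitive recovery
  checks use the full sizes (n = 2000 for association recovery, 5000
  for CFA and moderation recovery, 8000 per half for hold-out
  stability).
- Degenerate inputs: zero-variance metrics and non-converged fits
  become flagged rows, never batch failures; zero-variance edge columns
  are dropped from composites with a warning; empty masks and all-zero
  matrices are defined cases (efficiency 0, clustering 0), not errors.
- `netcog simulate` writes cohort-wide edge tables (participant × 3570
  canonical edge columns) rather than thousands of per-participant
  matrix files; dense per-participant matrices remain first-class for
  I/O and the `metrics` subcommand.

## Known limitations

- The SEM standard errors treat sd(g) as fixed when standardizing (a
  delta-method shortcut); coverage is nominal in the simulations but
  not proven in general.
- SRMR under missingness uses listwise-complete moments and is
  undefined when no complete cases exist.
- REML with three studies has low information about τ²; CIs on τ² are
  not reported.
- The edge-specific generator effects are calibrated loosely (recovery
  of the global effect is the precise target); only ordering/signal
  presence, not exact edge β values, should be expected to reproduce.
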
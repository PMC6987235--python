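# Methods

This note documents the models and procedures implemented in
`treesilience`, the assumptions behind them, the defaults and why they
were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that make results reproducible to
the bit.

## Study design

The analysis targets matched-pairs case–control tree-ring data: at each
site, trees that later died during drought ("now-dead", last ring =
death year) were sampled together with surviving conspecifics.  Because
both groups experienced the same site-level drought history, within-site
contrasts of their growth resilience to an earlier, non-lethal drought
isolate tree-level differences in drought response from site and climate
effects.

## Chronology standardisation

Each tree's ring-width series is divided by a cubic smoothing spline
whose frequency response is 0.50 at a wavelength of 67% of the series
length.  The spline is the penalised least-squares smoother
`min Σ(y−s)² + λ∫s″²` (scipy's `make_smoothing_spline`); the stiffness
follows the Cook–Peters relation

    λ = ((1−f)/f) · (2 + cos w) / (12 (1 − cos w)²),   w = 2π/wavelength,

which is the spectral form of the natural-spline penalty on unit-spaced
data and reduces to the familiar `1/w⁴` low-pass rule for long
wavelengths.  The relation is verified numerically: a sine at the cutoff
wavelength is attenuated to 0.499 of its amplitude in the series
interior (boundary columns of any symmetric smoother attenuate less, so
the response is measured over the middle third).

Ratio indices are prewhitened with an autoregressive model whose order
is chosen by AIC among 0…min(10, N/4), fitted by conditional maximum
likelihood with an intercept; candidate orders are compared on a common
estimation sample.  Residuals are re-centred on the series mean, scaled
to mean exactly one, and averaged across trees per year with Tukey's
biweight robust mean (tuning constant c = 9 on the MAD scale, iterated
to |Δ| < 1e−10, at most 50 iterations, median fallback when MAD = 0 —
the standard dendrochronological convention).  Both now-dead and
surviving trees enter the chronology; series shorter than 15 years are
skipped with a warning.  The whole pipeline is scale-invariant:
multiplying a tree's widths by a constant leaves the chronology
unchanged to 1e−10.

## SPEI

The monthly climatic water balance D = precipitation − PET (mm) is
summed over k ∈ 1…24 months ending in a target month; sums rather than
means are used (standardisation makes the two equivalent; the choice is
stated for bit-reproducibility).  A three-parameter log-logistic
distribution is fitted to the calibration values (default: the full
record, mirroring global SPEI products) by unbiased probability-weighted
moments; values are mapped through the fitted CDF and the standard
normal quantile.  When the moment estimates do not define a valid
distribution over the data (shape ≤ 1, or an observation at or below
the location bound — which happens for strongly left-skewed aggregates),
the implementation falls back to empirical-quantile standardisation
(Weibull plotting positions) with a warning; both maps are strictly
increasing, so orderings agree.  CDF values are clipped to
[1e−8, 1−1e−8] before the normal quantile.

Target months are June–October in the Northern Hemisphere.  In the
Southern Hemisphere the five target months are the exact half-year
mirror, December (of the calendar year preceding the labelled
ring-growth year) through April; windows crossing the calendar year are
assigned to the growth year containing the later months.  Each site's
grid therefore has 5 × 24 = 120 entries.  The aridity covariate is the
ratio of mean annual precipitation to mean annual PET over 1970–2000.

## Window selection and event detection

The residual chronology is regressed on each of the 120 SPEI windows
over a fixed common period (default 1931–1980; candidates with fewer
than 20 overlapping years are dropped with a warning).  Fits are
ordinary least squares (Gaussian errors, identity link); the Gaussian
maximum-likelihood AIC `n·log(2πRSS/n) + n + 2k` with k = 3 selects the
window, ties broken toward smaller scale, then earlier target month.
Selection is invariant to affine rescaling of the chronology.

Event eligibility: now-dead trees that died more than 50 years before
the site's last death are excluded; the search window spans 10–40 years
before the first retained death.  A year qualifies if (1) its SPEI at
the selected window is below the site's 10th percentile (computed over
the full record, linear interpolation between order statistics) and
(2) the site-mean TRW — all trees, both statuses — drops by more than 5%
relative to the preceding 4-year mean, in the same year or the year
after.  Among qualifying years the minimum-SPEI (most extreme) year is
the event; sites with no qualifying year carry no event and are excluded
downstream with a logged reason.  The tie-break and the full-record
percentile are package conventions where the procedure leaves the choice
open.

## Resilience indices and covariates

For event year i and window m (default 4, valid 1–8):
resistance = Dr/PreDr, recovery = PostDr/Dr, resilience = PostDr/PreDr,
with PreDr/PostDr arithmetic means of raw growth over the m years
strictly before/after the event (the event year is excluded — the
standard convention) and Dr the event-year growth.  The multiplicative
identity resilience = resistance × recovery holds to 1e−12 by
construction and is asserted over random records.  Trees lacking m full
years on either side (typically now-dead trees dying shortly after the
event) are skipped rather than scored on shortened windows, keeping the
index definition identical across trees; the skip reasons are logged.

BAI (mm²) is reconstructed outside-in: the radius after the last ring is
DBH/2 (bark ignored; DBH at sampling is the only anchor), earlier radii
subtract ring widths, and BAI(t) = π(r_t² − r_{t−1}²).  Locally absent
rings are bridged linearly for the radius accumulation only and excluded
from ratio indices.  DBH in the event year subtracts twice the later
ring widths.  Δtime = last recorded year − event year for every tree, so
surviving trees use the sampling year.

The drought-intensity covariates are SPEI_i and the window-matched
differences SPEIdiff_resist = SPEI_i − PreSPEI, SPEIdiff_recov =
PostSPEI − SPEI_i, SPEIdiff_resil = PostSPEI − PreSPEI (the last is the
sum of the first two, exactly).

Growth trajectories average log(TRW(t)/PreDr) per (group, status)
stratum over relative years −m…+half-window; 95% envelopes come from
resampling trees with replacement (default 1000 draws, percentile 2.5
and 97.5); strata with fewer than 5 trees are skipped.

## The status-contrast mixed model

Responses are log-transformed indices (log makes the multiplicative
lognormal indices approximately Gaussian).  Fixed effects: status
(reference now-dead — the intercept is the now-dead mean), taxonomic
group (reference angiosperm), DBH_i, SPEI_i, Δtime, aridity, soil PC1,
and all status interactions.  Because SPEI_i is nearly collinear with
SPEIdiff_resist and SPEIdiff_recov, only the resilience model carries a
SPEIdiff term (SPEIdiff_resil); the resistance and recovery models use
SPEI_i alone.  Random intercepts are nested site ⊂ species ⊂ genus,
implemented as a genus-level random intercept plus species and site
variance components within genus; a nesting level is included only when
it has more levels than its parent (otherwise its variance is
unidentifiable).  Singular fits are reported with a warning, never
silently simplified; genuine non-convergence raises.

Continuous predictors are standardised (centred, unit variance) so the
reported coefficients are standardised effects; the response is only
log-transformed and the intercept stays on the response scale.
Coefficient tests are Wald tests with the normal approximation (the
exact denominator-degrees-of-freedom method is an open choice in this
class of models; the normal approximation is accurate at the sample
sizes involved and is what the z-based confidence intervals imply).
Model-comparison AICs are computed from maximum-likelihood refits
(REML likelihoods are not comparable across fixed structures), counting
fixed effects, covariance parameters and the residual variance.  ΔAIC
for status refits the model without status and all its interactions.

Backward reduction repeatedly considers the least significant droppable
term — interactions first; a main effect is droppable only when none of
its interactions remain — and removes it if that lowers the ML AIC,
stopping otherwise.  R²m/R²c follow the Nakagawa–Schielzeth variance
decomposition: R²m = var(Xβ̂)/(var(Xβ̂) + Σσ²_random + σ²_resid), R²c adds
the random variances to the numerator.  Adjusted means fix continuous
covariates at their means, average the non-focal factor over its levels,
and back-transform by exponentiation with delta-method intervals; panels
are split by group only when a status × group interaction is in the
model.  `random=None` fits the same design by OLS (all random variances
zero), which is also the oracle used to test the mixed-model path.

Soil fertility is the first principal component of the standardised
ten-variable soil table (organic carbon, total nitrogen, C/N, bulk
density, available water capacity, depth to bedrock, pH, clay, silt,
sand); constant columns are dropped with a warning and the sign is
oriented so the nitrogen loading is positive (higher score = more
fertile).

## Synthetic data: what it emulates, what it does not

The generator writes complete study bundles with known ground truth:

* **Climate.**  Sinusoidal monthly climatologies (PET 15–105 mm/month
  peaking in midsummer, precipitation wetter in winter) with mean-one
  lognormal interannual noise (default sd 0.25 for precipitation, a
  third of that for PET).  In the planted event year, precipitation in
  the site's true (month, scale) window is removed (and PET raised if
  precipitation is exhausted) until that year's accumulated balance
  undercuts every other year by one standard deviation — guaranteeing
  the most extreme SPEI of the record at the true window.
* **Growth.**  log TRW = log(a·e^(−b·age) + c) + β·SPEI(true window) +
  AR(1) noise, with a modified negative-exponential size trend
  (a = 1.5 mm, b = 0.03/yr, c = 1.0 mm — a classic standardisation
  target, removable by the spline), β = 0.12 per SPEI unit, lag-1
  autocorrelation 0.3 and stationary sd 0.15 on the log scale.  The
  multiplicative lognormal form guarantees TRW > 0 and makes the
  log-indices Gaussian by construction.  Effect sizes are chosen for
  recoverability — real databases do not publish these generating
  values — and the planted event-year SPEI (≈ −2.5 to −4) with β = 0.12
  produces site-mean growth drops of ~25–40%, comfortably beyond the 5%
  detection rule.
* **Status deficits.**  Now-dead trees have event-year growth multiplied
  by a resistance deficit and post-event-window growth by resistance ×
  recovery deficit, so the planted dead/surviving ratios of the indices
  equal the two deficits.  Defaults encode the two taxon strategies:
  angiosperms resist 0.7 / recover 1.0, gymnosperms resist 0.9 /
  recover 0.7.  Death years are uniform in [event+10, event+40]
  (capped one year before span end), so the 10–40-year event-window rule
  is satisfiable by construction; surviving trees run to the span end.
* **Structure.**  Sites carry one species each, drawn from six genera of
  the two groups; soil tables have a latent fertility factor loading
  positively on nitrogen, organic carbon and available water capacity;
  texture sums to 100%.
* **Determinism.**  One seed; one spawned RNG stream per stage; byte-
  identical bundles for identical configurations.

Not emulated: spatial stand structure, competition, biotic mortality
agents, missing rings, cross-dating error, multi-species sites, and any
realistic covariance between climate, soil and taxon.  Passing recovery
tests therefore demonstrates that the estimators recover what the
generating model planted — not that real data satisfy the generating
model.

## Validation problem sizes

The self-validation experiments (`treesilience.evaluation`, also run by
`scripts/acceptance.py`) use: 50 sites × 20 trees for event detection;
100 replicates of a 50-year chronology for window recovery (planted
slope 0.3 at window (Aug, 6), noise variance 0.05); N = 500 for the
spline response; 3 sites × 120 grid entries for SPEI calibration;
10,000 random records for the index identity; 50 replicates of
100 sites × 30 trees for mixed-model bias/coverage/ΔAIC (planted status
effect −0.10 on log-resilience); 200 null replicates of 20 sites ×
10 trees for type-I control.  These sizes give Monte-Carlo error well
inside the tolerances tested while keeping a full run to a few minutes
on one CPU.

## Known limitations

* PET is an input; no Penman–Monteith/Thornthwaite computation.
* No cross-dating or COFECHA-style quality control; years are taken as
  correctly dated.
* The last ring of a dying tree is treated as a complete ring.
* Wald/normal inference for the mixed models; no Satterthwaite or
  Kenward–Roger degrees of freedom.
* Exact reproduction of published coefficient tables from the original
  pancontinental database is out of scope: those data are not bundled.
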
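# Methods

This note documents the models, estimators and conventions implemented in
`recplast`, the defaults chosen where the underlying experimental design
leaves choices open, and the known limitations — in particular what the
simulation-based tests do and do not establish about real data.

## The experimental design being analysed

The pipeline targets a classic backcross time-course design for measuring
recombination-rate plasticity. F1 females heterozygous across one assayed
chromosome are backcrossed to the homozygous recurrent strain, so each
progeny inherits one maternal meiotic product whose genotype at each marker
(heterozygous vs homozygous-recurrent) directly records its crossover
history. Females sit in replicate source vials (true replicates); females
within a vial are pseudo-replicates. Progeny are collected in consecutive
48 h broods: because oogenesis is a multi-day pipeline, the brood index
proxies the developmental stage at which the transmitted oocyte experienced
the treatment, which is what lets a time course discriminate early-meiotic
from late/post-meiotic mechanisms of plasticity.

## Crossover calling

A crossover is called between each pair of consecutive *informative*
(non-missing) markers whose states differ. Missing markers are skipped, so
a call may span several physical intervals ("wide" events); per-interval
recombinant status uses classical two-point scoring — an interval counts a
progeny only when both its flanking markers are informative, and scores it
recombinant when they differ. Counting state switches along the informative
subsequence makes the caller exactly equivalent to a brute-force
adjacent-difference oracle, which the tests enforce.

Because crossover interference in this system is strong out to tens of cM,
an apparent double crossover isolating a single marker
(…HET, HOM, HET…) is overwhelmingly more likely to be a genotyping error
than two real crossovers within one marker spacing. The tight-double filter
flags such patterns and by default sets the isolated marker missing and
re-calls (configurable to "keep"; an optional `min_cM_gap` restricts
flagging to doubles whose combined genetic span is below a threshold).
Simulation with 1% genotyping error under strong interference shows the
mask-and-recall policy recovers true interval rates with smaller absolute
bias than keeping the calls. Progeny with fewer than 50% informative
markers are excluded from counting by default (configurable, logged).

## Rates, smoothing, aggregation

Rates are recombinant fractions per adjacent-marker interval:
r = k/n, cM = 100·r, cM/Mb = 100·r / L where L is the physical interval
length in Mb (positions are 1-based bp; intervals half-open; Mb = bp/1e6
exactly). No Haldane/Kosambi map-function correction is applied by
default: at ~1.2 Mb spacing and ~4 cM/Mb the intervals are a few cM, and in
a strongly interfering organism double crossovers within an interval are
essentially absent, so the fraction *is* the map distance. (Without
interference the fraction under-measures the map by the Haldane factor —
about 4.5% at 4.7 cM — which is visible in the ν=1 simulations; a Haldane
correction is available via `map_function="haldane"`.)

The display smoother is a three-point neighbour LOESS: at each interval
midpoint, a weighted degree-1 fit over that position and its two flanking
positions (endpoints use their two available neighbours), pooling the
replicate females' point estimates. Weights are tricube in distance with
half-width 1.5× the maximum in-window distance — the factor keeps the
farthest neighbour's weight positive under equal marker spacing, where a
half-width equal to the window radius would zero it out and degenerate the
fit. The grey band reported with the smoother is the between-female
variability at each position (SD across female estimates / √n females),
i.e. a replicate-variability band, not a LOESS residual error. Local linear
fits reproduce constants and straight lines exactly and never leave the
range of their window; both properties are tested.

Brood aggregation into periods (e.g. early = days 1–4, late = days 5–10)
pools recombinant and total *counts* within period before recomputing r and
cM/Mb — equivalent to recounting the concatenated progeny, never an average
of ratios.

## Crossover control: interference and assurance

The coefficient of coincidence for an ordered interval pair (i, j) is
c = observed joint recombinants / expected under independence, with the
expectation n_ij·r_i·r_j taken from the pooled estimated genetic map (the
ratio is internal to the observed data; using an external map would bias c
by any calibration offset). Pairs are binned by midpoint-to-midpoint
genetic distance, 5 cM bins to 30 cM by default, and each bin reports
Σobs/Σexp with I = 1 − c. Bins whose expected joint count falls below 5 are
flagged low-confidence. Because only single transmitted chromatids are
observed (not tetrads), c conflates chiasma and chromatid interference;
that is what backcross progeny data permit.

Assurance — adherence to the obligate-crossover rule — is the proportion of
progeny chromatids carrying ≥1 detected crossover on the assayed
chromosome. Two-chiasma meioses with independent 2-of-4 chromatid
assignment give the analytic benchmark 1 − (1/2)² = 0.75. Treatments are
compared with a two-sided two-proportion chi-square test with continuity
correction, switching to Fisher's exact test when any expected cell is
below 5; all-same-outcome comparisons return p = 1 flagged degenerate.

## The plasticity mixed model

The response is cM/Mb at the female × interval × brood level. Fixed effects
are the full categorical factorial position × temperature × day; a random
intercept per replicate vial absorbs pseudo-replication:

    y_gi = x_gi'β + u_g + e_gi,  u_g ~ N(0, σ_rep²),  e_gi ~ N(0, σ²).

Fitting is by REML. With a single random intercept each replicate block has
covariance σ²(I + λJ), λ = σ_rep²/σ², so block inverses and determinants
are closed-form; β and σ² are profiled out and the REML criterion is
optimised over λ ≥ 0 alone (bounded 1-D search on log λ, with the λ = 0
boundary checked explicitly). All likelihood evaluations use per-replicate
sufficient statistics, so refitting is fast even with ~230 fixed-effect
columns. The implementation was cross-checked against an independent
general-purpose mixed-model fitter on shared data (variance components,
fixed effects, ANOVA and contrasts agree to at least 6 digits); the
degenerate λ = 0 limit reproduces OLS and classical fixed-effects ANOVA to
1e-6, which the tests enforce.

Inference:

* **LRT.** The model is compared against an intercept + random-intercept
  null by 2(ℓ_full − ℓ_null) on *ML* log-likelihoods (ML, not REML, because
  the models differ in fixed effects), referred to chi-square with df =
  difference in fixed-effect count.
* **Type-III ANOVA.** Factors use sum-to-zero coding, so testing a term's
  coefficients against zero is the Type-III hypothesis. Each term's F is
  the Wald quadratic form / q; the denominator df is Satterthwaite:
  for a one-df contrast l, df = 2g²/(∇g'A∇g) with g(θ) = l'C(θ)l, C(θ) the
  fixed-effect covariance at variance parameters θ = (σ_rep², σ²), ∇g by
  central differences of the closed-form covariance, and A the inverse
  negative Hessian of the REML log-likelihood in θ. Multi-df terms are
  decomposed along the eigenvectors of LCL′ and the one-df Satterthwaite
  dfs combined (den df = 2E/(E − q), E = Σν_i/(ν_i − 2)). Reported sums of
  squares are scaled so that F = MS/σ². When σ_rep² is estimated on the
  zero boundary the model is OLS and the classical residual df n − p is
  used exactly. Satterthwaite dfs are floored at 1e-8 and capped at the
  residual df.
* **Contrasts.** Estimated marginal means are computed on the full
  position × day × temperature grid; the reported contrast is the
  between-temperature difference within each (position, day) cell, with
  Satterthwaite df and Benjamini–Hochberg adjustment across the whole
  position × day family by default ("none" gives raw p). Cells unobserved
  in the data are flagged non-estimable and excluded from the adjustment
  family (with the saturated factorial this only occurs if the fit itself
  was possible through other cells).

Day and position are categorical throughout; continuous coding is
deliberately not offered, matching the factorial design of the experiment.

## The meiosis/brood simulator

Chiasmata are placed on the four-chromatid bundle by a stationary gamma
renewal process: inter-chiasma distances Gamma(shape ν, mean 50 cM) on the
bundle scale, i.e. two chiasmata per Morgan, so that 2-fold thinning
reproduces the chromatid map. ν = 1 is Poisson (no interference; the
pipeline then reproduces Haldane's map function, a closed-form check);
ν = 10 (default) gives the strong underdispersion and steep coincidence
curves characteristic of this organism. Stationarity comes from starting
the renewal sequence 20 mean spacings upstream; the obligate-crossover rule
is imposed by rejection (condition on ≥1 chiasma), which preserves the
conditional renewal law. Each chiasma involves one uniformly chosen
chromatid of each homolog, independently (no chromatid interference).
Transmission distortion weights the transmitted product by δ when it is
recombinant (δ = 1 is fair meiosis); with one chiasma the transmitted
product is recombinant with probability 2δ/(2δ + 2), an enumeration oracle
the tests use. Genotypes flip state at each crossover left of a marker
(HET at the left telomere by convention), then each call is independently
missing with probability μ, else flipped with probability ε. Genetic ↔
physical conversion is piecewise-linear per marker interval; the simulated
chromosome spans the marker panel.

Temporal mechanisms modulate the treated arm's per-interval map by a
fold-change map per brood: `permanent` applies to every brood; `late`
applies immediately and lasts while the treatment lasts
(`treatment_end_brood`); `early` applies after a one-brood onset delay for
roughly three broods by default, encoding the oogenesis pipeline delay — an
adult treatment affecting early meiosis cannot show in eggs laid before the
treated oocytes mature. The onset and duration are configuration values,
not biological claims: the precise delay depends on the species' oogenesis
timing.

Default experiment shape (the emulated study conditions): 24 markers at
1.23 Mb spacing on one chromosome; uniform background map 3.8 cM/Mb; two
arms (18C control, 23C treated); 5 broods of 48 h; 2 replicate vials × 4 F1
females per arm; 14 progeny per female per brood (≈224 progeny per brood
across arms, ≈1120 total); genotyping error ε = 0.001 and missingness
μ = 0.02 (typical SNP-platform values); between-vial variability as a
lognormal multiplicative map scaling with SD 0.1 (~10%), because the
replicate random intercept is the model's reason for existing and a
zero-variance default would make it degenerate in every fit. Random
streams are split per (arm, replicate, brood) with separate substreams for
chiasma placement and for product selection + genotyping, so chiasma-level
truth is invariant to δ and every run is byte-reproducible from its seed.

What the simulator does *not* emulate: mechanistic oogenesis (cyst
formation and oocyte selection are represented only phenomenologically via
the fold map and δ); male meiosis (achiasmate); gene conversion / NCO
events; linkage-disequilibrium or marker-quality structure of real SNP
panels; fecundity differences between arms (a per-arm progeny schedule
hook exists but defaults off). Passing tests therefore establish the
estimators' correctness under the stated generative model, not robustness
to real-data artefacts outside it.

## Calibration findings and honest limitations

Two properties of the analysis, measured by the package's own calibration
suite at the default study scale, deserve emphasis:

* **The chi-square LRT reference is anti-conservative at this model size.**
  With ~230 fixed effects against ~1600 residual df, the ML likelihood-ratio
  statistic exceeds its chi-square reference in expectation by a factor
  ≈ n/(n − p) (the classic Bartlett-type inflation): empirical size ≈ 0.17
  at nominal 0.05 — and the same holds on ideal iid normal responses, so it
  is a property of the reference distribution, not of the data or the
  fitter. Users should treat the LRT as a screening statistic at this
  design size or apply a Bartlett-style correction.
* **Interference violates the residual-independence assumption.** Under
  strong interference, crossover counts in nearby intervals of the same
  meiosis are negatively correlated, so the female × interval × brood
  response rows are not independent. The consequence, visible in null
  calibrations, is that day-level tests (which average across positions)
  become conservative while position-level tests run slightly hot; with
  ν = 1 (independent intervals) all within-design terms calibrate to
  ≈ 0.035–0.06. A GLMM on counts with a female-level covariance structure
  would address this but is outside the present model family, which
  deliberately mirrors the field-standard LMM.

Detection power is another real constraint: at ~224 progeny per brood, a
3-fold rate change at a single position sits near the edge of BH-adjusted
detectability across the 115-cell contrast family (per-cell detection
~0.4–0.5, either-day detection ~0.7 in the package's own power
simulations). This matches the design's known power envelope — roughly
two- to three-fold changes per interval are the smallest detectable at this
scale — and motivates the early/late aggregation option.

## Numerical conventions

Variance-ratio optimisation is bounded Brent on log λ ∈ [−15, 12] with
xatol 1e-12, and the λ = 0 boundary is taken whenever its criterion is at
least as good as the interior optimum. The REML Hessian in θ uses central
differences with relative step 1e-3. Design-matrix rank is checked before
fitting (rank deficiency, e.g. from empty cells, is an error). Zero-total
intervals yield missing rates and are dropped from the model response.
Recombinant fractions above 0.5 are flagged, not dropped. Bin edges, code
mappings, informativeness thresholds and the BH/none adjustment switch are
all configuration, not constants.
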
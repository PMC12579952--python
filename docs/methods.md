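# Methods

This note documents the models, numerical choices and known limitations of
the package. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic GRN traces

The generator emulates 3 s single-sensillum tip recordings digitized at
30 kHz. Spike times come from an inhomogeneous Poisson process with
phasic–tonic intensity

    r(t) = tonic_rate + (peak_rate − tonic_rate) · exp(−t/τ),

simulated by thinning a homogeneous process at the peak rate, then thinned
again with a 2 ms absolute refractory period so injected spikes remain
resolvable as distinct peaks. The default decay constant τ = 0.13 s puts
the rate within 5% of tonic by 0.4 s, matching the observed phasic decline
over roughly 0.4 s before the rate stabilizes. Default peak/tonic rates
(100 / 25 spikes s⁻¹) are plausible for antennal GRNs but not fitted —
inter-spike-interval statistics and noise spectra of real recordings are
not characterized, so the generator is a structural, not a distributional,
stand-in.

The spike waveform is a biphasic difference of Gaussians with nominal width
0.8 ms (configurable, bounded below 1.5 ms). The lobe scale (σ = w/4.5,
lobe separation 2w/3) keeps most spike energy inside the 100–1000 Hz
analysis band, as for real ~1 ms extracellular spikes; narrower lobes would
be attenuated by the band-pass filter far more than real spikes are.
Artifacts are injected on request: large-amplitude events (4× the spike
amplitude, ≥ the 3× contract) with normal width, and over-wide events
(2 ms, same amplitude as spikes). Artifact times are drawn at least 3 ms
away from spikes and from each other so the injected ground truth stays
unambiguous. Background noise is white Gaussian; a seed fully determines
the trace.

## Spike pipeline

* **Filter** — 4th-order Butterworth, 100–1000 Hz, applied
  forward–backward (`sosfiltfilt`) for zero phase distortion.
* **Normalization** — a centred 51 ms running-median baseline is
  subtracted; the residual is divided by its robust noise SD
  (1.4826 × MAD), so thresholds are in noise-SD units across traces.
  Zero-variance traces map to zeros rather than dividing by zero.
* **Detection** — local maxima above threshold with ≥ 1 ms separation
  (the larger peak wins; `scipy.signal.find_peaks` resolves ties by
  prominence order, effectively earlier-larger). The original recordings
  used manually set thresholds; the default `auto` threshold of 5 noise
  SDs is a documented stand-in and user-overridable. Waveforms are
  extracted ±2 ms around each peak, edge-padded at the trace boundaries.
* **Windowing** — half-open [0.1, 2.1) s. The 1 s mean rate is anchored to
  the start of the retained window ([0.1, 1.1) s), which makes it exactly
  the sum of the first ten 100 ms bins; the binning covers the full 2 s
  window in 20 bins.
* **Artifact rejection** — step 1 removes events with peak amplitude above
  mean + 3·SD of the per-trace amplitude distribution ("significantly
  higher than the mean", k configurable); step 2 removes events whose
  rectified-waveform span at half maximum exceeds 1.5 ms (45 samples at
  30 kHz). The span is measured within ±1.25 ms of the peak: wide enough
  for any event near the bound, narrow enough that a neighbouring spike at
  the snippet edge cannot inflate it.
* The original workflow ends with a manual visual inspection of retained
  waveforms; there is no algorithmic counterpart, so that step is replaced
  here by the invariant suite (recovery sensitivity/precision ≥ 0.95 at
  SNR 3, conservation of detected = retained + rejected, artifact
  specificity), which is what "passing" means in this package.
* Sensilla that did not respond to all four tastants are flagged by
  `flag_unresponsive_sensilla` (≥ 1 spike s⁻¹ per tastant) rather than
  silently dropped.

## Firing statistics

Rates (spikes per first second) are modelled as
`rate ~ stimulus × location` under Gamma, inverse-Gaussian (both log link)
and Gaussian (identity) families; the paper-style analysis names only the
families, and the log link matches the mixed-model specification. AIC
picks the family. Zero rates — impossible in responsive sensilla but
possible in simulation — are replaced by 0.5 spikes s⁻¹ with a warning.

Type-II Wald χ² tests: each term is tested in the model containing every
term not marginal to it, i.e. main effects are tested in the additive
refit and the interaction in the full model. This matches type-II ANOVA
conventions (`car::Anova`-style) up to the refit; the cross-check against
glmmTMB/car in the test suite shows agreement to a few percent on the χ²
values. With the estimated Gamma dispersion the Wald χ² is mildly
anticonservative at n ≈ 130 (empirical type-I error ≈ 0.06 at α = 0.05),
inside the calibration band asserted by the acceptance suite.

Estimated marginal means are computed on the link scale from the design
rows of the stimulus × location grid; pairwise stimulus differences within
each location are Tukey-adjusted via the studentized range with residual
degrees of freedom, and mid-vs-tip contrasts per stimulus are two-member
families (adjusted = unadjusted).

### Temporal mixed model

Binned counts (+1 to absorb empty bins) are fit with a Gamma/log GLMM,
`count+1 ~ stimulus × time + (1 | bee)`, with bee identity as the only
random effect (a sensillum-level effect is deliberately omitted, mirroring
the finding that it did not improve fit). No installed Python package fits
frequentist Gamma GLMMs, so the model is implemented in `glmm.py` by
Laplace approximation: penalized Newton iterations jointly maximize over
fixed effects and random intercepts (tolerance 1e-8, max 200 iterations),
and Nelder–Mead maximizes the Laplace marginal likelihood over (log shape,
log σ²), with the shape log-bounded in [−6, 9] so degenerate all-constant
responses converge to the boundary instead of diverging. The test suite
pins the fit against frozen glmmTMB 1.1.9 reference values (coefficients,
SEs, σ², log-likelihood). Non-convergence falls back to a fixed-effects
Gamma GLM and flags the report.

Time enters as a centred scaled covariate ((bin − 10.5)/19) rather than a
20-level factor: the phasic–tonic trend is monotone and the factor version
would cost ~100 interaction parameters on 26-sensillum designs. Per-time
stimulus contrasts are evaluated from the fitted surface at each bin's
covariate value, Tukey-adjusted across stimulus pairs within the bin.

## Forager agent

One agent visits a twelve-flower array, choosing flowers uniformly (flower
positions are randomized and relocated after every visit in the real assay,
so spatial layout is abstracted away). Probe probability is
`clamp(p₀ + salience·V(class), 0, 1)` with `p₀ = 0.5`. In conditioning,
probing yields an outcome (+1 sucrose, −1 water) and updates the visited
class's value by a delta rule `V += λ(outcome − V)`; leaving yields no
outcome and no update. Test-phase visits keep training class labels and
never update. Bout boundaries fall every 20 visits (flowers are cleaned,
optional scent marks reset, values decay by the forget rate); the test
phase starts on a fresh bout. With salience 0 the agent is cue-blind and
its success and response rates are exactly 0.5 in expectation — the
calibration the chance-level tests and the acceptance script measure.

An optional per-flower scent-mark cue (salience off by default) lets
previously probed flowers carry a signed mark; it exists to reproduce,
qualitatively, above-chance control-group training performance, and plays
no part in the default study conditions. A static `innate_bias` term
covers spontaneous preferences in the preference design; its default of 0
matches the observed absence of naive preferences. Mouthpart contact is a
rare independent Bernoulli event (p = 0.002, the observed order of
magnitude); contacts are scored normally and only counted.

Per-bee RNG streams are spawned from (master seed, bee index), so a bee's
log is independent of cohort size.

What the agent does *not* model: spatial search, bout-length variation,
satiation, colony effects, or any UV/texture confound. Passing tests show
the analysis chain recovers the structure this agent generates, not that
real bees behave like the agent.

## Behavioural statistics

* **Scoring** — preference: a landing favours treated flowers iff
  (treated ∧ probed) ∨ (untreated ∧ ¬probed); conditioning: correct iff
  (rewarding ∧ probed) ∨ (nonrewarding ∧ ¬probed). Success is summarized
  over the seven ten-visit training intervals (which exactly partition
  visits 1–70) and over the 20 test visits. Incomplete logs fail loudly,
  mirroring the exclusion of bees that did not complete the experiment.
* **Transform** — `asin(√p)`; the chance baseline is the exact π/4, with
  0.79 used only for display.
* **Wilcoxon** — zero differences dropped; W is the positive-rank sum.
  For n ≤ 25 the two-tailed p comes from the exact sign-flip null computed
  by convolution over (mid)ranks — enumeration that remains exact under
  ties, where R's `wilcox.test` would fall back to a normal approximation;
  above 25, normal approximation with continuity correction.
* **Learning curves** — Gaussian GLMs (identity link; the transform is
  variance-stabilizing) on the long-format interval data, over eight
  candidates crossing group structure (none / control-vs-conditioned /
  three groups) with an experience covariate (interval endpoint / 70) and
  its group interaction. Selection takes the simplest model within
  ΔAIC ≤ 2 of the minimum. Bee identity is not a blocking factor: groups
  are between-bee, so bee fixed effects would alias exactly the group
  contrasts of interest; repeated measures are instead acknowledged as a
  limitation (AIC comparisons treat interval points as exchangeable, as in
  the comparable published analyses this reconstructs).
* **Test phase** — one-way ANOVA on transformed test success (df 2, n−3),
  Tukey HSD (`scipy.stats.tukey_hsd`), and a compact letter display built
  from maximal cliques of the "not significantly different" graph, ordered
  by group mean; two groups share a letter iff their Tukey p ≥ α = 0.05.

## Problem sizes and determinism

Simulation-based checks use 50 seeds for spike recovery and artifact
specificity, 1000 replicates for each type-I-error calibration, 100
replicates for family-selection and learning-structure recovery, and
10,000 visits for chance-level calibration — sizes at which binomial noise
is well inside the asserted bands. All randomness flows through explicit
integer seeds (`numpy.random.default_rng` / `SeedSequence`); identical
seeds give bit-identical traces and visit logs.

## Known limitations

* Generator defaults are plausible rather than fitted; no real recordings
  or visit logs ship with the package.
* The spike pipeline assumes one pooled GRN response per sensillum — no
  multi-unit sorting, matching the threshold-crossing analysis it
  implements.
* The Gamma GLMM uses a first-order Laplace approximation; for very small
  group counts or shapes near the boundary its likelihood can differ from
  adaptive-quadrature implementations.
* Real-cohort headline statistics (e.g. specific χ² or F values from the
  original experiments) depend on raw data that are not public and are out
  of scope; the package demonstrates capability and calibration on its own
  generators.
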
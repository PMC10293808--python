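# Methods

## Pixel-to-metric scaling and altitude smoothing

A nadir camera at altitude *h* has ground sample distance
`GSD = h · p / f` (pixel pitch *p*, focal length *f*), so a subject of
*n* pixels measures `n · GSD`. No tilt, lens-distortion or
water-refraction correction is applied; the model assumes the subject at
the sea surface directly below the camera.

Laser altimeters occasionally log spurious readings. The despiking
filter replaces any point deviating from its running median (window 5
samples, threshold 1.0 m; both configurable) by that median, and the
pass is iterated to a fixed point (bounded at 100 passes). Iterating
makes the filter exactly idempotent — a desirable property for a
cleaning step, since re-cleaning cleaned data must be a no-op — while a
single pass is available via `max_passes=1`. Any robust smoother with
this property would serve; the running median was chosen for
reproducibility and insensitivity to isolated spikes.

Measurement error is summarised as the signed percent difference
`100·(estimate − reference)/reference` (positive = overestimate),
reported per group as mean, SD and SE. Internally all relative errors
are dimensionless fractions; percent appears only in rendered reports,
which avoids silent factor-of-100 bugs. Both SD and SE are carried
because summaries of this kind are quoted either way in the literature;
the simulator consumes the SD.

## TL~BHDF estimators

Let *T* be total length and *B* the blowhole-to-dorsal-fin distance (cm).

* ratio: coefficient `r = mean(100·B/T)` over records; prediction
  `T̂ = 100·B/r`. The mean-of-ratios (rather than ratio-of-means) weights
  animals equally; the alternative is exposed via `ratio_of_means=True`.
* linear: OLS `T = a + b·B`.
* loglinear: OLS `ln T = a + b·ln B`, prediction `T̂ = exp(a + b·ln B)`.
  Natural logs (base does not affect predictions). No smearing/Duan
  back-transform correction is applied: at the residual scales involved
  (~3%) the bias is ≈ σ²/2 < 0.1%, consistent with the near-zero bias
  these estimators show on physical BHDF.

Repeated measurements of one animal at a single age can be pooled with
`average_per_animal()` (or `per_animal=True` on the fitters) before
fitting, appropriate for facility reference panels; catalogue records
with one age per assessment are fitted as given.

Caveat: when the predictor *B* itself carries noise (as with the
synthetic generator's BHDF scatter, or field measurements), the log-log
slope estimates the attenuation factor
`λ = Var(ln T) / (Var(ln T) + cv²)`, not the generating exponent —
classical errors-in-variables. Tests assert the attenuated value
explicitly; exponent recovery is verified on response-noise data.

## Error propagation

UAS-simulated measurements multiply truth by `(1 + ε)`,
`ε ~ Normal(D_e, D_sd)`:

```
B_sim = B_physical · (1 + ε₁)
T_sim = T̂_loglinear(B_sim) · (1 + ε₂)
```

with ε₁, ε₂ independent (no correlation structure between the stages is
assumed; sequential application is the simplest reading). The default
`paper_default_noise()` sets both means to 0 and both SDs to 0.031 —
propagating the measured spread without transferring a
facility-specific bias. The two-stage form literally compounds the
errors (CV² ≈ b²·σ₁² + σ₂² for small σ); if the measured TL-stage SD is
taken to capture the *total* error, the single-stage mode
(`two_stage=False`) skips ε₂. Both are provided; two-stage is the
default. A Normal multiplier can go non-positive at extreme draws
(impossible at σ ≈ 0.03, possible under user configs); such draws are
redrawn up to 100 times, then error — preserving the distribution to
negligible approximation while keeping lengths positive.

## Age classifiers

Bins are half-open `[X, Y)` in years with an unbounded oldest bin.
Per-bin reference distributions (mean, SD, min, max, n of the physical
measure) require ≥ 2 records per bin. The assignment rule — the
functional form is a design choice — is the normalised Normal
likelihood: bin *i* gets weight `φ((v − μᵢ)/σᵢ)/σᵢ`, computed in
log-space with a row-max shift so values far from every bin still
normalise. The observed [min, max] enters only via the optional
`truncate` flag (default off: hard truncation can zero every bin for
extreme draws; when it does, the rule falls back to untruncated
weights). Bins with zero SD receive a configurable floor (default
10⁻⁶ cm) to keep densities finite.

Scoring accumulates, per replicate, either each assessment's full
probability vector into its actual-bin row (default, matching
mean-proportion reporting) or an argmax indicator (ties to the younger
bin — conservative toward detecting immature animals). Confusion rows
are normalised to percent; mean accuracy is the assessment-weighted
diagonal mean (unweighted available); within-band(k) accuracy sums each
row over assigned bins within ±k of the truth. Reference distributions
are built from the same records that are classified (resubstitution, the
standard design when a long-term catalogue is both reference and test
set); a leave-one-animal-out mode gives honest error estimates but is
not the default.

`population_age_structure` reports the mean assigned proportion per bin
across replicates with a 2.5/97.5 percentile interval.

## Synthetic data

The generator emulates a bottlenose-dolphin-like population:

* **Growth**: von Bertalanffy `L(a) = L∞(1 − e^(−k(a − a₀)))` with
  defaults L∞ = 250 cm, k = 0.35 /y, a₀ = −1.76 y — birth length
  ≈ 115 cm, ≥ 97% of the asymptote by age 10 (the observed plateau at
  10–15 y), and population TL mean/SD near 235 ± 26 cm under a uniform
  age distribution. The von Bertalanffy form was preferred to Gompertz
  for its closed form; only the plateau property matters downstream.
* **Between-animal variation**: a lognormal multiplier on L∞
  (CV 0.04). Within an animal, length is a deterministic function of
  age, so longer always means older.
* **Allometry**: `BHDF = c·TL^d · lognormal(0, cv)` with c = 0.292
  (ratio coefficient 29.2), d = 1 and cv = 0.03. With d = 1 all three
  estimator families are simultaneously correctly specified; tests that
  must separate them set d ≠ 1.
* **Design**: ages uniform on [0, 45] y by default (classifier tests
  need occupancy in every bin) or drawn from explicit per-bin weights —
  the acceptance script uses the published seven-bin sample counts
  (107/177/180/149/81/25/23) so the synthetic catalogue matches the
  real catalogue's age structure. 1–5 assessments per animal, each with
  its own age.
* **Facility panels**: known true TL/BHDF plus replicated noisy
  estimates with relative error `Normal(bias, cv)`, emulating
  ground-truthing of trained animals (e.g. bias 0.033 for the body-arch
  overestimate of surfacing BHDF).

What the generator does **not** emulate: behavioural availability bias
beyond a net relative error, altitude- or platform-dependent error
mixtures, autocorrelated errors within a flight, sex-specific growth,
and real catalogue age uncertainty (tooth-layer ages are treated as
exact). Passing tests therefore demonstrate the pipeline's internal
correctness and its behaviour under the stated error model, not field
performance on any particular population.

## Numerical and reproducibility choices

* One root seed per run; per-stage `SeedSequence` substreams let stages
  rerun in isolation without disturbing each other's draws.
* Probability normalisation via log-space max-shift (no underflow);
  assignment vectors sum to 1 within 10⁻⁹, confusion rows to 100 ± 10⁻⁶.
* Argmax ties resolve to the first (youngest) maximum.
* The classifier experiment at its defaults (776–818 assessments, 7
  bins, 1000 replicates) is fully vectorised and completes in well
  under a second per scenario.

## Known limitations

Resubstitution overstates field accuracy; the ratio/linear/loglinear
estimators ignore population differences in the TL–BHDF relationship;
the assignment rule assumes per-bin Normality of lengths; and the
two-stage error model double-counts if the measured TL SD already
includes the BHDF-stage error (the single-stage mode exists for that
reading).
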
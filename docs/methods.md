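# Methods notes

This note records the models implemented in `spindlequant`, the design
choices made where more than one reasonable convention exists, and what
the synthetic-data generators do and do not emulate.

## FRAP trace processing

**Correction.** Imaging itself bleaches fluorescence, so the raw
recovery of a bleached spindle confounds molecular turnover with
acquisition loss. Non-bleached control spindles imaged under the same
protocol estimate that loss, and the corrected trace is the ratio form

    F_corr(t) = F(t) · C_pre / F_control(t),

with `C_pre` the mean pre-bleach control intensity. When several control
spindles are available they are averaged into one control trace before
correction (`pipeline.mean_control`); this reduces the noise injected by
the division. Controls must be strictly positive and cover the sample's
time range (linear interpolation bridges grid mismatches).

**Normalization.** The corrected trace is normalized between the
pre-bleach mean and the first post-bleach frame:

    F_norm(t) = (F_corr(t) − F_corr(0)) / (F̄_pre − F_corr(0)),

so 0 is the bleach floor and 1 is full recovery to the pre-bleach
level. A trace whose value at `t = 0` equals the pre-bleach mean carries
no bleach signal and is rejected rather than silently producing a 0/0.
Pre-bleach frames sit at negative times (−3Δt, −2Δt, −Δt by default);
`t = 0` is the first post-bleach frame.

**Pooling.** Replicate normalized traces on a common grid are averaged
pointwise; the per-timepoint standard error is carried along for
plotting and diagnostics. Fitting operates on the pooled mean by
default; per-trace fitting and residual-bootstrap standard errors are
available for uncertainty estimates.

## Recovery model family and fitting

The model is a sum of up to two saturating exponentials with base-2
rates so the fitted half-times are directly the times to half of each
population's final recovery:

    F(t) = f (1 − 2^(−t/tf½)) + s (1 − 2^(−t/ts½)).

Three nested kinds are fitted:

* `full_single` — `f = 1`, `s = 0`: one population, full recovery
  (1 free parameter);
* `single_plus_immobile` — `f ∈ [0, 1]`, `s = 0`: one turnover
  population with an immobile remainder `1 − f` (2 parameters);
* `two_population` — two turnover populations, reported with
  `tf½ < ts½` (relabelled when an optimizer run crosses over).

**Closed vs open two-population model.** By default the two-population
fit is *closed*: `f + s = 1` (3 free parameters). This matches how
two-population turnover results are quoted — complementary percentages
such as 85% slow / 15% fast — and it is what makes the slow population
identifiable on a finite observation window: with `f + s` free, a large
slow half-time trades off almost perfectly against the mobile total when
the window (165 s) is shorter than the slow half-time (minutes), and
Monte-Carlo experiments at realistic noise show the unconstrained slow
fraction estimate has a standard deviation of ~0.18 and a strong
downward bias. The unconstrained variant remains available
(`fit_recovery(..., free_total=True)`); on noise-free data it recovers
`f + s < 1` truths exactly and is used that way in the validation sweep.
An explicitly immobile remainder combined with a single turnover pool is
the `single_plus_immobile` kind, which is the appropriate description of
syncytial-embryo data.

**Optimization.** Bounded least squares (`scipy.optimize.least_squares`,
trust-region reflective) with fractions in [0, 1] and half-times
optimized in log10 space within `[Δt/10, 100·t_end]`, where `Δt` is the
median sampling interval. Multistart initialization uses a log-spaced
half-time grid crossed with fraction splits {0.25, 0.5, 0.75}, trimmed
deterministically to `n_starts` (default 16); the lowest-RSS solution
wins, with ties implicitly broken by start order. Tolerances are set to
1e-14 so noise-free problems converge to machine precision. A flat
all-zero trace short-circuits to the degenerate plateau-0 solution with
a warning.

**Model selection.** Candidates are compared by AICc computed from the
least-squares likelihood, `n ln(RSS/n) + 2k + 2k(k+1)/(n−k−1)` with
`k = p + 1` (residual variance counted). The lowest AICc wins; a margin
under 2 AICc units over the runner-up is flagged *indeterminate* rather
than silently resolved, since such margins are not meaningful.

## Axial spindle profiles

Intensity is sampled along the pole-to-pole segment at one-pixel spacing
by bilinear interpolation, optionally averaged over a small odd number
of parallel lines (default width 1 — a single line). Position is
normalized to the spindle length, intensity to the *profile* maximum
(not the image maximum, which may sit outside the scan). The profile is
divided into 10 equal axial bins — bin `i` covering `[(i−1)/10, i/10)`,
the last bin closed — and per-bin medians are taken per spindle before
any cross-spindle statistics. The sub-polar/equator statistic is
`mean(m3, m8) / mean(m5, m6)`; both bin pairs are symmetric about the
spindle midpoint, so the statistic does not depend on which pole is
labelled position 0, and scale invariance is inherited from the
normalization. Groups of per-spindle ratios are compared with a
two-sided Wilcoxon rank-sum test: exact null distribution for combined
n ≤ 20 without ties, normal approximation with tie correction otherwise;
two groups of entirely identical values return p = 1 with a warning.

## Pole intensity and chromosome spread

The per-pixel pole intensity above background uses two nested ROIs: a
large ROI (spindle plus cytosol; summed intensity I1 over N1 pixels) and
the pole ROIs (I2 over N2). The cytosol background per pixel is
`b = (I1 − I2)/(N1 − N2)` and the reported value is `I2/N2 − b`. The
summed variant `I2 − b` is kept behind a `literal=True` flag for
comparison only: it mixes a sum with a per-pixel quantity and is not
dimensionally a per-pixel intensity. Adding a constant to the whole
image cancels exactly in the per-pixel form (property-tested).

Chromosome spread is the extent of the thresholded chromosome-channel
mask projected onto the pole-to-pole axis, in µm. Otsu's threshold is
the default for noisy data; a half-maximum threshold matches the
analytic geometry of the synthetic blobs and is used where exactness
matters. Connected blobs smaller than 10% of the largest blob's area can
be excluded (`exclude_smallest=True`), which is how the small 4th
chromosome is omitted from spread measurements while remaining included
when the flag is off.

Congression is summarized by the Pearson correlation between spread and
`ln(pole intensity)` with a two-sided t-distribution p-value. The log
base does not affect r (tested to machine precision).

## Synthetic data

The generators' defaults encode the standard acquisition conditions:

* **Traces** — 3 pre-bleach frames, one frame every 5 s to 165 s;
  pre-bleach level 100 (arbitrary units); bleach depth 0.2 (fraction of
  signal remaining at `t = 0`); acquisition bleaching applied
  multiplicatively as `exp(−r·t)` for `t ≥ 0` with `r` calibrated so a
  control loses 25% of its signal by 80 s (the three quick pre-bleach
  frames are treated as bleaching-free); additive Gaussian noise with SD
  0.03 of the pre-bleach level. Noise level and bleach depth are not
  reported quantities for the original acquisitions; these defaults are
  plausible confocal values and are configuration knobs, not claims.
  With zero noise and any bleaching rate, the full
  correct → normalize → pool pipeline returns the generating model curve
  exactly — the correction is the algebraic inverse of the simulated
  bleaching.
* **Images** — two-channel 2-D grids at 0.1 µm/pixel, generated directly
  as maximum-intensity projections (a thin z-stack wrapper exists only
  to exercise the projection step). The tubulin/Augmin channel is an
  axial profile (unit plateau, Gaussian pole peaks scaled by
  `pole_enrichment` and per-pole `pole_asymmetry`, and a sub-polar
  attenuation factor acting around fractional positions 0.25/0.75) with
  a Gaussian perpendicular envelope (σ = 1 µm) over a uniform cytosol
  background. The chromosome channel is axis-aligned Gaussian blobs
  whose half-maximum mask spans exactly `chromosome_spread` µm along the
  axis — chosen because the half-maximum radius of a Gaussian is known
  analytically, giving the measurement a ground truth. Ground-truth pole
  coordinates are recorded on the image. No point-spread function,
  3-D optics, or photon statistics are modelled, so passing tests
  demonstrate correctness of the measurement code, not robustness to
  real optical artifacts.
* **Congression datasets** — pole intensity lognormal, spread linear in
  log intensity plus Gaussian noise (clipped below at 0.2 µm). The
  population correlation is known in closed form,
  `ρ = slope·σ/√(slope²σ² + noise²)`, so the default noise is solved
  analytically rather than by grid search. Because the sample Pearson r
  is attenuated toward 0 at small n (E[r] ≈ ρ(1 − (1−ρ²)/(2(n−1)))), the
  calibration targets the *mean sample correlation* at the generated
  dataset size: for n = 26 the default population value is −0.778 so the
  sampling distribution of r centres on −0.772.

All generators are bitwise-reproducible under a fixed seed; ensembles
derive per-trace seeds from the master seed via `SeedSequence`.

## Validation problem sizes

The test suite validates parameter recovery at the pooled sizes used in
practice (15 oocytes, 11 embryos), a 50-draw noise-free sweep with rate
separation ≥ 5×, a 3×5 model-selection confusion check at noise SD 0.02,
48-per-group image comparisons, and 1000 congression replicates at
n = 26. These sizes make the whole suite run in well under a minute
while keeping Monte-Carlo error small relative to the tolerances
checked.

## Known limitations

* The fast half-time (~8 s) is close to the 5 s sampling interval, so
  its estimate from pooled data has a relative error of roughly 20%
  even at realistic noise; recovery tolerances for it are accordingly
  loose, and occasional excursions beyond ±25% are expected at
  unfavourable noise realizations.
* Diffusion-limited FRAP, spatial (2-D) recovery, and bleach-spot
  geometry corrections are out of scope; the kinetic model assumes
  reaction-dominated exchange.
* Pole coordinates are inputs (manual annotation or generator ground
  truth); no automatic pole detection is provided.
* Chromosome spreads are per-frame measurements; no time-lapse tracking
  or trajectory linking is implemented.
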
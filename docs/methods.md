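# Methods

`deepclick` studies how the seasonal presence of a deep-diving, echolocating
predator (the motivating case is sperm whales in the Northeast Pacific) can
be inferred from fixed-point passive acoustic monitoring, and which
individual-level movement strategy best explains the observed seasonality.
Everything runs on synthetic inputs produced by `deepclick.synthgen`, so the
whole pipeline is testable without any recordings or satellite data.

## Click-train detection

Detection is a two-step daily workflow.

**Band-limited energy detection (BLED).** The waveform is band-passed to
1.4–4 kHz (4th-order Butterworth, zero-phase), squared, and averaged over a
10 ms window hopped every 5 ms, giving a short-time in-band mean-square
envelope in dB. The background is a running median (percentile 0.5) of the
envelope over 60 s, robust to click energy leaking into the noise estimate.
A candidate click is a maximal run of frames at least 5 dB above background
whose duration lies in 2–50 ms; its onset frame defines the detection time
(onset rather than peak, because the onset is stable as SNR varies). Clicks
of this species are roughly 10–25 ms broadband impulses, which motivates the
window and duration bounds.

**Interval filtration.** BLED is deliberately permissive and fires on any
impulsive source. The species signature is *regularity*: echolocation
clicks repeat with a near-constant inter-click interval (ICI) of roughly
0.5–2 s. Successive detection times give inter-detection intervals (IDIs),
rounded to the nearest quarter second (exact midpoints round half-up, a
determinism choice). A qualifying sequence is a maximal run of at least
`r` consecutive IDIs that are (1) within [0.5, 2.0] s inclusive after
rounding and (2) all equal after rounding. `r` counts intervals, so a
qualifying sequence spans at least `r + 1` detections. A change in rounded
value terminates a run and overlapping sub-runs are not emitted, so one
physical click train yields one sequence. A day is "present" when at least
one qualifying sequence exists.

`r` is tuned against day-level truth labels by maximizing balanced accuracy
(mean of sensitivity and specificity); ties break toward the larger, more
conservative `r`. On the default 50-day synthetic corpus the tuned value is
r = 6: smaller r remains perfect here because negative-day transients are
irregular, while r > 6 loses recall on days whose only train is minimal
(7–8 clicks).

## Synthetic audio

A synthetic day is flat-spectrum Gaussian noise at a configurable spectral
level (default −40 dB re arbitrary units) carrying rendered click trains.
Each click is a 10 ms Gabor-like impulse (Gaussian-windowed 2.7 kHz tone, the
detector's center frequency) scaled so its peak short-time in-band energy
exceeds the noise band level by the train's SNR. Inter-click intervals are
`ici_mean + N(0, jitter)`; for jitter ≤ 0.1 s the deviations are truncated
to the quarter-second rounding bin of `ici_mean`, so a generated train is
"regular but not exactly constant" and never straddles a rounding boundary.
Negative corpus days carry Poisson-timed impulses (rate 0.03 s⁻¹) with the
same spectral shape but irregular spacing — confounders that the energy
detector flags and only the interval filter rejects.

The default corpus is 50 days, half positive, with click SNR uniform on
6–20 dB (the detector threshold is 5 dB, so low-SNR trains are genuinely
marginal), 1–5 trains per positive day, and day length 600 s. Short days
stand in for full 86400 s days purely to bound compute; nothing in the
detector depends on day length beyond the background window. What passing
tests show is that the detector chain recovers regular trains against
stationary noise and irregular transients; they do not probe nonstationary
soundscapes (shipping, weather), overlapping whales, or propagation effects,
all of which real recordings contain.

## Monthly presence and seasonality

Daily calls aggregate to the monthly percent of *recording* days with
presence; non-recording days never enter the denominator, and months with no
recording days are reported missing rather than imputed. Display smoothing
uses a centered 3-month running mean (2-point means at the ends).

Seasonality is tested with a cyclic smooth of month plus a year random
intercept, fitted as a linear mixed model: the cyclic basis is harmonic
(three sine/cosine pairs, period 12 — dimension 6, the smallest cyclic basis
that can express one asymmetric annual peak). The p-value is a likelihood
ratio test of the six month columns (ML fits, χ² with 6 df); deviance
explained is relative to the intercept-only model. When the year-level
variance collapses to the boundary and the mixed fit is singular, the
fixed-effects F-test is reported instead. When the basis reproduces the
series exactly (zero residual), the model is bypassed and a perfect fit
reported — the mixed model is degenerate there.

Mean ICI classifies sequences demographically: small (< 0.6 s; females and
juveniles), large (> 0.8 s; adult males), intermediate otherwise; exact
boundary values fall in the intermediate class since the named classes are
defined by strict inequalities. The month/year ANOVA on ln(ICI) first
aggregates sequences to month × year cell means, so factor dfs follow the
between-cells convention (11 and 7 on a 12 × 8 design). Identical cell
means give F = 0 by convention rather than 0/0.

## Movement simulation

100 agents take daily steps for ten 365-day years in a 1000 × 3000 abstract
arena (y is latitude) with reflecting walls and two disjoint listening
ranges of radius 150 centered at (500, 750) ("south") and (500, 2250)
("north"). The domain is deliberately abstract — no projection, bathymetry,
or calibrated detection ranges. A station-day is present when any agent is
inside the disc, matching the daily presence metric of the acoustic
pipeline; monthly detection is the mean over years 2–10 (year 1 is burn-in)
of the percent of days present.

All strategies share a correlated-random-walk base: gamma step lengths
(shape 2) and wrapped-Cauchy turning angles. Strategy overlays:

- **Seasonal resource tracking.** A Gaussian resource ridge in latitude
  (SD 400) whose peak oscillates sinusoidally with amplitude 750 around
  mid-domain, phased to sit on the southern station in mid-January and the
  northern station in mid-July. Headings mix the CRW proposal with the
  ridge-gradient direction, weighted by `taxis_strength` (0.35) times the
  normalized gradient magnitude. Because the pull vanishes in the ridge
  tails, the population self-organizes into a tracking core plus a diffuse
  cloud of agents dropped during fast ridge transits and recaptured when the
  ridge returns — producing year-round detection at both stations with
  opposite-phase seasonal cycles, the defining signature of this strategy.
- **Nomadic resource tracking.** The same taxis applied to an aseasonal
  mixture of 8 Gaussian patches (SD 180) relocating independently at
  exponential epochs (mean 10 days), with a faster step scale (80/day).
  Loose, short-lived aggregations keep mean station coverage aseasonal and
  decorrelate within a month, so the monthly cycle shows no coherent annual
  component.
- **Seasonal to-and-fro migration.** Northward transit during days
  97.5–142.5 and southward during 277.5–322.5 (45-day windows), with strong
  persistence (wrapped-Cauchy concentration 0.9) toward the target range
  center and step scale 40/day — enough to cover the 1500-unit separation
  within a window. Otherwise agents are residents: localized steps
  (step/5, concentration 0.3) with weak homing toward the seasonal range
  center whenever they stray beyond a 300-unit home-range radius. Homing
  makes the off-season structural zeros exact: no agent can random-walk a
  net 1350 units against it over nine years.
- **Sex-specific partial migration.** A 50/50 sex ratio; males follow the
  to-and-fro rules, females keep the southern home range year-round, giving
  year-round southern detection and summer-only northern detection.

The free movement parameters (taxis strength, ridge and patch widths, patch
count and relocation rate, home-range radius) are not observable quantities;
they were calibrated once so each strategy expresses its defining phenotype
robustly across seeds — structural zeros for to-and-fro, no coherent annual
harmonic for nomadism (< 15 percentage points peak-to-trough), year-round
anticorrelated cycles for resource tracking — and then frozen. "No coherent
seasonality" is measured as the peak-to-trough amplitude of the annual
(period-12) harmonic of the monthly cycle, because the raw 12-month range of
an aseasonal process is dominated by sampling noise rather than seasonality.

**Reference series and RMSD.** The southern reference is a 12-month
sinusoid through the anchored extrema (59.3% of days in January, 31.1% in
July); the northern reference is opposite in phase with a stronger summer
peak (85% July, 20% January), emulating high-latitude seasonality with
year-round presence. Model–reference agreement is the root-mean-square
deviation over the 24 cells (12 months × 2 stations) of across-year monthly
means, averaged over 10 replicate simulations run under identical per-rep
seeds for all strategies. Under the defaults the ranking is stable across
seeds: resource tracking (RMSD ≈ 24) < nomadic (≈ 30) < to-and-fro (≈ 33)
< partial (≈ 44). Absolute RMSD values depend on the abstract geometry and
the reference fixture and are not comparable across studies; the ranking
and the phenotypes are the result.

With 100 agents and radius-150 discs in this domain, any near-uniform
population saturates daily presence (~90%), and any coherent aggregation
crossing a station saturates it seasonally; intermediate detection levels
require loose clustering. This geometry-driven saturation is why simulated
seasonal amplitudes exceed the empirical reference amplitudes and why RMSD
magnitudes are interpreted only relatively.

## Oceanographic comparison

The transition-zone index is the mean latitude of the 18 °C SST isotherm
over longitude columns within 160–180 °W (handled in the 0–360 convention
to avoid the dateline seam). Each column's crossings are located by linear
interpolation between adjacent grid latitudes; multiple crossings in a
non-monotone column are averaged; columns without a crossing are excluded.
The synthetic SST generator produces a linear meridional gradient
(default −0.5 °C per degree latitude) with optional Gaussian pixel noise,
so the recovery error under 0.1 °C noise is a direct test of the extractor.

Monthly presence is regressed on isotherm latitude with ranged-major-axis
(model II) regression: both variables are divided by their ranges, the
major-axis slope of the standardized scatter is taken in closed form, and
the slope is back-transformed, with the line through the bivariate mean.
Significance is a two-sided permutation test on |r| (999 permutations,
seeded) rather than a parametric approximation — no distributional
assumptions, fully reproducible.

## Numerical choices and degenerate inputs

- Quarter-second rounding uses half-up at exact midpoints (platform
  determinism); `round_quarter(0.625) = 0.75`.
- Zero envelope energy maps to a −200 dB floor, never −inf.
- All simulation and synthesis randomness flows through
  `numpy.random.default_rng` seeds; identical seeds give bit-identical
  corpora, waveforms, and simulation results.
- Degenerate regressions (constant x, zero range) and degenerate corpora
  (single-class truth) raise rather than returning silent answers.
- Calendar convention: simulation years are 365 days with standard month
  lengths; dates elsewhere are ISO-8601, UTC throughout.

## Limitations

- Synthetic audio has stationary noise and isolated trains; no propagation
  modeling, no overlapping animals, no nonstationary soundscapes. Detector
  accuracy on the corpus is an upper bound on real-data performance.
- The movement arena is abstract; RMSD values and seasonal amplitudes are
  meaningful only relative to other strategies in the same arena.
- The seasonal model's deviance explained depends on basis and estimator
  choices and is not numerically comparable to values fitted with other GAM
  machinery on real series.
- ICI demography treats every sequence as an independent detection; it
  speaks to presence of size classes, never abundance.
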
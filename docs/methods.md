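# Methods

`pulsegerm` implements an at-line method for monitoring fungal spore
germination in bioreactor batch cultures from scanning flow-cytometry
data.  This note records the models, the numerical choices, what the
synthetic data generator does and does not emulate, and the known
limitations.

## Problem and measurement model

Spore inoculum quality drives pellet morphology and process performance
in filamentous bioprocesses (*Penicillium chrysogenum* penicillin
production being the motivating system).  Classical viability counting
(CFU plating) is slow and — critically — counts spores that germinate on
agar, which is not the same population that germinates in the liquid
bioreactor environment.  The method monitored here instead

1. stains a diluted broth sample with FDA (fluorescein diacetate, an
   ester converted to fluorescent fluorescein by intracellular
   esterases, marking metabolically active spores) and PI (propidium
   iodide, marking dead cells red);
2. measures it on a scanning flow cytometer that records a sampled
   intensity curve — a *pulse shape* — per particle and channel (two
   forward scatters `FWS_L`/`FWS_R`, sideward scatter `SWS`, and
   yellow/orange/red fluorescence `FLY`/`FLO`/`FLR`);
3. gates FDA-positive (viable) spores out of the complex-medium
   background with two 2-D gates;
4. classifies every FDA-positive spore as germinated or non-germinated
   from five pulse-shape features with a logistic model.

A spore counts as germinated when its germ tube reaches half the body's
largest dimension; "germinating" denotes the intermediate state below
that criterion.

## Pulse-shape features

All support-based features use the bounding interval of samples strictly
above `baseline + f·(max − baseline)` with threshold fraction `f = 0.02`
by default and no smoothing.  With the canonical forward-scatter signal
defined as the per-sample mean of the two FWS detectors (falling back to
`FWS_L` alone):

| feature | definition | units |
|---|---|---|
| `fws_total`, `sws_total` | Σ samples over support × spacing | AU·μm |
| `fly_max`, `flo_max` | max over all samples | AU |
| `fws_length` | (support sample count) × spacing | μm |
| `fws_cvrmse` | 100 × RMSE of a single-Gaussian fit ÷ mean(support) | % |
| `fly_inertia` | Σ sᵢ(xᵢ−x_c)² ÷ (Σ sᵢ·(L/2)²) | – |
| `fly_fill_factor` | total ÷ (max × length) | – |

The vendor software that originally produced "inertia" and "fill factor"
does not publish formulas; the definitions above (normalised second
moment about the intensity-weighted centroid; bounding-rectangle
solidity) follow the verbal descriptions — inertia is high when signal
mass sits near the pulse edges, fill factor is 1 for a perfectly solid
rectangle.  Two conventions deserve note:

* **Inertia span.**  `L` is the span between the first and last support
  sample, `(count − 1) × spacing`.  With this convention the extremal
  configuration — two equal spikes at the support ends — is exactly 1
  and the bound `inertia ≤ 1` is tight (the centroid minimises the
  second moment); a uniform rectangle converges to 1/3 as O(1/n).  The
  alternative count convention makes the rectangle converge as O(1/n²)
  but the two-spike case only approach 1; the extremal case was chosen
  to be exact.  A single-sample support is a point mass and returns 0.
* **CVRMSE normalisation.**  RMSE is divided by the *mean* of the
  observed support samples (a coefficient of variation of the RMSE),
  expressed in percent.  Normalising by the signal range instead is
  plausible but indistinguishable from the published coefficient
  magnitudes; the mean convention is fixed here.

The Gaussian fit is nonlinear least squares (`scipy.optimize.
least_squares`) from moment-based starts (A = max, μ = centroid,
σ = √second central moment), bounds A > 0, σ > 0, μ inside the support,
relative tolerance 1e-8, at most 200 iterations; it needs at least four
support samples.  The fit is deterministic given these choices.  Note
that a flat-topped pulse whose support contains no flanks is fit almost
residual-free by a very wide Gaussian — a property, not a bug, of the
unbounded-σ model.

## Gating

Gates are convex polygons in log10 feature space (rectangles are
4-vertex polygons so one inclusive point-in-polygon routine serves
both): a fluorescence gate on (`fly_max`, `flo_max`) and a scatter gate
on (`fws_total`, `sws_total`).  Only particles inside **both** gates are
FDA-positive.  Gate coordinates are always calibration output, never
constants.  Calibration uses three control measurements mirroring the
wet-lab procedure — viable spores in filtrated medium, killed spores,
blank medium — and proceeds in two phases from symmetric quantiles of
the viable control (target capture 0.99): upper bounds are dilated
generously first (the viable population grows larger and brighter over
process time through swelling, germination and hyphal outgrowth, while
the background sits below the spores), then lower bounds are relaxed
toward the capture target; every dilation step is accepted only while
joint contamination from the dead and blank controls stays ≤ 1 %.
Calibration fails outright when the minimal gate already admits > 5 %
background.

Gated counts convert to concentrations as `count / volume × dilution`
with a default total dilution of 500 (1:10 staining step × 1:50
measurement step), matching inoculum concentrations of 2×10⁸–2×10⁹
spores/l.

## The germination classifier

The log-odds of "non-germinated" are linear in the five features:

    ln p(non-germinated)/p(germinated) =
        a0 + a1·FWS length + a2·CVRMSE + a3·FLY max
           + a4·FLY inertia + a5·FLY fill factor

Published coefficient sets ship for two FLY sensitivity (gain) levels,
50 and 65: (28.31, −0.337, −0.184, −0.006, 54.05, −59.54) and
(29.01, −0.346, −0.106, −0.001, 40.35, −52.44).  Scores above 0 classify
as non-germinated; the tie at exactly 0 breaks toward "germinated"
(conservative toward detecting germination onset).  Saturated FLY
signals are scored on the clipped value with a warning — the method's
remedy for saturation is a lower sensitivity level, not imputation.

`GerminationLogit.fit` refits by maximum likelihood (Newton/IRLS,
relative log-likelihood tolerance 1e-8, ≤ 100 iterations), reporting
standard errors from the inverse observed information, Wald z and p per
coefficient, and optional backward elimination until all retained
predictors have p < 0.05.  Complete separation is detected (all fitted
probabilities within 5e-5 of 0/1, or diverging coefficients) and raised
with the documented fallback: an L2 ridge (1e-6, intercept excluded).
Intermediate "germinating" particles map to the germinated class for
training; evaluation treats them by explicit policy (below).

Two practical caveats, both visible in the synthetic experiments:

* The published coefficients transfer only *qualitatively* to any data
  whose feature scales differ from the original instrument (the
  amplitude scale of FLY and the vendor's exact inertia/fill formulas
  are not recoverable).  On the simulator's default population the
  published model classifies small and germinated spores correctly but
  sits near its decision boundary for fully swollen (~25 μm) round
  spores — consistent with germination occurring at that diameter.
  Quantitative work on new data should refit.
* A training set restricted to one sampling time is nearly separable
  and yields unstable extrapolation (e.g. to hyphae); training pools
  samples over process time, as the original photograph-annotated data
  set did.

## Evaluation

Contingency tables keep the originating method's cell convention: the
positive class is *germinated*, `fp` counts germinated spores not
categorised as germinated (a miss in standard usage) and `fn`
non-germinated spores categorised as germinated (a false alarm);
accessors `miss`/`false_alarm` disambiguate.  The intermediate class is
handled by policy: `excluded` (default — reported error rates omit the
in-between spores), `as_germinated`, `as_non_germinated`, or
`best_case` (dual allocation: an intermediate is never an error).
Reported error is `100·(fp+fn)/total` rounded to one decimal; raw
values stay available.  When intermediates are frequent and the
classifier splits them, forced single-class policies report larger
errors than the excluded policy — the same divergence the published
validation shows at the germination-onset sampling point.

FCM-vs-CFU agreement is ordinary least squares of CFU on FCM counts
with R² as squared Pearson correlation (slope ≈ 1, R² ≈ 0.97 being the
benchmark for a trusted viable count).  Time courses report germinated
spores as a percentage of FDA-positive events per sampling time;
feature distributions are per-time class-split histograms normalised to
100 %.

## Synthetic data generator

The simulator emulates CytoSense-like pulse shapes so the entire
pipeline is testable without instrument data.  Study conditions are the
generator defaults:

* **Geometry** (positions in μm along the flow; 0.5 μm/sample): a round
  spore is a Gaussian lobe whose 2 %-threshold support equals its
  diameter (σ = d/(2√(2 ln 50))).  Spores swell linearly from 4 μm at
  inoculation to 25 μm — the germination diameter — over the lag phase,
  with 6 % lognormal per-particle diameter jitter.  A germ tube is a
  second, 0.4-amplitude lobe displaced downstream (particles align with
  the flow).  Hyphae are smoothed plateaus of 3–6 (unbranched) body
  lengths.  Dead spores stay small (3–6 μm); debris spans 2.5–8 μm.
* **Tube-length bands**: germinating U(0.25, 0.55)×body, germinated
  U(0.55, 1.8)×body.  The germination criterion is 0.5×, but a spore
  annotated "germinated" at a sampling point has typically elongated
  past it, and annotation exactly at the criterion is ambiguous — the
  boundary band is absorbed into the intermediate class.
* **Fluorescence**: per-class esterase activity (AU at unit gain) 40
  (non-germinated), 80 (germinating), 120 (germinated), 130 (hyphae),
  1.5 (dead), 3 (debris), rising through germination, with a wide 50 %
  lognormal per-particle spread — esterase activity is heterogeneous,
  and peak fluorescence alone must not separate the classes (its
  published coefficient, −0.006/AU, says it barely discriminated).
  FLO is 0.35×FLY; FLR is bright only for PI-stained dead spores.
  Sensitivity level 65 applies an 8× gain before clipping at the
  1023 AU ceiling (both package defaults; the instrument's digitiser
  scale and gain curve are not public).
* **Noise**: additive Gaussian with σ = 0.5 % of the lobe peak per
  sample, 10 % lognormal per-particle brightness jitter, 2 % relative
  mismatch between the two FWS detectors; negatives clip at zero.
* **Kinetics**: the germinated fraction is 0 through a lag, then
  `plateau·(2/(1+e^(−k(t−lag)))−1)` with k = ln 19/rise, so the curve
  passes 0.9×plateau exactly at lag+rise.  Young inocula (≤ 3 months):
  lag 15 h, rise 10 h, plateau 0.90.  Old inocula (≥ 8 months): rise
  20 h, plateau 0.55.  The intermediate band is a thin transition
  population, `0.25·g·(1−g/plateau)`, carved from the non-germinated
  side.  Past lag+rise, 15 % of the germinated mass appears as hyphae.
* **Mixture and artifacts**: default 70 % viable / 15 % dead / 15 %
  debris.  Two documented failure modes are injected: 2.9 % of
  germinated spores flow *upright* and present a single Gaussian-like
  scatter lobe (they are systematically misclassified as
  non-germinated, including by the published model), and 3.2 % of
  non-germinated spores carry an attached medium particle (a secondary
  bump that pushes them toward "germinated").
* **CFU plating** is a Poisson draw with mean `concentration × plated
  volume ÷ dilution`, refusing plates expected to exceed 10⁶ colonies.

Every stochastic operation takes an explicit seed or generator; equal
seeds give bit-identical output.

**What the simulator does not emulate** — and hence what passing tests
do not show about real data: optical point-spread blur and coincidence
doublets; fluid-dynamic orientation variability beyond the binary
upright artifact; spectral crosstalk between channels; autofluorescent
medium backgrounds that overlap the spore gates; branched-hyphae
morphology beyond plateau length; biological correlation between spore
size and esterase activity; and the real instrument's amplitude scale
and signal-to-noise ratio, which are unpublished.  Absolute error rates
measured on synthetic data are therefore statements about the generator,
not the instrument; the qualitative contrasts (round vs. two-lobe
pulses, rising FLY, the 25-μm transition, the artifact failure modes)
are what the generator is calibrated to reproduce.

## Problem sizes

The package's own reference computations use 100,000 synthetic
observations for coefficient recovery and 2,000 + 2,000 labelled
particles (plus 250 intermediates) with a 50 % train/test split for the
held-out error bound; control calibrations use 400 particles per
control, and the end-to-end demo simulates 2,000 particles at each of
six sampling times.  These sizes put Monte-Carlo error well below the
tolerances asserted and run in seconds to a couple of minutes on one
core.

## Known limitations

* The published coefficient sets are bound to the original instrument's
  feature scales; on any re-scaled data they are qualitative defaults.
* Gate calibration assumes the background (dead/debris) sits below the
  viable population in fluorescence and scatter; inverted backgrounds
  would need polygon gates set manually.
* The upright-artifact and attachment rates are fixed class-conditional
  probabilities, not mechanistic models of flow orientation.
* FCS export is write-only and covers integrated parameters, not the
  pulse shapes themselves (no standard FCS representation exists for
  per-particle curves).
* No multiclass (hyphal sub-stage) classification; hyphal forms are
  scored as germinated.
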
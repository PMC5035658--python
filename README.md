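# pulsegerm

At-line monitoring of fungal spore germination from flow-cytometric
pulse shapes.

Spore inoculum quality — how many spores are viable and how fast they
germinate — is a critical parameter of filamentous bioprocesses such as
*Penicillium chrysogenum* penicillin production.  Classical CFU plating
is slow and counts spores that germinate on agar, not the population
that actually germinates in the liquid bioreactor.  `pulsegerm`
implements the flow-cytometric alternative: a scanning cytometer records
a sampled intensity curve (*pulse shape*) per particle on scatter and
fluorescence channels; FDA viability staining lights up metabolically
active spores; and the pulse-shape morphology distinguishes round from
germinated spores directly in complex medium, sample-to-answer in
minutes.

The pipeline is

1. **features** — per-particle scalars from the pulse shapes: integrated
   scatter (`FWS total`, `SWS total`), peak fluorescence (`FLY max`,
   `FLO max`), signal length in μm, the quality of a single-Gaussian fit
   to the forward-scatter curve (CVRMSE, %), and the FLY *inertia* and
   *fill factor* shape factors;
2. **gating** — FDA-positive spores are the particles inside both a
   fluorescence gate on (FLY max, FLO max) and a scatter gate on
   (FWS total, SWS total), calibrated from control measurements (spores
   in filtrated medium, killed spores, blank medium); gated counts
   convert to spores/l;
3. **classify** — each FDA-positive spore is scored with the logistic
   model

       ln p(non-germinated)/p(germinated) = a₀ + a₁·FWS length
           + a₂·CVRMSE + a₃·FLY max + a₄·FLY inertia + a₅·FLY fill factor

   using published coefficient sets for two instrument sensitivity
   levels, or coefficients refit by maximum likelihood
   (`GerminationLogit` → `GerminationLogitResults` with standard
   errors, Wald tests and `summary()`);
4. **evaluate** — contingency tables against annotated truth,
   error rates, FCM-vs-CFU regression, germination time courses and
   per-time feature distributions;
5. **simulate** — a labelled synthetic pulse-shape generator (spore
   swelling, germ-tube growth, hyphae, dead spores, debris, orientation
   and attachment artifacts, germination kinetics, CFU plating) so the
   whole pipeline is testable without instrument data.

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

The `demo` subcommand runs the full synthetic pipeline — control
calibration, a six-point batch time course, feature extraction, gating,
a pooled refit, classification and evaluation:

```bash
pulsegerm demo --out demo_out --seed 7
```

prints

```
demo complete: error 1.9 % at t=25.0 h, artifacts in demo_out
```

and writes, among other artifacts, the germination time course
(`timecourse.csv`):

```
time_h,percent_germinated,n_fda_positive
2.0,0.07137758743754462,1401
10.0,0.21629416005767843,1387
16.0,15.120525931336742,1369
20.0,63.32129963898917,1385
25.0,82.01539538138559,1429
30.0,86.73323823109843,1402
```

Read: of ~1400 FDA-positive spores per sample, none had germinated
before the 15 h lag, germination was underway at 16–20 h, and ~87 % of
viable spores had germinated by 30 h — a young-inoculum batch
approaching its 90 % plateau.  The classifier behind those numbers was
refit on the pooled labelled samples (`fit_report.txt`):

```
term                    coef   std err        z    P>|z|
intercept            31.6936    4.4846     7.07 1.58e-12
fws_length           -0.1398    0.0306    -4.57 4.78e-06
fws_cvrmse           -0.3421    0.0745    -4.59 4.45e-06
fly_max              -0.0482    0.0030   -16.31 7.74e-60
fly_inertia          14.2672   20.6455     0.69     0.49
fly_fill_factor     -51.1736   13.5776    -3.77 0.000164
```

Longer signals, worse Gaussian fits and brighter FLY all push toward
"germinated" (negative coefficients on the non-germinated log-odds),
matching the sign pattern of the published model.  The 1.9 % error at
t = 25 h is the mid-germination contingency against simulator truth with
intermediate "germinating" spores excluded (`contingency.csv`).

The same steps are available as library calls
(`simulate_sample → extract_feature_table → gate_table →
GerminationLogit(...).fit() → classify_table → contingency/timecourse`)
and as individual subcommands (`simulate`, `extract`, `gate`,
`classify`, `fit`, `evaluate`, `timecourse`); every subcommand is a pure
function of its inputs, config and seed.

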
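# Methods

This note documents the models, algorithms and numerical choices behind the
`racir` package: what each stage assumes, which knobs matter, and what the
synthetic-data generator does and does not emulate.

## The measurement problem

A CO2 response curve (A–Ci curve) relates net assimilation A to
intercellular CO2 Ci and is the standard route to the photosynthetic
capacity parameters Vcmax (maximum Rubisco carboxylation rate) and Jmax
(maximum electron transport rate). Stepping the chamber through set points
takes 30–60 min per curve. The rapid alternative ramps chamber CO2
continuously — here a down ramp 420→20 ppm at 200 ppm min⁻¹ followed by an
up ramp 20→1520 ppm at 100 ppm min⁻¹, logged every 2 s — which cuts a curve
to ~20 min but means the reference and sample analyzers never see the same
air at the same time. In a large needle-and-leaf cuvette (193.7 cm³, 36 cm²
aperture, 600 µmol s⁻¹ flow) the mixing volume and plumbing introduce
reference-to-sample lags of tens of seconds, producing large apparent
fluxes that must be removed before fitting. Only the up ramp is used for
fitting; down-ramp records are discarded at the split stage.

## Gas-exchange bookkeeping (`racir.gasx`)

Standard open-system equations with a single lumped conductance (no
separate boundary-layer term, which the logs cannot constrain):

    A   = flow (c_r − c_s (1000 − w_r)/(1000 − w_s)) / (100 S)
    E   = flow (w_s − w_r) / (100 S (1000 − w_s))
    gtw = E (1000 − (W_leaf + w_s)/2) / (W_leaf − w_s)
    gtc = gtw / 1.6
    Ci  = ((gtc − E/2) c_s − A) / (gtc + E/2)

Units follow the instrument logs: CO2 in µmol mol⁻¹, H2O in mmol mol⁻¹,
flow in µmol s⁻¹, area in cm². W_leaf is the saturation water mole fraction
at leaf temperature from the Buck formula
e_s(T) = 0.61365·exp(17.502 T/(240.97+T)) kPa (the common instrument
default). The 1.6 water:CO2 diffusivity ratio is a module constant.

Zero or negative leaf area and out-of-range humidities raise typed errors;
physically degenerate records (no vapour gradient, non-positive
conductance, negative Ci) are *flagged* and carried along rather than
silently dropped. Leaf-area corrections — needed for non-flat conifer
shoots whose true area is measured after the fact — replace the area and
recompute every derived quantity from the raw fields; A and E are exactly
inversely proportional to area, Ci responds through the full recomputation.

## Quasi-linear selection (`racir.filtering`)

The filter implements the delta-threshold rule: consecutive-point changes
delta_i = A_i − A_{i−1} must satisfy |delta| ≤ 0.05 µmol m⁻² s⁻¹ (default).
Steady state is declared at the first run of `min_run_length` (default 10,
= 20 s) consecutive in-threshold deltas; everything before the point
anchoring that run is the lag block. After it, each point is compared to
the last kept point (default) or to its raw predecessor (config switch) and
rejected as an outlier if it jumps more than the threshold.

Two refinements beyond the bare rule, both off-by-default-able:

* `lag_pad` (pipeline default 30 points = 60 s): when deltas first fall
  inside ±0.05, an exponential mixing transient of amplitude up to
  ~threshold·τ/Δt ≈ 0.33 µmol m⁻² s⁻¹ may still be decaying; the pad lets
  it die out (τ ≈ 13 s, so 60 s ≈ 4.5 time constants).
* `min_kept_fraction` (default 0.5): a transient sweeping through its
  turning point momentarily has near-zero deltas and can fake a steady run;
  a run is accepted only if at least half of what follows survives the
  outlier test, otherwise the search continues.

The kept/lag/outlier sets always partition the input, and the filter is
idempotent on its own output in last-kept mode. Threshold monotonicity (a
larger threshold keeps at least as much) holds in predecessor mode for all
points except possibly the steady-state anchor itself, and the kept count
is always monotone; in last-kept mode a shifted anchor can reclassify
individual points, which is why both comparison modes are provided.

Leaf curves genuinely climb by ~0.1–0.3 µmol m⁻² s⁻¹ per 2 s log on the
Rubisco-limited rise, so the pipeline filters leaf ramps with a wider
default threshold (0.5) that still removes the mixing transient and
isolated spikes; the strict 0.05 default applies to empty-chamber curves,
whose artifact drifts slowly.

## Empty-chamber correction (`racir.ecrc`)

An empty chamber should show A = 0; the apparent flux it does show (mixing
lag, IRGA match offsets, residual delays) is smooth in reference CO2.
Polynomials of degree 1–3 are fitted to apparent A (computed with the
36 cm² nominal aperture) versus co2_ref by OLS — numerically in a scaled
domain, reported as raw ascending coefficients — and the degree is chosen
by BIC = n ln(RSS/n) + k ln n with k = degree+1 (Gaussian concentrated
likelihood; additive constants cancel in comparison). An RSS below 1e-12·n
is treated as exact and the lowest exact degree wins. Ties break to the
lower degree.

Correction subtracts the selected polynomial from the leaf curve's A at
each record's co2_ref. The polynomial is never extrapolated: records
outside the fitted domain are dropped, and if fewer than 20% survive the
correction refuses and advises a fresh empty-chamber curve. Because the
artifact is a chamber-level flux expressed at the nominal aperture, the
subtraction is scaled by nominal_area/leaf_area when the leaf curve's
fluxes are computed at a different area. Ci is then *recomputed* from the
corrected flux (not shifted additively) since Ci is nonlinear in A.

## FvCB model and fitting (`racir.fvcb`)

    Ac = Vcmax (Ci − Γ*)/(Ci + Km),  Km = Kc (1 + O/Ko)
    Aj = J (Ci − Γ*)/(4 Ci + 8 Γ*)
    A  = min(Ac, Aj) − Rd

with J the smaller root of θJ² − (αQ + Jmax)J + αQ·Jmax = 0 at the fixed
measurement light Q = 1200 µmol m⁻² s⁻¹. Kinetic constants default to the
widely used 25 °C values Γ* = 42.75 µmol mol⁻¹, Kc = 404.9 µmol mol⁻¹,
Ko = 278.4 mmol mol⁻¹, O = 210 mmol mol⁻¹, θ = 0.85, α = 0.24 — the
defaults of the common A–Ci fitting packages — and all are overridable. No
temperature response is implemented: all supported data are at 25 °C.
Branches combine by hard minimum; triose-phosphate limitation is not
modelled.

Fitting minimises Σ(A_obs − A_model)² by bounded trust-region NLS from
three starts (Vcmax ∈ {25, 50, 100}, Jmax = 1.9·Vcmax, Rd = 1 when free),
keeping the best converged solution; multi-start guards against
branch-assignment local minima. Rd is fixed when an independently measured
value is supplied (the recommended workflow) and estimated otherwise. RMSE
is reported on the fitted Ci range. The Rubisco/RuBP transition Ci is found
by root-finding on the branch *slope* difference — the (Ci − Γ*) factor
common to both branches is removed first, since otherwise every bracket
straddles the trivial intersection at Γ*. The CO2 compensation point has
the closed form Ci = (Γ* Vcmax + Rd Km)/(Vcmax − Rd) on the
Rubisco-limited branch (undefined for Rd ≥ Vcmax).

A dense 2-D grid search over (Vcmax, Jmax) serves as a brute-force oracle
in the tests; the NLS optimum is required to match it within one grid step.

## Chamber simulator (`racir.simulate`)

One well-mixed compartment plus a pure transport delay:

    n dc/dt = flow·c_in(t − D) − flow·d·c − 1e6·A(c)·S_m²

where n = PV/RT is the molar air content (7917 µmol at defaults —
193.7 cm³, 101.325 kPa, 25 °C), giving a mixing constant τ = n/flow ≈
13.2 s, and d = (1000−w_r)/(1000−w_s) is the transpiration dilution factor
that keeps the simulator mass-balance consistent with the instrument
equations used to invert its logs. The reference channel reads the
programmed ramp directly. The leaf is an FvCB demand curve intersected with
the diffusion supply A = (gtc − E/2)c − (gtc + E/2)Ci at a fixed total
conductance (default 0.12 mol m⁻² s⁻¹ — stomata are slow relative to the
ramp); each branch gives a quadratic in Ci solved in closed form, the
operative branch being the one with the larger Ci (verified against brentq
root-finding). Sample humidity is the steady solution of the chamber water
budget with small seeded jitter; humidity control-loop dynamics are not
modelled.

The residual system delay D defaults to 50 s: the two-parameter model must
reproduce both τ ≈ 13 s (set by volume/flow) and reference-to-sample lag
times of roughly 48–92 s observed with large conifer chambers, and
D = (observed mean lag 63 s) − τ places the simulated lag (58 s, measured
by cross-correlating first-differenced channels) at the centre of that
band. IRGA imperfections enter as an apparent-A offset polynomial in
reference CO2, injected through the sample channel at the equivalent CO2
magnitude for the nominal aperture, plus white noise per channel. The CO2
noise default (0.04 µmol mol⁻¹ SD per 2 s log) is chosen so that a ±0.05
delta filter sits at ≈3.8σ of consecutive-A noise — the level at which
such a threshold functions as a routine outlier rule, i.e. the level
consistent with instruments where it is used. Integration is explicit
Euler at a fixed 0.1 s step with mid-step input evaluation (τ ≥ 13 s makes
this stable; the tracking-offset error is ~0.4%), logged every 2 s. All
randomness flows from one seed; identical seeds give bit-identical curves.

What the generator deliberately does not emulate: water-vapour control-loop
oscillations (only white jitter), temperature transients, match procedure
dynamics (a constant is part of the offset polynomial), stomatal kinetics,
and multi-compartment analyzer plumbing. Passing the recovery tests
therefore shows the pipeline handles first-order mixing physics and static
analyzer offsets, not every pathology of field data.

### A known, physical residual bias

A static polynomial in co2_ref cannot represent the *dynamic* lag of a
changing leaf flux: after correction, A sags below truth by roughly
τ·dA/dt — ~0.8 µmol m⁻² s⁻¹ where the curve is steepest, fading to ~0 on
the plateau. The consequences match what is reported for rapid curves
measured at 100 ppm min⁻¹ in large chambers: slightly elevated CO2
compensation points, Vcmax biased low by a few percent when Rd is fixed at
its measured value (median ≈ 4% at the default conditions), an inflated Rd
when it is instead estimated from the curve, and Jmax nearly unaffected.
The package does not attempt a dynamic deconvolution; the bias is part of
the method being implemented.

## Pipeline and I/O

The standard workflow (`racir.pipeline.correct_and_fit`, also behind the
`racir` CLI and YAML-driven batch processing) is: split at the smoothed
co2_ref minimum and keep the up ramp → compute (apparent) A → filter ECRC
(threshold 0.05) and fit/select the correction polynomial → filter the
leaf curve (threshold 0.5) → optional leaf-area rescale → subtract the
artifact and recompute Ci → optional Ci-window exclusion (e.g. 450–600 ppm
artifacts) → FvCB fit over the full range and optionally a partial range
such as Ci ∈ [200, 800]. Every discarded record class (down-ramp, lag,
outlier, domain trim, Ci window) is counted and reported; batch entries
fail independently and the summary records the error.

Files are plain CSV with canonical column names (written round-trippable
to full float precision) or the two-header-row tab-delimited instrument
dialect; common instrument labels are mapped automatically and a
`ColumnMap` handles anything else.

## Problem sizes used in tests

Simulated curves are one full two-segment program (~20 min of instrument
time, 607 logs) per seed; end-to-end recovery uses 20 seed pairs, the
ECRC round trip 9 (3 degrees × 3 seeds), and the grid-search oracle 5
noisy instances on a 241 × 481 grid. The whole suite runs in a few
seconds on one core.
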
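# Methods

## Maturation model

Chromophore maturation is single-step first-order: a molecule of age `a`
is fluorescent with probability `1 − exp(−m·a)`, with one rate per
chromophore (`m_fast`, `m_slow`; half-time `ln 2 / m`).  Defaults are the
calibrated wing-disc half-times, 3 h (fast, GFP-like) and 6 h (slow,
Cherry-like).  No dark/intermediate chromophore states and no
photobleaching are modeled; only half-times are ever fitted, so extra
states would be unidentifiable.  All fluorescence is reported normalized
so that a fully matured pool has ratio 1 — per-fluorophore brightness and
detector gain cancel in every quantity the package outputs.

For a synthesis pulse of duration `D` (default 1 h) at constant rate with
no degradation, integrating over cohorts gives the normalized matured
fraction

```
f(t) = [t − (1 − e^{−mt})/m] / D          t ≤ D
f(t) = [D − e^{−mt}(e^{mD} − 1)/m] / D    t ≥ D
```

and the calibration curve is `r(t) = f_slow(t)/f_fast(t)`, strictly
increasing from `m_slow/m_fast` to 1.  An expression-onset lag parameter
exists and defaults to 0: pure first-order maturation does not reproduce
a ~2.5 h first-detection delay of the fast channel, which likely reflects
detection thresholds and transcription/translation delay rather than
maturation kinetics; we do not attempt to model it.

A constitutively synthesized pool that exits with first-order rate `k`
has an exponential age distribution, matured fraction `m/(m+k)` per
chromophore, and ratio `R(k) = [m_s/(m_s+k)]·[(m_f+k)/m_f]`, inverted
algebraically by `k = m_s m_f (1−R)/(R m_f − m_s)`.

## Trafficking model

Per region, protein enters a basolateral membrane pool B at rate σ,
transfers apically at `k_exit` (mean basolateral residence time
`τ_B = 1/k_exit`), and is degraded apically at `k_deg`:

```
B'    = σ − k_exit B          Bmat' = m (B − Bmat) − k_exit Bmat
E'    = k_exit B − k_deg E    Emat' = k_exit Bmat + m (E − Emat) − k_deg E mat
```

(one matured pair per chromophore).  The system is linear; the ODE is
integrated with LSODA at rtol 1e−8 with an auxiliary cumulative-degradation
state for mass-balance checks, and the closed-form steady state
(`B = σ/k_exit`, `Bmat = mB/(m+k_exit)`, `E = σ/k_deg`,
`Emat = (k_exit Bmat + mE)/(m+k_deg)`) serves as its oracle.  The model
assumes all protein transits the basolateral membrane before apical
degradation ("all-transit"); inferred membrane ages are therefore upper
bounds on τ_B if some protein is routed directly to degradation.
Acidic quenching is multiplicative per pool: apical fluorescence of
chromophore f is scaled by `q_f_acidic` (defaults: fast 0.0, slow 1.0);
the ammonium-chloride condition sets both to 1.

## Two inversion methods, and why they differ

The default residence readout (`curve_lookup`) reads the measured membrane
ratio off the pulse calibration curve, mirroring the experimental
procedure.  A steady-state membrane pool is an exponential *mixture* of
ages, and matured amounts weight old cohorts, so the single-age curve
readout systematically exceeds the mean residence `1/k_exit`; the
closed-form `steady_state` inversion recovers `1/k_exit` exactly and is
reported alongside as a cross-check.  Both are monotone transforms of the
same ratio, so regional orderings always agree.

This distinction drives the wild-type generator defaults.  The regional
readouts to emulate are curve-lookup values (~8 h posterior, ≤4.5 h ptc
band, ≤2 h far anterior, a roughly two-fold Hh-dependent contrast), so the
generator encodes membrane ratios that invert to those values: latent
residence times τ_B = 6.0 h (P), 2.2 h (ptc band), 0.7 h (far anterior),
giving steady-state ratios 0.705 / 0.601 / 0.537 and curve readouts
≈ 8.0 / 4.0 / 1.7 h.  These latents are this package's modeling choice,
not measured values.  σ = 1 unit/h and k_deg = 0.5 /h everywhere: regional
Smo differences are carried by residence time alone, which suffices for
every ratio- and ordering-level readout (absolute intensities are
arbitrary units).

## Synthetic disc generator

Geometry: 60 × 60 µm field at 0.2 µm/px, cells of 2.5 µm diameter on a
hexagonal-ish lattice, A/P boundary at mid-field, ptc band = 3 cells
immediately anterior (x increases anterior→posterior; masks are 0-based,
half-open).  Two 2-D sections stand in for apical and basolateral
confocal planes — all quantified measurements are per-section, so no 3-D
stack is needed.  Channel order is fixed: fast, slow, hh, rab7, membrane.
A dedicated Hh channel is used because the fast (GFP) channel of the
timer is quenched apically and cannot double as the Hh marker.

The basolateral section draws each region's `Bmat` per chromophore on a
1-px-dilated cell-outline lattice; the apical section draws Smo puncta
(Gaussian spots, σ = 0.4 µm) splitting the quenched `Emat` amounts, Hh
puncta partitioned 95%:5% posterior:anterior, and Rab7 puncta (σ =
0.65 µm, enclosing their cargo) centered on a chosen fraction of Hh
puncta — 85% of anterior and 50% of posterior Hh intensity — plus
unpaired Rab7 kept away from Hh so realized overlaps stay within 0.02 of
intended.  Everything is blurred with a Gaussian PSF (σ = 0.15 µm) and
passed through a Poisson–Gaussian detector model (shot noise scaling
1/4 unit per count equivalent, read noise sd 0.5, background offset 2);
amplitudes are set well above this floor, as in well-exposed confocal
data.  One integer seed fixes all randomness; identical seeds give
bit-identical images.

What the generator does *not* emulate: cell-shape variability, z-axis
structure, chromatic shift, uneven illumination, autofluorescence
texture, and biological punctum-intensity heterogeneity beyond the
per-region pool split.  Passing recovery tests therefore shows the
estimators are correct for this noise and geometry model, not that they
are robust to every real-microscope artifact.

## Quantification choices

* Background: 5th-percentile subtraction, floored at 0 (region-wise where
  a region is specified).  The residual after flooring is positive
  (~1.6× the noise sd), so generator amplitudes are large relative to
  noise, as the partition example requires.
* Colocalization is intensity-weighted (Manders M1: fraction of signal
  intensity inside the partner channel's Otsu mask), not Pearson, because
  the quantity of interest is "proportion of signal that overlaps".  The
  Otsu mask is dilated 2 px so the blurred skirt of a perfectly
  colocalized object is not clipped (without dilation the estimator is
  biased low by ~5 pp).  CIs bootstrap over detected puncta.
* Puncta detection: scale-normalized LoG at the generator spot scale,
  Otsu threshold on the response, connected components, intensity-weighted
  centroids, sorted for determinism.
* Membrane ratio: membrane pixels come from the membrane-marker channel
  (Otsu → skeleton → dilate 1 px); external data may supply a mask
  instead.  Region masks are eroded 6 px before measuring because cell
  outlines straddling a region boundary carry mixed signal from both
  regions and otherwise bias the ratio by ~0.005.  Per-channel background
  is the mean over region pixels > 4 px from the membrane; its standard
  error is propagated into the pixel bootstrap (otherwise CIs undercover
  in the dim far-anterior region).  Regions whose fast channel is within
  5 standard errors of background report "undefined" rather than a
  number — the quenched/undetectable-GFP regime.
* Ratio is slow/fast (Cherry/GFP) everywhere; the calibration constant
  (ratio of an infinitely old pool) defaults to 1 because generator units
  are equal-brightness.

## Numerical details

ODE: LSODA, rtol 1e−8, atol 1e−10, negative round-off clipped at 0.
Curve inversion: PCHIP interpolation of the strictly monotone grid +
Brent bisection, xtol 1e−6 h; ratios at/beyond the curve range raise a
flagged error ("younger than resolution" / "older than horizon") instead
of returning a number.  Maturation fit: joint least squares of both
channels (shared amplitude, per-channel log-rate), initialized from the
half-rise time per channel and plateau amplitude, with 3 jittered
restarts on failure; CIs by residual bootstrap (200 resamples, seeded).
Fold-change CIs combine interval endpoints.  A single run seed fans out
to per-stage child seeds via SHA-256, all below 2³¹.

## Preset scenarios

`wild_type` as above; `disp_mutant` sets both anterior regions to the
short far-anterior residence (no Hh reaches the anterior); `hh_cd2`
raises anterior residences toward posterior values (membrane-tethered
Hh); `nh4cl` neutralizes quenching; `uniform_turnover` gives every region
identical parameters — the null in which the timer cannot distinguish
regions; `usp8_dorsal` halves dorsal `k_exit` and renders the state 6 h
into the transient from the wild-type steady state, because the apical
slow-pool decrease is a transient-approach effect (at the new steady
state apical totals return to σ/k_deg).

Directional contrasts are stated at the level the model supports: under
fixed synthesis, lowering residence time lowers *every* matured-slow
amount (faster transit shortens protein lifetime, bounding total slow
maturation), so "relatively more Cherry" in fast-turnover genotypes is
expressed as the apical-slow : basolateral-fast contrast rather than as
an absolute Cherry increase; absolute fast-channel (GFP) directions are
preserved.

## Problem sizes

Default images are 300 × 300 px × 5 channels × 2 sections; pulse series
are 49 time points × 2 channels × 3 replicates; bootstraps use 500
(pixel), 1000 (puncta) and 200 (fit) resamples.  These sizes keep a full
pipeline run under ~2 s while leaving every estimator's sampling error
well inside its test tolerance.

## Known limitations

Residence estimates are upper bounds under the all-transit assumption;
σ and k_deg are not identifiable from a single ratio and are never
inferred; the generator's intensity scale is arbitrary; embryo stripe and
myoblast geometries are out of scope (the quantification operators apply,
but no generators are provided); Pearson-style pixel correlation and cell
segmentation are deliberately absent.
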
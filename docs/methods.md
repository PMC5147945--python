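# Methods

This note records the statistical model behind `conjuqc`, the defaults that
matter, the design choices made where the protocol leaves the design open, and
what the synthetic-data tests do and do not demonstrate about real instrument
data.

## Scales and decoding

The canonical in-memory scale is linear relative fluorescence. Channels stored
under a log amplifier (`$PnE` with positive decades) are decoded exactly once,
at read time, by the standard transform `10^(decades·x/max_channel)`, which maps
channel 0 to 1.0 and full scale to `10^decades`. Every downstream statistic —
geometric means, CVs, the MESF regression — is defined on linear intensities.
Whether vendor analysis software computes its statistics on channel (log) or
linear values is not observable from the outside; the linear convention is this
package's declared choice, and the CV values it produces correspond to the
linear-scale convention (`CV% = 100·sqrt(exp(σ²)−1)` for a lognormal peak of
log-shape σ).

## Singlet gate

The bead population is selected by a deterministic axis-aligned box on
FSC×SSC. A bare "median ± k·MAD" box fails on multimodal scatter: for a
balanced two-cluster cloud the coordinate-wise median falls in the empty gap
between clusters and the global MAD spans both, so the box keeps everything.
The gate therefore seeds at the robust mode — the densest bin of a coarse 2D
histogram, ties broken toward the bin nearest the joint median — and then
iterates centre = per-axis median of the kept events, half-width = k·1.4826·MAD
of the kept events, to a fixed point (bounded at 100 iterations; degenerate
zero-MAD axes get an epsilon floor so half-widths stay positive). The fixed
point makes the gate idempotent and locks it onto a single cluster. The default
k = 4 keeps ≥ 95% of a Gaussian singlet cloud while excluding doublets at ~2×
scatter essentially completely; k is configurable. Doublet handling is by the
scatter gate only — the wet protocol relies on vortex/sonication plus the
scatter gate, and no fluorescence-based doublet discrimination is attempted.

Acquisitions with fewer than 2000 gated events (configurable) are flagged, not
dropped: the minimum-event rule is an acquisition-quality statement, and the
caller decides what to do with a flagged tube.

## Histogram statistics

* FI is the geometric mean `exp(mean(ln v))`. Non-positive intensities (possible
  after baseline subtraction in other pipelines) are excluded with a recorded
  count; if more than 1% of events are excluded the statistic carries a flag.
* CV% uses the n−1 denominator on linear intensities. A robust alternative
  (`100·0.7413·IQR/median`) is available but not the default.
* The positivity threshold defaults to the 99th percentile of an uncoupled-bead
  control, so a sample identical to its control reads ~1% positive. The
  protocol uses uncoupled-bead controls without defining the threshold; the
  99th percentile is this package's choice and is configurable.

## MESF calibration

The calibration is OLS of `log10(assigned MESF)` on `log10(measured GM)` over
the non-blank standards — the standard quantitative-cytometry model for a
log-log-linear kit. The certified blank is excluded from the fit and defines
the lower detection limit (the model evaluated at the blank's GM); the upper
limit is the brightest standard's measured GM. Samples above the upper limit
get a numerically extrapolated MESF plus a hard non-evaluable flag, and all
MESF-based stability statements exclude them — their stability is assessed on
raw FI, with an "FI-only" provenance tag in rankings. The calibration is
refitted from the concurrent standards tube at every timepoint, because the
standards are acquired immediately after the samples under identical settings.

The kit's certified MESF assignments are lot-specific and never hard-coded: the
synthetic defaults (GM levels 2/30/65/278/1443 on the line
`log10(MESF) = log10(GM) + 2`) are explicitly labelled synthetic and exist so
the pipeline is exercisable without a lot file.

## Instrument drift and attribution

Per timepoint, each standard's relative deviation from baseline
`(GM_t − GM_0)/GM_0` is computed. A timepoint is attributed to the instrument
only when **all** non-blank standards move in the same direction beyond the
tolerance (default 10%, configurable): a coherent shift of four independent
bead populations is the signature of a sensitivity change, while a lone
deviating standard raises an inconsistent-standard warning instead. Conjugate
series never label a timepoint "instrument" unless the standards flag is set
for that month.

ΔFI = initial − final FI and the percent decrease use the first and last
non-excluded timepoints, excluding drift-flagged months; the raw full-span
values are kept alongside (`delta_fi_raw`), since whether a manual analysis
includes such months in endpoint arithmetic is ambiguous and both are defensible.
The overall attribution verdict is a "true conjugate decrease" when the
endpoint decline over non-flagged months exceeds the same drift tolerance.

## Decision rules

* **Concentration choice**: the level maximizing mean replicate FI is chosen
  when its mean CV is within a 15% relative slack of the panel minimum
  (`cv_conflict_slack`); a clearly lower-CV different level triggers an
  explicit FI/CV conflict verdict rather than a silent choice. A non-significant
  ANOVA across levels yields "no level preferred" with the lowest level as the
  conservative default. Dilution series run through the same operation with
  dilutions as ordinal levels; when CVs are flat across dilutions the FI
  criterion alone decides.
* **Homogeneity**: Welch's two-sided t-test on replicate CVs of the lowest vs.
  highest level. Welch rather than pooled is the default (safer under unequal
  variances; pooled available by flag). No multiple-testing correction by
  default, matching the per-comparison α = 0.05 convention; Holm is available
  but off.
* **Stain integrity**: retention = exposed FI / protected FI per channel. A
  FITC-secondary-stain retention below 75% means the antibody itself left the
  bead — verdict "uncoupling/degradation" regardless of PE. Otherwise PE
  retention below 50% is "fluorochrome fading", and both retained is "stable".
  The 50%/75% defaults separate the observed fading regime (PE retention
  ~8–10%, FITC retention ~78–90%) from genuine uncoupling by a wide margin and
  are configurable.

## Synthetic-data generator

Single-bead fluorescence is lognormal — the single noise family — matching the
unimodal log-scale peaks of bead histograms and keeping closed forms available
(sample GM → gm, CV% → `100·sqrt(exp(σ²)−1)`). Scatter is normal per axis
(FSC 500 ± 8%, SSC 300 ± 10% by default, clipped at 0); doublets are exact 2×
aggregates of scatter and fluorescence at a default 2% rate — the simplest
mechanism that exercises the gate. Conjugate decay is geometric per month
(positivity preserved over long horizons); the default study spans months 0–18
with total decreases of 30%/79%/77% for conjugates A1/A2/A3, initial GMs
1633.3/1200/950, and a 20% multiplicative instrument dip over months 4–7
applied to every population, standards included. Bead codes sit 10-fold apart
in FL4 (50/500/5000) with σ_log 0.15. Default tube sizes are 3000 events per
conjugate tube and 2000 per standard population (1500 in the repeated-seed
tests and the acceptance script, to keep the runs quick at equal power for the
properties being checked).

All randomness flows through one integer seed (a single `numpy` Generator per
simulation call), so identical configuration + seed is bit-identical.

What the generator does **not** emulate: electronic/photon-counting noise on
top of the lognormal shape, spectral spillover between channels, log-amplifier
digitization artifacts, bead aggregation beyond exact doublets, carryover
between tubes, or day-to-day voltage adjustments. Passing tests therefore show
that the pipeline's estimators and decision rules are correct under the stated
generative model, not that real instrument idiosyncrasies are handled; the I/O
layer's log-decoding and the robust gate are the components that would absorb
the first two in practice.

## Numerical choices and degenerate inputs

* Geometric means and the calibration operate in log space throughout; no
  intensity smaller than machine-positive reaches a logarithm (non-positives
  are excluded up front).
* Two-point calibrations are solved exactly rather than via the regression
  routine (R² is 1 by construction).
* Zero-variance group comparisons: identical constant groups return an
  undefined-test flag (p = NaN, not significant) rather than a division error.
* Gate boxes on zero-spread axes get an epsilon half-width floor so the
  half-width invariant (> 0) holds even for all-identical scatter.
* Interval classification uses half-open `[lo, hi)` intervals; auto-derived
  code bounds place boundaries at log-space geometric midpoints.

## Known limitations

* No compensation/spillover handling, FCS ANALYSIS segments, or instruments
  with more than the five canonical channels.
* The gate is an axis-aligned box; strongly correlated or non-convex scatter
  populations would need an ellipse or density gate.
* MESF values are not converted to antibody-binding capacity, and no
  cross-instrument harmonization is attempted.
* Shelf-life extrapolation (e.g. Arrhenius modelling) and control charting are
  out of scope; the stability analysis is descriptive over the observed span.
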
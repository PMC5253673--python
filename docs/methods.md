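# Methods

This note documents the models, conventions and numerical choices behind
`irheat`, in the order the pipeline uses them.

## Fluorescence thermometry

The thermometer is a red fluorescent reporter whose emission decreases
linearly with temperature over the calibrated window 15–40 °C:

    F(T) = F_ref · (1 − s · (T − T_ref)),

with sensitivity s ≈ 0.017 per °C (1.7 %/°C) and normalization anchor
T_ref = 20 °C. `fit_sensitivity` normalizes measured totals to the value
at (or linearly interpolated at) T_ref and fits an ordinary least-squares
line; s is the negated slope. The fit is invariant to uniform rescaling
of all fluorescence values, so camera gain does not matter. Temperatures
outside the window are rejected rather than extrapolated. Two distinct
temperatures are accepted (the slope is then a two-point estimate and a
warning is emitted); a single temperature is a degenerate-fit error.

**Ratio inversion.** An ON/OFF image (or per-cell total) ratio R is
converted to an elevation by inverting the linear law anchored at the
ambient temperature T_b:

    ΔT = (1 − R) · (1 − s · (T_b − T_ref)) / s.

This is exact under the model. The common approximation ΔT = (1 − R)/s is
exposed via `naive=True` and coincides with the exact form when
T_b = T_ref. Apparent cooling (R > 1) beyond a 0.5 °C tolerance is
returned as a negative elevation with a warning, never silently clipped:
moderate negative values are expected from noise and carry information.

**Temperature maps.** Both images are reduced by a non-overlapping block
mean (default 3×3; remainder rows/columns dropped — the simplest reading
of "downsample by 3×"), background subtracted, and divided. The
background estimate is the mean of a user-supplied background ROI when
available, otherwise the mode of a 256-bin intensity histogram with a
robust spread (1.4826·MAD). Grid cells whose OFF signal after subtraction
falls below a validity floor of 5× the background spread of a block mean
are masked (NaN): ratios there are dominated by division noise. On
noiseless synthetic scenes the interior of the map reproduces the
block-meaned truth field to ~1e-9 °C; cells straddling the sheet edge
carry partial-coverage bias, which is why map consumers should stay a few
grid cells inside the valid mask.

**Distance binning.** Independent per-cell measurements are pooled into
half-open distance bins [k·w, (k+1)·w) with w = 2 μm by default. Each bin
reports the mean, standard deviation (0 for a single member) and count.
The representative distance is the mean member distance, not the bin
centre — this removes most of the discretization bias that a centre
convention would feed into downstream decay fits.

## Heat-field model

The laser heat field is phenomenological, not a conduction PDE:

- focal elevation is linear in power, ΔT(0) = k·P with k ≈ 4 °C/mW
  (the raw regression estimate 4.1 °C/mW is kept as a separate named
  constant; neither is silently preferred);
- the in-plane profile is a base-2 exponential, ΔT(r) = k·P·2^(−r/r½),
  parameterized directly by the half-maximal distance r½ ≈ 11 μm
  (equivalently an e-folding length r½/ln 2 ≈ 15.9 μm). Profiles at
  different powers therefore collapse onto one curve when divided by
  power;
- switching transients are first-order: heating
  ΔT(t) = ΔT_ss·(1 − e^(−t/τ)), cooling symmetric. "Steady state within
  500 ms" is operationalized as ≥95 % of the asymptote at 500 ms, fixing
  the default τ = 500/ln 20 ≈ 167 ms. The 95 % level is a declared
  convention; τ is configurable.

The axial (z) dimension is not modelled; all distances are in-plane,
matching how the calibration measurements are taken.

**Slope fit.** `fit_power_slope` regresses (T − ambient) on P with the
intercept fixed at zero by default — elevation must vanish at zero
power — with a free-intercept option retained as a diagnostic.

**Spatial fit.** `fit_spatial_profile` jointly fits A_p·2^(−r/r½) across
all powers with the plateau fixed at zero elevation: one shared r½, one
amplitude per power. Initialization: r½ from the first pooled
(amplitude-normalized) crossing below 0.5, amplitudes from the innermost
bin; bounds keep all parameters positive. The fit uses
`scipy.optimize.least_squares`; non-convergence raises an error carrying
the start point and residuals. A collapse diagnostic reports the relative
RMS departure of the fitted amplitudes from strict proportionality to
power (≲0.5 % under the default noise model). Each power needs ≥4
distance bins.

**Pulsed operation.** A schedule (frequency f, pulse width w, peak power
P_pk) has duty cycle f·w/1000 and time-averaged power P_pk·duty. When
pulses are short relative to the thermal response (w < 3τ) the attained
per-pulse peak is scaled by the step response at w; the planner's
ablation mode still reports the steady-state focal aim ambient + k·P_pk,
the conservative figure for damage assessment.

## Parameter planning

**Induction.** Given a band (T_low, T_high) — default 32–34 °C, the range
giving a robust heat-shock response with high viability — and ambient
T_a < T_low, the feasible power interval is
[(T_low − T_a)/k, (T_high − T_a)/k]. The plan takes the midpoint
(symmetric margin against under- and over-shoot); `edge="low"` reproduces
the band-lower-edge choice used in practice (3.0 mW at 20 °C ambient).
Feasibility additionally requires the predicted absolute temperature at
the nearest neighbour, T_a + k·P·2^(−d/r½), to stay below T_low. The
neighbour distance is per-embryo geometry and must be supplied; it has no
default. `classify_cells` labels arbitrary cell positions induced /
sub-threshold under a feasible plan and is monotone in distance.

**Ablation.** The focal cell must reach a lethal temperature (default
50 °C — a convention: the package exposes it as a parameter; prior
continuous protocols computed at 50–70 °C destroyed cells) while pulsing
keeps time-averaged neighbour heating below the induction threshold. The
default schedule is 6 Hz / 8.3 ms / 13 mW for 10 s (duty ≈ 5 %,
averaged power ≈ 0.65 mW).

## Morphometrics

Neurite length is the summed Euclidean length of consecutive annotated
3-D points; it is invariant under rigid transforms and bounded below by
the endpoint chord. Developmental stage is the tail-to-head distance
mapped linearly from the comma-stage anchor (0) to the 2-fold anchor (1);
the tail-to-head metric is taken as the straight-line 3-D distance
between landmarks (chord, not arc — the curvature handling is a
documented convention). Values outside [0, 1] are clamped with a warning
rather than rejected. Growth curves pair stage with length per timepoint;
unstaged timepoints (neurite not visible) are omitted, never
interpolated.

Group comparisons estimate per-curve outgrowth onset as the first stage
with length above 1 μm (the initiation criterion is a convention; no
numeric threshold exists in the field) and rate as the least-squares
slope beyond onset; group differences carry seeded percentile-bootstrap
95 % CIs (default 1000 resamples of curves within groups).

Division-timing comparisons are paired treated-minus-control differences;
the untreated control condition uses absolute left/right differences
(natural bilateral asymmetry). The percent cell-cycle increase is the
per-embryo mean of (treated − control)/control cycle times, requiring
both cycle fields. Induction-kinetics curves divide each embryo's
intensity series by the imaging laser power before averaging across
embryos, aligning mismatched time grids by nearest timepoint within a
tolerance.

## Synthetic data

The generator emulates the statistical structure the analyses assume:

- **Scenes**: cells are uniform-intensity discs with 1-pixel Gaussian
  edge softening on a flat background (no real cell appearance model is
  needed for ROI summation); the mapping scenes use an overlapping disc
  grid forming a confluent sheet with a background margin. Default scene:
  160×160 px at 0.25 μm/px, 2000 counts/px cell signal over 100 counts
  background.
- **Noise**: Poisson shot noise plus Gaussian read noise (sd 3 counts by
  default, both switchable). Defaults were chosen so a per-cell ΔT
  estimate scatters by ≈0.3 °C, the regime visible in per-cell in-vivo
  measurements; the per-cell measurement generator injects that 0.3 °C
  directly.
- **Physics**: images follow the linear fluorescence law exactly;
  ON-image temperatures come from the base-2 decay field; truth maps,
  per-cell truth columns and generative parameters are always returned.
- **Tracks and timings**: neurites grow along straight 3-D lines at a
  constant rate after an onset stage (point lists reproduce the scheduled
  length exactly; optional Gaussian length jitter is off by default);
  division timings pair a between-embryo baseline (sd 8 min) with a
  treated-side delay plus natural left/right noise.

Every generator is bit-reproducible given its seed. What passing tests on
these data do **not** show: robustness to focus drift, embryo twitching,
out-of-plane fluorescence, photobleaching, non-Poisson camera artifacts,
or deviations of the true heat field from the exponential model — none of
which the generator simulates.

## Problem sizes and tolerances

The test suite and the acceptance script run at the study's own scales:
calibration series of 11 temperatures (15–40 °C in 2.5 °C steps); 40
cells per power at three powers (2, 3, 4 mW) with distances uniform in
[0, 35] μm for decay fits; 8 power levels × 5 replicates (sd 0.5 °C) for
slope fits; n = 50 embryo pairs for division-delay recovery; 160×160 px
noiseless scenes for the thermometry round trip. Under these conditions
the fits recover generating parameters to ≤1e-6 relative error without
noise and within 10 % (half-distance, slope) or 5 % (sensitivity,
amplitude proportionality) with the default noise.

## Known limitations

- The heat field is phenomenological; no conduction, geometry or
  absorption modelling, and no axial profile.
- ROIs are inputs; there is no segmentation or tracking.
- The planner treats neighbour geometry as a single nearest-neighbour
  distance (full per-cell classification is available separately) and
  does not model the empirical spread of induction efficiency.
- The stage clock assumes linearity between its two anchors.
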
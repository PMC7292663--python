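# Methods

This note documents the models implemented in porekit, the defaults and why
they were chosen, what the synthetic-data generators do and do not emulate,
and the numerical choices that matter.

## Bilayer biophysics

**Sign convention.** All voltages are cis relative to trans (cis = the
protein-addition chamber).  Under this convention the Nernst potential is
E = (RT/zF)·ln(a_trans/a_cis): a cis-rich gradient of a permeant cation
pulls E_rev negative.  The bi-ionic GHK form, with zero anion permeability,
is E_rev = (RT/F)·ln(p_trans·a_trans/(p_cis·a_cis)), solved for
p_cis/p_trans with the trans ion normalized to 1.0.  Consistency between
the two (GHK degenerates to Nernst for identical species) is asserted in
tests.

**Temperature.** Bilayer work at the bench is commonly at room temperature,
so the default is 295.15 K (22 °C), overridable everywhere through
`PhysConstants`.  The Na⁺:K⁺ bi-ionic ratio from a −2 mV reversal rounds to
1.1 at any temperature from 20–25 °C.  The choline⁺:K⁺ ratio from +60 mV is
more delicate at one significant figure: exp(−60 mV/(RT/F)) is 0.093 at
20 °C, 0.095 at 22 °C and 0.097 at 25 °C, so the conventional one-figure
value 0.1 is obtained at 25 °C while cooler temperatures round to 0.09.
The worked examples and the reproduction script therefore evaluate the
monovalent ratios at 25 °C; either way the channel passes choline⁺ about an
order of magnitude worse than K⁺.

**Activities.** Single-ion activity coefficients default to the Davies
equation at 25 °C (A = 0.5092 (mol/L)^−1/2), log₁₀γ = −A·z²·(√I/(1+√I) −
0.3·I), with an explicit-γ override for users working from published
activity tables.  Gradient-style inputs (e.g. a 1.95-fold cis:trans Ca²⁺
activity gradient) can be passed directly as concentration ratios with
γ = 1.

**Lewis relation.** ΔE_rev = (RT/2F)·ln(1 + (p_Ca/p_K)·4[Ca²⁺]/[K⁺]) in
monovalent excess.  The implementation returns the magnitude of the shift;
the direction (negative-going for cis additions under our convention) is
the caller's bookkeeping, because the relation itself is unsigned.  The
inverse uses expm1/log1p and round-trips with the forward form to ≤1e−9
relative error.

**Reversal-potential estimation.** The bench procedure — adjust the voltage
until the current reads zero — is implemented as an ordinary least-squares
line I = G·(V − E_rev) over a user-chosen time window of an I–V record;
E_rev is the fitted zero-crossing, G the slope (pA/mV ≡ nS), with residual
RMSE reported.  A linear open-channel I–V is assumed within the window; a
window containing only one commanded voltage is rejected as unidentifiable.
The conductance fold-change across a pH event is the ratio of per-window
fitted slopes, refusing to divide by a before-conductance at or below a
configurable noise floor.

## Trace analysis

**ΔF/F₀.** F₀ is the mean of the first three recorded frames of each cell
(configurable via `n_baseline`), and ΔF/F₀ = (F_t − F₀)/F₀.  The
three-frame average is used as the primary definition (some descriptions
conflate it with the t = 0 frame; the average is the explicit one).  The
statistic is invariant under multiplicative gain and equivariant under
baseline shifts, both asserted as property tests.

**Onset detection.** Visual identification of a "sustained rise" is
replaced by a reproducible rule: onset is the first frame where ΔF/F₀
exceeds median + k·MAD of the first `baseline_window` frames for at least
`min_consecutive` consecutive frames.  Defaults: k = 5, baseline_window =
12 frames, min_consecutive = 3.  A zero-spread (noiseless) baseline makes
the MAD rule degenerate; the detector then falls back to an absolute floor
(default 0.2 ΔF/F₀, exposed as `zero_spread_floor`).  For sensors with
small dynamic range — a membrane-voltage reporter plateaus near 0.2–0.3
ΔF/F₀ — the floor should be set below the per-frame rise increment; the
exact-lag tests use 0.02.  On ramp signals, threshold crossing happens a
fraction (threshold/plateau) into the rise time, so detected onsets on
noisy low-amplitude channels are biased late by design; this is a property
of any threshold rule, and the lag analyses in the tests quantify it at
zero noise where the recovery is exact.

**Lysis.** First frame where the membrane-impermeant dye's ΔF/F₀ exceeds a
step threshold (default 1.0) for 2 consecutive frames.

**Population summaries.** Per-condition mean ΔF/F₀ at requested timepoints;
cells not spanning a timepoint are excluded and counted, never
interpolated, matching per-cell dot-plot semantics.  `fold_vs_reference`
is the ratio of condition means of per-cell ΔF/F₀ and is reported as NaN
when the reference mean is indistinguishable from zero — a fold against a
flat reference is not a meaningful number.  Consequently the fold-recovery
preset gives the reference condition a small late plateau (1.0) against the
risk-variant-like 2.5, putting the programmed fold at 2.5.

## Imaging quantification

**Segmentation recipe.** Gaussian smoothing (σ = 2 px), Otsu global
threshold, hole filling, removal of objects ≤ 30 px, then a
distance-transform watershed seeded at local maxima (min separation 7 px)
to split touching nuclei.  Cell proxies are nucleus labels expanded by a
fixed radius (default 15 px at the synthetic pixel scale) with contested
pixels assigned to the nearest nucleus, so label count is preserved and
every nucleus is contained in its cell.  All coordinates are row-major,
0-based; the pipeline consumes 2-D arrays (a max-projection helper is
provided for z-stacks, projection otherwise happens upstream).

**Permeabilization filter.** Cells whose summed in-mask calnexin exceeds a
threshold are flagged and excluded before any stain quantification.  The
"auto" threshold is twice the population median, which cleanly separates
surface-calnexin-positive (permeabilized) cells when most of the population
is intact; an absolute cutoff can be supplied instead.

**Positivity threshold.** The cutoff is the maximum per-cell summed stain
intensity across all retained cells of all untransfected control fields,
computed per analysis batch.  By construction a batch with no transfection
anywhere measures 0% positive.

## Cytotoxicity

Per well R = cytotoxicity/viability (dual-channel mode) or the raw
cytotoxicity signal (LDH-only mode); percent death = 100·(R − R̄_min)/
(R̄_max − R̄_min) using the plate's min/max death control means.  Values
outside [0, 100] — possible with noisy controls — are flagged, never
silently clipped, because clipping hides control failures.  Rescue is
100·(1 − death_treated/death_baseline).  BH adjustment delegates to the
standard step-up implementation in statsmodels and is cross-checked in the
tests against an independent brute-force step-up.

## Synthetic-data generators

All generators are deterministic functions of their config (seed included);
bit-identical outputs for identical configs are asserted in tests.

**Bilayer records.** Ohmic current I = G(t)·(V(t) − E_rev) + Gaussian
noise, with G switching between a closed-dominated conductance (default
0.004 nS) and an open conductance (default closed × 450) at pH events; pH
≥ 6.8 counts as neutral/open.  Default noise 2 pA at 50 Hz over a
±80 mV staircase.  Not emulated: single-channel gating noise, capacitive
transients, slow drift.

**Trace cohorts.** Baseline × (1 + signal) + Gaussian noise per channel;
the Ca²⁺ signal is a piecewise-linear ramp to plateau (default rise 30 min)
beginning at a drawn onset, chosen as the simplest shape with a
well-defined onset for recovery testing.  The first elevated frame *is* the
ground-truth onset, so noiseless detection is exact by construction.  The
voltage channel follows the same ramp a fixed number of frames later
(default plateau 0.25, matching the ~20–30% dynamic range typical of
voltage reporters); the dye channel is a step at lysis.  Release-style
presets draw onsets uniformly in 120–240 min at 5-min frames; induction-
style timings (12–18 h) are reachable through the same config.  Defaults:
baseline 100 AU, noise 5 AU (5%).  Not emulated: cell migration,
photobleaching, focus drift, overlapping cells.

**Image fields.** Hard-disc cells (nucleus r = 6 px inside cell r = 15 px)
placed without contact in a 512×512 field; Gaussian blur (σ = 1 px) as a
point-spread stand-in; sqrt-intensity Gaussian noise approximating shot
noise.  Permeabilized cells carry whole-cell surface calnexin; PM-positive
cells carry 10 boundary punctae.  Counts are exact: permeabilized =
round(fraction·n), positives = round(fraction·retained) drawn disjointly
from the permeabilized set and within the transfected set, so ground-truth
percent-positive is exact on the retained population.  The default punctum
intensity (460) was calibrated once so that the retained-cell mixture with
positive fractions 0.05 → 0.20 yields a mean summed-intensity uplift of
1.275× under the analysis defaults (the uplift is a mixture ratio
(1 + 0.20·k)/(1 + 0.05·k) with k the punctae-to-background sum ratio;
k ≈ 2.02 gives 1.275).  Not emulated: 3-D optics, intracellular signal,
spectral bleed-through, illumination gradients.

**Plates.** The per-well cytotoxicity/viability ratio is linear in the
death fraction between anchors at 0% (R = 0.05) and 100% (R = 0.95) death,
so min/max normalization recovers programmed values exactly at zero noise.
Well-to-well noise is a single multiplicative Gaussian CV applied to the
ratio: dual-channel assays are ratiometric precisely because common-mode
channel noise cancels, so the surviving variability is well-level.  Channel
gains then split the ratio into a decreasing viability signal and a
cytotoxicity signal.  At 5% CV with 6 wells per condition, the mean
absolute recovery error over a {0, 25, 50, 75, 100}% grid averages ~1.2
percentage points across plates.

**Movies.** Cohort tracks rendered as Gaussian blobs (σ = 3 px) at static
positions with amplitude following the simulated indicator intensity, for
exercising the spot detector/linker (cells in these simulations do not
migrate, so linking is intentionally easy; the linker's displacement gate
and mutual-nearest-neighbour rule are what is under test).

## Problem sizes and determinism

The test suite runs the full recovery analyses at reduced but meaningful
sizes — 100 bilayer records, 500-cell cohorts, 10 fields × 4 conditions ×
44 cells plus 10 untransfected control fields, 10 replicate plates — sizes
chosen so the whole suite completes in well under a minute on one CPU while
keeping Monte-Carlo assertions stable.  Every stochastic test is seeded;
hypothesis runs derandomized.

## Known limitations

- The linear I–V assumption fails for rectifying channels; the fit window
  must then be restricted to the quasi-linear region around E_rev.
- Threshold-based onset detection cannot separate a slow drift from a slow
  ramp; the QC rules remove tracks, not artifacts within tracks.
- The segmentation recipe expects blob-like, well-separated nuclei; dense
  tissue-like fields would need a learned or seeded segmentation upstream.
- Generator calibrations (punctum intensity, plateau ratios) define the
  simulated study conditions; passing recovery tests demonstrates the
  analysis is correct under those conditions, not that real data share
  them.
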
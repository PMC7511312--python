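# Methods

This note documents the models, conventions and parameter choices behind
the package, what the synthetic-data generators do and do not emulate, and
the known limitations.

## Membrane-charging model

A spherical cell of radius *a* in a uniform step field *E* charges
according to

    V_m(θ, t) = E·a·cos θ · (1 − exp(−t/τ_C)),
    τ_C = a·C_m·(1/σ_i + 1/(2σ_e)),

where θ is the azimuth from the field-axis pole, `C_m` the membrane
capacitance per unit area, and `σ_i`, `σ_e` the cytoplasm and external
conductivities. Assumptions: single shell (no organelle membranes), fixed
membrane properties during charging, ideal rectangular pulse with zero
rise time, uniform far field. The classical steady-state Schwan relation
carries a geometric factor 3/2; the model defaults to a factor of 1,
matching the convention of the reference charging curves this package
reproduces, with `schwan_factor=1.5` available for the textbook variant.

Reference parameters (the *H. pluvialis* treatment conditions):
*a* = 14 µm, `C_m` = 1 µF·cm⁻² (0.01 F·m⁻²), σ_i = 10 mS·cm⁻¹ (1 S·m⁻¹),
σ_e = 1.6 mS·cm⁻¹ (0.16 S·m⁻¹), E = 40 kV·cm⁻¹ (4·10⁶ V·m⁻¹). Direct
evaluation gives τ_C = 5.775·10⁻⁷ s. The published value for the same
nominal parameters is 5.98·10⁻⁷ s, ~3.5% higher; the published parameter
list states the capacitance as "µF cm⁻¹", presumably a misprint for
µF·cm⁻², and which single parameter differs cannot be recovered. Functions
therefore accept an explicit `tau_c_s` override so published curves can be
reproduced verbatim; comparisons against the published constant use a 5%
tolerance.

The β-dispersion characteristic frequency is reported as `f_c = 1/τ_C`
(not `1/(2π·τ_C)`), following the convention used alongside this charging
law. Note that with the reference parameters this is ≈1.7 MHz, not the
tens-of-MHz range sometimes quoted for cell suspensions; the package
reports the value exactly as defined.

### Permeabilisation geometry

Voltages above the threshold `V_th` (default 1.0 V, the usual scale for
irreversible electroporation) are reported unclamped but flagged
"hypothetical": physically the membrane breaks down and the voltage
collapses, so the flagged region of a charging curve is an extrapolation.
Inverting the charging law gives the threshold azimuth

    θ* = arccos(V_th / (E·a·(1 − exp(−t/τ_C)))),

returned as "unreached" while the polar voltage is still below threshold.
Coverage conventions (a design choice, since both hemispheres polarise
symmetrically): the circumference fraction counts both polar arcs of the
great circle through the field axis, `c = 4θ*/360`; the surface fraction
counts both spherical caps, `s = 1 − cos θ*`. With the reference
parameters: θ* ≈ 65° and c ≈ 0.72 at 25 ns ("around 2/3 of the
circumference"); θ* ≈ 78° at 50 ns (permeabilisation "almost over the
entire sphere", below the 80° bound).

### Dosimetry and flow

Per-pulse energy density `w₁ = σ_e·E²·Δt` (rectangular pulse, medium
conductivity, no temperature correction) and specific treatment energy
`W = N·w₁/ρ` with suspension density ρ = 1000 kg·m⁻³ by default. For the
reference protocol (N = 32) this yields 2.048 J·g⁻¹ at 25 ns and
4.096 J·g⁻¹ at 50 ns, matching the conventional "2 / 4 J·g⁻¹" labels of
these treatments. The flow-chamber pulse count is `N = round(f·V_ch/Q)`;
the chamber volume defaults to 0.5 ml, chosen so that the documented flow
rate (3.75 ml·min⁻¹) and repetition rate (4 Hz) give the documented 32
pulses per cell — the volume itself is not independently documented and is
overridable.

## Astaxanthin scoring

The per-cell score follows the channel-arithmetic recipe: invert the 8-bit
RGB image (v → 255 − v), split channels, form the signed per-pixel
difference `A = G_inv − R_inv` (astaxanthin corrected against
chlorophyll), and sum A over each segmented cell ("integrated density",
arbitrary units). Design choices where the recipe is silent:

* subtraction is signed and unclipped by default — this preserves
  additivity over regions and invariance to offsets common to both
  channels; `clip_negative=True` reproduces the clamped dialect of common
  image software;
* segmentation (not described in the original procedure): Otsu threshold
  on inverted luminance, hole filling, connected components, minimum area
  50 px, border-touching regions discarded — all configurable;
* 16-bit inputs are rescaled to 8 bits; pixel coordinates are 0-based
  row-major.

Population summaries average per cell within an experiment, then report
mean ± s.e. across experiments (the reporting convention targets ≥500
cells per data point and three independent series; shortfalls warn rather
than fail).

## Viability

Tabular mode computes mortality as `100·stained/total` per count record
and aggregates mean ± s.e. across experimental series per condition ×
timepoint (warning below the 1,500-cell counting target). Image mode is an
explicit stand-in for visual scoring — the original assay has no stated
colour threshold: a segmented cell is called dead when its mean blue
intensity exceeds the larger of the red and green means by a relative
margin (default 0.4). The rule operates in original intensity space
because a bright-field Evans-Blue-stained cell transmits blue while
absorbing red and green, whereas the photosynthetic pigments of live cells
absorb blue at least as strongly — so blue dominance by a wide margin
marks dead cells.

## qPCR (2^(−ΔΔCt))

Collapse order is technical → biological → summary: technical replicates
are averaged to one Ct per biological replicate; `ΔCt = Ct_target −
Ct_actin` is paired within each sample; `ΔΔCt` is taken against the *mean*
reference ΔCt (the untreated control at 18 h by default) because no
pairing between control and treated replicates exists. The summary fold of
a group is `2^(−(mean ΔCt − mean ΔCt_ref))` — the fold of the mean ΔΔCt —
which makes the reference cell of the table exactly 1 by construction; the
standard error spans the three biological-replicate folds only (an
`se_across="measurements"` option spans all nine measurements instead, for
the alternative reading of the replicate convention). Amplification
efficiency is fixed at 2 by default, with a Pfaffl-style `efficiency`
parameter available. The timepoint grid defaults to {18, 24, 48, 72, 96} h.

## Statistics

Group comparisons use a two-sided two-sample t-test, pooled-variance by
default (the likeliest spreadsheet-software default; Welch by flag), with
strict star thresholds `**` p < 0.01 and `*` p < 0.05. No multiple-testing
correction is applied, matching the original reporting; a
Benjamini–Hochberg helper exists as a clearly-labelled extension.

## Synthetic data

The generators emulate the study conditions; their defaults are the
conditions, not tuning knobs.

**Micrographs.** Cells are anti-aliased disks (radius uniform over
8–50 µm at 0.5 µm/px) placed by dart-throwing without overlap (≤10⁴
attempts). Image formation is subtractive from a bright background (230):
astaxanthin attenuates green (per-cell level ~ N(scenario level, 0.08)),
chlorophyll attenuates red (~N(0.45, 0.02)), and both attenuate blue
(coefficient 0.6 on their sum), as the pigments' absorption spectra
suggest. Dead cells additionally receive a stain absorbance that is
additive and equal on red and green (depth 100) with only slight blue
absorption — an idealised dye that (a) makes blue dominant so the
classifier can find dead cells and (b) leaves the G−R difference of every
pixel unchanged, so a cell's pigment score is invariant to staining. This
idealisation underlies the pipeline's per-cell argument that rising
mortality cannot inflate the population astaxanthin score. Gaussian pixel
noise (sd 2 intensity units) is added before 8-bit quantisation.

**Ct tables.** `Ct = baseCt(gene) − log₂(fold) + N(0, sd)` per technical
measurement, sd 0.2 cycles by default; actin is constant across conditions
up to the same noise. Base Cts (psy 24, crtR-b 26, bkt 1 25, actin 18) are
plausible mid-range values; fold-change recovery is invariant to them.

**Counts.** `stained ~ Binomial(total, p)` with total 1,500 per series and
three series.

**Presets.** Twelve scenarios = 3 pulse conditions × 4 inhibitor states.
The no-inhibitor family carries the 18–96 h time course normalised to the
untreated control at 18 h (control mortality 2%; 50 ns trajectory
14→19% with a ~2× transcript peak at 72 h; 25 ns trajectory 6→17% with
crtR-b repressed to 1/3); the inhibitor families (+DPI, +A23187, +GdCl₃)
are single-timepoint 72 h designs normalised to the untreated un-pulsed
control at 72 h, because those experiments were reported on a different
internal standard and their values are not comparable to the time-course
normalisation. Approximate narrative values are encoded as point
parameters ("around twofold" → 2.0; "roughly doubled" → 2.0; DPI
astaxanthin "+80%" → level ×1.8).

**What the generators do not emulate:** optics (no point-spread function,
no depth of field), chloroplast morphology and subcellular structure,
cell-wall autofluorescence, clumping and overlapping cells, flow-chamber
hydrodynamics, amplification curves or primer efficiency differences, and
any coupling between mortality and pigment content. Passing
parameter-recovery tests therefore shows that the analysis stages are
correct and unbiased under the planted noise model — not that they are
robust to every artefact of real micrographs or real qPCR runs.

## Numerical conventions

Angles are degrees at public interfaces, radians internally; times in
seconds, SI units throughout the model layer, with `nspef.units` helpers
for bench units (kV/cm, ns, mS/cm, µm, µF/cm², ml/min). Threshold
comparisons are strict (`V_m > V_th` flags, p-value stars). CSV output is
serialised to six significant digits; mortality percentages are reported
to one decimal by the CLI. Degenerate inputs: empty grids, empty record
sets, zero-total counts, missing housekeeping or reference samples all
raise typed errors (validation vs configuration) mapped to CLI exit codes
2 and 3.

## Problem sizes in tests

The test suite sizes simulations for quick feedback while keeping the
statistical claims meaningful: 5,000 null simulations for t-test
calibration, 50 seeds for fold-change recovery (sd 0.2 cycles), 60–200
seeds for binomial mortality recovery at n = 1,500, and ~500 synthetic
cells for classifier accuracy. These sizes put Monte-Carlo error well
below each asserted tolerance.

## Known limitations

* The single-shell model cannot address chloroplast-membrane
  permeabilisation, which for this organism is the mechanistically
  interesting difference between 25 and 50 ns pulses; no pore-kinetics
  (Smoluchowski-type) modelling is included — permeabilisation is a pure
  voltage-threshold criterion.
* The image classifier and segmentation are stand-ins for manual scoring;
  their accuracy figures hold for the synthetic image model only.
* The 2^(−ΔΔCt) method assumes perfect and equal amplification efficiency
  across genes unless overridden.
* The published τ_C and f_c inconsistencies (see above) are documented,
  not resolved.
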
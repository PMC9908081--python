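# Methods

This note defines every quantity ribbonquant computes, the defaults it
ships with, and where the package makes a judgement call that a reader
should know about.

## Freeze timing (`hpf_timing`)

**Model.** An HPM100 shot is timed on two clocks: the pneumatic
pressure sensor runs on the absolute clock (0 = HPM START), while the
internal chamber sensors start recording only when chamber pressure
reaches 65 bar.  The freeze time on the absolute clock is

    T_HPM_delay = T_N2_pressurized + T_mechanics + T_specimen_at_0

with defaults `T_N2_pressurized = 400 ms` (instrument nominal),
`T_specimen_at_0 = T_chamber_at_0 + T_sapphire_at_0 + T_sample_center_at_0
= 5.41 + 0.01 + 1.1 = 6.52 ms`.  `T_chamber_at_0` is re-estimable from
test shots as mean(rise time + p/T shift) (`chamber_cooling_from_shots`,
sample SD with n−1).  The effective stimulation per shot is
`max(0, T_HPM_delay − StimStart)`; StimStart 425 ms labels ShortStim,
390 ms LongStim.

**Valve-dip detection.** The valve opening shows as a small dip in the
pneumatic trace before the final build-up and sudden drop.  The
operative definition (the dip, not the drop) anchors the relative
clock; `--anchor drop` is available.  Algorithm: centered moving-average
smoothing (default 1 ms), the sudden drop is the largest negative first
difference, the global maximum before it bounds the search; walking
backwards from that maximum we track the running minimum and stop once
the signal climbs a tolerance above it — the tolerance is
max(2 % of signal range, 6× the smoothed-noise floor estimated from a
robust MAD of the raw first differences) — then refine with an argmin in
a ±2 ms window.  This is deliberately insensitive to flat plateaus and
to noise runs, and works on irregular sampling (all widths in ms, not
samples).  Degenerate traces (flat, no drop, no dip deeper than the
tolerance) raise `NoValveEvent`.

Negative mechanical delays (valve apparently before 400 ms) are clamped
to zero with a warning by default — a miscalibrated `T_N2` should not
crash a batch — or raised with `on_negative_mechanics="raise"`.

## Irradiance (`irradiance`)

Photodiode voltage → radiant flux uses the affine calibration
`Φe(U) = 0.67 mW + 0.64 mW/V · U · 20`.  The printed form is ambiguous
about whether the ND-filter factor 20 multiplies only the slope term or
the whole affine sum; both interpretations are implemented (`literal`,
the left-to-right reading, is the default) and neither can be
discriminated without a recorded (U, Φe) pair, so the choice is
explicit rather than silent.

An irradiance map distributes a measured flux over the
background-subtracted (clipped at zero; scalar or dark-frame
background) gray values of a CCD frame: `pixel_flux = gv′ · Φe / Σgv′`.
Flux is conserved by construction to float precision.  Peak irradiance
is max(pixel_flux)/pitch².  The chamber-replica optics are treated as
metadata; no optical model is applied.

## EPSC metrics (`ephys`)

Baseline mean/SD come from a pre-stimulus window (default 50 ms, ≥ 10
samples) ending at light onset.  Event onset is the first time at or
after light onset where the signal leaves the baseline ± k·SD band
(k = 4) and stays out for m = 3 consecutive samples; the consecutive-m
requirement makes the rule robust to single-sample noise at high
sampling rates.  Latency = onset − light onset.

Amplitude is the extremal signed deviation from the baseline mean after
light onset.  The end of release (EPSC offset) is the first time after
the peak at which the signal re-enters the band and stays inside for
≥ 2 ms; the re-entry test runs on a 1-ms moving-average copy of the
trace to keep the crossing jitter well below the charge tolerance.  If
the band is never re-entered (e.g. noiseless decays, where the band has
zero width), the metrics are truncated at trace end and flagged.
Return to baseline = offset − onset.

Charge is the trapezoidal integral of the baseline-subtracted current
from **light onset** (not EPSC onset) to the offset, in pC; Q₂₀/Q₅₀
truncate the same integral 20/50 ms after light onset.  Integration
interpolates the window endpoints, so it is correct on irregular grids.
Note the measurand: charge *up to the detected end of release*.  For a
decaying transient this deliberately excludes the sub-threshold tail
below the ±4·SD band; synthetic-recovery tests therefore compare
against the closed-form charge of the clean waveform over the same
window (for the double exponential `A(e^{−t/τd} − e^{−t/τr})`, total
charge `A(τd − τr)` truncated at the clean band re-entry).  With noise
SD 2–10 pA and amplitudes −100…−700 pA, latency is recovered to
< 0.5 ms per event and charge to ≪ 3 % mean relative error; single
events at the low-amplitude/high-noise corner can deviate a few percent
from offset jitter alone.

QC: IHCs are excluded when leak < −50 pA or Rs > 30 MΩ; boutons when
leak < −100 pA or Rs > 80 MΩ; comparisons are strict, so boundary
values are kept.  Missing metadata excludes with reason `MissingQC`.
When series metadata is present, only each cell's first stimulus series
is analyzed (channelrhodopsin inactivates over repeated series).

## Vesicle pools (`tomo_quant`, `geometry`)

All coordinates are nm; the optional point-listing importer multiplies
pixel coordinates by `voxel_nm` (default 1.18).  Distances are measured
from the vesicle's outer layer: exact point-to-mesh distance (minimum
over faces of the exact point-to-triangle distance, not vertex-only)
minus the radius, floored at zero.  Point-cloud structures use nearest
points.

* **MP**: first-row vesicle with membrane distance ≤ 50 nm and lateral
  PD distance ≤ 100 nm.  "Vertical" membrane distance is implemented as
  nearest-point distance (the AZ is locally planar at vesicle scale).
  Lateral PD distance projects the vesicle center and the PD points
  onto the local AZ plane (principal-component fit of membrane vertices
  within 150 nm of the vesicle) and takes the 2D nearest-point distance
  minus the radius.
* **docked**: MP with membrane distance ≤ 2 nm (closed intervals
  throughout — "0–2 nm", "maximum 50", "maximal 80" read as inclusive).
* **MP sub-pools**: docked > tethered > non-tethered precedence from
  the tether annotations; tethered MP vesicles are further categorized
  by count and target (single membrane / single PD / interconnected /
  multiple).
* **RA**: not MP, first row from the ribbon, ribbon distance ≤ 80 nm;
  sub-pools from filament targets (none / ribbon-attached /
  interconnected / both).
* **First row** is operationalized as an occlusion test: a candidate
  qualifies iff the segment from its outer edge to its nearest point on
  the target structure passes through no other vesicle's sphere
  (`first_row="none"` disables it; the thresholds alone nearly
  determine membership).
* Clathrin-coated structures are never pooled; they are censused within
  500 nm of the PD (bins 0–200 / 200–500 nm), with diameters from the
  stored outer-leaflet radius (coat excluded by construction).
* **Ribbon halves**: split plane through the ribbon centroid, normal
  along the centroid → nearest-membrane-point axis; proximal = membrane
  side; MP and CC vesicles excluded.  A ribbon with no extent along the
  axis raises `SplitUndefined`.
* Diameter: spheres `D = 2r`; irregular structures the mean of the
  long and short axes.  Histogram bins ≤40, (40,45], (45,50], (50,55],
  (55,60], >60 nm (the conventional 5-nm binning; edges configurable).

Aggregation is per ribbon for counts and sub-pool fractions (mean ±
SEM over ribbons; a ribbon with no MP vesicles contributes null, not
zero) and per vesicle for distances and diameters.  `docked_per_az` is
the total docked count divided by the number of tomograms, rounded to
two decimals in reports.

## Group statistics (`group_stats`)

Gate: Shapiro-Wilk per group and Brown-Forsythe (median-centered
Levene) across groups, both at α = 0.05 (configurable).  All gates must
pass for the parametric branch; groups with < 3 values are untestable
and force the non-parametric branch with a flag.  Parametric: one-way
ANOVA omnibus + Tukey HSD (family-adjusted p).  Non-parametric:
Kruskal-Wallis + Dunn's all-pairs rank test with tie correction;
Dunn's p-values are Bonferroni-adjusted by default (the conventional
choice; `holm`/`none` selectable, and the variant is reported in the
output).  Two-way designs always run parametric two-way ANOVA (OLS,
type-II table) with Tukey HSD over the factor cells.  The gate is
applied once per outcome over all its groups.  Reports carry group
means with SEM.  Note that with g groups and per-gate α = 0.05, even
perfectly normal data take the parametric branch only ≈ 0.95^(g+1) of
the time — that is the gate working as specified, not a defect.

## Synthetic data (`synthetic`)

One global seed is split into independent per-generator streams
(`numpy.random.SeedSequence([seed, tag])`), so outputs are reproducible
bit-for-bit and adding a generator never shifts another's draws.

* **Shots**: pneumatic rise to a 5 bar plateau, a cosine-squared dip of
  0.3 bar (half-width 1.5 ms) at 400 + T_mechanics ms, a steady rise to
  7 bar, and a sudden drop 60 ms later; internal pressure sigmoidal to
  2100 bar; temperature declining through 0 °C at `T_chamber_at_0`.
  Noise is Gaussian with SD = `noise_rel` × the noiseless signal range.
  10 kHz default sampling.
* **EPSCs**: sums of double-exponential transients on a Gaussian
  baseline at 50 kHz; the truth records each event's analytic charge,
  peak time and peak value.  Default event scales follow the recorded
  range: amplitudes −100…−700 pA, latencies 10–25 ms, τ_rise ~0.5 ms,
  τ_decay ~5 ms.
* **Synapse models**: planar AZ mesh (600 × 600 nm), a PD point patch
  (120 × 40 nm footprint, 30 nm tall), an ellipsoidal ribbon
  (60/45/85 nm semi-axes) above it.  MP vesicles: docked distance
  U[0, 2] nm (with a 0.05 nm guard band), others U(2, 50) nm or the
  `table2` profile (truncated normal, mean 21 nm) matching the
  reported mean membrane distances (~19–24 nm); lateral PD placement
  within 95 nm; diameters Normal(49, 3) nm truncated positive.  RA
  vesicles sit on the upper ribbon hemisphere at gaps U(1, 75) nm.
  Placement is rejection sampling with pairwise-overlap rejection and
  explicit line-of-sight bookkeeping (a new vesicle may not block any
  planted vesicle's first-row segment), so planted pool labels are
  geometrically true; a retry cap (10⁴) raises `PlacementError`.
  Docked counts are binomial in `docked_fraction` (or exact via
  `n_docked`).
* **Groups**: normal (parametric by construction) or Cauchy
  (non-parametric by construction) samples at given means/scales.

**What the generators do not emulate**: real tomograms have curved
membranes, partial ribbons at section edges, anisotropic missing-wedge
distortion, and annotation error in tether calls; sensor traces have
correlated (non-white) noise and shot-to-shot waveform variability.
Passing round-trip tests therefore demonstrates the correctness of the
measurement definitions and their implementation, not robustness to
every artifact of real acquisitions.

## Problem sizes and numerical choices

Simulation-based checks use 100 seeded shots/events, 200 small synapse
models for the oracle comparison, 20 ribbons per planted fraction, and
1000–2000 seeds for the statistical-gate calibration; these sizes give
Monte-Carlo errors comfortably below the asserted tolerances.  Mesh
distances are exact (no sampling); brute-force verification in the test
suite uses an independently coded distance formulation and, for the
distance primitive itself, 10⁵-point surface sampling.  Trapezoidal
integration is used throughout for irregular grids.  Ties in peak
finding break to the earliest sample.  Degenerate inputs (flat traces,
empty structures, zero-variance groups, zero-MP ribbons) raise typed
errors or return nulls as documented above, never silent zeros.

## Known limitations

* The dip detector assumes one valve event per trace; double shots are
  out of scope.
* Lateral PD distance in strongly oblique sections depends on the local
  plane fit; the 150 nm neighborhood is a compromise between locality
  and stability.
* EPSC charge excludes the sub-band tail by definition of "end of
  release"; for slowly decaying events this is a few percent of the
  total analytic charge.
* The per-ribbon docked-fraction denominator excludes clathrin-coated
  vesicles (tracked separately by the census).
* Two-way designs skip the normality/variance gate by design (they are
  always parametric), mirroring the study's usage.
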
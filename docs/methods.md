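# Methods

`beadpulse` models and analyses a continuous bead-based quantum-dot sandwich
immunoassay: antibody-coated magnetic beads capture a blood hormone (insulin
or glucagon), QDot-tagged detection antibodies label the captured antigen,
and each bead transiting an optofluidic interrogation spot produces a
fluorescence pulse on one of two spectral channels (QDot 655 nm reports
insulin, QDot 605 nm glucagon).  Concentration is read out from the
normalised mean area under the pulses of a fixed-duration scan, through a
four-parameter logistic (4PL) calibration.  This note documents the models,
the defaults and why they hold, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## Binding kinetics

The sandwich assembles in two sequential reversible bimolecular steps,

    bead:Ab + Ag      <->  bead:Ab:Ag         (kon1, koff1)
    bead:Ab:Ag + dAb  <->  bead:Ab:Ag:dAb     (kon2, koff2)

integrated as mass-action ODEs with site bookkeeping (free capture sites =
`cap_sites - captured - sandwich`, free detection antibody =
`det_ab - sandwich`) in a closed system, so free + captured + sandwich
equals the initial antigen concentration identically.  Solution-phase
pre-binding of detection antibody to free antigen is neglected: only
bead-bound complexes contribute to the bead's fluorescence, and the two-step
scheme is the minimal model for that readout.  Chaotic-advection micromixing
in the incubation channel is represented by a single dimensionless
`enhancement >= 1` multiplying both on-rates — a lumped stand-in for the
increase of diffusion-limited association rates under chaotic flow; no
spatial transport is modelled.  The fluorescence excess over background is
`dF(t) = A * [sandwich](t)` with `A` an instrument constant (a.u. per molar).

Integration uses SciPy's LSODA (stiff-capable, adaptive) at `rtol = 1e-10`,
`atol = 1e-13 x` the largest species concentration; the output grid is
purely an evaluation grid, so results are independent of the requested step
count.  Tiny negative excursions (within solver tolerance) are clipped to
zero; substantial negativity or non-convergence raises instead of returning
NaNs.  A fixed-step explicit-Euler integrator exists only in the test suite
and acceptance script as an independent oracle.

Default rate constants (`kon = 1e5 /M/s`, `koff = 1e-4 /s`,
`enhancement = 10`, `cap_sites = det_ab = 1 nM`, `A = 1e14 a.u./M`) are
**placeholders**: the device-specific fitted constants are not publicly
tabulated.  They are chosen to be typical antibody-antigen magnitudes and to
reproduce the system's documented operating regime — equilibration takes
roughly two hours, far longer than the ~30 s on-chip incubation, so the
assay runs pre-equilibrium while `dF(30 s)` remains strictly monotone
(near-linear) in antigen concentration over the physiological pM range.
All values are config-overridable.

`time_to_equilibrium` reports the first trajectory point within a relative
tolerance of the plateau, where the plateau is the trajectory value at
~100x the slowest pseudo-first-order relaxation time (doubled up to four
times if the tail has not flattened), not an analytic solution of the
coupled system; with zero antigen or zero detection antibody it returns a
`no_complex` sentinel.

## Synthetic trace generator

The generator emulates the detection module so every analysis stage can be
validated against known ground truth.  One 60-s scan per sample is
synthesised at 1 kHz as

    y(t) = baseline(t) + pulses(t) + noise(t)

* **Bead transits**: Poisson arrivals at 1 bead/s (the documented average of
  ~30 peaks per 30-s window), each a Gaussian pulse of sigma 50 ms
  (sd 10 ms across beads).  Sampling rate and pulse width are engineering
  choices — the acquisition hardware's values are not documented — subject
  to a validity check of >= 8 samples per pulse width.
* **Amplitudes**: the analyte-dependent mean times a unit-mean lognormal
  per-bead factor with CV 0.30, modelling beads riding at different heights
  in a channel taller than the bead.  The CV is chosen from the published
  per-concentration signal ranges (e.g. blanks 3-10 a.u., top insulin level
  30-60 a.u., i.e. a ~2-3x spread), which a multiplicative lognormal with
  CV ~0.3 reproduces.
* **Concentration -> amplitude**: per analyte,
  `amp(c) = blank + (ref_amp - blank) * dF(c, 30 s) / dF(ref, 30 s)` using
  the kinetics model, anchored to the published ranges: insulin blank
  6.5 a.u., 1000 pM -> 45 a.u.; glucagon blank 15 a.u., 100 pM -> 60 a.u.
* **Baseline and noise**: polynomial drift (default 2 + 0.05 t a.u.) plus
  white Gaussian noise of sd 0.3 a.u. — well below the smallest real pulses,
  consistent with a regime where a 10%-of-max amplitude threshold separates
  beads from noise.
* **Washing imperfections**: each bead is dropped with probability 0.2
  (80% recovery) and small contaminant events (residual blood-cell
  autofluorescence) arrive at 0.1/s with ~5% of the channel's mean
  amplitude (>90% purity).  Note that with the arrival rate fixed at the
  documented 1/s and loss applied downstream, the *observed* rate is
  ~0.8 beads/s.
* **Channels**: the two bead streams are independent (two bead populations);
  a 2x2 crosstalk matrix (identity by default, reflecting the spectrally
  clean filters) mixes the noiseless event components only, with noise drawn
  per output channel.  Each channel consumes its own seed substream, so
  changing one channel's parameters leaves the other channel's samples
  bit-identical — deliberate common-random-number pairing that makes
  selectivity experiments exact.
* Overlapping pulses add; there is no coincidence rejection at generation
  time.  Ground truth records event times, amplitudes, widths and the
  analytic area `amplitude * sigma * sqrt(2*pi)` per event.

What the generator does **not** emulate: optical physics (fibre geometry,
filter curves), RBC/WBC autofluorescence beyond the contaminant abstraction,
flow-rate drift, bead aggregation, or detector nonlinearity.  Tests passing
on this generator show the *analysis chain* is correct and robust under the
stated statistical model of the data; they do not certify performance on
real oscilloscope records.

## Scan analysis

Each 60-s scan window is processed independently per channel:

1. **Baseline** — iterative polynomial regression (degree 3, up to 100
   iterations, tolerance 1e-6 on the coefficient vector): fit, clip the
   working signal to the fit from above, refit; positive pulses are thereby
   excluded.  Three refinements, all exact no-ops on noiseless polynomial
   input: the fit uses a decimated subgrid (<= ~6000 points) for speed; after
   convergence the polynomial is refitted once on the identified baseline
   samples (residual <= 3 robust SDs), removing the ripple the clipping
   iteration leaves near pulses; and the result is recentred on the median
   residual, because clip-from-above otherwise settles on the *lower
   envelope* of the noise band.
2. **Peak detection** — local maxima of the corrected signal (minimum
   spacing 50 ms); a maximum is a bead only if its corrected amplitude
   *exceeds* 10% of the scan's largest corrected amplitude.  The same
   relative threshold is applied to the prominence: for isolated pulses
   prominence equals amplitude (so clean behaviour is unchanged), while
   noise wiggles riding on a pulse's flank — whose height clears the rule
   but whose prominence is only the noise scale — are rejected.
3. **Boundaries and width** — the peak base is defined at a 99% drop from
   the apex.  Rather than hunting for the 1% crossing directly (a level
   inside the noise band for small peaks), each side's half-maximum crossing
   is located on a lightly smoothed copy (7 ms boxcar, far narrower than a
   pulse) and extrapolated to the base with the Gaussian shape factor
   `sqrt(log(1/0.01)/log 2) ~ 2.58`; this reproduces the width-at-base
   exactly for clean Gaussian pulses and is amplitude-uniform under noise.
   Apexes closer than one mean pulse width (FWHM) are merged keeping the
   higher (tie: earlier) — one bead, one event; boundaries of adjacent
   retained peaks are truncated at the midpoint between their apexes, and
   amplitudes/areas always use the unsmoothed signal.
4. **Area** — trapezoidal integral of the corrected signal (clipped below
   at zero) between the boundary samples.
5. **Scan summary** — `F1` is the arithmetic mean of retained peak areas.
   A scan is *valid* only if every full 30-s window tiled from its start
   contains >= 10 peaks (enough beads transited); a trailing partial window
   is exempt, and invalid scans still report their count.  Scans shorter
   than one validity window are vacuously valid.

Indexing is 0-based, times in seconds, signal in a.u.  The polynomial
degree, iteration budget and width conventions above are package decisions;
the acquisition software's exact settings are not documented.

Because bead transits are Poisson, a fraction of pulses overlap within one
FWHM and are physically unresolvable; the merged peak then carries both
beads' area.  At 0.8 observed beads/s this inflates `F1` by a nearly
amplitude-independent factor (~1.2) that cancels in the F1/F0 ratio, at the
cost of scan-to-scan jitter that dominates the readout noise — an inherent
property of a mean-area statistic on overlapping pulse trains.

## Normalisation, calibration, LOD

The readout of a scan is `F1/F0`.  `F0` is, configurably, the mean `F1` of
designated blank (wash) scans (in-vitro calibration mode), the mean of the
first scans of a run (continuous in-vivo mode, signals prior to the
challenge), or a fixed value.

Calibration fits the increasing 4PL
`y = d0 + (dmax - d0) / (1 + (c50/x)^b)`, `y(0) = d0`, by least squares
(lmfit; `dmax` parameterised as `d0 + delta` with `delta >= 0`; initials
`d0 = min y`, `delta = range`, `c50 = median positive concentration`,
`b = 1`; `b` bounded to [0.05, 50]).  At least 4 distinct concentrations
are required; an essentially flat response is flagged degenerate rather
than rejected.  Inversion is closed-form on `(d0, dmax)`; ratios at or
below `d0` map to 0 pM with a `below_range` flag and ratios at or above
`dmax` are flagged `saturated` — flags, never silent clipping.

`LOD = 3.3 * SD_blank / S` with `SD_blank` the standard deviation of blank
replicate ratios and `S`, by default, the OLS slope through the blank and
the two lowest non-zero concentrations — the low range is where the LOD
lives; the 4PL derivative at `c50` is available as an alternative.  Where
on the curve the slope is taken is a convention the source material leaves
open.

With the kinetics defaults the synthetic concentration-response is
near-linear over the tested range (site occupancy stays low at 30 s), so
the 4PL's `c50` and `b` are weakly identified — the fitted curve is then an
interpolator whose predictions inside the calibrated range are stable even
when individual parameters are not.

## Run orchestration and the recovery experiment

A run's traces are segmented into fixed 60-s windows from the start of the
record (no gap detection), analysed per channel, normalised, and inverted
into time-stamped concentration estimates; invalid scans carry no estimate.
Crosstalk is not unmixed — channels are reported independently, as the
spectrally clean hardware justifies.  Every report embeds the config
snapshot, its hash and the package version, and `RunResult.report_hash()`
is stable for identical inputs.

`recovery_experiment` is the self-test of the whole stack: it simulates a
calibration run, fits per-analyte 4PL models, simulates an independent
held-out run, and compares estimates to generator truth.  The study design
mirrors the continuous in-vitro protocol: four insulin/glucagon
concentration pairs (1000/10, 400/40, 100/100, 200/80 pM), wash blanks
interleaved before and after every level (all blank scans feed F0 and the
blank SD), and each level measured as three replicates of three scans
(9 scans/level).  A level's concentration estimate inverts the mean ratio
of its scans, as when plotting the mean of replicate scans on a calibration
curve.  Reported per (analyte, level): per-scan estimates, level estimate,
bias, relative RMSE; plus rank-order correctness and the
calibration-derived LODs.

Under these defaults (20 seeds) the rank ordering of all four levels is
recovered for both analytes in every repetition and the pooled relative
RMSE of level estimates is ~10%.  The glucagon 10 pM level is the hardest:
it sits within ~1.5x of the synthetic assay's own empirical LOD
(~9 pM median), so its single-level relative error is LOD-limited by
construction — a property of measuring at the toe of the curve, not of the
implementation.  The synthetic LODs quantify the *simulated* instrument
(they depend on the placeholder kinetics, amplitude anchors and noise
model) and are not estimates of the physical device's detection limits.

## Problem sizes and runtime

Defaults keep everything desk-scale on one CPU: a 60-s, 1 kHz dual-channel
scan analyses in well under one second (comfortably inside the real-time
budget of one scan duration); the full 20-seed recovery study (~2000
scan-channel analyses) runs in a few minutes; the Euler oracle uses 1e6
fixed steps over 30 s.  The acceptance script reruns all of the above from
scratch.

## Known limitations

* Kinetics constants are placeholders; absolute `dF` values and synthetic
  LODs are therefore illustrative, though the qualitative regime
  (pre-equilibrium operation, monotone readout) is robust to the choice.
* The mean-area `F1` statistic is sensitive to pulse pile-up; at bead rates
  well above ~1/s the overlap-merge factor would bias and noise the readout
  appreciably.
* The baseline model is a single polynomial per scan; step artefacts or
  drifts faster than the scan length are out of scope.
* 5PL calibration, non-uniform fit weighting, inter-assay drift correction
  and crosstalk unmixing are deliberately not implemented.
* The in-vivo analysis mode only changes the F0 convention; no physiology
  (hormone secretion dynamics) is modelled.
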
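# beadpulse

Desk-scale simulation and analysis for **continuous bead-based quantum-dot
sandwich immunoassays** — the class of optofluidic instruments that measure
picomolar blood hormones (insulin, glucagon) in real time by flowing
antibody-coated beads through a laser interrogation spot and reading each
bead transit as a fluorescence pulse on a spectral channel (QDot 655 →
insulin, QDot 605 → glucagon).

The package is for people building or evaluating such pipelines: it
implements the complete computational stack between raw photodetector
traces and concentration estimates, plus a ground-truth trace generator so
every stage can be verified without the physical device.

## What it computes

* **Binding kinetics** (`beadpulse.kinetics`) — the two-step reversible
  sandwich scheme as mass-action ODEs,

  d[AbAg]/dt = e·k<sub>on1</sub>[Ag][Ab] − k<sub>off1</sub>[AbAg] − (e·k<sub>on2</sub>[AbAg][dAb] − k<sub>off2</sub>[S]),
  d[S]/dt = e·k<sub>on2</sub>[AbAg][dAb] − k<sub>off2</sub>[S],

  with micromixing enhancement *e* ≥ 1, signal ΔF(t) = A·[S](t), mass
  conservation by construction, closed-form capture isotherm and
  equilibration-time search.  With the documented defaults the assay
  operates pre-equilibrium: equilibration takes ≫ 30 s while ΔF(30 s)
  stays monotone in concentration.
* **Synthetic traces** (`beadpulse.synth`) — Poisson bead transits
  (~1/s), Gaussian pulses, lognormal per-bead amplitude factors
  (bead-height variation), polynomial baseline drift, white noise, channel
  crosstalk, bead loss (80% recovery) and contaminant events (>90%
  purity), all with exact ground truth and bit-reproducible seeding.
* **Scan analysis** (`beadpulse.peaks`) — iterative polynomial baseline
  removal, peak detection with the relative 10%-of-max rule, base-width
  boundaries, trapezoidal areas, and per-scan summaries: mean area *F*₁
  and the ≥ 10 peaks / 30 s validity rule.
* **Calibration** (`beadpulse.calibration`) — 4PL fits
  y = d₀ + (d<sub>max</sub> − d₀)/(1 + (c₅₀/x)<sup>b</sup>) of
  (concentration, *F*₁/*F*₀) replicates, closed-form inversion with
  below-range/saturated flags, and LOD = 3.3 · SD<sub>blank</sub> / S.
* **Orchestration** (`beadpulse.pipeline`) — trace IO, 60-s scan
  segmentation, *F*₀ normalisation modes, concentration time series, and
  the end-to-end simulate → calibrate → analyze recovery experiment.

## Worked example

Calibrate from a simulated ladder, then quantify a held-out spiked sample
(pair B: 400 pM insulin + 40 pM glucagon between wash blanks):

```python
from beadpulse import AnalysisConfig, ChannelMap, SyntheticSpec, analyze_run, generate_experiment
from beadpulse.pipeline import SAMPLE_PAIRS, calibrate_from_experiment
from beadpulse.synth import default_signal_models

cm, template, amps = ChannelMap(), SyntheticSpec(), default_signal_models()
pairs = [{"insulin": 100.0, "glucagon": 10.0}, {"insulin": 200.0, "glucagon": 40.0},
         {"insulin": 400.0, "glucagon": 80.0}, {"insulin": 1000.0, "glucagon": 100.0}]
models = calibrate_from_experiment(pairs, template, cm, amps, AnalysisConfig(),
                                   seed=123, scans_per_level=3, n_blanks=2)
exp = generate_experiment([{}, {}] + [SAMPLE_PAIRS["B"]] * 3, template,
                          cm.channel_to_analyte, amps, seed=777)
result = analyze_run(exp.traces, cm, models,
                     AnalysisConfig(f0_mode="blank_scans", f0_scan_indices=(0, 1)))
print(result.to_frame())
```

prints (abridged):

```
glucagon: d0=1.016 c50=... LOD=8.4 pM
insulin:  d0=1.000 c50=... LOD=63.3 pM
 scan_index channel  analyte  n_peaks  valid       F1  F_ratio    conc_pM        flag
          0   ch605 glucagon       47   True 2.002860 0.996145   0.000000 below_range
          2   ch605 glucagon       53   True 4.661632 2.318515  42.913494          ok
          3   ch605 glucagon       31   True 4.351240 2.164138  38.461140          ok
          4   ch605 glucagon       45   True 4.431548 2.204080  39.620266          ok
          2   ch655  insulin       44   True 3.658282 3.986316 493.574703          ok
          3   ch655  insulin       43   True 2.996000 3.264649 370.393724          ok
          4   ch655  insulin       43   True 3.385361 3.688923 442.451230          ok
```

Read it as: every scan was valid (enough bead transits per 30-s window);
blank scans invert to 0 pM with a `below_range` flag; the three sample
scans recover the spiked 40 pM glucagon as 38–43 pM and the 400 pM insulin
as 370–494 pM, i.e. within the scan-to-scan noise of the mean-area
statistic.  The quoted LODs characterise the *simulated* instrument.

A CLI mirrors the library: `beadpulse simulate|calibrate|analyze|recover`,
each taking a YAML config (`--config`), a seed, and writing CSV/JSON.

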
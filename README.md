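# endoquant

Quantification of receptor-mediated ligand internalization from two-channel
fluorescence microscopy and flow cytometry.

The scientific question this package serves: how fast does a cell-surface
receptor carry its ligand inside the cell?  The concrete system is the
insulin receptor isoform B (IR-B) expressed in HeLa cells as a fluorescent
fusion protein, with its two ligands — insulin and insulin-like growth
factor II (IGF-II) — tracked via quantum dots (QD) coupled to the
biotinylated ligand.  The same machinery applies to any receptor/ligand pair
imaged as a "cell outline" channel plus a punctate ligand channel, or
measured as two-channel cytometry events.

## What it computes

**Internalization ratio (imaging).**  Each cell, segmented on the receptor
channel, is split into a *membrane* rim and an *interior* core by iterated
binary erosion with alternating 4-/8-connected structuring elements.  The
per-cell measure is

    ratio = QD_interior / (QD_interior + QD_membrane)

summed over QD-positive pixels in each compartment.  Because both sums share
the acquisition gain, the ratio is internally calibrated: detector gain and
zoom cancel exactly.

**Kinetics.**  Per-ligand mean ratios over time are fit with a
four-parameter sigmoid (default: the symmetric logistic
`y(t) = a1 + (a2 - a1)/(1 + exp(-(t - x0)/dx))`, fractions bounded to
[0, 1]; the power-law log-logistic form is also available).  The maximal
slope of the fitted curve is the rate constant `k_max` (min⁻¹) and the
characteristic half-time is `t½ = ln 2 / k_max`.

**Colocalization.**  Manders coefficients per channel and the PDM map
(per-pixel product of the differences from the channel means).

**Flow cytometry.**  SYFP-positive gating against a non-transfected control,
quadrant statistics II/(II+IV), per-time QD geometric means normalized to
time zero, and the M1 marker (threshold leaving ≈4% of time-zero gated
events above it) whose normalized exceedance ("Marker/0 min") tracks
internalized label.

**Synthetic data.**  Because no raw images or event files accompany the
published summary tables, a ground-truthed generator simulates both
modalities: star-convex cells with membrane-enriched receptor signal,
QD puncta split between membrane and deep interior according to a logistic
time course, Poisson/Gaussian camera noise, and bivariate log-normal
cytometry populations with a per-event acid-strip flag.

## Worked example

Fit the published mean internalization ratios (0, 10, 20, 150 min at 37 °C)
and derive the kinetic constants:

```sh
$ endoquant kinetics ref_summary.csv
 ligand           a1       a2        x0    p        dx    k_max    t_half  r_squared
 IGF-II 6.667930e-34 0.931222  8.149081 None  6.925816 0.033614 20.620685   0.959610
insulin 9.241462e-33 0.946903 21.022270 None 12.257363 0.019313 35.890309   0.950285
```

Reading: IGF-II reaches its maximal internalization rate
k_max ≈ 0.034 min⁻¹ (half-time ≈ 20.6 min) while insulin internalizes more
slowly, k_max ≈ 0.019 min⁻¹ (half-time ≈ 35.9 min) — IGF-II is carried in
roughly 1.7× faster through the same receptor.

The full simulated pipeline (render fields → segment → measure → filter →
summarize → fit) runs end to end from one seed:

```sh
$ endoquant quantify --seed 1 --outdir demo_out
 ligand  time_min     mean      sem  n
 IGF-II       0.0 0.168615 0.012746 15
 IGF-II      10.0 0.645198 0.016145 15
 IGF-II      20.0 0.801435 0.017544 15
 IGF-II     150.0 0.956385 0.008067 15
insulin       0.0 0.058871 0.010099 15
insulin      10.0 0.278588 0.017930 15
insulin      20.0 0.496749 0.024537 15
insulin     150.0 0.909859 0.012077 15
 ligand    k_max    t_half  r_squared
 IGF-II 0.047212 14.681624   0.980874
insulin 0.027599 25.114738   0.994721
```

Here the per-timepoint means are measured from rendered images (15 cells per
ligand × time), and the fitted constants recover the faster-ligand ordering
built into the simulation truth.  `demo_out/` holds the per-cell table, the
exclusion log, summary/comparison/fit CSVs and a JSON run report.

Other subcommands: `simulate-images`, `simulate-events`, `coloc`, `flow`,
`run-all` (see `endoquant --help`).  Everything is also callable as a
library; the CLI is a thin shell over `endoquant.pipeline`.

## Layout

```
src/endoquant/
  synthetic.py        ground-truthed image + event simulation
  segmentation.py     background, cell masks, erosion partition, QD mask
  internalization.py  ratios, expression filter, summaries, t-tests
  kinetics.py         sigmoid fits, k_max, half-times
  colocalization.py   Manders coefficients, PDM map
  cytometry.py        gating, quadrants, geometric means, M1 marker
  pipeline.py         orchestration, TIFF/CSV/YAML I/O, run reports
  cli.py              click command line
docs/methods.md       model assumptions, defaults, limitations
```
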
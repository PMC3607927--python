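# Methods

This note documents the models, defaults and numerical choices behind
endoquant, and what the simulation-based tests do and do not demonstrate.

## Internalization measurement

A field carries two registered channels: the receptor fusion protein
(delineates the cell, membrane-enriched) and the quantum-dot ligand
(punctate).  The quantitative path is deliberately filter-free: a scalar
background (image median by default; mean of a user-supplied empty region
as an alternative) is subtracted and clipped at zero, and no smoothing is
applied before measurement.

**Cell segmentation.**  Otsu threshold on the background-subtracted
receptor channel, hole filling (cells must be solid for the erosion step),
8-connected components, area filter (default ≥ 200 px), border-touching
cells flagged and excluded (their rim/core partition is truncated).  Each
retained label is then expanded outward by `grow_px = 2` px
(nearest-label expansion, so neighbors never merge).  The expansion exists
for a measurable reason: the intensity threshold crosses the flank of the
PSF-blurred membrane signal, so membrane-bound ligand puncta — which sit at
the cell outline — would otherwise lose part of their blurred flux just
outside the detected boundary, biasing the interior fraction upward.  Two
pixels ≈ 1.3 PSF sigma at the default optics recovers most of that skirt
while keeping the detection boundary (`core_mask`) available unmodified.
A fixed threshold and externally supplied masks are supported for manual
workflows.

**Membrane/interior partition.**  The cell mask is eroded `iterations`
times (default 8, valid range of interest 5–20); iteration k uses the
4-connected cross for odd k and the 8-connected square for even k.
Alternating the two elements approximates a disk better than either alone
(pure-4 erodes to a diamond, pure-8 to a square); both pure settings remain
available.  The eroded core is the *pre-interior*, the peeled rim the
*pre-membrane*; intersecting both with the QD-positive mask yields the
measured *membrane* and *interior* compartments.  The partition is exact by
construction: rim and core are disjoint and cover the cell, so the two
compartment sums add to the total QD signal inside the masked cell with no
tolerance.  A cell whose core is exhausted by the erosion is flagged
degenerate and excluded, never imputed.

**QD mask.**  QD-positive pixels exceed `k_sigma` (default 3) times a
robust noise scale of the background-subtracted QD image.  Because the
subtraction clips at zero, symmetric noise becomes half-normal; its scale
equals the 84.13th percentile of the clipped image, which is the estimator
used (a plain MAD on clipped data underestimates sigma about two-fold and
floods the mask with noise pixels).  When that percentile is zero —
noiseless or extremely sparse images — every strictly positive pixel is
treated as signal.

**Per-cell statistics.**  ratio = interior sum / (interior + membrane sum);
gain-invariant under joint rescaling.  Receptor expression is estimated as
the mean receptor intensity over the cell, and the analysis retains only
cells within a fold window (default 2×) of the experiment-wide median
expression, because over-expression alters internalization rates; every
exclusion is logged with its value and the window.  Group summaries are
mean ± s.e.m. (sample SD/√n); ligands are compared per timepoint with
two-tailed t-tests (pooled-variance Student by default, Welch optional,
and a summary-based variant t = Δm/√(sem₁²+sem₂²) with Welch–Satterthwaite
degrees of freedom for published tables).

## Kinetics

Two four-parameter sigmoid families are supported.

* **Symmetric logistic** (default): y(t) = a1 + (a2−a1)/(1+exp(−(t−x0)/dx)).
* **Log-logistic**: y(t) = a2 + (a1−a2)/(1+(t/x0)^p), anchored at y(0)=a1.

Fits are bounded least squares (scipy trf) with a multi-start grid
(a1 = min y, a2 = max y; x0 at the time of the closest-to-midpoint value
and at the median time; dx ∈ {span/10, span/4, span/2} or p ∈ {1, 2, 4});
the best residual wins, ties break to the smoothest curve.  Baseline and
plateau are bounded to [0, 1] by default because the measured quantity is a
fraction.  That bound is load-bearing: with four points and four
parameters, permitting a plateau above 1 admits an exactly interpolating
log-logistic solution with p < 1 whose slope diverges at the origin,
yielding a physically meaningless rate constant.  Constrained to physical
fractions, the symmetric logistic reproduces the published rate constants
from the published summary means (k_max 0.0336 min⁻¹ for IGF-II against
the printed 0.034 ± 0.002; 0.0193 min⁻¹ for insulin against the printed
0.021 ± 0.001 — the insulin point estimate sits just below the printed
band, consistent with fitting rounded two-decimal summary means rather
than the original per-cell data).  The shape parameter is kept resolvable
(p ≤ 20; dx ≥ span/100) to exclude step-function corners on degraded data.

k_max is the maximum of the analytic derivative located on a dense grid
(10⁴ points over (0, 1.1·t_max]) and refined by bounded scalar
minimization; t = 0 is excluded so p ≤ 1 log-logistic fits report the
maximum over observable times.  Closed forms — (a2−a1)/(4dx) at x0 for the
symmetric family, t* = x0((p−1)/(p+1))^{1/p} for the log-logistic with
p > 1 — serve as independent cross-checks in the tests, not as the
implementation.  The half-time is ln(2)/k_max by default (the maximal
slope read as an effective first-order rate constant); the curve midpoint
x0 is available as an alternative definition but is not consistent with
the published half-times, which match the ln 2 convention.

Weighted fits (by n or 1/sem²) are available; the unweighted fit of the
per-timepoint means is the default and is what the reported constants use.

## Synthetic data generator

The generator emulates the study conditions so that every analysis stage
can be validated against known truth.

* **Geometry.** Star-convex cells: an ellipse (eccentricity ≤ 0.15)
  modulated by low-order cosine modes (irregularity ≤ 0.10), radius
  18–28 px, placed by dart throwing with ≥ 3 px gaps and a 3 px border
  clearance.  Membrane band width 4 px.
* **Receptor channel.** Membrane band at the cell's expression level
  (800–1600 counts) plus a 25% cytoplasmic haze, blurred by a Gaussian PSF
  (σ = 1.5 px).
* **QD channel.** 30–50 point-source puncta per cell, each ~2500 counts
  total flux (log-normal, CV 20%), assigned to the interior with the
  cell's true fraction f and to the membrane band otherwise, then
  PSF-blurred.  Interior puncta are placed in a deep-interior region (cell
  eroded by band width + 8 px): internalized ligand resides in endosomes
  that traffic away from the cortex toward the perinuclear region, and
  this placement depth is deliberately decoupled from the analysis erosion
  depth so partition robustness can be probed by sweeping the iteration
  count.
* **Noise.** Scalar background (100 counts), Poisson shot noise on
  signal + background, Gaussian read noise (SD 2) — SNR ≈ 10 at punctum
  peaks.  With noise and background off, the rendered QD channel conserves
  punctum flux to < 1% (blur truncation at field edges only).
* **Time courses.** Per-ligand log-logistic truth; the bundled two-ligand
  defaults approximate the published mean ratios (fast ligand:
  a1 0.17, a2 0.96, x0 8.5 min, p 1.4; slow: 0.06, 0.95, 22 min, 1.5).
* **Cytometry events.** Four subpopulations from transfected × labeled
  Bernoulli draws; SYFP ~ log-normal (median 100 untransfected / 3000
  transfected), QD ~ log-normal (median 50 unlabeled / 2000 labeled).
  Acid stripping is a per-event boolean: a labeled event keeps the labeled
  QD distribution only if internalized by its sampling time (Bernoulli
  with the time-course probability, default a1 0.15, a2 0.95, x0 35 min,
  p 2 — baseline matching the measured time-zero internalized fraction and
  magnitudes in the range the flow experiment reports); stripped events
  fall back to the unlabeled distribution.  Without acid, all labeled
  events keep full label, which is why the no-acid geometric-mean series
  stays flat.
* **Determinism.** All randomness flows from one master seed through
  spawned child generators (one per field / sample); identical
  config + seed reproduces arrays and manifests bit-exactly.

What the generator does *not* model: 3-D optics (single plane only, no
z-stacks), QD blinking (endpoint snapshots), spectral bleed-through,
cell-to-cell variation in the true interior fraction at a timepoint
(variation arises from the binomial punctum split and noise), debris and
doublets in cytometry, and compensation/spillover.  Passing recovery tests
therefore demonstrates the correctness and internal consistency of the
measurement chain under the stated model — not robustness to every
real-microscope artifact.

## Parameter-recovery behavior

At default settings (8 erosion iterations, 3σ QD mask, 2 px label growth,
50 cells per condition) the mean measured ratio tracks the true interior
fraction within 0.05 across 0.1–0.9, with a residual positive bias of
~0.02–0.03 at low fractions from membrane-punctum flux blurred beyond the
grown boundary.  Deep erosion settings (≥ 16 iterations on ~20 px-radius
cells) exhaust most of the interior and degrade absolute ratios, but the
faster/slower ligand ordering of fitted k_max survives the full 5–20
iteration sweep.

## Problem sizes

Defaults for the bundled simulated experiment are 2 ligands × 4
timepoints × 3 fields × 5 cells at 256×256 px; the recovery analysis uses
50 cells per condition (10 fields × 5 cells).  These sizes give s.e.m.s
comparable to the published per-timepoint summaries (n ≈ 19–29 cells)
while keeping a full pipeline run in seconds on one core.

## Known limitations

* The original study's exact erosion-element sequence, QD threshold and
  expression window are not recorded; the defaults here are documented
  choices within the stated ranges, and all are configurable.
* Published p-values were computed from unrounded per-cell data; from the
  rounded summary tables only order-of-magnitude agreement is possible.
* The flow-cytometry marker magnitudes (Marker/0 min per ligand) are
  measurements on cells; the event model emulates their structure, and
  the package reproduces them only by construction, not from raw data.
* Cytometry input is CSV event tables; list-mode FCS files must be
  exported to CSV upstream.
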
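# Methods

This document describes the signal model, the analysis choices, the synthetic
generator, and the package's numerical conventions and limitations.

## Signal model and contrast

An interleaved acquisition alternates *nulled* volumes (intravascular blood
signal suppressed) and *control* volumes at a volume TR of 6.082 s, so one
nulled/control pair spans an effective TR of 12.164 s. Writing `S` for the
extravascular tissue signal, `v` for the fractional intravascular (blood
volume) signal, and `b` for the multiplicative BOLD factor shared by both
volumes of a pair:

```
C = S · b            (control)
N = S · (1 − v) · b  (nulled)
vaper = (C − N) / C = v
```

The division removes `b` *exactly* — not approximately — for any positive
multiplicative factor, which is the central algebraic property the test suite
asserts to machine precision. The package also forms the uncorrected BOLD
series (the control signal) so the two contrasts can be compared; and an MT
anatomical contrast `(control − MT) / MT` for tissue delineation in the same
distorted space.

Conventions: pairs are formed in acquisition order regardless of which
condition leads; an unequal condition count is truncated with a warning;
control values ≤ 0 give a missing (NaN) contrast value and are counted;
pair timestamps are the midpoint of the two constituent volumes.

## Preprocessing

* **Censoring.** A pair is censored when either constituent volume has
  (a) motion-derivative Euclidean norm (enorm) > 0.4 mm — e.g. a combined
  0.3/0.3 step, enorm √0.18 ≈ 0.424, is censored while an isolated 0.3 step
  is kept; (b) a volume outlier fraction ≥ 0.10 (inclusive); or (c) a dummy
  (pre-steady-state) flag. Outlier fractions are computed per volume as the
  share of in-mask voxels whose residual from a Legendre trend fit (orders
  0–5, fitted excluding dummy volumes) exceeds 4.5 × MAD; a relative
  zero-MAD guard (MAD ≤ 1e−9 × voxel scale) prevents constant voxels from
  being flagged through float rounding.
* **Nuisance regression.** Per voxel, over kept pairs only: Legendre drift
  (orders 0–5), six pair-level motion parameters and their backward
  derivatives, the mean CSF signal, and a local white-matter regressor — the
  mean raw WM signal within a 15 mm sphere of the voxel (ANATICOR-style),
  computed by FFT convolution with a spherical kernel. Residuals are divided
  by the voxel's pre-regression mean; censored pairs are NaN in the output.
  Rank-deficient designs drop collinear columns with a warning.
* **Evoked removal (optional).** A shared evoked response can be projected
  out of the laminar series within a region before connectivity analysis.

## Surfaces and depths

Depth surfaces are placed by the equi-volume rule. With per-vertex one-ring
areas `a_w` (white) and `a_p` (pial), the distance fraction `ρ` at cumulative
volume fraction `α` solves `a_w ρ + (a_p − a_w) ρ²/2 = α (a_w + a_p)/2`,
giving

```
ρ = (−a_w + sqrt((1 − α) a_w² + α a_p²)) / (a_p − a_w)
```

which reduces to the equidistant rule `ρ = α` when `a_w = a_p`. The default
18 depth bins use bin-center fractions `α_d = (d + 0.5)/18`. Sampling to the
laminar mesh is trilinear and NaN-aware: corner voxels that are NaN at every
timepoint are dropped and the remaining corner weights renormalized, so a
gray-matter mask can be applied to the volume without eroding the sampled
ribbon; a 5× upsampled nearest-neighbor mode is also provided. Within-depth
smoothing uses iterated neighbor averaging calibrated to a target FWHM
(default 3 mm) and never mixes depths. Surface registration applies one
vertex correspondence at every depth (block-diagonal over depths), so it can
never blur a laminar profile across depths — an exactness the tests assert.

## Connectivity and laminar typing

FCS (functional connectivity strength) at a (vertex, depth) sample is the
mean of positive Fisher-z-transformed Pearson correlations with a target
set: all depths of the other network vertices (network FCS), a seed series
or seed vertex set (seed FCS), or representative series of a whole-cortex
columnar parcellation (hubness; 1000 nodes by default). Correlations are
clipped to |r| ≤ 1 − 1e−7 before `atanh` (z ≈ 8.406 at the clip); values
within 1e−6 above 1 are tolerated as float rounding. At least 8 timepoints
are required.

Laminar typing clusters per-vertex depth profiles with k-means under the
correlation distance (k = 2, 10 restarts). Cluster indices are *anchored*:
the cluster whose mean profile peaks in the middle third of the ribbon
(depths 7–12 of 18, 1-based) is labeled 1 (feedforward-type), the other 2
(feedback-type). Reliability is the mean anchored-label Dice over 50
split-half repetitions, compared by t-test against 50 pairs of fair random
labelings, whose expected Dice is exactly 0.5.

## Synthetic generator

The generator builds a spherical two-surface cortex (white radius 8 mm,
thickness 2–3 mm) on a 40³ grid of 0.7 mm voxels, plants geodesic network
patches whose coupling to shared latent signals follows a laminar profile
(middle-peak, superficial-peak, double-bump, or uniform; Gaussian bumps with
σ = 0.16 in depth fraction over a 0.15 baseline), and synthesizes the
interleaved series from the signal model above with:

* linear vein-bias BOLD gain `bold_gain · (1 + slope · depth_frac)`
  (slope 1.0): the BOLD series inherits the superficial bias, the
  blood-volume contrast must not;
* baseline blood fraction 0.05, idiosyncratic vertex signals, CSF leakage,
  multiplicative thermal noise (default sd 0.02 of baseline), slow drift,
  random-walk + spike motion with data glitches, and 1.05× pre-steady-state
  dummy volumes.

Groups tie several sessions to one template through known
rotation-plus-relabeling deformations, so registration accuracy is checkable
exactly. Every output is a deterministic function of the integer seed.

What the generator does *not* emulate: hemodynamic response dynamics and
delays (latents couple instantaneously), geometric distortion,
physiological (cardiac/respiratory) noise spectra, realistic folded cortical
geometry, partial-volume effects beyond the grid discretization itself, and
actual blood-nulling pulse physics.

## Parameter defaults and rationale

| parameter | default | rationale |
|---|---|---|
| volume TR / effective TR | 6.082 s / 12.164 s | targeted acquisition protocol |
| depth bins | 18 | fine enough to resolve middle vs superficial peaks at 0.7 mm |
| enorm threshold | 0.4 mm | standard strict motion censoring at high resolution |
| outlier fraction | 0.10 (inclusive) | volumes with ≥ 10 % outlier voxels are unusable |
| drift polynomial order | 5 | matches run lengths of ~10–15 min |
| local WM radius | 15 mm | large enough for stable local averages, small enough to stay local |
| smoothing FWHM | 3 mm | within-depth only; preserves laminar resolution |
| columnar nodes | 1000 | whole-cortex coverage for hubness at tractable cost |
| k, restarts | 2, 10 | two laminar types; restarts stabilize the correlation k-means |
| reliability repetitions | 50 | matches the random-null sample size |

## Numerical choices

* Exact integer bookkeeping for grid/laminar sizes (no float round-off even
  at 10¹⁵ voxels).
* The equi-volume formula is evaluated in a numerically safe form and
  validated against a Brent-root oracle to 1e−10.
* The local-WM regressor uses FFT convolution (O(N log N)) rather than
  per-voxel neighborhood queries; counts are rounded to integers before
  division.
* All stochastic steps take explicit integer seeds; pipeline reruns are
  bit-identical.
* Missing data is NaN end to end: censored pairs, out-of-mask samples, and
  zero-variance series propagate as NaN and are counted, never silently
  dropped.

## Limitations

* The synthetic cortex is a sphere; results on folded geometry (high
  curvature, kissing gyri) are validated only through the equi-volume area
  terms, not through realistic meshes.
* FCS is restricted to positive correlations by construction;
  anti-correlated coupling maps to zero, not to a negative strength.
* The group template registration assumes a known vertex correspondence;
  no registration *estimation* is implemented.
* Statistical inference is limited to the split-half Dice t-test against the
  random-pattern null; no spatial autocorrelation correction is attempted.
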
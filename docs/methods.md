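# Methods

This note documents the models, parameter choices and numerical decisions
behind `kinorm`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Array model

A slide carries `n_sets` (default 3) identical replicate sets of
`set_rows × set_cols` (default 32×32) substrates, stacked vertically, spotted
at a 560 μm pitch with ~250 μm spot diameter; each 8×8 sub-block comes from
one spotting pin. All normalization geometry uses Euclidean distances
between *nominal* grid centers in micrometres — never refined image centers —
so that normalization results cannot depend on sub-pixel refinement noise.

The nearest-spot search grows a circle around the query spot in steps of one
pitch until it holds at least N eligible spots, then returns everything
inside the final radius (boundary ties included, which keeps the result
deterministic and order-independent). The search never crosses replicate-set
boundaries: a deviation is a property of a location *within* a set, and a
cross-set neighbourhood would mix gradient regimes.

## Imaging

The phosphorimager stores square-root-compressed 16-bit pixels. The exact
published form of the reversal is not available to us beyond its constant,
so the package uses `I = raw²/TF` with `TF = 42752`, the form consistent
with "reversing a square-root compression" and with the saturation level
(95 000 is reachable below the 16-bit ceiling, since 65535²/42752 ≈ 100 459).
The transform is exposed as a configurable callable.

Enhancement (gridding/QC only — quantification always reads the
reverse-transformed raw image):

| step | parameter | default | rationale |
|---|---|---|---|
| median filter | size | 3×3 px | shot-noise suppression |
| −LoG | σ | spot radius/√2 ≈ 1.8 px | matched filter: zero-crossing at the spot edge |
| grey opening | disc radius | 1 px (50 μm) | removes structures < 100 μm |
| Gaussian | σ | 1 px | final smoothing |

Rotation alignment thresholds the enhanced image at its 87th percentile and
scans ±3° (coarse 0.5°, fine 0.1°), maximizing the variance of the
column-sum profile — sharp column peaks are equivalent to vertical
alignment. An optimum on the ±3° bound is clamped with a warning.

Grid fitting per pin block detects round, spot-sized objects at two
thresholds (96th percentile = bright, weight 3; 85th = weak, weight 1;
non-round or wrongly sized components are discarded), then searches grid
translation (±half a pitch, 0.25 px steps) and pitch scale (±5%), scoring
the summed weights of objects whose centroid lies within 125 μm of a grid
node. Because that score has plateaus, ties prefer scale 1 and a final
weighted least-squares polish refits translation and pitch to the matched
centroids. Blocks with no detected objects fall back to the nominal grid
with a warning. Object detection applies a noise guard (thresholds must
also clear median + 4–6 robust SD of the block) so that blank blocks
genuinely yield no objects.

## Quantification and flags

Net intensity = mean over the 21-pixel disc (Ø 250 μm) minus the median of
the local background; `net_log2 = log2(net)` when net > 0, missing
otherwise (the no-contrast condition; we treat net ≤ 0 as missing so the
logarithm is always defined for unflagged spots). The spot center is
refined within ±2 px of the fitted grid node by maximizing disc mean.

The background window is the square of **side** 550 μm (11×11 px) around
the center minus the inscribed 275 μm-radius circle — i.e. the four window
corners, which sit in the diagonal gaps between neighbouring spots. We
read the published "square range of 550 μm" as a side length: with the
560 μm pitch, a 550 μm *half*-width window would overlap all eight
neighbouring spot footprints and contaminate the background median on dense
slides, while the 275 = 550/2 exclusion radius makes the inscribed-circle
reading internally consistent. Pixels belonging to large artifacts or
overly large spots (connected components above 4× the disc area) are also
excluded from the background; fewer than 10 surviving background pixels is
a background failure and flags the spot as artifact.

Flags (0 = reliable, 1 = unreliable; overall = OR of the seven):

* **artifact** — a large connected above-threshold object covers > 30% of
  the spot's background window or of its disc. "Large" means elongated
  (aspect > 1.6) and > 2× the disc area, or bigger than any credible single
  spot (default 200 px); the verbal flag definition fixes no formula, so
  this operationalization is a package design choice, tuned to catch
  stripes and blemishes without mistaking bright round spots for artifacts.
* **overshine** — a bright neighbour (net_log2 > 8) whose intensity
  decreases monotonically along the ray from the midpoint between the spots
  into the spot center, while the disc mean exceeds background + 3 SD. A
  genuine spot has its own peak, so the profile rises near the center and
  the flag stays off.
* **ks** — two-sample Kolmogorov–Smirnov test of disc vs background pixels
  fails to reject at α = 0.01: the spot is indistinguishable from
  background, i.e. an off-spot. (Polarity note: the flag marks
  *indistinguishable* spots; downstream normalization excludes them like
  any other flag. The asymptotic KS p-value is used; at 21 vs ~24 pixels
  the exact method is needlessly slow and changes no decisions at α = 0.01.)
* **no-contrast** — net ≤ 0, or the enhanced response is negative over the
  whole disc.
* **saturated** — more than 3 of the 21 disc pixels exceed 95 000 on the
  reverse-transformed scale.
* **shape** — the 500 μm window is thresholded at its 80th percentile
  (with ≥, so plateaus of equal-valued pixels survive); the component
  nearest the center must have aspect ratio ≤ 1.6 for bright spots
  (net_log2 > 8) or ≤ 2.0 for weak spots.
* **position** — the intensity-weighted centroid of the 20% brightest
  window pixels must lie within 100 μm (configurable) of the grid node.
  Shape and position are evaluated only for spots with positive net signal;
  off-spots are already covered by ks/no-contrast.

Flagged spots are excluded downstream, never repaired or imputed.

## Intra-array gradient correction

For each spot, deviations against its two replicate counterparts are
computed (only between unflagged spots). The local gradient at a spot is
the median deviation over the 20 nearest eligible same-set spots (self
excluded), taken separately against each replicate set, and the correction
`(gradient₁ + gradient₂)/3` is **subtracted**. The divisor and sign are
fixed by the uniform-offset identity: if one set is shifted by −δ, the
corrections are +δ/3, +δ/3, −2δ/3 and all three sets land exactly on the
common value — the test suite verifies this to machine precision over
random offsets and layouts. The correction is a single pass (iterating it
is possible but changes little once replicates agree); flagged spots pass
through uncorrected since they are excluded downstream anyway. A 2-D
lowess surface is deliberately *not* used: with ~1000 features and a large
off-spot fraction there are too few reliable anchors for surface fitting,
which is the reason the replicate-based local-median design exists.

## RSE interarray normalization

Slides are normalized per control/treatment pair on substrate triplicate
means (only unflagged replicates averaged; a substrate is eligible when it
has a mean in both conditions):

1. **Local median-centering** over eligible substrates: for substrate s,
   d(s) = meanB − meanA and m(s) = median of d over the N = 20 nearest
   eligible substrates. Unlike the intra-array step, the querying
   substrate itself is *included* in its own neighbourhood (there is no
   reason to exclude it: d(s) is not being compared against itself).
   The offset is applied symmetrically (+m/2 to A, −m/2 to B), preserving
   the pair mean; anchoring one slide instead is an exposed option.
2. **Exclusion**: a two-sided pooled-variance Student t-test on the ≤3
   replicate values per condition (p < 0.1) marks substrates plausibly
   affected by treatment. Pooled variance rather than Welch: with n = 3
   per group the Welch degrees of freedom are unstable; the variant is
   switchable. Zero pooled variance resolves to p = 1 (equal means) or 0.
   Untestable substrates (< 2 unflagged replicates on either slide) are
   treated as unaffected for normalization purposes.
3. **Re-centering** on the eligible-minus-excluded set, rebuilt from the
   *original* (gradient-corrected) values — so substrates excluded early
   can re-enter later. Tests run on the currently centered values, which
   makes the decision invariant to the array effect being removed.

Steps 2–3 iterate until the exclusion set repeats. Convergence is exact
set identity; a cycle with period > 1 (which exact-identity detection can
produce on marginal substrates) is resolved by normalizing on the
complement of the union of the cycling sets, with a warning. The converged
normalization set typically holds 70–90% of substrates under the default
simulated design — recomputed, not assumed, by `scripts/acceptance.py`.

Baselines, for comparison studies: global median-centering over all spots
(flags ignored), and Bolstad-style quantile normalization (rank → mean of
order statistics; ties get their tied quantile mean; missing values are
left unnormalized and excluded from quantile estimation, with interpolation
across unequal finite counts).

## In-silico experiment generator

Each spot value (log2, dimensionless) is the sum of: basic intensity
N(10, 1.5) per substrate (shared by both conditions and all replicates);
inter-patient variation N(0, 0.5); the treatment effect E on induced
substrates (treatment slide only; default E = 0.8 = 2× the spot error SD,
197 of 1024 substrates induced, mirroring two activated pathways with 18
kinases); one of 15 smooth 96×32 gradient fields per slide (drawn
independently per slide); a per-slide array effect U[−2, 0]; and a
per-replicate spot error N(0, 0.4). Pathway mode adds biological
(per-patient, N(0, 0.4)) and technical (per-substrate, uniform ±0.2 or
±0.33·E) effect-size variation.

Choices where the published design is silent:

* **Gradient fields** are parametric (1–3 low-frequency cosine bumps,
  rescaled so max − min equals the configured strength, zero mean) rather
  than fixed lookup surfaces; "strength" is the field's range in log2
  units, anchored to the 0.4–1.5 range reported for real slides, default
  1.0 (mid-range).
* **Off-spots** (default fraction 0 in the validation design, sweepable)
  are modelled as detection-floor noise (N(floor, σ_spot), floor = 3.0
  log2) carrying a pre-set KS flag — off-spots are reliably
  unphosphorylated and are recognized as background-like by QC.
* **Spot error is per replicate**, not per substrate; otherwise triplicate
  t-tests would be degenerate.
* One master seed spawns named substreams (basic, patient, effect,
  gradient, array, spot error, induced set, off-spots, fields), so changing
  one component leaves the other draws untouched.

The renderer draws each spot as a flat 250 μm disc convolved with a 75 μm
Gaussian excitation spread — fuzzy boundaries with compact tails. A pure
Gaussian with FWHM = 250 μm was tried and rejected: its tails overlap
neighbouring background windows at the 560 μm pitch and bias the
background median upward on dense slides. Amplitudes are set so the disc
mean exceeds background by exactly 2^net_log2, then the forward square-root
compression and 16-bit quantization are applied.

What the generator does *not* emulate: heavy-tailed real background,
spatially correlated noise, chemistry-driven spot morphology differences,
and the real substrate→kinase annotation. Passing tests therefore
demonstrate correctness of the algorithms under the stated stochastic
model, not performance on any particular biological data set.

## Evaluation harness

Per-substrate two-sided pooled t-tests (same variant as the RSE exclusion
step) are classified against the simulated truth; the ROC sweeps the
p-value threshold (score = −p, ties rank-averaged) and the trapezoidal AUC
equals the Mann–Whitney statistic — verified against exhaustive pair
counting in the tests. Pathway tests pair each substrate's triplicate mean
in condition A with condition B (paired t across substrates, within
patient); pathways with < 3 usable substrates are skipped. The benchmark
driver runs simulate → (optional) gradient-correct → normalize → test →
AUC per patient and reports mean ± SEM over 8 virtual patients per cell.

## Problem sizes and tolerances

The default designs used by the tests and the acceptance script are the
full-scale ones (8 patients, 3×1024 spots); imaging round-trips use one
full slide (~1120×404 px) plus small 8×8 blocks for unit-level geometry.
Monte-Carlo bands in the tests are 3-SE-style tolerances at the stated
replication (e.g. type-I error in [0.03, 0.07] at 8×1024 null tests).
Numerical comparisons against brute-force oracles are exact to 1e-12;
the uniform-offset gradient identity holds to machine precision by
construction.

## Known limitations

* RSE is pairwise by design (the study design it supports is
  control/treatment per patient); no multi-slide generalization.
* Layouts must be whole-set replicates; scattered replicate placement is
  unsupported.
* The exact published reverse-transform equation body and the original
  gradient surfaces are unavailable; both are replaced by documented,
  configurable stand-ins (see above).
* Quality-flag operationalizations (artifact geometry, overshine ray test)
  are package design choices where the published descriptions are verbal;
  their parameters are all exposed in `QuantifyParams`.
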
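# Methods

## Objective: Kapur entropy over gray-level classes

An *n*-bit image has `L = 2^n` gray levels with empirical probabilities
`p_i = counts_i / Σ counts`.  A threshold set `t_1 < … < t_k` (each in
`[1, L−1]`) induces classes `[0, t_1−1], [t_1, t_2−1], …, [t_k, L−1]`;
classes are lower-closed and the top class is closed at `L−1`, the largest
representable value.  The objective is the sum of within-class Shannon
entropies of the normalised class distributions (natural logarithm
throughout).  Two conventions keep it total: `0·ln 0 := 0`, and an empty
class contributes zero entropy — so degenerate threshold placements are
scored, not rejected.  Restricting thresholds to `[1, L−1]` means no class
is structurally empty at the boundary.

The implementation precomputes prefix sums of `p_i` and `p_i ln p_i`, so a
class entropy is `ln ω − S/ω` in O(1) and a whole batch of candidate
threshold tuples is scored vectorised.  A direct double-loop reference
implementation exists only in the test suite and agrees to 1e−10.

## Search space and decoding

Particles move in the continuous box `[1, L−1]^D` with `D` the threshold
count.  Decoding rounds half-up, sorts, and repairs duplicates by pushing
the later duplicate to the next unused integer (with a backward pass when
the ceiling `L−1` is hit).  Repair rather than rejection keeps every
particle evaluable in the unconditional update loop.  `D ≥ L−1` is an
error: there are not enough distinct integer levels.

## Baseline PSO

Classic velocity/position update with `ω = 0.8`, `c1 = c2 = 1.5`,
population 30, 100 iterations (the standard comparison protocol for this
problem family).  `r1, r2` are drawn independently per particle *and per
dimension* — the canonical formulation, which explores better in `D > 1`
than a scalar draw.  Positions are clamped (not reflected) at the bounds
with the velocity left unchanged.  Velocity is clamped at
`v_max = v_max_fraction · (UB − LB)` with a **default fraction of 1.0**:
a particle may cross the entire box in one step, so the update is
effectively unclamped, as in the classic formulation, and the cap only
guards against numeric runaway.  This default matters scientifically: a
tight clamp (e.g. 0.2) suppresses exactly the premature-convergence
behaviour of fixed-inertia PSO on wide 12-bit ranges that the CIWP variant
addresses, and simultaneously over-restricts the CIWP update (whose
attraction term is already damped by `ω_reverse ≈ 0.5`), distorting any
comparison between the two.

## CIWP-PSO

Per iteration: evaluate all particles → update personal/global bests →
partition by fitness → layered update.

**Partition.**  Stable sort by fitness descending (ties: lower index ranks
better).  Elite = the single best; worst tier = bottom
`round((1 − rate)·N)` (with `rate = 0.9` and `N = 30`: 3 particles, i.e.
10%, inside the 5–20% band the strategy calls for); middle = the rest.
The tier size is capped at `N − 2` so the middle is never empty;
`rate = 1` yields an empty worst tier and disables opposition learning.

**Elite.**  Frozen for the iteration (position and velocity untouched) —
pure elitism; it still attracts the middle tier through `gbest`.

**Worst tier — random opposition learning.**  `P ← LB + UB − r·P`,
clamped to the box.  `r` is drawn per dimension by default (a scalar draw
per particle is available via `rol_per_dimension=False`); per-dimension
draws produce more diverse opposite points, which is the purpose of the
strategy.  Velocity and personal-best history are retained — only the
position is replaced, and the moved particle is evaluated at the start of
the next iteration.

**Middle tier — complementary weights.**  The fitness coordinate
`x = (f − (f_best + f_worst)/2)/(f_best − f_worst)` uses the *current
iteration's* swarm extremes (not all-time records) so the weights keep
adapting as the swarm converges; the degenerate case `f_best = f_worst`
maps to `x = 0` (both weights at the midpoint).  The scaled logit uses
`s_x = 0.96` (keeping the log finite at `x = ±0.5`), `s_y = 7.8`,
`m_x = 0.5`; with natural log, `S(±0.5) = ±ln(49)/7.8 ≈ ±0.49895`, so with
`ω_min = 0.5, ω_max = 0.9` the weights span `[0.50042, 0.89958]` —
essentially the full band.  The pair is computed as
`midpoint ± span·S(x)`, which preserves `ω + ω_reverse = ω_min + ω_max`
exactly in floating point for these parameter magnitudes (verified over
10^6 draws).

**Reduction to the baseline.**  With the worst tier disabled
(`rate = 1`) and `ω_min = ω_max = 1`, both weights are exactly 1 and the
CIWP update coincides term-for-term with the baseline update at `ω = 1`.
Random draws are consumed in the same order (full `(N, D)` blocks for
`r1`, `r2`, opposition draws only when the tier is non-empty), so the two
optimizers follow bitwise-identical trajectories from a shared stream —
an executable correctness check of the whole update path.  For any common
weight `ω ≠ 1` an exact reduction is impossible by construction, because
`ω_reverse` scales the attraction term that the baseline leaves unscaled.

## Exhaustive oracle and rebinning

The oracle enumerates all `C(L−1, k)` tuples (lexicographic order, first
argmax wins, so ties break to the smallest tuple) with vectorised scoring,
and *refuses* instances beyond its budget (default 10^7 tuples) instead of
subsampling — certifiability over convenience.  For 12-bit data the
histogram is first aggregated to 256 levels (adjacent-bin sums; a coarse
threshold `t` maps back to level `t·(L/256)`).  On smooth mixtures the
mapped-back coarse optimum scores within 1% of the full-resolution
optimum (tested at 10-bit/128-level scale, where both oracles are
tractable).

## Synthetic images

Pixels are i.i.d. draws from a Gaussian mixture over the gray range,
rounded half-up and clipped; a fixed seed gives bit-identical images.
Seeded multimodal recipes place 2–5 mode means over the central 80% of the
range (evenly spaced anchors with ±5%-of-range jitter), widths 1.5–4% of
the range, Dirichlet(2) weights — smooth histograms with well-separated
peaks, the regime where segmenting at 4–8 thresholds is meaningful, as in
12-bit medical scans.  The generator emulates only the gray-level
*distribution*, not spatial structure (anatomy, texture, correlated
noise).  Histogram-based thresholding is blind to pixel arrangement, so
optimizer results transfer; the quality metrics (SSIM/FSIM), however, do
see spatial structure, and metric values on mixture images should be read
as sanity checks rather than as predictions for clinical data.  Default
study conditions: 12-bit depth, 256×256 pixels, population 30, 100
iterations, 10 repeats with the median reported (lower-middle order
statistic for even counts).

## Quality metrics

* **PSNR** uses `MAX = 2^n` (the level count) by default — the convention
  under which a uniform unit difference at 12 bits gives
  `20·log10(4096) ≈ 72.2472 dB`; the textbook `2^n − 1` is available via
  `max_convention="levels-1"`.
* **SSIM** follows the universal defaults: `C1 = (0.01 D)^2`,
  `C2 = (0.03 D)^2`, `C3 = C2/2` with `D = 2^n − 1`, an 11×11 Gaussian
  window (σ = 1.5), per-pixel luminance·contrast·structure pooled after
  cropping the half-window border.  A `global` mode (one window, population
  moments) supports closed-form checks.  The windowed mode is cross-checked
  against scikit-image's implementation to 1e−7 in the test suite.
* **FSIM** combines phase-congruency similarity (`T1 = 0.85`) and
  Scharr-gradient similarity (`T2 = 160`), pooled with the pointwise
  phase-congruency maximum.  Both inputs are rescaled to the 0–255 range
  first, so the standard stabilisers apply unchanged at any bit depth
  (equivalent to rescaling `T2` quadratically with the dynamic range;
  gradient magnitude is linear in intensity and enters the similarity
  quadratically).  The phase-congruency transform is implemented from
  scratch (no installed package provides one): 4 log-Gabor scales from
  wavelength 6 at octave spacing, bandwidth `σ_onf = 0.55`, 4 orientations,
  Rayleigh-based noise compensation (`k = 2`) and sigmoid frequency-spread
  weighting.  Published FSIM values are not bit-reproducible across
  implementations — filter-bank details differ — so tests assert
  identities, symmetry, range and agreement with an independent pooling of
  the same feature maps rather than external reference numbers.  Two equal
  constant images (zero congruency everywhere) define FSIM = 1; otherwise
  an ε-guard (1e−12) protects the pooling denominator.

## Win counting and reference tables

An algorithm wins a score-table row when its cell equals the row optimum;
**ties count for every tied algorithm** — the only rule under which the
packaged reference tables reproduce their published win counts (18/27
Kapur-entropy cases and 12/27 PSNR cases for CIWP-PSO on the nine 12-bit
MRI images).  The tables are shipped as CSV at full printed precision
(four decimals); tied entries are digit-identical, so exact float
comparison after parsing is equivalent to exact decimal comparison.

## Benchmark harness

Per-run seeds derive from
`SeedSequence(base_seed, spawn_key=(image, n_thresholds, algorithm, repeat))`,
so adding an algorithm or image never perturbs the other cases' random
streams and identical configs give identical tables.  The median run's
thresholds are rendered (class-mean representative per class, round half
up; interval midpoint for an empty class) and scored with all three
metrics.

## Problem sizes used in the checks

Oracle certification runs at 256 levels with 1–2 thresholds (≈ 32k tuples
at the heaviest); the paired CIWP-vs-PSO comparison runs 5 images × 2
algorithms × 10 repeats at full 4096-level resolution with 8 thresholds;
the per-bin histogram-vs-density check aggregates to 64 bins, where the
expected number of chance 3σ excursions across bins is well below one.
These sizes certify the algorithmic claims exactly or with comfortable
stochastic margins while keeping the whole suite's runtime in seconds.

## Known limitations

* The optimizers certify against the oracle only where enumeration is
  tractable; at 6–8 thresholds on full 12-bit histograms the reported
  entropies are best-found values, bounded above by no certificate.
* The generator's i.i.d. pixels make SSIM/FSIM values optimistic relative
  to structured clinical images.
* FSIM agrees with other implementations qualitatively, not bitwise (see
  above).
* Only the two PSO variants are registered; the harness accepts any
  callable with the same contract, but no other metaheuristics ship with
  the package.
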
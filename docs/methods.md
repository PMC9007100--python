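# Methods

## The surface and the spine model

A trunk segment is modelled as a cylinder of circumference *C* and height *H*
(default 30 cm, the scale of a basal trunk strip), unrolled to a plane strip.
The x axis is periodic with period *C* ("torus wrap"): all circumferential
distances are computed modulo *C*, so an animal reaching around the stem is
handled correctly and a spine on the far side of a thin stem is genuinely far
from a bite on the near side.  The y axis is not periodic; y = 0 is the
bottom and climbing proceeds in +y.

Spines are point obstacles located at their base.  Spine length is recorded
and carried through I/O but does not enter the default simulations: no
observation ties blocking radius to spine length, and making points the
default keeps the two simulators' geometry assumptions minimal and explicit.
Coordinates are continuous centimetres; x is stored normalized to [0, C).

## Synthetic maps

The analyses were designed for field-digitized spine maps, which are not
distributed; the generator reproduces their statistical structure so the
pipeline is testable end to end.

Four syndrome presets fix density and mean spine length at the published
per-syndrome means — prickly 2500 m⁻² / 2.2 cm, thorny 1800 m⁻² / 8.9 cm,
crown 800 m⁻² / 2.7 cm, liana 1300 m⁻² / 2.0 cm — with arrangement `random`
for prickly and liana (internodal cork spines / prickles) and `phyllotaxic`
for thorny and crown (thorns and stipular spines exist only at nodes).

- **Random** maps are homogeneous Poisson processes with the preset
  intensity.  The measured maps were never modelled as a process, so the
  minimal-assumption stationary choice is used.
- **Phyllotaxic** maps restrict spine bases to node rows spaced
  `node_spacing_cm` apart (default 2 cm, an internode-scale spacing), with
  `cluster_size` spines per occupied node, jittered in x only (σ = 0.5 cm) so
  node-row membership stays exact; the number of occupied nodes is Poisson so
  the expected total count still equals density × area.  Defaults:
  cluster_size 1 for thorny, 2 for crown (paired stipular spines).  With
  2-cm node rows the pattern is quasi-Poisson at the scale of a dilated bite
  window, which keeps the syndromes' simulated defence ranking a function of
  their printed density ranking; strong clumping (large cluster_size with
  wide node spacing) would instead open spine-free corridors and invert the
  thorny/liana ranking, contradicting the reported orderings.
- Spine lengths are i.i.d. log-normal with sd defaulting to 30 % of the mean
  (positive support, right skew).

Trait tables draw each species' categorical states from its syndrome's
profile with a default 5 % flip rate (clusters stay recoverable while
robustness is exercised), and continuous traits log-normally around the
preset means.  Nutrition tables follow a log-scale linear model
(baseline + group multiplier + species effect + month effect + residual)
with defaults: nitrogen 20 mg/g, total phenols 50 assay units, inner bark
3 mm, species/month/residual SDs 0.20/0.10/0.15, and the prickly syndrome's
inner bark ×2 — the headline nutrition contrast.  All generators take
explicit integer seeds; there is no global random state.

What the generator deliberately does **not** emulate: vertical density
gradients (reported qualitatively but not quantified; exposed as a possible
extension, not defaulted), spine growth and ontogeny, inter-spine repulsion
at contact scale, and bark texture.  Passing tests therefore show the
pipeline behaves correctly under the stated statistical structure, not that
any particular real species is well described by a Poisson map.

## Debarking simulation

Bite windows are squares of side *s* ∈ {1..10} cm.  Two curvature effects on
thin stems: window width is capped at `max_width_fraction × C` (default one
quarter; the cap shrinks width only — curvature constrains circumferential
mouth insertion, not vertical extent), and the wrap metric keeps far-side
spines from blocking.  "A spine in or within 1 cm of the bite area prevents
insertion" is realized as rectangle dilation by `margin_cm` = 1 on all four
sides.  Windows are clipped vertically; candidate anchors exclude positions
where the window would leave [0, H].

Both outputs are computed on a raster of step `grid_step_cm` (default
0.5 cm; anchors and cells share the grid, with the effective step C/round(C/g)
so the grid tiles the cylinder exactly):

- a cell is *removable* iff its centre is covered by ≥ 1 accessible window;
  `accessible_fraction` = removable cells / all cells;
- a band (height *s*, bottoms on the anchor grid) is *ring-debarkable* iff
  the accessible windows anchored in it cover every cell column of the full
  circumference; `ring_risk` = ring-debarkable bands / candidate bands.

Numerical conventions: boundary ties count inward (a spine exactly at margin
distance blocks; a cell centre exactly on a window edge is covered).
Discretization: results converge as the grid is refined (tests compare
0.5 cm production output against a 0.25-cm brute-force enumeration within
one cell's area).  One artifact is acknowledged: `accessible_fraction` is
non-increasing in bite size exactly in continuous anchor space, but when the
quarter-circumference cap is not a multiple of the grid step, quantization
can locally violate monotonicity by roughly one cell column (~10⁻³ of area
at default resolution).  Adding a spine, by contrast, can only shrink the
accessible set — that monotonicity is exact at any resolution.

## Climbing simulation

Paths are polylines from y = 0 to y = H whose interior points have strictly
increasing heights (the climber always progresses upward; a "change of
trajectory" is a change of direction, not backtracking), each segment taking
the shorter circumferential way.  Cost = length/speed + penalty × number of
*distinct* spines whose base lies within paw/2 of the polyline.  Choices:

- speed = 1 cm per time unit, so distance and penalty share units; the
  penalty (default 10) is an assumption, not a measured exchange rate.
- one penalty per spine per pass: a single climb over a spine is a single
  encounter; per-segment double counting would be meaningless.
- staged search: at level k, `paths_per_level` random k-turn polylines (turn
  x uniform; turn heights uniform then sorted) plus deterministic vertical
  candidates at every grid x-position, so the bare-trunk optimum (cost = H)
  is exact rather than asymptotic.  The search stops at the first level that
  fails to strictly improve the incumbent (`max_levels` = 10 guards
  non-termination).
- random streams are keyed by (seed, level) only — shared across maps and
  paw sizes.  `climb_sweep` additionally re-evaluates every paw's best path
  under every other paw; because an individual path's cost is non-decreasing
  in paw size, the sweep's best costs are then exactly monotone in paw size.

The Monte-Carlo search is validated against an exact oracle on small
instances: a dynamic program over monotone lattice polylines (0.25-cm mesh)
whose state carries a bitmask of already-penalized spines, so the "count
each spine once" cost is handled exactly.  On 100 random toy maps the search
with 10⁴ paths per level lands within 5 % of the DP optimum in ≥ 95 cases.

## Morphology

Continuous traits (density, length) are natural-log transformed (base is
irrelevant after scaling) and min–max scaled to [0, 1]; a zero-range column
maps to all zeros so the matrix stays defined.  Binary traits become 0/1;
the three-state shape trait is one-hot encoded ("straightened" is not
intermediate between curved and straight in any stated sense, so ordinal
coding was rejected).  Spine type (thorn/leaf/stipule/prickle/cork) is
metadata only — anatomical origin must not be confounded with function.
Clustering is Ward's minimum-variance method on Euclidean distances of the
full matrix (scipy's `ward`, the Ward.D2 convention — dendrogram heights
differ between conventions), cut at k = 4 (the study's design; choosing k is
out of scope).  Correlation ratios are η² = between-cluster SS / total SS
per encoded column, averaged over a variable's columns; ordination is the
SVD of the centred matrix with variance percentages per axis.

## Comparison models

Model structures follow the reference analysis: binomial errors for bark
removal (fractions converted to counts with the raster-cell total as
denominator — the natural "bounded between 0 and 100" unit), Poisson errors
for climbing costs (rounded half-up to integers), each with an
observation-level Gaussian random effect (OLRE) absorbing overdispersion;
log-normal errors for the three nutrition responses with crossed species and
sampling-month random effects.  The species effect replaces a phylogenetic
random effect: no phylogeny ships with this package, and with synthetic
inputs the species level is the exchangeable unit.

Fitting: the OLRE models are maximized a posteriori with weakly informative
priors (fixed effects N(0, 5²) on the link scale; half-normal(1) on the OLRE
SD), the random effect integrated out by **adaptive** Gauss–Hermite
quadrature (21 nodes, re-centred at the per-observation mode found by Newton
steps and rescaled by the curvature — plain GH fails when binomial
denominators are in the thousands, because the integrand is then far
narrower than the node grid).  Contrasts use the Laplace (normal)
approximation to the posterior from the numerical Hessian.  The nutrition
model is REML via `statsmodels.MixedLM` with variance components.  MCMC
chain settings (4 chains × 35 000 iterations, 10 000 warm-up, thin 10) are
retained as configuration metadata so an external sampler can mirror the
reference settings; the deterministic Laplace route is the package's
default because the scientific content is the comparison structure, not the
sampler.

Contrast conventions: groups are coded as no-intercept dummies, so a
contrast is a difference of group coefficients with full covariance; the 95 %
interval is normal; the evidence ratio is the posterior odds of the better
supported sign, ER = max(p, 1−p)/min(p, 1−p) with p = P(Δ > 0); the decision
flag marks intervals excluding zero.  Calibration and recovery are verified
by simulation (null false-exclusion ≤ 10 % over 20 replicates; 2-fold
effects recovered with |bias| < 0.15 at 15 species/group).

Fruit attractiveness rules: fleshy + smelly/colourful → high; non-fleshy
with large structurally unprotected seeds → medium; non-fleshy with small or
wind-dispersed seeds → low; fleshy without the display syndrome → medium (a
design decision — the rules leave that combination open).  Corolla ≤ 2 cm →
small flower, > 2 cm → large.

## Problem sizes and seeds

The validation suite and `scripts/acceptance.py` run at sizes chosen for a
single-CPU workstation: 10 preset maps per syndrome on a 40 × 30 cm surface,
bite sizes 4–10 cm, the paw subset {4, 6, 8, 10} cm, 10⁴ climbing paths per
level (the search is within a few percent of its 10⁵-path answer on these
maps, which matters only near ties), 20 clustering seeds and 20 null
replicates per model.  All randomness flows from explicit integer seeds.

## Known limitations

- Spine length, orientation and curvature do not affect the simulators by
  default; blocking is purely positional.
- Ring-debarkable bands are fixed-height horizontal bands; a band may not
  snake vertically.
- No bite force, bark toughness/thickness mechanics, grip biomechanics or
  energetics; no downward or lateral travel.
- The raster estimator has one-cell quantization error (see above); report
  results with their grid step and check convergence at a finer step.
- Laplace/REML intervals are asymptotic; with very few groups or maps they
  can be slightly anti-conservative compared to full MCMC.
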
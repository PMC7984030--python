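# Methods

## The measurement problem

Cooking time (CT) of boiled cassava roots is scored by an operator probing
pieces with a fork — precise to 1–2 min at best, and subjective.  The two
proxy protocols implemented here replace that judgement with weighings:
water absorption of boiled pieces (WAB, Experiment-1 style) and the fall in
relative density of immersed pieces (DEN, Experiment-2 style).  The package
treats the protocols, their noise sources and their genetic evaluation as
one testable pipeline over synthetic campaigns.

## Time conventions

All analysis axes are cumulative **in-water** minutes.  Every weighing in
the WAB protocol removes the strainer from the pot for about a minute
(drawn 60 ± 10 s uniform); these intervals are recorded as `air`/`water`
phase transitions, excluded from the boiling clock, and subtracted from
softening instants when CT is computed.  The identity
`corrected CT + out-of-water time before softening = total-clock softening
instant` is enforced by a property test.

## Cooking-time rule

CT of a replication is the k-th order statistic of the piece softening
times with k = ⌈0.75 n⌉ (6 of 8 in the optimised protocol; for legacy
single-piece replications this reduces to the piece's own softening time),
minus the accumulated out-of-water time before that instant.  If fewer
than k pieces soften within the observation window the replication is
right-censored and reported as `> T`.  Censored values are excluded from
means, correlations and variance components by default (substituting the
window end is available by flag); exclusion avoids fabricating values the
trial never observed.

## Synthetic generator

Latent truth per genotype: CT group (short ≤ 25 < medium ≤ 40 < long,
minutes), true CT uniform within the group interval (long capped at
60 min), dry matter content DMC ~ N(38, 3.5²)% truncated to (20.5, 49.5),
saturating uptake kinetics `wab(t) = wab_max (1 − e^{−t/τ})`, and a
swelling ratio α ≥ 1 (volume gained per gram of absorbed water).

Group sizes follow deterministic largest-remainder quotas on proportions
15:8:11 (the observed short/medium/long counts).  True WAB at 30 min
follows a piecewise-linear trend through (CT 20 → 15.3%), (32.5 → 10.7%)
and (50 → 4.9%) — the observed group means — plus genotype scatter with
the observed group SDs (3.1/1.7/3.8%).  τ = CT/2, so fast cookers absorb
faster; this single link produces the negative CT–WAB correlation without
further tuning.  Within-group CT is uniform because no distribution is
reported; the choice is exposed in configuration.

Harvest effects: monthly harvests at 8–11 months after planting shift CT
by (+3, −3, −1, +2) min and DMC by (−1.5, −2.5, +0.5, +1.0)%, reproducing
the observed pattern (fastest cooking at 9–10 months, dry matter rising
with age).  The first two harvests use the legacy protocol (1 piece ×
4 or 6 reps, weighing stops at CT); the last two the optimised one
(8 pieces × 3 reps, weighing to the full boil).

Noise model:

* Piece softening: N(0, ve_ct) around the genotype's shifted CT,
  ve_ct = 12 min² by default (per-piece SD ≈ 3.5 min, consistent with the
  stated ±5 min accuracy of the fork method).
* Genotype/residual variance magnitudes default to vg_ct = 150 min²,
  ve_wab = 5 %² — the order of the published per-harvest components.
* Weighing: hot-air convection over the balance perturbs an in-air
  weighing uniformly over a 20 g full range **at a 1000 g gross reference,
  scaled by gross weight** — the disturbance acts on the assembly's drag
  area, so a lone ~60 g piece on a ~30 g tray barely feels it while the
  ~800–1100 g strainer assembly sees the full swing.  Without this scaling
  the legacy protocol's WAB residual variance comes out an order of
  magnitude above the published ~5 %²; with it, simulated campaigns give
  legacy wab20 components ≈ (Vg 20, Ve 3.4, H² 0.85) and optimised
  ≈ (Vg 24, Ve 1.3, H² 0.95), matching the published structure.  Readings
  are rounded to the 0.01 g scale resolution.
* Fragmentation: short-group genotypes lose mass linearly at 0.4%/min
  starting 10 min after their true CT, reproducing the non-monotone WAB
  curve and the late upturn of the immersed-weight curve seen in the
  fastest cooker.

Hydrostatics: initial relative density comes from DMC through the
classical specific-gravity map d0 = (DMC + 142)/158.3 (a generator
constant, not a scientific claim); samples with d0 ≤ 1 would float and
raise a simulation error.  With water density 1 g/cm³ the immersed weight
after absorbing `a` grams is `(m0 + a) − (m0/d0 + α a)`, strictly
decreasing while α > 1 until fragmentation reverses it.

Calibration of the density side: α defaults to 1.41, chosen so that the
OLS slope of the normalized immersed-weight curve over 0–30 min equals
−1.25 %/min exactly at the CT = 30 boundary genotype — the stated
screening threshold then splits short from long cookers by construction,
with misclassification coming only from genotype scatter.  Because the
hydrostatic trial uses different root samples than the WAB trial, its
genotype deviations are the WAB30 deviations rescaled so that the implied
DEN30 group spreads match the observed 9.8/11.1/6.9% (the rescaling is
rank-preserving, keeping the two protocols' deviations fully associated).
Generated DEN30 group SDs still run some 10–30% above those targets
because the within-group CT trend and the density-multiplier spread
(via DMC) add variance on top of the calibrated scatter.

What the generator does **not** emulate: heterogeneity along the root
axis, thermal gradients inside pieces, starch gelatinisation chemistry,
solid release into the cooking water before 30 min (treated as
negligible), and operator drift.  Passing tests therefore demonstrate that
the pipelines recover the structure the generator encodes — not that the
protocols themselves are valid on real roots.

## Curve features

Curves are normalized to percent of the time-0 value; features are
extracted only at window ends lying on the weighing grid (no
interpolation — the real instrument records nothing between weighings).
AUWCC is the trapezoidal area divided by the full `100% × window`
rectangle, so an inert sample scores exactly 1.  LINEAR is the OLS slope
of percent on minutes.  QUADRATIC fits `b0 + b1 t + b2 t²`; the feature
regressed against CT is b1 (the stated "first coefficient" is ambiguous
between b1 and b2; b1 is used and both are reported so either can be
analysed).  r² of CT on a feature is the squared Pearson correlation,
identical to simple-OLS r².  The slope classifier assigns the boundary
value to `predicted_short`: in a pre-selection context a false positive
(boiling a slow cooker once more) is cheaper than discarding a good one.

## Variance components and BLUP

Per-harvest repeatability uses Henderson's method III with replications
fixed: Ve is the residual mean square after fitting replications and
genotypes by least squares; Vg = (R(g|μ, rep) − df_g·Ve)/c with
c = tr(Z'(I − P_X)Z).  For balanced data c/df_g equals the replicate
count, recovering the textbook expected-mean-squares estimator exactly;
for unbalanced data (genotypes lost to rot) the trace coefficient is used
rather than the harmonic-mean replicate count — it is the exact
expectation and needs no balancedness argument.  Negative Vg estimates
are truncated to zero with a warning; numerically-exact-zero residuals
are clamped so degenerate inputs (all values equal) report Vg = Ve = 0
with H² undefined.

H² = Vg/(Vg + Ve), clipped to [0, 1], measures how well a protocol
controls experimental error: the design comparison (1 piece × 6 reps vs
8 pieces × 3 reps under identical genotype truth) raises H² in ~100% of
simulations because the 6-of-8 order statistic averages piece-level
spread (per-replication CT variance falls roughly fourfold).

Across-harvest genotype merit uses BLUP under `y = μ + G + H + GH + ε`
(all random but μ), solved through the dense mixed-model equations.
Unknown components are estimated by EM-REML from an equal split of the
total variance, iterated to relative change < 1e-8 (cap 5000 iterations —
EM converges linearly and slowly when H² is high; non-convergence raises
an error carrying the last iterate).  A factor with zero variance is
pinned to zero effect; when a vanishing residual removes the damping that
separates the intercept from the incidence columns, the minimum-norm
(pseudo-inverse) solution is taken, which reduces to genotype means in
the no-shrinkage limit.  The solver is verified against an independent
dense GLS oracle (`u = D Z' V^{-1}(y − Xβ̂)`).

Shrinkage caveat: |BLUP − grand mean| ≤ |raw mean − grand mean| is a
theorem only when raw genotype means weight harvests equally.  With
unequal per-harvest replication (6/4/3/3), raw means over-weight the
low-CT harvest and the harvest-adjusted BLUP can sit slightly farther
from the grand mean for extreme genotypes.  Aggregating to
genotype × harvest cell means restores the inequality for genotypes
observed in every harvest; the tests assert it there.

## Statistics

Pearson correlations carry two-sided p-values from the exact t transform
with n − 2 df (matching small-n practice better than the Fisher-z
approximation); zero-variance inputs yield undefined entries rather than
exceptions, and the significance threshold is fixed at 0.05.  All-pairs
comparisons use LSD t statistics with p-values multiplied by the number
of pairs (capped at 1); letters come from the insert-and-absorb
compact-letter-display algorithm, with ties in means broken by label
order so letter strings are deterministic.  The error df for letters is
supplied explicitly by the caller (pooled within-genotype replicate df in
the campaign report), since the appropriate stratum depends on the design.

## Problem sizes and numerical choices

Monte-Carlo checks use the sizes the analyses were designed at: 200
balanced simulations of 100 genotypes × 3 reps for parameter recovery,
100 paired simulations for the protocol comparison, 30 full campaigns for
the correlation structure and group summaries, and 200 campaigns for the
slope-threshold screen.  Curve-feature solvers are validated against
independent normal-equations solutions to 1e-8 on random curves.  Grid
membership of window ends is tested to 1e-9 min.  CSV outputs carry the
seed and a config hash in header comments and are byte-identical across
reruns of the same seed.

## Known limitations

* The generator's CT–WAB link is a single monotone trend plus noise;
  real genotype-by-environment interaction in uptake kinetics is richer.
* Legacy-harvest WAB curves stop at CT, so WAB30 exists only for slow
  cookers there; correlation entries at 30 min for those harvests are
  computed on the surviving subset and flagged by their n.
* EM-REML is slow near the H² → 1 boundary; the iteration cap is sized
  for campaign-scale problems (≤ ~200 genotype × harvest cells).
* The slope-threshold screen's balanced accuracy (~0.81 over default
  campaigns) reflects the calibrated scatter; it is a property of the
  generator's conditions, not a clinical claim about real roots.
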
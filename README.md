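# cooktime

Boiling-trial phenotyping pipelines for cassava root cooking time.

Consumers strongly prefer cassava (*Manihot esculenta*) varieties whose
roots soften quickly when boiled, but measuring cooking time (CT) directly
is slow, operator-dependent and hard to scale across a breeding program.
`cooktime` implements two faster, objective proxy protocols and the
quantitative-genetic machinery used to judge how repeatable they are:

* **Water absorption (WAB)** — root pieces in a tared strainer are boiled,
  lifted out roughly every 10 in-water minutes, towel-dried, weighed and
  returned to the pot.  Weight gain as percent of initial weight,
  `WAB(t) = 100 (w_t − w_0)/w_0`, correlates negatively with CT: fast
  cookers drink more water.  CT itself is scored as the time at which
  6 of 8 pieces turn soft, minus the accumulated time the strainer spent
  out of the boiling water.
* **Relative density change (DEN)** — a mesh bag of root pieces hangs from
  a balance while fully immersed in boiling water.  By Archimedes'
  principle the apparent weight is `m(t) − ρ V(t)`; as starch gelatinises
  and tissue swells, density falls and the immersed weight drops.  The
  normalized curve is summarised by three features over a truncated window:
  AUWCC (area under the curve as a fraction of the plot rectangle), LINEAR
  (OLS slope, %/min) and QUADRATIC (coefficients of a degree-2 fit).
  A slope threshold of −1.25 %/min at the 30-min window screens genotypes
  into predicted short (CT ≤ 30 min) vs long cookers.

The evaluation layer estimates per-harvest variance components with
Henderson's method III under the model `y = μ + rep (fixed) + genotype
(random) + ε`, reports broad-sense heritability `H² = Vg/(Vg + Ve)` as the
protocol-repeatability measure, and predicts genotype merit across harvests
by BLUP under the crossed random model `y = μ + G + H + G×H + ε`
(EM-REML variance components).  Genotype comparisons carry compact letter
displays from all-pairs LSD tests with Bonferroni adjustment.

Because no public dataset of such trials exists, the package includes a
first-class synthetic generator (`cooktime.synthetic`) that emulates the
full measurement structure: 36 genotypes in three CT groups, four monthly
harvests with CT and dry-matter shifts, the legacy (1 piece × 4–6 reps)
vs optimised (8 pieces × 3 reps) protocol variants, hot-air convection
weighing noise, out-of-water clock interruptions, saturating water-uptake
kinetics and the fragmentation artefact of very fast cookers.

## Worked example

```python
from pathlib import Path
from cooktime import Campaign, run_report

res = run_report(Campaign(out_dir=Path("demo"), seed=42,
                          config={"n_genotypes": 36}))
print(res["tables"]["group_summary"].round(2))
print(res["tables"]["heritability"].round(3))
```

The report simulates a four-harvest campaign, runs both pipelines and
writes every table as CSV under `demo/`.  The group summary shows mean
WAB at 30 min falling as CT rises across the short/medium/long groups:

```
 group  n  wab30_mean  wab30_sd
 short 16       13.54      2.69
medium  8       11.41      1.67
  long 12        5.00      3.33
```

The heritability table shows why the pooled 8-piece protocol replaced the
single-piece one — residual variance collapses and H² rises:

```
harvest trait  n_reps      vg     ve    h2
  H-10M    ct       3 177.185  1.779 0.990
  H-11M    ct       3 150.627  1.939 0.987
   H-8M    ct       4 152.427 13.650 0.918
   H-9M    ct       6 172.568 12.687 0.932
```

CT correlates with WAB30 at r ≈ −0.80 per harvest (`correlations.csv`),
the Table-2-style r² grid (`density_r2_grid.csv`) shows the LINEAR feature
losing precision beyond the 30–40 min windows, and the
`confusion_matrix.csv` table scores the −1.25 %/min screen against the
generator's true CT (here 28 of 36 genotypes classified correctly).

The same pipelines run from the shell:

```bash
cooktime simulate --out-dir sim --seed 42
cooktime wab --weights sim/weights.csv --softening sim/softening.csv --report wab.csv
cooktime density --in sim/density.csv --out classes.csv
cooktime report --out-dir demo --seed 42
```

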
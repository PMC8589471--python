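# interprox

Interproximal contact morphometry of molar pairs, and the statistics of
food-impaction risk.

Food impaction — food wedging into the space between adjacent teeth under
chewing force — can occur even when the proximal contact is tight (feeler
gauge < 60 µm). Whether it does depends on the local morphology of the
contact between the first and second molar: how long and how large the
contact is, and how widely the embrasures (abduction gaps) around it open.
`interprox` implements the quantitative chain for studying this on
segmented 3D scans: extraction of five interproximal features from a
labeled two-tooth point cloud, cohort-level statistics, and a fixed
logistic risk score.

The five features, measured in a canonical frame (x mesiodistal,
y buccolingual with +y buccal, z occlusal; units mm/degrees):

* **adjacent line length** *L* — span between the two farthest points of
  the dividing line between the teeth in occlusal projection (mm);
* **adjacent surface area** *A* — area of the contact facet on the
  vertical partition plane (mm²);
* **tongue / buccal abduction gap angles** *θ<sub>t</sub>, θ<sub>b</sub>* —
  three-point opening angles of the lingual and buccal embrasures in
  occlusal projection (°);
* **occlusal abduction gap angle** *θ<sub>o</sub>* — the same construction
  for the occlusal embrasure in mesiodistal (vertical) projection (°).

The statistics module carries a cohort feature table through normality
testing (Kolmogorov–Smirnov/Lilliefors and Shapiro–Wilk), Welch t-tests
between impaction and non-impaction groups, Spearman correlations,
correlation-matrix PCA with Kaiser retention (eigenvalue > 1) and
iterative communality screening (items below 0.4 dropped), and binary
logistic regression fit by IRLS. The published risk model is built in as
a fixed scorer:

```
ln(p / (1 − p)) = 0.889·L + 3.396·A − 0.071·θ_b − 0.089·θ_o − 19.797
```

Because raw clinical scans are not redistributable, the package includes
a first-class synthetic-data module: molar pairs built from superellipse
crowns with planar embrasure chamfers, whose five features are known
exactly by construction, and cohort tables drawn from the published group
distributions. Every downstream stage is validated by parameter recovery
against this analytic ground truth.

## Worked example

```python
from interprox.features import measure_all
from interprox.synthetic import REFERENCE_SPEC, generate_tooth_pair

cloud, truth = generate_tooth_pair(REFERENCE_SPEC)   # 60,000 labeled points
record = measure_all(cloud)
```

Running `python examples/01_generate_and_measure.py` prints:

```
feature                          measured       true  rel err
adjacent_line_length_mm             3.520      3.520   -0.01%
adjacent_surface_area_mm2           6.223      6.210   +0.22%
tongue_angle_deg                   52.237     52.240   -0.01%
buccal_angle_deg                   54.140     54.150   -0.02%
occlusal_angle_deg                 89.237     89.260   -0.03%
```

i.e. the measurement pipeline recovers a known tight-contact geometry
(3.52 mm contact line, 6.21 mm² facet, 52.24°/54.15°/89.26° embrasures)
to a fraction of a percent. `examples/02_cohort_statistics.py` runs the
full statistical chain on a simulated 250+250 cohort (line length, facet
area and occlusal angle separate the groups at p < 0.001);
`examples/03_risk_scoring.py` scores contrasting morphologies with the
fixed model (an impaction-like pair scores p ≈ 0.96, the reference pair
p ≈ 0.0006); `examples/04_full_pipeline.py` drives the end-to-end
simulate → measure → analyze → score pipeline.

A thin CLI mirrors the library:

```sh
interprox simulate-teeth --seed 1 --n 2 --out pairs/
interprox measure --in pairs/pair_000.ply --out features.csv
interprox simulate-cohort --seed 1 --n 250 --out cohort.csv
interprox analyze --in cohort.csv --out report/
interprox score --in features.csv
interprox run --seed 1 --out study/
interprox validate pairs/pair_000.ply
```

## Layout

```
src/interprox/
  synthetic.py   molar-pair generator with analytic ground truth; cohorts
  geometry.py    containers, STL/PLY I/O, curvature, sampling, projections
  features.py    dividing line, embrasure angles, facet area
  stats.py       normality, t-tests, correlation, PCA screening, logistic
  pipeline.py    end-to-end orchestration and input validation
  cli.py         command-line interface
docs/methods.md  model and measurement methodology
examples/        narrative scripts, one per capability
```
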
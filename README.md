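# bayrsf

Use–availability **resource selection functions (RSFs)** for marine animal
telemetry, with principled down-weighting of observations for telemetry error
and temporal autocorrelation. The package was built around fine-scale
space-use analysis of green turtles (*Chelonia mydas*) foraging in an
urbanized embayment, tracked with Fastloc-GPS transmitters, but every stage
is generic: it applies to any tagged marine animal whose surface fixes carry
a Fastloc residual value and satellite count and whose habitat is described
by vector patches (seagrass) and rasters (bathymetry, relative temperature).

## The model

Telemetry fixes ("use", $y=1$) are contrasted against regular-grid
pseudo-absences ("availability", $y=0$) sampled inside the 99% volume contour
of a pooled bivariate-normal kernel utilization distribution. A weighted
binomial GLM with logit link maximises

$$\ell(\beta) = \sum_i w_i\,[\,y_i\log p_i + (1-y_i)\log(1-p_i)\,],\qquad
\operatorname{logit} p_i = x_i^\top\beta ,$$

where $x_i$ holds signed distance to the nearest seagrass edge (optionally
quadratic), depth (optionally quadratic), relative water temperature, and
interactions of these with diel period (day/night by solar altitude) and body
size (straight carapace length, SCL). The observation weight $w_i$ is the
product of

1. an **error weight** per satellite count — inverse mean calibration error,
   truncated at the 95th quantile and rescaled so the largest weight is 1
   (pseudo-absences take the minimum weight), and
2. an **autocorrelation weight** $w_i = 1/\sum_j \rho(|t_i-t_j|)$ from the
   AICc-best continuous-time movement model (IID / Ornstein–Uhlenbeck / OUF)
   fitted per individual, giving an effective sample size
   $N_\mathrm{EFF} = \sum_i w_i \le N$,

allocated 50/50 between an individual's fixes and its pseudo-absences per
season and rescaled so each seasonal dataset's weights sum to its row count.
Candidate models are compared by AICc in three phases (quadratic structure →
single-factor interactions → second factor and three-way terms, ~25 models
per season) with Akaike weights, a variance-function pseudo-$R^2$, Type II
analysis of deviance, and effect-curve / spatial predictions with Wald
intervals on the link scale.

A synthetic-data module generates landscapes and habitat-selective,
autocorrelated movement by a Metropolis sampler whose stationary density is
*exactly* $\exp(\beta^\top X)$ inside the bay, so the whole pipeline is
testable against known coefficients.

## Worked example

```python
from bayrsf.simulate import ScenarioParams, simulate_scenario
from bayrsf.pipeline import run_pipeline_in_memory

params = ScenarioParams(n_individuals=5, duration_days=45.0)
landscape, truths, fixes, individuals = simulate_scenario(3, params)
report = run_pipeline_in_memory(landscape, fixes, individuals, seed=3)
print(report["fits"]["warm"].summary())
```

```
Weighted use-availability logistic RSF
==============================================================
season: warm   n rows: 1337   k: 7   converged: True
log-likelihood (weighted): -807.655   AICc: 1629.393
pseudo-R2 (variance-function): 0.0074
--------------------------------------------------------------
term                          coef         se       z        p
const                       0.6444      0.318    2.02   0.0429
dist                     -0.001784   0.000281   -6.36 2.01e-10
depth                     -0.01884      0.107   -0.18     0.86
depth^2                   -0.01273    0.00884   -1.44     0.15
temp                        0.3885     0.0668    5.81 6.07e-09
night                     -0.07545      0.124   -0.61    0.543
night:dist                0.001329   0.000385    3.45 0.000559
==============================================================
```

The scenario was generated with day-time eelgrass selection twice as strong
as at night: the phased comparison selects exactly the `diel*{dist}`
interaction, the negative `dist` coefficient (−0.0018 per metre of distance
from the seagrass edge; the generating value was −0.8 per SD ≈ 450 m) means
use concentrates inside patches by day, and the positive `night:dist` term
halves that selection at night. `report["tables"]["warm"]` holds the full
20–25 model AICc ledger with Akaike weights (0.44 for the winner here), and
`report["summary"]` the per-individual $N$, $N_\mathrm{EFF}$ and durations.

A thin CLI wraps the same library: `bayrsf simulate`, `bayrsf filter`,
`bayrsf run --config run.yaml`.

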
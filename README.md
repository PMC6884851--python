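# spatqreg

Bayesian spatial quantile regression for child birth weight.

Low (< 2.5 kg) and high (> 4.5 kg) birth weight are tail phenomena:
covariates that matter for them need not be the ones that move the
mean, and their effects can even flip sign between the tails.
`spatqreg` models the conditional quantile of birth weight directly,

    q(τ | x_i) = w_i' γ_τ + f_1,τ(age_i) + f_2,τ(visits_i) + f_spat,τ(d_i)

at extreme levels (τ = 0.05 and 0.95 by default), where `w_i` are
dummy-coded maternal covariates (BMI class, smoking, birth order,
education, wealth quintile, height and weight class), the metrical
covariates get second-order random-walk (RW2) smooths, and the child's
district `d_i` gets an intrinsic CAR (ICAR) effect on the district
adjacency graph — the structured surrogate for unobserved area-level
influences.  Inference is by Gibbs sampling under the asymmetric
Laplace working likelihood in its normal–exponential mixture form, with
Gamma hyperpriors on each Gaussian-Markov-random-field block precision
and exact sum-to-zero constraints.  The package is aimed at
epidemiologists and biostatisticians analysing DHS-style survey
extracts with district-level geography.

It also ships the surrounding pipeline: three-way birth-weight
cross-tabulations with Pearson chi-square tests, bivariate
quantile-regression screening at the permissive 20% level,
credible-interval classification of district effects (the tabular form
of a significance map), DIC model comparison, and a synthetic-data
generator with known ground truth so every stage is testable without
any external data.

## Worked example

```python
import spatqreg as sq

# a Malawi-scale synthetic survey: 28 districts on a rook grid,
# ALD noise at tau = 0.05 so the truth is the exact 5% quantile
graph = sq.gen_adjacency("grid", 28)
data, truth = sq.simulate_dataset(3000, graph, noise="ald", tau=0.05, seed=1)

fit = sq.fit_model(data, graph, sq.default_spec(0.05),
                   sq.MCMCSettings(seed=2, iters=3000, burnin=1000, thin=2))

table = sq.posterior_summary(fit)
print(table[table.block == "fixed"].head(4).round(4).to_string(index=False))
print(f"DIC {fit.dic.dic:.1f} (pD {fit.dic.pd:.1f})")
districts = sq.spatial_effect_table(fit)
print(districts.category.value_counts().to_dict())
```

prints

```
block              name    mean     sd  ci_lower  ci_upper  significant
fixed         intercept  3.1095 0.0176    3.0765    3.1440         True
fixed bmi_class=18.5-25  0.1908 0.0085    0.1749    0.2081         True
fixed     bmi_class=>25  0.2348 0.0099    0.2156    0.2545         True
fixed       smoking=yes -0.1158 0.0142   -0.1457   -0.0893         True
DIC 2132.6 (pD 59.5)
{'negative': 14, 'positive': 12, 'insignificant': 2}
```

The intercept's credible interval covers the true 3.1 kg; the BMI
contrasts recover their generating values (0.20 and 0.25 kg) and the
smoking effect its −0.12 kg; the district table classifies each area
by whether its 95% CI lies below, across, or above zero — here the
generated spatial truth is strong enough that most districts are
resolved away from zero.

The same model runs from the shell:

```bash
spatqreg simulate --n 3000 --districts 28 --noise ald --tau 0.05 --seed 1 --out data/
spatqreg screen   --data data/records.csv --tau 0.05 --alpha 0.2
spatqreg fit      --data data/records.csv --adjacency data/graph.txt \
                  --tau 0.05 --seed 2 --out results/
spatqreg pipeline --config run.yaml    # screen + fit tau = 0.05 and 0.95
```

## Layout

| module | contents |
| --- | --- |
| `spatqreg.data_model` | record/adjacency I/O, schemas, design matrices |
| `spatqreg.gmrf` | RW1/RW2/ICAR structure matrices, constrained sampling |
| `spatqreg.ald` | check loss, ALD density/CDF/quantiles, mixture constants |
| `spatqreg.mcmc` | the Gibbs sampler, posterior summaries, DIC |
| `spatqreg.screening` | weight classes, crosstabs, chi-square, 20% screen |
| `spatqreg.synthetic` | adjacency/covariate/dataset generators with truth |
| `spatqreg.pipeline` / `spatqreg.cli` | end-to-end runs, manifests, CLI |

See `docs/methods.md` for the model, priors, sampler derivations,
generator design and known limitations.
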
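# healthineq

Measuring socioeconomic inequality in health-care utilisation from household
survey microdata: weighted fractional income ranks, concentration curves,
standard / Erreygers-corrected / Wagstaff-normalised concentration indices
for binary utilisation outcomes, and decomposition of the corrected index
into Andersen-framework covariate contributions via a probit model.

The package is aimed at health economists and epidemiologists who work with
national household surveys (the canonical setting is Brazil's PNAD/PNS-style
surveys: person-level records carrying household income per capita, design
weights, region, and binary indicators such as "any doctor visit in the past
year" or "mammogram in the past two years"). Because such microdata are
large and access-restricted, the package ships a synthetic survey generator
with a fully known latent utilisation model, so every estimator can be
validated against analytic or simulation-based ground truth.

## The statistics

With persons ranked from poorest to richest by household income per capita,
the **fractional rank** of person *i* is
`R_i = (cumulative weight before i + w_i/2) / W` (the textbook
`R_i = (i - 0.5)/n` under equal weights; tied incomes share their block's
weighted mid-rank). The **standard concentration index** of a health
variable *h* is

    C(h) = 2 cov_w(h, R) / h̄,

twice the area between the concentration curve and the 45° equality line;
positive values are pro-rich, negative pro-poor. For bounded (especially
binary) outcomes the attainable range of C shrinks with the mean, so the
package also provides the **Erreygers correction**

    E(h) = 4 h̄ C(h) / (h_max − h_min)

(mirror-symmetric, transfer-sensitive, invariant to level shifts and linear
rescaling) and the **Wagstaff normalisation** `W(h) = C(h)/(1 − h̄)` for 0/1
outcomes, linked by `E = 4 h̄ (1 − h̄) W`. Confidence intervals come from
the convenient weighted-least-squares regression with robust (optionally
cluster-robust) standard errors, or from a clustered percentile bootstrap
that re-ranks every resample.

For **decomposition**, a binary outcome is fitted with a weighted probit
`E(y|x) = Φ(Σ_j β_j x_j)`; each coefficient is linearised into a partial
effect `β_j^m` (binary covariates: the discrete 0→1 change averaged over the
subgroup holding the attribute; continuous: the average derivative), and

    E(h) = 4 [ Σ_j β_j^m GC(x_j) + GC(e) ],

where `GC(x) = 2 cov_w(x, R)` is the generalized concentration index. Each
term is the product of how strongly a covariate moves utilisation and how
unequally that covariate is distributed over income; the residual closes the
identity exactly.

## Worked example

```python
import numpy as np
from healthineq import (
    default_config, generate, eligibility_filter,
    fractional_rank, index_ci, classify_inequality,
)

data, truth = generate(default_config(n_persons=20_000, seed=3))
eligible, log = eligibility_filter(data, "mammogram")   # women aged 50-69
print(log)

df = eligible.table
ranked = fractional_rank(df["income_pc"], df["weight"])
est = index_ci(df["mammogram"], ranked, df["weight"], variant="erreygers")
print(f"E = {est.value:.3f}{est.stars} "
      f"({est.ci_low:.3f}-{est.ci_high:.3f}) -> {classify_inequality(est)}")
```

Output:

```
FilterLog(outcome='mammogram', rows_in=20000, rows_retained=2813, rows_excluded=17187, rows_recoded=0)
E = 0.321*** (0.277-0.366) -> pro-rich
```

The filter keeps the 2,813 women in the 50–69 screening window; the
Erreygers-corrected index of 0.321 with a CI entirely above zero says
mammogram use in this synthetic population is strongly concentrated among
the rich (the generator gave the outcome a steep income-rank gradient plus
insurance and education effects, so this is expected).

A full multi-wave study — prevalence tables, national and within-region
indices with significance stars, and decomposition tables — runs from a YAML
config through the CLI:

```bash
healthineq simulate --n 100000 --seed 1 --out data/
healthineq index --data data/microdata.csv --outcome mammogram --variant erreygers
healthineq report --config study.yaml --out report/
```

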
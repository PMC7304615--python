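# fsint — rank-based inverse normal transformation association tests

`fsint` is a library and command-line tool for testing association
between a quantitative trait and single genetic variants under
covariate adjustment when the trait (or its residual) distribution is
non-normal. It is aimed at statistical geneticists and biostatisticians
running single-variant scans — particularly rare-variant scans, where a
handful of carriers make the usual normal-theory tests fragile under
skewness and outliers.

## The methods

For trait `y`, covariates `X` (with intercept) and additive genotype
dosage `g`, the working model is `y = Xα + gβ + ε` and the hypothesis
is `H0: β = 0`. The package centres on transformations built from the
rank-based inverse normal transformation (INT)

    RN(v_i) = Φ⁻¹((rank(v_i) − c)/n),   c = 1/2 by default,

and provides eight procedures behind one interface:

| key | procedure |
|---|---|
| `fs-int` | **fully adjusted full-stage INT**: iteratively re-residualize on `X` and re-apply the INT until no covariate predicts the transformed residuals (screen at 0.05) or the coefficients stabilize (L∞ < 1e−6), then score-test `g` adjusting `X` |
| `ts-int` | fully adjusted two-stage INT: INT the residuals of `y ~ X`, score-test `g` re-adjusting `X` |
| `pts-int` | partly adjusted two-stage INT (no covariate re-adjustment; library-only) |
| `d-int` / `i-int` / `o-int` | direct (transform the trait), indirect (transform residuals, residualized genotype), and their Cauchy-combination omnibus |
| `skat-score` | covariate-adjusted score test on the raw trait (the single-variant equivalent of a kernel/SKAT-type test) |
| `mr` | median (0.5-quantile) regression with bootstrap fallback |
| `yjpt` | Yeo-Johnson power-transform regression, λ by profile ML |

The full-stage procedure is the point of the package: the two-stage
test quietly assumes the INT-transformed residuals are again linear in
the covariates with normal errors, which fails under outlier-heavy
error distributions and leaves `ts-int` miscalibrated for rare
variants; iterating the transform until the covariate screen passes
restores calibration while reducing *bitwise* to `ts-int` whenever the
first screen already passes. See `docs/methods.md` for the full
algorithm, constants, and design rationale.

## Worked example

With a phenotype table (`sample_id,bmi,age_std,sex`) and a dosage
matrix (`sample_id,rs101,rs202`) for 500 samples — here simulated with
chi-squared(2) noise, a real effect of 0.35 per allele on `rs101`, and
a null rare variant `rs202`:

```
fsint assoc --pheno example_pheno.csv --trait bmi --covar age_std,sex \
      --geno example_geno.csv --method fs-int,ts-int,skat-score \
      --seed 7 --out example_results.tsv
```

produces

```
# fsint 0.1.0
# seed=7
# config_hash=4e6399018cdd
variant	method	n_used	beta_hat	se	statistic	p_value	iterations	converged	flags
rs101	fs-int	500	0.315976	0.0719384	19.2924	1.12149e-05	0	True
rs101	ts-int	500	0.315976	0.0719384	19.2924	1.12149e-05	0	True
rs101	skat-score	500	0.333327	0.154362	4.66297	3.08199e-02	0	True
rs202	fs-int	500	-0.257443	0.205425	1.57057	2.10124e-01	0	True
rs202	ts-int	500	-0.257443	0.205425	1.57057	2.10124e-01	0	True
rs202	skat-score	500	-0.54468	0.440789	1.52694	2.16572e-01	0	True
```

Reading this: the INT-based tests recover the true `rs101` effect
(β̂ ≈ 0.32) at p ≈ 1.1e−5, while the raw-trait score test is blunted by
the skewed noise (p ≈ 0.03); the null variant is flat everywhere. The
full-stage test needed 0 iterations here — with well-behaved residuals
it *is* the two-stage test — and `iterations`/`converged` record when
it does have to iterate.

Simulation grids run from a YAML config (list-valued fields become grid
axes):

```
fsint simulate --config grid.yaml --workers 4 --out rates.csv
```

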
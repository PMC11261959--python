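# mixdoc — direction-of-causation twin models with causal-direction mixtures

`mixdoc` asks a question classical comorbidity analyses cannot: *does the
causal direction between two traits differ across people?*  In psychiatric
epidemiology, trait X (say, depression) may drive trait Y (substance use)
in one part of the population while Y drives X in another.  Cross-sectional
data from monozygotic (MZ) and dizygotic (DZ) twin pairs identify causal
direction through the pattern of cross-twin cross-trait covariances, and a
finite mixture over causal directions turns that identification into a
test for *causal heterogeneity*.

## The model

Each trait decomposes into additive genetic (A), shared environmental (C)
and unique environmental (E) components with loadings `a, c, e`; A
correlates 1 across MZ and 0.5 across DZ co-twins, C correlates 1, E is
twin-specific.  Within a twin, the phenotypes obey causal regressions
(`b_xy`: X→Y, `b_yx`: Y→X).  For the pair vector *y* = (x₁, y₁, x₂, y₂)
each causal-direction class *i* implies

    μ_i = (I − B_i)⁻¹ ν_i,     Σ_i = (I − B_i)⁻¹ Ψ (I − B_i)⁻ᵀ,

with Ψ the pre-causal ACE covariance and ν_i class-specific trait
intercepts.  Because a pair samples two people, two causal subpopulations
yield **four classes per zygosity group** — X→Y in both twins, Y→X in
both, and the two (equated) discordant combinations — and the data density
is the mixture

    f(y) = Σ_i ω_i Φ(y; μ_i, Σ_i),   Σ ω_i = 1,  ω₃ = ω₄.

Classification quality is summarized by the relative entropy index
`Ent = 1 − Σᵢ Σ_c (−p_ic ln p_ic) / (N ln C)` on the posterior class
probabilities (0 = uninformative, 1 = perfect assignment), and competing
models are ranked by `AIC = −2LL + 2k`.

Six model families are implemented behind one estimator: the 4-class
mixture (`mix4`), the concordant-only 2-class mixture (`mix2`), the
single-class unidirectional (`doc_xy`, `doc_yx`) and reciprocal
(`doc_bidir`) models, and the saturated bivariate Cholesky ACE model
(`cholesky`), which nests the unidirectional models.

## Worked example

```python
import mixdoc as mx

# a heterogeneous population: equal quarters of the four classes,
# b = 0.5 each way, class intercepts one unit apart on both traits
scenario = mx.mixture_comparison_scenario(n_per_zygosity=1000, seed=0)
data = mx.simulate_dataset(scenario, seed=42)

est = mx.MixDoC(family="mix4", n_starts=4, random_state=1).fit(data.to_frame())
print(f"-2LL {est.minus2ll_:.1f}  k {est.k_}  AIC {est.aic_:.1f}")
print("MZ class proportions:", [round(float(w), 3) for w in est.weights_.omega_mz])

post = mx.posterior_probabilities(data, est.result_)
print(f"relative entropy {mx.relative_entropy(post):.3f}")
```

prints (exact output of this snippet):

```
-2LL 23106.3  k 16  AIC 23138.3
MZ class proportions: [0.236, 0.239, 0.263, 0.263]
relative entropy 0.532
```

The fitted proportions recover the generating quarters to within sampling
error, and an entropy of 0.53 says the posteriors are informative but far
from certain at this class separation — larger mean differences drive the
index toward 1.  `mx.fit_model_set(data)` fits all six families and
returns the df / −2LL / AIC comparison table; on this dataset the 4-class
mixture wins by ~460 AIC points, while on homogeneous data the
single-class models win (the mixture pays its 16-parameter price).

The same operations are available from a shell:

```sh
mixdoc simulate --config scenario.json --out pairs.csv
mixdoc fit pairs.csv --family mix4 --out fit.json
mixdoc compare pairs.csv
mixdoc posteriors pairs.csv --fit-json fit.json --out posteriors.csv
mixdoc study --reps 50 --out report.json
```

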
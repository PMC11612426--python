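# poolfish

Hierarchical multi-species distribution modelling of fish in the
disconnected pools of intermittent rivers, with multi-gear detection
sub-models and a water-take scenario engine.

## The problem

When an intermittent river stops flowing, its fish contract into isolated
dry-season pools; the depth of a pool governs which species persist there
until the next wet season.  Water managers setting extraction rules need
species-specific depth relationships — but raw catch data confound the
ecology with the sampling process, because each gear (boat or backpack
electrofishing, large- or small-mesh seine) selects for different depths
and body sizes.  `poolfish` is for quantitative ecologists and
environmental-flow scientists who need to (1) separate latent abundance
from capture probability in multi-gear detection/non-detection surveys,
and (2) turn the fitted depth relationships into predicted distribution
losses under candidate water-take rules.

## The model

Latent abundance of species *i* at site-visit *j* is
`N_ij ~ Poisson(λ_ij)` with a Ricker depth response,

```
log λ_ij = (β1_i + β3_i M_j) + log D_j − e^{β2_i + β4_i M_j} D_j
           + β5_i T_j + β6_i T_j M_j + β7_i S_j + β8_i S_j M_j
           + β9_i R_j + β10_i R_j M_j + ε_pool + ε_time ,
```

so λ vanishes as the pool dries and peaks at scaled depth
`D* = exp(−(β2 + β4 M))`.  Each gear has a catchability predictor
`log q = φ1 + log D́ − e^{φ2} D́ + φ3 T + φ4 T² + φ5 Ś [+ φ6 C]`
(conductivity only for electrofishing), converted to a capture
probability `r = ς·E^υ (1 − e^{−q})` with effort `E ∈ (0,1]`, effort
exponent `υ ∈ [0,1]` and a 5-m seine scalar `ς`.  Detection is
`y_ijk ~ Bernoulli(1 − (1−r_ijk)^{N_ij})`, and N is marginalized over a
truncated Poisson support in the likelihood.  Species-level coefficients
follow a fourth-corner hierarchy, `coeff_si ~ N(η1_s + η2_s L_i, σ_s²)`,
so mean body length `L_i` drives systematic across-species variation in
depth preference and gear vulnerability.  See `docs/methods.md` for the
full account, priors, and the blocked NUTS-within-Gibbs sampler.

No field data ship with the package: `poolfish.synthetic` generates
surveys from the exact model at field-realistic designs (59 pools across
two mesohabitats, 107 site-visits, 2–18 samples per visit across four
gears), so the whole pipeline is testable end to end.

## Worked example

```python
from poolfish import PoolAbundanceModel, synthetic

ds = synthetic.simulate("fitzroy_small", seed=42)     # 12 species, 30 pools
model = PoolAbundanceModel(ds)                        # filters, scales, indexes
res = model.fit(chains=2, draws=300, warmup=150, seed=0)
print(res.summary().loc[["eta1[beta1]", "eta2[beta1]", "eta2[beta2]",
                         "upsilon[seine_LM]", "sigma_lm", "sigma_pool"]])
print(f"overall fidelity: {res.fidelity(thin=30).overall_accuracy:.1f}%")
scen = res.predict_scenario("min_depth", thin=30)
print(scen.objective_counts().query("rule in (0.5, 1.0, 1.5, 2.0)")
      .pivot(index="rule", columns="objective_pct", values="n_species"))
```

prints (abridged):

```
survey: 12 species, 30 pools, 30 visits, 180 gear samples
                   mean    sd    q5   q95  rhat     ess
eta1[beta1]        2.24  0.95  0.39  3.55  1.00  110.58
eta2[beta1]       -0.83  0.36 -1.37 -0.23  1.01  182.99
eta2[beta2]       -0.70  0.55 -1.65  0.25  1.02   83.93
upsilon[seine_LM]  0.52  0.21  0.20  0.87  1.03  204.51
sigma_lm           0.72  0.14  0.49  0.95  1.05   81.07
sigma_pool         0.50  0.16  0.26  0.80  1.04   41.85
overall fidelity: 89.3%
objective_pct  5.0   10.0  15.0
rule
0.5               0     0     4
1.0               5     9    11
1.5               9    12    12
2.0              11    12    12
```

Reading it: `eta1[beta1]` is the community-mean log peak abundance
(generating value 3.0, inside the 90% interval), `eta2[beta1]` the
length slope on abundance (truth −0.5: smaller species are more
abundant), and `eta2[beta2]` the length slope on the depth-decay rate
(truth −0.6: larger species peak in deeper pools).  The effort exponent
of the large-mesh seine and the 5-m seine scalar (`upsilon[seine_LM]`,
`sigma_lm`; truths 0.7 and 0.7) are recovered with honest uncertainty.
The objective table is the management product: at a 0.5 m minimum-depth
rule no species keeps its distribution loss below 5%, while a 1.5 m rule
protects 9 of 12 species at the 5% objective and all 12 at 10%.

The same pipeline runs from the shell:

```
poolfish simulate --preset fitzroy_small --seed 42 --out survey/
poolfish fit --data survey/ --out posterior/ --chains 4 --seed 0
poolfish evaluate --data survey/ --posterior posterior/ --out eval/
poolfish predict-scenarios --data survey/ --posterior posterior/ \
         --scenario min_depth --out scen/
```

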
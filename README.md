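# corrdelta

Two-stage global sensitivity analysis (GSA) based on the moment-independent
δ index, for input→output models whose parameters are *correlated* — with
the secondary metrics of a tumor-in-host DEB-TGI (Dynamic Energy Budget,
Tumor Growth Inhibition) model built in as ready-made outputs.

It is aimed at pharmacometricians and modellers who need to know which
parameter uncertainties actually drive the uncertainty of a model-derived
prediction when the parameter estimates are statistically dependent — a
setting where classical variance-based (Sobol) GSA loses its interpretation.

## The method

For a scalar output `Y = g(X)` the δ sensitivity index of input `X_i` is
half the expected L1 distance between the output density and the output
density conditional on fixing `X_i`:

```
δ_i = ½ E_{X_i} [ ∫ | f_Y(y) − f_{Y|X_i}(y) | dy ]
```

`δ_i ∈ [0, 1]`, it is zero iff `Y` carries no information about `X_i`, it
is invariant under monotone transformations of inputs and output, and it is
well defined for correlated inputs. Estimation is "given data": from one
Monte Carlo sample, each input is rank-partitioned into equal-frequency
classes and the class-conditional kernel density estimates of `Y` are
compared with their pooled mixture.

The analysis runs twice:

* **Step 1 — independent sampling.** The inputs keep their marginals but
  the correlation is dropped; `δ₁ > 0` identifies *causal* effects.
* **Step 2 — full joint distribution.** `δ₂` additionally captures the
  *indirect* influence carried by the correlation structure.

A standard-normal spurious input ("Noise") passes through the same
estimator in each step; the 97.5th percentile of its bootstrap δ
distribution is the threshold below which a δ is declared zero. Comparing
the two significance flags classifies every parameter as
`causal_and_indirect`, `indirect_only`, `causal_suppressed` or
`negligible`.

Built-in DEB-TGI outputs (closed form): tumor growth rate
`λ = m·g·μ_u/g_u − m_u`, doubling time `TVDT = ln 2 / λ`, eradication
concentration threshold `C_T = λ / k₂`, food-supply coefficient
`ρ_b = 1/(1+R_b)`; plus the trajectory-based toxicity delay
`ΔT_δVmax = T_δVmax,control − T_δVmax,treated` extracted from
user-supplied degradation-rate curves.

## Worked example

Two-stage GSA of the eradication threshold `C_T` under the accurate-estimate
(CV1) uncertainty scenario, with the packaged correlation template (a strong
positive k₂–IC₅₀ estimation correlation, all other pairs unknown and hence
completed to zero):

```python
import corrdelta as cd

host = cd.load_host_constants()
joint = cd.build_joint(
    cd.deb_parameter_scenario("CV1"),
    cd.complete_correlation(cd.deb_correlation_template()),
)
report = cd.run_two_stage(cd.ct_model(host), joint,
                          n=20_000, partitions=30, B=200, seed=42)
for name in report.names:
    e1 = report.step1.estimates[name]
    e2 = report.step2.estimates[name]
    print(f"{name:12s} {e1.zeroed_value:7.3f} {e2.zeroed_value:7.3f}  "
          f"{report.effect_classes[name].value}")
```

prints

```
mu_u           0.092   0.087  causal_and_indirect
g_u            0.094   0.096  causal_and_indirect
m_u            0.000   0.000  negligible
delta_Vmax     0.000   0.000  negligible
Vu10           0.000   0.000  negligible
W0             0.000   0.000  negligible
Rb             0.000   0.000  negligible
IVu50          0.000   0.000  negligible
k1             0.000   0.000  negligible
k2             0.581   0.583  causal_and_indirect
IC50           0.000   0.493  indirect_only
```

Reading: the drug potency `k₂` dominates the causal impact on `C_T`
(δ ≈ 0.58), the tumor growth parameters `μ_u`, `g_u` have a moderate causal
effect, and `IC₅₀` — which does not appear in the `C_T` formula at all —
gains the second-largest δ in Step 2 purely through its estimation
correlation with `k₂`: an *indirect-only* input. Reducing the uncertainty
of `C_T` therefore requires disentangling `IC₅₀` from `k₂` during model
identification, not merely estimating `k₂` more precisely. Parameters whose
δ falls below the Noise threshold (here ≈ 0.05 at n = 20,000) are reported
as exactly zero.

The same engine accepts any user model: a callable mapping the sampled
parameter `DataFrame` to one scalar per row.

## Command line

```
corrdelta fixtures --write fixtures/          # params CSVs, correlation template
corrdelta sample --params p.csv --n 100000 --seed 1 --noise --out s.csv
corrdelta delta --samples s.csv --outputs y.csv --out delta.csv
corrdelta two-stage --params p.csv --corr c.csv --model ct --seed 1 --out run/
corrdelta ua --params p.csv --model tvdt --independent --seed 1 --out run/
corrdelta complete-corr --template t.csv --out completed.csv
```

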
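# sewerch4

Empirical modelling of methane formation in gravity sewers.

Gravity sewers grow a wall biofilm whose anaerobic depths host
methanogenic archaea. How much methane a sewer reach emits depends on how
much of that microbial biomass the flow lets accumulate, and the flow's
controlling variable is the **wall-shear stress** F (Pa) that the
wastewater exerts on the pipe wall. `sewerch4` implements a compact,
fully tested model chain for this system, aimed at sanitary engineers and
environmental microbiologists working with pilot-sewer data:

1. **Hydraulics.** A fitted second-order response surface gives F from
   the sewer slope I (‰), fullness degree n and flow velocity v (m/s):

       F = 0.21941 + 0.44146·I + 1.73331·n − 0.52041·v + 0.13167·n·I
           − 0.24688·v·I − 1.47281·n·v + 0.23833·I² − 0.12750·n² + 1.88828·v²

   with an exact quadratic inversion for v.
2. **Biofilm reduction.** Raw observations become model inputs: the
   maturity day (thickness stable over a 10-day window to within 5%), the
   oxygen penetration depth (linear interpolation of the DO microprofile
   to zero), and the microorganism amount X = ρ·δ·A − EPS (kg), the
   TS-based biomass with the extracellular polymeric matrix removed.
3. **Community summaries.** Taxa × condition relative-abundance tables
   (the packaged reference table covers nine archaeal lineages at three
   shear stresses) with consistency checks, combined abundances, percent
   changes and dominance rankings.
4. **Methane models.** The biomass quadratic X(F) = a·F² + b·F + c
   (defaults −0.0485, 0.161, −0.0142), the production law
   Q = Y·X·θ^(T−20)·HRT with θ = 1.05, and two legacy surface-area-based
   correlations for comparison.
5. **Fitting.** statsmodels-style model objects — construct from data,
   `fit()`, read a Results object. Because T and HRT are not separately
   identifiable from production data, the primary estimand is the
   composite proportionality c* = Y·θ^(T−20)·HRT in Q = c*·X(F), with
   closed form c* = ΣXQ/ΣX².
6. **Synthetic experiments.** A seeded generator emits complete virtual
   seven-sewer datasets (thickness, density, DO, methane, community, plus
   a truth file) so the whole chain is testable with known ground truth.

## Worked example

Fit the proportional methane model to the packaged seven-sewer rates and
predict the production at the optimal shear stress:

```python
from sewerch4 import ProportionalMethaneModel, datasets

model = ProportionalMethaneModel.from_dataframe(datasets.methane_rates())
res = model.fit()
print(res.summary())
print("Q at 1.45 Pa:", round(float(res.predict(1.45)), 4), "mg/(L·day)")
```

prints

```
Proportional methane model  Q = c*·X(F)
=======================================
c* = Y·θ^(T−20)·HRT  16.5519 (se 0.3102)
R² (centered)        0.9558
pct diff range (%)   2.4 – 6.9
n                    7
Q at 1.45 Pa: 1.9412 mg/(L·day)
```

The fitted proportionality c* ≈ 16.55 means each kilogram of biofilm
biomass contributes ≈ 16.55 mg CH₄ per litre of wastewater per day at
the experiment's (unresolved) temperature and retention time; the model
explains 96% of the between-sewer variance in the measured rates, and no
sewer deviates from its prediction by more than ≈ 7%. The predicted peak
rate at 1.45 Pa, 1.94 mg/(L·day), sits just below the measured 2.04.

The same flow is available from the shell, including a full synthetic
experiment round trip:

```bash
sewerch4 shear --slope 8 --fullness 0.5 --velocity 0.6   # F in Pa
sewerch4 simulate --seed 42 --out dataset/
sewerch4 analyze dataset/                                 # blind re-fit
sewerch4 community summary --threshold 10
```

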
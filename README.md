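# epagrowth

Size-dependent demands for eicosapentaenoic acid (EPA, 20:5ω3) in
*Daphnia*, modelled with Monod-type saturation kinetics.

## The scientific problem

EPA is an essential ω-3 polyunsaturated fatty acid for *Daphnia*: juvenile
somatic growth saturates with the dietary EPA concentration, and the
concentration at which growth saturates — the food-quality threshold — may
depend on body size. If large-bodied species need more EPA per unit carbon,
warm, cyanobacteria-dominated (PUFA-poor) waters should favour small-bodied
cladocerans, one candidate mechanism behind the midsummer decline of large
zooplankton in eutrophic lakes.

`epagrowth` is for ecologists and biostatisticians who want to fit and probe
this model family on beaker-level growth experiments: clonal *Daphnia*
lineages grown for ~6 days across a gradient of dietary EPA
(µg EPA mg C⁻¹), with replicate beakers per treatment.

## The model

Juvenile growth rate g (day⁻¹, from dry masses as g = (ln Wt − ln W0)/t)
follows a Monod-like saturation function with a shift parameter:

    g(S) = g0 + (g∞ − g0) · S / (S + K_S)

with baseline g0 (growth without EPA), asymptote g∞ and half-saturation
constant K_S. Two fixed-effect families are compared by maximum likelihood:

- **family A** — one common K_S for all clones;
- **family B** — a linear body-size law K_S = K0 + K_L·L, where L is the
  clone's body size at first reproduction (mm).

Clone-level Gaussian random effects act on nested subsets of
{g0, g∞, K_S} (model names A1…A3, B1…B3; the digit is the number of random
effects). The marginal likelihood integrates random effects out clone by
clone with a Laplace approximation (exact when only g0 and g∞ — which enter
the mean linearly — carry random effects); the residual SD is profiled out
analytically. Model choice uses AIC plus pairwise A-vs-B likelihood-ratio
tests (B nests A via K_L = 0, one degree of freedom). Uncertainty comes
from a residual bootstrap. Derived thresholds: the EPA concentration giving
a fraction p of the asymptotic increment is S_p = K_S·p/(1−p), so
S₇₅ = 3·K_S.

The package also fits the same machinery to clutch sizes (rescaled and
arcsin-square-root transformed, c′ = 2·arcsin(√c)/π), and computes
fatty-acid statistics: totals (PUFA = LIN + ALA + ETE + EPA), the
"minimum tissue quota" of newly built biomass
((C₆m₆ − C₀m₀)/(m₆ − m₀)), species tables of unweighted clone means, and
Kruskal–Wallis species comparisons.

No raw beaker data are distributed; a synthetic-data generator reproduces
the study design (12 clones of three species spanning 1.43–3.54 mm, seven
EPA levels from 0 to 10 µg EPA mg C⁻¹, three replicate beakers, six days)
so the full pipeline runs out of the box.

## Worked example

```python
import epagrowth as eg

cfg = eg.default_config(seed=1)          # the default study design
records = eg.simulate_growth(cfg)        # 12 clones x 7 levels x 3 beakers
table = eg.run_model_series(records, list(cfg.clones))
print(table.best_model)
b1 = table.fits["B1"]
print({k: round(v, 3) for k, v in b1.fixed_estimates.items()})
print(round(eg.saturation_threshold(b1.ks_for_clone("Dg"), 0.75), 2))
```

prints

```
B1
{'g0': 0.305, 'ginf': 0.543, 'K0': -1.324, 'KL': 1.065}
1.68
```

i.e. on this simulated dataset the size-law model with a clonal random
baseline (B1) has the lowest AIC; the fitted half-saturation constant
increases by ≈1.07 µg EPA mg C⁻¹ per mm of body size (true slope 1.04);
and the small-bodied clone Dg reaches 75 % of its asymptotic growth
increment near 1.7 µg EPA mg C⁻¹ (true value 1.80).

The same pipeline is scriptable from the shell:

```sh
epagrowth simulate --seed 1 --out data/
epagrowth select --growth data/growth.csv --clones data/clones.csv --out table.csv
epagrowth report --seed 1 --out report/      # full bundle + summary.json
```

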
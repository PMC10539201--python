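# copetherm

Quantitative analysis of multigenerational thermal-exposure experiments on
marine copepods. The package is written for experimentalists who incubate
replicate bottles of adult females across a temperature gradient and need to
turn per-bottle survival counts and egg-production rates into thermal
tolerance and performance metrics: lethal temperatures (LT50/LT90), cardinal
temperatures of the reproductive response (Tmin, Topt, Tmax = CTmax),
thermal breadth, thermal safety margin, Q10 coefficients and a recruitment
(survival x fecundity) fitness proxy — each with case-resampling bootstrap
confidence intervals.

## Models

**Survival.** After a fixed exposure (24 h or 7 d), the proportion of
surviving females at test temperature *T* follows a descending logistic

```
S(T) = c / (1 + exp(a (T − b)))
```

with plateau *c* (maximum survival), transition midpoint *b* and slope *a*.
Lethal temperatures are defined relative to the plateau:
LT50 = *b* and LT(m) = *b* + ln(m/(1−m))/*a*, so LT90 − LT50 = ln(9)/*a*.

**Egg production.** Rates follow the cardinal-temperature model with
inflexion (Lobry–Rosso–Flandrois family)

```
R(T) = Rmax (T − Tmax)(T − Tmin)² /
       [(Topt − Tmin)((Topt − Tmin)(T − Topt) − (Topt − Tmax)(Topt + Tmin − 2T))]
```

which is zero at *Tmin* and *Tmax* (= CTmax) and equals *Rmax* at *Topt*.
Thermal breadth is the interval where R ≥ 0.8 Rmax; the thermal safety
margin is *Topt* minus the rearing temperature; Q10 = exp(10 · slope) from a
regression of ln R on *T* over a phase window; potential recruitment is
S(T)·R(T) from the 7-day curves, compared between lines as a fold-change.

Both fits are nonlinear least squares on per-bottle values with multi-start
initialisation; CIs resample bottles with replacement within each test
temperature. Curve families compete by AIC = n·ln(RSS/n) + 2k (cardinal,
Gaussian and quadratic ship by default; the registry is extensible).

A synthetic-data module generates experiment-shaped datasets (binomial
mortality, Gaussian rate noise, exponentially decaying egg diameters) with
known ground truth, so every stage of the pipeline is testable end to end.

## Worked example

```python
import copetherm as ct

design = ct.ExperimentDesign()           # 13 temperatures, 2 lines, 4 bottles x 20 females
truth = ct.default_truth()
surv = ct.generate_survival(design, truth, seed=1)
rates = ct.generate_egg_rates(design, truth, seed=1)

fit24 = ct.fit_survival(surv, line=19.0, duration=24.0, boot_n=999, seed=1)
print(f"LT50 = {fit24.lt50:.2f} (95% CI {fit24.ci95['lt50'][0]:.2f}-{fit24.ci95['lt50'][1]:.2f})")

tfit = ct.fit_tpc(rates, line=19.0, boot_n=999, seed=1)
print(f"Topt = {tfit.topt:.2f}, Rmax = {tfit.rmax:.1f}, CTmax = {tfit.ctmax:.2f}")
print(f"safety margin = {tfit.safety_margin:.2f}, breadth = {tfit.breadth_width:.2f}")
```

prints (seed 1):

```
LT50 = 32.46 (95% CI 32.31-32.74)
Topt = 26.47, Rmax = 97.9, CTmax = 32.11
safety margin = 7.47, breadth = 7.57
```

i.e. the control line loses half its plateau survival at 32.5 °C after 24 h,
its egg production peaks near 26.4 °C at ~98 eggs ind⁻¹ d⁻¹ and ceases by
~32.1 °C, it is reared 7.5 °C below its reproductive optimum, and performance
stays above 80% of the maximum across a ~7.6 °C band.

The same analysis runs from the shell:

```
copetherm run --out report --seed 1 --boot-n 999
```

writing the survival and TPC parameter tables, the Q10 table, the
recruitment profile and a JSON manifest under `report/`.

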
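# fermkin

Kinetic analysis of batch DHA fermentations — for bioprocess scientists
modelling growth, glucose consumption and docosahexaenoic acid (DHA)
production of thraustochytrids (*Aurantiochytrium* / *Schizochytrium*-type
strains) in shake flasks.

The package covers the full desk-side workflow around a three-state ODE
model (time in days, concentrations in g/L):

```
dC_X/dt = mu·C_X          with  mu = mu_max·(1 − C_X/C_Xm)     logistic growth
dC_S/dt = −(1/Y_X/S)·dC_X/dt − m_S·C_X                          uptake + maintenance
dC_P/dt = (alpha·mu + beta)·C_X                                 Luedeking–Piret
```

* **simulate** the model forward (event-handled substrate exhaustion,
  closed-form logistic oracle),
* **generate** realistic noisy triplicate time courses from three built-in
  strain parameter sets (`native`, `BBF001`, `BBF002`),
* **fit** `(mu_max, C_Xm, m_S, alpha, beta)` by joint bounded least squares
  with `Y_X/S` fixed at 0.45 g/g, reporting a per-variable
  `R² = SSM/(SSM+SSE)` fit statistic,
* **describe** a run by its endpoint kinetic panel
  `Q_X, Q_S, Q_P, mu, Y_X/S, Y_P/S` over the window from inoculation to
  peak product titer.

See `docs/methods.md` for the model assumptions, estimation procedure and
numerical conventions.

## Worked example

Generate a noisy synthetic BBF002 shake-flask data set (5 % CV, daily
sampling over 5 days, triplicates), fit it, and summarize it:

```python
from fermkin import (NoiseSpec, builtin_scenario, compute_descriptors,
                     fit_parameters, generate, mixed_growth_partition)

sc = builtin_scenario("BBF002")        # mu_max 1.617, C_Xm 19.891, m_S 0.033, ...
data = generate(sc, NoiseSpec(seed=1))

res = fit_parameters(data)
print(f"mu_max = {res.params.mu_max:.3f} 1/d   C_Xm = {res.params.C_Xm:.3f} g/L")
print(f"R2 (DCW, glucose, DHA) = {res.r2_X:.4f}, {res.r2_S:.4f}, {res.r2_P:.4f}")

panel = compute_descriptors(data)
print(f"Q_X = {panel.Q_X:.3f}  Q_S = {panel.Q_S:.3f} g/L/d   "
      f"mu = {panel.mu:.3f} 1/d  Y_XS_obs = {panel.Y_XS_obs:.3f} g/g")

sh = mixed_growth_partition(res, data)
print(f"growth-associated share = {sh.growth_associated:.2f}  alpha > beta: {sh.alpha_dominant}")
```

prints

```
mu_max = 1.652 1/d   C_Xm = 19.539 g/L
R2 (DCW, glucose, DHA) = 0.9950, 0.9915, 0.9961
Q_X = 3.815  Q_S = 8.311 g/L/d   mu = 0.377 1/d  Y_XS_obs = 0.459 g/g
growth-associated share = 0.51  alpha > beta: True
```

The two growth parameters come back within ~2 % of the generating values
(1.617 1/d, 19.891 g/L) despite 5 % measurement noise; the maintenance and
product coefficients are more weakly identified from six time points, which
is exactly what the stochastic tests characterize.  The descriptor panel
says biomass accumulated at 3.8 g/L/d and the observed biomass yield was
0.46 g biomass per g glucose over the 0–5 d window.  The partition confirms
DHA behaves as a mixed-growth-associated product, with about half of it
formed through the growth-coupled term.

The same pipeline from the shell:

```
fermkin generate --scenario BBF002 --seed 1 --out runs/
fermkin fit      --input runs/BBF002_synthetic_seed1.csv --out runs/
fermkin describe --input runs/BBF002_synthetic_seed1.csv --out runs/
```

Every output CSV gets a `.meta.json` sidecar with the configuration, its
hash and the seed; identical configurations produce byte-identical files.
A YAML file passed with `--config` can override initial states, noise
levels, bounds and tolerances.

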
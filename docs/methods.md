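# Methods

## The model

`fermkin` describes a batch shake-flask fermentation of a DHA-producing
thraustochytrid (*Aurantiochytrium limacinum*) with three coupled state
variables, all in g/L: biomass dry cell weight `C_X`, glucose `C_S` and DHA
titer `C_P`.  Time is in days everywhere.

```
dC_X/dt = mu * C_X,            mu = mu_max * (1 - C_X / C_Xm)
dC_S/dt = -(1/Y_XS) dC_X/dt - m_S * C_X
dC_P/dt = (alpha * mu + beta) * C_X
```

Growth is logistic: the specific growth rate declines linearly from `mu_max`
at vanishing density to zero at the carrying capacity `C_Xm`.  Growth is
*density*-limited, not substrate-limited — there is no Monod term, which is
the model's central assumption and its main limitation (see below).  Glucose
is consumed stoichiometrically for growth (yield `Y_XS`) plus a
maintenance drain `m_S * C_X` (Pirt form).  DHA formation follows the
Luedeking–Piret law: a growth-associated term `alpha * mu * C_X` and a
non-growth-associated term `beta * C_X`; the product is "mixed-growth
associated" when both coefficients are nonzero, and `alpha > beta` is the
conventional qualitative indicator that formation is growth-dominated.

Parameters, units and defaults:

| symbol   | meaning                               | unit      | built-in values (native / BBF001 / BBF002) |
|----------|---------------------------------------|-----------|--------------------------------------------|
| `mu_max` | maximum specific growth rate          | 1/d       | 1.568 / 1.585 / 1.617                      |
| `C_Xm`   | carrying-capacity biomass             | g/L       | 12.934 / 17.866 / 19.891                   |
| `Y_XS`   | stoichiometric biomass yield          | g/g       | 0.45 (fixed, from the elemental biomass formula CH1.79O0.5N0.2 on glucose) |
| `m_S`    | maintenance coefficient               | g/(g·d)   | 0.005 / 0.024 / 0.033                      |
| `alpha`  | growth-associated product coefficient | g/g       | 0.100 / 0.033 / 0.055                      |
| `beta`   | non-growth product coefficient        | g/(g·d)   | 0.001 / 0.029 / 0.020                      |

The three named parameter columns correspond to the native,
acid-tolerant (BBF001) and acid/high-temperature-tolerant (BBF002) strains
fermented at pH 4.5 and 30 °C.

### Closed-form solution

Because the biomass equation is autonomous and decoupled, the whole system
integrates in closed form: `C_X(t)` is the logistic function, its running
time-integral `I(t) = ∫ C_X dτ` has an elementary expression, and

```
C_S(t) = C_S0 - (C_X(t) - C_X0)/Y_XS - m_S * I(t)       (clamped at 0)
C_P(t) = C_P0 + alpha * (C_X(t) - C_X0) + beta * I(t)
```

The closed form is used two ways: as the independent oracle the numerical
integrator is validated against, and as the exact, fast predictor inside the
least-squares objective.  The logistic function is evaluated in its
decaying-exponential form so large times cannot overflow.

### Substrate exhaustion

The published equations let glucose go negative once it is exhausted,
because growth does not depend on it.  Our convention: `dC_S/dt` is forced
to 0 from the instant `C_S` reaches 0; growth and product formation are
untouched.  The simulator implements this with event detection (terminal
event at `C_S = 0`, restart with the substrate equation frozen) so the
adaptive integrator never steps across a discontinuity; naive clamping
inside the right-hand side makes LSODA's step-size collapse near the
crossing.  Whether the original fits handled exhaustion this way is
unknown; it is a package convention.

One concrete consequence: with the BBF001/BBF002 parameter sets and the
default initial state, 40 g/L glucose runs out before day 5 while biomass
keeps growing.  Two things follow.  First, the endpoint observed yield
`Y_XS_obs = ΔC_X/(-ΔC_S)` is only guaranteed to sit *below* the
stoichiometric 0.45 g/g while substrate remains positive over the window;
once exhaustion censors ΔS the observed yield can exceed it (BBF002 over
0–5 d gives 0.477).  Second, the post-exhaustion glucose observations are
identically zero and carry no information about `m_S`, yet the noise-free
fits still recover it exactly from the pre-exhaustion samples.

## Simulation

`simulate` integrates with `scipy.integrate.solve_ivp` (LSODA — adaptive,
stiff-capable, deterministic) and returns states at exactly the requested
sample times via dense output.  Default tolerances `rel_tol = 1e-8`,
`abs_tol = 1e-10` keep integration error far below fitting error for
parameters quoted to 3–4 significant figures.  The default initial state is
`(C_X, C_S, C_P) = (0.6, 40, 0.02)` g/L: the glucose concentration is the
production-medium recipe; biomass and product carryover of the 10 % (v/v)
inoculum are not published anywhere, so plausible values were chosen once
and are exposed in configuration, never hard-coded in the science code.

## Synthetic data

`generate` emulates triplicate 5-day shake-flask sampling: the noise-free
trajectory on a daily 0–5 d grid plus independent Gaussian noise per
variable, standard deviation `max(CV · value, floor)`, truncated at 0.
Defaults: CV 5 % on all three variables (typical DCW/HPLC/GC assay
precision), floors 0 g/L, 3 replicates.  One root seed spawns three
per-variable `numpy` child streams, so a seed pins the table bit-for-bit.

What the generator does *not* emulate: autocorrelated or heteroscedastic
instrument drift, sampling-volume effects, missing values, and any
systematic model misfit — the synthetic truth is the model itself.  Passing
recovery tests therefore demonstrate correctness of the estimation
machinery and identifiability under the stated noise, not that the model
describes any particular real culture.

## Parameter estimation

`fit_parameters` estimates `(mu_max, C_Xm, m_S, alpha, beta)` jointly from
all observations of all three variables, with `Y_XS` fixed at 0.45 g/g
(estimating it is deliberately unsupported: it is collinear with `m_S` from
a single batch).  Choices made where the original procedure is unstated
(a black-box desktop optimizer):

- **Joint, range-weighted objective.** Residuals of each variable are
  divided by that variable's observed range before squaring, so glucose
  (~40 g/L) and DHA (~2.5 g/L) contribute comparably.  A single coherent
  objective is reproducible; sequential per-equation fitting is not better
  identified and needs arbitrary ordering.
- **Bounded trust-region least squares** (`scipy.optimize.least_squares`,
  `trf`) with generous default boxes: `mu_max ∈ (0, 5]` 1/d,
  `C_Xm ∈ (0, 60]` g/L, `m_S ∈ [0, 0.5]`, `alpha ∈ [0, 1]`,
  `beta ∈ [0, 0.5]`.
- **Deterministic multistart.** One data-driven start (carrying capacity
  from the biomass maximum) plus 8 Latin-hypercube starts drawn with a
  fixed seed; best final objective wins, ties to the earliest start.  This
  guards against local minima without nondeterminism.
- **Initial conditions** are taken from the first observation (replicate
  mean), not estimated.
- The accepted-objective trace and all per-start objectives are kept on the
  result for diagnostics.

Goodness of fit is reported per variable as `R² = SSM/(SSM + SSE)` with
`SSM = Σ(C_cal − C̄_exp)²`, `SSE = Σ(C_cal − C_exp)²`.  This statistic is
bounded in [0, 1] and equals 1 exactly at a perfect fit, but it is *not*
the classical coefficient of determination (model deviations, not data
deviations, appear in the numerator), so only those two properties are
asserted.  Per-variable reporting is strictly more informative than a
single pooled value; the pooled "blanket" figure is available as the
minimum of the three.

`mixed_growth_partition` splits total product formed over a trajectory into
its two sources using the closed form: the growth-associated integral
`∫ alpha·mu·C_X dt = alpha·ΔC_X` and the non-growth integral `beta·I`.
Shares sum to 1 whenever any product is formed.

## Kinetic descriptors

`compute_descriptors` evaluates the endpoint panel over a window
`(t1, t2)`: volumetric rates `Q_X = ΔC_X/Δt`, `Q_S = −ΔC_S/Δt`,
`Q_P = ΔC_P/Δt`; specific growth rate `mu = Q_X / mean(C_X,1, C_X,2)`;
observed yields `Y_XS_obs = Q_X/Q_S`, `Y_PS_obs = Q_P/Q_S` (the interval
lengths cancel — an exact algebraic identity the tests assert).  The
default window runs from the first sample to the time of maximum product
titer (earliest time on ties).  Descriptors use sampled endpoints only;
requesting an off-grid time is an error, never a silent interpolation.
Replicates are averaged per time point by default; per-replicate panels are
available for mean ± SD reporting.  When no glucose is consumed the yields
are NaN and the rates are still returned.

## Numerical and degenerate-input conventions

- Exhaustion switch: terminal event with direction −1; the restarted phase
  pins `C_S` to exactly 0 (not round-off noise) at all later samples.
- Output states are floored at 0 to absorb integrator round-off.
- Windows with identical endpoint states give zero rates and NaN yields.
- A constant observed series predicted exactly gives R² = 1 (the 0/0 limit
  is resolved in favor of the perfect fit).
- Fit preconditions: at least 6 distinct sampling times and each variable
  observed at 4 or more of them; otherwise a validation error, never a
  silent fit.

## Problem sizes

The shipped analyses run at the scale of the study design: 6 daily samples
over 5 days, 3 replicates, three strains; the stochastic recovery
characterization uses 50 independently seeded synthetic data sets.  The
full test suite runs in well under a minute on one CPU.

## Known limitations

- No substrate dependence of growth: the model cannot describe starvation
  arrest, and post-exhaustion biomass/product predictions should be read
  as extrapolations of the logistic law.
- `alpha`, `beta` and `m_S` are weakly identified from 6 time points under
  realistic noise; the noise-robustness tests therefore bound only the
  well-identified `mu_max` and `C_Xm` (median relative error < 10 % at 5 %
  CV with triplicates) and the observed spread of the rest is left to the
  user to characterize for their own design.
- Temperature and pH enter only through the parameter values of each named
  scenario; there is no explicit dependence.
- No fed-batch, bioreactor mass transfer, or lipid-class partitioning.
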
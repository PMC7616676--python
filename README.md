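# chaostrench

Deterministic chaos in the *Escherichia coli* oxidative stress response:
a mother-machine trench simulator plus the chaos-detection toolkit used to
analyse single-cell reporter dynamics.

Genetically identical bacteria respond to hydrogen peroxide with strikingly
variable, seemingly random expression of the OxyR regulon. `chaostrench`
implements a purely deterministic multi-scale model showing that this
heterogeneity can arise without any molecular noise, from the coupling of
three processes in a one-dimensional microfluidic growth trench:

* **S — stress response.** H₂O₂ entering a cell oxidises the transcription
  factor OxyR; oxidised OxyR induces the scavengers KatG (catalase) and AhpC
  (peroxidase) and the glutaredoxin GrxA, which re-reduces OxyR:

  ```
  d[OxyR_red]/dt = −K_ox [OxyR_red][H₂O₂]cell + K_red [GrxA] · Ox/(Ox + h_OxyR)
  d[X]/dt        = R_X,basal + K_X,act · Ox/(Ox + h_X,act) − g [X]      X ∈ {GrxA, KatG, AhpC}
  d[H₂O₂]cell/dt = R_influx [H₂O₂]ext + R_basal − Σ_E K_E [E] · [H₂O₂]cell/([H₂O₂]cell + h_E)
  ```

  with `Ox = OxyR_total − OxyR_red`. A Langevin variant (S\*) adds gene
  expression noise by the Euler–Maruyama method in growth-rate
  non-dimensionalised time.

* **G — growth.** Adder cell-size homeostasis, `l(t+1) = l(t)(1+g)` with
  division into equal halves once 2 µm have been added since birth, and
  sigmoidal growth inhibition `g(h) = g₀ (1 − 1/(1 + 10^(−c₁(h − c₂))))`
  that halves exactly at `h = c₂`.

* **I — cell–cell interaction.** A steady-state reaction–diffusion balance
  between diffusion along the trench and absorption across the cell envelope,
  `u(x) = u(0) cosh((x − l)/λ′)/cosh(l/λ′)`, chained cell by cell from the
  open end, so that barrier cells shield the mother cell at the closed end.

The analysis toolkit quantifies the resulting mother-cell GrxA traces:
largest Lyapunov exponent (Rosenstein time-delay-embedding estimator),
Grassberger–Procaccia correlation dimension versus embedding dimension,
autocorrelation periodicity of the frame-difference signal, a
permutation-entropy determinism test against shuffled surrogates, dead-cell
classification, and GrxA × cell-count cross-correlation. A generic
toxin/detox-enzyme variant of the model and two MAE grid-search calibration
fits (growth-sensitivity steepness `c₁` and the GrxA-to-reporter intensity
scale) are included.

## Worked example

```python
from chaostrench import default_parameters
from chaostrench.simulator import SimulationConfig, run_single
from chaostrench.metrics import (lyapunov_exponent, correlation_dimension,
                                 acf_with_peaks, difference_signal,
                                 determinism_test)

params = default_parameters("oxidative", "glucose")   # g0 = 0.042/min
cfg = SimulationConfig(duration=5250, h_treatment=80.0, rng_seed=1)
res = run_single(cfg, params)                         # 25 um trench, 1-min steps
trace = res.mother_steady_trace("grxA")               # 700-5200 min post-treatment

lam = lyapunov_exponent(trace)
cd = correlation_dimension(trace)
_, _, period = acf_with_peaks(difference_signal(trace), max_lag=400)
det, stat = determinism_test(trace, seed=0)
idt = res.mother_interdivision_times(t_min=750).mean()

print(f"mother GrxA over 750-5250 min: mean {trace.y.mean():.3f} uM, "
      f"sd {trace.y.std():.3f} uM")
print(f"largest Lyapunov exponent: {lam:+.4f} per minute")
print(f"correlation dimension plateau: {cd.saturation:.2f} "
      f"(saturated: {cd.saturated})")
print(f"first ACF peak of the difference signal: {period:.0f} min "
      f"(mean interdivision time {idt:.1f} min)")
print(f"permutation-entropy classification: {det}, {stat}")
```

prints

```
mother GrxA over 750-5250 min: mean 0.353 uM, sd 0.047 uM
largest Lyapunov exponent: +0.0234 per minute
correlation dimension plateau: 1.71 (saturated: True)
first ACF peak of the difference signal: 37 min (mean interdivision time 30.7 min)
permutation-entropy classification: deterministic, stationary
```

A positive Lyapunov exponent means nearby trajectories diverge exponentially
(chaos); a low, saturating correlation dimension (~2 effective variables,
versus `D_corr ≈ E` for a shuffled surrogate) marks deterministic dynamics;
the ACF period matches the mother's interdivision time, identifying the cell
cycle as the underlying oscillator. Starting two otherwise identical trenches
with the mother's cell-cycle state shifted by 2.5·10⁻⁴ % separates the GrxA
traces by more than 10 % of their range after about 6.8 hours
(`init_mode="synchronized"`, `epsilon=2.5e-6`).

There is also a CLI:

```
chaostrench simulate --h2o2 80 --duration 5250 --seed 1 --out traces.csv
chaostrench analyze lyapunov --input traces.csv --passes 0 --t-start 750 --out report.jsonl
chaostrench bifurcation --concentrations 80,140,260 --out extrema.csv
```

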
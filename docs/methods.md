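# Methods

## The model

One growth trench of a mother-machine device is represented as an ordered row
of rod-shaped cells in a dead-end channel of length `L_trench` (default 25 µm)
and square cross-section `W²` (W = 1.2 µm). Index 0 is the outermost cell at
the open end, where the feed medium sets the boundary H₂O₂ concentration; the
last cell is the mother at the closed end. The boundary concentration is 0
before the treatment time point (default time point 50) and the treatment
concentration afterwards. Each 1-minute outer step applies three stages in
order:

1. **Interaction (I).** The external stressor profile is the steady state of
   a reaction–diffusion balance: diffusion through the free trench volume
   around each cell against absorption across its envelope. Per cell of
   length `l`, with screening length

   λ′² = (W²·l − πR_c²·l + (2/3)πR_c³) · D / (2πR_c·k_abs·l),

   the concentration decays as `u(x) = u(0)·cosh((x−l)/λ′)/cosh(l/λ′)`
   (Dirichlet at the source-facing pole, zero flux at the far pole — the next
   cell starts there with the continued value). The `(2/3)πR_c³` term is the
   extra free volume contributed by the two hemispherical caps of a
   sphero-cylindrical cell. Chaining this solution from the open end gives
   each cell's local concentration; barrier cells thereby shield the mother.
   The concentration fed to the response model is the value at the cell's
   source-facing pole (`interaction_driver="entry"`); a length-averaged
   alternative (`"average"`, the spatial mean `u(0)·(λ′/l)·tanh(l/λ′)`) is
   available and behaves qualitatively identically. The steady state is
   recomputed every step from current lengths; there are no transient
   diffusion dynamics, which is justified because H₂O₂ diffuses across a
   trench in well under a second while lengths change on the minute scale.

2. **Response (S).** The OxyR regulon ODEs (five species: reduced OxyR, GrxA,
   KatG, AhpC, intracellular H₂O₂) are advanced over the outer step holding
   the local external concentration and the *previous* step's elongation rate
   fixed. Gene expression has a basal and an oxidised-OxyR-inducible
   Michaelis–Menten term and is diluted at the growth rate; intracellular
   H₂O₂ balances influx (`R_influx · [H₂O₂]ext`) and endogenous production
   against Michaelis–Menten scavenging by AhpC and KatG. The general variant
   replaces this circuit by a single toxin/detox-enzyme pair in arbitrary
   units.

3. **Growth (G).** The new elongation rate is the sigmoid
   `g(h) = g₀(1 − 1/(1+10^(−c₁(h−c₂))))` of the updated intracellular
   stressor; every cell elongates geometrically, divides into two equal
   daughters when its added length exceeds `L_div = 2 µm` (both daughters
   occupy the parent's slot; the closed-end daughter inherits the mother
   role), and when the summed lengths exceed `L_trench` the outermost cell is
   flagged and removed at the start of the next step. The mother is never
   removed.

Coupling labels S / S+G / S+I / S+G+I (and S\*, … with the Langevin response)
switch stages off: without I every cell sees the boundary concentration;
without G the elongation rate is pinned at g₀.

## Parameters

All kinetics run in µM, µm and minutes; literature per-second constants are
converted once at construction. Defaults (oxidative variant, M9 glucose):
g₀ = 0.042 min⁻¹ (0.025 glycerol, 0.065 glucose + 10 % LB), c₁ = 2·10⁴ µM⁻¹,
c₂ = 10⁻⁴ µM, W = 1.2 µm, R_c = 0.575 µm, D = 10⁻⁹ m²/s, k_abs = 1.6·10⁻⁵
m/s, K_ox = 0.1 µM⁻¹s⁻¹, K_red = 8 s⁻¹, h_OxyR = 2583 µM, OxyR_total = 1 µM,
K_{grxA,katG,ahpC},act = {0.1, 0.15, 0.2} µM/min, h_{grxA,katG,ahpC},act =
{0.1, 0.18, 0.1} µM, basal rates {0, 0, 0.01} µM/min, K_AhpC = 660 s⁻¹,
h_AhpC = 1.2 µM, K_KatG = 4.9·10⁵ s⁻¹, h_KatG = 5900 µM, R_H2O2,basal = 0.02
µM/min, R_influx = 1 min⁻¹; Langevin amplitudes σ = {2·10⁻⁴, 0.02, 0.02,
0.02} with non-dimensional inner step Δt_nd = 5·10⁻⁶; reporter scale
k_GrxA,calibration = 1150.

Two unit choices deserve note. The cell radius is stored as 0.575 **µm**
(0.575 mm is dimensionally impossible inside a 1.2 µm trench). K_red is
treated as a per-second catalytic rate applied per µM of GrxA (8 s⁻¹ → 480
min⁻¹): the literature quotes it with a concentration unit attached, but the
OxyR reduction term multiplies K_red by [GrxA] and a dimensionless
saturation, so only a 1/time·1/µM reading makes the equation dimensionally
consistent.

The general variant keeps the geometry and g₀ but uses its own growth-sigmoid
scale, c₁ = 1 a.u.⁻¹ and c₂ = 1 a.u. (the scale of h_E and h_act). With the
oxidative c₂ = 10⁻⁴ carried over literally, any toxin influx freezes every
cell permanently and the model has no dynamics at all, which contradicts the
behaviour the abstract model is meant to display; placing the half-inhibition
point at the toxin scale of order one restores growing, dividing, chaotic
populations.

## Numerics

The intracellular H₂O₂ balance is stiff: once KatG accumulates, its
relaxation rate reaches 10⁴–10⁵ min⁻¹ against a 1-minute outer step. The
deterministic integrator therefore treats H₂O₂ with an exponential
(integrating-factor) update — exact for the frozen-coefficient linearisation
`dH/dt = a − bH` and unconditionally stable — and the four slow gene species
with Heun's method, on 100 fixed sub-steps per outer minute, compiled with
numba. In practice H₂O₂ rides its quasi-steady value `a/b` and the scheme is
second-order accurate in the slow variables: halving the sub-step changes a
1-minute result by < 10⁻⁶ relative (away from the treatment-onset boundary
layer, where the true solution itself has a sub-millisecond transient), and
long integrations converge to independently root-found steady states to
machine precision. The scheme's fixed points are exactly the ODE roots.

The stochastic variant follows the published recipe: the gene equations are
non-dimensionalised in time (t_nd = t·g) and advanced by explicit
Euler–Maruyama with inner step Δt_nd, each inner step adding σ·Z·√Δt_nd to
its species (the √Δt_nd reading is required for a Wiener increment; tests pin
the resulting variance). H₂O₂ is co-integrated deterministically on the inner
grid with the same exponential update — explicit Euler would destabilise once
KatG grows large during growth stalls. Concentrations are clipped at 0 (and
OxyR_red at OxyR_total) after every sub-step. Inside the trench simulator a
fully stalled cell (g underflows to exactly 0 through the sharp sigmoid) is
advanced with g clamped to 10⁻¹², which makes the noise amplitude √(g·dt)
vanish and reduces smoothly to the deterministic limit; the public
`stochastic_step` refuses g ≤ 0 outright.

Initial conditions: cells start at the unstressed steady state of the
response (found by a root solver). "Random" loading draws lengths uniformly
on [L_div/2, L_div] with the adder counter uniform over the cycle,
emulating an unsynchronised culture; "synchronized" loading uses identical
mid-cycle cells with the mother's initial length *and* adder counter scaled
by (1 + ε). Scaling the counter alone would be a null perturbation in
discrete time — it changes nothing until a division lands on a different
1-minute step — whereas the length enters the diffusion model continuously,
which is what makes the sensitivity experiment meaningful (the perturbation
is described at its source as a length difference).

## Chaos metrics

* **Lyapunov exponent.** The trace is z-scored and delay-embedded (delay =
  first ACF 1/e-crossing, dimension 3 by default, Theiler exclusion at the
  dominant FFT period). Each point is paired with its nearest neighbour and
  the mean log separation is tracked forward; the exponent is the slope of
  the initial linear region (up to 50 % of the total rise, or the whole
  horizon when there is no rise), per minute. On the regression battery the
  estimator recovers ln 2 for the logistic map at r = 4 within a few percent
  and ~0 for noiseless periodic signals. On weakly aperiodic oscillatory
  traces it is biased upward (it reports the early decorrelation rate, which
  exceeds the asymptotic divergence rate), so its *sign* is meaningful but
  small positive magnitudes should be read alongside the twin-divergence
  experiment.

* **Correlation dimension.** Grassberger–Procaccia correlation sums C(E, r)
  over delay vectors (Chebyshev norm, computed incrementally across E), radii
  log-spaced from 0.01 σ to 3 σ of the trace, temporally adjacent pairs
  excluded by default (|i−j| ≤ E; a switch restores the all-pairs sum).
  D_corr(E) is the log–log slope over the small-r scaling region
  (10⁻³ ≤ C ≤ 10⁻¹, widened when fewer than 5 radii qualify); radii where C
  stalls — exactly repeated values, as in sample-locked periodic signals —
  carry no scaling information and are dropped. The saturation value averages
  D_corr over the last three embedding dimensions; "saturated" requires the
  final increments to stay below 0.25 per dimension (white noise gives ~0.7–1
  per dimension).

* **ACF periodicity.** Traces are (optionally) moving-mean filtered with a
  shrinking centred window — no padding, no fabricated edge samples — then
  frame-differenced; the autocorrelation (statsmodels, FFT) is scanned for
  peaks of prominence 0.2 (scipy `find_peaks`); the first peak lag is the
  oscillation period. Simulated traces are analysed unsmoothed.

* **Determinism test.** Normalised ordinal-pattern (permutation) entropy,
  order 4, delay 1, ties broken by temporal order; compared against 200
  random shuffles of the same trace (which preserve the value multiset and
  hence mean and SD exactly). Entropy below the lower α/2 = 2.5 % surrogate
  quantile ⇒ deterministic, otherwise stochastic. Traces shorter than 110
  points are rejected as insufficient. Shuffle surrogates destroy *all*
  temporal structure, so strongly autocorrelated linear noise (e.g. an AR(1)
  process) is classified deterministic by this test — a known limitation of
  the surrogate family, inherited from the published procedure; white noise
  is the appropriate stochastic control. Stationarity is a windowed drift
  check: non-stationary when the spread of four block means exceeds one
  overall SD.

* **Alive/dead.** A mother cell is dead when its mean length growth rate is
  below 0.0024 min⁻¹.

* **Cross-correlation.** Frame-differenced, z-scored, normalised
  cross-correlation over ± max_lag. At 1-minute resolution the GrxA ×
  cell-count anti-correlation appears at short positive lags (the response
  integrates cell-count changes over a few minutes) and at lag 0 after
  smoothing both signals to the cell-cycle scale, which is how the test
  asserts it.

## Calibration fits

Both published fits are MAE grid searches where MAE is the mean of absolute
*relative* errors, and "steady state" is the time average over the final 20 %
of the run. `fit_c1` simulates the full model at each observed H₂O₂ condition
per grid value and compares per-position elongation rates (inner join over
(condition, position): the number of occupied positions varies with c₁;
an error is raised when fewer than half the observed pairs match).
`fit_reporter_scale` is a linear grid (0–2500, step 50) on the open-end
cell's steady-state GrxA. Both are exact-recovery consistent: data generated
by the forward model at a grid value are recovered at that value with zero
error, which the tests assert.

## What the synthetic data do and do not show

The simulator doubles as the package's data generator: every metric is
exercised both on known-dynamics fixtures (sine, logistic map, white noise,
AR(1), constant) and on simulated trace tables in the same tidy schema an
imaging pipeline would export (one row per cell per frame). The simulation
emulates deterministic single-trench dynamics at 1-minute resolution; it does
not emulate measurement noise, photobleaching, segmentation errors, uneven
frame intervals, or 2-D microcolony geometry, so passing tests validate the
method implementations and the model's internal predictions, not instrument
behaviour.

## Known limitations and regime differences

With the printed parameter set, this implementation's full deterministic
model is *weakly chaotic at every treatment concentration probed*
(2–1700 µM): synchronized twin runs with a 2.5·10⁻⁶ relative shift in the
mother's initial state separate to the scale of the trace range within
5–20 h everywhere, and the Lyapunov estimate is accordingly positive
everywhere (≈ +0.003 to +0.05 min⁻¹). Published descriptions of this system
instead report periodic oscillation at low-to-intermediate stress (λ ≤ 0
around 80–140 µM) with chaos from roughly 200–260 µM upward. The qualitative
signatures all reproduce — regular division-locked ACF peaks at 140 µM
versus steep peak-free ACF decay at 1.7 mM; ACF period equal to the
interdivision time; a saturating correlation dimension near 2 for the
deterministic model against non-saturating curves for shuffled surrogates
and the noise-only response model; divergence of minute initial-condition
differences on the ~6–7 h timescale; fluctuations requiring the interaction
coupling (S+G settles to a fixed point) and chaos requiring the growth
coupling (S+I is strictly periodic) — but the location of the
periodic-to-chaotic boundary along the concentration axis does not. A
plausible cause is that c₁·c₂ = 2 leaves the growth sigmoid partially
engaged at every concentration, so division timing is always sensitive to
the stressor gradient; differences in the original integration scheme (not
specified at sub-minute resolution) could damp that sensitivity. The
discrepancy is reported as-is rather than tuned away.

Desk-scale defaults throughout: one trench (3 for replicate ensembles), 5250
one-minute time points, treatment from time point 50, analysis over the
700–5200 min post-treatment window — a full deterministic run takes ~2 s and
the entire acceptance computation well under a minute on one CPU.
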
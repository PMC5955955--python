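# Methods

`etmodel` models how the electrically silent human Kv9.2 (KCNS2)
subunit — wild type and the essential-tremor-associated D379E pore
mutant — modifies the *Drosophila* Shab (Kv2) delayed-rectifier K⁺
current, and how that modification propagates to the spontaneous
firing of l-LNv clock neurons and to circadian/sleep behavior.  This
note records the models, the conventions, the calibrated defaults and
the choices made where the design was genuinely open.

## Units

Fixed package-wide: mV, ms, nS, pA, pF.  With these, nS·mV = pA and
pA/pF·ms = mV, so the current-balance equation needs no unit
constants.

## Channel model

Each ionic current is Hodgkin–Huxley:

    I = gmax · m^P · h^Q · (V − E)

with first-order gates

    dx/dt = (x∞(V) − x) / τx(V)
    x∞    = 1 / (1 + exp(∓(V − Vh)/k))     (− activation, + inactivation)
    τx    = Amp · exp(−(V − Vmax)/σ)

* `k > 0` always; the sigmoid direction is carried by the gate's
  polarity flag, not the sign of `k`.
* τ is floored at `TAU_FLOOR_MS = 0.01 ms` (configurable).  The single
  exponential is unbounded below in V and would otherwise make the
  ODEs arbitrarily stiff.  With the shipped parameter sets the floor
  never engages in the physiological range.
* Shab-family K⁺ currents default to P = 4, Q = 1 (Q = 0 for the
  non-inactivating native channel); Na is m³h, Ca is m·h.
* Activation and inactivation gates have fully independent
  (Amp, Vmax, σ); nothing is shared between gates.
* Gates are true dynamical state.  Simulations initialize them at
  steady state for the holding/first-epoch voltage; holding epochs are
  long enough that this is inconsequential.

Under piecewise-constant voltage the gate ODE has the exact solution
`x(t) = x∞ + (x0 − x∞)·exp(−t/τ)`.  Voltage-clamp simulation uses this
closed form epoch by epoch, so clamp traces are exact to floating
point; the closed form is independently cross-checked against direct
ODE integration in the test suite (relative error ≤ 1e−6 over random
parameter draws).

## Voltage-clamp protocol and measurements

The standard I–V family is: hold −93 mV (100 ms settle) → prepulse
−133 mV for 500 ms → test step, −93…−3 mV in 10 mV increments, 200 ms
→ return epoch.  The return epoch is −80 mV while holding is −93 mV;
both values are retained as given, and the return epoch is excluded
from every measurement, so the discrepancy has no effect on results.
All model voltages are treated as junction-corrected values.

Conventions chosen where standard practice had to fill gaps:

* **Epoch boundaries are right-open.**  The sample at an epoch
  boundary belongs to the epoch that starts there (the step happens at
  the boundary), so test-epoch measurements exclude it.
* **Peak** = signed extremum over the test epoch after blanking the
  first 1 ms (capacitive-artifact guard; configurable).
* **Sustained** = mean of the final 5 ms of the test step, not the
  single end sample (noise robustness; configurable).
* **Percent of peak** = 100·sustained/peak, undefined at zero peak.
* Drug-subtraction (`pre − post`) requires bit-identical time grids;
  nothing is resampled silently.

The genotype × voltage comparison of percent-of-peak uses a two-way
fixed-effects ANOVA (Type I on a balanced design, which equals
Type III there); unbalanced designs are rejected explicitly rather
than silently reweighted.

## Parameter estimation

`ChannelFitModel` fits the channel parameters (gmax plus the gate
Boltzmann and τ parameters; E, P, Q fixed) to isolated-current traces
by bounded trust-region least squares (`scipy.optimize.least_squares`,
`trf`) on the test-epoch samples of all sweeps jointly.  The loss
surface has local minima, so the optimizer restarts from a seeded
Latin-hypercube sample of the bound box (default 16 starts) and
reports the best start; ties break by SSE, then activation Vh, then
the remaining parameters lexicographically, making results
reproducible bit for bit for a given seed.

Default bounds: gmax [0, 500 nS], Vh [−120, 20 mV], k [0.5, 40 mV],
Amp [0.1, 500 ms], Vmax [−120, 20 mV], σ [1, 200 mV].  σ ∈ (−1, 1) is
excluded because τ = Amp·e^(−ΔV/σ) blows up there; the default search
uses the positive branch (gates speed up with depolarization), and the
negative branch is available by setting `sigma_bounds=(−200, −1)`.

The fit target is the full subtracted trace, not peak/sustained I–V
summaries (the full trace is strictly more informative).  A summary
loss was considered and not implemented; the residual API makes it
easy to add externally.

Identifiability: activation parameters are sharply identified by the
I–V family (the recovery study in the acceptance tests finds the
activation midpoint to ≪ 1 mV under 2 % noise).  The *inactivation*
midpoint and slope, in contrast, are only weakly identified by this
protocol — the prepulse resets h ≈ 1 and h∞ ≈ 0 at all strongly
activating steps, so (Vh, k) trade off along a plateau and fits can
park Vh at a bound while leaving the current fit essentially perfect.
The quantities the genotype comparison relies on (inactivation k and σ
orderings, and the speed/extent of decay) are robust to this; the
individual inactivation Vh/k values should not be over-interpreted.
Resolving them would need a dedicated steady-state-inactivation
protocol, which is out of scope.

## Whole-cell l-LNv model

Single compartment, current balance:

    C dV/dt = Iapp − g_Na m³h(V−E_Na) − g_Ca mh(V−E_Ca)
              − Σ_{i=1..4} g_Ki m⁴h(V−E_K) − g_leak(V−E_leak)

with E_Na = 52 mV, E_Ca = 132 mV, E_K = −90 mV, E_leak = −7 mV (values
derived from the recording solutions via Nernst/GHK).  The four K
slots represent Shaker (K1), Shab/Kv2 (K2), Shaw (K3) and Shal (K4);
only K2 differs between genotype configurations, so rate comparisons
isolate the manipulated current.

The Na, Ca, K1, K3, K4 kinetics and all conductances are **calibrated
by this package**, not taken from any recording: they were chosen once
to produce tonic spontaneous firing in the low-Hz range at Iapp = 0
and are labelled accordingly.  The load-bearing calibration choices:

* the depolarized leak reversal (−7 mV) with a small g_leak
  (0.05 nS) is the spontaneous drive;
* Shaw-like K3 is given a far-depolarized inactivation midpoint
  (+20 mV) so a sustained K⁺ current survives at spike peaks —
  without it, every K current in the m⁴h structure eventually
  inactivates and the cell locks up in depolarization block;
* Shal-like K4 is a slow A-type (inactivation τ ≈ 300 ms near rest)
  whose gradual inactivation paces the interspike depolarization,
  putting rates in the observed 1–20 Hz band;
* the Kv2 slot uses the shipped genotype kinetics at a whole-cell
  conductance of 12 nS; the variants' inactivation midpoint (−55 mV)
  puts meaningful steady-state inactivation at interspike voltages, so
  losing Kv2 current through inactivation — not the activation left
  shift — dominates the excitability effect.  This yields the
  hyperexcitability ordering native < wild-type variant < mutant with
  comfortable margins (3.2, 9.8, 16.2 Hz over 5 s at the defaults).

Integration: LSODA (stiff-capable, adaptive) with `max_step` 0.25 ms,
rtol = atol = 1e−8, dense output sampled at 0.05 ms; `init="steady"`
starts gates at steady state for −55 mV and discards a 500 ms
transient.  Runs are deterministic, and halving `max_step` leaves the
5 s spike count unchanged.  Spikes are upward crossings of −20 mV with
linear interpolation and a 2 ms refractory guard (both configurable;
the recordings being emulated report rates without stating a rule).
Iapp defaults to 0 (spontaneous activity).

When the full pipeline places *fitted* variant kinetics into the cell,
absolute rates run higher than with the shipped kinetics (the weakly
identified inactivation midpoint lands deep, over-inactivating K2);
the genotype orderings are unaffected.  Rate-band statements therefore
refer to the shipped configurations.

## Circadian and sleep analysis

* **Sleep**: a minute is asleep iff it lies in a maximal run of
  zero-count minutes of length ≥ 5 (the threshold run itself counts).
  Verified against brute-force run enumeration.
* **Days** are Zeitgeber-aligned (ZT0 = lights-on); partial leading
  and trailing days are dropped.  Night = ZT12–ZT24.
* **Diurnal/nocturnal index** = day activity / total activity (1 =
  diurnal, 0 = nocturnal, undefined for an inactive record).  The
  index is used descriptively here; published tables using this name
  do not define it, so no numerical agreement is claimed.
* **Dead-tube exclusion**: records with zero counts over the final
  24 h are dropped by default (window configurable).
* **Periodogram**: Sokolove–Bushell χ².  For candidate period P (whole
  minutes, default grid 16–32 h in 0.1 h steps),
  `Qp = (N/P)·N·Σ_h(M_h−M̄)² / Σ_i(x_i−M̄)²` with df = P−1.  The rhythm
  statistic is the peak height of Qp above its significance line,
  maximized over the grid; rhythmic ⇔ statistic > 0.  Because the
  maximum is taken over ~161 correlated tests, the line is drawn at
  **family-wise** α = 0.01 (Bonferroni over the grid) by default: with
  the uncorrected per-period line, white-noise counts were called
  rhythmic in ~75 % of replicates, while the corrected line yields
  ~1 % family-wise false positives and still recovers 24 h and 26 h
  synthetic rhythms to the grid resolution.  `multiplicity="none"`
  restores the per-period line.  A Lomb–Scargle alternative was
  considered and deferred.

## Synthetic data

The generators are seeded pure functions.

**Voltage clamp** (`make_vclamp_dataset`): for each step and sweep,
`post_drug` = ohmic background leak (0.5 nS, E = −10 mV) + noise;
`pre_drug` = leak + exact channel current + independent noise;
subtraction recovers channel + √2-noise.  Noise is additive i.i.d.
Gaussian with SD = 2 % of that step's peak channel current by default
(the emulated recordings state no noise model; pink noise was
deferred).  The three shipped genotype parameter sets
(`data/genotypes.cfg`) are this package's own calibration, constrained
to the qualitative pattern — native non-inactivating; variants'
activation ≥ 5 mV left-shifted; the mutant with lower inactivation k,
higher inactivation σ, and faster decay — not to any cell's fitted
values, which are not available.

**Activity** (`make_activity`): per-minute Poisson counts whose rate
follows the light schedule (day 2.0, night 1.0 counts/min by default;
square 12:12 profile in LD, a sinusoid between the two rates at the
free-running period in DD, phase-continuous with the LD schedule).
Sleep bouts start with per-minute probability 0.02 (×6 during
[subjective] night), last Geometric(mean 20 min), and zero the counts.
Geometric durations make the expected asleep fraction analytic,
`p·L/(1 + p·L)` ≈ 0.71 for the default night — a realistic
consolidated night-sleep level for control flies — and the
"hyperexcitable" variant (night rate ×1.8, night sleep pressure ×0.5)
moves both night activity and night sleep in the directions reported
for the Kv9.2-expressing genotypes.  The default recording is 5 days
LD + 7 days DD.  What the generator does **not** emulate: activity
autocorrelation beyond sleep bouts, fly mortality, monitor artifacts;
passing round-trip tests therefore shows the analyzers are correct and
the effect directions are recoverable, not that real recordings would
give these magnitudes.

## Junction potential

Henderson equation with limiting equivalent ionic conductivities
(CRC values for inorganic ions; JPCalc-style estimates for gluconate
24.3, HEPES⁻ 22.05, EGTA²⁻ 24.3 S·cm²/equiv), evaluated at 295.15 K.
Solutions are built from their salt recipes with full dissociation;
EGTA is taken as the 2− species and HEPES as half-ionized at pH 7.2,
each accompanied by the charge-balancing cations of the titrant base
(KOH internally, NaOH externally); glucose is non-ionic.  The returned
sign is the potential of the pipette relative to the bath — the value
*added* to measured potentials — so the standard K-gluconate/saline
pair gives −13.3 mV and a nominal −80 mV holding corresponds to a true
−93 mV.  Charge states and organic-ion mobilities are the dominant
uncertainty, worth roughly ±1.5 mV.  Double application of the
correction to a trace raises.

## Numerical and testing choices

* Sigmoids saturate via `expit`; τ exponents are clipped before `exp`;
  no overflow up to |V − Vh|/k = 500.
* Deterministic seeds everywhere: generator seeds live in the specs,
  fit multistart uses a seeded Latin hypercube, pipeline stage seeds
  derive from the run seed via CRC32 of the genotype name.
* Problem sizes in the test suite are chosen to keep the full run a
  few minutes: 5 s whole-cell simulations for rate statements, 20-seed
  recovery studies at 16 starts, 100-replicate periodogram null, and
  1,000-sequence sleep-scoring enumeration.

## Known limitations

* Monotone-exponential τ(V) cannot produce the bell-shaped time
  constants of classical channel kinetics; it is adequate over the
  protocol's voltage range but should not be extrapolated.
* No Markov-state gating, temperature (Q10) effects, stochastic
  channels, series-resistance/space-clamp artifacts, or drug-binding
  kinetics (subtraction is ideal).
* The whole-cell model is a single compartment with calibrated
  non-Kv2 kinetics; its absolute rates are illustrative, and only
  within-model genotype comparisons are meaningful.
* No time-of-day dependence is modelled in the whole-cell equations
  (none is specified for the system being emulated).
* Inactivation midpoint/slope are weakly identified by the I–V
  protocol alone (see Parameter estimation).
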
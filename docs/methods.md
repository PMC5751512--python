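# Methods

`minicalor` models and inverts a heat-conduction calorimetry minisensor: a
thermopile between a 2 × 2 cm contact plate and a thermostated aluminium
block, used to measure the heat power a patch of human skin dissipates
through its surface. This note records the models, the numerical choices and
the limits of what the synthetic test bench can demonstrate.

## Sensor model

The instrument is treated as a linear time-invariant system with two inputs
and two outputs, sampled at 1 s:

* inputs — `W1(t)`: power crossing the measurement face (Joule calibration
  resistor, or the body), and `W2(t)`: power dissipated in the thermostat to
  hold its programmed temperature;
* outputs — `y1(t)`: thermopile voltage (mV), and `y2(t)`: thermostat
  temperature (°C).

Each of the four transfer functions shares one pair of real poles and has one
zero and a static gain,

```
TF_i(s) = K_i (1 + s·τ_i*) / ((1 + s·τ1)(1 + s·τ2)),     i = 1..4,
```

equivalently, in the time domain each output solves

```
τ1τ2·y'' + (τ1+τ2)·y' + y = K_a(τ_a*·W1' + W1) + K_b(τ_b*·W2' + W2).
```

The two-pole/one-zero order is what the instrument's signal-to-noise ratio
supports; the slow pole (~80 s) dominates settling, the fast pole is ~8–10 s.
A `SensorCalibration` (gains `K1, K2` in mV/W, `K3, K4` in K/W, poles and
four zeros in s) fully defines the model. The shipped `S1`/`S2` parameter
files hold the two physical devices' published values and round-trip
bit-exactly.

**Simulation.** Each channel is advanced with an exact zero-order-hold
discretization (`scipy.signal.cont2discrete` on the 2×2 companion form,
`lfilter` for the recursion), treating inputs as piecewise-constant over each
1 s interval. The numerator (zero) terms enter through the output matrix, so
no input derivative is ever formed numerically. This scheme is
unconditionally stable — important because the 1 s sampling step is not small
against the ~9 s fast pole — and is *exact* for step inputs, which the test
suite uses as an oracle: the simulated step response matches the closed form

```
y(t) = K·A·[1 − c1·e^(−t/τ1) − c2·e^(−t/τ2)],
c1 = (τ1 − τ*)/(τ1 − τ2),  c2 = (τ* − τ2)/(τ1 − τ2)
```

to ≤ 1e−6 relative (in practice ~1e−13). A repeated pole falls back to the
confluent form `K·A·[1 − e^(−t/τ)(1 + (1 − τ*/τ)t/τ)]`; the discretized
recursion needs no special casing. Signals are stored in instrument units
(mV, mW, °C) and converted to W/K only at the model boundary, so published
parameter tables survive round trips unchanged.

Thermostat-power saturation is modelled as a bounds check only: samples where
`W2` leaves `[0, W2max]` are flagged (log warning + mask), never clipped.

## Calibration

A calibration run programs the thermostat at 24 °C (to t = 150 s), 28 °C (to
t = 1050 s), then back to 24 °C until t = 1500 s, with a 300 mW Joule pulse
on the calibration base during t = 451–750 s. This yields five quasi-steady
zones (a–e). The chain is:

1. **Baseline correction** — subtract, per channel, the line joining the
   opening-window mean to the closing-window mean (level + linear drift);
   with only a pre-window, subtract its mean. Body runs default to
   pre-window-only correction: their return baseline is approached only
   asymptotically, and anchoring a drift line on it measurably distorts the
   record (the effect is visible at the 0.1 % reconstruction level on ideal
   data).
2. **Steady-state extraction** — inside each zone, discard the first
   `settle_multiplier × τ_rough` seconds (default 1.2 × 100 s, leaving 180
   averaging samples in the 300 s zones) and estimate the steady level. The
   default estimator fits `a + b·e^(−t/τ)` and reports the asymptote `a`,
   because a plain tail mean over a zone only a few time constants long
   carries an O(1 %) residual-transient bias; the plain mean remains
   available (`method="mean"`). Zones whose post-settle standard deviation
   exceeds the instrument's steady ripple (0.2 mV on y1, 5 mK on y2) are
   flagged.
3. **Sensitivities** — each zone obeys `K1·ΔW1 + K2·ΔW2 = Δy1` and
   `K3·ΔW1 + K4·ΔW2 = Δy2`; with five zones this is an overdetermined linear
   system solved by OLS, independently per output row, with least-squares
   standard errors reported (they describe this solve, not run-to-run
   repeatability). Proportional `(ΔW1, ΔW2)` zone geometry raises a
   singularity error.
4. **Dynamics** — the default fit (`method="varpro"`) searches only the two
   shared poles with Nelder–Mead on a log scale; for any candidate pole pair
   the four gains and four zeros are solved exactly by linear least squares
   on the full 1500-sample transient, since the numerator coefficients
   (`K_i` and `K_i·τ_i*`) enter the outputs linearly. Per output, four
   nuisance regressors join the design: a constant and a ramp (finite
   baseline windows misplace the `W2` reference by a few mW, because the
   thermostat ripple is strongly autocorrelated) and the two homogeneous
   solutions `e^(−t/τ1)`, `e^(−t/τ2)` (a noisy first input sample otherwise
   injects a spurious slow decay through the steady-state initialization).
   This estimator uses every sample for the gains too, which removes the
   finite-zone bias entirely: noiseless round trips recover all ten
   parameters to ~1e−5 %.

   A staged variant (`method="staged"`) reproduces the classical procedure —
   gains frozen at the steady-state estimates, Nelder–Mead over the six time
   constants (log-poles; zeros on a softplus transform with an exact-zero
   snap below 1e−3 s, poles sorted slow-first after each evaluation). It is
   kept because it isolates the two stages for study; its accuracy is limited
   by whatever bias the gain estimates carry.

   Both channels are fitted jointly, minimizing the noise-normalized sum
   `σ_y1/0.2 mV + σ_y2/5 mK` — the shared poles couple the channels, and the
   weights are the instrument's steady ripple amplitudes. Per-channel RMS
   errors `σ_y1` (mV) and `σ_y2` (mK) are reported. Optimizer settings:
   relative f-tolerance 1e−10, x-tolerance 1e−6, ≤ 5000 evaluations, up to 3
   restarts jittered with a fixed seed (20171128).

## Body heat flux

During a skin-contact measurement the power crossing the sensor is modelled
as a constant plus decaying exponentials,

```
W1(t) = A0 + Σ A_i·e^(−(t−t0)/τ_i),
```

with `t0` the contact instant (taken from the phase marker; no sub-sample
alignment). Two terms suffice in practice: a fast (~3 s) term from the
thermal discontinuity of moving the sensor from its base to the skin, and a
slow (~70 s) term tracking the body's adaptation to the contact. `A0` is the
steady flux through the 4 cm² contact area. Amplitudes are unconstrained in
sign — above the skin temperature (~32 °C) the transient terms go negative.

**Inverse fit.** Candidate fluxes are pushed through the calibrated `TF1`
channel together with the *measured* `W2` through `TF2` (the thermostat's
regulation transient is inherited exactly, so the fit only explains what the
body added), and compared to the measured calorimetric signal with the
normalized RMS error

```
σ_y1 (%) = 100 · sqrt( Σ(y1_exp − y1_cal)² / Σ y1_exp² ).
```

Because the sensor is linear in `W1`, amplitudes are separable: for fixed
time constants they solve an exact linear least-squares problem (variable
projection). Free-τ fits therefore run Nelder–Mead only over the log time
constants (initialized at 3 and 70 s) with the amplitude solve inside;
fixed-τ fits — the recommended mode, with the canonical (3, 70) s — are a
single linear solve. Pinning the time constants makes the amplitudes
independent of each other; on ideal data the recovered `A0` moves by < 0.5 %
as the slow constant sweeps 50–90 s. More than four terms are rejected as
unidentifiable at the instrument's noise level. `Wmean`, the older
window-mean estimator that the exponential model refines, is computed in
closed form over the application window; the expected ordering (`A0 < Wmean`
for a thermostat colder than the skin, equal near it, reversed above) falls
out of the sign of the transient terms.

## Thermal resistance and conductivity

Across a series of measurements at different thermostat temperatures, the
steady flux falls on a line `A0 = α + β·Tcal`. The chain
`R_T = 1/|β|` (total thermostat-to-body-core resistance),
`R_body = R_T − R_sensor`, `λ = L/(S·R_body)` gives an order-of-magnitude
tissue conductivity under a flat-wall assumption (slab of depth `L` = 1 cm —
about half a hand's width — and area `S` = 4 cm²). `R_sensor` defaults to
12 K/W, the rounded value from the sensor-on-sensor contact experiment
(10 K across two sensors passing 420 mW → 5/0.420 ≈ 11.905 K/W per sensor;
the unrounded value is available). By default the A0 slope is rounded to one
decimal before inversion, matching how the chain is quoted at the
instrument's printed precision (`slope_decimals=None` disables this). The
flat wall is knowingly crude — tissue heat transport is dominated by
perfusion — and the result is only meant to land on the literature's
0.2–0.7 W/m/K scale.

## Synthetic instrument

No public data sets exist for this instrument, so the package carries a
generator that emulates it end to end:

* **Thermostat loop** — a PI controller (`Kp` = 2 W/K, `Ki` = 0.05 W/(K·s),
  `Kd` = 0; artifact tuning, chosen so a +4 K setpoint step settles within
  ±5 mK in under 300 s) acts on the *measured* thermostat temperature and
  drives the sensor's state-space model one sample at a time, with output
  clamping to [0, 1] W and conditional-integration anti-windup. Divergence
  is detected and reported with the offending gains. The characteristic
  `W2`/`y1` oscillation at setpoint changes and at skin contact — larger for
  larger |Tcal − Tbody| — emerges from this loop, as does the ±10 mW steady
  ripple of `W2` (the controller's response to the ±5 mK temperature noise;
  no ripple is injected directly).
* **Noise** — the instrument exhibits peak steady-state oscillations of
  ±0.2 mV (y1), ±5 mK (y2) and ±0.1 mW (W1). The default noise model draws
  white Gaussian samples with σ = half-amplitude/2 and applies a 5-sample
  moving average, giving band-limited traces with ≳95 % of excursions inside
  the stated bounds; a uniform option exists. An optional slow sinusoid on
  the body flux emulates the low-frequency physiological oscillation that
  destabilizes free-τ fits.
* **Body ground truth** — either an explicit exponential flux model or a
  coupling rule tying the flux to the thermostat temperature:
  `A0 = (Tcore − Tcal)/R_T` (defaults `Tcore` ≈ 40 °C, `R_T` ≈ 71.9 K/W,
  matching the reference hand series), a contact term
  `A1 = g1·(Tbody − Tcal)` with `g1` = 90.49 mW/K vanishing at the skin
  temperature (32 °C), and an adaptation term on the published
  `A2`-versus-temperature line, with the canonical (3, 70) s time constants.
  The contact event is modelled purely as this flux; no separate
  contact-resistance transient is added (the ~3 s term plays that role).
* Room temperature is emitted as a constant 24.7 °C channel; no
  room-coupling is simulated.

**What the synthetic bench does and does not show.** Passing round trips
demonstrate that the estimators are consistent and unbiased *when the data
really follow the two-pole/one-zero sensor and the exponential flux model*,
at the instrument's noise level and protocol durations. They do not validate
the physical model against a real body: real skin flux is not exactly a
biexponential, the real thermostat's control law is undocumented (the PI
loop here is a stand-in validated only by reproducing the qualitative
transient signatures), and slow physiological oscillations make free-τ
estimates disperse — which is why the fixed-(3, 70) s mode exists.

## Problem sizes and determinism

The default suite and the acceptance script use the protocol-length records
the method itself prescribes (1500 s calibration runs, 900 s three-phase
body runs at 1 s sampling). Monte-Carlo checks use 20 seeded calibration
replicates for gain/residual statistics and 5 seeded random ground-truth
draws for the identifiability round trip. All randomness flows from explicit
seeds (`numpy.random.default_rng`); identical seeds give bit-identical
records and output files.

## Known limitations

* The exponential-asymptote zone estimator assumes a single dominant
  residual mode per zone; its estimates are initial/diagnostic values with
  ~1 % accuracy, and final gains come from the full-transient fit.
* Gain standard errors are least-squares errors of the steady-state solve
  only; no full uncertainty propagation is attempted.
* Free-τ flux fits on noisy or drifting data can land in the shallow,
  bimodal region of the slow time constant; fixed-τ refits are the
  recommended production mode.
* `R_body = R_T − R_sensor` treats the contact as ideal; the two-sensor
  resistance experiment itself is noted to be imprecise at the ~1 K/W level.
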
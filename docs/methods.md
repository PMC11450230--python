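# Methods

## The four-state symport cycle

The model treats the transporter as a single-file 1 K⁺ : 1 H⁺ carrier with
four lumped states: outward-open empty (C1), protonated (C2), fully loaded
(C3) and inward-open (C4). Internal release of K⁺ and H⁺ and the return of
the empty inward-facing carrier are lumped into the single composite state
C4, so the re-binding step carries the product of both internal
concentrations, `k43 = k43⁰ [H⁺]i [K⁺]i`. All charge movement is assigned
to the C1↔C4 transition through a single symmetric Eyring barrier,
`k14 = k14⁰ e^{FV/RT}` and `k41 = k41⁰ e^{−FV/RT}`; the product `k14·k41`
is therefore voltage independent, which the tests assert. Microscopic
reversibility removes one degree of freedom:
`k41⁰ k12⁰ k23⁰ k34 = k14⁰ k21 k32 k43⁰`. `KineticParams` always recomputes
one designated constant (default `k43⁰`, the one multiplying the tiny
internal concentration product) so the identity holds by construction to
1e−10 relative.

Steady-state occupancies come from the King–Altman enumeration of the
sixteen directed spanning trees of the 4-cycle; the current is
`I = 2eN (k14 C1 − k41 C4)` (two charges per cycle), computed in the
factorised closed form and verified internally against the flux form. The
two are algebraically identical, but near equilibrium the flux form
subtracts two nearly equal unidirectional terms, so the internal
consistency check scales roundoff by those terms rather than by the net
current.

### Numeric oracle

`numeric_occupancy_oracle` solves the stationary master equation
independently of the closed form by Gaussian elimination of the generator
matrix in the cancellation-free GTH (Grassmann–Taksar–Heyman) form:
diagonal pivots are recomputed as sums of off-diagonal rates, so the
elimination uses only nonnegative additions and multiplications and the
result is componentwise accurate even when occupancies span >10 orders of
magnitude. A plain double-precision least-squares null-space solve cannot
certify 1e−9 *relative* agreement on occupancies near 1e−13 (its absolute
error floor of ~1e−20 translates to ~1e−7 relative there); the GTH form
can, which is what the oracle-equivalence tests require.

## Reduced Michaelis–Menten descriptions

The King–Altman denominator is affine in each external concentration, so at
fixed voltage and co-substrate the influx branch is exactly hyperbolic.
Collecting the sixteen terms by their [K⁺]o dependence yields the closed
forms for `K_K` and `I_Kmax`; collecting by [H⁺]o yields `K_H`. In the
[K⁺]o-proportional block of the `K_H` numerator the exact spanning-tree
grouping contains the cross term `k14·k43` (the C₃,₃ tree). The reductions
are exact when the internal concentration product is zero and are verified
against numerically located half-saturations of the full current (grid
bracketing + Brent root finding) to 0.1%; at the default internal
conditions (pH 7.1, 100 mM K⁺) the `k43` perturbation shifts `K_K` by well
under 1%.

`K_K` is homogeneous of degree −1 in `k23⁰` when everything else is held
fixed, which is the basis of the K⁺-site mutant scenario: dividing `k23⁰`
by 1000 multiplies `K_K` by exactly 1000 in the pure influx regime (within
1% at default internals, because the derived `k43⁰` is re-derived to keep
detailed balance). Multiplying `k32` by 1000 instead gives current–[K⁺]o
curves agreeing within ~2% (≤5% asserted) — the two mutant modes are
approximately, not exactly, equivalent, the residual coming from the `k34`
admixture in the denominator and the re-derived `k43⁰`.

## Calibration of the default parameter set

No published table of the eight rate constants is available, so the
defaults are produced by `calibrate_default_params`: six log₁₀ rate
constants fitted by deterministic least squares (log-ratio residuals,
fixed starting point, bounds 10⁻²–10¹²) to published oocyte anchors, then
the transporter count N set analytically from the saturating current
(current is linear in N; only the product of N and the rate scale is
identifiable). Default targets:

| observable | value | conditions |
|---|---|---|
| K_m[K⁺] | 23.56 µM | −120 mV, pH 4.5 |
| K_m[H⁺] | 4.81 µM | −120 mV, 200 µM K⁺ |
| K_m[H⁺] | 24.81 µM | −90 mV, 200 µM K⁺ (the ~20 µM rise per +30 mV) |
| \|I_Kmax\| | 417 nA | −140 mV, pH 4.5 (sets N) |

All three affinity targets are met to <1e−6 relative (asserted; the
calibration raises on residuals above that). Two structural choices close
the identifiability gap:

* **k21 = k34/2, held fixed.** The targets cannot identify the external H⁺
  debinding rate. The ratio `k21/k34` controls two observed *directions*:
  `k21 < k34·k41/(k41+k34)` makes a weaker K⁺ site (k23⁰÷1000) *increase*
  the apparent H⁺ affinity, and a sub-unity ratio makes external
  acidification raise the K⁺ affinity. Both hold on the defaults.
* **Starting point.** Chosen from the structure of the closed forms so that
  the K⁺ affinity stays weakly voltage dependent (the `(k41+k14)` factor
  appears in both numerator and denominator of `K_K` but only in the
  numerator of `K_H`): `k14⁰/k41⁰ ≈ 1.5e4` puts the voltage sensitivity in
  `K_H` (60-fold over −60…−150 mV) while `K_K` varies <2-fold over
  −60…−140 mV, and the maximal current collapses above −40 mV.

The exact mutant affinity value (K_m[H⁺] = 0.36 µM) is *not* a calibration
target: imposing it forces `k34 ≫ k21`, which through detailed balance
inflates `k43` and makes `K_K` strongly voltage dependent, contradicting
the observed weak dependence. The defaults reproduce the mutant shift's
direction (4.81 → 2.85 µM) but not its full magnitude; reproducing both
simultaneously is outside what this four-state scheme with a single scaled
constant and these anchors can deliver.

Temperature is never stated for the original recordings; the package
defaults to 298.15 K (RT/F = 25.693 mV), user-overridable everywhere.

## Thermodynamic uptake limits

`thermo` computes equilibrium (zero-current) limits only: a channel
equilibrates at `[K⁺]o = [K⁺]i·10^{V/s}`; an n:1 H⁺-coupled symporter at
`[K⁺]i·10^{n·ΔpH}·10^{(1+n)V/s}` with ΔpH = pH_out − pH_in. The default
decadic slope is 60 mV (the textbook round-number convention, which makes
the 150 mM/−180 mV/2-pH-unit scenario give exactly 150 µM, 1.5 nM and a
10⁵ advantage); the exact temperature-derived slope (59.16 mV at 25 °C) is
available via `haksym.constants.nernst_slope_mV`. The symport limit is
exactly the concentration at which the kinetic model's reversal potential
equals the scenario voltage — a cross-module identity the tests verify to
1e−6 mV. No activity coefficients or surface potentials.

## Dose-response fitting

Responses are fitted as magnitudes |ΔI| by unweighted least squares (lmfit,
Levenberg–Marquardt, xtol = ftol = 1e−13; optional per-point weights).
`K_m` is initialised at the concentration nearest half the largest response
(log-interpolated over replicate-averaged points) with bounds 1e−15–1e3 M;
a fit ending on a bound raises rather than returning a silently clipped
value. The Hill exponent starts at 1 (bounds 0.05–20), making the
Michaelis–Menten fit the exact h = 1 special case — the nestedness the
tests assert. The bell-shaped steady-state fit holds `K_m` at the peak-fit
value and frees only the scale `I_max` and offset `I_s`; its argmax equals
`K_m` analytically (`bell_argmax`), confirmed by a grid-search oracle.

Trace features: baseline = median current over the pre-step window;
ΔI_peak = max |I − baseline| in the step; ΔI_SS = mean |I − baseline| over
the final 5% of the step window (the pulse-end rule, widened to a window
for noise robustness); percent inactivation = 100·(ΔI_peak − ΔI_SS)/ΔI_peak,
undefined (NaN) for a flat trace.

## Synthetic data generator

`generate_dose_response` draws `model(c)·(1 + cv·z) + σ_add·z′` per point
(z, z′ standard normal, clipped at zero), with the default replicate noise
CV of 5% used in the recovery studies. `simulate_tevc_trace` builds
per-segment currents `(ss + (peak − ss)e^{−t/τ_inact})(1 − e^{−t/τ_act})`,
adds a per-trace leak (default −84.55 ± 7.2 nA, the control-oocyte response
to 2 mM K⁺) and seeded noise. Defaults τ_act = 0.7 s and τ_inact = 20 s are
anchored to the only printed timing facts — peaks after about 2 s, complete
decay within the 120 s pulse; no measured time constants exist.

The wild-type preset's peak surface is Michaelis–Menten in the cation
(K_m = 23.56 µM) times a Hill factor in H⁺ (K_m = 4.81 µM, h = 1.67). Its
steady-state level keeps the bell *shape* `gain·K_ss·c/(c+K_ss)² + offset`
(relative to the maximal peak, clamped to the peak) with gain = 2.0 and
offset = 0.04 chosen at design time to reproduce the observed inactivation
ladder — 0% at 10–20 µM/pH 4.5, ~68% at 200 µM, ~92% at 2 mM, ~83% at
20 µM/pH 6.5 (`K_ss` scales with [H⁺]o). The published bell-fit constants
themselves (I_max = 1.01 µA, I_s = 124 nA) predict ~26% inactivation at
10 µM, inconsistent with the observed flat traces there, so the preset is
calibrated to the ladder, not to those constants. A `KineticParams` source
uses the cycle current for the peak and, since the pure four-state cycle
has no inactivation mechanism, sets the steady state equal to the peak.

What passing tests do **not** show about real data: the generator has no
capacitive transients, series-resistance or bath-exchange kinetics, no
oocyte-to-oocyte leak correlation, and its inactivation is a phenomenological
relaxation, not a mechanistic state. Estimator-recovery results transfer to
real recordings only insofar as the multiplicative-noise model does.

## Numerical conventions

Concentrations in mol/L, voltages in mV at every interface, currents in
ampere (examples print nA/µA). Inward (cytosol-entering) current is
negative; dose-response layers work on magnitudes. Percent-inactivation and
trace features are undefined on zero peaks rather than silently zero.
Simulated traces used in ladder tests run with the generator's noiseless
default (cv = 0): peak extraction from noisy traces is max-biased, a
property of the estimator, not of the ladder. Known limitations: no
pre-steady-state (time-dependent) solution of the master equation, no
six-state scheme, single 1:1 stoichiometry, local (covariance-based)
standard errors only.
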
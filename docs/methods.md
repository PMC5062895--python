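# Methods

## Scope and assumptions

`smokekin` models the gas-phase kinetics of nicotine during tobacco
pyrolysis under three simplifying assumptions about the temperature sweep:
(1) below the yield peak, formation outpaces destruction; (2) at the peak
the two rates balance, so the peak yield is the reference concentration C₀;
(3) above the peak, destruction dominates and the yield decline over the
residence time is pseudo-first-order in the parent compound. Yields are
GC-area counts — a relative unit; every quantity the package reports is
either a ratio of counts (calibration cancels) or a rate parameter, so no
absolute calibration is required.

The chemistry behind the consecutive model is a single destruction channel,
Nic → pyridinyl radical → pyridine. Parallel channels (e.g. the
3-methylpyridine route), reversible steps and oxygen-dependent chemistry
are out of scope; consequently the inferred intermediate is an upper-bound
style estimate that attributes all pyridine to this one route, and the
budget check [Nic]₀/(I + product) < 1 is the model's own flag that other
sources of pyridine exist.

## Parameters

| parameter | units | default | role |
|---|---|---|---|
| residence time t | s | 2.0 | reaction time per puff; the kinetic clock for every rate constant |
| gas constant R | J K⁻¹ mol⁻¹ | 8.314 | Arrhenius exponent scale |
| temperature grid | K | 473–973, step 50 | pyrolysis sweep (200–700 °C) |
| k₁ | s⁻¹ | — | nicotine destruction rate constant |
| k₂ | s⁻¹ | — | intermediate → product conversion |
| [Nic]₀ | counts | — | original nicotine (peak or extrapolated) |

Activation energies are stored in J/mol and only formatted as kJ/mol at the
report layer; mixing the two scales inside an exponent is a silent
1000-fold error, so no computation ever sees kJ.

Temperatures are converted to kelvin once, at the I/O boundary, using
273.15. Input files declare their unit (`--temp-unit`, default celsius).

## Estimation choices

* **Arrhenius fit.** Unweighted ordinary least squares of ln k on 1/T
  (Ea = −slope·R, A = e^intercept). With the few temperatures a furnace
  sweep provides, weighting cannot be estimated; r² of the same regression
  is the only uncertainty measure reported. A perfectly flat table
  degenerates to Ea = 0, A = k.
* **Temperature exponent.** The modified law k = A·Tⁿ·e^(−Ea/RT) is solved
  for n per temperature in closed form, n = [ln k − ln A + Ea/RT]/ln T —
  no iteration, since the law is monotone in n at fixed T. Reports quote
  the in-window entry nearest 673 K, the conventional reference
  temperature for these kinetics.
* **Peak and window.** The peak is the grid argmax; ties break toward the
  lowest temperature (earliest formation). C₀ is that single peak yield —
  never pooled or smoothed (with ~6–11 temperatures, smoothing would
  invent data; an optional config hook exists but is off by default).
  Post-peak points whose yield ties C₀ are excluded with a logged reason
  rather than clamped to k = 0, which would bias the fit; strict mode
  turns the exclusion into an error. Since C₀ is the global maximum, a tie
  is the only reachable violation.
* **Formation fit.** The puff-time ordinate is the measured nicotine
  amount; the regression is ln(yield) on puff time, which is what the
  zero-puff-time extrapolation of the original amount requires. Three
  points cannot support weighting. A positive slope is flagged
  (`non_decaying`) instead of silently reported as a negative rate.
* **k₂ inversion.** `invert_k2_from_product` applies the rate-determining
  step simplification, k₂ = −ln(1 − product/[Nic]₀)/t. Note that with
  [Nic]₀ = 8.0×10⁸, product = 4.4×10⁸ and t = 2 s this gives 0.399 s⁻¹,
  not the 0.13 s⁻¹ sometimes quoted alongside those inputs (0.13 coincides
  with the formation-side constant); the package computes the closed form
  and leaves the choice of input to the caller.

## Numerical choices

* The intermediate concentration uses the `expm1` rewriting
  k₁[Nic]₀·e^(−k₂t)·expm1((k₂−k₁)t)/(k₂−k₁), immune to the catastrophic
  cancellation of the naive difference of exponentials; within a relative
  rate difference of 10⁻⁶ the analytic equal-rate limit
  [Nic]₀·k·t·e^(−kt) is used (the raw formula divides by zero). Continuity
  across the branch is tested.
* The product uses the mass-conserving closed form
  [Nic]₀[1 + (k₂e^(−k₁t) − k₁e^(−k₂t))/(k₁−k₂)]; conservation
  nic + I + product = [Nic]₀ then holds algebraically and is tested at
  10⁻⁹ relative.
* The independent ODE oracle integrates the three coupled linear rate
  equations with LSODA at rtol 1e-10, atol 1e-12·[Nic]₀; closed forms are
  validated against it at 10⁻⁶ relative with an absolute floor at the
  integrator's resolution (exponentially tiny tails cannot be resolved in
  relative terms by any integrator).
* Reports round floats to 12 significant digits before JSON serialization
  with sorted keys, so identical inputs give byte-identical files; CSV
  round trips are exact (`%.17g` out, round-trip parsing in).

## Synthetic data

The generator emulates the competition that shapes the sweep: a formation
process saturating as 1 − e^(−k_f(T)t) and a destruction process surviving
as e^(−k_d(T)t), both Arrhenius. Two curve models are provided:

* `ideal` (default): formation-limited rise below the peak,
  y = S·(1 − e^(−k_f t)); above it, first-order decay of the peak
  concentration, y = C₀·e^(−k_d t). This is exactly the idealization the
  destruction pipeline inverts, so the noise-free pipeline returns the
  generating (Ea, A) to machine precision — the core end-to-end identity
  test of the whole package.
* `batch`: the literal product y = S·(1 − e^(−k_f t))·e^(−k_d t), in which
  each temperature is an independent batch whose formed amount also
  decays. Physically more literal, but the peak yield then already
  contains the survival factor e^(−k_d(T_peak)t), so the peak-as-C₀
  convention underestimates every extracted rate constant by k_d(T_peak)
  and biases the recovered Ea by several percent even without noise. It is
  retained for studying exactly that model error.

Noise is multiplicative lognormal with median 1 and relative sd
`noise_sd` — GC-area counts are strictly positive and heteroscedastic, so
additive Gaussian noise would be the wrong shape. A single integer seed
drives all draws; replicate r of seed s uses `default_rng((s, r))`.

Fixture defaults are the study conditions: ES1 destruction
(Ea 108.85 kJ/mol, A 2.1×10⁶ s⁻¹), precursor pool 8.0×10⁸ counts, and
formation Ea 60 kJ/mol with A = 1.2×10⁵ s⁻¹ placing the noise-free peak at
673 K (400 °C); SM1 destruction (136.52 kJ/mol, 3.0×10⁷ s⁻¹), pool
8.0×10⁷ counts (one tenth of ES1, an approximation of the roughly tenfold
yield difference between the cigarettes), and formation A = 2.2×10⁴ s⁻¹
placing the peak at 773 K (~500 °C). The generator does **not** emulate:
multi-peak curves, temperature-dependent matrix effects, chromatographic
artifacts, or pyridine formation routes other than nicotine destruction —
so passing recovery tests demonstrate correctness of the inversion under
the model's own assumptions, not robustness to real-sweep systematics.

### What recovery tests show — and a known limitation

Noise-free, the destruction pipeline is an exact inverse of the `ideal`
generator (Ea and A to machine precision, tested for both fixtures). Under
2 % multiplicative noise the recovered Ea has a relative sd near 9 %: the
first post-peak temperature (723 K for the ES1 fixture) has k_d·t ≈ 0.057,
the same order as the noise on ln(C₀/y) (sd ≈ 0.028), and that point
carries the highest leverage in the unweighted 1/T regression. Ea recovery
error is verified to grow monotonically with noise, but users should not
expect few-percent Ea accuracy from a single noisy sweep at this grid;
averaging replicate sweeps or widening the post-peak temperature range is
the practical remedy.

## Problem sizes

Simulation-based tests use the default 11-temperature grid with 100 seeded
replicates per noise level (destruction recovery) and 500 replicates of
3-point puff series (formation recovery); the whole suite runs in a few
seconds on one CPU.
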
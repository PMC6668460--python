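# Methods

## Exchange model and its assumptions

The dispersion of the rotating-frame relaxation rate with spin-lock strength
is modelled in the fast-exchange limit of two-site chemical exchange:

    R1rho(w1) = R1rho_0 + phi_ex * kex / (w1^2 + kex^2)

where `kex` is the sum of forward and backward rate constants and
`phi_ex = pA*pB*ddelta^2` collapses the state populations and the
chemical-shift difference between the states into one parameter — in the
fast limit the two are not separable from dispersion data alone. The model
is valid when `kex` is large compared with `ddelta` (in rad/s); this is
documented, not enforced, since the fitted rates here (~1e4 s^-1) sit
comfortably in that regime for amide 15N shifts. Slow-exchange numerical
propagation of the full two-site evolution is out of scope.

`R1rho_0` absorbs every exchange-free rate contribution, including the
uniform paramagnetic relaxation enhancement introduced by doping: a PRE
agent shifts the plateau but not the exchange term, which is exactly how the
synthetic generator models it and why doped and undoped datasets should give
the same `(kex, phi_ex)`.

Multi-field data are fitted jointly. `phi_ex` is expressed at the lowest
static field present (the reference); for a higher field the exchange term
is multiplied by the squared ratio of proton Larmor frequencies, because the
shift difference in angular units grows linearly with B0.

### Off-resonance correction

Measured rates are tilted back on-resonance with
`R1rho = (R1rho_obs - cos^2(theta) R1) / sin^2(theta)`,
`theta = arctan(w1/|Omega|)`. The point error is scaled by `1/sin^2(theta)`
accordingly. Peaks poorly covered by the spin lock are excluded rather than
corrected: the default threshold is `theta < 45 deg` (equivalently
`|Omega| >= w1`), configurable, and each exclusion is recorded with its
reason. The threshold is a design choice: practice in the field excludes
such peaks per condition without a published formula, and 45 degrees is the
natural geometric boundary where the offset term starts to dominate.

## Fitting machinery

With `kex` held fixed the model is linear in `phi_ex` and the plateaus, so
all fits use variable projection: per residue, a nonnegative linear
least-squares solve (NNLS) for `(R1rho_0 per field, phi_ex)` against the
error-weighted design, inside a one-dimensional search over `kex`. The
outer search is a 50-point log-spaced grid on [1e2, 1e6] s^-1 followed by
bounded scalar refinement between the bracketing grid points (xatol 1e-10
on log10 kex). This is deterministic, has no starting-value sensitivity,
and enforces `phi_ex >= 0`, `R1rho_0 >= 0` exactly. Groups refuse to fit
when points are fewer than parameters; each member needs at least three
distinct spin-lock frequencies.

The chi-square target is `sum_f w_f sum_i (calc-exp)^2/sigma^2`. When data
from several fields are combined, weights `w_f` can be derived so that each
field contributes equally: each field is first fitted separately (own free
kex) and `w_f = min-chi2(reference)/min-chi2(f)`. Weighting is disabled
with a warning if any per-field fit fails.

Fixed-kex profiles re-run the inner solves across a grid (>= 25 points over
>= 2 decades) and report `chi2 / min(chi2)`; a sharp minimum means the data
restrain `kex`, a shallow one that they do not. Model comparison uses
`BIC = chi2 + k ln(n)` with `k = 1 + n_residues + n_residues*n_fields` for
a shared-kex group (plateaus are per residue and per field by default,
since dopant concentrations — and hence plateaus — can differ between
fields; a combined candidate built from a partition sums chi2, k and n).
Candidates are only comparable on the identical point set, which is
enforced. No multiple-testing correction is applied across residues in the
per-residue dispersive/flat classification; it is a descriptive BIC
comparison.

## Monte-Carlo errors

Decay fits: the fitted curve is back-calculated, perturbed, and refit 2000
times; the reported error is 2 x SD of replicate rates. Two perturbation
modes exist. `literal` adds `U(0,1) * sigma` to each back-calculated
integral — a one-sided perturbation that biases replicate amplitudes upward
(the rate spread is still meaningful, and the mode is provided for
protocol fidelity). `gaussian` adds `N(0, sigma)` and is the default; no
intent is guessed beyond offering both, and the mode used is recorded in
output metadata. Dispersion fits use the same scheme on the back-calculated
on-resonance rates with 250 replicates; each replicate re-searches `kex`
within one decade of the base fit. Errors are flagged unreliable when more
than 10% of replicates pin `kex` at the local search bounds.

Numerical choice: the 2000 decay replicates are refit by a damped
Gauss-Newton iteration vectorised across replicates and started from the
base fit (14 iterations, rate clipped to [0, 5000] s^-1). Perturbed optima
lie close to the base fit, so this converges to machine precision at
realistic noise levels; the base fit itself uses bounded trust-region least
squares with multi-start from the log-linear estimate and 0.5x/2x of it,
tie-broken by residual sum.

## MAS-dependent rates

The spinning-frequency dependence of R1rho is modelled as the sum of the NH
dipolar and 15N CSA contributions, each a weighted sum of the simple
model-free spectral density `J(w) = (1-S^2) tau / (1+(w tau)^2)` evaluated
at the spin-lock/MAS combination frequencies `w1 +/- wr`, `w1 +/- 2wr` and
the Larmor frequencies. J is even, so the (always negative) combinations
like `w1 - 2wr` are evaluated at their absolute value. Defaults:
`r_NH = 1.02 A`, axially symmetric CSA with
`delta_sigma = sigma_par - sigma_perp = -170 ppm`, `eta = 0`, tensor
collinear with NH. Asymmetric tensors and 13C relaxation are out of scope.

**Unit caveat, prominent by design:** the CSA prefactor takes
`delta_sigma` in ppm and converts it to angular frequency as
`delta_sigma * 1e-6 * omega_N` *before* squaring. Written with a bare ppm
value the expression would not be dimensionally a rate; the conversion at
the measurement field is the only reading that yields s^-1.

15N's gyromagnetic ratio is negative; it is stored signed, and every
prefactor squares the coupling so only the magnitude enters. The
heteronuclear combination `wH - wN` uses magnitudes, `|wH| - |wN|`.

`S^2` is fitted at fixed `tau` by a bounded weighted linear solve (the rate
is linear in `1 - S^2`); `tau` is an input — typically the inverse of the
average fitted `kex` — never a free parameter, because two-parameter
model-free fits on two or three MAS points are underdetermined. An optional
nonnegative additive baseline per residue is available but off by default
(whether such an offset belongs in the fit is genuinely open; the flag
makes both choices available, and a degenerate MAS grid that cannot
separate the two is flagged unconstrained). Jump-angle interpretation
inverts `S^2 = 1 - 3 pA pB sin^2(theta)`; populations below the attainable
floor `1 - 3 pA pB` are marked rather than clamped.

## Synthetic data generator

The generator emulates the pseudo-3D measurement model the analysis
assumes: for each (residue, field, spin lock) a mono-exponential decay at
the observed rate, built by forward application of the exchange model, the
field scaling, and the tilt-angle construction
`R1rho_obs = sin^2(theta) R1rho + cos^2(theta) R1`, with additive Gaussian
noise on the integrals. Defaults are the study conditions: two fields (600
and 700 MHz 1H Larmor) at 60 kHz MAS, ten spin-lock strengths spanning
1-25 kHz, eight delays to 0.11 s, ten residues sharing `kex = 1.4e4 s^-1`
with `phi_ex` spread over 2.5e4-1.4e5 rad^2 s^-2, plateaus of 8-12 s^-1,
`R1 = 1.5 s^-1`, amplitude 100 and integral noise sigma 1 — which yields
relaxed-rate errors of roughly 3-8%, the scale of real data of this kind.
Offsets alternate in sign up to 8 ppm so the tilt correction is exercised.
The noise sigma is reported as the per-series integral error (a noiseless
run reports a nominal 1.0 so chi-square weights stay defined). Doping is a
uniform plateau increment with the exchange term unchanged.

What the generator does *not* emulate: spectral overlap and lineshapes,
coherent dipolar-dephasing contributions near rotary-resonance conditions,
site-specific distance-dependent PRE profiles, or the occasional raised
rates near particular spin-lock strengths seen in some real datasets.
Passing tests therefore demonstrate correct inversion of the stated
measurement model, not robustness to those artefacts.

Determinism: a single integer seed fully determines every output; stage
seeds are derived by hashing `seed:stage-name`, and replicate seeds for
batch decay fitting from the seed and the series index. Reruns are
byte-identical.

## Problem sizes used in the validation suite

Statistical properties are exercised at the study's scale: 20 synthetic
two-field datasets of 10 residues for exchange-parameter recovery (decay MC
at 2000 replicates, dispersion MC at 250), 150 curves x 500 replicates for
decay-error coverage, and 100 trials x 100 replicates for S^2 coverage —
sizes chosen to give stable pass/fail statistics for nominal-95% coverage
assertions at a >= 90% threshold.

## Known limitations

- Fast-exchange only; no numerical Bloch-McConnell propagation.
- The per-field plateau default inflates parameter counts when dopant
  concentrations are in fact equal across fields; a shared-plateau fit is
  available by restricting to one field or post-hoc comparison.
- The field-weighting scheme equalises *minimum* chi-square contributions;
  it is not a maximum-likelihood treatment of heteroscedasticity between
  fields.
- The literal one-sided MC perturbation mode reproduces a protocol exactly
  as stated elsewhere, including its amplitude bias; use the gaussian
  default for statistically conventional errors.
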
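# Methods

## Model

Neural field theory averages spiking activity into mean firing-rate fields.
Each population `a` has a cell-body potential V_a whose firing response is
the sigmoid S(V) = Q_max / (1 + exp(−(V − θ)/σ′)); linear perturbations
about the alert steady state are governed by the slope ρ_a = dS/dV, which
combines with anatomical connection strengths ν_ab into dimensionless gains
G_ab = ρ_a ν_ab. Synaptodendritic dynamics give every connection the
second-order low-pass L(s) = [(1 + s/α)(1 + s/β)]⁻¹ (α = 80 s⁻¹ decay,
β = 320 s⁻¹ rise); only cortical excitatory axons are long enough to need
the damped-wave operator D_e(k, s) = (1 + s/γ_e)² + k²r_e², with
γ_e = 100 s⁻¹. Conduction between thalamus and cortex introduces pure
delays τ_es = 20 ms (forward) and τ_se = 60 ms (feedback).

The loop couples four dynamical populations. In the Laplace domain the
perturbation equations are linear in (φ_e, φ_i, φ_r, φ_s); eliminating
φ_i and φ_r yields the closed forms implemented in `ctloop.transfer` (see
the module docstring for the block algebra). Two structural identities of
cortical connectivity are enforced at validation time — G_ee = G_ie,
G_es = G_is, G_ei = G_ii — because the cortical elimination step
(absorbing φ_i into M = D_e(1 − G_ei L) − G_ee L) is only exact under
them. The inhibitory self-gain therefore carries the sign of G_ei
(G_ii = −8.1); an `allow_asymmetric` flag permits experimentation outside
this regime, but the closed forms are then approximations.

Every closed-form transfer function is verified in the test suite against
an independent direct solve of the 4×4 linear system at random complex
frequencies (relative error < 1e−10), so the elimination algebra is not
taken on trust.

All analyses fix the spatial wavenumber k = 0 (spatially uniform stimuli,
the SSVEP configuration); the operator carries k for completeness. The
sigmoid utilities are provided for completeness of the parameter layer —
the linear analysis consumes gains directly, and no steady-state solver is
included (gains are inputs, estimated elsewhere).

## Rational approximation

The transfer functions are transcendental (delay exponentials). For
control-systems analysis they are approximated by stable pole-residue
models Σ r_j/(s − λ_j), fitted to the response sampled on a uniform
1024-point grid over 0–150 Hz:

* **Vector fitting** (Sanathanan–Koerner style pole relocation via the
  sigma-function eigenvalue step) with uniform least-squares weighting,
  at base order 16. Initial poles: conjugate pairs seeded at the known 9
  and 18 Hz loop resonances (damping −0.1·Ω), extra pairs log-spaced to
  the band edge, two real poles log-spaced in 5–50 s⁻¹. Unstable poles
  are reflected into the left half-plane each iteration; the iteration cap
  (60) and fixed initialization make the fit deterministic. Nearly
  degenerate poles are perturbed by 1e−9 (relative) with a warning.
* **Modal truncation** to a requested lower order: the least-damped,
  highest-energy poles are retained (score |r_j|/|Re λ_j|, the integrated
  magnitude of the mode's impulse response; conjugate pairs kept whole)
  and residues are re-fit by linear least squares at the fixed poles.
  For all four populations this yields the same physical mode structure —
  one real pole pair plus conjugate pairs near 9.0 and 18.2 Hz — which the
  band decomposition requires. Direct low-order vector fits can merge or
  displace these modes for the thalamic responses; balanced truncation was
  evaluated as an alternative reduction and rejected for the same reason.

**Error measure.** `rms_fractional_error` is the global relative error
rms(|T_fit − T|)/rms(|T|) over the grid. A pointwise-relative measure
(rms of |ΔT|/|T|) is uninformative here: T_en carries the pure factor
e^(−s τ_es), whose phase winds ~19 rad by 150 Hz while |T_en| falls five
orders of magnitude; any low-order rational has bounded phase, so the
pointwise ratio saturates at O(1) over most of the band for every 6-pole
model, regardless of how well the model captures the dynamics that matter.
The global measure reflects fit quality where the response has mass. The
16-pole fit of T_en reaches ~3e−4; the canonical 6-pole model ~0.05, with
an intrinsic floor near 0.03 (the best local least-squares optimum found)
set by the untrackable delay phase above ~30 Hz.

Band decomposition assigns the real pair to the low band and conjugate
pairs to alpha/beta by |Im λ|/2π with edges at 5 and 15 Hz (edge ties go to
the lower band); if both pairs land in one band the split falls back to
frequency order with a warning. Residues are preserved, so the three
2-pole parts sum exactly to the parent model.

## Filter identification

Each pole pair defines the second-order predictive filter
K(s + 1/τ_p)/((s + p₁)(s + p₂)) with p_j = −λ_j, K = r₁ + r₂ and
τ_p = (r₁ + r₂)/(r₁p₂ + r₂p₁). Characteristics follow the standard
second-order formulas (Ω₀² = p₁p₂, 2ζΩ₀ = p₁ + p₂, bandwidth B = 2ζΩ₀,
Ω_peak = Ω₀√(1 − 2ζ²) and M_peak = 1/(2ζ√(1 − ζ²)) for ζ < 1/√2). Two
conventions are worth noting:

* The stored gain K is the pair-sum (numerator) convention; the
  low-frequency gain of the convolution stage alone is K/Ω₀², and both are
  derivable from the reported rows.
* Resonance frequencies quoted by the package are Ω_peak of the identified
  band filter. For T_en the beta resonance appears in the raw magnitude
  |T_en(i2πf)| only as a shoulder near 16 Hz (no interior local maximum —
  the cortical low-pass is steep enough to flatten it), while the
  underlying beta mode sits at 18.2 Hz; the filter characterization
  recovers the mode, the grid peak-finder intentionally does not invent
  one. The identified resonances with default parameters are ≈8.7 Hz
  (alpha) and ≈17.8 Hz (beta) for the cortical response and ≈8.7 Hz for
  the relay nuclei.

With the default parameters the cortical (T_en) and relay (T_sn) band
filters all have positive prediction times (the loop anticipates its
input); the inhibitory and reticular responses each have one band whose
residue phase makes τ_p marginally negative under this fit — prediction
times are ratios of near-cancelling residue combinations and inherit a few
tens of percent of fit-algorithm sensitivity, so their signs near zero are
not robust quantities.

The small-damping approximation τ_pΩ₀ ≈ −Re(r)/Im(r) (for the residue at
the Im λ > 0 pole; the sign flips under the classical Γ − iΩ_c pole
notation) is reported alongside the exact value and flagged inapplicable
for real residues.

## Tracking simulation

The stimulus is Gaussian white noise hard-masked in the frequency domain
above 30 Hz, de-meaned and scaled to unit power: 100 s at 512 Hz per seed,
first 2 s discarded as filter transient, ten seeds. These sizes put the
standard error of each residual fraction well below 0.01 while keeping the
whole experiment in seconds of compute. Band responses use an exact
per-mode first-order-hold discretization (each mode x′ = λx + u integrated
exactly for piecewise-linear input), so in-band sinusoidal gains match the
analytic frequency response to well under 1%.

Delays are estimated as the lag (resolution 1/fs, window 0–200 ms)
maximizing the magnitude of the cross-correlation — magnitude, because
the optimal gain may be negative and the best alignment anticorrelated.
Gains solve ordinary least squares in closed form; at the optimum the
residual is orthogonal to every regressor (asserted to 1e−8). Summed
schemes estimate one common delay on the summed output and re-estimate it
once on the optimally weighted sum; `separate_gains` also supports
per-band delays (`delay_mode="per_band"`), which lowers the residual
further (≈0.13) because each band aligns at its own lobe.

With defaults, mean residual fractions over ten seeds are ≈0.89 (low
alone), 0.40 (alpha), 0.39 (beta), 0.74 (single common gain), 0.52
(separate gains at the common delay); the low-band delay is ≈52 ms. Two
bounds frame these numbers: a single delayed-and-scaled copy of a filter
output can never explain more stimulus variance than the filter passes
coherently — for the ~2 Hz-bandwidth low filter under a flat 0–30 Hz
stimulus that caps the explained share near 12%, so its residual fraction
cannot drop much below 0.85 — and the nested least-squares structure
forces separate_gains ≤ single_gain ≤ 1 always. The orderings
beta < alpha < low and separate < single hold for every seed.

## What the synthetic stimulus does and does not capture

The generator emulates the statistics of flicker-SSVEP luminance
perturbations: stationary, Gaussian, zero-mean, spectrally flat to 30 Hz.
It does not emulate natural-scene temporal spectra (which are strongly
red), retinal preprocessing, nonstationarity, or any spatial structure —
so tracking results quantify the linear filters' band-capture properties
under a maximally severe flat-spectrum test, not performance on natural
input. A redder stimulus concentrates power where the low filter operates
and would reduce all residual fractions while compressing the
beta < alpha < low ordering.

## Numerical choices and degenerate inputs

* Conjugate pairs are stored once (Im λ > 0) and expanded on evaluation,
  keeping all models real-coefficient by construction.
* Evaluation exactly at a pole raises; repeated poles are rejected at
  model construction (degenerate roots are outside scope).
* Validation errors name the offending field; delays may be given in ms
  (default) or s in config files.
* The discrete derivative in `predict`/`pid_output` is central in the
  interior and one-sided at the edges.
* `power_spectrum` is a Hann-window Welch estimate (nperseg 4096) whose
  integral matches the series variance to a few percent.

## Known limitations

* The 6-pole global-relative fit error (~0.05) is dominated by the delay
  phase above 30 Hz; applications needing phase fidelity there should use
  the 16-pole model or the exact transcendental form.
* Prediction times of weakly excited bands (notably T_in alpha, T_rn low)
  are sensitive to the reduction algorithm; treat their magnitudes, not
  signs, as meaningful.
* Spatial modes (k ≠ 0), nonlinear dynamics, steady-state/gain estimation
  and closed-loop gain adaptation (attention) are out of scope.
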
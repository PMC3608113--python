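# Methods

This note records the models implemented in `misovolterra`, the parameter
choices behind the defaults, the numerical decisions, and what the synthetic
study does and does not demonstrate.

## Volterra identification

The discrete Volterra model of order `P ≤ 3` and memory `M` is linear in its
kernels, so identification is ordinary least squares on the regressor matrix
whose row at time `n` holds the constant 1, the lags `x(n−k)`, and the
unique quadratic and cubic lag products. Two conventions matter:

* **Symmetric-unique parameterization.** The full product enumeration
  `x(n−k1)x(n−k2)` over all `(k1, k2)` is rank deficient by permutation
  symmetry. We estimate one coefficient per sorted lag tuple
  (`k1 ≤ k2 ≤ k3`), giving `1 + M + M(M+1)/2 + M(M+1)(M+2)/6` parameters
  (1540 at `M = 19, P = 3`). The full symmetric tensor is available via
  `VolterraKernels.to_symmetric`, with the unique coefficient spread evenly
  over its permutations.
* **Valid rows.** The model output is defined for `n ≥ M−1` (0-based); all
  sample means (the least-squares objective and the RMSE metric) are taken
  over those rows only. The first `M−1` predicted samples are emitted as
  zeros and excluded from every metric.

**Solver.** Least squares is solved with an SVD pseudo-inverse at a relative
singular-value cutoff of 1e−10, after *column equilibration*: each regressor
column is scaled to unit norm before the solve and the coefficients are
rescaled afterwards. Equilibration is essential at physical amplitudes — a
1.2 MPa excitation makes cubic columns ~1e18 while the constant column is
~16 in norm, and without scaling the relative cutoff would discard the
constant and linear columns instead of genuine rank deficiencies. An
optional ridge penalty (default 0) is applied in the equilibrated space.

Rank deficiency is the *normal* operating regime here, not an edge case: the
regressors of a pure tone span only the lines `{0, f0, 2f0, 3f0}` whatever
`M` is (numerical rank 7 at `M = 19`), and the pseudo-inverse returns the
minimum-norm solution among the least-squares minimizers. This is also the
formal content of the single-input model's limitation: its output lies in
the span of those lines, so subharmonic energy in the echo is an
irreducible residual. The test suite asserts this closure property
(out-of-band output energy < 1e−10 of the total for a tone input).

## The MISO construction

The excitation is decomposed as `x = Σ_i α_i Ψ_i` into `N = 2` periodic
orthogonal sub-inputs with a spectral line at `f0/2`; each sub-input drives
its own Volterra branch and the branch outputs are summed. No cross-branch
lag products are included — the model class is exactly `N` parallel SISO
systems. (A research helper, `cross_term_fit`, fits the full polynomial in
the stacked lag vector for comparison; mixed products do not factor into
parallel branches, so it returns a coefficient vector rather than a model.)

* **rect basis**: sample-exact gating of alternate carrier periods, period
  boundaries at multiples of `fs/f0` samples counted from the record start.
  Requires integer `fs/f0` (15 at the default 60 MHz / 4 MHz); a
  non-integer ratio raises an error instructing resampling rather than
  silently rounding. `α_i = 1`, orthogonality exact.
* **hilbert basis**: `Ψ_i = x + (−1)^(i−1)[x cos(w0 n Ts/2) + x̃ sin(w0 n Ts/2)]`
  with the Hilbert transform computed by the one-sided-spectrum (analytic
  signal) method on the full record, no windowing. `α_i = 1/2` for `N = 2`.
  The modulation phase is referenced to the record start. For records with
  an integer number of carrier periods the analytic signal of a tone is
  exact; for very short or non-periodic records edge effects leak into the
  orthogonality figure — `check_orthogonality` reports the measured values
  over whole subharmonic periods so this can be monitored.
* **N > 2** is accepted by the code paths but experimental for the hilbert
  basis: the modulation formula yields only two distinct components and no
  closed-form coefficients exist, so the `α_i` are obtained by
  least-squares projection. Only `N = 2` is validated; it is the relevant
  case for subharmonic imaging.

**Fit modes.** `joint` (default) solves one least-squares system over the
concatenated branch regressors; `parallel` fits each branch independently
against the shared target. They coincide when the branch regressors are
mutually orthogonal; with the rect basis the memory window straddles gate
boundaries for up to `M−1` samples, so `joint` is the correct least-squares
solution in general and is never worse (asserted in tests). In the joint
solve the per-branch constants are collinear — only their sum is
identifiable — and the pseudo-inverse distributes the total evenly.

**Branch-output orthogonality is conditional.** The two hilbert sub-inputs
of a tone are time-translates of one another (`Ψ2(t) = Ψ1(t + 1/f0)`), so
two branches with kernels `H` produce outputs whose inner product over a
subharmonic period is `Σ_m (−1)^m |a_m|²` over the output lines `m·f0/2` —
zero only when the line energies balance. It is exact for identity branches
(where it reduces to the input orthogonality) and fails for arbitrary
kernels; measured values for fitted models on the simulated echo range from
0.02 to 0.66. The package therefore treats output separability
(`ŷ = Σ ŷ_i`, which holds by construction) as structural, and output
*orthogonality* as a diagnostic to be checked per case with
`branch_output_orthogonality`.

## Microbubble echo simulator

Radial dynamics follow the shell-modified Rayleigh–Plesset equation
(Church's model in Hoff's thin-shell form):

```
ρ (R R̈ + 3/2 Ṙ²) = p0 (r0/R)^{3κ} − p0 − p_i(t)
                    − 4 μ_L Ṙ/R
                    − 12 η dSe r0² Ṙ / R⁴
                    − 12 Gs dSe r0² (1 − r0/R) / R³
```

with equilibrium gas pressure `p0` (surface tension neglected, as usual for
shelled agents whose shell carries the static stress).

| parameter | default | meaning |
|---|---|---|
| `r0` | 1.5 µm | resting radius |
| `dSe` | 1.5 nm | shell thickness |
| `Gs` | 10 MPa | shell shear modulus |
| `η` | 1.49 Pa·s | shell shear viscosity |
| `ρ` | 1000 kg/m³ | water density |
| `μ_L` | 1 mPa·s | water viscosity |
| `p0` | 101.325 kPa | ambient pressure |
| `κ` | 1.07 | polytropic exponent (air core, near-adiabatic at this size) |
| `Nb` | 1 | bubbles in the cloud |

The shell defaults describe a 1.5 µm shelled agent; the ambient constants
are ordinary water at atmospheric pressure and are overridable in the
config. The transmit burst defaults to 18 cycles of a 4 MHz cosine at
1.2 MPa sampled at 60 MHz — a drive near twice the bubble's resonance, in
the pressure range where subharmonics appear while bubble destruction stays
moderate. Destruction is *not* modeled; neither are bubble–bubble
interaction, polydispersity (a cloud of `Nb` bubbles is `Nb` times one
bubble), shell rupture, or nonlinear tissue propagation.

**Linearization.** Perturbing `R = r0(1+ε)` gives the undamped resonance

```
ω0² = (3 κ p0 + 12 Gs dSe / r0) / (ρ r0²),
```

which reduces to the Minnaert frequency for a free bubble and gives
2.239 MHz for the defaults — the shell elasticity contributes roughly a
quarter of the stiffness. The effective damping (liquid plus shell
viscosity) puts the quality factor near 1.4: the onset transient of a
gated burst rings down within a few carrier periods, which is why the
linear-regime spectral test evaluates the steady-state portion of the
record.

**Integration.** `scipy.integrate.solve_ivp` with LSODA (adaptive,
stiff-capable), `rtol = 1e−8`, `atol = 1e−12`, maximum step of one sample
period, drive interpolated with a cubic spline of the sampled burst.
Solver failure raises with the solver diagnostics; a collapse event
(`R < 0.01 r0`) raises naming the collapse time. The scattered pressure
`p_s ∝ ρ(R²R̈ + 2RṘ²)` is evaluated on the burst's own sample grid
(`R̈` from the ODE right-hand side), normalized to unit peak for the
single-bubble echo — no observation distance is modeled because the
identification problem is scale invariant — and multiplied by `Nb`.

Under the default drive the simulated echo is strongly nonlinear: about 26%
of its energy lies in the `f0/2` and `3f0/2` bands. This fraction is what
makes the single-input model saturate near −5 dB RMSE.

## Evaluation protocol

`RMSE = E[(ŷ−y)²]/E[y²]` with sample means over the valid rows, reported as
`10·log10`. The sweep adds white Gaussian noise to the simulated echo at a
target SNR (`var_noise = var(y)/10^(SNR/10)`), fits every method on the
*noisy* record and evaluates RMSE against that same noisy record — an
identification protocol, in which RMSE flattens at the noise floor rather
than diverging. (Evaluating against the clean echo instead is a one-line
switch: pass the clean record as `echo` and add noise externally.) Fits are
in-sample, matching the single-burst setting; ten independent noise
realizations quantify the fluctuations, summarized as mean ± standard
deviation. Noise seeds derive from the experiment seed via
`numpy.random.SeedSequence.spawn`, so identical configurations reproduce
bit-identical tables.

The default memory grid is `{2, 5, 10, 19}`: RMSE varies smoothly with `M`,
so a four-point grid up to 19 captures the monotone trend at a fraction of
the cost of the full 1–19 grid. Spectra are rectangular-window periodograms
of the full valid region with one-sided Parseval normalization
(`Σ power = Σ y(n)²`), with a band-energy helper for reading
sub/ultraharmonic content.

## What the synthetic study shows — and does not

The generator reproduces the physics that matters for the modeling claim:
a realistic shelled-bubble echo whose sub/ultraharmonic content a
single-input Volterra model provably cannot represent. Passing tests
demonstrate (i) the structural spectral limitation, (ii) that both
orthogonal decompositions remove it, and (iii) a 5–10 dB RMSE advantage for
the multi-input models across noise levels at `M = 19`. They do not
demonstrate performance on measured RF data, where transducer bandpass,
attenuation, polydisperse clouds and bubble destruction intervene; nor
numerical agreement with any particular laboratory simulator, since the
ambient constants and shell law variants differ between implementations
(the resonance and the qualitative spectrum are the validated quantities).
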
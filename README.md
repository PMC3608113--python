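# misovolterra

Sub- and ultraharmonic modeling of ultrasound contrast-agent echoes with
multiple-input single-output (MISO) Volterra models.

## The problem

Ultrasound contrast agents are encapsulated gas microbubbles. Driven near
twice their resonance frequency at high acoustic pressure they scatter
energy not only at harmonics of the transmit frequency `f0` but also at the
subharmonic `f0/2` and the ultraharmonics `3f0/2, 5f0/2, ...` — bands that
surrounding tissue does not populate, which makes them ideal for contrast
imaging. Separating those components calls for a nonlinear model of the
echo.

The classical tool, a single-input Volterra model of order `P` and memory `M`,

```
ŷ(n) = h0 + Σ h1(k1) x(n−k1)
          + Σ h2(k1,k2) x(n−k1) x(n−k2)
          + Σ h3(k1,k2,k3) x(n−k1) x(n−k2) x(n−k3),
```

cannot do it: a polynomial in lagged copies of a tone at `f0` only produces
output at `{0, f0, 2f0, 3f0}`. Half-integer multiples are structurally
unreachable.

The fix implemented here is to split the excitation into `N` periodic,
mutually **orthogonal** sub-inputs, each carrying a spectral line at the
subharmonic `f0/N`, and to drive one Volterra branch per sub-input:

```
x(n) = Σ_i α_i Ψ_i(n),      ŷ(n) = Σ_i ŷ_i(n).
```

Two bases are provided for `N = 2`:

* **rect** (“MISO1”) — gate the excitation with complementary rectangular
  combs: component 1 keeps the odd carrier periods, component 2 the even
  ones (`α_i = 1`). Supports are disjoint, so orthogonality is exact.
* **hilbert** (“MISO2”) — modulate the analytic signal:
  `Ψ_i = x + (−1)^(i−1) [x cos(w0 n Ts/2) + x̃ sin(w0 n Ts/2)]` with `x̃`
  the Hilbert transform and `α_i = 1/2`. For a pure cosine this is
  `A cos(w0 n Ts) ± A cos(w0 n Ts/2)`: the carrier plus an antiphase
  subharmonic line.

Kernels are identified by linear least squares (SVD pseudo-inverse with
column equilibration; optional ridge), and models are compared by the
relative mean square error `RMSE = E[(ŷ−y)²] / E[y²]`, reported in dB.

The package also ships a shelled-microbubble echo simulator — the
shell-modified Rayleigh–Plesset (Church/Hoff) equation integrated with a
stiff-capable adaptive solver — so the whole study is reproducible without
laboratory data.

## Worked example

```python
import numpy as np
from misovolterra import (BubbleParams, BurstSpec, ExperimentConfig,
                          make_burst, simulate_echo, resonance_frequency,
                          run_sweep, summarize_sweep)

params = BubbleParams()          # 1.5 um radius, 1.5 nm shell, Gs = 10 MPa
print(f"resonance: {resonance_frequency(params)/1e6:.3f} MHz")

burst = make_burst(BurstSpec())  # 4 MHz, 1.2 MPa, 18 cycles at 60 MHz
echo = simulate_echo(params, burst)

cfg = ExperimentConfig(memories=(19,), seed=1)
table = run_sweep(cfg, burst=burst, echo=echo)
s = summarize_sweep(table).set_index(["method", "snr_db"])["mean"]
for snr in cfg.snr_levels:
    gap = s[("siso", snr)] - max(s[("miso1", snr)], s[("miso2", snr)])
    print(f"SNR {snr:>4} dB:  siso {s[('siso', snr)]:6.2f}  "
          f"miso1 {s[('miso1', snr)]:6.2f}  miso2 {s[('miso2', snr)]:6.2f}  "
          f"gap {gap:5.2f} dB")
```

prints

```
resonance: 2.239 MHz
SNR  inf dB:  siso  -5.41  miso1 -35.15  miso2 -15.85  gap 10.44 dB
SNR 20.0 dB:  siso  -5.31  miso1 -20.30  miso2 -14.63  gap  9.32 dB
SNR 15.0 dB:  siso  -5.11  miso1 -15.65  miso2 -12.69  gap  7.59 dB
SNR 10.0 dB:  siso  -4.48  miso1 -10.98  miso2  -9.70  gap  5.22 dB
```

The simulated echo carries about a quarter of its energy in the
sub/ultraharmonic bands; the single-input model cannot represent that energy
and saturates near −5 dB, while both multi-input models track it, leaving a
gap of 5–10 dB depending on the noise level.

The same study is available from the shell:

```
misovolterra simulate --out echo.npz --burst-out burst.npz
misovolterra decompose --basis hilbert --f0 4e6 --input burst.npz --outdir basis/
misovolterra fit --mode miso2 --memory 19 --f0 4e6 \
    --input burst.npz --output echo.npz --kernels model.npz
misovolterra sweep --out results.csv --summary summary.csv --plot rmse.png
```

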
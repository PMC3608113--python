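"""Periodic orthogonal decompositions of the excitation signal.

A Volterra model driven by a tone at ``f0`` can only produce integer
harmonics of ``f0``.  To let it reach the subharmonic ``f0/N`` the single
excitation ``x(n)`` is split into ``N`` sub-inputs

    x(n) = sum_i alpha_i Psi_i(n),

where the ``Psi_i`` are periodic with period ``N/f0`` (hence carry a
spectral line at ``f0/N``) and mutually orthogonal — the orthogonality is
what makes the multi-input model well posed and its branch outputs
separable.  Two constructions are provided:

* ``rect`` — gate the excitation with complementary rectangular combs:
  component ``i`` keeps every ``N``-th carrier period starting at period
  ``i-1``.  The supports are disjoint, so orthogonality and reconstruction
  (``alpha_i = 1``) are exact at machine precision.  Requires an integer
  number of samples per carrier period.
* ``hilbert`` — modulate the analytic signal:

      Psi_i(n) = x(n) + (-1)^(i-1) [ x(n) cos(w0 (N-1)/N n Ts)
                                     + xt(n) sin(w0 (N-1)/N n Ts) ],

  with ``xt`` the Hilbert transform of ``x`` and ``w0 = 2 pi f0``.  For a
  pure cosine ``A cos(w0 n Ts)`` and ``N = 2`` this collapses to
  ``A cos(w0 n Ts) +/- A cos(w0 n Ts / 2)``: the carrier plus an antiphase
  subharmonic line, and ``alpha_i = 1/2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .signals import Signal

__all__ = [
    "BasisSet",
    "analytic_signal",
    "decompose",
    "decompose_rect",
    "decompose_hilbert",
    "check_orthogonality",
]


@dataclass
class BasisSet:
    """Decomposition of an excitation into periodic orthogonal components.

    ``components`` holds the basis functions ``Psi_i``; the sub-inputs that
    actually drive the model branches are ``alpha_i * Psi_i`` (see
    :meth:`sub_inputs`), which sum back to the original excitation.
    """

    components: list[Signal]
    alphas: np.ndarray
    f0: float
    N: int
    kind: str  # "rect" or "hilbert"

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=np.float64)
        if len(self.components) != self.N or self.alphas.shape != (self.N,):
            raise ValueError("need N components and N coefficients")

    def sub_inputs(self) -> list[Signal]:
        """The branch inputs ``x_i = alpha_i Psi_i`` with ``sum_i x_i = x``."""
        return [
            c.copy_with(a * c.samples) for a, c in zip(self.alphas, self.components)
        ]

    def reconstruct(self) -> Signal:
        """``sum_i alpha_i Psi_i`` on the common grid."""
        total = sum(a * c.samples for a, c in zip(self.alphas, self.components))
        return self.components[0].copy_with(total)

    @property
    def samples_per_subperiod(self) -> float:
        """Samples in one subharmonic period ``N / f0``."""
        return self.N * self.components[0].fs / self.f0


def analytic_signal(x: Signal) -> tuple[np.ndarray, np.ndarray]:
    """Real part and Hilbert transform of *x* (one-sided-spectrum method).

    Computed on the full record without windowing; edge effects are small
    for multi-cycle bursts but grow for records of a few cycles.
    """
    z = scipy.signal.hilbert(x.samples)
    return z.real, z.imag


def _samples_per_period(x: Signal, f0: float) -> int:
    spp = x.fs / f0
    if abs(spp - round(spp)) > 1e-9 * spp:
        raise ValueError(
            f"fs/f0 = {spp:g} is not an integer number of samples per carrier "
            "period; resample the record (no silent rounding is performed)"
        )
    spp = int(round(spp))
    if spp < 2:
        raise ValueError("need at least 2 samples per carrier period")
    return spp


def decompose_rect(x: Signal, f0: float, N: int = 2) -> BasisSet:
    """Rectangular-comb decomposition: disjoint gating of carrier periods.

    Component ``i`` (1-based) equals ``x`` on carrier periods
    ``p = i-1, i-1+N, i-1+2N, ...`` (period ``p`` spanning samples
    ``[p*fs/f0, (p+1)*fs/f0)``, counted from the record start) and zero
    elsewhere.  The components partition the samples, so
    ``sum_i Psi_i = x`` exactly and all ``alpha_i = 1``.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    spp = _samples_per_period(x, f0)
    if len(x) < N * spp:
        raise ValueError(
            f"record of {len(x)} samples is shorter than one subharmonic "
            f"period ({N * spp} samples)"
        )
    period_of = np.arange(len(x)) // spp
    comps = []
    for i in range(N):
        mask = (period_of % N) == i
        comps.append(x.copy_with(np.where(mask, x.samples, 0.0)))
    return BasisSet(comps, np.ones(N), f0, N, "rect")


def decompose_hilbert(x: Signal, f0: float, N: int = 2) -> BasisSet:
    """Analytic-signal decomposition with an explicit subharmonic line.

    For ``N = 2`` the coefficients are ``alpha_i = 1/2`` and reconstruction
    is exact up to Hilbert-transform edge effects.  For ``N > 2`` the same
    modulation formula is applied but only two distinct components exist and
    no exact coefficients are known; the ``alpha_i`` are then obtained by
    least-squares projection of ``x`` onto the components (experimental).
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if len(x) < 2:
        raise ValueError("record too short")
    xr, xt = analytic_signal(x)
    # phase referenced to the record start (n = 0)
    phase = 2 * np.pi * f0 * (N - 1) / N * np.arange(len(x)) / x.fs
    mod = xr * np.cos(phase) + xt * np.sin(phase)
    comps = [
        x.copy_with(x.samples + (-1) ** i * mod) for i in range(N)
    ]
    if N == 2:
        alphas = np.full(N, 0.5)
    else:
        A = np.column_stack([c.samples for c in comps])
        alphas, *_ = np.linalg.lstsq(A, x.samples, rcond=None)
    return BasisSet(comps, alphas, f0, N, "hilbert")


def decompose(x: Signal, kind: str, f0: float, N: int = 2) -> BasisSet:
    """Dispatch on ``kind`` ('rect' or 'hilbert')."""
    if kind == "rect":
        return decompose_rect(x, f0, N)
    if kind == "hilbert":
        return decompose_hilbert(x, f0, N)
    raise ValueError(f"unknown basis kind {kind!r}; expected 'rect' or 'hilbert'")


def check_orthogonality(basis: BasisSet, tol: float = 1e-6) -> dict:
    """Normalised pairwise inner products of the sub-inputs.

    Inner products are evaluated over the largest whole number of
    subharmonic periods in the record (orthogonality of the modulated basis
    holds per subharmonic period; a fractional tail biases the estimate).

    Returns a dict with ``max`` (worst normalised ``|<x_i, x_j>|``),
    ``pairs`` mapping ``(i, j)`` to per-pair values, ``degenerate`` (indices
    of zero-norm components, excluded from normalisation) and ``passed``.
    """
    subs = basis.sub_inputs()
    spsub = basis.samples_per_subperiod
    n_keep = len(subs[0])
    if abs(spsub - round(spsub)) < 1e-9:
        whole = int(len(subs[0]) // round(spsub) * round(spsub))
        if whole >= 1:
            n_keep = whole
    arrs = [s.samples[:n_keep] for s in subs]
    norms = [float(np.linalg.norm(a)) for a in arrs]
    degenerate = [i for i, nm in enumerate(norms) if nm == 0.0]
    pairs: dict[tuple[int, int], float] = {}
    for i in range(basis.N):
        for j in range(i + 1, basis.N):
            if i in degenerate or j in degenerate:
                continue
            pairs[(i, j)] = float(abs(arrs[i] @ arrs[j]) / (norms[i] * norms[j]))
    worst = max(pairs.values(), default=0.0)
    return {
        "max": worst,
        "pairs": pairs,
        "degenerate": degenerate,
        "tol": tol,
        "passed": worst <= tol,
        "n_samples_used": n_keep,
    }
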
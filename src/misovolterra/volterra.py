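"""Discrete Volterra model: regressors, least-squares identification, prediction.

The single-input single-output (SISO) Volterra model of order ``P <= 3`` and
memory ``M`` writes the output as a polynomial in lagged inputs::

    yhat(n) = h0 + sum_k1 h1(k1) x(n-k1)
                 + sum_{k1<=k2} h2(k1,k2) x(n-k1) x(n-k2)
                 + sum_{k1<=k2<=k3} h3(k1,k2,k3) x(n-k1) x(n-k2) x(n-k3)

Kernels are stored in symmetric-unique form (sorted lag tuples): the full
product enumeration is rank deficient because ``x(n-k1)x(n-k2)`` repeats
under index permutation, so only one column per unique product is estimated
and the full symmetric tensor is reconstructed on demand.  Identification is
linear least squares over the valid rows ``n in [M-1, L-1]`` (0-based),
solved with a singular-value pseudo-inverse so that rank-deficient regressor
matrices (e.g. pure-tone inputs, whose regressors span only a handful of
spectral lines) get the minimum-norm solution; an optional ridge penalty is
available as an alternative regulariser.

Driven by a single tone at ``f0`` this model class can only produce output
at ``{0, f0, 2 f0, 3 f0}`` — products of sinusoids at ``f0`` never create
half-integer multiples — which is why the MISO construction in
:mod:`misovolterra.miso` exists.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from .signals import Signal

__all__ = [
    "VolterraKernels",
    "kernel_index",
    "n_parameters",
    "build_regressors",
    "fit_siso",
    "predict",
    "save_kernels",
    "load_kernels",
    "export_kernels_text",
]

#: relative singular-value cutoff of the pseudo-inverse solver
SV_CUTOFF = 1e-10


def kernel_index(M: int, P: int) -> list[tuple[int, ...]]:
    """Column order of the regressor matrix: sorted lag tuples per order.

    ``()`` is the constant term, ``(k1,)`` the linear lags in ascending
    order, then unique quadratic pairs ``k1 <= k2`` and cubic triples
    ``k1 <= k2 <= k3`` in lexicographic order.
    """
    if not (1 <= P <= 3):
        raise ValueError(f"order P must be 1, 2 or 3, got {P}")
    if M < 1:
        raise ValueError(f"memory M must be >= 1, got {M}")
    cols: list[tuple[int, ...]] = [()]
    for p in range(1, P + 1):
        cols.extend(itertools.combinations_with_replacement(range(M), p))
    return cols


def n_parameters(M: int, P: int) -> int:
    """Number of kernel parameters: ``1 + M + M(M+1)/2 + M(M+1)(M+2)/6`` at P=3."""
    return len(kernel_index(M, P))


@dataclass
class VolterraKernels:
    """Estimated Volterra kernels in symmetric-unique (sorted-lag) form.

    ``h1`` has shape ``(M,)``; ``h2`` and ``h3`` are flat arrays over the
    unique lag tuples in the :func:`kernel_index` order.  ``h2``/``h3`` may
    be ``None`` when ``P < 3``.
    """

    M: int
    P: int
    h0: float
    h1: np.ndarray
    h2: np.ndarray | None = None
    h3: np.ndarray | None = None
    residual_db: float | None = None  # relative residual of the fit, in dB
    rank: int | None = None  # numerical rank of the regressor matrix

    def __post_init__(self) -> None:
        counts = _order_counts(self.M, self.P)
        self.h1 = np.asarray(self.h1, dtype=np.float64)
        if self.h1.shape != (self.M,):
            raise ValueError(f"h1 must have shape ({self.M},)")
        for name, arr, n in (("h2", self.h2, counts.get(2)), ("h3", self.h3, counts.get(3))):
            if n is None:
                if arr is not None:
                    raise ValueError(f"{name} given but P = {self.P}")
            else:
                a = np.asarray(arr, dtype=np.float64)
                if a.shape != (n,):
                    raise ValueError(f"{name} must have {n} entries for M = {self.M}")
                setattr(self, name, a)

    @property
    def n_params(self) -> int:
        return n_parameters(self.M, self.P)

    def pack(self) -> np.ndarray:
        """Flatten to the regressor column order."""
        parts = [np.atleast_1d(self.h0), self.h1]
        if self.h2 is not None:
            parts.append(self.h2)
        if self.h3 is not None:
            parts.append(self.h3)
        return np.concatenate(parts)

    @classmethod
    def unpack(cls, h: np.ndarray, M: int, P: int, **kw) -> "VolterraKernels":
        """Inverse of :meth:`pack`."""
        h = np.asarray(h, dtype=np.float64)
        if h.size != n_parameters(M, P):
            raise ValueError(
                f"expected {n_parameters(M, P)} parameters for M={M}, P={P}, got {h.size}"
            )
        counts = _order_counts(M, P)
        i = 1 + M
        h2 = h3 = None
        if P >= 2:
            h2 = h[i : i + counts[2]]
            i += counts[2]
        if P >= 3:
            h3 = h[i : i + counts[3]]
        return cls(M=M, P=P, h0=float(h[0]), h1=h[1 : 1 + M], h2=h2, h3=h3, **kw)

    def to_symmetric(self, order: int) -> np.ndarray:
        """Full symmetric kernel tensor of the given order.

        The unique coefficient of a lag tuple is spread evenly over its
        distinct permutations, so the symmetric tensor reproduces the same
        input-output map under the full (permutation-redundant) summation.
        """
        if order == 1:
            return self.h1.copy()
        flat = {2: self.h2, 3: self.h3}.get(order)
        if flat is None:
            raise ValueError(f"order {order} not present (P = {self.P})")
        out = np.zeros((self.M,) * order)
        for coeff, lags in zip(flat, itertools.combinations_with_replacement(range(self.M), order)):
            perms = set(itertools.permutations(lags))
            for perm in perms:
                out[perm] = coeff / len(perms)
        return out


def _order_counts(M: int, P: int) -> dict[int, int]:
    counts = {1: M}
    if P >= 2:
        counts[2] = M * (M + 1) // 2
    if P >= 3:
        counts[3] = M * (M + 1) * (M + 2) // 6
    return counts


def build_regressors(x: Signal | np.ndarray, M: int, P: int) -> np.ndarray:
    """Regressor matrix over the valid rows ``n in [M-1, L-1]``.

    Row ``n`` holds ``1``, the lags ``x(n-k)``, and the unique quadratic and
    cubic lag products in :func:`kernel_index` order; shape is
    ``(L - M + 1, n_parameters(M, P))``.

    Raises
    ------
    ValueError
        If the signal is shorter than the memory ``M``.
    """
    xs = x.samples if isinstance(x, Signal) else np.asarray(x, dtype=np.float64)
    L = xs.size
    if L < M:
        raise ValueError(f"signal length {L} is shorter than memory M = {M}; need >= {M}")
    rows = L - M + 1
    # lag matrix: lags[r, k] = x(n - k) with n = M - 1 + r
    lags = np.empty((rows, M))
    for k in range(M):
        lags[:, k] = xs[M - 1 - k : L - k]
    cols = kernel_index(M, P)
    X = np.empty((rows, len(cols)))
    X[:, 0] = 1.0
    for j, tup in enumerate(cols[1:], start=1):
        col = lags[:, tup[0]].copy()
        for k in tup[1:]:
            col *= lags[:, k]
        X[:, j] = col
    return X


def _lstsq(X: np.ndarray, y: np.ndarray, ridge: float = 0.0):
    """Least squares with SVD cutoff, or ridge when ``ridge > 0``.

    Columns are equilibrated to unit norm before solving: lag-product
    columns of different polynomial orders differ by many orders of
    magnitude for physical pressure amplitudes, and without scaling the
    relative singular-value cutoff would discard the small-scale (constant,
    linear) columns rather than genuine rank deficiencies.
    """
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0.0] = 1.0
    Xs = X / scale
    if ridge > 0:
        A = Xs.T @ Xs + ridge * np.eye(X.shape[1])
        h = scipy.linalg.solve(A, Xs.T @ y, assume_a="pos")
        rank = X.shape[1]
    else:
        h, _, rank, _ = scipy.linalg.lstsq(Xs, y, cond=SV_CUTOFF, lapack_driver="gelsd")
    return h / scale, rank


def fit_siso(x: Signal, y: Signal, M: int, P: int = 3, *, ridge: float = 0.0) -> VolterraKernels:
    """Identify Volterra kernels by least squares on an input/output record.

    Minimises the mean squared error between ``y(n)`` and the model output
    over the valid rows ``n >= M-1``.  Rank-deficient regressor matrices
    (common: a pure-tone input spans only a few spectral lines regardless of
    ``M``) are handled by the pseudo-inverse, which returns the minimum-norm
    solution among the least-squares minimisers.

    Parameters
    ----------
    x, y : Signal
        Input and output records; must share length and sampling grid.
    M, P : int
        Memory (lags per kernel dimension) and model order.
    ridge : float, optional
        Tikhonov penalty added to the normal equations (default 0).
    """
    if not x.same_grid(y):
        raise ValueError("x and y must share length, fs and origin")
    X = build_regressors(x, M, P)
    yv = y.samples[M - 1 :]
    h, rank = _lstsq(X, yv, ridge)
    resid = yv - X @ h
    energy = float(np.mean(yv**2))
    if energy > 0:
        ratio = float(np.mean(resid**2) / energy)
        residual_db = 10 * np.log10(ratio) if ratio > 0 else -np.inf
    else:
        residual_db = np.nan
    return VolterraKernels.unpack(h, M, P, residual_db=residual_db, rank=int(rank))


def predict(h: VolterraKernels, x: Signal) -> Signal:
    """Model output for input *x*; samples before ``n = M-1`` are zero.

    The first ``M-1`` samples have no complete lag vector and are emitted as
    zeros; downstream error metrics restrict themselves to ``n >= M-1``.
    """
    X = build_regressors(x, h.M, h.P)
    yhat = np.zeros(len(x))
    yhat[h.M - 1 :] = X @ h.pack()
    return Signal(yhat, x.fs, x.t0)


def save_kernels(h: VolterraKernels, path: str | Path) -> None:
    """Archive kernels (``.npz``): P, M, column order and kernel arrays."""
    data = {"M": h.M, "P": h.P, "h0": h.h0, "h1": h.h1}
    if h.h2 is not None:
        data["h2"] = h.h2
    if h.h3 is not None:
        data["h3"] = h.h3
    np.savez(Path(path), **data)


def load_kernels(path: str | Path) -> VolterraKernels:
    with np.load(Path(path)) as d:
        return VolterraKernels(
            M=int(d["M"]),
            P=int(d["P"]),
            h0=float(d["h0"]),
            h1=d["h1"],
            h2=d["h2"] if "h2" in d else None,
            h3=d["h3"] if "h3" in d else None,
        )


def export_kernels_text(h: VolterraKernels, path: str | Path) -> None:
    """Plain-text export: one line per kernel entry, ``order lags... value``."""
    with open(path, "w") as f:
        f.write(f"# Volterra kernels, P={h.P} M={h.M}, symmetric-unique form\n")
        f.write(f"0\t{h.h0:.17g}\n")
        for tup, val in zip(kernel_index(h.M, h.P)[1:], h.pack()[1:]):
            lags = ",".join(map(str, tup))
            f.write(f"{len(tup)}\t{lags}\t{val:.17g}\n")
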
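"""Multiple-input single-output Volterra model on an orthogonal decomposition.

The excitation is split into ``N`` periodic orthogonal sub-inputs (see
:mod:`misovolterra.basis`); each sub-input drives its own SISO Volterra
branch and the branch outputs are summed::

    yhat(n) = sum_i yhat_i(n),      x(n) = sum_i x_i(n).

Because each sub-input carries a spectral line at ``f0/N``, the branch
polynomials generate every half-integer multiple of ``f0`` (for ``N = 2``):
subharmonic and ultraharmonics become reachable while the parallel-branch
structure — no cross-branch lag products — keeps the branch outputs
orthogonal whenever the inputs are.

Two fit modes are provided.  ``joint`` (default) solves one least-squares
problem over the concatenated branch regressors; ``parallel`` fits each
branch independently against the shared target.  They coincide exactly when
the branch regressors are mutually orthogonal; with the rect basis the
memory window straddles gate boundaries for up to ``M - 1`` samples, so the
joint solve is the safer default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .basis import BasisSet, decompose
from .signals import Signal
from .volterra import (
    VolterraKernels,
    _lstsq,
    build_regressors,
    n_parameters,
    predict,
)

__all__ = [
    "MISOModel",
    "fit_miso",
    "predict_miso",
    "branch_output_orthogonality",
    "cross_term_fit",
    "save_miso",
    "load_miso",
]


@dataclass
class MISOModel:
    """N parallel SISO Volterra branches bound to a basis decomposition."""

    basis_kind: str
    f0: float
    N: int
    M: int
    P: int
    branches: list[VolterraKernels]
    fit_mode: str = "joint"
    basis: BasisSet | None = None  # decomposition of the training excitation
    residual_db: float | None = None
    rank: int | None = None

    def __post_init__(self) -> None:
        if len(self.branches) != self.N:
            raise ValueError(f"need {self.N} branches, got {len(self.branches)}")
        for b in self.branches:
            if b.M != self.M or b.P != self.P:
                raise ValueError("all branches must share memory M and order P")


def fit_miso(
    x: Signal,
    y: Signal,
    basis_kind: str,
    f0: float,
    N: int = 2,
    M: int = 10,
    P: int = 3,
    fit_mode: str = "joint",
    *,
    ridge: float = 0.0,
) -> MISOModel:
    """Decompose *x* and identify all branch kernels against *y*.

    Parameters
    ----------
    basis_kind : str
        ``'rect'`` (gated carrier periods) or ``'hilbert'`` (analytic-signal
        modulation).
    fit_mode : str
        ``'joint'`` solves one least-squares system over the concatenated
        branch regressor columns; ``'parallel'`` fits each branch on its own
        against *y*.  With ``N = 1`` both reduce to the plain SISO fit.

    Notes
    -----
    The per-branch constant terms are collinear in the joint solve (only
    their sum is identifiable); the pseudo-inverse distributes the total
    evenly across branches.  Cross-branch lag products are deliberately
    absent from the model class — the parallel structure is what guarantees
    orthogonal branch outputs; see :func:`cross_term_fit` for the research
    variant that includes them.
    """
    if not x.same_grid(y):
        raise ValueError("x and y must share length, fs and origin")
    if fit_mode not in ("joint", "parallel"):
        raise ValueError("fit_mode must be 'joint' or 'parallel'")
    if N == 1:
        # degenerate decomposition: the single sub-input is x itself
        from .volterra import fit_siso

        k = fit_siso(x, y, M, P, ridge=ridge)
        return MISOModel(basis_kind, f0, 1, M, P, [k], fit_mode,
                         basis=None, residual_db=k.residual_db, rank=k.rank)

    basis = decompose(x, basis_kind, f0, N)
    subs = basis.sub_inputs()
    yv = y.samples[M - 1 :]
    energy = float(np.mean(yv**2))

    n_par = n_parameters(M, P)
    if fit_mode == "parallel":
        branches = []
        for s in subs:
            X = build_regressors(s, M, P)
            h, rank = _lstsq(X, yv, ridge)
            branches.append(VolterraKernels.unpack(h, M, P, rank=int(rank)))
        rank_total = None
    else:
        X = np.hstack([build_regressors(s, M, P) for s in subs])
        h, rank_total = _lstsq(X, yv, ridge)
        branches = [
            VolterraKernels.unpack(h[i * n_par : (i + 1) * n_par], M, P)
            for i in range(N)
        ]

    model = MISOModel(basis_kind, f0, N, M, P, branches, fit_mode, basis=basis,
                      rank=int(rank_total) if rank_total is not None else None)
    yhat, _ = predict_miso(model, x)
    resid = yv - yhat.samples[M - 1 :]
    if energy > 0:
        ratio = float(np.mean(resid**2) / energy)
        model.residual_db = 10 * np.log10(ratio) if ratio > 0 else -np.inf
    else:
        model.residual_db = np.nan
    for b in model.branches:
        b.residual_db = model.residual_db
    return model


def cross_term_fit(x: Signal, y: Signal, basis_kind: str, f0: float, N: int,
                   M: int, P: int, *, ridge: float = 0.0):
    """Research fit with cross-branch lag products.

    Builds a full symmetric-unique polynomial of order ``P`` in the stacked
    lag vector of all ``N`` sub-inputs (``N*M`` variables), so products such
    as ``x1(n-k1) x2(n-k2)`` appear.  Returns the coefficient vector, the
    column index (tuples over the stacked variables) and the residual in dB.
    The result is not a :class:`MISOModel` — mixed products do not factor
    into parallel branches.
    """
    basis = decompose(x, basis_kind, f0, N)
    subs = basis.sub_inputs()
    yv = y.samples[M - 1 :]
    h, cols, rank = _fit_cross_terms(subs, yv, M, P, ridge, return_cols=True)
    lagmat = _stacked_lags(subs, M)
    yhat = _eval_cols(lagmat, cols, h)
    ratio = float(np.mean((yv - yhat) ** 2) / np.mean(yv**2))
    resid_db = 10 * np.log10(ratio) if ratio > 0 else -np.inf
    return h, cols, resid_db


def _stacked_lags(subs: list[Signal], M: int) -> np.ndarray:
    L = len(subs[0])
    rows = L - M + 1
    lagmat = np.empty((rows, len(subs) * M))
    for i, s in enumerate(subs):
        for k in range(M):
            lagmat[:, i * M + k] = s.samples[M - 1 - k : L - k]
    return lagmat


def _eval_cols(lagmat, cols, h):
    out = np.full(lagmat.shape[0], h[0])
    for j, tup in enumerate(cols[1:], start=1):
        col = lagmat[:, tup[0]].copy()
        for k in tup[1:]:
            col *= lagmat[:, k]
        out += h[j] * col
    return out


def _fit_cross_terms(subs, yv, M, P, ridge, return_cols=False):
    lagmat = _stacked_lags(subs, M)
    nv = lagmat.shape[1]
    cols: list[tuple[int, ...]] = [()]
    for p in range(1, P + 1):
        cols.extend(itertools.combinations_with_replacement(range(nv), p))
    X = np.empty((lagmat.shape[0], len(cols)))
    X[:, 0] = 1.0
    for j, tup in enumerate(cols[1:], start=1):
        col = lagmat[:, tup[0]].copy()
        for k in tup[1:]:
            col *= lagmat[:, k]
        X[:, j] = col
    h, rank = _lstsq(X, yv, ridge)
    if return_cols:
        return h, cols, rank
    return h, rank


def predict_miso(model: MISOModel, x: Signal) -> tuple[Signal, list[Signal]]:
    """Combined prediction and the individual branch outputs.

    *x* is decomposed with the model's basis (recomputed for the given
    record) and each branch predicts on its own sub-input; the first
    ``M - 1`` samples of every output are zero (incomplete lag window).
    """
    if model.N == 1:
        yhat = predict(model.branches[0], x)
        return yhat, [yhat]
    basis = decompose(x, model.basis_kind, model.f0, model.N)
    outs = [predict(b, s) for b, s in zip(model.branches, basis.sub_inputs())]
    total = np.sum([o.samples for o in outs], axis=0)
    return Signal(total, x.fs, x.t0), outs


def branch_output_orthogonality(model: MISOModel, x: Signal) -> dict:
    """Normalised pairwise inner products of the branch outputs on *x*.

    The parallel-branch structure makes the combined output separable into
    per-branch components; whether those components are themselves
    orthogonal depends on the branch kernels.  It is exact when each branch
    acts as the identity (the sub-inputs are orthogonal by construction) and
    approximately holds when the branch responses weight the carrier and
    subharmonic lines equally, but it fails for arbitrary kernels — the two
    hilbert-basis sub-inputs of a tone are time-translates of each other, so
    equal-kernel outputs correlate through their common spectral lines.
    This diagnostic reports the measured values so the assumption can be
    checked case by case.

    Inner products are evaluated over whole subharmonic periods starting at
    the first sample where every branch output is defined (``n = M - 1``
    rounded up to a period boundary).

    Returns a dict with ``max``, per-pair values in ``pairs``, and the
    sample range used.
    """
    _, outs = predict_miso(model, x)
    spsub = model.N * x.fs / model.f0
    start = model.M - 1
    if abs(spsub - round(spsub)) < 1e-9:
        spsub_i = int(round(spsub))
        start = int(np.ceil(start / spsub_i) * spsub_i)
        stop = start + (len(x) - start) // spsub_i * spsub_i
    else:
        stop = len(x)
    arrs = [o.samples[start:stop] for o in outs]
    norms = [float(np.linalg.norm(a)) for a in arrs]
    pairs: dict[tuple[int, int], float] = {}
    for i in range(model.N):
        for j in range(i + 1, model.N):
            if norms[i] == 0.0 or norms[j] == 0.0:
                continue
            pairs[(i, j)] = float(abs(arrs[i] @ arrs[j]) / (norms[i] * norms[j]))
    return {"max": max(pairs.values(), default=0.0), "pairs": pairs,
            "range": (start, stop)}


def save_miso(model: MISOModel, path: str | Path) -> None:
    """Archive (``.npz``): basis kind, f0, N, M, P and all branch kernels."""
    data = {
        "basis_kind": model.basis_kind,
        "f0": model.f0,
        "N": model.N,
        "M": model.M,
        "P": model.P,
        "fit_mode": model.fit_mode,
    }
    for i, b in enumerate(model.branches):
        data[f"branch{i}_h"] = b.pack()
    np.savez(Path(path), **data)


def load_miso(path: str | Path) -> MISOModel:
    with np.load(Path(path)) as d:
        N, M, P = int(d["N"]), int(d["M"]), int(d["P"])
        branches = [
            VolterraKernels.unpack(d[f"branch{i}_h"], M, P) for i in range(N)
        ]
        return MISOModel(str(d["basis_kind"]), float(d["f0"]), N, M, P,
                         branches, str(d["fit_mode"]))
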
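"""Uniformly sampled real-valued signals and their file formats.

The :class:`Signal` container carries the sample array together with the
sampling frequency ``fs`` and a time origin ``t0``.  Two on-disk formats are
supported by every tool in the package:

* delimited text with two columns (time in seconds, value), from which ``fs``
  is inferred on read;
* a NumPy ``.npz`` archive with keys ``samples``, ``fs`` and ``t0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Signal", "read_signal", "write_signal"]


@dataclass
class Signal:
    """A real-valued, uniformly sampled time series.

    Parameters
    ----------
    samples : ndarray
        Sample values; coerced to a contiguous float64 array.
    fs : float
        Sampling frequency in Hz, strictly positive.
    t0 : float, optional
        Time of the first sample in seconds (default 0).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.ascontiguousarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not (self.fs > 0):
            raise ValueError(f"fs must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def ts(self) -> float:
        """Sampling period in seconds."""
        return 1.0 / self.fs

    @property
    def t(self) -> np.ndarray:
        """Time axis in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        """Record duration ``len / fs`` in seconds."""
        return self.samples.size / self.fs

    def copy_with(self, samples: np.ndarray) -> "Signal":
        """New signal on the same time grid with different samples."""
        if np.asarray(samples).size != self.samples.size:
            raise ValueError("replacement samples must have the same length")
        return Signal(np.asarray(samples, dtype=np.float64), self.fs, self.t0)

    def same_grid(self, other: "Signal", rtol: float = 1e-9) -> bool:
        """True if *other* shares length, fs and origin with this signal."""
        return (
            len(other) == len(self)
            and np.isclose(other.fs, self.fs, rtol=rtol)
            and np.isclose(other.t0, self.t0, rtol=rtol, atol=1e-15)
        )


def write_signal(sig: Signal, path: str | Path) -> None:
    """Write *sig* to *path*; format chosen by extension.

    ``.npz`` gives the binary archive, anything else the two-column
    (time, value) text format.
    """
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, samples=sig.samples, fs=sig.fs, t0=sig.t0)
    else:
        np.savetxt(
            path,
            np.column_stack([sig.t, sig.samples]),
            header="time_s\tvalue",
            delimiter="\t",
        )


def read_signal(path: str | Path) -> Signal:
    """Read a signal written by :func:`write_signal`.

    For the text format the sampling frequency is inferred from the time
    column, which must be uniform.
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as data:
            return Signal(data["samples"], float(data["fs"]), float(data["t0"]))
    arr = np.loadtxt(path)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (time, value)")
    t, v = arr[:, 0], arr[:, 1]
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples to infer fs")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError(f"{path}: time column is not uniformly sampled")
    return Signal(v, 1.0 / dt.mean(), t0=float(t[0]))
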
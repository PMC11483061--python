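"""Pressure-tensor time series: container and whitespace-table I/O."""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = ["PressureSeries", "load_pressure_series", "write_pressure_series"]

_SPACING_RTOL = 1e-5


@dataclass
class PressureSeries:
    """Uniformly sampled 3×3 pressure-tensor samples.

    Attributes
    ----------
    times : ndarray, shape (n,)
        Sample times in ns, uniformly spaced.
    tensors : ndarray, shape (n, 9)
        The nine components Pαβ in bar, row-major (xx, xy, xz, yx, ...).
    volume : float
        System volume, Å³.
    temperature : float
        Temperature, K.
    """

    times: np.ndarray
    tensors: np.ndarray
    volume: float
    temperature: float
    ground_truth: "object | None" = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.ndim != 2 or self.tensors.shape[1] != 9:
            raise ValueError("tensors must have shape (n_samples, 9)")
        if self.times.shape[0] != self.tensors.shape[0]:
            raise ValueError("times and tensors length mismatch")
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if len(self.times) > 1:
            dts = np.diff(self.times)
            if np.any(dts <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dts, dts[0], rtol=_SPACING_RTOL, atol=0):
                raise ValueError("sample spacing is not uniform")

    @property
    def n_samples(self) -> int:
        return self.tensors.shape[0]

    @property
    def dt(self) -> float:
        """Sample spacing, ns."""
        if self.n_samples < 2:
            raise ValueError("need >= 2 samples for a spacing")
        return float(self.times[1] - self.times[0])

    def time_slice(self, mask: np.ndarray) -> "PressureSeries":
        return replace(self, times=self.times[mask], tensors=self.tensors[mask])


def load_pressure_series(path, volume: float,
                         temperature: float) -> PressureSeries:
    """Read a whitespace table of (time, 9 tensor components) rows.

    Times in the file are in ns; tensor components in bar.
    """
    try:
        data = np.loadtxt(path, ndmin=2)
    except Exception as exc:
        raise ValueError(f"unreadable pressure table {path}: {exc}") from exc
    if data.shape[1] != 10:
        raise ValueError(
            f"{path}: expected 10 columns (time + 9 tensor components), "
            f"got {data.shape[1]}")
    return PressureSeries(data[:, 0], data[:, 1:], volume, temperature)


def write_pressure_series(series: PressureSeries, path) -> None:
    data = np.column_stack([series.times, series.tensors])
    header = (f"pressure tensor series: volume={series.volume:.10g} A^3 "
              f"temperature={series.temperature:.10g} K\n"
              "time[ns] Pxx Pxy Pxz Pyx Pyy Pyz Pzx Pzy Pzz [bar]")
    np.savetxt(Path(path), data, fmt="%.17g", header=header)
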
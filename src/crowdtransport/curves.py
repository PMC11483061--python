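"""Shared lightweight curve containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CorrelationCurve:
    """A lag-resolved correlation function with per-replica spread.

    Attributes
    ----------
    lags : ndarray
        Lag times, ns, starting at 0, uniformly spaced.
    values : ndarray
        Ensemble-mean correlation at each lag.
    spread : ndarray or None
        Standard deviation across replicas/trajectories at each lag.
    replicas : ndarray or None
        Per-replica curves, shape (n_replicas, n_lags); kept so later
        stages can form their own cross-trajectory statistics.
    counts : ndarray or None
        Number of averaged (origin, item) pairs per lag.
    """

    lags: np.ndarray
    values: np.ndarray
    spread: np.ndarray | None = None
    replicas: np.ndarray | None = None
    counts: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape:
            raise ValueError("lags and values must have matching shapes")

    def __len__(self) -> int:
        return self.lags.size

    def window(self, lo: float, hi: float) -> "CorrelationCurve":
        """Restrict the curve to lags in [lo, hi]."""
        mask = (self.lags >= lo) & (self.lags <= hi)
        return CorrelationCurve(
            self.lags[mask], self.values[mask],
            None if self.spread is None else self.spread[mask],
            None if self.replicas is None else self.replicas[:, mask],
            None if self.counts is None else self.counts[mask],
            dict(self.meta))
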
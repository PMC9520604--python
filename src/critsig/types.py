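"""Shared containers and error types."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Raster", "InsufficientDataError", "DegenerateNetworkError"]


class InsufficientDataError(ValueError):
    """Too few samples for the requested statistic."""

    def __init__(self, message: str, n_tail: int = 0):
        super().__init__(message)
        self.n_tail = n_tail


class DegenerateNetworkError(ValueError):
    """Connectivity parameters cannot yield a meaningful network."""


@dataclass
class Raster:
    """Binary neuron x time-bin spike matrix, the common currency of the package.

    ``spikes[i, t] == 1`` means neuron ``i`` fired in bin ``t``.  The per-bin
    population activity is the column sum.
    """

    spikes: np.ndarray
    bin_ms: float = 1.0

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes)
        if self.spikes.ndim != 2:
            raise ValueError("spikes must be a 2-D (neurons x bins) array")
        vals = np.unique(self.spikes)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("raster entries must be 0 or 1")
        self.spikes = self.spikes.astype(np.uint8)

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_bins(self) -> int:
        return self.spikes.shape[1]

    def activity(self) -> np.ndarray:
        """Population spike count per time bin."""
        return self.spikes.sum(axis=0).astype(np.int64)
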
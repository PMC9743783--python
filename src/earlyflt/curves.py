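"""Binned time-resolved signals (FTPSF, FTR, IRF) on a uniform time grid."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics import DomainError

CURVE_KINDS = ("FTPSF", "FTR", "IRF")


@dataclass
class TimeCurve:
    """A binned time-resolved signal.

    ``bin_edges`` (ps) has one more element than ``values``; bins are
    uniform.  ``values`` holds detected weight (simulated curves) or photon
    counts (synthetic/measured responses) per bin and must be nonnegative.
    ``kind`` is one of ``FTPSF``, ``FTR``, ``IRF``.
    """

    bin_edges: np.ndarray
    values: np.ndarray
    kind: str = "FTPSF"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.bin_edges.ndim != 1:
            raise DomainError("bin_edges and values must be 1-D")
        if len(self.values) != len(self.bin_edges) - 1:
            raise DomainError("len(values) must equal len(bin_edges) - 1")
        widths = np.diff(self.bin_edges)
        if len(widths) == 0 or not np.allclose(widths, widths[0]):
            raise DomainError("bin_edges must form a nonempty uniform grid")
        if np.any(self.values < 0.0):
            raise DomainError("curve values must be nonnegative")
        if self.kind not in CURVE_KINDS:
            raise DomainError(f"kind must be one of {CURVE_KINDS}")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def with_values(self, values: np.ndarray, **meta) -> "TimeCurve":
        """Copy of this curve with new values (same grid and kind)."""
        merged = dict(self.meta)
        merged.update(meta)
        return TimeCurve(self.bin_edges.copy(), np.asarray(values, float),
                         self.kind, merged)


def uniform_grid(max_time: float, bin_width: float) -> np.ndarray:
    """Bin edges 0, Δt, 2Δt, … covering [0, max_time]."""
    n = int(round(max_time / bin_width))
    return np.arange(n + 1, dtype=float) * bin_width
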
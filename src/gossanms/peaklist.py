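"""The universal input record: an ordered centroided peak list."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Optional, Tuple

import numpy as np

__all__ = ["PeakList"]


@dataclass
class PeakList:
    """Ordered (m/z, intensity) pairs with polarity and free-form metadata.

    ``mz`` must be sorted ascending; construction enforces this so that
    downstream sliding-window algorithms can rely on order.
    """

    mz: np.ndarray
    intensity: np.ndarray
    polarity: Optional[str] = None  # "positive" | "negative" | None
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            raise ValueError("peak list must be sorted ascending by m/z")
        if self.polarity not in (None, "positive", "negative"):
            raise ValueError(f"invalid polarity: {self.polarity!r}")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")

    @classmethod
    def from_pairs(cls, pairs, polarity=None, metadata=None) -> "PeakList":
        """Build from an iterable of (mz, intensity); sorts by m/z."""
        arr = np.asarray(list(pairs), dtype=float)
        if arr.size == 0:
            arr = arr.reshape(0, 2)
        order = np.argsort(arr[:, 0], kind="stable")
        return cls(arr[order, 0], arr[order, 1], polarity, metadata or {})

    def __len__(self) -> int:
        return self.mz.size

    def __iter__(self) -> Iterator[Tuple[float, float]]:
        return iter(zip(self.mz.tolist(), self.intensity.tolist()))

    @property
    def tic(self) -> float:
        """Total ion current (sum of intensities)."""
        return float(self.intensity.sum())

    def merged_duplicates(self, tol: float = 1e-9) -> "PeakList":
        """Merge peaks closer than ``tol`` Da by summing their intensities."""
        if len(self) < 2:
            return self
        groups = np.concatenate([[0], np.cumsum(np.diff(self.mz) > tol)])
        mz = np.array([self.mz[groups == g].mean() for g in range(groups[-1] + 1)])
        inten = np.array(
            [self.intensity[groups == g].sum() for g in range(groups[-1] + 1)]
        )
        return PeakList(mz, inten, self.polarity, dict(self.metadata))
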
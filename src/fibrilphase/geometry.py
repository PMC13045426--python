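"""Rigid-rod descriptors for amyloid fibrils."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = ["FibrilGeometry"]


@dataclass(frozen=True)
class FibrilGeometry:
    """Rod geometry: bare diameter D, contour length L, persistence length Lp.

    The excluded-volume theory in :mod:`fibrilphase.phase_model` assumes
    thin rigid rods, i.e. aspect ratio L/D of order 1e2 and Lp/L >= 1; a
    warning is emitted when the flexibility condition is violated.
    All lengths in nm.
    """

    D: float
    L: float
    Lp: float | None = None

    def __post_init__(self) -> None:
        if self.D <= 0 or self.L <= 0:
            raise ValueError("D and L must be positive")
        if self.L / self.D < 10:
            raise ValueError(
                f"aspect ratio L/D={self.L / self.D:.1f} < 10: outside the "
                "rigid-rod regime the theory assumes"
            )
        if self.Lp is not None and self.Lp < self.L:
            warnings.warn(
                f"Lp/L={self.Lp / self.L:.2f} < 1: fibrils are semiflexible; "
                "rigid-rod predictions may be biased",
                stacklevel=2,
            )

    @property
    def aspect_ratio(self) -> float:
        return self.L / self.D

    @property
    def radius(self) -> float:
        return 0.5 * self.D

    @classmethod
    def from_aspect_ratio(cls, D: float, aspect_ratio: float, Lp: float | None = None):
        return cls(D=D, L=aspect_ratio * D, Lp=Lp)


#: Lysozyme fibril default geometry: D = 20.9 nm / 5.4 (the SAXS inter-fibril
#: spacing divided by the reduced nematic spacing), aspect ratio ~95.
LYSOZYME = FibrilGeometry.from_aspect_ratio(D=20.9 / 5.4, aspect_ratio=95.0)

#: beta-lactoglobulin fibril default geometry (aspect ratio ~80).
BETA_LACTOGLOBULIN = FibrilGeometry.from_aspect_ratio(D=20.9 / 5.4, aspect_ratio=80.0)
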
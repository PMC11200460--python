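"""Frequency-band definitions for LFP band-power features.

The three canonical bands used throughout the pipeline are delta (1-4 Hz),
theta (6-10 Hz) and gamma (40-100 Hz).  They are pairwise disjoint, so the
per-band spectral ratios of any signal sum to at most one.
"""
from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError


@dataclass(frozen=True)
class BandSpec:
    """A closed frequency band [low, high] in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high):
            raise ConfigurationError(
                f"band {self.name!r}: need 0 < low < high, got [{self.low}, {self.high}]"
            )

    def validate_for_fs(self, fs: float) -> None:
        """Check the band sits strictly below the Nyquist frequency of ``fs``."""
        if self.high >= fs / 2.0:
            raise ConfigurationError(
                f"band {self.name!r}: high edge {self.high} Hz >= Nyquist {fs / 2.0} Hz"
            )


DELTA = BandSpec("delta", 1.0, 4.0)
THETA = BandSpec("theta", 6.0, 10.0)
GAMMA = BandSpec("gamma", 40.0, 100.0)

#: Canonical band triple, in feature order.
DEFAULT_BANDS: tuple[BandSpec, BandSpec, BandSpec] = (DELTA, THETA, GAMMA)
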
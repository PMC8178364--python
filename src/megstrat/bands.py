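"""Canonical oscillatory frequency bands.

Resting-state neural activity is conventionally analysed in a small set of
frequency bands, from slow delta rhythms up to high gamma. All band-limited
operations in this package (band power integration, band-pass filtering for
envelope connectivity) are parameterised by a :class:`BandDefinition`.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band ``[lo, hi]`` in Hz.

    Parameters
    ----------
    name : str
        Band label, e.g. ``"alpha"``.
    lo, hi : float
        Band edges in Hz; ``0 < lo < hi`` is enforced.
    """

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(
                f"band {self.name!r}: need 0 < lo < hi, got lo={self.lo}, hi={self.hi}"
            )

    @property
    def width(self) -> float:
        return self.hi - self.lo

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)


#: The seven canonical bands used throughout: delta through high gamma.
CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 3.0),
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 8.0, 14.0),
    BandDefinition("beta", 15.0, 30.0),
    BandDefinition("low_gamma_1", 30.0, 55.0),
    BandDefinition("low_gamma_2", 65.0, 80.0),
    BandDefinition("high_gamma", 80.0, 150.0),
)

BAND_MAP: dict[str, BandDefinition] = {b.name: b for b in CANONICAL_BANDS}


def get_band(name: str) -> BandDefinition:
    """Look up a canonical band by name."""
    try:
        return BAND_MAP[name]
    except KeyError:
        raise KeyError(
            f"unknown band {name!r}; canonical bands: {sorted(BAND_MAP)}"
        ) from None
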
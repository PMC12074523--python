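"""Flowmotion frequency bands.

Microvascular blood-flow oscillations ("flowmotion") are conventionally
decomposed into five frequency bands: endothelial (metabolic) activity up to
0.021 Hz, neurogenic (sympathetic) activity 0.021-0.052 Hz, myogenic
(vascular smooth muscle) activity 0.052-0.15 Hz, respiration 0.15-0.6 Hz and
the cardiac pulse around 1 Hz.  Band membership is half-open ``(lower,
upper]`` so that contiguous bands partition the axis with no bin counted
twice.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Band:
    """Half-open frequency interval ``(lower, upper]`` in Hz."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower < self.upper):
            raise ValueError(f"invalid band ({self.lower}, {self.upper}]")

    def __contains__(self, frequency: float) -> bool:
        return self.lower < frequency <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower


class BandScheme(dict):
    """Ordered, contiguous mapping of band name -> :class:`Band`."""

    def __init__(self, bands: dict[str, Band]):
        super().__init__(bands)
        items = list(bands.values())
        for lo, hi in zip(items, items[1:]):
            if hi.lower != lo.upper:
                raise ValueError(
                    f"bands must be contiguous and increasing; got "
                    f"({lo.lower}, {lo.upper}] followed by ({hi.lower}, {hi.upper}]"
                )

    @property
    def lowest(self) -> float:
        return next(iter(self.values())).lower

    @property
    def highest(self) -> float:
        return list(self.values())[-1].upper


#: The canonical five-band flowmotion scheme.  The cardiac band is bounded
#: above at 2 Hz (the pulse sits near 1 Hz); the endothelial band starts at
#: 0 Hz nominally -- in practice the lowest resolvable bin is 1/duration,
#: and the DC bin is always excluded by the half-open lower edge.
DEFAULT_BAND_SCHEME = BandScheme(
    {
        "endothelial": Band(0.0, 0.021),
        "neurogenic": Band(0.021, 0.052),
        "myogenic": Band(0.052, 0.15),
        "respiratory": Band(0.15, 0.6),
        "cardiac": Band(0.6, 2.0),
    }
)

MYOGENIC = DEFAULT_BAND_SCHEME["myogenic"]
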
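"""Frequency-band and electrode-montage definitions.

Two 14-channel montages are provided: the *online* montage of a
consumer 14-electrode headset, and the *offline* montage used with
public affect databases, which additionally defines three symmetric
left/right channel pairs whose band-power differences capture
hemispheric asymmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [low, high) in Hz.

    The half-open convention assigns a spectral bin lying exactly on a
    boundary (e.g. 8 Hz) to the band whose lower edge it is (slow
    alpha), never to the band below.
    """

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"require 0 < low < high, got ({self.low}, {self.high})")


#: The five canonical bands: theta, slow alpha, alpha, beta, gamma.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("slow_alpha", 8.0, 10.0),
    BandDefinition("alpha", 10.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("gamma", 30.0, 45.0),
)

BAND_NAMES = tuple(b.name for b in DEFAULT_BANDS)


@dataclass(frozen=True)
class Montage:
    """Ordered channel list plus optional symmetric (left, right) pairs."""

    channels: tuple[str, ...]
    pairs: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("montage channels must be unique")
        for left, right in self.pairs:
            for name in (left, right):
                if name not in self.channels:
                    raise ValueError(f"pair channel {name!r} not in montage channels")

    @property
    def n_channels(self) -> int:
        return len(self.channels)


ONLINE_MONTAGE = Montage(
    channels=(
        "AF3", "F3", "F7", "FC5", "T7", "P7", "O1",
        "AF4", "F4", "F8", "FC6", "T8", "P8", "O2",
    ),
)

OFFLINE_MONTAGE = Montage(
    channels=(
        "Fp1", "T7", "CP1", "Oz", "Fp2", "F8", "FC6",
        "FC2", "Cz", "C4", "T8", "CP6", "CP2", "PO4",
    ),
    pairs=(("T7", "T8"), ("Fp1", "Fp2"), ("CP1", "CP2")),
)

MONTAGES = {"online": ONLINE_MONTAGE, "offline": OFFLINE_MONTAGE}
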
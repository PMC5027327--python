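"""10-20 system electrode montage: names, hemispheres, and brain-lobe assignment.

Electrode labels in the international 10-20 system encode anatomy: the letter
prefix names the underlying region (``Fp`` prefrontal, ``F`` frontal, ``T``
temporal, ``C`` central sulcus, ``P`` parietal, ``O`` occipital) and the suffix
encodes laterality — ``z`` marks the midline, odd digits the left hemisphere,
even digits the right, increasing with distance from the midline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping

FRONTAL = "frontal"
TEMPORAL = "temporal"
PARIETAL = "parietal"
OCCIPITAL = "occipital"
CENTRAL = "central"

#: The five lobe labels used throughout the package.
LOBES: tuple[str, ...] = (FRONTAL, TEMPORAL, PARIETAL, OCCIPITAL, CENTRAL)

LEFT = "left"
RIGHT = "right"
MIDLINE = "midline"

_NAME_RE = re.compile(r"^([A-Za-z]+?)(\d+|[zZ])$")

# Letter prefix -> lobe. Fronto-central (FC) and fronto-temporal (FT) sites are
# grouped with frontal, centro-parietal (CP) with parietal, and bare C with a
# "central" pseudo-lobe over the central sulcus.
_PREFIX_LOBE: Mapping[str, str] = {
    "Fp": FRONTAL,
    "AF": FRONTAL,
    "FC": FRONTAL,
    "FT": FRONTAL,
    "F": FRONTAL,
    "TP": TEMPORAL,
    "T": TEMPORAL,
    "CP": PARIETAL,
    "PO": OCCIPITAL,
    "P": PARIETAL,
    "C": CENTRAL,
    "O": OCCIPITAL,
}

#: 32-channel actiCAP-style layout (channel order is also the default column
#: order of every feature table produced downstream).
ACTICAP_32: tuple[str, ...] = (
    "Fp1", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "FT9", "FT10",
    "T7",
    "C3", "Cz", "C4",
    "T8",
    "TP9",
    "CP5", "CP1", "CP2", "CP6",
    "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)

_LOBE_FUNCTIONS: Mapping[str, str] = {
    FRONTAL: "executive control, motor planning, thinking, and speech",
    TEMPORAL: "auditory processing and perception of biological motion",
    PARIETAL: "somatosensory, spatial, and tactile perception",
    OCCIPITAL: "visual processing and visual imagery",
    CENTRAL: "sensorimotor sites over the central sulcus",
}


def parse_channel_name(name: str) -> tuple[str, str]:
    """Split a 10-20 electrode name into letter prefix and hemisphere.

    Parameters
    ----------
    name
        Electrode label such as ``"Fp1"``, ``"Oz"``, or ``"CP2"``.

    Returns
    -------
    tuple of (prefix, hemisphere)
        Hemisphere is ``"midline"`` for a ``z`` suffix, ``"left"`` for odd
        digits, ``"right"`` for even digits.

    Raises
    ------
    ValueError
        If the name does not match the letters+digits / letters+``z`` pattern.
    """
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"malformed 10-20 electrode name: {name!r}")
    prefix, suffix = m.group(1), m.group(2)
    if suffix.lower() == "z":
        return prefix, MIDLINE
    return prefix, LEFT if int(suffix) % 2 == 1 else RIGHT


def lobe_for_name(name: str) -> str:
    """Return the lobe an electrode sits over, from its letter prefix."""
    prefix, _ = parse_channel_name(name)
    try:
        return _PREFIX_LOBE[prefix]
    except KeyError:
        raise ValueError(f"unknown electrode prefix {prefix!r} in {name!r}") from None


@dataclass(frozen=True)
class MontageChannel:
    """A single scalp electrode with its anatomical annotation."""

    name: str
    lobe: str
    hemisphere: str

    def __post_init__(self) -> None:
        if self.lobe not in LOBES:
            raise ValueError(f"unknown lobe {self.lobe!r} for channel {self.name!r}")
        _, hemi = parse_channel_name(self.name)
        if hemi != self.hemisphere:
            raise ValueError(
                f"hemisphere {self.hemisphere!r} inconsistent with name {self.name!r} "
                f"(expected {hemi!r})"
            )

    @classmethod
    def from_name(cls, name: str) -> "MontageChannel":
        """Build a channel by deriving lobe and hemisphere from the name alone."""
        _, hemisphere = parse_channel_name(name)
        return cls(name=name, lobe=lobe_for_name(name), hemisphere=hemisphere)


def build_default_montage() -> list[MontageChannel]:
    """The default 32-channel cap layout, each channel annotated with lobe
    and hemisphere."""
    return [MontageChannel.from_name(n) for n in ACTICAP_32]


@dataclass(frozen=True)
class LobeMap:
    """Electrode name -> (lobe, function note) lookup used for attribution."""

    entries: Mapping[str, tuple[str, str]]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def lobe_of(self, name: str) -> str:
        try:
            return self.entries[name][0]
        except KeyError:
            raise ValueError(f"electrode {name!r} is not in the lobe map") from None

    def function_of(self, name: str) -> str:
        if name not in self.entries:
            raise ValueError(f"electrode {name!r} is not in the lobe map")
        return self.entries[name][1]

    @property
    def lobes(self) -> frozenset[str]:
        return frozenset(lobe for lobe, _ in self.entries.values())

    @classmethod
    def from_montage(cls, channels: list[MontageChannel]) -> "LobeMap":
        return cls(
            entries={
                ch.name: (ch.lobe, _LOBE_FUNCTIONS[ch.lobe]) for ch in channels
            }
        )


def default_lobe_map() -> LobeMap:
    """Lobe map covering the full default montage."""
    return LobeMap.from_montage(build_default_montage())
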
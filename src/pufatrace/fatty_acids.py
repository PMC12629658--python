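"""Fatty-acid identities and the lipid shorthand parser.

Fatty acids are named throughout by the ``C:Dn-F`` shorthand used in
lipidomics tables: ``C`` carbons, ``D`` double bonds, omega family ``n-F``
(position of the first double bond counted from the methyl end).  Saturated
or odd-chain acids with no omega designation (e.g. the 17:0 internal
standard) carry ``omega_family="other"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum


class OmegaFamily(str, Enum):
    N3 = "n-3"
    N6 = "n-6"
    OTHER = "other"


@dataclass(frozen=True)
class FattyAcidId:
    """Identity of one fatty acid.

    Attributes
    ----------
    shorthand:
        Canonical ``C:D`` or ``C:Dn-F`` string, e.g. ``"22:6n-3"``.
    n_carbons:
        Carbon count of the free fatty acid (the ``n`` of the
        methylation correction; the methyl-ester derivative has one more).
    n_double_bonds:
        Number of carbon–carbon double bonds.
    omega_family:
        ``n-3``, ``n-6`` or ``other``.
    """

    shorthand: str
    n_carbons: int
    n_double_bonds: int
    omega_family: OmegaFamily

    def __post_init__(self) -> None:
        if self.n_carbons < 2:
            raise ValueError(f"{self.shorthand!r}: need at least 2 carbons, got {self.n_carbons}")
        if self.n_double_bonds < 0 or self.n_double_bonds >= self.n_carbons:
            raise ValueError(
                f"{self.shorthand!r}: double bond count {self.n_double_bonds} "
                f"must be in [0, {self.n_carbons})"
            )

    def __str__(self) -> str:
        return self.shorthand


_SHORTHAND_RE = re.compile(r"^(\d+):(\d+)(?:n-(\d+))?$")

# omega positions outside {3, 6} are legal shorthand but fall outside the
# two pathways tracked here
_FAMILY_BY_POSITION = {3: OmegaFamily.N3, 6: OmegaFamily.N6}


def parse_fatty_acid(shorthand: str) -> FattyAcidId:
    """Parse ``"C:D"`` / ``"C:Dn-F"`` shorthand into a :class:`FattyAcidId`.

    >>> parse_fatty_acid("22:6n-3")
    FattyAcidId(shorthand='22:6n-3', n_carbons=22, n_double_bonds=6, omega_family=<OmegaFamily.N3: 'n-3'>)
    """
    token = shorthand.strip()
    m = _SHORTHAND_RE.match(token)
    if m is None:
        raise ValueError(
            f"cannot parse fatty-acid shorthand {token!r}: expected 'C:D' or 'C:Dn-F', "
            "e.g. '18:3n-3' or '17:0'"
        )
    carbons, bonds = int(m.group(1)), int(m.group(2))
    family = OmegaFamily.OTHER
    if m.group(3) is not None:
        family = _FAMILY_BY_POSITION.get(int(m.group(3)), OmegaFamily.OTHER)
    return FattyAcidId(token, carbons, bonds, family)


# Named acids of the two elongation/desaturation chains
ALA = parse_fatty_acid("18:3n-3")
EPA = parse_fatty_acid("20:5n-3")
DPA = parse_fatty_acid("22:5n-3")
DHA = parse_fatty_acid("22:6n-3")
LA = parse_fatty_acid("18:2n-6")
DGLA = parse_fatty_acid("20:3n-6")
ARA = parse_fatty_acid("20:4n-6")

COMMON_NAMES = {
    ALA: "ALA", EPA: "EPA", DPA: "DPA", DHA: "DHA",
    LA: "LA", DGLA: "DGLA", ARA: "ARA",
}
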
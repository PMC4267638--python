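"""Splicing consensus region definitions.

The splice-site windows used throughout the package follow the Burge
convention: donor (5' splice site) positions -3..+8 and acceptor (3' splice
site) positions -12..+2, counted relative to the exon/intron boundary with no
position zero.  Negative offsets are exonic at the donor and intronic at the
acceptor; the nearly invariant GT (donor +1,+2) and AG (acceptor -2,-1)
dinucleotide positions are flagged so variant enumeration can exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class RegionDefinition:
    """Ordered offset layout of one splice-site consensus window.

    Parameters
    ----------
    site_kind : {"donor", "acceptor"}
    exonic_span : int
        Number of exonic positions in the window.
    intronic_span : int
        Number of intronic positions in the window.
    offsets : tuple of int
        Signed positions in increasing order; zero is never used.
    invariant_offsets : tuple of int
        Offsets of the invariant GT/AG dinucleotide.
    """

    site_kind: str
    exonic_span: int
    intronic_span: int
    offsets: tuple = field(default_factory=tuple)
    invariant_offsets: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.site_kind not in ("donor", "acceptor"):
            raise ValueError(f"unknown site_kind {self.site_kind!r}")
        if len(self.offsets) != self.exonic_span + self.intronic_span:
            raise ValueError("offset count does not match spans")
        if any(b <= a for a, b in zip(self.offsets, self.offsets[1:])):
            raise ValueError("offsets must be strictly increasing")
        if 0 in self.offsets:
            raise ValueError("offset 0 is not defined for splice-site windows")

    def __len__(self) -> int:
        return len(self.offsets)

    @property
    def mutable_offsets(self) -> tuple:
        """Offsets that may carry scSNVs (window minus GT/AG positions)."""
        return tuple(o for o in self.offsets if o not in self.invariant_offsets)

    def is_exonic(self, offset: int) -> bool:
        """Whether ``offset`` lies on the exon side of the boundary."""
        if offset not in self.offsets:
            raise ValueError(f"offset {offset} outside {self.site_kind} window")
        # donor: exon upstream (negative side); acceptor: exon downstream.
        return offset < 0 if self.site_kind == "donor" else offset > 0


def donor_region() -> RegionDefinition:
    """Donor window -3..+8: 3 exonic, 8 intronic, GT at +1,+2 (11 positions)."""
    offsets = tuple(o for o in range(-3, 9) if o != 0)
    return RegionDefinition("donor", 3, 8, offsets, (1, 2))


def acceptor_region() -> RegionDefinition:
    """Acceptor window -12..+2: 12 intronic, 2 exonic, AG at -2,-1 (14 positions)."""
    offsets = tuple(o for o in range(-12, 3) if o != 0)
    return RegionDefinition("acceptor", 2, 12, offsets, (-2, -1))


def region_for(site_kind: str) -> RegionDefinition:
    if site_kind == "donor":
        return donor_region()
    if site_kind == "acceptor":
        return acceptor_region()
    raise ValueError(f"unknown site_kind {site_kind!r}")
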
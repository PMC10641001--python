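"""Reference strain library: identities, rep-PCR band profiles, ITS sequences.

A :class:`StrainLibrary` bundles the single-letter-tagged reference strains of
a mixed inoculant, any indigenous (soil-derived) strains, and a distant
outgroup taxon used to root phylogenies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["StrainProfile", "StrainLibrary", "NUCLEOTIDES"]

NUCLEOTIDES = "ACGT"

_MIN_BAND_BP = 50
_MAX_BAND_BP = 5000
_MIN_ITS_LEN = 200


def _check_bands(bands: list[int], what: str) -> None:
    if any(b < _MIN_BAND_BP or b > _MAX_BAND_BP for b in bands):
        raise ValueError(f"{what}: band sizes must lie in [{_MIN_BAND_BP}, {_MAX_BAND_BP}] bp")
    if any(b2 <= b1 for b1, b2 in zip(bands, bands[1:])):
        raise ValueError(f"{what}: band sizes must be strictly ascending")


@dataclass
class StrainProfile:
    """One strain: id, inoculant tag (references only), fingerprints, ITS.

    Parameters
    ----------
    id : str
        Strain identifier, e.g. ``"9-5"``.
    tag : str or None
        Single uppercase letter (A, B, ...) for inoculant-mix reference
        strains; ``None`` for indigenous strains and outgroups.
    eric_bands, box_bands : list of int
        rep-PCR fragment sizes in bp, strictly ascending.
    its_seq : str
        16S-23S internal transcribed spacer sequence over {A, C, G, T}
        (aligned coordinates; at least 200 columns).
    clade : str
        Phylogenetic cluster label, e.g. ``"reference-1"``, ``"reference-2"``,
        ``"novel-indigenous"`` or ``"outgroup"``.
    """

    id: str
    tag: str | None
    eric_bands: list[int] = field(default_factory=list)
    box_bands: list[int] = field(default_factory=list)
    its_seq: str = ""
    clade: str = ""

    def __post_init__(self) -> None:
        if self.tag is not None:
            if len(self.tag) != 1 or not self.tag.isalpha() or not self.tag.isupper():
                raise ValueError(f"strain {self.id!r}: tag must be a single uppercase letter")
        _check_bands(self.eric_bands, f"strain {self.id!r} ERIC")
        _check_bands(self.box_bands, f"strain {self.id!r} BOX")
        if len(self.its_seq) < _MIN_ITS_LEN:
            raise ValueError(f"strain {self.id!r}: ITS sequence shorter than {_MIN_ITS_LEN} nt")
        bad = set(self.its_seq) - set(NUCLEOTIDES)
        if bad:
            raise ValueError(f"strain {self.id!r}: ITS contains non-ACGT symbols {sorted(bad)}")

    def bands(self, method: str) -> list[int]:
        """Band profile for a fingerprinting method ("ERIC" or "BOX")."""
        method = method.upper()
        if method == "ERIC":
            return self.eric_bands
        if method == "BOX":
            return self.box_bands
        raise ValueError(f"unknown fingerprinting method {method!r}")


@dataclass
class StrainLibrary:
    """Reference + indigenous strains of a competition study, with outgroup."""

    strains: list[StrainProfile]
    outgroup: StrainProfile

    def __post_init__(self) -> None:
        ids = [s.id for s in self.strains] + [self.outgroup.id]
        if len(set(ids)) != len(ids):
            raise ValueError("strain ids must be unique")
        tags = [s.tag for s in self.strains if s.tag is not None]
        if len(set(tags)) != len(tags):
            raise ValueError("reference tags must be unique")
        lens = {len(s.its_seq) for s in self.strains} | {len(self.outgroup.its_seq)}
        if len(lens) != 1:
            raise ValueError("all ITS sequences must share one aligned length")

    @property
    def references(self) -> list[StrainProfile]:
        """Inoculant-mix reference strains, in tag order."""
        return sorted((s for s in self.strains if s.tag is not None), key=lambda s: s.tag)

    @property
    def indigenous(self) -> list[StrainProfile]:
        return [s for s in self.strains if s.tag is None]

    @property
    def tags(self) -> list[str]:
        return [s.tag for s in self.references]

    @property
    def its_length(self) -> int:
        return len(self.outgroup.its_seq)

    def by_tag(self, tag: str) -> StrainProfile:
        for s in self.strains:
            if s.tag == tag:
                return s
        raise KeyError(f"no reference strain with tag {tag!r}")

    def all_taxa(self) -> list[StrainProfile]:
        """Every taxon including the outgroup (outgroup last)."""
        return [*self.strains, self.outgroup]
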
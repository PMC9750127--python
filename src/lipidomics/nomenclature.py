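"""Parsing and formatting of lipid species names in shorthand notation.

Lipid species are written in the LIPID MAPS-style shorthand used by most
identification software: a class code followed by a parenthesized chain
descriptor, e.g. ``PC(16:0/18:1)`` (molecular-species level, chains
resolved) or ``PC(34:1)`` (species level, only totals known).  Chain
tokens may carry an ether (``O-``) or vinyl-ether/plasmalogen (``P-``)
linkage prefix, a sphingoid-base prefix (``d`` = dihydroxy, ``t`` =
trihydroxy), and an optional hydroxylation suffix (``(OH)`` / ``(2OH)``).
Chains are separated by ``/`` when sn-positions are known and ``_`` when
they are not.  An adduct such as ``+H`` or ``-H`` may trail the closing
parenthesis (LipidSearch "LipidIon" style).

The parse produces the class / total-carbon / double-bond stratification
that the filtering, summary and enrichment stages all key on.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "Linkage",
    "Resolution",
    "FattyAcylChain",
    "LipidSpecies",
    "LipidParseError",
    "parse_lipid_name",
    "format_lipid_name",
    "has_odd_chain",
    "load_class_vocabulary",
    "DEFAULT_CLASSES",
]


class Linkage(str, Enum):
    """Bond type attaching a fatty acyl/alkyl chain to the backbone."""

    ESTER = "ester"
    ETHER = "ether"              # O- prefix (alkyl ether)
    VINYL_ETHER = "vinyl_ether"  # P- prefix (plasmalogen)
    SPHINGOID_D = "sphingoid_d"  # d prefix, dihydroxy sphingoid base
    SPHINGOID_T = "sphingoid_t"  # t prefix, trihydroxy sphingoid base


class Resolution(str, Enum):
    SPECIES = "species_level"
    MOLECULAR = "molecular_species_level"


class LipidParseError(ValueError):
    """Raised when a lipid name cannot be parsed.

    Carries the offending token so import code can build a rejects report.
    """

    def __init__(self, name: str, token: str, reason: str):
        self.name = name
        self.token = token
        self.reason = reason
        super().__init__(f"cannot parse lipid name {name!r}: {reason} (token {token!r})")


# Common glycerolipid, glycerophospholipid, sphingolipid and sterol codes.
# Extendable at runtime via load_class_vocabulary().
DEFAULT_CLASSES = frozenset(
    {
        "PC", "PE", "PS", "PI", "PG", "PA",
        "LPC", "LPE", "LPS", "LPI", "LPG", "LPA",
        "TG", "DG", "MG",
        "Cer", "CerP", "SM", "SPH", "HexCer", "Hex2Cer", "GlcCer", "GalCer",
        "CE", "ChE", "FA", "FFA", "CL", "CAR",
        "MGDG", "DGDG", "SQDG",
    }
)


@dataclass(frozen=True)
class FattyAcylChain:
    """One fatty acyl/alkyl or sphingoid chain: carbons:double_bonds."""

    carbons: int
    double_bonds: int
    linkage: Linkage = Linkage.ESTER
    hydroxyls: int = 0

    def __post_init__(self) -> None:
        if self.carbons < 1:
            raise ValueError(f"chain carbons must be >= 1, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError(f"double bonds must be >= 0, got {self.double_bonds}")
        if self.double_bonds > self.carbons:
            raise ValueError(
                f"double bonds ({self.double_bonds}) exceed carbons ({self.carbons})"
            )
        if self.hydroxyls < 0:
            raise ValueError("hydroxyl count must be >= 0")


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed lipid name.

    ``chains`` is empty when only species-level totals are known; when it is
    populated the totals are forced to equal the chain sums.  ``raw_name``
    is excluded from equality so that a reparsed canonical name compares
    equal to the original parse.
    """

    raw_name: str = field(compare=False)
    lipid_class: str
    chains: tuple[FattyAcylChain, ...]
    total_carbons: int
    total_double_bonds: int
    resolution: Resolution
    positions_known: bool = True
    adduct: Optional[str] = None
    is_internal_standard: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.chains:
            tc = sum(c.carbons for c in self.chains)
            db = sum(c.double_bonds for c in self.chains)
            if (tc, db) != (self.total_carbons, self.total_double_bonds):
                raise ValueError(
                    f"totals ({self.total_carbons}:{self.total_double_bonds}) do not "
                    f"match chain sums ({tc}:{db}) for {self.raw_name!r}"
                )
            if self.resolution is not Resolution.MOLECULAR:
                raise ValueError("chain-resolved species must be molecular_species_level")
        elif self.resolution is not Resolution.SPECIES:
            raise ValueError("species without chains must be species_level")
        if len(self.chains) <= 1 and not self.positions_known:
            object.__setattr__(self, "positions_known", True)  # trivially known

    @classmethod
    def from_chains(
        cls,
        lipid_class: str,
        chains: Sequence[FattyAcylChain],
        *,
        raw_name: Optional[str] = None,
        positions_known: bool = True,
        adduct: Optional[str] = None,
        is_internal_standard: bool = False,
    ) -> "LipidSpecies":
        chains = tuple(chains)
        sp = cls(
            raw_name=raw_name or "",
            lipid_class=lipid_class,
            chains=chains,
            total_carbons=sum(c.carbons for c in chains),
            total_double_bonds=sum(c.double_bonds for c in chains),
            resolution=Resolution.MOLECULAR,
            positions_known=positions_known,
            adduct=adduct,
            is_internal_standard=is_internal_standard,
        )
        if not raw_name:
            object.__setattr__(sp, "raw_name", format_lipid_name(sp))
        return sp

    @classmethod
    def from_totals(
        cls,
        lipid_class: str,
        total_carbons: int,
        total_double_bonds: int,
        *,
        raw_name: Optional[str] = None,
        adduct: Optional[str] = None,
        is_internal_standard: bool = False,
    ) -> "LipidSpecies":
        sp = cls(
            raw_name=raw_name or "",
            lipid_class=lipid_class,
            chains=(),
            total_carbons=total_carbons,
            total_double_bonds=total_double_bonds,
            resolution=Resolution.SPECIES,
            adduct=adduct,
            is_internal_standard=is_internal_standard,
        )
        if not raw_name:
            object.__setattr__(sp, "raw_name", format_lipid_name(sp))
        return sp

    @property
    def canonical_name(self) -> str:
        return format_lipid_name(self)


_CHAIN_RE = re.compile(
    r"^(?P<link>O-|P-)?(?P<sph>[dt])?(?P<c>\d+):(?P<db>\d+)"
    r"(?:\((?P<noh>\d*)OH\)|;O(?P<noh2>\d*))?$"
)
_NAME_RE = re.compile(
    r"^\s*(?P<cls>[A-Za-z][A-Za-z0-9]*?)\s*\((?P<desc>[^()]*(?:\([^()]*\)[^()]*)*)\)"
    r"\s*(?P<adduct>[+-][A-Za-z0-9+\-]*)?\s*$"
)

_SPH_LINKAGE = {"d": Linkage.SPHINGOID_D, "t": Linkage.SPHINGOID_T}
_SPH_HYDROXYLS = {"d": 2, "t": 3}


def _parse_chain(token: str, name: str) -> FattyAcylChain:
    m = _CHAIN_RE.match(token)
    if not m:
        raise LipidParseError(name, token, "malformed chain descriptor")
    link = Linkage.ESTER
    hydroxyls = 0
    if m.group("link"):
        link = Linkage.ETHER if m.group("link") == "O-" else Linkage.VINYL_ETHER
    if m.group("sph"):
        if m.group("link"):
            raise LipidParseError(name, token, "sphingoid and ether prefixes conflict")
        link = _SPH_LINKAGE[m.group("sph")]
        hydroxyls = _SPH_HYDROXYLS[m.group("sph")]
    noh = m.group("noh") if m.group("noh") is not None else m.group("noh2")
    if noh is not None:
        hydroxyls += int(noh) if noh else 1
    try:
        return FattyAcylChain(int(m.group("c")), int(m.group("db")), link, hydroxyls)
    except ValueError as exc:
        raise LipidParseError(name, token, str(exc)) from None


def parse_lipid_name(
    name: str,
    *,
    known_classes: Optional[Iterable[str]] = None,
    warn_unknown_class: bool = True,
) -> LipidSpecies:
    """Parse a shorthand lipid name into a :class:`LipidSpecies`.

    Parameters
    ----------
    name
        Shorthand name, e.g. ``"PC(16:0/18:1)"``, ``"Cer(d18:1/24:0)"``,
        ``"PC(34:1)"`` or ``"PE(P-16:0/20:4)+H"``.
    known_classes
        Class vocabulary; unknown class codes still parse but emit a
        warning (the vocabulary is configuration, not a hard gate).

    Raises
    ------
    LipidParseError
        On any malformed name; never returns a silent partial parse.
    """
    if not isinstance(name, str) or not name.strip():
        raise LipidParseError(str(name), str(name), "empty name")
    m = _NAME_RE.match(name)
    if not m:
        raise LipidParseError(name, name.strip(), "does not match CLASS(chains) shorthand")
    cls = m.group("cls")
    desc = m.group("desc").strip()
    adduct = m.group("adduct")
    vocab = DEFAULT_CLASSES if known_classes is None else set(known_classes)
    if warn_unknown_class and cls not in vocab:
        warnings.warn(f"unknown lipid class code {cls!r} in {name!r}", stacklevel=2)
    if not desc:
        raise LipidParseError(name, "()", "empty chain descriptor")

    positions_known = "_" not in desc
    tokens = re.split(r"[/_]", desc)
    tokens = [t.strip() for t in tokens]
    if any(not t for t in tokens):
        raise LipidParseError(name, desc, "empty chain token")

    if len(tokens) == 1 and re.fullmatch(r"\d+:\d+", tokens[0]):
        # A single bare C:DB token carries only species-level totals.
        c, db = (int(x) for x in tokens[0].split(":"))
        if db > c or c < 1:
            raise LipidParseError(name, tokens[0], "invalid totals")
        return LipidSpecies(
            raw_name=name,
            lipid_class=cls,
            chains=(),
            total_carbons=c,
            total_double_bonds=db,
            resolution=Resolution.SPECIES,
            adduct=adduct,
        )

    chains = tuple(_parse_chain(t, name) for t in tokens)
    return LipidSpecies(
        raw_name=name,
        lipid_class=cls,
        chains=chains,
        total_carbons=sum(c.carbons for c in chains),
        total_double_bonds=sum(c.double_bonds for c in chains),
        resolution=Resolution.MOLECULAR,
        positions_known=positions_known,
        adduct=adduct,
    )


_LINK_PREFIX = {
    Linkage.ESTER: "",
    Linkage.ETHER: "O-",
    Linkage.VINYL_ETHER: "P-",
    Linkage.SPHINGOID_D: "d",
    Linkage.SPHINGOID_T: "t",
}


def _format_chain(chain: FattyAcylChain) -> str:
    prefix = _LINK_PREFIX[chain.linkage]
    # Sphingoid prefixes already encode 2 (d) or 3 (t) hydroxyls.
    extra_oh = chain.hydroxyls - _SPH_HYDROXYLS.get(prefix, 0)
    s = f"{prefix}{chain.carbons}:{chain.double_bonds}"
    if extra_oh == 1:
        s += "(OH)"
    elif extra_oh > 1:
        s += f"({extra_oh}OH)"
    return s


def format_lipid_name(species: LipidSpecies) -> str:
    """Canonical shorthand for a species; inverse of :func:`parse_lipid_name`.

    The adduct is intentionally omitted: the canonical name identifies the
    lipid species, and different adduct ions of one species are duplicates
    to be resolved by the filtering stage.
    """
    if species.chains:
        sep = "/" if species.positions_known else "_"
        desc = sep.join(_format_chain(c) for c in species.chains)
    else:
        desc = f"{species.total_carbons}:{species.total_double_bonds}"
    return f"{species.lipid_class}({desc})"


def has_odd_chain(species: LipidSpecies) -> bool:
    """True when the species contains (or must contain) an odd-carbon chain.

    Chain-resolved: any chain with odd carbons.  Species-level: an odd
    carbon total forces at least one odd chain; an even total is treated
    as not-odd since the chains are unresolved.
    """
    if species.chains:
        return any(c.carbons % 2 == 1 for c in species.chains)
    return species.total_carbons % 2 == 1


def load_class_vocabulary(path: str | Path) -> frozenset[str]:
    """Read a class vocabulary file: one class code per line, '#' comments."""
    codes = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            codes.append(line)
    return frozenset(codes)
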
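"""Lipid shorthand nomenclature: parsing and per-chain saturation bookkeeping.

This module turns annotation strings as exported by LC-MS peak-processing
software (MS-DIAL-era shorthand) into structured :class:`LipidSpecies`
records, and derives the per-chain quantities every downstream stage uses:

* ``count_chain_saturation`` — how many acyl chains of a species are
  saturated (0 double bonds) vs unsaturated, the weights entering the
  class saturation index;
* ``max_chain_double_bonds`` — the largest double-bond count found in any
  single chain, the key for double-bond stratification of a class.

Supported shorthand dialects::

    TG(16:0/18:1/18:2)    chain-resolved, "/" or "_" separated
    TG 16:0/18:1/18:2     space-separated composition
    PC 34:1               sum composition (total carbons : total double bonds)
    PE(P-18:0/20:4)       vinyl-ether (plasmenyl) chain -> class PPE
    PC(O-16:0/18:1)       alkyl-ether chain, stays in the base class
    SM(d18:1/16:0)        sphingoid base chain

"/" vs "_" carries no positional (sn) information here; neither is used
downstream.  The vinyl-ether oxygen linkage of plasmalogens is *not*
counted as a chain double bond.  For sum-composition annotations the
per-chain saturation split is not knowable; a conservative fallback
(``n_unsaturated = min(total_double_bonds, chain_count)``) is applied and
flagged ``inferred`` so consumers can report the fraction of species it
affects.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "ESTER",
    "VINYL_ETHER",
    "ALKYL_ETHER",
    "SPHINGOID_BASE",
    "LIPID_CLASSES",
    "CATEGORY_BY_CLASS",
    "EXPECTED_CHAIN_COUNT",
    "AcylChain",
    "LipidSpecies",
    "LipidParseError",
    "SaturationCount",
    "parse_lipid_name",
    "render_lipid_name",
    "classify_category",
    "count_chain_saturation",
    "max_chain_double_bonds",
]

# chain linkage kinds
ESTER = "ester"
VINYL_ETHER = "vinyl_ether"  # plasmalogen "P-" prefix
ALKYL_ETHER = "alkyl_ether"  # "O-" prefix
SPHINGOID_BASE = "sphingoid_base"  # "d" prefix

_PREFIX_TO_LINKAGE = {
    "P-": VINYL_ETHER,
    "O-": ALKYL_ETHER,
    "d": SPHINGOID_BASE,
    "": ESTER,
}
_LINKAGE_TO_PREFIX = {v: k for k, v in _PREFIX_TO_LINKAGE.items()}

#: lipid class -> broad category
CATEGORY_BY_CLASS = {
    "PC": "phospholipid",
    "lysoPC": "phospholipid",
    "lysoPE": "phospholipid",
    "PG": "phospholipid",
    "PPE": "phospholipid",
    "PPC": "phospholipid",
    "PE": "phospholipid",
    "BMP": "phospholipid",
    "CE": "neutral",
    "MG": "neutral",
    "DG": "neutral",
    "TG": "neutral",
    "SM": "sphingomyeline",
    "Acylcarnitine": "acylcarnitine",
    "LanosterylOleate": "other_sterol",
    "LanosterylPalmitoleate": "other_sterol",
}

LIPID_CLASSES = tuple(CATEGORY_BY_CLASS)

#: number of fatty-acyl (or sphingoid) chains fixed by the class backbone
EXPECTED_CHAIN_COUNT = {
    "TG": 3,
    "DG": 2,
    "MG": 1,
    "PC": 2,
    "PE": 2,
    "PPC": 2,
    "PPE": 2,
    "PG": 2,
    "BMP": 2,
    "SM": 2,
    "lysoPC": 1,
    "lysoPE": 1,
    "CE": 1,
    "Acylcarnitine": 1,
    "LanosterylOleate": 1,
    "LanosterylPalmitoleate": 1,
}

# accepted class spellings -> canonical class; matched case-insensitively,
# longest alias first
_CLASS_ALIASES: dict[str, str] = {cls: cls for cls in LIPID_CLASSES}
_CLASS_ALIASES.update(
    {
        "LPC": "lysoPC",
        "LysoPC": "lysoPC",
        "LPE": "lysoPE",
        "LysoPE": "lysoPE",
        "AcCa": "Acylcarnitine",
        "ACar": "Acylcarnitine",
        "CAR": "Acylcarnitine",
        "Lanosteryl oleate": "LanosterylOleate",
        "Lanosteryl palmitoleate": "LanosterylPalmitoleate",
    }
)
_ALIASES_BY_LENGTH = sorted(_CLASS_ALIASES, key=len, reverse=True)

_CHAIN_RE = re.compile(r"^(P-|O-|d)?(\d+):(\d+)$")


class LipidParseError(ValueError):
    """Raised when an annotation string does not follow the shorthand grammar."""


@dataclass(frozen=True)
class AcylChain:
    """A single fatty-acyl / ether / sphingoid chain, ``carbons:double_bonds``."""

    carbons: int
    double_bonds: int
    linkage: str = ESTER

    def __post_init__(self) -> None:
        if self.carbons < 1:
            raise ValueError(f"chain carbons must be >= 1, got {self.carbons}")
        if not 0 <= self.double_bonds <= self.carbons:
            raise ValueError(
                f"double bonds must satisfy 0 <= db <= carbons, got "
                f"{self.double_bonds} for {self.carbons} carbons"
            )
        if self.linkage not in _LINKAGE_TO_PREFIX:
            raise ValueError(f"unknown linkage {self.linkage!r}")

    @property
    def is_saturated(self) -> bool:
        return self.double_bonds == 0

    def render(self) -> str:
        return f"{_LINKAGE_TO_PREFIX[self.linkage]}{self.carbons}:{self.double_bonds}"


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed lipid annotation.

    ``chains`` is empty for sum-composition annotations (``chain_resolved``
    False), in which case only ``total_carbons``/``total_double_bonds`` are
    known.
    """

    raw_name: str
    lipid_class: str
    category: str
    chains: tuple[AcylChain, ...]
    chain_resolved: bool
    total_carbons: int
    total_double_bonds: int
    expected_chain_count: int

    def __post_init__(self) -> None:
        if self.chain_resolved:
            if len(self.chains) != self.expected_chain_count:
                raise ValueError(
                    f"{self.raw_name!r}: {len(self.chains)} chains but class "
                    f"{self.lipid_class} expects {self.expected_chain_count}"
                )
            if self.total_carbons != sum(c.carbons for c in self.chains):
                raise ValueError(f"{self.raw_name!r}: total carbons inconsistent")
            if self.total_double_bonds != sum(c.double_bonds for c in self.chains):
                raise ValueError(f"{self.raw_name!r}: total double bonds inconsistent")
        elif self.chains:
            raise ValueError(f"{self.raw_name!r}: sum composition cannot carry chains")


class SaturationCount(NamedTuple):
    n_saturated: int
    n_unsaturated: int
    inferred: bool


def classify_category(lipid_class: str) -> str:
    """Map a lipid class to its broad category (phospholipid, neutral, ...)."""
    try:
        return CATEGORY_BY_CLASS[lipid_class]
    except KeyError:
        raise ValueError(f"unknown lipid class {lipid_class!r}") from None


def _match_class(s: str) -> tuple[str, str]:
    """Greedy longest-alias class match at the start of ``s``.

    Returns (canonical class, remainder after the class token)."""
    low = s.casefold()
    for alias in _ALIASES_BY_LENGTH:
        a = alias.casefold()
        if low.startswith(a):
            nxt = s[len(alias) : len(alias) + 1]
            if nxt in ("", "(", " ", "\t"):
                return _CLASS_ALIASES[alias], s[len(alias) :].strip()
    token = re.split(r"[\s(]", s, maxsplit=1)[0]
    raise LipidParseError(f"unrecognized lipid class token {token!r} in {s!r}")


def _parse_chain_token(token: str, name: str) -> AcylChain:
    m = _CHAIN_RE.match(token)
    if m is None:
        raise LipidParseError(f"malformed composition token {token!r} in {name!r}")
    prefix, carbons, double_bonds = m.group(1) or "", int(m.group(2)), int(m.group(3))
    try:
        return AcylChain(carbons, double_bonds, _PREFIX_TO_LINKAGE[prefix])
    except ValueError as exc:
        raise LipidParseError(f"{name!r}: {exc}") from None


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse a shorthand annotation into a :class:`LipidSpecies`.

    Raises :class:`LipidParseError` for unknown class tokens, malformed
    ``C:D`` tokens, or a chain count that is neither 1 (sum composition)
    nor the class's expected chain count.
    """
    if not name or not name.strip():
        raise LipidParseError("empty annotation string")
    s = name.strip()
    lipid_class, rest = _match_class(s)
    if not rest:
        raise LipidParseError(f"{name!r}: missing composition")
    if rest.startswith("("):
        if not rest.endswith(")"):
            raise LipidParseError(f"{name!r}: unbalanced parentheses")
        comp = rest[1:-1].strip()
    else:
        comp = rest
    if not comp:
        raise LipidParseError(f"{name!r}: empty composition")

    tokens = [t.strip() for t in re.split(r"[/_]", comp)]
    chains = tuple(_parse_chain_token(t, name) for t in tokens)

    # plasmenyl (vinyl-ether) chains promote PC/PE to the dedicated classes
    if any(c.linkage == VINYL_ETHER for c in chains):
        lipid_class = {"PC": "PPC", "PE": "PPE"}.get(lipid_class, lipid_class)

    expected = EXPECTED_CHAIN_COUNT[lipid_class]
    category = classify_category(lipid_class)

    if len(chains) == expected:
        return LipidSpecies(
            raw_name=name,
            lipid_class=lipid_class,
            category=category,
            chains=chains,
            chain_resolved=True,
            total_carbons=sum(c.carbons for c in chains),
            total_double_bonds=sum(c.double_bonds for c in chains),
            expected_chain_count=expected,
        )
    if len(chains) == 1:  # sum composition
        (chain,) = chains
        return LipidSpecies(
            raw_name=name,
            lipid_class=lipid_class,
            category=category,
            chains=(),
            chain_resolved=False,
            total_carbons=chain.carbons,
            total_double_bonds=chain.double_bonds,
            expected_chain_count=expected,
        )
    raise LipidParseError(
        f"{name!r}: found {len(chains)} chain tokens but class {lipid_class} "
        f"expects {expected} (or a single sum composition)"
    )


def render_lipid_name(sp: LipidSpecies) -> str:
    """Canonical rendering: ``CLASS(c1:d1/c2:d2/...)`` or ``CLASS C:D``."""
    if sp.chain_resolved:
        return f"{sp.lipid_class}({'/'.join(c.render() for c in sp.chains)})"
    return f"{sp.lipid_class} {sp.total_carbons}:{sp.total_double_bonds}"


def count_chain_saturation(sp: LipidSpecies) -> SaturationCount:
    """Split a species' chains into saturated / unsaturated counts.

    A chain is saturated iff it has zero C=C double bonds; ether and
    sphingoid linkages do not count as unsaturation.  For sum-composition
    species the split is inferred: each double bond is assigned to a
    distinct chain until chains run out.
    """
    k = sp.expected_chain_count
    if sp.chain_resolved:
        n_sat = sum(1 for c in sp.chains if c.is_saturated)
        return SaturationCount(n_sat, k - n_sat, False)
    n_unsat = min(sp.total_double_bonds, k)
    return SaturationCount(k - n_unsat, n_unsat, True)


def max_chain_double_bonds(sp: LipidSpecies) -> int:
    """Largest double-bond count in any single chain.

    Sum-composition species fall back to the total double-bond count (an
    upper bound); callers can detect the fallback via ``sp.chain_resolved``.
    """
    if sp.chain_resolved:
        return max(c.double_bonds for c in sp.chains)
    return sp.total_double_bonds
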
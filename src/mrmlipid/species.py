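"""Sum-composition lipid nomenclature and category systems.

Shotgun MRM lipidomics annotates each analyte at the *sum composition*
level: a lipid class plus the total number of acyl/alkyl carbons and total
double bonds (e.g. ``PC aa C34:2``), without resolving the individual
sn-1/sn-2 fatty acids.  This module parses the naming dialects found in
practice, renders a single canonical form, and assigns species to the
category systems used downstream:

* saturation — SFA (0 double bonds), MUFA (1), PUFA (>= 2);
* chain length — SHORT / MEDIUM / LONG relative to class-specific carbon
  bins (diacyl/plasmalogen PC and PE: C32–C36; lyso species: C16–C20);
* carnitine type — free carnitine (C0), acetyl-carnitine (C2),
  acyl-carnitine (C3 and longer, optionally hydroxylated).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

from .errors import LipidNameError

__all__ = [
    "LipidClass",
    "LipidSpecies",
    "SaturationCategory",
    "CarnitineCategory",
    "ChainLength",
    "ChainLengthBins",
    "parse_species",
    "format_species",
    "saturation_category",
    "chain_length_category",
    "carnitine_category",
]


class LipidClass(str, Enum):
    """The eight analyte classes covered by the panel."""

    PC_AA = "PC_AA"   # diacyl phosphatidylcholine
    PC_AE = "PC_AE"   # alkyl-acyl (plasmalogen) phosphatidylcholine
    LPC = "LPC"       # lyso-phosphatidylcholine
    PE_AA = "PE_AA"   # diacyl phosphatidylethanolamine
    PE_AE = "PE_AE"   # alkyl-acyl (plasmalogen) phosphatidylethanolamine
    LPE = "LPE"       # lyso-phosphatidylethanolamine
    CAR = "CAR"       # (acyl-/acetyl-/free) carnitine
    TAG = "TAG"       # triacylglyceride


class SaturationCategory(str, Enum):
    SFA = "SFA"
    MUFA = "MUFA"
    PUFA = "PUFA"


class CarnitineCategory(str, Enum):
    FREE = "FREE"
    ACETYL = "ACETYL"
    ACYL = "ACYL"


class ChainLength(str, Enum):
    SHORT = "SHORT"
    MEDIUM = "MEDIUM"
    LONG = "LONG"


# Canonical class prefix used by format_species for non-carnitine classes.
_CLASS_TOKEN = {
    LipidClass.PC_AA: "PC aa",
    LipidClass.PC_AE: "PC ae",
    LipidClass.LPC: "lyso-PC",
    LipidClass.PE_AA: "PE aa",
    LipidClass.PE_AE: "PE ae",
    LipidClass.LPE: "lyso-PE",
    LipidClass.TAG: "TAG",
}

# Accepted dialect patterns for class prefixes, tried in order.  Matching is
# case-insensitive on the lyso prefix; "lysoPC a" style ("a" = acyl) is
# tolerated.
_CLASS_PATTERNS: list[tuple[re.Pattern[str], LipidClass]] = [
    (re.compile(r"PC\s?aa", re.IGNORECASE), LipidClass.PC_AA),
    (re.compile(r"PC\s?ae", re.IGNORECASE), LipidClass.PC_AE),
    (re.compile(r"PE\s?aa", re.IGNORECASE), LipidClass.PE_AA),
    (re.compile(r"PE\s?ae", re.IGNORECASE), LipidClass.PE_AE),
    (re.compile(r"lyso[\s-]?PC(?:\s?a\b)?", re.IGNORECASE), LipidClass.LPC),
    (re.compile(r"lyso[\s-]?PE(?:\s?a\b)?", re.IGNORECASE), LipidClass.LPE),
    (re.compile(r"TAG", re.IGNORECASE), LipidClass.TAG),
]

_COMPOSITION_RE = re.compile(r"C?(\d+):(\d+)")
_CARNITINE_RE = re.compile(r"C(\d+)(?::(\d+))?((?:[\s-])?OH)?", re.IGNORECASE)


@dataclass(frozen=True)
class LipidSpecies:
    """One analyte identified at sum-composition level.

    ``total_carbons`` is the summed fatty-acyl/alkyl carbon count (0 only
    for free carnitine); ``hydroxylated`` marks carnitine "OH" variants.
    """

    lipid_class: LipidClass
    total_carbons: int
    double_bonds: int
    hydroxylated: bool = False

    def __post_init__(self) -> None:
        if self.total_carbons < 0:
            raise LipidNameError(f"negative carbon count {self.total_carbons}")
        if self.double_bonds < 0:
            raise LipidNameError(f"negative double-bond count {self.double_bonds}")
        if self.double_bonds > self.total_carbons:
            raise LipidNameError(
                f"double bonds ({self.double_bonds}) exceed carbons "
                f"({self.total_carbons})"
            )
        if self.hydroxylated and self.lipid_class is not LipidClass.CAR:
            raise LipidNameError("hydroxylation is only defined for carnitines")
        if self.total_carbons == 0 and self.lipid_class is not LipidClass.CAR:
            raise LipidNameError("zero carbons only allowed for free carnitine")

    @property
    def canonical_name(self) -> str:
        return format_species(self)


def format_species(species: LipidSpecies) -> str:
    """Render the canonical name; inverse of :func:`parse_species`.

    Carnitines follow the conventional short forms: ``C0`` and ``C2`` for
    free and acetyl-carnitine, two-digit zero-padded carbon counts below ten
    (``C03``, ``C03 OH``), and an explicit ``:db`` suffix whenever the
    species is unsaturated or has >= 10 carbons (``C16:0``, ``C18:1``).
    All other classes render as ``"<class token> C<carbons>:<db>"``.
    """
    cls = species.lipid_class
    c, d = species.total_carbons, species.double_bonds
    if cls is LipidClass.CAR:
        if c < 10 and d == 0:
            base = "C0" if c == 0 else ("C2" if c == 2 else f"C{c:02d}")
        elif c < 10:
            base = f"C{c:02d}:{d}"
        else:
            base = f"C{c}:{d}"
        if species.hydroxylated:
            base += " OH"
        return base
    return f"{_CLASS_TOKEN[cls]} C{c}:{d}"


def parse_species(name: str) -> LipidSpecies:
    """Parse a species name in any accepted dialect.

    Accepted forms include ``"PC aa C34:2"``, ``"PCaa 34:2"``,
    ``"lysoPC a C18:1"``, ``"lyso-PC C18:1"``, ``"PE ae C38:4"``,
    ``"TAG 52:2"`` and carnitine names ``"C0"``, ``"C2"``, ``"C03 OH"``,
    ``"C18:1"``.  Raises :class:`LipidNameError` naming the offending
    token on malformed input.
    """
    if not isinstance(name, str) or not name.strip():
        raise LipidNameError("empty lipid name")
    text = " ".join(name.split())

    for pattern, cls in _CLASS_PATTERNS:
        m = pattern.match(text)
        if m is None:
            continue
        rest = text[m.end():].strip()
        comp = _COMPOSITION_RE.fullmatch(rest)
        if comp is None:
            raise LipidNameError(
                f"malformed composition {rest!r} in {name!r} "
                "(expected C<carbons>:<double bonds>)"
            )
        return LipidSpecies(cls, int(comp.group(1)), int(comp.group(2)))

    m = _CARNITINE_RE.fullmatch(text)
    if m is not None:
        carbons = int(m.group(1))
        db = int(m.group(2)) if m.group(2) is not None else 0
        return LipidSpecies(LipidClass.CAR, carbons, db, m.group(3) is not None)

    token = text.split(" C")[0] if " C" in text else text.split(":")[0]
    raise LipidNameError(f"unknown lipid class token {token!r} in {name!r}")


def saturation_category(species: LipidSpecies) -> SaturationCategory:
    """SFA / MUFA / PUFA assignment from the total double-bond count.

    Carnitines are categorized by :func:`carnitine_category` instead.
    """
    if species.lipid_class is LipidClass.CAR:
        raise LipidNameError(
            "saturation categories are not defined for carnitines; "
            "use carnitine_category"
        )
    if species.double_bonds == 0:
        return SaturationCategory.SFA
    if species.double_bonds == 1:
        return SaturationCategory.MUFA
    return SaturationCategory.PUFA


def _default_bins() -> dict[LipidClass, tuple[int, int]]:
    return {
        LipidClass.PC_AA: (32, 36),
        LipidClass.PC_AE: (32, 36),
        LipidClass.PE_AA: (32, 36),
        LipidClass.PE_AE: (32, 36),
        LipidClass.LPC: (16, 20),
        LipidClass.LPE: (16, 20),
    }


@dataclass(frozen=True)
class ChainLengthBins:
    """Inclusive medium-chain carbon windows per class.

    Defaults: C32–C36 for diacyl/plasmalogen PC and PE, C16–C20 for lyso
    species.  Classes absent from ``bins`` (carnitines, TAG) have no
    chain-length categories.
    """

    bins: dict[LipidClass, tuple[int, int]] = field(default_factory=_default_bins)

    def __post_init__(self) -> None:
        for cls, (lo, hi) in self.bins.items():
            if lo > hi:
                raise ValueError(f"bin for {cls.value} has medium_min > medium_max")

    def applicable(self, lipid_class: LipidClass) -> bool:
        return lipid_class in self.bins


def chain_length_category(
    species: LipidSpecies, bins: ChainLengthBins | None = None
) -> ChainLength:
    """SHORT / MEDIUM / LONG by total carbons against the class bin."""
    bins = bins if bins is not None else ChainLengthBins()
    if not bins.applicable(species.lipid_class):
        raise LipidNameError(
            f"no chain-length bins defined for class {species.lipid_class.value}"
        )
    lo, hi = bins.bins[species.lipid_class]
    if species.total_carbons < lo:
        return ChainLength.SHORT
    if species.total_carbons > hi:
        return ChainLength.LONG
    return ChainLength.MEDIUM


def carnitine_category(species: LipidSpecies) -> CarnitineCategory:
    """FREE (C0) / ACETYL (C2) / ACYL (C3 and longer)."""
    if species.lipid_class is not LipidClass.CAR:
        raise LipidNameError(
            f"carnitine categories are not defined for {species.lipid_class.value}"
        )
    if species.total_carbons == 0:
        return CarnitineCategory.FREE
    if species.total_carbons == 2:
        return CarnitineCategory.ACETYL
    return CarnitineCategory.ACYL
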
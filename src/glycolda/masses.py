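"""Composition grammar and monoisotopic mass arithmetic for AA-labeled N-glycans.

Glycan compositions are written in the compact letter/digit shorthand used
throughout serum-glycomics work: ``N`` = HexNAc (GlcNAc), ``H`` = hexose
(mannose/galactose), ``S`` = NeuAc (sialic acid), ``F`` = deoxyhexose
(fucose).  A digit after a letter gives the residue count; a missing digit
means one (``N4H5SF`` = 4 HexNAc, 5 Hex, 1 NeuAc, 1 Fuc).  ``G`` (galactose)
is accepted on input and folded into the hexose count.

Glycans here carry an anthranilic-acid (2-aminobenzoic acid, AA) tag at the
reducing end, attached by reductive amination; the net mass increment is
+121.05276 Da (AA − H2O + H2).  Ions are negative-mode deprotonated species
[M − zH]^z− ; m/z is computed by subtracting one hydrogen atom per charge
(1.007825 Da; the electron mass, 0.00055 Da, is below the 0.01-Da precision
at which values are reported).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from types import MappingProxyType

__all__ = [
    "RESIDUE_MASSES",
    "WATER",
    "HYDROGEN",
    "PROTON",
    "CO2",
    "AA_LABEL",
    "CROSS_RING_C2H4O2",
    "GlycanComposition",
    "IonSpec",
    "CompositionError",
    "parse_composition",
    "format_composition",
    "neutral_mass",
    "mz",
    "round_half_away",
]

#: Monoisotopic residue masses (glycosidic residues, i.e. monosaccharide − H2O), Da.
RESIDUE_MASSES = MappingProxyType(
    {
        "N": 203.07937,  # HexNAc
        "H": 162.05282,  # Hex
        "S": 291.09542,  # NeuAc
        "F": 146.05791,  # dHex / fucose
    }
)

WATER = 18.01056
#: H-atom mass used for deprotonation ([M − zH]^z−); see module docstring.
HYDROGEN = 1.007825
#: Bare-proton mass, kept for reference/conversions.
PROTON = 1.00728
CO2 = 43.98983
#: Net reducing-end increment of the anthranilic-acid label (AA − H2O + H2).
AA_LABEL = 121.05276
#: C2H4O2 remnant retained by the 0,4A2 cross-ring cleavage of a hexose.
CROSS_RING_C2H4O2 = 60.02113


class CompositionError(ValueError):
    """Raised for malformed composition strings or invalid compositions."""


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching how m/z tables are printed."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GlycanComposition:
    """Counts of monosaccharide classes, plus the reducing-end label state."""

    n_hexnac: int = 0
    n_hex: int = 0
    n_neuac: int = 0
    n_fuc: int = 0
    labeled: bool = False

    def __post_init__(self) -> None:
        for name in ("n_hexnac", "n_hex", "n_neuac", "n_fuc"):
            if getattr(self, name) < 0:
                raise CompositionError(f"{name} must be >= 0")

    @property
    def counts(self) -> dict[str, int]:
        return {"N": self.n_hexnac, "H": self.n_hex, "S": self.n_neuac, "F": self.n_fuc}

    @property
    def n_residues(self) -> int:
        return self.n_hexnac + self.n_hex + self.n_neuac + self.n_fuc

    def validate_agp(self) -> None:
        """AGP is a sialoglycoprotein: every detected glycan carries >=1 NeuAc."""
        if self.n_neuac < 1:
            raise CompositionError(
                f"{format_composition(self)!r}: AGP glycans carry at least one sialic acid"
            )

    def merge(self, other: "GlycanComposition") -> "GlycanComposition":
        """Residue-wise union (label kept if either part carries it)."""
        return GlycanComposition(
            self.n_hexnac + other.n_hexnac,
            self.n_hex + other.n_hex,
            self.n_neuac + other.n_neuac,
            self.n_fuc + other.n_fuc,
            self.labeled or other.labeled,
        )

    def subtract(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(
            self.n_hexnac - other.n_hexnac,
            self.n_hex - other.n_hex,
            self.n_neuac - other.n_neuac,
            self.n_fuc - other.n_fuc,
            self.labeled,
        )

    def __str__(self) -> str:
        return format_composition(self)


_TOKEN = re.compile(r"([A-Za-z]+?)(\d*)")
_LETTERS = {"N", "H", "S", "F", "G"}


def parse_composition(text: str, labeled: bool = False) -> GlycanComposition:
    """Parse a composition string such as ``"N4H5S2F"``.

    Letters come from {N, H, S, F, G}; a letter may appear once; an absent
    digit means a count of one.  ``G`` (galactose) increments the hexose
    count, since galactose is a hexose.
    """
    if not isinstance(text, str) or not text:
        raise CompositionError("empty composition string")
    counts: dict[str, int] = {"N": 0, "H": 0, "S": 0, "F": 0}
    seen: set[str] = set()
    pos = 0
    # Tokenize as letter(+optional digits); NG-style multi-letter runs are split
    # letter by letter, so only single known letters are accepted.
    for m in re.finditer(r"([A-Za-z])(\d*)", text):
        if m.start() != pos:
            raise CompositionError(f"unexpected token {text[pos:m.start()]!r} in {text!r}")
        pos = m.end()
        letter, digits = m.group(1), m.group(2)
        if letter not in _LETTERS:
            raise CompositionError(f"unknown residue letter {letter!r} in {text!r}")
        if letter in seen:
            raise CompositionError(f"repeated residue letter {letter!r} in {text!r}")
        seen.add(letter)
        count = int(digits) if digits else 1
        if count <= 0:
            raise CompositionError(f"count for {letter!r} must be positive in {text!r}")
        key = "H" if letter == "G" else letter
        counts[key] += count
    if pos != len(text):
        raise CompositionError(f"unexpected token {text[pos:]!r} in {text!r}")
    return GlycanComposition(counts["N"], counts["H"], counts["S"], counts["F"], labeled)


def format_composition(comp: GlycanComposition) -> str:
    """Canonical formatter: N, H, S, F order; zero counts omitted; 1 → bare letter."""
    out = []
    for letter, count in comp.counts.items():
        if count == 1:
            out.append(letter)
        elif count > 1:
            out.append(f"{letter}{count}")
    return "".join(out) if out else ""


@dataclass(frozen=True)
class IonSpec:
    """Negative-mode deprotonated ion: charge state and optional CO2 losses."""

    charge: int = 1
    n_co2_losses: int = 0
    polarity: str = "negative"

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.n_co2_losses < 0:
            raise ValueError("n_co2_losses must be >= 0")
        if self.polarity != "negative":
            raise ValueError("only negative polarity is supported")


def neutral_mass(comp: GlycanComposition) -> float:
    """Monoisotopic neutral mass: residue sum + water (+ AA label if labeled)."""
    mass = sum(count * RESIDUE_MASSES[k] for k, count in comp.counts.items())
    mass += WATER
    if comp.labeled:
        mass += AA_LABEL
    return mass


def mz(mass: float, ion: IonSpec = IonSpec()) -> float:
    """m/z of [M − zH − n·CO2]^z− for a neutral mass M."""
    if mass <= 0:
        raise ValueError("neutral mass must be positive")
    value = (mass - ion.charge * HYDROGEN - ion.n_co2_losses * CO2) / ion.charge
    if value <= 0:
        raise ValueError(f"non-physical m/z {value:.4f} for mass {mass:.4f}")
    return value
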
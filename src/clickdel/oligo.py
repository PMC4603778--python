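"""Average-mass arithmetic for modified, triazole-linked oligonucleotides.

Chemically ligated encoding tags carry 5'-azide and 3'-O-propargyl handles;
CuAAC ("click") ligation fuses an azide/alkyne pair into a 1,2,3-triazole
that replaces the usual phosphodiester backbone linkage. Cycloaddition is
atom-conserving, so the mass of a ligated product is exactly the sum of the
fragment masses; equivalently, a triazole backbone linkage weighs
``AZIDO + PROPARGYL - TERMINUS`` = +1.08 Da relative to a phosphodiester.

All masses are average (not monoisotopic), free-acid, no counterions --
the convention under which vendor-reported oligo molecular weights are
quoted. An unmodified oligo with 5'-OH and 3'-OH termini weighs the sum of
its nucleoside-monophosphate residue masses minus 61.96 Da (loss of one
HPO3, gain of one H2O).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

__all__ = [
    "Residue",
    "OligoSpec",
    "ModificationTable",
    "StallEvent",
    "DEFAULT_MODIFICATIONS",
    "residue_mass",
    "oligo_mass",
    "ligate",
    "ligate_mass",
    "product_mass_delta",
    "parse_oligo",
    "OligoParseError",
    "DA_RESIDUE_MASS",
    "TERMINUS_CORRECTION",
    "TRIAZOLE_LINKAGE_DELTA",
]

# Average masses of internal nucleoside-5'-monophosphate residues (Da).
_DEOXY_RESIDUE_MASS = {
    "A": 313.21,
    "C": 289.18,
    "G": 329.21,
    "T": 304.20,
    "U": 290.17,  # 2'-deoxyuridine (dT minus CH2)
}
_RIBO_OXYGEN = 16.00  # 2'-OH adds one oxygen

#: 5'-OH / 3'-OH terminus correction: remove one HPO3 (79.98), add H2O (18.02).
TERMINUS_CORRECTION = -61.96

#: Average mass of one deoxyadenosine residue; the unit of the +/-A artifacts.
DA_RESIDUE_MASS = 313.21


class OligoParseError(ValueError):
    """Raised when an oligo notation string cannot be parsed."""


@dataclass(frozen=True)
class Residue:
    base: str  # A, C, G, T, U
    sugar: str = "deoxy"  # "deoxy" | "ribo"

    def __post_init__(self) -> None:
        if self.base not in _DEOXY_RESIDUE_MASS:
            raise OligoParseError(f"unknown base {self.base!r}")
        if self.sugar not in ("deoxy", "ribo"):
            raise OligoParseError(f"unknown sugar {self.sugar!r}")


def residue_mass(base: str, sugar: str = "deoxy") -> float:
    """Average mass (Da) of an internal nucleotide residue."""
    try:
        m = _DEOXY_RESIDUE_MASS[base]
    except KeyError:
        raise OligoParseError(f"unknown base {base!r}") from None
    if sugar == "ribo":
        return m + _RIBO_OXYGEN
    if sugar != "deoxy":
        raise OligoParseError(f"unknown sugar {sugar!r}")
    return m


@dataclass
class ModificationTable:
    """Named terminal/internal modification mass deltas (average Da).

    Each entry carries a provenance note; deltas for which no independent
    vendor value exists are back-calculated from measured product masses of
    the reference oligo set and are flagged as such.
    """

    entries: dict[str, tuple[float, str]] = field(default_factory=dict)

    def add(self, name: str, delta: float, provenance: str) -> None:
        self.entries[_norm_mod(name)] = (float(delta), provenance)

    def delta(self, name: str) -> float:
        total = 0.0
        for part in name.split("+"):
            key = _norm_mod(part)
            if key not in self.entries:
                raise KeyError(f"unknown modification {part!r}")
            total += self.entries[key][0]
        return total

    def __contains__(self, name: str) -> bool:
        return _norm_mod(name) in self.entries

    def names(self) -> list[str]:
        return sorted(self.entries)

    def to_config(self) -> dict[str, dict[str, float | str]]:
        return {
            k: {"delta_da": v[0], "provenance": v[1]}
            for k, v in sorted(self.entries.items())
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "ModificationTable":
        t = cls()
        for k, v in cfg.items():
            t.add(k, v["delta_da"], str(v.get("provenance", "")))
        return t


def _norm_mod(name: str) -> str:
    return re.sub(r"[\s_]+", "", name).lower()


def _default_modifications() -> ModificationTable:
    t = ModificationTable()
    t.add("azido", 24.99, "5'-azide replaces the 5'-hydroxyl: -OH +N3")
    t.add("propargyl", 38.05, "3'-O-propargyl ether: +C3H2 on the 3'-OH")
    t.add(
        "propargyl-TIPS",
        194.39,
        "3'-O-propargyl with triisopropylsilyl on the terminal alkyne (+SiC9H20)",
    )
    t.add("Cy5", 533.7, "5' Cy5 phosphoramidite; consistent with measured primer masses")
    t.add("FAM", 537.5, "5' 6-FAM phosphoramidite (vendor average)")
    t.add("NH2-C6", 178.2, "5'-amino C6 phosphate linker (C6H14NO3P on the 5'-O)")
    t.add(
        "biotin-PEG4-amide",
        473.6,
        "biotin-PEG4 acid amidated onto an amino linker; back-calculated from the "
        "ligated, labelled reference product",
    )
    t.add(
        "biotin-PEG4-CONH-C6",
        178.2 + 473.6,
        "amino-C6 linker carrying a biotin-PEG4 amide label",
    )
    t.add("biotin-TEG", 661.8, "5' biotin-TEG phosphoramidite (vendor average)")
    t.add("spacerC3", 138.1, "C3 phosphate spacer (vendor average)")
    return t


DEFAULT_MODIFICATIONS = _default_modifications()

#: Mass of a triazole backbone linkage relative to a phosphodiester:
#: the azide and alkyne handles are consumed into the ring, and the two
#: fragment termini stop being termini.
TRIAZOLE_LINKAGE_DELTA = round(
    DEFAULT_MODIFICATIONS.delta("azido")
    + DEFAULT_MODIFICATIONS.delta("propargyl")
    + TERMINUS_CORRECTION,
    2,
)  # +1.08 Da


@dataclass
class OligoSpec:
    """A modified oligonucleotide.

    ``junctions`` lists 0-based residue indices i such that the backbone
    linkage between residue i and residue i+1 is a triazole (written
    ``X^tr Y`` in sequence notation, with X 5' of the junction).
    """

    residues: list[Residue]
    five_prime_mod: str | None = None
    three_prime_mod: str | None = None
    internal_mods: list[tuple[int, str]] = field(default_factory=list)
    junctions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.residues)
        if any(not (0 <= j < n - 1) for j in self.junctions):
            raise OligoParseError("junction position outside linkage range")
        if any(b >= a for a, b in zip(self.junctions[1:], self.junctions[:-1])):
            raise OligoParseError("junction positions must be strictly increasing")
        if any(not (0 <= p < n) for p, _ in self.internal_mods):
            raise OligoParseError("internal modification outside sequence bounds")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        """Plain base string (sugar and linkage annotations dropped)."""
        return "".join(r.base for r in self.residues)

    @classmethod
    def from_bases(
        cls,
        bases: str,
        five_prime_mod: str | None = None,
        three_prime_mod: str | None = None,
        junctions: Iterable[int] = (),
    ) -> "OligoSpec":
        return cls(
            residues=[Residue(b) for b in bases],
            five_prime_mod=five_prime_mod,
            three_prime_mod=three_prime_mod,
            junctions=list(junctions),
        )


def oligo_mass(spec: OligoSpec, mods: ModificationTable | None = None) -> float:
    """Average molecular weight (Da) of a modified oligo.

    Sum of residue masses, the 5'/3'-OH terminus correction, +1.08 Da per
    internal triazole linkage, plus all named modification deltas.
    """
    if not spec.residues:
        raise OligoParseError("empty oligo")
    mods = mods if mods is not None else DEFAULT_MODIFICATIONS
    total = sum(residue_mass(r.base, r.sugar) for r in spec.residues)
    total += TERMINUS_CORRECTION
    total += TRIAZOLE_LINKAGE_DELTA * len(spec.junctions)
    for name in (spec.five_prime_mod, spec.three_prime_mod):
        if name:
            total += mods.delta(name)
    for _, name in spec.internal_mods:
        total += mods.delta(name)
    return total


_ALKYNE_MODS = {"propargyl", "propargyl-tips"}


def ligate(a: OligoSpec, b: OligoSpec) -> OligoSpec:
    """CuAAC-ligate two fragments: ``a`` 3'-propargyl onto ``b`` 5'-azido.

    The azide and alkyne handles are consumed into a triazole backbone
    linkage at the new junction. The TIPS-protected alkyne must be
    deprotected first (it cannot click).
    """
    if not a.residues or not b.residues:
        raise OligoParseError("cannot ligate an empty fragment")
    three = _norm_mod(a.three_prime_mod or "")
    if three != "propargyl":
        if three == _norm_mod("propargyl-TIPS"):
            raise OligoParseError("3'-alkyne is TIPS-protected; deprotect before ligation")
        raise OligoParseError("ligation requires a 3'-propargyl on the upstream fragment")
    if _norm_mod(b.five_prime_mod or "") != "azido":
        raise OligoParseError("ligation requires a 5'-azido on the downstream fragment")
    na = len(a.residues)
    return OligoSpec(
        residues=a.residues + b.residues,
        five_prime_mod=a.five_prime_mod,
        three_prime_mod=b.three_prime_mod,
        internal_mods=a.internal_mods + [(p + na, m) for p, m in b.internal_mods],
        junctions=a.junctions + [na - 1] + [j + na for j in b.junctions],
    )


def ligate_mass(
    a: OligoSpec, b: OligoSpec, mods: ModificationTable | None = None
) -> float:
    """Mass of the CuAAC ligation product of ``a`` and ``b``.

    Cycloaddition conserves atoms, so this equals
    ``oligo_mass(a) + oligo_mass(b)``; the azido/propargyl deltas of the
    consumed handles are exactly absorbed into the new triazole linkage.
    """
    mods = mods if mods is not None else DEFAULT_MODIFICATIONS
    product = ligate(a, b)
    m = oligo_mass(product, mods)
    # internal consistency of the additivity identity
    assert abs(m - (oligo_mass(a, mods) + oligo_mass(b, mods))) < 1e-6
    return m


class StallEvent(str, Enum):
    MINUS_A = "minus_A"
    PLUS_A = "plus_A"


def product_mass_delta(event: StallEvent | str) -> float:
    """Mass delta (Da) of a stall artifact: loss or gain of one dA residue."""
    event = StallEvent(event)
    return -DA_RESIDUE_MASS if event is StallEvent.MINUS_A else DA_RESIDUE_MASS


# ---------------------------------------------------------------------------
# Notation parser
# ---------------------------------------------------------------------------

# Longest-first so composite names win over their components.
_MOD_ALIASES: dict[str, str] = {
    "biotin-peg4-conh-c6": "biotin-PEG4-CONH-C6",
    "biotin-peg4-amide": "biotin-PEG4-amide",
    "propargyl-tips": "propargyl-TIPS",
    "biotin-teg": "biotin-TEG",
    "spacerc3": "spacerC3",
    "nh2-c6": "NH2-C6",
    "azido": "azido",
    "propargyl": "propargyl",
    "cy5": "Cy5",
    "fam": "FAM",
}
_MOD_TOKENS = sorted(_MOD_ALIASES, key=len, reverse=True)


def _normalize(text: str) -> str:
    text = text.replace("′", "'").replace("’", "'")
    text = re.sub(r"[\s_]+", "", text)
    return text


def parse_oligo(text: str) -> OligoSpec:
    """Parse a vendor-style oligo notation string into an :class:`OligoSpec`.

    Accepted notation (whitespace-insensitive):

    * optional ``5'-`` prefix followed by dash-separated modification names
      (e.g. ``5'-Cy5-``, ``5'-Biotin-TEG-spacerC3-spacerC3-``);
    * bases ``A C G T U``, with ``r`` prefixing a ribose residue (``rG``);
    * ``^tr^`` (or ``^tr``) after a residue marking a triazole backbone
      linkage to the next residue;
    * optional ``-3'-<mod>`` suffix (e.g. ``-3'-Propargyl``).
    """
    s = _normalize(text)
    if not s:
        raise OligoParseError("empty oligo string")

    five_mods: list[str] = []
    if s.lower().startswith("5'-"):
        s = s[3:]
        while True:
            low = s.lower()
            for tok in _MOD_TOKENS:
                if low.startswith(tok + "-"):
                    five_mods.append(_MOD_ALIASES[tok])
                    s = s[len(tok) + 1 :]
                    break
            else:
                break

    three_mod: str | None = None
    m = re.search(r"-3'-(.+)$", s, flags=re.IGNORECASE)
    if m:
        suffix = m.group(1).lower()
        if suffix not in _MOD_ALIASES:
            raise OligoParseError(f"unknown 3' modification {m.group(1)!r}")
        three_mod = _MOD_ALIASES[suffix]
        s = s[: m.start()]

    residues: list[Residue] = []
    junctions: list[int] = []
    i = 0
    while i < len(s):
        c = s[i]
        if c == "^":
            if s[i : i + 4].lower() == "^tr^":
                step = 4
            elif s[i : i + 3].lower() == "^tr":
                step = 3
            else:
                raise OligoParseError(f"bad junction marker at position {i}")
            if not residues:
                raise OligoParseError("junction marker before any residue")
            junctions.append(len(residues) - 1)
            i += step
            continue
        if c == "r" and i + 1 < len(s) and s[i + 1].upper() in _DEOXY_RESIDUE_MASS:
            residues.append(Residue(s[i + 1].upper(), "ribo"))
            i += 2
            continue
        if c.upper() in _DEOXY_RESIDUE_MASS:
            residues.append(Residue(c.upper()))
            i += 1
            continue
        raise OligoParseError(f"unexpected character {c!r} at position {i}")

    if not residues:
        raise OligoParseError("no residues found")
    return OligoSpec(
        residues=residues,
        five_prime_mod="+".join(five_mods) if five_mods else None,
        three_prime_mod=three_mod,
        junctions=junctions,
    )
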
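"""Elemental-formula arithmetic and GIPC molecular assembly.

GIPCs (glycosyl inositol phospho ceramides) are built from a small set of
building blocks: a ceramide (long-chain base amide-linked to a fatty acyl),
an inositol-phosphate core, and a glycan chain whose composition defines the
series (series 0 = bare IPC, series A = Hex(R1)-HexA-IPC, ...).  This module
provides exact monoisotopic formula arithmetic for those blocks and the
assembly of full molecules and adduct ions.

Atomic masses and block formulas live in a versioned YAML registry
(``data/building_blocks.yaml``) so that new residues are configuration, not
code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterator, Mapping

import yaml

__all__ = [
    "ConfigError",
    "ElementalFormula",
    "BlockRegistry",
    "LcbSpec",
    "FattyAcylSpec",
    "CeramideSpec",
    "GipcComposition",
    "TheoreticalIon",
    "default_registry",
    "formula_mass",
    "ceramide_formula",
    "gipc_formula",
    "adduct_mz",
    "ADDUCTS",
]


class ConfigError(ValueError):
    """Raised for unknown elements, blocks, series or adducts."""


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Integer element counts with an exact monoisotopic mass.

    Counts may be negative in transient deltas (e.g. the NH-for-O swap of an
    amine R1 substituent); :meth:`validate` asserts non-negativity for stored
    molecular formulas.  Arithmetic is commutative and associative.
    """

    counts: tuple[tuple[str, int], ...] = ()

    @classmethod
    def from_dict(cls, counts: Mapping[str, int]) -> "ElementalFormula":
        items = tuple(sorted((el, int(n)) for el, n in counts.items() if n != 0))
        return cls(items)

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-style formula string such as ``C6H10O5``."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_RE.finditer(text):
            if match.start() != pos:
                raise ConfigError(f"cannot parse formula {text!r} at position {pos}")
            pos = match.end()
            el, num = match.group(1), match.group(2)
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        if pos != len(text):
            raise ConfigError(f"cannot parse formula {text!r} at position {pos}")
        return cls.from_dict(counts)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        out = self.as_dict()
        for el, n in other.counts:
            out[el] = out.get(el, 0) + n
        return ElementalFormula.from_dict(out)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        out = self.as_dict()
        for el, n in other.counts:
            out[el] = out.get(el, 0) - n
        return ElementalFormula.from_dict(out)

    def __mul__(self, k: int) -> "ElementalFormula":
        return ElementalFormula.from_dict({el: n * k for el, n in self.counts})

    __rmul__ = __mul__

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.counts)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def validate(self, context: str = "formula") -> "ElementalFormula":
        for el, n in self.counts:
            if n < 0:
                raise ValueError(f"{context}: negative count {el}{n}")
        return self

    def hill(self) -> str:
        """Hill-notation string (C, H, then alphabetical)."""
        d = self.as_dict()
        parts = []
        for el in ["C", "H"] + sorted(k for k in d if k not in ("C", "H")):
            n = d.get(el, 0)
            if n == 0:
                continue
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts) or "(empty)"


@dataclass(frozen=True)
class BlockRegistry:
    """Atomic masses, named building blocks and R1 substituent deltas."""

    atomic_masses: Mapping[str, float]
    proton: float
    electron: float
    blocks: Mapping[str, ElementalFormula]
    r1_deltas: Mapping[str, ElementalFormula]

    @classmethod
    def from_config(cls, cfg: Mapping) -> "BlockRegistry":
        blocks = {}
        for name, spec in cfg["blocks"].items():
            if name in blocks:
                raise ConfigError(f"duplicate block {name!r}")
            f = spec["formula"]
            blocks[name] = (
                ElementalFormula.parse(f) if isinstance(f, str) else ElementalFormula.from_dict(f)
            )
        r1 = {
            name: ElementalFormula.from_dict(delta or {})
            for name, delta in cfg.get("r1_deltas", {}).items()
        }
        return cls(
            atomic_masses=dict(cfg["atomic_masses"]),
            proton=float(cfg["particles"]["proton"]),
            electron=float(cfg["particles"]["electron"]),
            blocks=blocks,
            r1_deltas=r1,
        )

    def mass(self, f: ElementalFormula) -> float:
        total = 0.0
        for el, n in f.counts:
            try:
                total += self.atomic_masses[el] * n
            except KeyError:
                raise ConfigError(f"unknown element {el!r}") from None
        return total

    def block(self, name: str) -> ElementalFormula:
        try:
            return self.blocks[name]
        except KeyError:
            raise ConfigError(f"unknown building block {name!r}") from None

    def r1_delta(self, r1: str) -> ElementalFormula:
        try:
            return self.r1_deltas[r1]
        except KeyError:
            raise ConfigError(f"unknown R1 substituent {r1!r}") from None


@lru_cache(maxsize=1)
def default_registry() -> BlockRegistry:
    text = resources.files("gipctools.data").joinpath("building_blocks.yaml").read_text()
    return BlockRegistry.from_config(yaml.safe_load(text))


def formula_mass(f: ElementalFormula, registry: BlockRegistry | None = None) -> float:
    """Monoisotopic mass of a formula in Da (reproducible to >= 6 decimals)."""
    return (registry or default_registry()).mass(f)


# ---------------------------------------------------------------------------
# Ceramide building blocks
# ---------------------------------------------------------------------------

_HYDROXYL_CLASS = {2: "d", 3: "t", 4: "q"}
_CLASS_HYDROXYLS = {v: k for k, v in _HYDROXYL_CLASS.items()}


@dataclass(frozen=True)
class LcbSpec:
    """A sphingoid long-chain base: C<carbons> amino-polyol with the stated
    number of double bonds and hydroxyls (2 = d, 3 = t, 4 = q)."""

    carbons: int
    double_bonds: int
    hydroxyls: int

    def __post_init__(self) -> None:
        if self.carbons < 12:
            raise ValueError(f"LCB carbons must be >= 12, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError("LCB double bonds must be >= 0")
        if self.hydroxyls not in _HYDROXYL_CLASS:
            raise ValueError(f"LCB hydroxyls must be 2, 3 or 4, got {self.hydroxyls}")

    @classmethod
    def parse(cls, name: str) -> "LcbSpec":
        m = re.fullmatch(r"([dtq])(\d+):(\d+)", name)
        if not m:
            raise ValueError(f"cannot parse LCB name {name!r}")
        return cls(int(m.group(2)), int(m.group(3)), _CLASS_HYDROXYLS[m.group(1)])

    @property
    def name(self) -> str:
        return f"{_HYDROXYL_CLASS[self.hydroxyls]}{self.carbons}:{self.double_bonds}"

    def formula(self) -> ElementalFormula:
        # amino-polyol: C_n H_(2n+3-2db) N O_h  (sphinganine d18:0 = C18H39NO2)
        h = 2 * self.carbons + 3 - 2 * self.double_bonds
        if h < 0:
            raise ValueError(f"impossible LCB {self.name}: negative hydrogen count")
        return ElementalFormula.from_dict(
            {"C": self.carbons, "H": h, "N": 1, "O": self.hydroxyls}
        )


@dataclass(frozen=True)
class FattyAcylSpec:
    """A fatty acid, optionally alpha-hydroxylated (h prefix; n = plain)."""

    carbons: int
    double_bonds: int
    hydroxylated: bool = False

    def __post_init__(self) -> None:
        if self.carbons < 12:
            raise ValueError(f"fatty acyl carbons must be >= 12, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError("fatty acyl double bonds must be >= 0")

    @classmethod
    def parse(cls, name: str) -> "FattyAcylSpec":
        m = re.fullmatch(r"([hn]?)(\d+):(\d+)", name)
        if not m:
            raise ValueError(f"cannot parse fatty acyl name {name!r}")
        return cls(int(m.group(2)), int(m.group(3)), m.group(1) == "h")

    @property
    def name(self) -> str:
        return f"{'h' if self.hydroxylated else 'n'}{self.carbons}:{self.double_bonds}"

    def formula(self) -> ElementalFormula:
        # free acid: C_n H_(2n-2db) O_2 (+O if hydroxylated)
        h = 2 * self.carbons - 2 * self.double_bonds
        if h < 0:
            raise ValueError(f"impossible fatty acyl {self.name}: negative hydrogen count")
        return ElementalFormula.from_dict(
            {"C": self.carbons, "H": h, "O": 2 + (1 if self.hydroxylated else 0)}
        )


@dataclass(frozen=True)
class CeramideSpec:
    """Either a resolved LCB/FA pair or a sum-level (class, C, DB) description.

    The resolved form reduces to the sum form with carbons and double bonds
    added and hydroxyl count = LCB hydroxyls + (1 if the acyl is hydroxylated),
    so e.g. t18:1/h24:0 and q42:1 denote the same elemental composition.
    """

    lcb: LcbSpec | None = None
    fa: FattyAcylSpec | None = None
    sum_carbons: int | None = None
    sum_double_bonds: int | None = None
    sum_hydroxyls: int | None = None

    @classmethod
    def resolved(cls, lcb: LcbSpec | str, fa: FattyAcylSpec | str) -> "CeramideSpec":
        if isinstance(lcb, str):
            lcb = LcbSpec.parse(lcb)
        if isinstance(fa, str):
            fa = FattyAcylSpec.parse(fa)
        return cls(lcb=lcb, fa=fa)

    @classmethod
    def sum_level(cls, hydroxyl_class: str, carbons: int, double_bonds: int) -> "CeramideSpec":
        return cls(
            sum_carbons=carbons,
            sum_double_bonds=double_bonds,
            sum_hydroxyls=_CLASS_HYDROXYLS[hydroxyl_class],
        )

    @property
    def is_resolved(self) -> bool:
        return self.lcb is not None

    @property
    def carbons(self) -> int:
        return self.lcb.carbons + self.fa.carbons if self.is_resolved else self.sum_carbons

    @property
    def double_bonds(self) -> int:
        if self.is_resolved:
            return self.lcb.double_bonds + self.fa.double_bonds
        return self.sum_double_bonds

    @property
    def hydroxyls(self) -> int:
        if self.is_resolved:
            return self.lcb.hydroxyls + (1 if self.fa.hydroxylated else 0)
        return self.sum_hydroxyls

    @property
    def hydroxyl_class(self) -> str:
        return _HYDROXYL_CLASS[self.hydroxyls]

    @property
    def sum_name(self) -> str:
        return f"{self.hydroxyl_class}{self.carbons}:{self.double_bonds}"

    @property
    def name(self) -> str:
        if self.is_resolved:
            return f"{self.lcb.name}/{self.fa.name}"
        return self.sum_name

    def to_sum_level(self) -> "CeramideSpec":
        return CeramideSpec.sum_level(self.hydroxyl_class, self.carbons, self.double_bonds)


def ceramide_formula(c: CeramideSpec) -> ElementalFormula:
    """Elemental formula of a ceramide: C_X H_(2X+1-2Y) N O_(hydroxyls+1).

    A resolved spec assembles as LCB + fatty acid - H2O (amide condensation)
    and is identical to the equivalent sum-level formula.
    """
    x, y, oh = c.carbons, c.double_bonds, c.hydroxyls
    h = 2 * x + 1 - 2 * y
    if h < 0:
        raise ValueError(f"impossible ceramide {c.name}: negative hydrogen count")
    return ElementalFormula.from_dict({"C": x, "H": h, "N": 1, "O": oh + 1}).validate(
        f"ceramide {c.name}"
    )


# ---------------------------------------------------------------------------
# Full GIPC assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GipcComposition:
    """A candidate GIPC: glycan series + terminal-hexose substituent R1 +
    ceramide.  ``residues`` is the series' glycan chain (core-proximal first);
    ``r1`` is None for series without an R1-bearing terminal residue."""

    series: str
    residues: tuple[str, ...]
    r1: str | None
    ceramide: CeramideSpec

    @property
    def name(self) -> str:
        head = self.series if self.r1 is None else f"{self.series}-{self.r1}"
        return f"{head}-{self.ceramide.name}"

    @property
    def sum_name(self) -> str:
        head = self.series if self.r1 is None else f"{self.series}-{self.r1}"
        return f"{head}-{self.ceramide.sum_name}"

    def to_sum_level(self) -> "GipcComposition":
        return GipcComposition(self.series, self.residues, self.r1, self.ceramide.to_sum_level())


def gipc_formula(
    comp: GipcComposition, registry: BlockRegistry | None = None
) -> ElementalFormula:
    """Neutral molecular formula: ceramide + HPO3 + inositol - H2O
    + glycan residues + R1 delta on the terminal hexose."""
    reg = registry or default_registry()
    f = (
        ceramide_formula(comp.ceramide)
        + reg.block("HPO3")
        + reg.block("inositol")
        - reg.block("H2O")
    )
    for res in comp.residues:
        f = f + reg.block(res)
    if comp.r1 is not None:
        f = f + reg.r1_delta(comp.r1)
    return f.validate(f"GIPC {comp.name}")


# ---------------------------------------------------------------------------
# Adducts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TheoreticalIon:
    """A predicted ion: name (adduct or fragment), m/z, polarity ('+'/'-')."""

    name: str
    mz: float
    polarity: str
    formula: ElementalFormula | None = None
    tags: tuple[str, ...] = field(default_factory=tuple)


ADDUCTS = ("[M+H]+", "[M+Na]+", "[M-H]-")


def adduct_mz(
    f: ElementalFormula, adduct: str, registry: BlockRegistry | None = None
) -> TheoreticalIon:
    """m/z of a singly charged adduct of the neutral formula ``f``."""
    reg = registry or default_registry()
    neutral = reg.mass(f)
    if adduct == "[M+H]+":
        return TheoreticalIon(adduct, neutral + reg.proton, "+", f)
    if adduct == "[M+Na]+":
        na = reg.atomic_masses["Na"] - reg.electron
        return TheoreticalIon(adduct, neutral + na, "+", f)
    if adduct == "[M-H]-":
        return TheoreticalIon(adduct, neutral - reg.proton, "-", f)
    raise ConfigError(f"unsupported adduct {adduct!r}; supported: {ADDUCTS}")
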
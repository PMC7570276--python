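"""Enumeration of GIPC candidate spaces and mass-list / inclusion-list export.

The default space reproduces the precursor lists used for targeted ddMS2
acquisition: LCBs {d18:0, d18:1, d18:2, t18:0, t18:1} crossed with fatty
acyls h15:0-h26:0, h15:1-h26:1 and n20:0-n28:0, each head-group series with
R1 in {OH, NH2, NAc} on the terminal hexose.  t18:2 is available behind an
opt-in flag (proposed but unconfirmed LCB).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .chem import (
    ADDUCTS,
    BlockRegistry,
    CeramideSpec,
    ConfigError,
    FattyAcylSpec,
    GipcComposition,
    LcbSpec,
    adduct_mz,
    default_registry,
    gipc_formula,
)

__all__ = [
    "SeriesDefinition",
    "SeriesTable",
    "CompositionSpace",
    "MassListEntry",
    "default_series_table",
    "default_lcbs",
    "default_fatty_acyls",
    "enumerate_space",
    "mass_list_frame",
    "export_mass_list",
    "export_inclusion_list",
]


@dataclass(frozen=True)
class SeriesDefinition:
    """A glycan series: ordered residue names beyond the inositol-phosphate
    core (core-proximal first) and whether the terminal residue carries R1."""

    series_id: str
    residues: tuple[str, ...]
    r1_terminal: bool


class SeriesTable:
    def __init__(self, definitions: Sequence[SeriesDefinition]):
        self._table = {}
        for d in definitions:
            if d.series_id in self._table:
                raise ConfigError(f"duplicate series {d.series_id!r}")
            self._table[d.series_id] = d

    @classmethod
    def from_config(cls, cfg: dict) -> "SeriesTable":
        defs = [
            SeriesDefinition(sid, tuple(spec.get("residues", [])), bool(spec.get("r1_terminal")))
            for sid, spec in cfg["series"].items()
        ]
        return cls(defs)

    def get(self, series_id: str) -> SeriesDefinition:
        try:
            return self._table[series_id]
        except KeyError:
            raise ConfigError(
                f"series {series_id!r} is not defined; defined series: "
                f"{sorted(self._table)}"
            ) from None

    def __contains__(self, series_id: str) -> bool:
        return series_id in self._table

    def ids(self) -> list[str]:
        return list(self._table)


@lru_cache(maxsize=1)
def default_series_table() -> SeriesTable:
    text = resources.files("gipctools.data").joinpath("series.yaml").read_text()
    return SeriesTable.from_config(yaml.safe_load(text))


def default_lcbs(include_t18_2: bool = False) -> list[LcbSpec]:
    names = ["d18:0", "d18:1", "d18:2", "t18:0", "t18:1"]
    if include_t18_2:
        names.append("t18:2")
    return [LcbSpec.parse(n) for n in names]


def default_fatty_acyls() -> list[FattyAcylSpec]:
    """h15:0-h26:0, h15:1-h26:1 and n20:0-n28:0 (33 acyls)."""
    fas = [FattyAcylSpec(c, db, True) for db in (0, 1) for c in range(15, 27)]
    fas += [FattyAcylSpec(c, 0, False) for c in range(20, 29)]
    return fas


@dataclass(frozen=True)
class CompositionSpace:
    """The candidate space: series x R1 x LCB x FA x adduct."""

    series: tuple[str, ...] = ("A",)
    r1: tuple[str, ...] = ("OH", "NH2", "NAc")
    lcbs: tuple[LcbSpec, ...] = field(default_factory=lambda: tuple(default_lcbs()))
    fas: tuple[FattyAcylSpec, ...] = field(default_factory=lambda: tuple(default_fatty_acyls()))
    adducts: tuple[str, ...] = ADDUCTS


@dataclass(frozen=True)
class MassListEntry:
    composition: GipcComposition
    adduct: str
    mz: float
    polarity: str

    @property
    def name(self) -> str:
        return self.composition.name

    @property
    def sum_name(self) -> str:
        return self.composition.sum_name


def enumerate_space(
    space: CompositionSpace,
    series_table: SeriesTable | None = None,
    registry: BlockRegistry | None = None,
) -> list[MassListEntry]:
    """One entry per (series, R1, LCB, FA, adduct), deduplicated on exact
    (name, formula, adduct) and sorted by series, R1, m/z, name.

    For series without an R1-bearing terminal residue the R1 axis collapses:
    the same candidates would repeat for every R1, so they are emitted once
    with ``r1=None``.
    """
    table = series_table or default_series_table()
    reg = registry or default_registry()
    missing = [s for s in space.series if s not in table]
    if missing:
        raise ConfigError(f"undefined series in space: {missing}")

    entries: dict[tuple[str, str], MassListEntry] = {}
    for sid in space.series:
        sdef = table.get(sid)
        r1_choices = space.r1 if sdef.r1_terminal else (None,)
        for r1 in r1_choices:
            for lcb in space.lcbs:
                for fa in space.fas:
                    comp = GipcComposition(
                        sid, sdef.residues, r1, CeramideSpec.resolved(lcb, fa)
                    )
                    f = gipc_formula(comp, reg)
                    for adduct in space.adducts:
                        ion = adduct_mz(f, adduct, reg)
                        key = (comp.name, adduct)
                        entries.setdefault(key, MassListEntry(comp, adduct, ion.mz, ion.polarity))

    r1_order = {r1: i for i, r1 in enumerate(("OH", "NH2", "NAc"))}
    return sorted(
        entries.values(),
        key=lambda e: (
            e.composition.series,
            r1_order.get(e.composition.r1, 99),
            e.mz,
            e.name,
            e.adduct,
        ),
    )


def mass_list_frame(entries: Sequence[MassListEntry]) -> pd.DataFrame:
    from .chem import gipc_formula as _gf  # local to avoid cycle at import time

    rows = [
        {
            "name": e.name,
            "sum_name": e.sum_name,
            "formula": _gf(e.composition).hill(),
            "adduct": e.adduct,
            "mz": round(e.mz, 6),
            "polarity": e.polarity,
        }
        for e in entries
    ]
    return pd.DataFrame(rows, columns=["name", "sum_name", "formula", "adduct", "mz", "polarity"])


def export_mass_list(entries: Sequence[MassListEntry], path: str | Path) -> None:
    mass_list_frame(entries).to_csv(path, index=False, float_format="%.6f")


def export_inclusion_list(
    entries: Sequence[MassListEntry],
    path: str | Path,
    mz_min: float = 500.0,
    mz_max: float = 3000.0,
) -> int:
    """Instrument-ready two-column inclusion list (mz, polarity), one polarity
    per file, restricted to the acquisition window (default 500-3000 m/z).

    Returns the number of rows written; warns (and writes a header-only file)
    when the window excludes everything.
    """
    if not mz_min < mz_max:
        raise ValueError(f"mz_min must be < mz_max, got {mz_min} >= {mz_max}")
    polarities = {e.polarity for e in entries}
    if len(polarities) > 1:
        raise ValueError(
            "inclusion list must contain a single polarity; got entries for "
            + " and ".join(sorted(polarities))
        )
    kept = sorted(
        {round(e.mz, 6) for e in entries if mz_min <= e.mz <= mz_max}
    )
    polarity = next(iter(polarities)) if polarities else ""
    df = pd.DataFrame({"mz": kept, "polarity": [polarity] * len(kept)})
    if not kept:
        warnings.warn(f"inclusion-list window [{mz_min}, {mz_max}] excludes all entries")
    df.to_csv(path, index=False, float_format="%.6f")
    return len(kept)
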
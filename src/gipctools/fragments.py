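"""Diagnostic fragment prediction for GIPC candidates.

Fragment recipes are declarative (building-block sums, neutral losses, an
ionization step) and live in the rule-set config, so new fragments are
configuration.  Three context tokens resolve against the candidate:

* ``GLYCAN_HEAD`` — glycan residues + inositol + HPO3 + R1 delta (the C3PO3
  head fragment family; R1-dependent, hence 597/596/638 for OH/NH2/NAc).
* ``CERAMIDE``    — the ceramide formula (Z0 / Z0PO3 / Y1 family).
* ``LCB``         — the long-chain base (positive-mode W series; requires a
  resolved ceramide).  Trihydroxylated bases yield three W ions (W, W-H2O,
  W-2H2O), dihydroxylated bases only two — the basis for LCB discrimination.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping

import yaml

from .chem import (
    BlockRegistry,
    ConfigError,
    ElementalFormula,
    GipcComposition,
    TheoreticalIon,
    ceramide_formula,
    default_registry,
)

__all__ = [
    "FragmentRecipe",
    "PredictedFragments",
    "default_recipes",
    "load_recipes",
    "predict_fragments",
    "fragment_mz",
]

_CONTEXT_TOKENS = {"GLYCAN_HEAD", "CERAMIDE", "LCB"}
_GATES = {"r1_bearing", "resolved_lcb", "trihydroxy_lcb"}


@dataclass(frozen=True)
class FragmentRecipe:
    """How to build one named fragment ion for a candidate."""

    name: str
    polarity: str  # '+' or '-'
    components: tuple[str, ...]
    losses: tuple[str, ...] = ()
    ionize: str = "-H"
    requires: str | None = None

    @property
    def tags(self) -> tuple[str, ...]:
        tags = []
        # losing the R1-substituted terminal hexose cancels the head's R1 term
        if ("GLYCAN_HEAD" in self.components) != ("TERMINAL_HEXOSE" in self.losses):
            tags.append("r1_dependent")
        if "LCB" in self.components:
            tags.append("lcb_dependent")
        if "CERAMIDE" in self.components:
            tags.append("ceramide_dependent")
        return tuple(tags)


def _parse_recipes(cfg: Mapping) -> dict[str, dict[str, FragmentRecipe]]:
    out: dict[str, dict[str, FragmentRecipe]] = {"+": {}, "-": {}}
    pol_map = {"positive": "+", "negative": "-"}
    for pol_name, recipes in cfg.items():
        pol = pol_map[pol_name]
        for name, spec in recipes.items():
            requires = spec.get("requires")
            if requires is not None and requires not in _GATES:
                raise ConfigError(f"fragment {name!r}: unknown gate {requires!r}")
            out[pol][name] = FragmentRecipe(
                name=name,
                polarity=pol,
                components=tuple(spec["components"]),
                losses=tuple(spec.get("losses", ())),
                ionize=spec.get("ionize", "-H" if pol == "-" else "+H"),
                requires=requires,
            )
    return out


def load_recipes(path_or_cfg) -> dict[str, dict[str, FragmentRecipe]]:
    if isinstance(path_or_cfg, Mapping):
        cfg = path_or_cfg
    else:
        with open(path_or_cfg) as fh:
            cfg = yaml.safe_load(fh)
    return _parse_recipes(cfg["fragments"] if "fragments" in cfg else cfg)


@lru_cache(maxsize=1)
def default_recipes() -> dict[str, dict[str, FragmentRecipe]]:
    text = resources.files("gipctools.data").joinpath("rules_a.yaml").read_text()
    return _parse_recipes(yaml.safe_load(text)["fragments"])


def _glycan_head_formula(comp: GipcComposition, reg: BlockRegistry) -> ElementalFormula:
    f = reg.block("inositol") + reg.block("HPO3")
    for res in comp.residues:
        f = f + reg.block(res)
    if comp.r1 is not None:
        f = f + reg.r1_delta(comp.r1)
    return f


def _recipe_formula(
    recipe: FragmentRecipe, comp: GipcComposition, reg: BlockRegistry
) -> ElementalFormula:
    f = ElementalFormula()
    for token in recipe.components:
        if token == "GLYCAN_HEAD":
            f = f + _glycan_head_formula(comp, reg)
        elif token == "CERAMIDE":
            f = f + ceramide_formula(comp.ceramide)
        elif token == "LCB":
            f = f + comp.ceramide.lcb.formula()
        else:
            f = f + reg.block(token)
    for token in recipe.losses:
        if token == "TERMINAL_HEXOSE":
            loss = reg.block("Hexose")
            if comp.r1 is not None:
                loss = loss + reg.r1_delta(comp.r1)
            f = f - loss
        else:
            f = f - reg.block(token)
    return f.validate(f"fragment {recipe.name} of {comp.name}")


def _ionize(neutral_mass: float, ionize: str, reg: BlockRegistry) -> float:
    if ionize == "-H":
        return neutral_mass - reg.proton
    if ionize == "+H":
        return neutral_mass + reg.proton
    if ionize == "+Na":
        return neutral_mass + reg.atomic_masses["Na"] - reg.electron
    raise ConfigError(f"unknown ionization {ionize!r}")


def _gate(recipe: FragmentRecipe, comp: GipcComposition) -> str:
    """'predict', 'omit' (evidence unavailable at this resolution) or 'skip'
    (fragment does not exist for this candidate)."""
    if recipe.requires == "r1_bearing":
        return "predict" if comp.r1 is not None else "skip"
    if recipe.requires == "resolved_lcb":
        return "predict" if comp.ceramide.is_resolved else "omit"
    if recipe.requires == "trihydroxy_lcb":
        if not comp.ceramide.is_resolved:
            return "omit"
        return "predict" if comp.ceramide.lcb.hydroxyls >= 3 else "skip"
    return "predict"


@dataclass(frozen=True)
class PredictedFragments:
    """Predicted ions plus the names omitted because the ceramide was not
    resolved to LCB/FA level (absence of evidence, not an error)."""

    ions: tuple[TheoreticalIon, ...]
    omitted: tuple[str, ...]

    def by_name(self) -> dict[str, TheoreticalIon]:
        return {ion.name: ion for ion in self.ions}


def predict_fragments(
    comp: GipcComposition,
    polarity: str,
    recipes: Mapping[str, Mapping[str, FragmentRecipe]] | None = None,
    registry: BlockRegistry | None = None,
) -> PredictedFragments:
    """All diagnostic fragments of ``comp`` for one polarity ('+' or '-')."""
    if polarity not in ("+", "-"):
        raise ValueError(f"polarity must be '+' or '-', got {polarity!r}")
    reg = registry or default_registry()
    table = (recipes or default_recipes())[polarity]
    ions, omitted = [], []
    for recipe in table.values():
        verdict = _gate(recipe, comp)
        if verdict == "skip":
            continue
        if verdict == "omit":
            omitted.append(recipe.name)
            continue
        f = _recipe_formula(recipe, comp, reg)
        mz = _ionize(reg.mass(f), recipe.ionize, reg)
        ions.append(TheoreticalIon(recipe.name, mz, polarity, f, recipe.tags))
    return PredictedFragments(tuple(ions), tuple(omitted))


def fragment_mz(
    name: str,
    comp: GipcComposition,
    polarity: str | None = None,
    recipes: Mapping[str, Mapping[str, FragmentRecipe]] | None = None,
    registry: BlockRegistry | None = None,
) -> float:
    """Exact m/z of one named fragment for a candidate."""
    reg = registry or default_registry()
    table = recipes or default_recipes()
    pols = [polarity] if polarity else ["-", "+"]
    for pol in pols:
        recipe = table[pol].get(name)
        if recipe is None:
            continue
        if _gate(recipe, comp) != "predict":
            raise ConfigError(f"fragment {name!r} is not defined for candidate {comp.name}")
        f = _recipe_formula(recipe, comp, reg)
        return _ionize(reg.mass(f), recipe.ionize, reg)
    raise ConfigError(f"unknown fragment name {name!r}")
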
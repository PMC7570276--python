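"""Internal-standard and dry-weight normalized relative quantification.

No GIPC standards are commercially available, so quantification is relative:
each species' MS1 area is divided by the internal-standard area (a lactosyl
ceramide spiked before extraction) and the sample dry weight, giving a
normalized ratio per gram dry weight.  Ratios are averaged over the
IS-spiked replicates of each group; the deliberately unspiked replicate
(used to verify the IS is absent from the sample itself) is excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

__all__ = ["SampleMeta", "QuantResult", "normalize", "group_average", "quantify_table"]


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: replicate group, dry weight (g), IS area."""

    sample: str
    group: str
    dry_weight: float  # g
    is_area: float
    is_spiked: bool = True

    def __post_init__(self) -> None:
        if self.dry_weight <= 0:
            raise ValueError(f"sample {self.sample!r}: dry weight must be > 0")
        if self.is_spiked and self.is_area <= 0:
            raise ValueError(f"sample {self.sample!r}: IS area must be > 0 when spiked")


@dataclass(frozen=True)
class QuantResult:
    composition: str
    group: str
    per_sample: tuple[tuple[str, float], ...]  # (sample, normalized ratio)
    mean: float
    n: int


def normalize(area: float, is_area: float, dry_weight: float) -> float:
    """Normalized ratio per g dry weight: area / (IS area x dry weight)."""
    if is_area <= 0:
        raise ValueError("IS area must be > 0")
    if dry_weight <= 0:
        raise ValueError("dry weight must be > 0")
    return area / (is_area * dry_weight)


def group_average(
    ratios: Mapping[str, float], samples: Sequence[SampleMeta], composition: str = ""
) -> list[QuantResult]:
    """Arithmetic group means over IS-spiked replicates.

    ``ratios`` maps sample id -> normalized ratio.  Samples without IS spike
    are excluded with a warning; groups with zero valid replicates are
    omitted with a warning.
    """
    meta = {s.sample: s for s in samples}
    by_group: dict[str, list[tuple[str, float]]] = {}
    for sample, ratio in ratios.items():
        m = meta.get(sample)
        if m is None:
            warnings.warn(f"sample {sample!r} missing from metadata; skipped")
            continue
        if not m.is_spiked:
            warnings.warn(f"sample {sample!r} is not IS-spiked; excluded from averaging")
            continue
        by_group.setdefault(m.group, []).append((sample, ratio))
    results = []
    for group in sorted(by_group):
        vals = by_group[group]
        if not vals:
            warnings.warn(f"group {group!r}: no valid replicates for {composition!r}; omitted")
            continue
        mean = sum(v for _, v in vals) / len(vals)
        results.append(QuantResult(composition, group, tuple(sorted(vals)), mean, len(vals)))
    return results


def quantify_table(
    areas: pd.DataFrame, samples: Sequence[SampleMeta]
) -> pd.DataFrame:
    """Long-format quantification of an area table.

    ``areas`` needs columns ``composition``, ``sample``, ``area``.  Returns a
    frame with composition, sample, ratio, group, mean, n — one row per
    (composition, spiked sample), the group mean repeated on each row.
    """
    required = {"composition", "sample", "area"}
    missing = required - set(areas.columns)
    if missing:
        raise ValueError(f"area table missing columns: {sorted(missing)}")
    meta = {s.sample: s for s in samples}
    rows = []
    for comp, sub in areas.groupby("composition", sort=True):
        ratios = {}
        for _, r in sub.iterrows():
            m = meta.get(r["sample"])
            if m is None or not m.is_spiked:
                continue
            ratios[r["sample"]] = normalize(float(r["area"]), m.is_area, m.dry_weight)
        for res in group_average(ratios, samples, composition=str(comp)):
            for sample, ratio in res.per_sample:
                rows.append(
                    {
                        "composition": comp,
                        "sample": sample,
                        "ratio": ratio,
                        "group": res.group,
                        "mean": res.mean,
                        "n": res.n,
                    }
                )
    return pd.DataFrame(rows, columns=["composition", "sample", "ratio", "group", "mean", "n"])
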
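"""Species-by-trait tables with mixed continuous/categorical typing.

The canonical trait set for lake macrophytes has five traits: life history
(annual vs. perennial, categorical), shoot height (cm), specific leaf area
(mm^2 mg^-1), leaf dry mass content (mass fraction) and flowering duration
(months, treated as continuous). Any trait table with declared per-trait
kinds is accepted; the five-trait schema is merely the default used by the
synthetic generator and the worked examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._errors import ValidationError

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"

#: Trait schema of the macrophyte study: name -> (kind, unit, levels).
DEFAULT_TRAIT_SCHEMA: dict[str, dict] = {
    "life_history": {
        "kind": CATEGORICAL,
        "unit": "class",
        "levels": ["annual", "perennial"],
    },
    "shoot_height": {"kind": CONTINUOUS, "unit": "cm"},
    "specific_leaf_area": {"kind": CONTINUOUS, "unit": "mm2/mg"},
    "leaf_dry_mass_content": {"kind": CONTINUOUS, "unit": "mass fraction"},
    "flowering_duration": {"kind": CONTINUOUS, "unit": "months"},
}


@dataclass(frozen=True)
class TraitDefinition:
    """Declaration of a single trait: its measurement kind and unit."""

    name: str
    kind: str
    unit: str = ""
    levels: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.kind not in (CONTINUOUS, CATEGORICAL):
            raise ValidationError(
                f"trait {self.name!r}: kind must be "
                f"{CONTINUOUS!r} or {CATEGORICAL!r}, got {self.kind!r}"
            )
        if self.kind == CATEGORICAL and not self.levels:
            raise ValidationError(
                f"categorical trait {self.name!r} needs a declared level set"
            )


class TraitTable:
    """Validated species x trait table.

    Parameters
    ----------
    data:
        DataFrame indexed by species label, one column per trait.
    definitions:
        Trait declarations; every column of ``data`` must be declared.

    Invariants enforced at construction: unique species labels, no missing
    values, finite continuous values, categorical values drawn from the
    declared level set.
    """

    def __init__(self, data: pd.DataFrame, definitions: Iterable[TraitDefinition]):
        defs = {d.name: d for d in definitions}
        if set(data.columns) != set(defs):
            raise ValidationError(
                "trait columns and declarations differ: "
                f"table has {sorted(data.columns)}, declared {sorted(defs)}"
            )
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate species labels: {dup}")
        if data.isna().any().any():
            bad = data.columns[data.isna().any()].tolist()
            raise ValidationError(f"missing trait values in columns {bad}")
        data = data.copy()
        data.index = data.index.astype(str)
        for d in defs.values():
            col = data[d.name]
            if d.kind == CONTINUOUS:
                vals = pd.to_numeric(col, errors="coerce")
                if vals.isna().any() or not np.isfinite(vals.to_numpy(float)).all():
                    raise ValidationError(
                        f"continuous trait {d.name!r} has non-finite values"
                    )
                data[d.name] = vals.astype(float)
            else:
                bad = set(col.astype(str)) - set(d.levels)
                if bad:
                    raise ValidationError(
                        f"categorical trait {d.name!r} has undeclared levels {sorted(bad)}"
                    )
                data[d.name] = col.astype(str)
        self._data = data
        self._defs = defs

    # -- accessors ---------------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def species(self) -> list[str]:
        return list(self._data.index)

    @property
    def n_species(self) -> int:
        return len(self._data)

    @property
    def trait_names(self) -> list[str]:
        return list(self._data.columns)

    @property
    def definitions(self) -> dict[str, TraitDefinition]:
        return dict(self._defs)

    def kind(self, trait: str) -> str:
        try:
            return self._defs[trait].kind
        except KeyError:
            raise KeyError(f"unknown trait {trait!r}") from None

    @property
    def continuous_traits(self) -> list[str]:
        return [t for t in self.trait_names if self.kind(t) == CONTINUOUS]

    @property
    def categorical_traits(self) -> list[str]:
        return [t for t in self.trait_names if self.kind(t) == CATEGORICAL]

    def values(self, trait: str) -> pd.Series:
        self.kind(trait)
        return self._data[trait]

    def __repr__(self) -> str:  # pragma: no cover
        return f"TraitTable({self.n_species} species, {len(self.trait_names)} traits)"

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path, config_path: str | Path) -> "TraitTable":
        """Load a trait table from CSV plus a YAML sidecar of declarations.

        The CSV has a ``species`` column (or the species label as first
        column); the YAML maps trait names to ``{kind, unit, levels}``.
        """
        data = pd.read_csv(path)
        first = data.columns[0]
        data = data.set_index(first if first != "species" else "species")
        with open(config_path) as fh:
            raw = yaml.safe_load(fh)
        defs = definitions_from_config(raw)
        return cls(data, defs)

    def to_csv(self, path: str | Path) -> None:
        self._data.rename_axis("species").to_csv(path)

    def config_dict(self) -> dict:
        out = {}
        for d in self._defs.values():
            entry: dict = {"kind": d.kind, "unit": d.unit}
            if d.levels:
                entry["levels"] = list(d.levels)
            out[d.name] = entry
        return {"traits": out}

    def config_to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.config_dict(), fh, sort_keys=False)


def definitions_from_config(raw: Mapping) -> list[TraitDefinition]:
    """Build trait declarations from a parsed YAML mapping."""
    traits = raw.get("traits", raw)
    defs = []
    for name, entry in traits.items():
        levels = entry.get("levels")
        defs.append(
            TraitDefinition(
                name=name,
                kind=entry["kind"],
                unit=entry.get("unit", ""),
                levels=tuple(levels) if levels else None,
            )
        )
    return defs


def default_definitions() -> list[TraitDefinition]:
    """Trait declarations for the canonical five-trait macrophyte schema."""
    return definitions_from_config({"traits": DEFAULT_TRAIT_SCHEMA})
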
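"""Community abundance matrices and the nested spatial sampling design.

The survey design is hierarchical: quadrats are pooled into plots, plots sit
in 0.5 m water-depth strata, strata in lakes, lakes in one of two regions.
`pool_to_scale` aggregates abundances (by summation, conserving totals) up
this hierarchy; `beta_groups` enumerates the sub-unit groupings used for
within-group functional beta diversity.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from ._errors import ValidationError

logger = logging.getLogger(__name__)

#: Nested spatial scales, finest to coarsest.
SCALES = ("plot", "depth", "lake", "region")

#: Hierarchy column holding the unit id of each scale.
SCALE_COLUMN = {
    "plot": "plot",
    "depth": "depth_stratum",
    "lake": "lake",
    "region": "region",
}

#: Enclosing (grouping) scale used for within-group beta diversity; the
#: coarsest scale has a single global group.
PARENT_SCALE = {"plot": "depth", "depth": "lake", "lake": "region", "region": None}


class CommunityMatrix:
    """Samples x species abundance matrix (non-negative, finite).

    All-zero sample rows are dropped at construction with a log entry;
    their labels are kept in ``dropped_samples``.
    """

    def __init__(self, data: pd.DataFrame):
        data = data.copy()
        data.index = data.index.astype(str)
        data.columns = data.columns.astype(str)
        if data.index.has_duplicates:
            raise ValidationError("duplicate sample labels in community matrix")
        if data.columns.has_duplicates:
            raise ValidationError("duplicate species labels in community matrix")
        vals = data.to_numpy(float)
        if not np.isfinite(vals).all():
            raise ValidationError("community matrix has non-finite abundances")
        if (vals < 0).any():
            raise ValidationError("community matrix has negative abundances")
        empty = data.index[vals.sum(axis=1) == 0]
        self.dropped_samples = list(empty)
        if len(empty):
            logger.warning("dropping %d all-zero sample(s): %s", len(empty), list(empty))
            data = data.drop(index=empty)
        if data.empty:
            raise ValidationError("community matrix has no non-empty samples")
        data.index.name = None
        data.columns.name = None
        self._data = data.astype(float)

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def samples(self) -> list[str]:
        return list(self._data.index)

    @property
    def species(self) -> list[str]:
        return list(self._data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def abundances(self, sample: str) -> pd.Series:
        return self._data.loc[str(sample)]

    def relative_abundances(self) -> pd.DataFrame:
        """Rows rescaled to sum to one (the weights used by all metrics)."""
        return self._data.div(self._data.sum(axis=1), axis=0)

    def richness(self) -> pd.Series:
        """Per-sample count of species with positive abundance."""
        return (self._data > 0).sum(axis=1).rename("richness")

    def __repr__(self) -> str:  # pragma: no cover
        return f"CommunityMatrix({self.shape[0]} samples x {self.shape[1]} species)"

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path) -> "CommunityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df)

    @classmethod
    def from_quadrat_csv(cls, path: str | Path, plot_column: str = "plot") -> "CommunityMatrix":
        """Load quadrat-level records, summing quadrats into their plot.

        The CSV has one row per quadrat with a ``plot`` column naming the
        containing plot; any number of quadrats per plot is accepted.
        """
        df = pd.read_csv(path)
        if plot_column not in df.columns:
            raise ValidationError(f"quadrat table needs a {plot_column!r} column")
        pooled = df.groupby(plot_column).sum(numeric_only=True)
        return cls(pooled)

    def to_csv(self, path: str | Path) -> None:
        self._data.rename_axis("sample").to_csv(path)


class SpatialHierarchy:
    """Plot -> depth stratum -> lake -> region tree with unit attributes.

    One row per plot with columns ``plot, depth_stratum, water_depth_m,
    lake, region, elevation_m``. The mapping must be a tree: a stratum
    belongs to exactly one lake and a lake to exactly one region.
    """

    REQUIRED = ["plot", "depth_stratum", "water_depth_m", "lake", "region", "elevation_m"]

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValidationError(f"hierarchy table missing columns {missing}")
        table = table[self.REQUIRED].copy()
        for c in ("plot", "depth_stratum", "lake", "region"):
            table[c] = table[c].astype(str)
        table["water_depth_m"] = table["water_depth_m"].astype(float)
        table["elevation_m"] = table["elevation_m"].astype(float)
        if table["plot"].duplicated().any():
            raise ValidationError("each plot must appear exactly once in the hierarchy")
        if (table["water_depth_m"] <= 0).any():
            raise ValidationError("water depth must be positive")
        if not np.isfinite(table["elevation_m"]).all():
            raise ValidationError("elevation must be finite")
        for child, parent in (("depth_stratum", "lake"), ("lake", "region")):
            n_parents = table.groupby(child)[parent].nunique()
            bad = n_parents[n_parents > 1]
            if len(bad):
                raise ValidationError(
                    f"hierarchy is not a tree: {child} unit(s) {list(bad.index)} "
                    f"map to multiple {parent}s"
                )
        depth_var = table.groupby("depth_stratum")["water_depth_m"].nunique()
        if (depth_var > 1).any():
            raise ValidationError("a depth stratum must have a single water depth")
        self._table = table.set_index("plot", drop=False)
        self._table.index.name = None

    @property
    def table(self) -> pd.DataFrame:
        return self._table.reset_index(drop=True)

    @property
    def plots(self) -> list[str]:
        return list(self._table.index)

    def unit_of_plot(self, scale: str) -> pd.Series:
        """Map each plot to its unit id at ``scale``."""
        col = _scale_column(scale)
        return self._table[col]

    def units(self, scale: str) -> list[str]:
        return list(pd.unique(self.unit_of_plot(scale)))

    def unit_attribute(self, scale: str, attribute: str) -> pd.Series:
        """Per-unit value of a plot-level attribute (must be constant in unit)."""
        col = _scale_column(scale)
        grouped = self._table.groupby(col)[attribute]
        if (grouped.nunique() > 1).any():
            raise ValidationError(f"{attribute!r} is not constant within {scale} units")
        return grouped.first()

    def parent_of_unit(self, scale: str) -> pd.Series:
        """Map each unit at ``scale`` to its enclosing unit (NaN-free)."""
        parent = PARENT_SCALE[_check_scale(scale)]
        if parent is None:
            raise ValidationError("region units have no enclosing scale")
        child_col, parent_col = _scale_column(scale), _scale_column(parent)
        return self._table.groupby(child_col)[parent_col].first()

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path) -> "SpatialHierarchy":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def __repr__(self) -> str:  # pragma: no cover
        t = self._table
        return (
            f"SpatialHierarchy({len(t)} plots, {t.depth_stratum.nunique()} strata, "
            f"{t.lake.nunique()} lakes, {t.region.nunique()} regions)"
        )


def _check_scale(scale: str) -> str:
    if scale not in SCALES:
        raise ValidationError(f"unknown scale {scale!r}; choose from {SCALES}")
    return scale


def _scale_column(scale: str) -> str:
    return SCALE_COLUMN[_check_scale(scale)]


def pool_to_scale(
    comm: CommunityMatrix, hier: SpatialHierarchy, scale: str
) -> CommunityMatrix:
    """Sum plot abundances into the units of a coarser scale.

    Total abundance per species is conserved exactly; output sample labels
    are the unit ids at ``scale``.
    """
    mapping = hier.unit_of_plot(scale)
    missing = [s for s in comm.samples if s not in mapping.index]
    if missing:
        raise ValidationError(f"samples missing from hierarchy: {missing[:5]}")
    groups = mapping.loc[comm.samples]
    pooled = comm.data.groupby(groups.to_numpy()).sum()
    pooled = pooled.loc[pd.unique(groups)]  # stable unit order
    return CommunityMatrix(pooled)


def richness_profile(comm: CommunityMatrix) -> tuple[pd.Series, dict]:
    """Per-sample richness plus a (min, median, max) summary."""
    r = comm.richness()
    summary = {
        "min": int(r.min()),
        "median": float(r.median()),
        "max": int(r.max()),
    }
    return r, summary


def beta_groups(hier: SpatialHierarchy, scale: str) -> dict[str, list[str]]:
    """Groups of sub-units for within-group beta diversity at ``scale``.

    At scale s the sub-units are the units of s and the groups are their
    enclosing units (plots within a stratum, strata within a lake, lakes
    within a region); at the coarsest scale the regions form one global
    group. Groups with fewer than two sub-units are skipped with a log
    entry.
    """
    _check_scale(scale)
    if PARENT_SCALE[scale] is None:
        groups = {"all": hier.units(scale)}
    else:
        parent = hier.parent_of_unit(scale)
        groups = {g: list(members.index) for g, members in parent.groupby(parent)}
    out = {}
    for g, members in groups.items():
        if len(members) < 2:
            logger.info("beta group %r has < 2 sub-units at scale %r; skipped", g, scale)
            continue
        out[g] = members
    return out
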
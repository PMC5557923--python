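"""Pairwise functional distance matrices over a species pool.

Two builders are provided: a Gower distance for categorical or mixed trait
sets (range-normalized absolute differences for continuous traits, 0/1
mismatch for categorical ones, unweighted mean across traits, bounded in
[0, 1]) and a Euclidean distance on a single z-standardized continuous
trait. Both return a :class:`TraitDistanceMatrix`, the common currency of
the dendrogram and dispersion-metric layers.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

from ._errors import NumericalError, ValidationError
from .traits import CATEGORICAL, CONTINUOUS, TraitTable

logger = logging.getLogger(__name__)


class TraitDistanceMatrix:
    """Symmetric, zero-diagonal, non-negative distance matrix with labels."""

    def __init__(
        self,
        values: np.ndarray,
        labels: Sequence[str],
        name: str = "",
        validate: bool = True,
    ):
        values = np.asarray(values, dtype=float)
        labels = [str(x) for x in labels]
        if validate:
            if values.ndim != 2 or values.shape[0] != values.shape[1]:
                raise ValidationError(f"distance matrix must be square, got {values.shape}")
            if len(labels) != values.shape[0]:
                raise ValidationError("label count does not match matrix size")
            if len(set(labels)) != len(labels):
                raise ValidationError("duplicate labels in distance matrix")
            if not np.isfinite(values).all():
                raise ValidationError("non-finite distances")
            if not np.allclose(values, values.T, atol=1e-12):
                raise ValidationError("distance matrix is not symmetric")
            if not np.allclose(np.diag(values), 0.0, atol=1e-12):
                raise ValidationError("distance matrix diagonal is not zero")
            if (values < -1e-12).any():
                raise ValidationError("negative distances")
        # exact symmetry/zero diagonal so downstream squareform is safe
        values = np.clip((values + values.T) / 2.0, 0.0, None)
        np.fill_diagonal(values, 0.0)
        self.values = values
        self.labels = labels
        self.name = name
        self._pos = {lab: i for i, lab in enumerate(labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def index_of(self, labels: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._pos[str(x)] for x in labels], dtype=int)
        except KeyError as exc:
            raise KeyError(f"label {exc.args[0]!r} not in distance matrix") from None

    def between(self, a: str, b: str) -> float:
        ia, ib = self.index_of([a, b])
        return float(self.values[ia, ib])

    def relabel(self, new_labels: Sequence[str]) -> "TraitDistanceMatrix":
        """Return the same matrix with replaced labels (taxa-shuffle core)."""
        if len(new_labels) != len(self.labels):
            raise ValidationError("relabel needs one new label per species")
        return TraitDistanceMatrix(self.values, new_labels, self.name, validate=False)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().rename_axis("species").to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, name: str = "") -> "TraitDistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(float), list(df.index.astype(str)), name=name)

    def __repr__(self) -> str:  # pragma: no cover
        return f"TraitDistanceMatrix({len(self)} species, name={self.name!r})"


def _check_pool(traits: TraitTable) -> None:
    if traits.n_species < 2:
        raise ValidationError("need at least 2 species for a distance matrix")


def gower_distance(
    traits: TraitTable, trait_subset: Sequence[str] | None = None
) -> TraitDistanceMatrix:
    """Gower distance over a subset of traits (default: all).

    Per-trait contribution for species pair (i, j): ``|x_i - x_j| / range``
    for a continuous trait, 0/1 level mismatch for a categorical one. The
    returned distance is the unweighted mean of contributions, hence in
    [0, 1]. A trait constant across the pool contributes 0 to every pair and
    is reported via a warning log; if every selected trait is constant the
    distance is undefined and an error is raised.
    """
    _check_pool(traits)
    if trait_subset is None:
        trait_subset = traits.trait_names
    trait_subset = list(trait_subset)
    if not trait_subset:
        raise ValidationError("trait_subset must not be empty")
    for t in trait_subset:
        traits.kind(t)  # KeyError for unknown traits

    n = traits.n_species
    total = np.zeros((n, n))
    n_informative = 0
    for t in trait_subset:
        if traits.kind(t) == CONTINUOUS:
            x = traits.values(t).to_numpy(float)
            rng = np.ptp(x)
            if rng == 0.0:
                logger.warning("trait %r is constant; contributes 0 to Gower distance", t)
                continue
            total += np.abs(x[:, None] - x[None, :]) / rng
        else:
            x = traits.values(t).to_numpy(str)
            levels = np.unique(x)
            if len(levels) < 2:
                logger.warning("trait %r is constant; contributes 0 to Gower distance", t)
                continue
            total += (x[:, None] != x[None, :]).astype(float)
        n_informative += 1
    if n_informative == 0:
        raise NumericalError("all selected traits are constant; Gower distance undefined")
    # constant traits still count in the unweighted mean (contribution 0)
    d = total / len(trait_subset)
    name = "+".join(trait_subset) if len(trait_subset) > 1 else trait_subset[0]
    return TraitDistanceMatrix(d, traits.species, name=f"gower:{name}")


def euclidean_distance(traits: TraitTable, trait: str) -> TraitDistanceMatrix:
    """Euclidean distance on one z-standardized continuous trait.

    Values are centred and scaled by the sample standard deviation (ddof=1)
    before taking pairwise absolute differences, so distances from different
    traits live on a comparable scale.
    """
    _check_pool(traits)
    if traits.kind(trait) != CONTINUOUS:
        raise ValidationError(
            f"trait {trait!r} is categorical; use gower_distance instead"
        )
    x = traits.values(trait).to_numpy(float)
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise NumericalError(f"trait {trait!r} has zero variance")
    z = (x - x.mean()) / sd
    d = np.abs(z[:, None] - z[None, :])
    return TraitDistanceMatrix(d, traits.species, name=f"euclidean:{trait}")
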
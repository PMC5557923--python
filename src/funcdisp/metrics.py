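"""Abundance-weighted functional alpha and beta dispersion metrics.

Within one community, with relative abundances ``f`` over the species
present and cophenetic distances ``d``:

* ``PW  = sum_{i != j} f_i f_j d_ij / sum_{i != j} f_i f_j`` — mean pairwise
  trait distance;
* ``NN  = sum_i f_i min_{j != i} d_ij`` — mean nearest-neighbor distance.

Between two communities A and B:

* ``Dpw = sum_{i in A} sum_{j in B} f_iA f_jB d_ij`` — mean pairwise
  dissimilarity;
* ``Dnn = 1/2 [ sum_i f_iA min_{j in B} d_ij + sum_j f_jB min_{i in A} d_ij ]``
  — nearest-neighbor dissimilarity, symmetrized over both directions.

All four are invariant to uniform abundance rescaling and to zero-abundance
species. PW/NN are undefined (NaN) for communities with fewer than two
species present; that is a flag, not an exception, so degenerate plots are
excluded from downstream standardized-effect-size aggregation rather than
biasing it.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .community import CommunityMatrix, SpatialHierarchy, beta_groups, pool_to_scale
from .distance import TraitDistanceMatrix

ALPHA_METRICS = ("PW", "NN")
BETA_METRICS = ("Dpw", "Dnn")


def _weights(abundances: Mapping[str, float] | pd.Series, dist: TraitDistanceMatrix):
    """Indices into `dist` and relative abundances of the species present."""
    s = pd.Series(abundances, dtype=float)
    if (s < 0).any() or not np.isfinite(s.to_numpy()).all():
        raise ValidationError("abundances must be finite and non-negative")
    s = s[s > 0]
    idx = dist.index_of(s.index)  # KeyError if absent from the matrix
    f = s.to_numpy() / s.sum() if len(s) else s.to_numpy()
    return idx, f


def _pw(f: np.ndarray, sub: np.ndarray) -> float:
    # sub has zero diagonal, so f' D f sums over ordered pairs i != j
    return float(f @ sub @ f / (1.0 - f @ f))

def _nn(f: np.ndarray, sub: np.ndarray) -> float:
    m = sub.copy()
    np.fill_diagonal(m, np.inf)
    return float(m.min(axis=1) @ f)


def alpha_pw(abundances, dist: TraitDistanceMatrix) -> float:
    """Abundance-weighted mean pairwise distance; NaN if < 2 species present."""
    idx, f = _weights(abundances, dist)
    if len(idx) < 2:
        return float("nan")
    return _pw(f, dist.values[np.ix_(idx, idx)])


def alpha_nn(abundances, dist: TraitDistanceMatrix) -> float:
    """Abundance-weighted mean nearest-neighbor distance; NaN if < 2 species."""
    idx, f = _weights(abundances, dist)
    if len(idx) < 2:
        return float("nan")
    return _nn(f, dist.values[np.ix_(idx, idx)])


def beta_dpw(abundances_a, abundances_b, dist: TraitDistanceMatrix) -> float:
    """Mean pairwise functional dissimilarity between two communities."""
    ia, fa = _weights(abundances_a, dist)
    ib, fb = _weights(abundances_b, dist)
    if len(ia) == 0 or len(ib) == 0:
        raise ValidationError("beta diversity needs two non-empty communities")
    return float(fa @ dist.values[np.ix_(ia, ib)] @ fb)


def beta_dnn(abundances_a, abundances_b, dist: TraitDistanceMatrix) -> float:
    """Mean nearest functional neighbor dissimilarity, symmetrized."""
    ia, fa = _weights(abundances_a, dist)
    ib, fb = _weights(abundances_b, dist)
    if len(ia) == 0 or len(ib) == 0:
        raise ValidationError("beta diversity needs two non-empty communities")
    sub = dist.values[np.ix_(ia, ib)]
    return float(0.5 * (sub.min(axis=1) @ fa + sub.min(axis=0) @ fb))


def alpha_table(comm: CommunityMatrix, dist: TraitDistanceMatrix) -> pd.DataFrame:
    """Observed PW and NN for every sample of a community matrix.

    Long format: community, metric, value, defined.
    """
    rows = []
    rel = comm.relative_abundances()
    for sample in comm.samples:
        w = rel.loc[sample]
        for metric, fn in (("PW", alpha_pw), ("NN", alpha_nn)):
            v = fn(w, dist)
            rows.append(
                {"community": sample, "metric": metric, "value": v, "defined": not np.isnan(v)}
            )
    return pd.DataFrame(rows)


def beta_within_group(
    comm: CommunityMatrix,
    hier: SpatialHierarchy,
    scale: str,
    dist: TraitDistanceMatrix,
) -> pd.DataFrame:
    """Dpw and Dnn for all unordered sub-unit pairs within each enclosing group.

    ``comm`` is the plot-level matrix; it is pooled to the sub-unit scale
    internally. Long format: group, unit_a, unit_b, metric, value, defined.
    """
    pooled = pool_to_scale(comm, hier, scale)
    groups = beta_groups(hier, scale)
    rel = pooled.relative_abundances()
    rows = []
    for g, members in groups.items():
        present = [m for m in members if m in rel.index]
        for a, b in combinations(present, 2):
            wa, wb = rel.loc[a], rel.loc[b]
            for metric, fn in (("Dpw", beta_dpw), ("Dnn", beta_dnn)):
                v = fn(wa, wb, dist)
                rows.append(
                    {
                        "group": g,
                        "unit_a": a,
                        "unit_b": b,
                        "metric": metric,
                        "value": v,
                        "defined": True,
                    }
                )
    return pd.DataFrame(rows, columns=["group", "unit_a", "unit_b", "metric", "value", "defined"])
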
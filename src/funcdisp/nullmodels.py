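"""Taxa-shuffle null models and standardized effect sizes (SES).

The null model randomly reassigns species labels to the tips of the trait
dendrogram (equivalently: applies one random permutation jointly to the
rows and columns of the cophenetic distance matrix). Community composition,
abundances, occupancy and spatial structure are untouched, so only the
mapping from species identity to trait position is randomized. One shuffle
per iteration is shared by *all* communities, preserving cross-community
structure for the beta metrics.

For each observed metric value the standardized effect size is

    SES = (Metric_obs - Metric_null) / Metric_SD

with Metric_null and Metric_SD the mean and standard deviation of the
metric over the null iterations (the observed value is not part of the
null sample). Negative SES indicates functional under-dispersion
(clustering, the abiotic-filtering signature); positive SES indicates
over-dispersion. Group-level departure of SES from zero is assessed with a
two-sided Wilcoxon signed-rank test (exact sign-flip distribution for small
samples, normal approximation with continuity correction otherwise).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import NumericalError, ValidationError
from .community import CommunityMatrix, SpatialHierarchy, beta_groups, pool_to_scale
from .distance import TraitDistanceMatrix
from .metrics import _nn, _pw, _weights

DEFAULT_ITERATIONS = 999

#: SES variants keyed by the underlying metric.
SES_METRICS = {"PW": "SES PW", "NN": "SES NN", "Dpw": "SES Dpw", "Dnn": "SES Dnn"}


def derive_seed(seed: int, *keys: str) -> int:
    """Deterministic child seed (< 2**31) for a named pipeline stage."""
    h = zlib.crc32("/".join(keys).encode())
    return int((seed * 0x9E3779B1 + h) % (2**31 - 1))


def taxa_shuffle(
    dist: TraitDistanceMatrix, rng: np.random.Generator | int | None = None
) -> TraitDistanceMatrix:
    """One uniformly random relabeling of the distance matrix.

    The permutation acts jointly on rows and columns, so the multiset of
    pairwise distances is exactly preserved.
    """
    rng = np.random.default_rng(rng)
    p = rng.permutation(len(dist))
    return TraitDistanceMatrix(
        dist.values[np.ix_(p, p)], dist.labels, name=dist.name, validate=False
    )


def _permutations(n: int, n_iter: int, rng: np.random.Generator) -> np.ndarray:
    return np.array([rng.permutation(n) for _ in range(n_iter)])


@dataclass(frozen=True)
class NullDistribution:
    """Summary of a metric's taxa-shuffle null distribution."""

    metric: str
    mean: float
    sd: float
    n_iter: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.mean)


def null_distribution(
    metric_fn: Callable[[Mapping[str, float], TraitDistanceMatrix], float],
    abundances: Mapping[str, float] | pd.Series,
    dist: TraitDistanceMatrix,
    n_iter: int = DEFAULT_ITERATIONS,
    rng: np.random.Generator | int | None = None,
) -> NullDistribution:
    """Null mean/SD of one alpha-type metric for one community.

    Reference implementation via explicit matrix shuffles; the table
    builders below use an equivalent vectorized path.
    """
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    rng = np.random.default_rng(rng)
    vals = np.empty(n_iter)
    for k in range(n_iter):
        vals[k] = metric_fn(abundances, taxa_shuffle(dist, rng))
    if np.isnan(vals).any():
        return NullDistribution(getattr(metric_fn, "__name__", "metric"), np.nan, np.nan, n_iter)
    sd = vals.std(ddof=1) if n_iter > 1 else 0.0
    return NullDistribution(
        getattr(metric_fn, "__name__", "metric"), float(vals.mean()), float(sd), n_iter
    )


def ses(observed: float, null_mean: float, null_sd: float) -> float:
    """Standardized effect size; NaN when the null SD is zero or inputs undefined."""
    if not (np.isfinite(observed) and np.isfinite(null_mean) and np.isfinite(null_sd)):
        return float("nan")
    # SD indistinguishable from zero at float precision (degenerate null,
    # e.g. a community holding the whole pool) -> undefined
    if null_sd <= 1e-12 * max(1.0, abs(null_mean)):
        return float("nan")
    return (observed - null_mean) / null_sd


# ---------------------------------------------------------------------------
# Vectorized SES tables
# ---------------------------------------------------------------------------

def _null_stats(null_vals: np.ndarray) -> tuple[float, float]:
    return float(null_vals.mean()), float(null_vals.std(ddof=1))


def alpha_ses_table(
    comm: CommunityMatrix,
    dist: TraitDistanceMatrix,
    n_iter: int = DEFAULT_ITERATIONS,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Observed, null mean/SD and SES of PW and NN for every community.

    All communities share the same shuffle in each iteration. Communities
    with fewer than two species present are reported with ``defined=False``.
    """
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    rng = np.random.default_rng(rng)
    D = dist.values
    P = _permutations(len(dist), n_iter, rng)
    rel = comm.relative_abundances()
    rows = []
    for sample in comm.samples:
        idx, f = _weights(rel.loc[sample], dist)
        if len(idx) < 2:
            for metric in ("PW", "NN"):
                rows.append(_ses_row(sample, metric, np.nan, np.nan, np.nan))
            continue
        sub_obs = D[np.ix_(idx, idx)]
        gathered = P[:, idx]  # (n_iter, r): null trait positions of the present species
        sub = D[gathered[:, :, None], gathered[:, None, :]]
        ff = f @ f
        pw_null = np.einsum("i,nij,j->n", f, sub, f) / (1.0 - ff)
        r = len(idx)
        sub[:, np.arange(r), np.arange(r)] = np.inf
        nn_null = sub.min(axis=2) @ f
        for metric, obs, null_vals in (
            ("PW", _pw(f, sub_obs), pw_null),
            ("NN", _nn(f, sub_obs), nn_null),
        ):
            mean, sd = _null_stats(null_vals)
            rows.append(_ses_row(sample, metric, obs, mean, sd))
    return pd.DataFrame(rows)


def beta_ses_table(
    comm: CommunityMatrix,
    hier: SpatialHierarchy,
    scale: str,
    dist: TraitDistanceMatrix,
    n_iter: int = DEFAULT_ITERATIONS,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """SES of Dpw and Dnn for all within-group sub-unit pairs at ``scale``."""
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    rng = np.random.default_rng(rng)
    D = dist.values
    P = _permutations(len(dist), n_iter, rng)
    pooled = pool_to_scale(comm, hier, scale)
    rel = pooled.relative_abundances()
    rows = []
    for g, members in beta_groups(hier, scale).items():
        present = [m for m in members if m in rel.index]
        weights = {m: _weights(rel.loc[m], dist) for m in present}
        for a, b in combinations(present, 2):
            ia, fa = weights[a]
            ib, fb = weights[b]
            ga, gb = P[:, ia], P[:, ib]
            sub = D[ga[:, :, None], gb[:, None, :]]  # (n_iter, ra, rb)
            dpw_null = np.einsum("i,nij,j->n", fa, sub, fb)
            dnn_null = 0.5 * (sub.min(axis=2) @ fa + sub.min(axis=1) @ fb)
            sub_obs = D[np.ix_(ia, ib)]
            dpw_obs = float(fa @ sub_obs @ fb)
            dnn_obs = float(0.5 * (sub_obs.min(axis=1) @ fa + sub_obs.min(axis=0) @ fb))
            for metric, obs, null_vals in (("Dpw", dpw_obs, dpw_null), ("Dnn", dnn_obs, dnn_null)):
                mean, sd = _null_stats(null_vals)
                row = _ses_row(f"{a}|{b}", metric, obs, mean, sd)
                row.update({"group": g, "unit_a": a, "unit_b": b})
                rows.append(row)
    cols = [
        "community", "metric", "observed", "null_mean", "null_sd", "ses", "defined",
        "group", "unit_a", "unit_b",
    ]
    return pd.DataFrame(rows, columns=cols)


def _ses_row(community: str, metric: str, obs: float, mean: float, sd: float) -> dict:
    s = ses(obs, mean, sd)
    return {
        "community": community,
        "metric": metric,
        "observed": obs,
        "null_mean": mean,
        "null_sd": sd,
        "ses": s,
        "defined": bool(np.isfinite(s)),
    }


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank departure from zero
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WilcoxonResult:
    n: int
    statistic: float
    pvalue: float
    direction: str  # "negative" | "positive" | "zero"
    method: str  # "exact" | "approx"


def _exact_signflip_pvalue(values: np.ndarray) -> tuple[float, float]:
    """Exact two-sided sign-flip p-value of the signed-rank statistic.

    Enumerates the 2^n sign assignments through a subset-sum count over
    doubled midranks (so ties are handled exactly); the distribution of the
    positive-rank sum is symmetric, giving the usual doubled-tail p.
    """
    ranks = stats.rankdata(np.abs(values))
    doubled = np.rint(2 * ranks).astype(int)
    w_pos = int(doubled[values > 0].sum())
    total = int(doubled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled:
        new = counts.copy()
        new[r:] += counts[: total + 1 - r]
        counts = new
    denom = counts.sum()  # == 2**n exactly (floats exact below 2**53)
    cdf = counts[: w_pos + 1].sum() / denom
    sf = counts[w_pos:].sum() / denom
    return float(ranks[values > 0].sum()), float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_departure(
    values: Sequence[float], exact_max_n: int = 25
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test of median zero for SES values.

    Zeros are dropped (Wilcoxon's convention); requires at least five
    defined values. Exact sign-flip distribution for n <= ``exact_max_n``,
    otherwise the normal approximation with continuity correction.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 5:
        raise ValidationError(f"need >= 5 defined SES values, got {len(v)}")
    nz = v[v != 0]
    if len(nz) == 0:
        raise NumericalError("all SES values are exactly zero; test undefined")
    median = float(np.median(v))
    direction = "negative" if median < 0 else ("positive" if median > 0 else "zero")
    if len(nz) <= exact_max_n:
        statistic, p = _exact_signflip_pvalue(nz)
        method = "exact"
    else:
        res = stats.wilcoxon(
            nz, alternative="two-sided", correction=True, method="approx"
        )
        statistic, p = float(res.statistic), float(res.pvalue)
        method = "approx"
    return WilcoxonResult(len(nz), statistic, min(p, 1.0), direction, method)


def significance_stars(p: float) -> str:
    """The 0.05 / 0.01 / 0.001 star convention."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def ses_summary(
    ses_table: pd.DataFrame, by: Sequence[str] = ("scale", "trait_metric", "metric")
) -> pd.DataFrame:
    """Per-group mean SES with Wilcoxon departure-from-zero test.

    Groups with fewer than five defined SES values get NaN p-values.
    """
    rows = []
    grouping = [c for c in by if c in ses_table.columns]
    for keys, grp in ses_table.groupby(list(grouping)):
        keys = keys if isinstance(keys, tuple) else (keys,)
        vals = grp.loc[grp["defined"].astype(bool), "ses"].to_numpy(float)
        row = dict(zip(grouping, keys))
        row["n_defined"] = len(vals)
        row["mean_ses"] = float(np.mean(vals)) if len(vals) else np.nan
        try:
            res = wilcoxon_departure(vals)
            row.update(pvalue=res.pvalue, direction=res.direction)
        except (ValidationError, NumericalError):
            row.update(pvalue=np.nan, direction="")
        row["stars"] = significance_stars(row["pvalue"])
        rows.append(row)
    return pd.DataFrame(rows)
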
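"""Scale decomposition and environmental-gradient analysis of SES values.

Three pieces of machinery:

* :func:`variance_partition` — REML variance components of SES across the
  nested sampling levels (region / lake / depth stratum / plot / residual),
  reported as percentage shares;
* :func:`pca_environment` — PCA of the (log-transformed, standardized) lake
  water parameters, axis 1 oriented so Secchi depth loads positively, used
  to pick the lake-scale gradient;
* :func:`gradient_trend` — linear mixed-effects trend of SES along a
  gradient (fixed slope, random intercept for the enclosing spatial unit),
  with the p-value from a likelihood-ratio test of the slope. Direction
  labels follow the interpretive rule: a negative significant slope means
  the metric becomes *more clustered* along the gradient, a positive one
  *less clustered*.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from sklearn.decomposition import PCA

from ._errors import NumericalError, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Variance components
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VarianceComponents:
    """Variance shares per nesting level (fractions summing to one)."""

    shares: dict[str, float]
    variances: dict[str, float]

    @property
    def percentages(self) -> dict[str, float]:
        return {k: 100.0 * v for k, v in self.shares.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": list(self.shares),
                "variance": [self.variances[k] for k in self.shares],
                "share_pct": [100.0 * self.shares[k] for k in self.shares],
            }
        )


def _moment_start(df: pd.DataFrame, usable: Sequence[str], value: str, model):
    """Crude method-of-moments starting values for the REML optimizer.

    Uses the variance of per-level group means (coarse levels) and the
    pooled within-finest-group variance as the residual; only a starting
    point, so bias is irrelevant.
    """
    from statsmodels.regression.mixed_linear_model import MixedLMParams

    finest = usable[-1]
    within = df.groupby(finest)[value].var(ddof=1).mean()
    resid = float(within) if np.isfinite(within) and within > 0 else float(
        df[value].var(ddof=1) / (len(usable) + 1)
    )
    resid = max(resid, 1e-8)
    comps = {}
    for c in usable:
        means = df.groupby(c)[value].mean()
        comps[c] = max(float(means.var(ddof=1)), 1e-8)
    vcomp = np.array([comps[name] for name in model.exog_vc.names]) / resid
    return MixedLMParams.from_components(
        fe_params=np.array([float(df[value].mean())]),
        cov_re=np.empty((0, 0)),
        vcomp=vcomp,
    )


def variance_partition(
    data: pd.DataFrame,
    levels: Sequence[str],
    value: str = "ses",
) -> VarianceComponents:
    """REML variance components of a response over nested grouping levels.

    ``levels`` are hierarchy columns of ``data`` ordered coarse to fine
    (e.g. ``("region", "lake", "depth_stratum", "plot")``); the within-finest
    remainder is reported as ``"residual"``. Estimated with a mixed model
    holding one variance component per level (non-negative by construction).
    Rows with undefined response are dropped.
    """
    levels = list(levels)
    missing = [c for c in levels + [value] if c not in data.columns]
    if missing:
        raise ValidationError(f"variance_partition: missing columns {missing}")
    df = data[levels + [value]].dropna().copy()
    if len(df) < len(levels) + 2:
        raise ValidationError("too few defined observations for variance partition")
    usable = []
    for c in levels:
        if df[c].nunique() < 2:
            logger.warning("level %r has < 2 units; its share is reported as 0", c)
        else:
            usable.append(c)
    if not usable:
        raise ValidationError("fewer than 2 units at every level")
    y = df[value].to_numpy(float)
    if np.ptp(y) == 0.0:
        raise NumericalError("response is constant; variance partition undefined")
    df["_one"] = 1
    vcf = {c: f"0 + C({c})" for c in usable}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(f"{value} ~ 1", df, groups="_one", vc_formula=vcf)
        fit = model.fit(reml=True)
        # the REML surface can have ridges/local optima when a level has very
        # few units (2 regions); retry from a method-of-moments start and
        # keep the fit with the higher restricted likelihood
        start = _moment_start(df, usable, value, model)
        candidates = [fit]
        try:
            candidates.append(model.fit(reml=True, start_params=start))
        except (np.linalg.LinAlgError, ValueError):  # pragma: no cover
            pass
        llfs = [f.llf for f in candidates if np.isfinite(f.llf)]
        # disagreement between starts signals a ridge/local optimum; only
        # then pay for a derivative-free search
        if len(llfs) < 2 or (max(llfs) - min(llfs)) > 1e-2:
            try:
                candidates.append(
                    model.fit(reml=True, start_params=start, method="nm", maxiter=2000)
                )
            except (np.linalg.LinAlgError, ValueError):  # pragma: no cover
                pass
        fit = max(
            (f for f in candidates if np.isfinite(f.llf)), key=lambda f: f.llf
        )
    vcomp = dict(zip(fit.model.exog_vc.names, np.maximum(fit.vcomp, 0.0)))
    variances = {c: float(vcomp.get(c, 0.0)) for c in levels}
    variances["residual"] = float(max(fit.scale, 0.0))
    total = sum(variances.values())
    if total <= 0:
        raise NumericalError("all variance components are zero")
    shares = {k: v / total for k, v in variances.items()}
    return VarianceComponents(shares=shares, variances=variances)


# ---------------------------------------------------------------------------
# Environmental PCA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnvAxes:
    """PCA of lake water parameters: scores, loadings, explained variance."""

    scores: pd.DataFrame  # lakes x axes
    loadings: pd.DataFrame  # parameters x axes, columns orthonormal
    explained_ratio: np.ndarray
    standardized: pd.DataFrame  # the matrix the PCA was run on


def pca_environment(
    env: pd.DataFrame,
    log_transform: bool | Sequence[str] = True,
    orient_by: str = "secchi_depth",
) -> EnvAxes:
    """PCA of per-lake water parameters.

    Parameters are log-transformed (all of them by default; pass a list to
    restrict, or False to skip) and z-standardized before the
    decomposition. Axis 1 is sign-oriented so ``orient_by`` (Secchi depth,
    i.e. water transparency) loads positively when that column is present.
    """
    if len(env) < 3:
        raise ValidationError("PCA needs at least 3 lakes")
    x = env.astype(float).copy()
    if log_transform is True:
        log_cols = list(x.columns)
    elif log_transform is False:
        log_cols = []
    else:
        log_cols = list(log_transform)
    for c in log_cols:
        if (x[c] <= 0).any():
            raise ValidationError(f"column {c!r} must be positive for log transform")
        x[c] = np.log(x[c])
    sd = x.std(ddof=0)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise NumericalError(f"constant column(s) after standardization: {bad}")
    z = (x - x.mean()) / sd
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(z.to_numpy())
    comps = pca.components_  # (n_axes, n_params), rows orthonormal
    if orient_by in env.columns:
        j = list(x.columns).index(orient_by)
        if comps[0, j] < 0:
            comps[0] *= -1.0
            scores[:, 0] *= -1.0
    axes = [f"PC{i + 1}" for i in range(comps.shape[0])]
    return EnvAxes(
        scores=pd.DataFrame(scores, index=env.index, columns=axes),
        loadings=pd.DataFrame(comps.T, index=x.columns, columns=axes),
        explained_ratio=pca.explained_variance_ratio_.copy(),
        standardized=z,
    )


# ---------------------------------------------------------------------------
# Gradient binning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradientBins:
    """Equal-width binning of a gradient into ordinal levels (1-based)."""

    edges: np.ndarray  # exact boundaries, len n_levels + 1
    display_edges: list[float]  # boundaries rounded half-up to 2 decimals
    levels: pd.Series  # per-unit level, 1..n_levels

    @property
    def n_levels(self) -> int:
        return len(self.edges) - 1


def _round2(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def bin_gradient(values: pd.Series | Sequence[float], n_levels: int) -> GradientBins:
    """Split a gradient into ``n_levels`` equal-width intervals over its range.

    Level assignment uses the unrounded boundaries with the upper edge
    inclusive for the last level; the reported boundaries are rounded
    half-up to two decimals for display.
    """
    if n_levels < 1:
        raise ValidationError("n_levels must be >= 1")
    s = pd.Series(values, dtype=float)
    lo, hi = float(s.min()), float(s.max())
    if not hi > lo:
        raise ValidationError("degenerate gradient range (max must exceed min)")
    edges = np.linspace(lo, hi, n_levels + 1)
    lev = np.minimum(np.searchsorted(edges, s.to_numpy(), side="right"), n_levels)
    lev = np.maximum(lev, 1)
    return GradientBins(
        edges=edges,
        display_edges=[_round2(e) for e in edges],
        levels=pd.Series(lev, index=s.index, name="level"),
    )


# ---------------------------------------------------------------------------
# Gradient trends
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradientTrendFit:
    slope: float
    pvalue: float
    direction: str  # "more clustered" | "less clustered" | "none"
    n: int
    method: str  # "mixed" | "ols"
    converged: bool = True
    slope_se: float = float("nan")

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        zcrit = stats.norm.ppf(0.5 + level / 2.0)
        return self.slope - zcrit * self.slope_se, self.slope + zcrit * self.slope_se


def _direction(slope: float, p: float) -> str:
    if not np.isfinite(p) or p >= 0.05:
        return "none"
    return "more clustered" if slope < 0 else "less clustered"


def gradient_trend(
    data: pd.DataFrame,
    value: str = "ses",
    gradient: str = "gradient",
    group: str | None = "group",
) -> GradientTrendFit:
    """Linear trend of SES along a gradient, random intercept per group.

    Fits ``value ~ gradient`` with a random intercept for ``group`` by
    maximum likelihood and tests the slope with a likelihood-ratio test
    against the intercept-only model (chi-square, 1 df); the reported slope
    comes from a REML refit of the full model. When fewer than two groups
    are available (or ``group`` is None) the model falls back to ordinary
    least squares with an LRT on the OLS likelihoods, logged as a warning.
    A two-level factor gradient is handled by the same machinery with the
    factor coded 0/1.
    """
    cols = [value, gradient] + ([group] if group else [])
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValidationError(f"gradient_trend: missing columns {missing}")
    df = data[cols].dropna().copy()
    n = len(df)
    if n < 3:
        raise ValidationError("need at least 3 observations for a trend")
    g = df[gradient]
    if not pd.api.types.is_numeric_dtype(g):
        levels = pd.unique(g)
        if len(levels) != 2:
            raise ValidationError(
                "non-numeric gradients must have exactly 2 levels (factor contrast)"
            )
        df[gradient] = (g == levels[1]).astype(float)
    if df[gradient].nunique() < 2:
        raise ValidationError("gradient is constant; no trend estimable")
    y = df[value].to_numpy(float)
    if np.ptp(y) == 0.0:
        # degenerate flat response: slope exactly 0, nothing to test
        return GradientTrendFit(0.0, 1.0, "none", n, "degenerate", True, 0.0)

    use_mixed = group is not None and df[group].nunique() >= 2
    if not use_mixed and group is not None:
        logger.warning("fewer than 2 groups; falling back to OLS for the trend")
    if use_mixed:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                full_ml = smf.mixedlm(f"{value} ~ {gradient}", df, groups=group).fit(reml=False)
                null_ml = smf.mixedlm(f"{value} ~ 1", df, groups=group).fit(reml=False)
                full_reml = smf.mixedlm(f"{value} ~ {gradient}", df, groups=group).fit(reml=True)
            lr = max(0.0, 2.0 * (full_ml.llf - null_ml.llf))
            p = float(stats.chi2.sf(lr, df=1))
            slope = float(full_reml.params[gradient])
            se = float(full_reml.bse[gradient])
            converged = bool(full_ml.converged and full_reml.converged)
            if not converged:
                logger.warning("mixed-model trend fit did not fully converge")
            return GradientTrendFit(slope, p, _direction(slope, p), n, "mixed", converged, se)
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("mixed-model trend failed (%s); falling back to OLS", exc)

    X = sm.add_constant(df[[gradient]].to_numpy(float))
    full = sm.OLS(y, X).fit()
    null = sm.OLS(y, np.ones((n, 1))).fit()
    lr = max(0.0, 2.0 * (full.llf - null.llf))
    p = float(stats.chi2.sf(lr, df=1))
    slope = float(full.params[1])
    se = float(full.bse[1])
    return GradientTrendFit(slope, p, _direction(slope, p), n, "ols", True, se)
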
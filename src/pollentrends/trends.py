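"""Per-pair similarity trends, site and occupancy summaries, spline curves.

Each site pair's within-interval similarities form a short time series
(interval midpoint age in cal yr BP vs similarity).  An ordinary
least-squares slope is fitted per pair; because age increases into the
past, a *negative* slope means similarity rises toward the present --
floristic homogenization -- and a positive slope means differentiation.
Pairs with fewer than four interval points are dropped.  Site-level and
occupancy-group summaries use median/quartile statistics with Tukey
whiskers; the overall trend across all comparisons is estimated with a
cubic smoothing spline whose roughness penalty is chosen by generalized
cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

logger = logging.getLogger(__name__)

__all__ = [
    "pair_slope",
    "pair_trend_table",
    "site_summary",
    "occupancy_summary",
    "fit_trend_spline",
    "abundance_by_settlement",
    "SplineFit",
]

MIN_POINTS = 4

HOMOGENIZING = "homogenizing"
DIFFERENTIATING = "differentiating"
FLAT = "flat"


def _classify(slope: float) -> str:
    if slope < 0:
        return HOMOGENIZING
    if slope > 0:
        return DIFFERENTIATING
    return FLAT


def pair_slope(ages: np.ndarray, similarities: np.ndarray) -> tuple[float, str] | None:
    """OLS slope of similarity on age (cal yr BP) with sign classification.

    Returns ``(slope, classification)`` or None if the series has fewer
    than :data:`MIN_POINTS` points (such pairs are dropped, not an error).
    Ages must be distinct.
    """
    x = np.asarray(ages, dtype=float)
    y = np.asarray(similarities, dtype=float)
    if x.size < MIN_POINTS:
        return None
    if np.unique(x).size != x.size:
        raise ValueError("ages in a pair series must be distinct")
    if np.all(y == y[0]):
        return 0.0, FLAT
    xc = x - x.mean()
    slope = float(np.dot(xc, y) / np.dot(xc, xc))
    return slope, _classify(slope)


def pair_trend_table(comparisons: pd.DataFrame) -> pd.DataFrame:
    """Fit one OLS trend per site pair from the pairwise-comparison table.

    Pairs with fewer than four interval points are dropped with a log
    entry.  Returns columns ``site_a, site_b, slope, n_points,
    classification``.
    """
    rows = []
    n_dropped = 0
    for (a, b), grp in comparisons.groupby(["site_a", "site_b"], sort=True):
        res = pair_slope(grp["age_mid"].to_numpy(), grp["similarity"].to_numpy())
        if res is None:
            n_dropped += 1
            continue
        slope, cls = res
        rows.append(
            {"site_a": a, "site_b": b, "slope": slope,
             "n_points": len(grp), "classification": cls}
        )
    if n_dropped:
        logger.info(
            "pair_trend_table: dropped %d pairs with fewer than %d points",
            n_dropped, MIN_POINTS,
        )
    return pd.DataFrame(
        rows, columns=["site_a", "site_b", "slope", "n_points", "classification"]
    )


def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    """Median and linearly interpolated quartiles (common boxplot default)."""
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    return float(q1), float(med), float(q3)


def _tukey_whiskers(values: np.ndarray, q1: float, q3: float) -> tuple[float, float]:
    """Furthest data points within 1.5 x IQR of the box."""
    iqr = q3 - q1
    lo = values[values >= q1 - 1.5 * iqr]
    hi = values[values <= q3 + 1.5 * iqr]
    return float(lo.min()), float(hi.max())


def site_summary(trends: pd.DataFrame, site_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-site distribution of pair slopes and the homogenizing proportion.

    A site's pairs are every fitted trend involving it (within-site pairs
    were never formed).  ``proportion_homogenizing`` is the fraction of its
    pair slopes below zero; exactly-zero slopes count toward neither
    direction.  Sites with no surviving pairs are flagged with
    ``n_pairs = 0`` and NaN statistics.
    """
    if site_ids is None:
        site_ids = sorted(set(trends["site_a"]) | set(trends["site_b"]))
    rows = []
    for site in site_ids:
        sub = trends.loc[(trends["site_a"] == site) | (trends["site_b"] == site)]
        if sub.empty:
            logger.warning("site %s has no pair trends", site)
            rows.append(
                {"site_id": site, "n_pairs": 0, "proportion_homogenizing": np.nan,
                 "median_slope": np.nan, "q1_slope": np.nan, "q3_slope": np.nan,
                 "min_slope": np.nan, "max_slope": np.nan}
            )
            continue
        slopes = sub["slope"].to_numpy()
        q1, med, q3 = _quartiles(slopes)
        rows.append(
            {
                "site_id": site,
                "n_pairs": len(sub),
                "proportion_homogenizing": float((slopes < 0).sum() / len(slopes)),
                "median_slope": med,
                "q1_slope": q1,
                "q3_slope": q3,
                "min_slope": float(slopes.min()),
                "max_slope": float(slopes.max()),
            }
        )
    return pd.DataFrame(rows)


def occupancy_summary(comparisons: pd.DataFrame) -> pd.DataFrame:
    """Boxplot statistics of similarity per occupancy status.

    For each status in (neither, one, both): count, median, quartiles and
    Tukey whiskers (furthest points within 1.5 x IQR).  Statuses with no
    comparisons report ``n = 0``.
    """
    from .similarity import OCCUPANCY_LEVELS

    rows = []
    for status in OCCUPANCY_LEVELS:
        vals = comparisons.loc[comparisons["occupancy"] == status, "similarity"].to_numpy()
        if vals.size == 0:
            rows.append(
                {"occupancy": status, "n": 0, "median": np.nan, "q1": np.nan,
                 "q3": np.nan, "whisker_low": np.nan, "whisker_high": np.nan}
            )
            continue
        q1, med, q3 = _quartiles(vals)
        wlo, whi = _tukey_whiskers(vals, q1, q3)
        rows.append(
            {"occupancy": status, "n": int(vals.size), "median": med,
             "q1": q1, "q3": q3, "whisker_low": wlo, "whisker_high": whi}
        )
    return pd.DataFrame(rows)


@dataclass
class SplineFit:
    """A smoothing-spline trend curve with pointwise 95% confidence bands."""

    grid: np.ndarray          # evaluation ages, cal yr BP (ascending)
    fit: np.ndarray           # fitted similarity on the grid
    ci_low: np.ndarray
    ci_high: np.ndarray
    lam: float                # roughness penalty selected by GCV
    sigma2: float             # residual variance estimate
    edf: float                # effective degrees of freedom of the smoother

    def at(self, age: float) -> float:
        """Linear interpolation of the fitted curve at one age."""
        return float(np.interp(age, self.grid, self.fit))


def fit_trend_spline(
    ages: np.ndarray,
    similarities: np.ndarray,
    n_grid: int = 100,
) -> SplineFit:
    """Cubic smoothing spline of similarity vs age with GCV smoothing.

    Duplicate ages (all comparisons within one interval share a midpoint)
    are collapsed to weighted means before fitting, which is exactly
    equivalent for the penalized least-squares criterion.  The smoothing
    parameter is selected by generalized cross-validation.  Pointwise 95%
    confidence bands are propagated through the linear smoother matrix with
    the residual variance estimated on ``n - edf`` degrees of freedom.
    """
    x = np.asarray(ages, dtype=float)
    y = np.asarray(similarities, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 points to fit a trend spline")
    xu, inv, counts = np.unique(x, return_inverse=True, return_counts=True)
    if xu.size < 3:
        raise ValueError("need at least 3 distinct ages to fit a trend spline")
    yu = np.bincount(inv, weights=y) / counts
    w = counts.astype(float)
    lam = _select_lambda_gcv(xu, yu, w, n_total=x.size,
                             within_ss=float(np.sum((y - yu[inv]) ** 2)))
    spl = make_smoothing_spline(xu, yu, w=w, lam=lam)
    grid = np.linspace(xu.min(), xu.max(), n_grid)
    fit_grid = spl(grid)
    # Linear smoother: columns of the map (unique-y -> grid fit) and
    # (unique-y -> data fit), obtained by smoothing unit vectors at fixed lam.
    a_grid = np.empty((grid.size, xu.size))
    s_data = np.empty((xu.size, xu.size))
    for j in range(xu.size):
        e = np.zeros(xu.size)
        e[j] = 1.0
        sj = make_smoothing_spline(xu, e, w=w, lam=lam)
        a_grid[:, j] = sj(grid)
        s_data[:, j] = sj(xu)
    edf = float(np.trace(s_data))
    resid = y - s_data.dot(yu)[inv]
    df_resid = max(x.size - edf, 1.0)
    sigma2 = float(np.dot(resid, resid) / df_resid)
    # var of the grid fit: grid = A yu, var(yu_j) = sigma2 / n_j
    var_grid = sigma2 * (a_grid**2 / w[None, :]).sum(axis=1)
    half = 1.959963984540054 * np.sqrt(var_grid)
    return SplineFit(
        grid=grid,
        fit=fit_grid,
        ci_low=fit_grid - half,
        ci_high=fit_grid + half,
        lam=lam,
        sigma2=sigma2,
        edf=edf,
    )


def _smoother_trace(xu: np.ndarray, w: np.ndarray, lam: float) -> float:
    """tr(S) of the weighted cubic smoothing spline at penalty ``lam``.

    Exact via unit-vector smoothing for few unique ages; Hutchinson
    sign-probe estimation (fixed internal seed, deterministic) otherwise.
    """
    m = xu.size
    if m <= 120:
        tr = 0.0
        for j in range(m):
            e = np.zeros(m)
            e[j] = 1.0
            tr += float(make_smoothing_spline(xu, e, w=w, lam=lam)(xu[j]))
        return tr
    rng = np.random.default_rng(0)
    probes = 12
    tr = 0.0
    for _ in range(probes):
        z = rng.choice([-1.0, 1.0], size=m)
        tr += float(z @ make_smoothing_spline(xu, z, w=w, lam=lam)(xu))
    return tr / probes


def _select_lambda_gcv(
    xu: np.ndarray, yu: np.ndarray, w: np.ndarray, n_total: int, within_ss: float
) -> float:
    """Minimize the GCV score ``n * RSS / (n - tr(S))^2`` over log-lambda.

    Duplicated ages are handled exactly: the full-data residual sum of
    squares decomposes into the (lambda-independent) within-age scatter
    plus the weighted RSS of the collapsed means.
    """

    def score(lam: float) -> float:
        f = make_smoothing_spline(xu, yu, w=w, lam=lam)(xu)
        rss = within_ss + float(np.sum(w * (yu - f) ** 2))
        tr = _smoother_trace(xu, w, lam)
        denom = max(n_total - tr, 1e-9)
        return n_total * rss / denom**2

    # natural units of the penalty; the solver loses accuracy far above
    # scale * 1e4, so the grid stops there (the fit is already linear)
    scale = float((xu.max() - xu.min()) ** 3)
    logs = np.log(scale) + np.log(10.0) * np.arange(-8.0, 5.0)
    vals = [score(float(np.exp(ll))) for ll in logs]
    j = int(np.argmin(vals))
    lo = logs[max(j - 1, 0)]
    hi = logs[min(j + 1, len(logs) - 1)]
    for _ in range(18):
        m1 = lo + (hi - lo) / 3
        m2 = hi - (hi - lo) / 3
        if score(float(np.exp(m1))) <= score(float(np.exp(m2))):
            hi = m2
        else:
            lo = m1
    return float(np.exp(0.5 * (lo + hi)))


def abundance_by_settlement(
    samples: pd.DataFrame,
    site_islands: dict[str, str] | pd.Series,
    settlements: dict[str, float],
) -> pd.DataFrame:
    """Mean percentage per taxon before vs after each island's settlement.

    Each sample is first converted to percentages of its own pollen sum;
    a sample is *pre*-settlement if it is older than its island's
    settlement date (never-settled islands contribute only pre-settlement
    samples).  The mean is taken over all samples in each phase with
    absent taxa counting as zero, and taxa are ranked by their
    post-settlement mean.

    Returns columns ``taxon, mean_pct_pre, mean_pct_post`` sorted by
    ``mean_pct_post`` descending.
    """
    site_islands = dict(site_islands)
    df = samples.copy()
    totals = df.groupby(["site_id", "age_bp"])["value"].transform("sum")
    df["pct"] = 100.0 * df["value"] / totals

    def _settle_age(isl: str) -> float:
        a = settlements.get(isl, np.nan)
        # inf / NaN both mean "never settled": no post-settlement samples
        return np.nan if (a is None or not np.isfinite(a)) else float(a)

    settle = df["site_id"].map(site_islands).map(_settle_age).astype(float)
    post = df["age_bp"].astype(float) < settle  # NaN compares False -> pre
    out = []
    for phase, mask in (("pre", ~post), ("post", post)):
        sub = df.loc[mask]
        n_samp = sub.drop_duplicates(["site_id", "age_bp"]).shape[0]
        if n_samp == 0:
            means = pd.Series(dtype=float)
        else:
            means = sub.groupby("taxon")["pct"].sum() / n_samp
        out.append(means.rename(f"mean_pct_{phase}"))
    table = pd.concat(out, axis=1).fillna(0.0)
    table.index.name = "taxon"
    return (
        table.sort_values("mean_pct_post", ascending=False)
        .reset_index()
    )
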
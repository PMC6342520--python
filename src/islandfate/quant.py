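"""Radial spatial statistics on per-cell tables from micropatterned islands.

Cells carry positions, immunolabel intensities and positivity flags; islands
carry centroids and effective radii.  All statistics are organised around
the dimensionless radius R = distance-to-centroid / effective radius, with
R > 0.75 conventionally "peripheral" and R < 0.75 "central".

The layer provides per-bin positive counts and percentages (30 radial bins
by default), kernel density estimates of positive-cell locations, locally
weighted polynomial profiles with 95% confidence ribbons, per-island OLS
count regressions against condition factors, two-sample Kolmogorov–Smirnov
comparisons of radial distributions, and Welch's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import RadialProfile

__all__ = [
    "assign_dimensionless_radius",
    "radial_counts",
    "positive_density",
    "smooth_profile",
    "ribbons_overlap",
    "fit_count_regression",
    "RegressionResult",
    "ks_two_sample",
    "KSResult",
    "welch_t",
    "peripheral_central_intensity",
]

OFF_ISLAND_R = 1.2  # cells beyond this dimensionless radius are print spread


def _on_island(cells: pd.DataFrame) -> pd.DataFrame:
    if "off_island" in cells.columns:
        return cells.loc[~cells["off_island"].astype(bool)]
    return cells


def assign_dimensionless_radius(
    cells: pd.DataFrame,
    islands: pd.DataFrame,
    off_island_r: float = OFF_ISLAND_R,
) -> pd.DataFrame:
    """Add ``R`` (dimensionless radius) and ``off_island`` columns.

    ``R = distance(cell, island centroid) / effective_radius`` per cell;
    cells with R > ``off_island_r`` are flagged (printing spread) and are
    excluded by the downstream statistics.
    """
    missing = set(cells["island_id"]) - set(islands["island_id"])
    if missing:
        raise KeyError(f"cells reference unknown island ids: {sorted(missing)}")
    merged = cells.merge(
        islands[["island_id", "centroid_x", "centroid_y", "effective_radius"]],
        on="island_id",
        how="left",
        validate="many_to_one",
    )
    R = np.hypot(
        merged["x"] - merged["centroid_x"], merged["y"] - merged["centroid_y"]
    ) / merged["effective_radius"]
    out = cells.copy()
    out["R"] = R.to_numpy()
    out["off_island"] = out["R"] > off_island_r
    return out


def radial_counts(
    cells: pd.DataFrame,
    marker: str,
    n_bins: int = 30,
    r_range: tuple[float, float] = (0.0, OFF_ISLAND_R),
) -> pd.DataFrame:
    """Per-island, per-bin positive counts and percentages.

    Returns a tidy frame with columns ``island_id, bin, R_lo, R_hi, R_mid,
    n_positive, n_total, percent`` where ``percent`` is missing (NaN) in
    bins without cells.  A marker positivity column ``{marker}_positive``
    (or a boolean column named ``marker``) must be present.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    col = f"{marker}_positive" if f"{marker}_positive" in cells.columns else marker
    if col not in cells.columns:
        raise KeyError(f"no positivity column for marker {marker!r}")
    data = _on_island(cells)
    edges = np.linspace(r_range[0], r_range[1], n_bins + 1)
    rows = []
    for island_id, grp in data.groupby("island_id"):
        idx = np.digitize(grp["R"].to_numpy(), edges) - 1
        idx[grp["R"].to_numpy() == edges[-1]] = n_bins - 1
        inside = (idx >= 0) & (idx < n_bins)
        tot = np.bincount(idx[inside], minlength=n_bins)
        pos = np.bincount(
            idx[inside], weights=grp[col].to_numpy(dtype=float)[inside], minlength=n_bins
        ).astype(int)
        with np.errstate(invalid="ignore"):
            pct = np.where(tot > 0, 100.0 * pos / np.maximum(tot, 1), np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "island_id": island_id,
                    "bin": np.arange(n_bins),
                    "R_lo": edges[:-1],
                    "R_hi": edges[1:],
                    "R_mid": 0.5 * (edges[:-1] + edges[1:]),
                    "n_positive": pos,
                    "n_total": tot,
                    "percent": pct,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def positive_density(
    cells: pd.DataFrame,
    marker: str,
    condition: dict | None = None,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Probability density of R among marker-positive cells.

    Gaussian KDE (Silverman bandwidth) with boundary reflection at R = 0;
    the returned density integrates to 1 over the evaluation support.
    ``condition`` optionally filters rows by column: value pairs.
    """
    col = f"{marker}_positive" if f"{marker}_positive" in cells.columns else marker
    data = _on_island(cells)
    if condition:
        for key, val in condition.items():
            data = data[data[key] == val]
    R = data.loc[data[col].astype(bool), "R"].to_numpy(dtype=float)
    if R.size < 2:
        raise ValueError("need at least 2 positive cells for a density estimate")
    kde = stats.gaussian_kde(R, bw_method="silverman")
    bw = np.sqrt(kde.covariance[0, 0])
    if grid is None:
        grid = np.linspace(0.0, R.max() + 4 * bw, 512)
    dens = kde(grid) + kde(-grid)  # reflect at 0
    return np.asarray(grid), dens


def smooth_profile(
    R: np.ndarray,
    y: np.ndarray,
    eval_points: np.ndarray | None = None,
    span: float = 0.4,
    degree: int = 2,
) -> RadialProfile:
    """Local polynomial regression of a statistic against R, with 95% CI.

    A tricube-weighted polynomial of ``degree`` is fitted around each
    evaluation point using the fraction ``span`` of nearest observations
    (loess-style); the pointwise CI uses the weighted-least-squares
    variance of the fitted value with a global residual-variance estimate.
    Observations pooled across islands are treated as independent.
    """
    R = np.asarray(R, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(R) & np.isfinite(y)
    R, y = R[ok], y[ok]
    if np.unique(R).size < 5:
        raise ValueError("need at least 5 distinct radii for a smoothed profile")
    if eval_points is None:
        eval_points = np.linspace(R.min(), R.max(), 60)
    eval_points = np.asarray(eval_points, dtype=float)
    n = R.size
    k = max(int(np.ceil(span * n)), degree + 2)

    # global residual variance from a coarse pass
    yhat = np.interp(R, *_quick_fit(R, y, degree, span))
    resid = y - yhat
    sigma2 = float(resid @ resid) / max(n - (degree + 1), 1)

    fitted = np.empty(eval_points.size)
    se2_unit = np.empty(eval_points.size)  # Var(fit)/sigma^2
    for i, x0 in enumerate(eval_points):
        d = np.abs(R - x0)
        h = max(np.partition(d, min(k, n) - 1)[min(k, n) - 1], 1e-12)
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        sel = w > 0
        X = np.vander(R[sel] - x0, degree + 1, increasing=True)
        W = w[sel]
        XtW = X.T * W
        A = XtW @ X
        A += np.eye(degree + 1) * 1e-12 * max(np.trace(A), 1.0)
        fitted[i] = np.linalg.solve(A, XtW @ y[sel])[0]
        Ainv = np.linalg.inv(A)
        # Var(fit(x0)) = e0' A^-1 X'W^2 X A^-1 e0 * sigma^2
        M = Ainv @ (X.T * W**2) @ X @ Ainv
        se2_unit[i] = M[0, 0]
    ci = 1.96 * np.sqrt(np.maximum(se2_unit, 0) * sigma2)
    edges = np.empty(eval_points.size + 1)
    mids = eval_points
    edges[1:-1] = 0.5 * (mids[:-1] + mids[1:])
    edges[0] = mids[0] - (edges[1] - mids[0])
    edges[-1] = mids[-1] + (mids[-1] - edges[-2])
    counts, _ = np.histogram(R, bins=edges)
    return RadialProfile(
        bin_edges=edges,
        values=fitted,
        counts=counts,
        ci_low=fitted - ci,
        ci_high=fitted + ci,
        statistic="loess_fit",
    )


def _quick_fit(R, y, degree, span):
    """Coarse loess pass used only to estimate the residual variance."""
    xs = np.linspace(R.min(), R.max(), 40)
    n = R.size
    k = max(int(np.ceil(span * n)), degree + 2)
    out = np.empty(xs.size)
    for i, x0 in enumerate(xs):
        d = np.abs(R - x0)
        h = max(np.partition(d, min(k, n) - 1)[min(k, n) - 1], 1e-12)
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        X = np.vander(R - x0, degree + 1, increasing=True)
        XtW = X.T * w
        A = XtW @ X
        A += np.eye(degree + 1) * 1e-12 * max(np.trace(A), 1.0)
        out[i] = np.linalg.solve(A, XtW @ y)[0]
    return xs, out


def ribbons_overlap(a: RadialProfile, b: RadialProfile) -> np.ndarray:
    """Pointwise overlap of two 95% CI ribbons evaluated on the same grid.

    Non-overlap at a point is the conventional P < 0.05 visual criterion
    for a difference between two conditions there.
    """
    if not np.allclose(a.bin_edges, b.bin_edges):
        raise ValueError("profiles must share evaluation points")
    return ~((a.ci_high < b.ci_low) | (b.ci_high < a.ci_low))


@dataclass
class RegressionResult:
    """OLS coefficient estimates for per-island counts vs condition factors."""

    terms: list[str]
    beta: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_value: np.ndarray
    diagnostics: dict
    model: object  # fitted statsmodels results, for inspection

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "beta": self.beta,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p_value": self.p_value,
            }
        )

    def __getitem__(self, term: str) -> dict:
        i = self.terms.index(term)
        return {
            "beta": float(self.beta[i]),
            "ci_low": float(self.ci_low[i]),
            "ci_high": float(self.ci_high[i]),
            "p_value": float(self.p_value[i]),
        }

    def summary(self) -> str:
        return self.model.summary().as_text()


def fit_count_regression(
    island_counts: pd.DataFrame,
    response: str = "count",
    factors: list[str] | None = None,
    reference: dict | None = None,
) -> RegressionResult:
    """OLS of per-island positive-cell counts on categorical condition factors.

    Each island contributes one observation.  β for a factor level is the
    mean change in counts relative to the reference level (default: the
    control level such as IgG, passed via ``reference={'ligand': 'IgG'}``);
    95% CIs and per-term p-values come straight from the OLS fit, and
    residual diagnostics (Breusch–Pagan heteroscedasticity and Jarque–Bera
    normality p-values) are attached.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.diagnostic import het_breuschpagan
    from statsmodels.stats.stattools import jarque_bera

    if factors is None:
        factors = [c for c in island_counts.columns if c not in (response, "island_id")]
    if not factors:
        raise ValueError("no condition factors given")
    for f in factors:
        counts = island_counts.groupby(f).size()
        if (counts < 2).any():
            raise ValueError(f"factor {f!r} has levels with fewer than 2 islands")
    reference = reference or {}
    terms = []
    for f in factors:
        if f in reference:
            terms.append(f"C({f}, Treatment(reference={reference[f]!r}))")
        else:
            terms.append(f"C({f})")
    formula = f"{response} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=island_counts)
    # refuse aliased designs with an explicit message
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        q, r = np.linalg.qr(model.exog)
        aliased = [
            model.exog_names[i]
            for i in range(r.shape[1])
            if abs(r[i, i]) < 1e-8 * abs(r[0, 0])
        ]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    res = model.fit()
    conf = res.conf_int(alpha=0.05)
    keep = [i for i, name in enumerate(res.params.index) if name != "Intercept"]
    names = [res.params.index[i] for i in keep]
    bp_p = het_breuschpagan(res.resid, model.exog)[1]
    jb_p = jarque_bera(res.resid)[1]
    diagnostics = {
        "breusch_pagan_p": float(bp_p),
        "jarque_bera_p": float(jb_p),
        "homoscedastic": bool(bp_p > 0.05),
        "residuals_normal": bool(jb_p > 0.05),
        "n_obs": int(res.nobs),
    }
    return RegressionResult(
        terms=[_clean_term(t) for t in names],
        beta=res.params.iloc[keep].to_numpy(),
        ci_low=conf.iloc[keep, 0].to_numpy(),
        ci_high=conf.iloc[keep, 1].to_numpy(),
        p_value=res.pvalues.iloc[keep].to_numpy(),
        diagnostics=diagnostics,
        model=res,
    )


def _clean_term(name: str) -> str:
    """'C(ligand, Treatment(...))[T.DLL4]' -> 'ligand[DLL4]'."""
    if "[" not in name:
        return name
    base, level = name.split("[", 1)
    level = level.rstrip("]").removeprefix("T.")
    factor = base[2:].split(",")[0].strip() if base.startswith("C(") else base
    factor = factor.rstrip(")")
    return f"{factor}[{level}]"


@dataclass
class KSResult:
    """Two-sample Kolmogorov–Smirnov comparison."""

    d_statistic: float
    p_value: float
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.d_statistic <= 1.0):
            raise ValueError("D must lie in [0, 1]")


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> KSResult:
    """Exact supremum distance D between two empirical CDFs, with the
    asymptotic two-sample p-value (exact enumeration for small samples)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if (a.size < 10 and b.size < 10) else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return KSResult(
        d_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=a.size,
        n_b=b.size,
    )


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: returns (t, df, p).

    Two groups with zero variance and equal means return (0, n_a+n_b-2, 1)
    by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return float("inf"), float(a.size + b.size - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    se2a, se2b = va / a.size, vb / b.size
    df = (se2a + se2b) ** 2 / (se2a**2 / (a.size - 1) + se2b**2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def peripheral_central_intensity(
    cells: pd.DataFrame,
    channel: str,
    r_cut: float = 0.75,
) -> dict:
    """Peripheral-vs-central intensity contrast within a condition.

    Returns the ratio of mean intensity over R > ``r_cut`` to the mean over
    R < ``r_cut`` together with a Welch test between the two cell sets.
    """
    col = f"{channel}_intensity" if f"{channel}_intensity" in cells.columns else channel
    data = _on_island(cells)
    hi = data.loc[data["R"] > r_cut, col].to_numpy(dtype=float)
    lo = data.loc[data["R"] < r_cut, col].to_numpy(dtype=float)
    if hi.size == 0 or lo.size == 0:
        raise ValueError("one side of the radial split is empty")
    t, df, p = welch_t(hi, lo)
    return {
        "ratio": float(hi.mean() / lo.mean()),
        "mean_peripheral": float(hi.mean()),
        "mean_central": float(lo.mean()),
        "n_peripheral": int(hi.size),
        "n_central": int(lo.size),
        "t": t,
        "df": df,
        "p_value": p,
    }


def percent_change(cells_a: pd.DataFrame, cells_b: pd.DataFrame, channel: str) -> dict:
    """Overall intensity percent change of condition A relative to B,
    (mean_A − mean_B)/mean_B × 100, with a Welch test."""
    col = f"{channel}_intensity"
    a = _on_island(cells_a)[col].to_numpy(dtype=float)
    b = _on_island(cells_b)[col].to_numpy(dtype=float)
    t, df, p = welch_t(a, b)
    return {
        "percent_change": float((a.mean() - b.mean()) / b.mean() * 100.0),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "t": t,
        "df": df,
        "p_value": p,
    }
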
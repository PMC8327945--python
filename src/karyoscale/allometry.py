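"""Allometric scaling of nucleus volume on cell volume.

The central model is the power law

    nucleus_volume = a · cell_volume^b

fitted on log10–log10 data, where ``a`` is the normalization constant and
``b`` the size-scaling exponent. Regressing the N:C ratio directly on cell
volume would put cell volume on both sides of the model (it is the
denominator of the response), so trends in the ratio are instead read off
the algebraic rearrangement

    log10(N/C) = log10(a) + (b − 1) · log10(C),

whose slope is exactly ``b − 1``. Isometry (b = 1) means a size-invariant
N:C ratio; b < 1 (hypoallometry) means larger cells have relatively
smaller nuclei.

Three line-fitting methods are offered: ordinary least squares (the
recommended default for allometric studies), classical major-axis
regression, and quantile regression — the latter two as robustness checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

__all__ = [
    "AllometryFit",
    "fit_allometry",
    "classify_isometry",
    "nc_ratio_slope",
    "fold_change_per_decade",
    "fit_allometry_groups",
]


@dataclass(frozen=True)
class AllometryFit:
    """Result of a log10–log10 allometric line fit.

    ``r_squared`` and ``residual_sd`` are on the log10 scale; ``r_squared``
    is reported for OLS only (NaN otherwise). ``ci_method`` records how the
    confidence interval was constructed.
    """

    log10_a: float
    b: float
    b_ci: tuple[float, float]
    method: str
    n: int
    r_squared: float = float("nan")
    residual_sd: float = float("nan")
    quantile_tau: float | None = None
    ci_method: str = "t"

    def __post_init__(self):
        lo, hi = self.b_ci
        if not (lo <= self.b <= hi):
            raise ValueError(f"b_ci {self.b_ci} does not bracket b={self.b}")
        if self.n < 3:
            raise ValueError("allometric fit requires n >= 3")


def _major_axis_ci(x: np.ndarray, y: np.ndarray, theta_hat: float, alpha: float):
    """CI for the major-axis slope by inverting the rotation test.

    For a hypothesised axis at angle θ, rotating the data by θ makes the
    along-axis and across-axis coordinates uncorrelated under H0; the
    correlation of the rotated coordinates is tested with the usual
    t = r·√((n−2)/(1−r²)) statistic (Jolicoeur's approach). The CI is the
    set of angles not rejected, found by root-finding on either side of the
    estimate and mapped back to slopes via tan θ.
    """
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = xc @ xc
    syy = yc @ yc
    sxy = xc @ yc
    tcrit = stats.t.ppf(1 - alpha / 2, n - 2)

    def tstat(theta):
        c, s = np.cos(theta), np.sin(theta)
        suu = c * c * sxx + 2 * s * c * sxy + s * s * syy
        svv = s * s * sxx - 2 * s * c * sxy + c * c * syy
        suv = s * c * (syy - sxx) + (c * c - s * s) * sxy
        denom = suu * svv
        if denom <= 0:
            return 0.0
        r = suv / np.sqrt(denom)
        r = np.clip(r, -0.999999999, 0.999999999)
        return r * np.sqrt((n - 2) / (1 - r * r))

    def crossing(lo, hi):
        # |t| rises from 0 at theta_hat; find where it first hits tcrit
        grid = np.linspace(lo, hi, 512)
        vals = np.abs([tstat(t) for t in grid]) - tcrit
        idx = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
        if len(idx) == 0:
            return None  # never rejected on this side: unbounded
        i = idx[0]
        f = lambda t: abs(tstat(t)) - tcrit
        return optimize.brentq(f, grid[i], grid[i + 1])

    eps = 1e-9
    upper_theta = crossing(theta_hat + eps, theta_hat + np.pi / 2 - eps)
    lower_theta = crossing(theta_hat - eps, theta_hat - np.pi / 2 + eps)
    hi = np.tan(upper_theta) if upper_theta is not None else np.inf
    lo = np.tan(lower_theta) if lower_theta is not None else -np.inf
    # tan is not monotone across ±π/2; guard against wrap-around
    if lo > hi:
        lo, hi = -np.inf, np.inf
    return lo, hi


def fit_allometry(
    cell_volume,
    nucleus_volume,
    method: str = "ols",
    quantile_tau: float = 0.5,
    ci_level: float = 0.95,
) -> AllometryFit:
    """Fit nucleus volume against cell volume on the log10–log10 scale.

    Parameters
    ----------
    cell_volume, nucleus_volume : array-like
        Paired volumes in μm³, strictly positive, length ≥ 3.
    method : {"ols", "major_axis", "quantile"}
        Line-fitting method. OLS is the primary estimator; major-axis and
        quantile regression serve as robustness checks.
    quantile_tau : float
        Quantile for ``method="quantile"`` (default: the median).
    ci_level : float
        Two-sided confidence level for the slope interval.
    """
    cell = np.asarray(cell_volume, dtype=float)
    nuc = np.asarray(nucleus_volume, dtype=float)
    if cell.shape != nuc.shape or cell.ndim != 1:
        raise ValueError("cell_volume and nucleus_volume must be equal-length 1-D")
    if len(cell) < 3:
        raise ValueError(f"need at least 3 pairs, got {len(cell)}")
    if (cell <= 0).any() or (nuc <= 0).any():
        raise ValueError("volumes must be strictly positive")
    x = np.log10(cell)
    y = np.log10(nuc)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in cell volume; slope is undefined")
    n = len(x)
    alpha = 1 - ci_level
    X = sm.add_constant(x)

    if method == "ols":
        res = sm.OLS(y, X).fit()
        lo, hi = res.conf_int(alpha=alpha)[1]
        return AllometryFit(
            log10_a=res.params[0],
            b=res.params[1],
            b_ci=(lo, hi),
            method="ols",
            n=n,
            r_squared=res.rsquared,
            residual_sd=float(np.sqrt(res.mse_resid)) if n > 2 else float("nan"),
            ci_method="t",
        )

    if method == "major_axis":
        xc = x - x.mean()
        yc = y - y.mean()
        sxx = xc @ xc
        syy = yc @ yc
        sxy = xc @ yc
        if sxy == 0 and syy <= sxx:
            b = 0.0
        else:
            # slope of the first principal axis of the (x, y) scatter
            b = (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy**2)) / (2 * sxy)
        theta_hat = np.arctan(b)
        lo, hi = _major_axis_ci(x, y, theta_hat, alpha)
        resid = y - (y.mean() + b * (x - x.mean()))
        return AllometryFit(
            log10_a=y.mean() - b * x.mean(),
            b=b,
            b_ci=(lo, hi),
            method="major_axis",
            n=n,
            residual_sd=float(resid.std(ddof=2)) if n > 2 else float("nan"),
            ci_method="rotation-test inversion",
        )

    if method == "quantile":
        res = sm.QuantReg(y, X).fit(q=quantile_tau)
        lo, hi = res.conf_int(alpha=alpha)[1]
        resid = y - res.predict(X)
        return AllometryFit(
            log10_a=res.params[0],
            b=res.params[1],
            b_ci=(lo, hi),
            method="quantile",
            n=n,
            residual_sd=float(resid.std(ddof=2)) if n > 2 else float("nan"),
            quantile_tau=quantile_tau,
            ci_method="asymptotic (kernel)",
        )

    raise ValueError(f"unknown method {method!r}; use ols, major_axis or quantile")


def classify_isometry(fit: AllometryFit) -> str:
    """Classify the scaling: isometric iff 1 lies in the 95% CI (inclusive).

    Returns "hypoallometric" (CI entirely below 1: N:C falls with cell
    size), "isometric", or "hyperallometric" (CI entirely above 1).
    Boundary convention: a CI endpoint exactly at 1 counts as isometric.
    """
    lo, hi = fit.b_ci
    if lo <= 1.0 <= hi:
        return "isometric"
    return "hypoallometric" if hi < 1.0 else "hyperallometric"


def nc_ratio_slope(fit: AllometryFit) -> tuple[float, tuple[float, float]]:
    """Slope of log10(N:C) on log10(cell volume): exactly b − 1.

    The N:C trend is size-invariant iff 0 lies in the returned CI — the
    same decision as :func:`classify_isometry`, by construction.
    """
    lo, hi = fit.b_ci
    return fit.b - 1.0, (lo - 1.0, hi - 1.0)


def fold_change_per_decade(fit: AllometryFit) -> float:
    """Multiplicative change in nucleus volume per 10-fold change in cell volume.

    10^b: 10 under isometry, 1 for a size-invariant nucleus.
    """
    return float(10.0**fit.b)


def fit_allometry_groups(cells, group_col: str, method: str = "ols", **kwargs):
    """Fit one allometry per group of a cell table; returns a summary frame.

    Each row carries the group label, n, b with CI, b − 1 with CI, 10^b,
    and the isometry classification — the shape of a per-dataset slope
    summary table.
    """
    import pandas as pd

    rows = []
    for name, grp in cells.groupby(group_col, sort=False):
        fit = fit_allometry(
            grp["cell_volume_um3"], grp["nucleus_volume_um3"], method=method, **kwargs
        )
        slope, (slo, shi) = nc_ratio_slope(fit)
        rows.append(
            {
                group_col: name,
                "n": fit.n,
                "b": fit.b,
                "b_lo": fit.b_ci[0],
                "b_hi": fit.b_ci[1],
                "b_minus_1": slope,
                "b_minus_1_lo": slo,
                "b_minus_1_hi": shi,
                "fold_per_decade": fold_change_per_decade(fit),
                "classification": classify_isometry(fit),
            }
        )
    return pd.DataFrame(rows)
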
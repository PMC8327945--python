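"""DNA-content → nucleus-volume calibration.

Genome size (C-value, pg) is reported far more often than nucleus volume,
and the two are close to proportional. The calibration is an ANCOVA on the
log10 scale: a single slope shared by all clades with clade-specific
intercepts,

    log10(nucleus μm³) = intercept(clade) + slope · log10(DNA pg).

Slope homogeneity across clades is checked with a partial F-test on the
clade × DNA interaction at α = 0.05; if the interaction is significant the
shared-slope model is still returned, with ``homogeneous_slopes = False``
and the per-clade slopes logged. Fitted models convert DNA-only species
records into inferred nucleus volumes, with back-transformed t-based 95%
prediction intervals (point predictions are medians on the natural scale;
no back-transform bias correction is applied).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger("karyoscale")

__all__ = [
    "CalibrationModel",
    "fit_calibration",
    "test_isometry_of_calibration",
    "predict_nucleus_volume",
    "augment_with_inferred_nuclei",
]

MIN_SPECIES_PER_CLADE = 3


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted shared-slope / clade-intercept calibration on the log10 scale."""

    slope: float
    intercepts: dict[str, float]
    residual_sd: float
    r_squared: float
    slope_ci: tuple[float, float]
    homogeneous_slopes: bool
    n_species: int
    df_resid: int
    # per-clade training summaries needed for prediction intervals
    slope_se: float = float("nan")
    clade_stats: dict[str, tuple[int, float, float]] = field(default_factory=dict)
    per_clade_slopes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")


def fit_calibration(table: pd.DataFrame, alpha: float = 0.05) -> CalibrationModel:
    """Fit the calibration from species with both DNA content and a measured nucleus.

    Clades with fewer than three usable species are excluded with a warning
    (their intercepts would be little more than noise); having no usable
    rows at all is an error. R² and the residual SD are on the log10 scale.
    """
    usable = table[
        table["nucleus_volume_um3"].notna() & table["dna_content_pg"].notna()
    ].copy()
    counts = usable.groupby("clade")["species"].size()
    small = counts[counts < MIN_SPECIES_PER_CLADE]
    if len(small):
        logger.warning(
            "excluding clades with < %d calibration species: %s",
            MIN_SPECIES_PER_CLADE,
            dict(small),
        )
        usable = usable[~usable["clade"].isin(small.index)]
    if usable.empty:
        raise ValueError("no usable calibration rows (need nucleus volume and DNA content)")

    y = np.log10(usable["nucleus_volume_um3"].to_numpy(float))
    x = np.log10(usable["dna_content_pg"].to_numpy(float))
    clades = sorted(usable["clade"].unique())
    n = len(y)

    # design: one intercept column per clade (cell-means coding) + shared slope
    dummies = pd.get_dummies(usable["clade"], dtype=float)[clades].to_numpy()
    X = np.column_stack([dummies, x])
    res = sm.OLS(y, X).fit()
    slope = float(res.params[-1])
    slope_se = float(res.bse[-1])
    df_resid = int(res.df_resid)
    tcrit = stats.t.ppf(1 - alpha / 2, df_resid)
    slope_ci = (slope - tcrit * slope_se, slope + tcrit * slope_se)
    # centered R^2 (the cell-means model has no single intercept column)
    ss_res = float(res.ssr)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    residual_sd = float(np.sqrt(res.ssr / df_resid)) if df_resid > 0 else 0.0

    homogeneous = True
    per_clade_slopes: dict[str, float] = {}
    if len(clades) > 1:
        Xint = np.column_stack([dummies, dummies * x[:, None]])
        res_int = sm.OLS(y, Xint).fit()
        # partial F-test of the clade x DNA interaction; an improvement at
        # floating-point rounding scale (e.g. exact-line data) is no evidence
        # of heterogeneity
        df_num = res.df_resid - res_int.df_resid
        negligible = (res.ssr - res_int.ssr) <= 1e-10 * max(ss_tot, 1.0)
        if df_num > 0 and res_int.df_resid > 0 and res_int.ssr > 0 and not negligible:
            f = ((res.ssr - res_int.ssr) / df_num) / (res_int.ssr / res_int.df_resid)
            p = stats.f.sf(f, df_num, res_int.df_resid)
            homogeneous = bool(p >= alpha)
        per_clade_slopes = {
            c: float(res_int.params[len(clades) + i]) for i, c in enumerate(clades)
        }
        if not homogeneous:
            logger.warning(
                "clade x DNA interaction significant (p=%.3g); per-clade slopes: %s",
                p,
                {c: round(v, 3) for c, v in per_clade_slopes.items()},
            )

    clade_stats = {}
    for i, c in enumerate(clades):
        mask = usable["clade"].to_numpy() == c
        xc = x[mask]
        clade_stats[c] = (int(mask.sum()), float(xc.mean()), float(((xc - xc.mean()) ** 2).sum()))

    return CalibrationModel(
        slope=slope,
        intercepts={c: float(res.params[i]) for i, c in enumerate(clades)},
        residual_sd=residual_sd,
        r_squared=max(0.0, min(1.0, r_squared)),
        slope_ci=slope_ci,
        homogeneous_slopes=homogeneous,
        n_species=n,
        df_resid=df_resid,
        slope_se=slope_se,
        clade_stats=clade_stats,
        per_clade_slopes=per_clade_slopes,
    )


def test_isometry_of_calibration(model: CalibrationModel) -> bool:
    """True iff the calibration slope's 95% CI contains 1 (inclusive).

    A slope of 1 means DNA content and nucleus volume are proportional, so
    DNA-inferred and directly measured nucleus sizes scale identically with
    cell size.
    """
    lo, hi = model.slope_ci
    return bool(lo <= 1.0 <= hi)


# not a pytest case, despite the conventional statistics naming
test_isometry_of_calibration.__test__ = False


def predict_nucleus_volume(
    model: CalibrationModel,
    clade: str,
    dna_content_pg,
    ci_level: float = 0.95,
):
    """Predicted nucleus volume (μm³) and prediction interval for a DNA content.

    The point prediction is 10^(intercept(clade) + slope·log10 DNA) — the
    median on the natural scale. The prediction interval is t-based on the
    log10 scale (residual variance + mean-estimation variance at the new x)
    and back-transformed. Scalar in, scalar out; array in, arrays out.
    """
    if clade not in model.intercepts:
        raise KeyError(
            f"clade {clade!r} not in calibration model; available: "
            f"{sorted(model.intercepts)}"
        )
    dna = np.asarray(dna_content_pg, dtype=float)
    scalar = dna.ndim == 0
    dna = np.atleast_1d(dna)
    if (dna <= 0).any():
        raise ValueError("dna_content_pg must be strictly positive")
    x = np.log10(dna)
    mean_log = model.intercepts[clade] + model.slope * x
    n_c, xbar_c, sxx_c = model.clade_stats.get(clade, (0, 0.0, 0.0))
    # variance of the fitted mean: intercept part (clade mean) + slope part
    if n_c > 0 and sxx_c > 0:
        var_mean = model.residual_sd**2 / n_c + (x - xbar_c) ** 2 * model.slope_se**2
    else:
        var_mean = np.zeros_like(x)
    se_pred = np.sqrt(model.residual_sd**2 + var_mean)
    tcrit = stats.t.ppf(1 - (1 - ci_level) / 2, max(model.df_resid, 1))
    lo = 10.0 ** (mean_log - tcrit * se_pred)
    hi = 10.0 ** (mean_log + tcrit * se_pred)
    point = 10.0**mean_log
    if scalar:
        return float(point[0]), (float(lo[0]), float(hi[0]))
    return point, (lo, hi)


def augment_with_inferred_nuclei(
    table: pd.DataFrame, model: CalibrationModel
) -> pd.DataFrame:
    """Fill missing nucleus volumes from DNA content via the calibration.

    Rows that already carry a measured nucleus volume are never touched.
    Rows whose clade is absent from the model pass through unchanged with a
    warning. Filled rows get ``nucleus_source = "inferred"``.
    """
    out = table.copy()
    needs = out["nucleus_volume_um3"].isna() & out["dna_content_pg"].notna()
    unknown = needs & ~out["clade"].isin(model.intercepts)
    if unknown.any():
        logger.warning(
            "%d row(s) have clades absent from the calibration model (%s); "
            "left unfilled",
            int(unknown.sum()),
            sorted(out.loc[unknown, "clade"].unique()),
        )
    fill = needs & ~unknown
    for clade, idx in out[fill].groupby("clade").groups.items():
        point, _ = predict_nucleus_volume(
            model, clade, out.loc[idx, "dna_content_pg"].to_numpy(float)
        )
        out.loc[idx, "nucleus_volume_um3"] = point
        out.loc[idx, "nucleus_source"] = "inferred"
    return out
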
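"""Mixed-effects scaling exponent for the artificial-selection experiment.

The size-scaling coefficient b between cell volume and nucleus volume in
the selection lineages is estimated with a linear mixed model on the log10
scale:

    log10(nucleus) ~ log10(cell) + generation block
                     + (random intercept + random slope | lineage-in-generation)

The generation block (350 vs 450 generations of selection) is a fixed
effect; each lineage nested within a generation gets a correlated random
intercept and random slope (unstructured 2×2 covariance, switchable to
independent). Fitting is by REML via statsmodels MixedLM. The slope CI is
a Wald normal-approximation interval, documented as such.

:func:`partial_residual_points` removes the block effect and the predicted
(BLUP) lineage contributions from each cell so that the adjusted points
can be plotted against cell volume; because the mixed-model residuals are
exactly orthogonal to the fixed-effect columns at the REML solution, an
OLS line through the adjusted points recovers the fixed slope.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

logger = logging.getLogger("karyoscale")

__all__ = ["SelectionFit", "fit_selection_lmm", "partial_residual_points"]


@dataclass(frozen=True)
class SelectionFit:
    """REML fit of the selection-experiment scaling model."""

    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    block_effects: dict[int, float]  # log10 shift of each non-reference generation
    random_sd: dict[str, float]  # lineage_intercept, lineage_slope, residual
    n_cells: int
    n_lineages: int
    converged: bool
    reference_generation: int
    random_effects: dict[str, pd.Series] | None = None

    def __post_init__(self):
        lo, hi = self.slope_ci
        if not (lo <= self.slope <= hi):
            raise ValueError("slope_ci must contain slope")


def fit_selection_lmm(
    cells: pd.DataFrame,
    correlated_random_effects: bool = True,
    ci_level: float = 0.95,
) -> SelectionFit:
    """Fit the random-slope model to a selection-experiment cell table.

    Requires ``lineage`` and ``generation`` columns and at least 3
    lineages (random effects are unidentifiable otherwise). On optimizer
    non-convergence the fit is still returned, with ``converged=False``
    and a logged warning.
    """
    for col in ("lineage", "generation"):
        if col not in cells.columns or cells[col].isna().all():
            raise ValueError(f"cell table must carry a populated {col!r} column")
    data = cells.dropna(subset=["lineage", "generation"]).copy()
    data["log10_cell"] = np.log10(data["cell_volume_um3"].astype(float))
    data["log10_nucleus"] = np.log10(data["nucleus_volume_um3"].astype(float))
    data["generation"] = data["generation"].astype(int)
    data["unit"] = (
        data["generation"].astype(str) + ":" + data["lineage"].astype(str)
    )
    n_lineages = data["unit"].nunique()
    if n_lineages < 3:
        raise ValueError(
            f"need >= 3 lineage units to identify random effects, got {n_lineages}"
        )
    generations = sorted(data["generation"].unique())
    ref = generations[0]

    fixed = "log10_nucleus ~ log10_cell"
    if len(generations) > 1:
        fixed += " + C(generation)"
    model = smf.mixedlm(
        fixed,
        data,
        groups=data["unit"],
        re_formula="~log10_cell" if correlated_random_effects else None,
    )
    if not correlated_random_effects:
        # independent intercept and slope via variance-components formulas
        model = smf.mixedlm(
            fixed,
            data,
            groups=data["unit"],
            re_formula="~1",
            vc_formula={"slope": "0 + log10_cell"},
        )
    # gradient methods can stall short of a variance boundary (true zero
    # lineage variance); Powell finds the boundary but is weaker in the
    # interior — fit with both and keep the higher REML likelihood
    candidates = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("bfgs", "powell"):
            try:
                candidates.append(model.fit(reml=True, method=method))
            except Exception as exc:
                logger.warning("MixedLM %s optimizer failed: %s", method, exc)
    if not candidates:
        raise RuntimeError("selection LMM failed under all optimizers")
    converged_fits = [c for c in candidates if getattr(c, "converged", False)]
    pool = converged_fits or candidates
    res = max(pool, key=lambda c: c.llf)
    converged = bool(getattr(res, "converged", True))
    if not converged:
        logger.warning("selection LMM did not converge; treat estimates with caution")

    slope = float(res.params["log10_cell"])
    se = float(res.bse["log10_cell"])
    zcrit = stats.norm.ppf(1 - (1 - ci_level) / 2)
    block_effects = {
        g: float(res.params[f"C(generation)[T.{g}]"]) for g in generations[1:]
    }
    if correlated_random_effects:
        cov_re = res.cov_re
        sd_int = float(np.sqrt(max(cov_re.iloc[0, 0], 0.0)))
        sd_slope = float(np.sqrt(max(cov_re.iloc[1, 1], 0.0)))
    else:
        sd_int = float(np.sqrt(max(res.cov_re.iloc[0, 0], 0.0)))
        sd_slope = float(np.sqrt(max(res.vcomp[0], 0.0)))
    return SelectionFit(
        slope=slope,
        slope_ci=(slope - zcrit * se, slope + zcrit * se),
        intercept=float(res.params["Intercept"]),
        block_effects=block_effects,
        random_sd={
            "lineage_intercept": sd_int,
            "lineage_slope": sd_slope,
            "residual": float(np.sqrt(res.scale)),
        },
        n_cells=len(data),
        n_lineages=n_lineages,
        converged=converged,
        reference_generation=int(ref),
        random_effects={k: v for k, v in res.random_effects.items()},
    )


def partial_residual_points(cells: pd.DataFrame, fit: SelectionFit) -> pd.DataFrame:
    """Adjust each cell's log10 nucleus volume for block and lineage effects.

    Subtracts the estimated generation-block shift and the predicted
    (BLUP) lineage intercept/slope contributions, leaving points whose OLS
    slope on log10 cell volume equals the fixed slope (and whose N:C slope
    equals b − 1). Returns a copy with ``log10_cell``,
    ``adj_log10_nucleus`` and ``adj_log10_nc`` columns.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; adjusted points would be unreliable")
    out = cells.dropna(subset=["lineage", "generation"]).copy()
    out["generation"] = out["generation"].astype(int)
    out["log10_cell"] = np.log10(out["cell_volume_um3"].astype(float))
    adj = np.log10(out["nucleus_volume_um3"].astype(float)).to_numpy()
    for g, eff in fit.block_effects.items():
        adj = adj - eff * (out["generation"] == g).to_numpy(float)
    if fit.random_effects:
        unit = out["generation"].astype(str) + ":" + out["lineage"].astype(str)
        for key, re_vals in fit.random_effects.items():
            mask = (unit == key).to_numpy()
            if not mask.any():
                continue
            vals = re_vals.to_dict()
            b0 = vals.get("Group", vals.get("unit", 0.0))
            b1 = vals.get("log10_cell", vals.get("slope", 0.0))
            adj[mask] -= b0 + b1 * out.loc[mask, "log10_cell"].to_numpy()
    out["adj_log10_nucleus"] = adj
    out["adj_log10_nc"] = adj - out["log10_cell"]
    return out
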
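"""End-to-end orchestration: simulate → calibrate → fit → classify → report.

A single YAML config drives the three study scales. Stages:

* ``simulate`` — generate the synthetic inputs (among-species tree and
  trait table, within-species cell tables, selection-experiment table)
  from the config's simulation specs, or load user-supplied CSV/Newick
  inputs instead;
* ``calibrate`` — fit the DNA→nucleus calibration on species with both
  measurements and fill DNA-only species with inferred nucleus volumes;
* ``among`` — per-clade allometric slope table plus the Bayesian
  phylogenetic mixed model;
* ``within`` — apply the inclusion rules (minimum observations,
  manipulated-strain exclusion) and fit one allometry per dataset;
* ``selection`` — the random-slope mixed model and partial-residual
  points;
* ``report`` — a markdown summary of slopes b, b − 1, CIs and isometry
  classifications per group.

Every stage is deterministic given the config and master seed; a manifest
records the seed, stage status, and SHA-256 hashes of every output file.
Input files are never modified.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allometry import fit_allometry_groups
from .calibration import augment_with_inferred_nuclei, fit_calibration
from .io import (
    aggregate_per_species,
    filter_cell_table,
    read_cell_table,
    read_species_table,
    read_tree,
    write_cell_table,
    write_newick,
    write_species_table,
)
from .phylo import PhyloModelSpec, fit_phylo_mm
from .selection import fit_selection_lmm, partial_residual_points
from .simulate import (
    AmongSpeciesSimSpec,
    SelectionSimSpec,
    simulate_among_species,
    simulate_selection_experiment,
    simulate_within_species,
)

logger = logging.getLogger("karyoscale")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "render_report"]

_STAGES = ("simulate", "calibrate", "among", "within", "selection", "report")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; see module docstring for stages.

    Methods-level constants (minimum observations per dataset, MCMC chain
    settings, CI level) are named keys with the study's values as
    defaults.
    """

    output_dir: str = "karyoscale_out"
    seed: int = 0
    stages: dict = field(
        default_factory=lambda: {s: True for s in _STAGES}
    )
    min_n: int = 20
    exclude_manipulated: bool = True
    allometry_method: str = "ols"
    quantile_tau: float = 0.5
    ci_level: float = 0.95
    # simulation specs (used when the simulate stage is on)
    among_sim: dict = field(default_factory=dict)
    infer_fraction: float = 0.5
    within_sim: list = field(
        default_factory=lambda: [
            {"b": 0.58, "log10_a": -1.0, "n": 300, "dataset_id": "within_b058"},
            {"b": 0.80, "log10_a": -1.1, "n": 300, "dataset_id": "within_b080"},
            {"b": 1.00, "log10_a": -1.2, "n": 300, "dataset_id": "within_b100"},
        ]
    )
    selection_sim: dict = field(default_factory=dict)
    # MCMC settings for the among-species model
    mcmc: dict = field(
        default_factory=lambda: {
            "nitt": 500_000,
            "thin": 100,
            "burnin": 10_000,
            "n_chains": 2,
        }
    )
    # user-supplied inputs (used when the simulate stage is off)
    species_table_path: str | None = None
    tree_path: str | None = None
    cell_table_path: str | None = None
    selection_table_path: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}; valid: {_STAGES}")
        for p in (
            self.species_table_path,
            self.tree_path,
            self.cell_table_path,
            self.selection_table_path,
        ):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")

    def stage_on(self, name: str) -> bool:
        return bool(self.stages.get(name, False))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_df(df: pd.DataFrame, path: Path, float_format="%.10g") -> None:
    df.to_csv(path, index=False, float_format=float_format)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the manifest dictionary.

    Outputs land under ``config.output_dir``: generated inputs in
    ``inputs/``, result tables in ``results/``, the report as
    ``report.md`` and the manifest as ``manifest.json``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    inputs_dir = out / "inputs"
    results_dir = out / "results"
    inputs_dir.mkdir(parents=True, exist_ok=True)
    results_dir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }
    results: dict = {}
    seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2**31)
    current = "simulate"

    try:
        # ------------------------------------------------------------------
        # inputs: simulate or load
        # ------------------------------------------------------------------
        tree = species = cells = selection_cells = None
        if config.stage_on("simulate"):
            among_spec = AmongSpeciesSimSpec(
                **{"seed": int(seeds[0]), **config.among_sim}
            )
            tree, species, truth = simulate_among_species(among_spec)
            # hide a fraction of measured nuclei so the calibration stage
            # has DNA-only species to infer
            rng = np.random.default_rng(int(seeds[1]))
            hide = rng.random(len(species)) < config.infer_fraction
            species = species.copy()
            species.loc[hide, "nucleus_volume_um3"] = np.nan
            species.loc[hide, "nucleus_source"] = np.nan
            (inputs_dir / "tree.nwk").write_text(write_newick(tree) + "\n")
            write_species_table(species, inputs_dir / "species.csv")
            truth_flat = {
                f"{k}[{c}]" if isinstance(v, dict) else k: (v[c] if isinstance(v, dict) else v)
                for k, v in truth.items() if k != "lineage_effects"
                for c in (v.keys() if isinstance(v, dict) else [None])
            }
            pd.DataFrame([truth_flat]).to_csv(inputs_dir / "among_truth.csv", index=False)

            within_tables = []
            for i, kw in enumerate(config.within_sim):
                within_tables.append(
                    simulate_within_species(**{"seed": int(seeds[2]) + i, **kw})
                )
            cells = pd.concat(within_tables, ignore_index=True) if within_tables else None
            if cells is not None:
                write_cell_table(cells, inputs_dir / "within_cells.csv")

            sel_spec = SelectionSimSpec(**{"seed": int(seeds[3]), **config.selection_sim})
            selection_cells, sel_truth = simulate_selection_experiment(sel_spec)
            write_cell_table(selection_cells, inputs_dir / "selection_cells.csv")
            sel_truth["lineage_effects"].to_csv(
                inputs_dir / "selection_truth.csv", index=False
            )
            manifest["stages"]["simulate"] = "ok"
        else:
            manifest["stages"]["simulate"] = "skipped"
            if config.species_table_path:
                species = read_species_table(config.species_table_path, clades=None)
            if config.tree_path:
                tree = read_tree(config.tree_path)
            if config.cell_table_path:
                cells = read_cell_table(config.cell_table_path)
            if config.selection_table_path:
                selection_cells = read_cell_table(config.selection_table_path)

        # ------------------------------------------------------------------
        current = "calibrate"
        if config.stage_on("calibrate") and species is not None:
            model = fit_calibration(species)
            results["calibration"] = model
            species = augment_with_inferred_nuclei(species, model)
            write_species_table(species, results_dir / "species_augmented.csv")
            cal_rows = {
                "slope": model.slope,
                "slope_lo": model.slope_ci[0],
                "slope_hi": model.slope_ci[1],
                "r_squared": model.r_squared,
                "residual_sd": model.residual_sd,
                "homogeneous_slopes": model.homogeneous_slopes,
                "n_species": model.n_species,
                **{f"intercept[{c}]": v for c, v in sorted(model.intercepts.items())},
            }
            _write_df(pd.DataFrame([cal_rows]), results_dir / "calibration.csv")
            manifest["stages"]["calibrate"] = "ok"
        else:
            manifest["stages"]["calibrate"] = "skipped"

        # ------------------------------------------------------------------
        current = "among"
        if config.stage_on("among") and species is not None and tree is not None:
            agg = aggregate_per_species(species.dropna(subset=["nucleus_volume_um3"]))
            clade_slopes = fit_allometry_groups(
                agg, "clade", method=config.allometry_method
            )
            results["among_slopes"] = clade_slopes
            _write_df(clade_slopes, results_dir / "among_clade_slopes.csv")

            spec = PhyloModelSpec(seed=int(seeds[4]), **config.mcmc)
            fit = fit_phylo_mm(spec, agg, tree)
            results["phylo_fit"] = fit
            summ = fit.summary
            rows = [
                {
                    "term": t,
                    "posterior_mean": m,
                    "ci_lo": lo,
                    "ci_hi": hi,
                    "geweke_z": summ.geweke_z.get(t, np.nan),
                }
                for t, (m, (lo, hi)) in summ.coefficients.items()
            ]
            rows += [
                {"term": t, "posterior_mean": v, "ci_lo": np.nan, "ci_hi": np.nan,
                 "geweke_z": summ.geweke_z.get(t, np.nan)}
                for t, v in summ.variance_components.items()
            ]
            _write_df(pd.DataFrame(rows), results_dir / "phylo_summary.csv")
            for i, ch in enumerate(fit.chains):
                _write_df(ch, results_dir / f"phylo_chain{i + 1}.csv")
            manifest["stages"]["among"] = "ok"
            manifest["phylo"] = {
                "n_retained": summ.n_retained,
                "interaction_dropped": summ.interaction_dropped,
                "converged": summ.converged,
            }
        else:
            manifest["stages"]["among"] = "skipped"

        # ------------------------------------------------------------------
        current = "within"
        if config.stage_on("within") and cells is not None:
            kept = filter_cell_table(
                cells, min_n=config.min_n, exclude_manipulated=config.exclude_manipulated
            )
            within_slopes = fit_allometry_groups(
                kept,
                "dataset_id",
                method=config.allometry_method,
                **(
                    {"quantile_tau": config.quantile_tau}
                    if config.allometry_method == "quantile"
                    else {}
                ),
            )
            results["within_slopes"] = within_slopes
            _write_df(within_slopes, results_dir / "within_dataset_slopes.csv")
            manifest["stages"]["within"] = "ok"
        else:
            manifest["stages"]["within"] = "skipped"

        # ------------------------------------------------------------------
        current = "selection"
        if config.stage_on("selection") and selection_cells is not None:
            fit = fit_selection_lmm(selection_cells, ci_level=config.ci_level)
            results["selection_fit"] = fit
            row = {
                "slope": fit.slope,
                "slope_lo": fit.slope_ci[0],
                "slope_hi": fit.slope_ci[1],
                "b_minus_1": fit.slope - 1.0,
                "intercept": fit.intercept,
                "n_cells": fit.n_cells,
                "n_lineages": fit.n_lineages,
                "converged": fit.converged,
                **{f"block[{g}]": v for g, v in fit.block_effects.items()},
                **{f"sd_{k}": v for k, v in fit.random_sd.items()},
            }
            _write_df(pd.DataFrame([row]), results_dir / "selection_fit.csv")
            adj = partial_residual_points(selection_cells, fit)
            _write_df(
                adj[
                    ["treatment", "lineage", "generation", "log10_cell",
                     "adj_log10_nucleus", "adj_log10_nc"]
                ],
                results_dir / "selection_adjusted_points.csv",
            )
            manifest["stages"]["selection"] = "ok"
        else:
            manifest["stages"]["selection"] = "skipped"

        # ------------------------------------------------------------------
        current = "report"
        if config.stage_on("report"):
            report = render_report(results)
            (out / "report.md").write_text(report)
            manifest["stages"]["report"] = "ok"
        else:
            manifest["stages"]["report"] = "skipped"

    except Exception as exc:
        manifest["stages"][current] = f"error: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise PipelineError(current, exc) from exc

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _slope_table_md(df: pd.DataFrame, group_col: str) -> str:
    lines = [
        f"| {group_col} | n | b [95% CI] | b−1 [95% CI] | classification |",
        "|---|---|---|---|---|",
    ]
    for _, r in df.iterrows():
        lines.append(
            f"| {r[group_col]} | {int(r['n'])} "
            f"| {r['b']:.3f} [{r['b_lo']:.3f}, {r['b_hi']:.3f}] "
            f"| {r['b_minus_1']:.3f} [{r['b_minus_1_lo']:.3f}, {r['b_minus_1_hi']:.3f}] "
            f"| {r['classification']} |"
        )
    return "\n".join(lines)


def render_report(results: dict) -> str:
    """Markdown report of slopes, b − 1 rearrangements and classifications.

    Scatter panels are described textually (log10 N:C against log10 cell
    volume, fitted line of slope b − 1, null line at slope 0); no figures
    are produced.
    """
    if not results:
        return "# N:C ratio scaling report\n\nno stages run\n"
    parts = ["# N:C ratio scaling report\n"]
    if "calibration" in results:
        m = results["calibration"]
        parts.append(
            "## DNA → nucleus-volume calibration\n\n"
            f"- shared slope: {m.slope:.3f} "
            f"[{m.slope_ci[0]:.3f}, {m.slope_ci[1]:.3f}] "
            f"(isometric: {'yes' if m.slope_ci[0] <= 1 <= m.slope_ci[1] else 'no'})\n"
            f"- R² (log10 scale): {m.r_squared:.3f}; "
            f"homogeneous slopes across clades: {m.homogeneous_slopes}\n"
            f"- n = {m.n_species} species, {len(m.intercepts)} clades\n"
        )
    if "among_slopes" in results:
        parts.append("## Among-species slopes by clade\n")
        parts.append(_slope_table_md(results["among_slopes"], "clade"))
        parts.append(
            "\nEach clade panel: log10(N:C) against log10(cell volume), fitted "
            "line of slope b−1, dashed null line at slope 0 (size-invariant ratio).\n"
        )
    if "phylo_fit" in results:
        s = results["phylo_fit"].summary
        parts.append("## Phylogenetic mixed model\n")
        for t, (mean, (lo, hi)) in s.coefficients.items():
            parts.append(f"- {t}: {mean:.3f} [{lo:.3f}, {hi:.3f}]")
        parts.append(
            f"- retained samples/chain: {s.n_retained}; interaction dropped: "
            f"{s.interaction_dropped}; converged: {s.converged}\n"
        )
    if "within_slopes" in results:
        parts.append("## Within-species slopes by dataset\n")
        parts.append(_slope_table_md(results["within_slopes"], "dataset_id"))
        parts.append("")
    if "selection_fit" in results:
        f = results["selection_fit"]
        parts.append(
            "## Artificial-selection experiment\n\n"
            f"- fixed slope b: {f.slope:.3f} [{f.slope_ci[0]:.3f}, {f.slope_ci[1]:.3f}]"
            f" → N:C slope (b−1): {f.slope - 1:.3f}\n"
            f"- {f.n_cells} cells in {f.n_lineages} lineage units; "
            f"converged: {f.converged}\n"
        )
    return "\n".join(parts) + "\n"
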
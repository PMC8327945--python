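"""Synthetic data with known ground truth for every pipeline stage.

Each simulator emulates the statistical structure one of the analyses
assumes, so that estimators can be tested for parameter recovery:

* a Yule (pure-birth) tree as a stand-in phylogeny;
* Brownian-motion trait evolution on a tree (the covariance model the
  phylogenetic mixed model assumes);
* an among-species dataset: clade-structured log10 cell volumes evolved by
  BM, nucleus volumes from a power law with exponent ``b`` plus a
  phylogenetic deviation and iid noise, and DNA contents generated by
  inverting the DNA→nucleus calibration model;
* within-species cell tables: log-normal cell sizes with power-law nuclei;
* a three-treatment artificial-selection experiment with lineage-level
  random slopes/intercepts nested in generation blocks.

All randomness flows from a single master seed through
:class:`numpy.random.SeedSequence`, so every simulator is a pure function
of its spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .io import CELL_COLUMNS, SPECIES_COLUMNS, validate_cell_table, validate_species_table

__all__ = [
    "AmongSpeciesSimSpec",
    "SelectionSimSpec",
    "simulate_yule_tree",
    "simulate_bm_on_tree",
    "simulate_among_species",
    "simulate_within_species",
    "simulate_selection_experiment",
]


def _rng_stream(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministic per-component generators derived from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Trees and Brownian motion
# ---------------------------------------------------------------------------

def simulate_yule_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    prefix: str = "sp",
) -> dendropy.Tree:
    """Simulate an ultrametric pure-birth (Yule) tree with ``n_tips`` leaves.

    The process starts at the root with two lineages; while k lineages are
    extant the waiting time to the next split is Exponential(k·birth_rate)
    and a uniformly chosen lineage splits. After the n-th lineage appears a
    final Exponential(n·birth_rate) interval is appended to every pendant
    edge, so the expected tree height is Σ_{k=2}^{n} 1/(k·birth_rate).
    """
    if n_tips < 1:
        raise ValueError(f"n_tips must be >= 1, got {n_tips}")
    if birth_rate <= 0:
        raise ValueError(f"birth_rate must be > 0, got {birth_rate}")
    if rng is None:
        rng = np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    width = max(3, len(str(n_tips)))

    if n_tips == 1:
        tree.seed_node.taxon = taxa.new_taxon(f"{prefix}{1:0{width}d}")
        tree.seed_node.edge.length = float(rng.exponential(1.0 / birth_rate))
        return tree

    t = 0.0
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = tree.seed_node.new_child()
        active.append((child, 0.0))
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = int(rng.integers(k))
        node, start = active.pop(idx)
        node.edge.length = t - start
        for _ in range(2):
            active.append((node.new_child(), t))
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    for node, start in active:
        node.edge.length = t - start
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(f"{prefix}{i:0{width}d}")
    return tree


def simulate_bm_on_tree(
    tree: dendropy.Tree,
    root_value: float = 0.0,
    rate: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Brownian motion down a tree: returns {tip label: trait value}.

    Along an edge of length ℓ the trait gains an independent
    Normal(0, rate·ℓ) increment, so tip values are jointly multivariate
    normal with covariance rate·A(tree), A being the shared-path-length
    matrix.
    """
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if rng is None:
        rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree.seed_node): float(root_value)}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            length = node.edge.length or 0.0
            parent_val = values[id(node.parent_node)]
            values[id(node)] = parent_val + rng.normal(0.0, math.sqrt(rate * length))
        if node.is_leaf() and node.taxon is not None:
            out[node.taxon.label] = values[id(node)]
    return out


# ---------------------------------------------------------------------------
# Among-species simulation
# ---------------------------------------------------------------------------

# Defaults place clades across the ~6 orders of magnitude of cell volume
# seen across the tree of life, with an among-species exponent b < 1 so the
# N:C ratio declines in larger cells.
_DEFAULT_ROOTS = {
    "bacteria": 0.0,
    "phytoplankton": 1.5,
    "angiosperms": 3.0,
    "fish": 2.6,
    "frogs": 3.3,
    "salamanders": 3.9,
    "reptiles": 2.6,
    "birds": 2.1,
    "mammals": 1.9,
}
# Calibration intercepts: log10 nucleus volume at 1 pg of DNA, varying
# modestly by clade (different chromatin compaction).
_DEFAULT_CAL_INTERCEPTS = {
    "bacteria": 1.45,
    "phytoplankton": 1.35,
    "angiosperms": 1.25,
    "fish": 1.20,
    "frogs": 1.05,
    "salamanders": 1.00,
    "reptiles": 1.15,
    "birds": 1.30,
    "mammals": 1.10,
}


@dataclass(frozen=True)
class AmongSpeciesSimSpec:
    """Generating parameters for the among-species dataset.

    ``true_b``, ``true_log10_a``, ``root_log10_cell_volume`` and
    ``calibration_intercepts`` may be a single float (shared by all clades)
    or a per-clade mapping. ``phylo_sd_nucleus`` is the BM rate^(1/2) per
    unit branch length of the phylogenetic deviation added to log10 nucleus
    volume. ``dna_noise_sd`` is the log10 scatter of DNA content around the
    calibration-inverse of the power-law signal (species genuinely differ
    in DNA content at a given cell size); ``iid_sd_nucleus`` is the log10
    residual of the observed nucleus around the calibration line — its
    default (0.2) puts the calibration R² near 0.94.
    """

    clades: tuple[str, ...] = ("fish", "frogs", "birds", "mammals", "phytoplankton")
    n_species_per_clade: int = 36
    tree_birth_rate: float = 1.0
    root_log10_cell_volume: float | dict[str, float] | None = None
    bm_rate_cell: float = 0.35
    true_b: float | dict[str, float] = 0.7
    true_log10_a: float | dict[str, float] = -0.45
    phylo_sd_nucleus: float = 0.08
    iid_sd_nucleus: float = 0.20
    calibration_slope: float = 1.03
    calibration_intercepts: float | dict[str, float] | None = None
    dna_noise_sd: float = 0.12
    seed: int = 0

    def __post_init__(self):
        for name in ("phylo_sd_nucleus", "iid_sd_nucleus", "dna_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tree_birth_rate <= 0 or self.bm_rate_cell < 0:
            raise ValueError("tree_birth_rate must be > 0 and bm_rate_cell >= 0")
        if self.n_species_per_clade < 1:
            raise ValueError("n_species_per_clade must be >= 1")

    def per_clade(self, attr: str, default: dict[str, float]) -> dict[str, float]:
        value = getattr(self, attr)
        if value is None:
            # fall back to stock values; unseen clade labels get the mean
            mean = float(np.mean(list(default.values())))
            return {c: default.get(c, mean) for c in self.clades}
        if isinstance(value, dict):
            missing = set(self.clades) - set(value)
            if missing:
                raise ValueError(f"{attr} missing entries for clades {sorted(missing)}")
            return {c: float(value[c]) for c in self.clades}
        return {c: float(value) for c in self.clades}


def simulate_among_species(
    spec: AmongSpeciesSimSpec,
) -> tuple[dendropy.Tree, pd.DataFrame, dict]:
    """Simulate (tree, species trait table, truth record).

    One Yule subtree per clade is grafted onto a common root with a short
    stem. log10 cell volume evolves by BM from the clade root value; the
    latent nucleus signal is log10 a(clade) + b(clade)·log10 cell + BM
    deviation; log10 DNA content scatters (``dna_noise_sd``) around the
    calibration-inverse of that signal, and the observed log10 nucleus
    volume sits on the calibration line (shared slope, clade intercepts)
    with iid residual ``iid_sd_nucleus`` — so the calibration module can
    recover its own generating parameters without attenuation.
    """
    roots = spec.per_clade("root_log10_cell_volume", _DEFAULT_ROOTS)
    b = spec.per_clade("true_b", {})
    log10_a = spec.per_clade("true_log10_a", {})
    cal_int = spec.per_clade("calibration_intercepts", _DEFAULT_CAL_INTERCEPTS)

    rngs = _rng_stream(spec.seed, 1 + 4 * len(spec.clades))
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    rows = []
    stem = 0.5  # stem edge grafting each clade subtree to the shared root

    for ci, clade in enumerate(spec.clades):
        rng_tree, rng_cell, rng_phylo, rng_noise = rngs[1 + 4 * ci : 5 + 4 * ci]
        sub = simulate_yule_tree(
            spec.n_species_per_clade,
            spec.tree_birth_rate,
            rng=rng_tree,
            prefix=f"{clade}_",
        )
        cell = simulate_bm_on_tree(sub, roots[clade], spec.bm_rate_cell, rng=rng_cell)
        phylo_dev = simulate_bm_on_tree(sub, 0.0, spec.phylo_sd_nucleus**2, rng=rng_phylo)
        for sp in sorted(cell):
            log10_cell = cell[sp]
            # latent power-law nucleus signal; DNA content scatters around its
            # calibration-inverse (genuine x-variation), and the observed
            # nucleus sits on the calibration line with iid residual — so the
            # calibration fit recovers slope and intercepts without
            # errors-in-variables attenuation
            latent = log10_a[clade] + b[clade] * log10_cell + phylo_dev[sp]
            log10_dna = (latent - cal_int[clade]) / spec.calibration_slope + (
                rng_noise.normal(0.0, spec.dna_noise_sd)
            )
            log10_nuc = (
                cal_int[clade]
                + spec.calibration_slope * log10_dna
                + rng_noise.normal(0.0, spec.iid_sd_nucleus)
            )
            rows.append(
                {
                    "species": sp,
                    "clade": clade,
                    "cell_volume_um3": 10.0**log10_cell,
                    "nucleus_volume_um3": 10.0**log10_nuc,
                    "dna_content_pg": 10.0**log10_dna,
                    "nucleus_source": "measured",
                }
            )
        # graft the clade subtree under the shared root
        for leaf in sub.leaf_node_iter():
            leaf.taxon = taxa.get_taxon(leaf.taxon.label) or taxa.new_taxon(
                leaf.taxon.label
            )
        sub.seed_node.edge.length = stem
        tree.seed_node.add_child(sub.seed_node)

    tree.update_taxon_namespace()
    table = pd.DataFrame(rows)[SPECIES_COLUMNS]
    validate_species_table(table, clades=None)
    truth = {
        "true_b": b,
        "true_log10_a": log10_a,
        "root_log10_cell_volume": roots,
        "calibration_slope": spec.calibration_slope,
        "calibration_intercepts": cal_int,
        "bm_rate_cell": spec.bm_rate_cell,
        "phylo_sd_nucleus": spec.phylo_sd_nucleus,
        "iid_sd_nucleus": spec.iid_sd_nucleus,
        "dna_noise_sd": spec.dna_noise_sd,
        "seed": spec.seed,
    }
    return tree, table, truth


# ---------------------------------------------------------------------------
# Within-species simulation
# ---------------------------------------------------------------------------

def simulate_within_species(
    b: float,
    log10_a: float,
    n: int,
    cell_mu_log10: float = 2.0,
    cell_sd_log10: float = 0.5,
    noise_sd_log10: float = 0.08,
    seed: int = 0,
    dataset_id: str = "sim",
    species: str = "synthetic_species",
    max_retries: int = 100,
) -> pd.DataFrame:
    """Simulate a within-species cell table under the power-law model.

    Cell volumes are log-normal (log10 mean/SD as given); nucleus volume
    follows nucleus = 10^log10_a · cell^b with multiplicative log-normal
    error. Rows violating the containment invariant nucleus < cell are
    resampled up to ``max_retries`` passes; exceeding the bound raises,
    advising a parameter change rather than silently truncating the noise.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    log_cell = rng.normal(cell_mu_log10, cell_sd_log10, size=n)
    log_nuc = log10_a + b * log_cell + rng.normal(0.0, noise_sd_log10, size=n)
    bad = log_nuc >= log_cell
    tries = 0
    while bad.any():
        tries += 1
        if tries > max_retries:
            raise RuntimeError(
                f"could not satisfy nucleus < cell after {max_retries} resampling "
                "passes; lower log10_a or the noise SD (the generating power law "
                "puts nuclei at or above cell volume too often)"
            )
        k = int(bad.sum())
        log_cell[bad] = rng.normal(cell_mu_log10, cell_sd_log10, size=k)
        log_nuc[bad] = (
            log10_a + b * log_cell[bad] + rng.normal(0.0, noise_sd_log10, size=k)
        )
        bad = log_nuc >= log_cell
    table = pd.DataFrame(
        {
            "dataset_id": dataset_id,
            "species": species,
            "cell_volume_um3": 10.0**log_cell,
            "nucleus_volume_um3": 10.0**log_nuc,
            "treatment": pd.Series([pd.NA] * n, dtype="object"),
            "lineage": pd.Series([pd.NA] * n, dtype="object"),
            "generation": pd.Series([pd.NA] * n, dtype="object"),
            "manipulated": False,
        }
    )[CELL_COLUMNS]
    return validate_cell_table(table)


# ---------------------------------------------------------------------------
# Artificial-selection simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionSimSpec:
    """Generating parameters for the artificial-selection experiment.

    Defaults mirror the study conditions: treatment mean cell volumes of
    97 / 177 / 915 μm³ (small / control / large), 12 lineages sampled per
    treatment per generation block, and 1332 cells measured at generation
    350 vs 1058 at generation 450. The log10-scale slope default 0.52
    corresponds to the observed fall of the N:C ratio from ~7.5% in
    ~100 μm³ cells to ~2.5% in ~1000 μm³ cells (b − 1 ≈ −0.48), and
    ``true_log10_a`` = −0.165 anchors the ratio at ~7.5% for a 100 μm³
    cell. Cell-volume means are arithmetic means: the log-normal location
    is shifted by −ln(10)·σ²/2 so realized arithmetic means match.
    """

    treatment_mean_volumes: tuple[float, float, float] = (97.0, 177.0, 915.0)
    lineages_per_treatment: int = 12
    generations: tuple[int, ...] = (350, 450)
    n_cells_per_generation: dict[int, int] = field(
        default_factory=lambda: {350: 1332, 450: 1058}
    )
    true_slope: float = 0.52
    true_log10_a: float = -0.165
    lineage_slope_sd: float = 0.03
    lineage_intercept_sd: float = 0.05
    lineage_cell_sd: float = 0.05
    cell_sd_log10: float = 0.12
    cell_noise_sd: float = 0.06
    generation_block_effect: float = 0.04
    seed: int = 0
    max_retries: int = 100

    def __post_init__(self):
        if any(m <= 0 for m in self.treatment_mean_volumes):
            raise ValueError("treatment mean volumes must be > 0")
        for name in (
            "lineage_slope_sd",
            "lineage_intercept_sd",
            "lineage_cell_sd",
            "cell_sd_log10",
            "cell_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.lineages_per_treatment < 1:
            raise ValueError("lineages_per_treatment must be >= 1")


def simulate_selection_experiment(
    spec: SelectionSimSpec,
) -> tuple[pd.DataFrame, dict]:
    """Simulate the selection-experiment cell table plus a truth record.

    Per (generation, treatment, lineage): a lineage-level cell-size offset,
    a random intercept and a random slope deviation are drawn; then for
    each cell, log10 nucleus = log10_a + block(generation) +
    (slope + lineage slope dev)·log10 cell + lineage intercept dev + noise.
    The generation-350 block is the reference (block effect 0).
    """
    rngs = _rng_stream(spec.seed, 2)
    rng_lineage, rng_cell = rngs
    treatments = ("small", "control", "large")
    means = dict(zip(treatments, spec.treatment_mean_volumes))
    # shift so the realized *arithmetic* mean cell volume matches the target
    ln10 = math.log(10.0)
    total_sd2 = spec.cell_sd_log10**2 + spec.lineage_cell_sd**2
    mu = {t: math.log10(means[t]) - ln10 * total_sd2 / 2.0 for t in treatments}

    rows = []
    lineage_truth = []
    for gen in spec.generations:
        n_gen = spec.n_cells_per_generation[gen]
        n_lineages = spec.lineages_per_treatment * len(treatments)
        base, extra = divmod(n_gen, n_lineages)
        block = spec.generation_block_effect if gen != spec.generations[0] else 0.0
        li = 0
        for trt in treatments:
            for j in range(spec.lineages_per_treatment):
                lid = f"{trt[0].upper()}{j + 1:02d}_g{gen}"
                n_cells = base + (1 if li < extra else 0)
                li += 1
                d_cell = rng_lineage.normal(0.0, spec.lineage_cell_sd)
                d_int = rng_lineage.normal(0.0, spec.lineage_intercept_sd)
                d_slope = rng_lineage.normal(0.0, spec.lineage_slope_sd)
                lineage_truth.append(
                    {"lineage": lid, "generation": gen, "treatment": trt,
                     "intercept_dev": d_int, "slope_dev": d_slope}
                )
                log_cell = rng_cell.normal(mu[trt] + d_cell, spec.cell_sd_log10, n_cells)
                log_nuc = (
                    spec.true_log10_a
                    + block
                    + d_int
                    + (spec.true_slope + d_slope) * log_cell
                    + rng_cell.normal(0.0, spec.cell_noise_sd, n_cells)
                )
                bad = log_nuc >= log_cell
                tries = 0
                while bad.any():
                    tries += 1
                    if tries > spec.max_retries:
                        raise RuntimeError(
                            "could not satisfy nucleus < cell; adjust the "
                            "selection simulation parameters"
                        )
                    k = int(bad.sum())
                    log_cell[bad] = rng_cell.normal(
                        mu[trt] + d_cell, spec.cell_sd_log10, k
                    )
                    log_nuc[bad] = (
                        spec.true_log10_a
                        + block
                        + d_int
                        + (spec.true_slope + d_slope) * log_cell[bad]
                        + rng_cell.normal(0.0, spec.cell_noise_sd, k)
                    )
                    bad = log_nuc >= log_cell
                for lc, ln_ in zip(log_cell, log_nuc):
                    rows.append(
                        {
                            "dataset_id": "selection",
                            "species": "Dunaliella tertiolecta",
                            "cell_volume_um3": 10.0**lc,
                            "nucleus_volume_um3": 10.0**ln_,
                            "treatment": trt,
                            "lineage": lid,
                            "generation": gen,
                            "manipulated": False,
                        }
                    )
    table = pd.DataFrame(rows)[CELL_COLUMNS]
    validate_cell_table(table)
    truth = {
        "true_slope": spec.true_slope,
        "true_log10_a": spec.true_log10_a,
        "generation_block_effect": spec.generation_block_effect,
        "treatment_mean_volumes": means,
        "lineage_effects": pd.DataFrame(lineage_truth),
        "seed": spec.seed,
    }
    return table, truth
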
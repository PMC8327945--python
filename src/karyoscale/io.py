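"""Domain tables, Newick trees, and data-hygiene rules.

Two tabular containers run through the whole pipeline, both plain pandas
DataFrames with a declared schema:

* **species trait table** — one row per species (after aggregation) with
  columns ``species, clade, cell_volume_um3, nucleus_volume_um3,
  dna_content_pg, nucleus_source``. Either a measured nucleus volume or a
  DNA content (C-value, pg) must be present; ``nucleus_source`` records
  whether the nucleus volume was measured directly or inferred from DNA
  content via the calibration model.
* **cell table** — one row per cell for within-species datasets and the
  artificial-selection experiment, with columns ``dataset_id, species,
  cell_volume_um3, nucleus_volume_um3, treatment, lineage, generation,
  manipulated``.

Units are fixed (μm³ for volumes, pg for DNA content) and are part of the
column names rather than carried per-cell.

Trees are :class:`dendropy.Tree` objects; :func:`parse_newick` adds the
validation the analyses rely on (unique tip labels, nonnegative branch
lengths, missing lengths defaulted with a warning).
"""

from __future__ import annotations

import logging
import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("karyoscale")

__all__ = [
    "DEFAULT_CLADES",
    "SPECIES_COLUMNS",
    "CELL_COLUMNS",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "read_tree",
    "validate_species_table",
    "validate_cell_table",
    "read_species_table",
    "write_species_table",
    "read_cell_table",
    "write_cell_table",
    "aggregate_per_species",
    "filter_cell_table",
]

#: Default clade vocabulary. Amphibia is pre-split into frogs and
#: salamanders (the two groups occupy non-overlapping cell-size ranges and
#: are analysed separately). User-supplied vocabularies may extend this.
DEFAULT_CLADES: tuple[str, ...] = (
    "bacteria",
    "phytoplankton",
    "angiosperms",
    "fish",
    "frogs",
    "salamanders",
    "reptiles",
    "birds",
    "mammals",
)

SPECIES_COLUMNS = [
    "species",
    "clade",
    "cell_volume_um3",
    "nucleus_volume_um3",
    "dna_content_pg",
    "nucleus_source",
]

CELL_COLUMNS = [
    "dataset_id",
    "species",
    "cell_volume_um3",
    "nucleus_volume_um3",
    "treatment",
    "lineage",
    "generation",
    "manipulated",
]

TREATMENTS = ("small", "control", "large")


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed or fails validation."""


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a validated :class:`dendropy.Tree`.

    Validation beyond the grammar: tip labels must be unique, branch
    lengths must be nonnegative, and edges without a stated length get a
    length of 1.0 with a logged warning (tree compilations do not always
    guarantee lengths). The root edge is left untouched.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick string: {exc}") from exc
    tree.is_rooted = True  # exactly one root; MRCA queries need this explicit

    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = sorted({lab for lab in labels if labels.count(lab) > 1})
    if dupes:
        raise NewickParseError(f"duplicate tip names in Newick string: {dupes}")

    n_missing = 0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            node.edge.length = 1.0
            n_missing += 1
        elif node.edge.length < 0:
            raise NewickParseError(
                f"negative branch length {node.edge.length} on edge above "
                f"{node.taxon.label if node.taxon else 'internal node'}"
            )
    if n_missing:
        logger.warning(
            "Newick string had %d edge(s) without branch lengths; defaulted to 1.0",
            n_missing,
        )
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree back to a one-line Newick string with branch lengths."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


def read_tree(path) -> dendropy.Tree:
    """Read a Newick tree file through the same validation as :func:`parse_newick`."""
    with open(path) as fh:
        return parse_newick(fh.read())


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Tip (leaf) labels in the tree's traversal order."""
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# Table validation
# ---------------------------------------------------------------------------

def validate_species_table(
    table: pd.DataFrame, clades: tuple[str, ...] | None = DEFAULT_CLADES
) -> pd.DataFrame:
    """Check the species trait table schema and invariants.

    Every row needs a strictly positive cell volume and at least one of
    nucleus volume / DNA content (also strictly positive where present).
    Clade labels must come from the declared vocabulary unless
    ``clades=None`` disables the check. Returns the table unchanged.
    """
    missing = [c for c in SPECIES_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"species table missing columns: {missing}")
    if (table["cell_volume_um3"] <= 0).any():
        raise ValueError("cell_volume_um3 must be strictly positive")
    nuc = table["nucleus_volume_um3"]
    dna = table["dna_content_pg"]
    if (nuc.notna() & (nuc <= 0)).any():
        raise ValueError("nucleus_volume_um3 must be strictly positive where present")
    if (dna.notna() & (dna <= 0)).any():
        raise ValueError("dna_content_pg must be strictly positive where present")
    neither = nuc.isna() & dna.isna()
    if neither.any():
        bad = table.loc[neither, "species"].tolist()[:5]
        raise ValueError(
            f"rows with neither nucleus_volume_um3 nor dna_content_pg: {bad}"
        )
    if clades is not None:
        unknown = set(table["clade"].dropna()) - set(clades)
        if unknown:
            raise ValueError(
                f"unknown clade labels {sorted(unknown)}; declared set is {clades}"
            )
    src = table["nucleus_source"].dropna()
    bad_src = set(src) - {"measured", "inferred"}
    if bad_src:
        raise ValueError(f"nucleus_source must be measured/inferred, got {bad_src}")
    return table


def validate_cell_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the cell table schema and invariants (positivity, nucleus < cell)."""
    missing = [c for c in CELL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
    if (table["cell_volume_um3"] <= 0).any() or (table["nucleus_volume_um3"] <= 0).any():
        raise ValueError("cell and nucleus volumes must be strictly positive")
    contained = table["nucleus_volume_um3"] < table["cell_volume_um3"]
    if not contained.all():
        n_bad = int((~contained).sum())
        raise ValueError(
            f"{n_bad} row(s) with nucleus_volume_um3 >= cell_volume_um3; "
            "the nucleus must fit inside the cell"
        )
    tr = table["treatment"].dropna()
    bad = set(tr) - set(TREATMENTS)
    if bad:
        raise ValueError(f"treatment labels must be in {TREATMENTS}, got {bad}")
    return table


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def read_species_table(path, clades=DEFAULT_CLADES) -> pd.DataFrame:
    table = pd.read_csv(path)
    return validate_species_table(table, clades=clades)


def write_species_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, columns=SPECIES_COLUMNS)


def read_cell_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if "manipulated" in table.columns:
        table["manipulated"] = table["manipulated"].astype(bool)
    return validate_cell_table(table)


def write_cell_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, columns=CELL_COLUMNS)


# ---------------------------------------------------------------------------
# Data hygiene
# ---------------------------------------------------------------------------

def aggregate_per_species(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse repeated measurements to one row per species.

    Numeric fields become the arithmetic mean of the available (non-missing)
    raw values. ``nucleus_source`` is "measured" if any contributing row was
    measured. Conflicting clade labels for one species are an error — that
    is a data problem, not something to average over.
    """
    clade_counts = table.groupby("species")["clade"].nunique(dropna=False)
    conflicted = clade_counts[clade_counts > 1]
    if len(conflicted):
        raise ValueError(
            f"species with conflicting clade labels: {sorted(conflicted.index)}"
        )

    def _collapse(group: pd.DataFrame) -> pd.Series:
        sources = set(group["nucleus_source"].dropna())
        if "measured" in sources:
            source = "measured"
        elif "inferred" in sources:
            source = "inferred"
        else:
            source = np.nan
        return pd.Series(
            {
                "clade": group["clade"].iloc[0],
                "cell_volume_um3": group["cell_volume_um3"].mean(),
                "nucleus_volume_um3": group["nucleus_volume_um3"].mean(),
                "dna_content_pg": group["dna_content_pg"].mean(),
                "nucleus_source": source,
            }
        )

    out = (
        table.groupby("species", sort=False)
        .apply(_collapse, include_groups=False)
        .reset_index()
    )
    return out[SPECIES_COLUMNS]


def filter_cell_table(
    table: pd.DataFrame,
    min_n: int = 20,
    exclude_manipulated: bool = True,
) -> pd.DataFrame:
    """Apply the inclusion rules for within-species datasets.

    Experimentally manipulated rows (e.g. yeast strains whose N:C ratio was
    altered) are dropped first when ``exclude_manipulated`` is set; then any
    dataset left with fewer than ``min_n`` usable rows is removed entirely,
    so the minimum-observations rule counts only rows that would actually be
    analysed. Row order is otherwise preserved. An empty result is returned
    (with a logged warning), not raised.
    """
    out = table
    if exclude_manipulated:
        out = out[~out["manipulated"].fillna(False).astype(bool)]
    counts = out.groupby("dataset_id")["dataset_id"].transform("size")
    out = out[counts >= min_n]
    if out.empty and not table.empty:
        logger.warning(
            "filter_cell_table removed every row (min_n=%d, exclude_manipulated=%s)",
            min_n,
            exclude_manipulated,
        )
    return out.copy()
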
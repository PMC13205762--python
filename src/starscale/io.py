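"""Reading and writing the pipeline's file formats.

Community tables are TSV with taxa as rows and samples as columns (a
BIOM-style ``#OTU ID`` header line is accepted); trees are Newick; metadata,
soil, and trait tables are TSV; configuration is YAML.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
import yaml
from skbio import TreeNode

from .accumulation import CommunityMatrix

__all__ = [
    "read_community_table",
    "write_community_table",
    "read_metadata",
    "write_metadata",
    "read_tree",
    "write_tree",
    "read_table",
    "write_table",
    "read_config",
    "write_config",
    "read_inputs",
]

_META_COLUMNS = ["site", "treatment", "point", "time"]


def write_community_table(matrix: CommunityMatrix, path) -> None:
    """Write counts as TSV, taxa as rows and samples as columns."""
    out = matrix.counts.T
    out.index.name = "#OTU ID"
    out.to_csv(path, sep="\t")


def read_community_table(path) -> pd.DataFrame:
    """Read a taxa x samples TSV (plain or BIOM-style) as samples x taxa."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        rest = fh.read()
    if first.startswith("# "):  # BIOM-style comment line
        text = rest
    else:
        text = first + rest
    df = pd.read_csv(_io.StringIO(text), sep="\t", index_col=0)
    df.index.name = "taxon"
    return df.T


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing required column(s): {missing}")
    return meta


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_tree(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_table(df: pd.DataFrame, path, index_label=None) -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def read_inputs(
    community_path,
    metadata_path,
    tree_path=None,
    soil_path=None,
    traits_path=None,
    require_pd: bool = False,
):
    """Load and cross-validate the analysis inputs.

    Every sample in the community table must have metadata; when a tree is
    given (and PD is requested) every taxon must be a tip, and offenders
    are named in the error.
    """
    counts = read_community_table(community_path)
    meta = read_metadata(metadata_path)
    missing = counts.index.difference(meta.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} samples lack metadata, e.g. {list(missing[:5])}"
        )
    meta = meta.loc[counts.index]
    matrix = CommunityMatrix(counts=counts.astype(int), meta=meta)

    tree = read_tree(tree_path) if tree_path else None
    if tree is None and require_pd:
        raise ValueError("phylogenetic diversity requested but no tree given")
    if tree is not None:
        tips = {t.name for t in tree.tips()}
        absent = [t for t in matrix.taxa if t not in tips]
        if absent:
            raise ValueError(
                f"{len(absent)} taxa absent from the tree: {absent[:10]}"
            )

    soil = read_table(soil_path) if soil_path else None
    traits = read_table(traits_path) if traits_path else None
    return matrix, tree, soil, traits
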
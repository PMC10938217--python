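"""Plain-text readers and writers for cohort tables.

Counts as TSV (samples as rows, ASVs as columns), taxonomy as TSV,
tree as Newick, metadata as CSV, distance matrices as square TSV, and a
JSON manifest recording the generating configuration and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from skbio import TreeNode

from .simulate import Cohort, CohortConfig


def write_counts(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="sample_id")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    taxonomy.to_csv(path, sep="\t", index_label="asv_id")


def read_taxonomy(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="asv_id")


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_tree(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, index_label="sample_id")


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")


def write_distance(distance: pd.DataFrame, path) -> None:
    distance.to_csv(path, sep="\t", index_label="sample_id")


def read_distance(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_cohort(cohort: Cohort, directory) -> dict:
    """Write all cohort tables plus a manifest; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_counts(cohort.counts, directory / "counts.tsv")
    write_taxonomy(cohort.taxonomy, directory / "taxonomy.tsv")
    write_tree(cohort.tree, directory / "tree.nwk")
    write_metadata(cohort.metadata, directory / "metadata.csv")
    manifest = {
        "config": cohort.config.to_dict(),
        "n_samples": int(len(cohort.counts)),
        "n_asvs": int(cohort.counts.shape[1]),
        "files": ["counts.tsv", "taxonomy.tsv", "tree.nwk", "metadata.csv"],
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_cohort(directory) -> Cohort:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg = CohortConfig(**manifest["config"])
    return Cohort(
        counts=read_counts(directory / "counts.tsv"),
        taxonomy=read_taxonomy(directory / "taxonomy.tsv"),
        tree=read_tree(directory / "tree.nwk"),
        metadata=read_metadata(directory / "metadata.csv"),
        config=cfg)
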
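"""Phylogenetic tree collapse and pathway-annotation export.

Consumes a newick tree (built elsewhere, e.g. from 16S alignments), collapses
it at an evolutionary-distance threshold — each maximal rooted clade whose
leaf-pairwise patristic diameter is strictly below the threshold is replaced
by its highest-quality leaf, OTU-style — and emits per-leaf pathway/
respiration annotation tables for tree viewers, including an outlier report
flagging leaves whose pathway vector differs from all near neighbours
(a screen for propagated annotation errors).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy

from .pathways import PATHWAY_NAMES, PathwayProfile

__all__ = [
    "load_tree",
    "collapse_tree",
    "export_tree_annotations",
    "outlier_report",
    "AnnotationRecord",
]

logger = logging.getLogger(__name__)

#: outlier search radius, in multiples of the collapse threshold
OUTLIER_RADIUS_FACTOR = 5.0


def load_tree(path: str | Path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    return tree


def _clade_metrics(tree: dendropy.Tree) -> tuple[dict, dict]:
    """Per internal node: max root-to-leaf depth beneath it and clade
    diameter (max leaf-pairwise path distance within the clade)."""
    depth: dict[int, float] = {}
    diameter: dict[int, float] = {}
    for node in tree.postorder_node_iter():
        key = id(node)
        if node.is_leaf():
            depth[key] = 0.0
            diameter[key] = 0.0
            continue
        child_heights = []
        diam = 0.0
        for child in node.child_nodes():
            edge = child.edge.length or 0.0
            child_heights.append(depth[id(child)] + edge)
            diam = max(diam, diameter[id(child)])
        depth[key] = max(child_heights)
        child_heights.sort(reverse=True)
        if len(child_heights) >= 2:
            diam = max(diam, child_heights[0] + child_heights[1])
        diameter[key] = diam
    return depth, diameter


def _collapse_once(
    tree: dendropy.Tree, threshold: float, quality: Mapping[str, float]
) -> tuple[dendropy.Tree, bool]:
    _, diameter = _clade_metrics(tree)

    keep: list[str] = []
    changed = False

    def representative(node) -> str:
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        scored = [lbl for lbl in leaves if lbl in quality]
        if scored:
            # max quality, ties toward the lexicographically smaller label
            return min(scored, key=lambda lbl: (-quality[lbl], lbl))
        logger.info("no quality score for clade leaves %s; lexicographic fallback", leaves[:3])
        return min(leaves)

    stack = [tree.seed_node]
    while stack:
        node = stack.pop()
        if node.is_leaf():
            keep.append(node.taxon.label)
            continue
        if diameter[id(node)] < threshold:
            leaves = [lf for lf in node.leaf_iter()]
            keep.append(representative(node))
            if len(leaves) > 1:
                changed = True
            continue
        stack.extend(node.child_nodes())

    if not changed:
        return tree, False
    collapsed = tree.extract_tree_with_taxa_labels(labels=set(keep))
    return collapsed, True


def collapse_tree(
    tree: dendropy.Tree,
    threshold: float = 0.01,
    quality: Mapping[str, float] | None = None,
) -> dendropy.Tree:
    """Collapse maximal clades of leaf-pairwise diameter strictly below
    ``threshold``, keeping the highest-quality leaf of each (missing scores
    fall back to the lexicographically smallest label). Iterated to a fixed
    point so the operation is idempotent. Unrooted (basal multifurcation)
    inputs are midpoint-rooted first."""
    if threshold <= 0:
        raise ValueError("collapse threshold must be positive")
    quality = quality or {}
    tree = tree.clone(depth=1)
    if len(tree.seed_node.child_nodes()) > 2:
        logger.info("input tree appears unrooted; midpoint-rooting before collapse")
        labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
        rerooted = tree.clone(depth=1)
        rerooted.reroot_at_midpoint(update_bipartitions=False)
        # when the midpoint falls exactly on a leaf node (degenerate ties,
        # e.g. perfect stars) dendropy demotes that leaf to the root label;
        # keep the original basal rooting in that case
        if {lf.taxon.label for lf in rerooted.leaf_node_iter()} == labels:
            tree = rerooted
        else:
            logger.info("midpoint falls on a leaf; keeping the basal multifurcation")
    while True:
        tree, changed = _collapse_once(tree, threshold, quality)
        if not changed:
            return tree


@dataclass
class AnnotationRecord:
    leaf: str
    vector: str  # "1"/"0" string over the 12 pathways, or "missing"
    respiration: str
    color: str


# a categorical palette cycled over distinct pathway vectors
_PALETTE = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b",
    "#e377c2", "#7f7f7f", "#bcbd22", "#17becf", "#aec7e8", "#ffbb78",
]


def export_tree_annotations(
    tree: dendropy.Tree,
    profiles: Mapping[str, PathwayProfile],
    path: str | Path | None = None,
) -> list[AnnotationRecord]:
    """One record per leaf: Boolean pathway vector, respiration class and a
    color code shared by identical vectors (iTOL-style dataset). Leaves
    without a profile get an explicit ``missing`` record."""
    records: list[AnnotationRecord] = []
    color_of: dict[str, str] = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        profile = profiles.get(label)
        if profile is None:
            records.append(AnnotationRecord(label, "missing", "missing", "#cccccc"))
            continue
        vec = "".join("1" if profile.presence[n] else "0" for n in PATHWAY_NAMES)
        if vec not in color_of:
            color_of[vec] = _PALETTE[len(color_of) % len(_PALETTE)]
        records.append(AnnotationRecord(label, vec, profile.respiration, color_of[vec]))
    if path is not None:
        header = "leaf\tvector\trespiration\tcolor\t# pathways: " + ",".join(PATHWAY_NAMES)
        lines = [header] + [
            f"{r.leaf}\t{r.vector}\t{r.respiration}\t{r.color}" for r in records
        ]
        Path(path).write_text("\n".join(lines) + "\n")
    return records


def outlier_report(
    tree: dendropy.Tree,
    profiles: Mapping[str, PathwayProfile],
    threshold: float = 0.01,
    radius_factor: float = OUTLIER_RADIUS_FACTOR,
) -> list[str]:
    """Leaves whose pathway vector differs from every leaf within patristic
    distance ``radius_factor * threshold`` — candidates for annotation
    errors (a profile that varies distinctly from all close neighbours)."""
    pdm = tree.phylogenetic_distance_matrix()
    radius = radius_factor * threshold
    leaves = [lf.taxon for lf in tree.leaf_node_iter()]
    vec = {
        t.label: tuple(profiles[t.label].presence[n] for n in PATHWAY_NAMES)
        for t in leaves
        if t.label in profiles
    }
    outliers = []
    for t in leaves:
        if t.label not in vec:
            continue
        neighbours = [
            u for u in leaves
            if u is not t and u.label in vec and pdm.patristic_distance(t, u) <= radius
        ]
        if neighbours and all(vec[u.label] != vec[t.label] for u in neighbours):
            outliers.append(t.label)
    return outliers
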
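"""Annotated single-cell atlas container and pre-processing operations.

An :class:`Atlas` holds a dense genes x cells expression matrix together with
per-cell type labels and a cell-type tree. The operations here cover the
standard pre-processing steps applied before signature construction:

* :func:`normalize_counts` -- depth-normalise every cell to a fixed total
  (10,000 counts per cell by default, the usual scRNA-seq convention);
* :func:`map_genes` -- translate gene/probe identifiers to symbols via a
  precomputed two-column mapping table;
* :func:`collapse_duplicates` -- resolve duplicated gene symbols either by
  keeping the row with the largest mean (``maxmean``, the microarray
  convention) or by element-wise summation (``sum``, the RNA-seq convention);
* :func:`collapse_tree` -- merge cell subtypes into coarser types (e.g.
  inflammatory + non-inflammatory macrophage -> macrophage) before building
  a signature, relabelling cells and rewiring the tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

log = logging.getLogger(__name__)

DEFAULT_ROOT = "root"


class TypeTree:
    """Rooted cell-type hierarchy.

    Parameters
    ----------
    children
        Mapping parent label -> list of child labels. Nodes absent from the
        mapping are leaves.
    root
        Label of the root node.
    """

    def __init__(self, children: Mapping[str, Sequence[str]], root: str = DEFAULT_ROOT):
        self.root = root
        self.children: dict[str, list[str]] = {
            parent: list(kids) for parent, kids in children.items() if kids
        }
        self._validate()

    def _validate(self) -> None:
        seen: set[str] = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node in seen:
                raise DataError(f"cell-type tree is not a tree: {node!r} reached twice")
            seen.add(node)
            stack.extend(self.children.get(node, []))
        orphans = set(self.children) - seen
        if orphans:
            raise DataError(
                f"cell-type tree nodes unreachable from root {self.root!r}: {sorted(orphans)}"
            )

    # -- queries ---------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        out: list[str] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(self.children.get(node, [])))
        return out

    def leaves(self) -> list[str]:
        """Leaf labels in deterministic depth-first order."""
        return [n for n in self.nodes if n not in self.children]

    def parent_of(self) -> dict[str, str]:
        return {
            child: parent for parent, kids in self.children.items() for child in kids
        }

    @classmethod
    def flat(cls, leaves: Sequence[str], root: str = DEFAULT_ROOT) -> "TypeTree":
        """A depth-one tree: every label hangs directly off the root."""
        return cls({root: list(leaves)}, root=root)

    def merged(self, merge_map: Mapping[str, str]) -> "TypeTree":
        """Return a new tree where subtypes are replaced by merged types.

        Every key of ``merge_map`` must be a leaf; the merged target becomes
        a leaf attached to the subtypes' common parent (or to the parent's
        own position, when the target *is* that parent node).
        """
        leaves = set(self.leaves())
        for sub in merge_map:
            if sub not in leaves:
                raise DataError(f"merge key {sub!r} is not a leaf of the type tree")
        children = {p: list(kids) for p, kids in self.children.items()}
        parent = self.parent_of()
        targets: dict[str, list[str]] = {}
        for sub, tgt in merge_map.items():
            targets.setdefault(tgt, []).append(sub)
        for tgt, subs in targets.items():
            sub_parents = {parent[s] for s in subs}
            for s in subs:
                children[parent[s]].remove(s)
            if tgt in children or tgt == self.root or tgt in parent:
                # merging into an existing node: it must end up childless
                if children.get(tgt):
                    raise DataError(
                        f"cannot merge into {tgt!r}: node retains children "
                        f"{children[tgt]} after the merge"
                    )
                children.pop(tgt, None)
            else:
                attach = sub_parents.pop() if len(sub_parents) == 1 else self.root
                children.setdefault(attach, []).append(tgt)
        # prune internal nodes left childless that are not leaves-with-cells
        changed = True
        new_leaf_set = set(targets) | (leaves - set(merge_map))
        while changed:
            changed = False
            for node in list(children):
                children[node] = [c for c in children[node] if c in children or c in new_leaf_set or c == self.root]
                if not children[node]:
                    del children[node]
                    changed = True
        return TypeTree(children, root=self.root)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, TypeTree)
            and self.root == other.root
            and {k: list(v) for k, v in self.children.items()}
            == {k: list(v) for k, v in other.children.items()}
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TypeTree(root={self.root!r}, leaves={self.leaves()})"


@dataclass
class GeneMatrix:
    """Dense genes x samples expression matrix with row/column names."""

    expr: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.expr = np.asarray(self.expr, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.expr.ndim != 2:
            raise DataError("expression matrix must be 2-D (genes x samples)")
        if self.expr.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"expression shape {self.expr.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.any(self.expr < 0):
            raise DataError("expression matrix contains negative entries")

    @property
    def n_genes(self) -> int:
        return self.expr.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.expr, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))


@dataclass
class Atlas:
    """Annotated single-cell expression atlas.

    ``expr`` is genes x cells; ``labels`` assigns each cell to a leaf of
    ``tree``. ``uns`` carries unstructured provenance (e.g. the planted
    marker lists of a synthetic atlas).
    """

    expr: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    labels: np.ndarray
    tree: TypeTree
    uns: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.expr = np.asarray(self.expr, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.expr.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise DataError(
                f"expression shape {self.expr.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.labels.shape != (len(self.cell_ids),):
            raise DataError("labels must assign exactly one type per cell")
        if np.any(self.expr < 0):
            raise DataError("atlas expression contains negative entries")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError(
                "atlas gene_ids are not unique; collapse duplicates first"
            )
        leaves = set(self.tree.leaves())
        missing = sorted(set(self.labels) - leaves)
        if missing:
            raise DataError(f"cell labels absent from the type-tree leaves: {missing}")

    @property
    def n_genes(self) -> int:
        return self.expr.shape[0]

    @property
    def n_cells(self) -> int:
        return self.expr.shape[1]

    def present_types(self) -> list[str]:
        """Leaf types with at least one cell, in tree order."""
        have = set(self.labels)
        return [t for t in self.tree.leaves() if t in have]

    def cells_of(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def type_counts(self) -> dict[str, int]:
        return {t: int(np.sum(self.labels == t)) for t in self.present_types()}


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def normalize_counts(atlas: Atlas, target: float = 10_000.0) -> Atlas:
    """Scale every cell column to sum to ``target`` counts.

    Relative gene proportions within each cell are preserved; applying the
    operation twice is a no-op (idempotent). A cell with zero total counts
    cannot be normalised and raises :class:`DataError` naming the cell.
    """
    if target <= 0:
        raise ConfigurationError(f"normalisation target must be positive, got {target}")
    totals = atlas.expr.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise DataError(
            f"cell {atlas.cell_ids[zero[0]]!r} has zero total counts and cannot "
            "be depth-normalised"
        )
    scaled = atlas.expr * (target / totals)
    return Atlas(scaled, atlas.gene_ids, atlas.cell_ids, atlas.labels, atlas.tree, dict(atlas.uns))


@dataclass
class GeneMapReport:
    """Bookkeeping of an identifier-translation pass."""

    n_input: int
    n_mapped: int
    n_dropped: int
    dropped_ids: list[str]


def map_genes(
    matrix: GeneMatrix,
    id_map: Mapping[str, str] | pd.DataFrame,
    uppercase_both: bool = False,
) -> tuple[GeneMatrix, GeneMapReport]:
    """Rename rows via a precomputed old-ID -> symbol table.

    Rows without a mapping are dropped and counted in the returned report
    (and the module log); many-to-one mappings deliberately leave duplicate
    symbols in place for :func:`collapse_duplicates` to resolve. Matching is
    case-sensitive unless ``uppercase_both`` is set (silent case-folding can
    cause false merges).
    """
    if isinstance(id_map, pd.DataFrame):
        if id_map.shape[1] < 2:
            raise ConfigurationError("id_map table needs two columns: old ID, symbol")
        id_map = dict(zip(id_map.iloc[:, 0].astype(str), id_map.iloc[:, 1].astype(str)))
    if uppercase_both:
        id_map = {k.upper(): v for k, v in id_map.items()}

    keep_rows: list[int] = []
    new_ids: list[str] = []
    dropped: list[str] = []
    for i, gid in enumerate(matrix.gene_ids):
        key = gid.upper() if uppercase_both else gid
        if key in id_map:
            keep_rows.append(i)
            new_ids.append(id_map[key])
        else:
            dropped.append(gid)
    if not keep_rows:
        raise DataError(
            f"no overlap between matrix gene IDs ({matrix.n_genes}) and the "
            f"mapping table ({len(id_map)} entries)"
        )
    report = GeneMapReport(matrix.n_genes, len(keep_rows), len(dropped), dropped)
    log.info(
        "map_genes: %d/%d rows mapped, %d dropped", report.n_mapped, report.n_input, report.n_dropped
    )
    out = GeneMatrix(matrix.expr[keep_rows], new_ids, matrix.sample_ids)
    return out, report


VALID_COLLAPSE = ("maxmean", "sum")


def collapse_duplicates(matrix: GeneMatrix, strategy: str) -> GeneMatrix:
    """Resolve duplicated gene symbols.

    ``maxmean`` keeps, for each duplicated symbol, the single input row with
    the largest row mean (first occurrence wins ties); ``sum`` replaces the
    duplicates by their element-wise sum. Output rows follow the first
    occurrence order of each symbol.
    """
    if strategy not in VALID_COLLAPSE:
        raise ConfigurationError(
            f"unknown collapse strategy {strategy!r}; valid strategies: {list(VALID_COLLAPSE)}"
        )
    ids = matrix.gene_ids
    if len(set(ids)) == len(ids):
        return GeneMatrix(matrix.expr.copy(), ids, matrix.sample_ids)

    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, gid in enumerate(ids):
        if gid not in groups:
            groups[gid] = []
            order.append(gid)
        groups[gid].append(i)

    rows = np.empty((len(order), matrix.n_samples))
    if strategy == "maxmean":
        means = matrix.expr.mean(axis=1)
        for r, gid in enumerate(order):
            idx = groups[gid]
            best = idx[int(np.argmax(means[idx]))]  # argmax -> first max wins ties
            rows[r] = matrix.expr[best]
    else:  # sum
        for r, gid in enumerate(order):
            rows[r] = matrix.expr[groups[gid]].sum(axis=0)
    return GeneMatrix(rows, order, matrix.sample_ids)


def collapse_tree(atlas: Atlas, merge_map: Mapping[str, str]) -> Atlas:
    """Merge cell subtypes into coarser types.

    ``merge_map`` maps subtype label -> merged-type label (e.g. both
    macrophage subtypes -> ``macrophage``). Cells are relabelled, the tree
    is rewired so merged types become leaves, and expression is untouched.
    """
    labels = set(atlas.labels)
    for key in merge_map:
        if key not in labels:
            raise DataError(f"merge key {key!r} is not a cell label of this atlas")
    if not merge_map:
        return atlas
    new_labels = np.array([merge_map.get(l, l) for l in atlas.labels], dtype=object)
    new_tree = atlas.tree.merged(merge_map)
    return Atlas(atlas.expr, atlas.gene_ids, atlas.cell_ids, new_labels, new_tree, dict(atlas.uns))


def type_mean_profiles(atlas: Atlas) -> tuple[np.ndarray, list[str]]:
    """Per-type mean expression profiles (genes x types, tree-leaf order)."""
    types = atlas.present_types()
    profiles = np.column_stack(
        [atlas.expr[:, atlas.cells_of(t)].mean(axis=1) for t in types]
    )
    return profiles, types
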
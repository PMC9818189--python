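"""Readers and writers for the pipeline's plain-text formats.

Dense expression matrices travel as tab-delimited tables whose first column
is headed ``GeneSymbol`` followed by one column per sample (or cell type,
for a signature). Sparse atlases are accepted as an MTX triplet plus genes
and barcodes files. Cell annotations are two-column TSVs (cell_id,
type_label); cell-type trees are ``child TAB parent`` lines. Everything is
UTF-8, unquoted, with missing values disallowed; every writer/reader pair
round-trips files byte-identically.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread

from .atlas import Atlas, GeneMatrix, TypeTree
from .deconv import AbundanceScore, FractionEstimate
from .errors import FileFormatError
from .signature import SignatureMatrix
from .survival import KMCurve, SplitResult, SurvivalRecord, records_from_frame, to_months
from .validation import ValidationResult

GENE_COL = "GeneSymbol"


def _read_tsv(path: str | Path, index_col: str | None = None) -> pd.DataFrame:
    path = Path(path)
    try:
        # round_trip parsing keeps write -> read -> write byte-identical
        df = pd.read_csv(path, sep="\t", header=0, float_precision="round_trip")
    except Exception as exc:  # pandas raises many flavours on malformed input
        raise FileFormatError(f"{path}: line 1: cannot parse as TSV ({exc})") from exc
    if index_col is not None:
        if df.columns[0] != index_col:
            raise FileFormatError(
                f"{path}: line 1: expected first column {index_col!r}, "
                f"found {df.columns[0]!r}"
            )
        df = df.set_index(index_col)
    return df


def _check_numeric(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    try:
        out = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FileFormatError(f"{path}: non-numeric expression value ({exc})") from exc
    if out.isna().any().any():
        row = int(np.flatnonzero(out.isna().any(axis=1))[0])
        raise FileFormatError(
            f"{path}: line {row + 2}: missing value in row {out.index[row]!r}"
        )
    return out


# -- expression matrices -----------------------------------------------------


def write_gene_matrix(gm: GeneMatrix, path: str | Path) -> None:
    df = gm.to_frame()
    df.index.name = GENE_COL
    df.to_csv(path, sep="\t")


def read_gene_matrix(path: str | Path) -> GeneMatrix:
    df = _check_numeric(_read_tsv(path, GENE_COL), path)
    return GeneMatrix(df.to_numpy(), [str(g) for g in df.index], [str(s) for s in df.columns])


# -- signature ---------------------------------------------------------------


def write_signature(sig: SignatureMatrix, path: str | Path) -> None:
    df = sig.to_frame()
    df.index.name = GENE_COL
    df.to_csv(path, sep="\t")


def read_signature(path: str | Path, mode: str = "S") -> SignatureMatrix:
    """Load a signature TSV; the condition number is recomputed on load."""
    df = _check_numeric(_read_tsv(path, GENE_COL), path)
    expr = df.to_numpy()
    return SignatureMatrix(
        expr=expr,
        marker_genes=[str(g) for g in df.index],
        cell_types=[str(t) for t in df.columns],
        mode=mode,
        condition_number=float(np.linalg.cond(expr)),
    )


# -- atlas -------------------------------------------------------------------


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    if list(df.columns[:2]) != ["cell_id", "type_label"]:
        raise FileFormatError(
            f"{path}: line 1: expected header 'cell_id\\ttype_label', got {list(df.columns)}"
        )
    return df


def write_annotation(atlas: Atlas, path: str | Path) -> None:
    pd.DataFrame({"cell_id": atlas.cell_ids, "type_label": atlas.labels}).to_csv(
        path, sep="\t", index=False
    )


def read_tree(path: str | Path) -> TypeTree:
    """Tree file: one ``child TAB parent`` pair per line, no header."""
    path = Path(path)
    children: dict[str, list[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FileFormatError(
                f"{path}: line {lineno}: expected 'child<TAB>parent', got {line!r}"
            )
        child, parent = parts
        children.setdefault(parent, []).append(child)
    if not children:
        raise FileFormatError(f"{path}: line 1: empty tree file")
    roots = set(children) - {c for kids in children.values() for c in kids}
    if len(roots) != 1:
        raise FileFormatError(f"{path}: tree must have exactly one root, found {sorted(roots)}")
    return TypeTree(children, root=roots.pop())


def write_tree(tree: TypeTree, path: str | Path) -> None:
    lines = [
        f"{child}\t{parent}"
        for parent in tree.nodes
        for child in tree.children.get(parent, [])
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def _atlas_from_parts(
    expr: np.ndarray,
    gene_ids: list[str],
    cell_ids: list[str],
    annotation: pd.DataFrame,
    tree: TypeTree | None,
) -> Atlas:
    label_map = dict(zip(annotation["cell_id"].astype(str), annotation["type_label"].astype(str)))
    missing = [c for c in cell_ids if c not in label_map]
    if missing:
        raise FileFormatError(
            f"annotation is missing {len(missing)} cell(s), first: {missing[0]!r}"
        )
    labels = np.array([label_map[c] for c in cell_ids], dtype=object)
    if tree is None:
        tree = TypeTree.flat(sorted(set(labels)))
    return Atlas(expr, gene_ids, cell_ids, labels, tree)


def read_atlas_dense(
    expr_path: str | Path, annotation_path: str | Path, tree_path: str | Path | None = None
) -> Atlas:
    gm = read_gene_matrix(expr_path)
    ann = read_annotation(annotation_path)
    tree = read_tree(tree_path) if tree_path else None
    return _atlas_from_parts(gm.expr, gm.gene_ids, gm.sample_ids, ann, tree)


def read_atlas_mtx(
    mtx_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    annotation_path: str | Path,
    tree_path: str | Path | None = None,
) -> Atlas:
    """Sparse atlas: MTX triplet (genes x cells) + genes/barcodes line files."""
    try:
        expr = np.asarray(mmread(str(mtx_path)).todense(), dtype=float)
    except Exception as exc:
        raise FileFormatError(f"{mtx_path}: line 1: cannot parse MTX ({exc})") from exc
    genes = [l.split("\t")[0] for l in Path(genes_path).read_text().splitlines() if l]
    cells = [l.split("\t")[0] for l in Path(barcodes_path).read_text().splitlines() if l]
    if expr.shape != (len(genes), len(cells)):
        raise FileFormatError(
            f"{mtx_path}: matrix is {expr.shape} but genes file has {len(genes)} "
            f"and barcodes file has {len(cells)} entries"
        )
    ann = read_annotation(annotation_path)
    tree = read_tree(tree_path) if tree_path else None
    return _atlas_from_parts(expr, genes, cells, ann, tree)


def write_atlas(atlas: Atlas, prefix: str | Path) -> dict[str, Path]:
    """Write expression TSV, annotation TSV and tree file under ``prefix``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": prefix.with_suffix(".expr.tsv"),
        "annotation": prefix.with_suffix(".cells.tsv"),
        "tree": prefix.with_suffix(".tree.tsv"),
    }
    write_gene_matrix(GeneMatrix(atlas.expr, atlas.gene_ids, atlas.cell_ids), paths["expression"])
    write_annotation(atlas, paths["annotation"])
    write_tree(atlas.tree, paths["tree"])
    return paths


# -- fractions / validation / survival --------------------------------------


def write_fractions(est: FractionEstimate, path: str | Path, fit_path: str | Path | None = None) -> None:
    df = est.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")
    if fit_path is not None:
        fit = est.fit_frame()
        fit.index.name = "sample_id"
        fit.to_csv(fit_path, sep="\t")


def read_fractions(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, "sample_id")
    return _check_numeric(df, path)


def write_abundance(scores: AbundanceScore, path: str | Path) -> None:
    df = scores.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def write_validation_report(results: Sequence[ValidationResult], path: str | Path) -> None:
    pd.DataFrame([r.to_row() for r in results]).to_csv(path, sep="\t", index=False)


def read_survival(path: str | Path, unit: str = "months") -> list[SurvivalRecord]:
    """Survival TSV (sample_id, time, event 0/1); times converted to months."""
    df = _read_tsv(path)
    need = ["sample_id", "time", "event"]
    if list(df.columns[:3]) != need:
        raise FileFormatError(
            f"{path}: line 1: expected header {need}, got {list(df.columns)}"
        )
    df = df.copy()
    df["time"] = [to_months(float(t), unit) for t in df["time"]]
    return records_from_frame(df)


def write_survival(records: Sequence[SurvivalRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "time": [r.time for r in records],
            "event": [int(r.event) for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def write_split_report(
    split: SplitResult, cell_type: str, path: str | Path
) -> None:
    """One-row summary plus the full per-cut p-value vector."""
    head = pd.DataFrame(
        [
            {
                "cell_type": cell_type,
                "strategy": split.strategy,
                "cut_rank": split.cut_rank,
                "p_value": split.p_value,
                "small_group": int(split.small_group),
                "tie_at_cut": int(split.tie_at_cut),
                "n_cuts_tested": split.all_p.size,
                "min_p": float(split.all_p.min()),
            }
        ]
    )
    head.to_csv(path, sep="\t", index=False)
    pvec = Path(path).with_suffix(".all_p.tsv")
    pd.DataFrame({"cut_rank": split.tested_cuts, "p_value": split.all_p}).to_csv(
        pvec, sep="\t", index=False
    )


def write_km_coordinates(curve: KMCurve, path: str | Path) -> None:
    curve.to_frame().to_csv(path, sep="\t", index=False)
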
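"""Pseudo-bulk validation of the deconvolution engine.

A pseudo-bulk sample is constructed for one target cell type by splitting
the atlas into that type versus all remaining cells collapsed into a single
"others" group, subsampling 10% of the cells of each group without
replacement, averaging each subsample into representative vectors
V_celltype and V_others, and mixing

    expr = V_celltype * f + V_others * (100 - f)

with f drawn uniformly on [0, 100]. The estimated fraction of the target
type (x 100) is compared with the preset f across ``n`` mixtures via the
Pearson correlation coefficient (PCC), the mean absolute error
(MAE = 1/n * sum |f' - f|, on the 0-100 scale), and the mean signed error
(positive = overestimation).

Intra-study validation draws the signature and the mixtures from the same
atlas; cross-study validation uses two different atlases sharing the target
label, exercising partial deconvolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .atlas import Atlas, GeneMatrix
from .deconv import estimate_fractions
from .errors import ConfigurationError, DataError
from .signature import SignatureMatrix, build_signature

log = logging.getLogger(__name__)

OTHERS = "others"


@dataclass
class MixtureSample:
    """One pseudo-bulk expression vector with its preset proportion f."""

    expr: np.ndarray
    true_f: float
    target_type: str

    def __post_init__(self) -> None:
        self.expr = np.asarray(self.expr, dtype=float)
        if not (0.0 <= self.true_f <= 100.0):
            raise DataError(f"true_f must lie in [0, 100], got {self.true_f}")
        if np.any(self.expr < 0):
            raise DataError("pseudo-bulk expression must be non-negative")


@dataclass
class ValidationResult:
    """Per-cell-type accuracy summary of one validation run."""

    target_type: str
    mode: str  # "intra" | "cross"
    n: int
    pcc: float
    mae: float
    mean_signed_error: float

    def to_row(self) -> dict:
        return {
            "target_type": self.target_type,
            "mode": self.mode,
            "n": self.n,
            "pcc": self.pcc,
            "mae": self.mae,
            "mean_signed_error": self.mean_signed_error,
        }


def make_pseudobulk(
    atlas: Atlas,
    target_type: str,
    f: float,
    cell_frac: float = 0.10,
    rng: np.random.Generator | None = None,
) -> MixtureSample:
    """Mix one pseudo-bulk sample at preset proportion ``f`` (0-100 scale).

    ``cell_frac`` of the target-type cells and of the pooled "others" cells
    are subsampled without replacement (independently per mixture) before
    averaging into the two representative vectors.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not (0.0 <= f <= 100.0):
        raise DataError(f"f must lie in [0, 100], got {f}")
    if not (0.0 < cell_frac <= 1.0):
        raise ConfigurationError(f"cell_frac must lie in (0, 1], got {cell_frac}")
    if target_type not in set(atlas.labels):
        raise DataError(
            f"unknown target_type {target_type!r}; atlas types: {atlas.present_types()}"
        )
    own = atlas.cells_of(target_type)
    rest = np.flatnonzero(atlas.labels != target_type)
    if rest.size == 0:
        raise DataError(f"no cells left in the {OTHERS!r} group")
    n_own = int(own.size * cell_frac)
    n_rest = int(rest.size * cell_frac)
    if n_own == 0 or n_rest == 0:
        raise DataError(
            f"cell_frac={cell_frac} subsamples 0 cells from a group "
            f"({own.size} target, {rest.size} others); increase cell_frac"
        )
    v_own = atlas.expr[:, rng.choice(own, size=n_own, replace=False)].mean(axis=1)
    v_rest = atlas.expr[:, rng.choice(rest, size=n_rest, replace=False)].mean(axis=1)
    expr = v_own * f + v_rest * (100.0 - f)
    return MixtureSample(expr=expr, true_f=float(f), target_type=target_type)


def validation_metrics(
    f_true: np.ndarray, f_est: np.ndarray
) -> tuple[float, float, float]:
    """PCC, MAE, and mean signed error between preset and estimated f (0-100)."""
    f_true = np.asarray(f_true, dtype=float)
    f_est = np.asarray(f_est, dtype=float)
    if f_true.shape != f_est.shape or f_true.ndim != 1:
        raise DataError("preset and estimated proportions must be 1-D and aligned")
    if f_true.size < 2:
        raise DataError("PCC needs at least 2 mixtures")
    diff = f_est - f_true
    mae = float(np.mean(np.abs(diff)))
    signed = float(np.mean(diff))
    if np.std(f_true) == 0 or np.std(f_est) == 0:
        pcc = float("nan")
    else:
        pcc = float(pearsonr(f_true, f_est)[0])
    return pcc, mae, signed


def run_validation(
    ref_atlas: Atlas,
    test_atlas: Atlas,
    target_type: str,
    n_mixtures: int = 50,
    mode: str = "intra",
    method: str = "nu-svr",
    cell_frac: float = 0.10,
    rng: np.random.Generator | int | None = None,
    signature: SignatureMatrix | None = None,
    sig_params: dict | None = None,
) -> ValidationResult:
    """Score the engine on ``n_mixtures`` pseudo-bulks of one target type.

    ``signature`` may be passed pre-built (it depends only on ``ref_atlas``)
    to amortise construction across the cell types of one atlas.
    """
    if mode not in ("intra", "cross"):
        raise ConfigurationError(f"mode must be 'intra' or 'cross', got {mode!r}")
    if mode == "intra" and ref_atlas is not test_atlas:
        raise ConfigurationError("intra mode requires ref_atlas and test_atlas to be the same atlas")
    if mode == "cross":
        ref_types, test_types = set(ref_atlas.labels), set(test_atlas.labels)
        if target_type not in ref_types or target_type not in test_types:
            raise DataError(
                f"cross mode: {target_type!r} must be present in both atlases; "
                f"shared labels: {sorted(ref_types & test_types)}"
            )
    if n_mixtures < 2:
        raise ConfigurationError("n_mixtures must be >= 2 for PCC")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)

    if signature is None:
        signature = build_signature(ref_atlas, **(sig_params or {}))
    if target_type not in signature.cell_types:
        raise DataError(
            f"{target_type!r} is not a signature cell type: {signature.cell_types}"
        )

    f_true = rng.uniform(0.0, 100.0, size=n_mixtures)
    mixtures = np.column_stack(
        [
            make_pseudobulk(test_atlas, target_type, f, cell_frac, rng).expr
            for f in f_true
        ]
    )
    bulk = GeneMatrix(
        mixtures, test_atlas.gene_ids, [f"mix_{i:03d}" for i in range(n_mixtures)]
    )
    est = estimate_fractions(signature, bulk, method=method)
    j = signature.cell_types.index(target_type)
    f_est = est.fractions[:, j] * 100.0
    pcc, mae, signed = validation_metrics(f_true, f_est)
    log.info(
        "validation (%s, %s): type %s, n=%d, PCC=%.4f, MAE=%.2f, signed=%.2f",
        mode, method, target_type, n_mixtures, pcc, mae, signed,
    )
    return ValidationResult(
        target_type=target_type,
        mode=mode,
        n=n_mixtures,
        pcc=pcc,
        mae=mae,
        mean_signed_error=signed,
    )
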
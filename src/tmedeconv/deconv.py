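"""Cell-fraction estimation by regression on a signature matrix.

Each bulk sample's expression vector over the shared marker genes is
regressed on the signature columns. Two engines are provided:

* ``nnls``: non-negative least squares (exact on noiseless mixtures; the
  oracle mode).
* ``nu-svr``: linear-kernel nu-support-vector regression, nu swept over
  {0.25, 0.5, 0.75} with the value minimising reconstruction RMSE kept per
  sample -- the convention of CIBERSORT-style deconvolution.

Negative coefficients are clipped to zero. *Fractions* are the clipped
coefficients divided by their sum (each sample's fractions sum to one and
are invariant to rescaling the bulk sample); *abundance scores* are the
clipped, un-normalised coefficients, comparable across samples for one cell
type but not across types within a sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import pearsonr
from sklearn.svm import NuSVR

from .atlas import GeneMatrix
from .errors import ConfigurationError, DataError
from .signature import SignatureMatrix

log = logging.getLogger(__name__)

NU_GRID = (0.25, 0.5, 0.75)
VALID_METHODS = ("nu-svr", "nnls")


@dataclass
class FractionEstimate:
    """Per-sample non-negative cell-type fractions summing to one."""

    fractions: np.ndarray  # samples x types
    sample_ids: list[str]
    cell_types: list[str]
    method: str
    fit_rmse: np.ndarray  # per sample
    fit_pcc: np.ndarray  # per sample

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if np.any(self.fractions < 0):
            raise DataError("fractions must be non-negative")
        rowsum = self.fractions.sum(axis=1)
        if np.any(np.abs(rowsum - 1.0) > 1e-9):
            raise DataError("every fraction row must sum to 1 within 1e-9")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fractions, index=self.sample_ids, columns=self.cell_types)

    def fit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rmse": self.fit_rmse, "pcc": self.fit_pcc}, index=self.sample_ids
        )


@dataclass
class AbundanceScore:
    """Clipped, un-normalised regression coefficients (nu-SVR)."""

    scores: np.ndarray  # samples x types
    sample_ids: list[str]
    cell_types: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any(self.scores < 0):
            raise DataError("abundance scores must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=self.cell_types)


def _intersect(signature: SignatureMatrix, bulk: GeneMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Shared-gene design matrix and bulk submatrix (signature gene order)."""
    bulk_pos = {g: i for i, g in enumerate(bulk.gene_ids)}
    sig_rows = [i for i, g in enumerate(signature.marker_genes) if g in bulk_pos]
    if not sig_rows:
        raise DataError(
            f"no shared genes between signature ({len(signature.marker_genes)} genes) "
            f"and bulk matrix ({bulk.n_genes} genes)"
        )
    if len(sig_rows) < signature.n_types:
        raise DataError(
            f"only {len(sig_rows)} shared genes for {signature.n_types} cell types; "
            "the regression is underdetermined"
        )
    bulk_rows = [bulk_pos[signature.marker_genes[i]] for i in sig_rows]
    log.info(
        "gene intersection: %d of %d signature markers present in bulk",
        len(sig_rows), len(signature.marker_genes),
    )
    return signature.expr[sig_rows], bulk.expr[bulk_rows]


def _fit_nnls(S: np.ndarray, b: np.ndarray) -> np.ndarray:
    w, _ = nnls(S, b)
    return w


def _fit_nusvr(S: np.ndarray, b: np.ndarray, C: float) -> np.ndarray:
    """CIBERSORT-style nu-SVR fit of one sample; returns clipped coefficients.

    Signature columns and the bulk vector are z-scored over the shared
    genes; coefficients are mapped back to the original scale before
    clipping, so abundance scores track the bulk sample's scale.
    """
    sd_S = S.std(axis=0)
    sd_S_safe = np.where(sd_S > 0, sd_S, 1.0)
    S_z = (S - S.mean(axis=0)) / sd_S_safe
    sd_b = b.std()
    if sd_b == 0:
        return np.zeros(S.shape[1])
    b_z = (b - b.mean()) / sd_b

    best_w: np.ndarray | None = None
    best_rmse = np.inf
    for nu in NU_GRID:
        svr = NuSVR(kernel="linear", nu=nu, C=C)
        svr.fit(S_z, b_z)
        coef = svr.coef_.ravel()
        w = np.where(sd_S > 0, coef * sd_b / sd_S_safe, 0.0)
        w = np.clip(w, 0.0, None)
        rmse = float(np.sqrt(np.mean((S @ w - b) ** 2)))
        if rmse < best_rmse:
            best_rmse, best_w = rmse, w
    assert best_w is not None
    return best_w


def _coefficients(
    signature: SignatureMatrix, bulk: GeneMatrix, method: str, C: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Clipped coefficients plus per-sample fit RMSE/PCC."""
    if method not in VALID_METHODS:
        raise ConfigurationError(
            f"unknown method {method!r}; valid methods: {list(VALID_METHODS)}"
        )
    S, B = _intersect(signature, bulk)
    n_samples = B.shape[1]
    W = np.zeros((n_samples, signature.n_types))
    rmse = np.zeros(n_samples)
    pcc = np.zeros(n_samples)
    for s in range(n_samples):
        b = B[:, s]
        if not np.any(b > 0):
            raise DataError(
                f"bulk sample {bulk.sample_ids[s]!r} is all-zero over the shared genes"
            )
        w = _fit_nnls(S, b) if method == "nnls" else _fit_nusvr(S, b, C)
        recon = S @ w
        rmse[s] = float(np.sqrt(np.mean((recon - b) ** 2)))
        if recon.std() > 0 and b.std() > 0:
            pcc[s] = float(pearsonr(recon, b)[0])
        W[s] = w
    return W, rmse, pcc


def estimate_fractions(
    signature: SignatureMatrix,
    bulk: GeneMatrix,
    method: str = "nu-svr",
    C: float = 1.0,
) -> FractionEstimate:
    """Estimate per-sample cell-type fractions (rows sum to one).

    A sample whose regression yields all-zero coefficients (no signature
    type explains it at all) falls back to uniform fractions with a
    warning; its fit statistics flag the failure.
    """
    W, rmse, pcc = _coefficients(signature, bulk, method, C)
    totals = W.sum(axis=1)
    dead = np.flatnonzero(totals == 0)
    if dead.size:
        log.warning(
            "sample(s) %s matched no signature column; reporting uniform fractions",
            [bulk.sample_ids[i] for i in dead],
        )
        W[dead] = 1.0
        totals[dead] = signature.n_types
    fractions = W / totals[:, None]
    return FractionEstimate(
        fractions=fractions,
        sample_ids=list(bulk.sample_ids),
        cell_types=list(signature.cell_types),
        method=method,
        fit_rmse=rmse,
        fit_pcc=pcc,
    )


def svr_abundance(
    signature: SignatureMatrix, bulk: GeneMatrix, C: float = 1.0
) -> AbundanceScore:
    """Un-normalised nu-SVR abundance scores.

    Unlike fractions, these scale with the bulk sample (doubling a sample
    doubles its scores) and are comparable across samples for one type.
    """
    W, _, _ = _coefficients(signature, bulk, "nu-svr", C)
    return AbundanceScore(
        scores=W, sample_ids=list(bulk.sample_ids), cell_types=list(signature.cell_types)
    )
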
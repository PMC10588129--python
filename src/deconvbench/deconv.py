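"""Cell-type signature construction and bulk deconvolution.

The built-in estimator is non-negative least squares on CPM-normalized data:
the bulk profile is modeled as a non-negative linear mixture of cell-type
mean expression columns, solved by the Lawson-Hanson active-set algorithm,
with the coefficients renormalized to RNA fractions. Other methods plug in
through a registry; adapters only translate I/O and declare a minimum number
of reference cells per quantifiable type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import (
    AnnotationError,
    ConvergenceError,
    GeneOverlapError,
    RegistryError,
    ShapeError,
)
from .simulate import BulkSample

__all__ = [
    "SignatureMatrix",
    "DeconvolutionResult",
    "build_signature",
    "nnls_solve",
    "deconvolve",
    "register_method",
    "available_methods",
]


@dataclass
class SignatureMatrix:
    """Genes x cell-types reference expression, counts-per-million scale."""

    values: pd.DataFrame  # index: gene ids, columns: cell types
    cell_counts: pd.Series  # cells per type used to build each column

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class DeconvolutionResult:
    """Estimated RNA fractions for one bulk sample under one method."""

    method: str
    sample_id: str
    protocol: str | None
    reference_tag: str | None
    fractions: pd.Series  # cell type -> fraction, >= 0, sums to 1
    excluded: dict = field(default_factory=dict)  # cell type -> reason string


def build_signature(reference: ad.AnnData) -> SignatureMatrix:
    """Average CPM-normalized cells within cell type.

    Each cell is scaled to one million total counts before averaging, so
    library-size differences between cells do not weight the mean. Genes with
    zero total expression across the reference are dropped.
    """
    if "cell_type" not in reference.obs:
        raise AnnotationError("reference lacks a cell_type annotation")
    ct = reference.obs["cell_type"].astype(str)
    if ct.isna().any() or (ct == "nan").any():
        raise AnnotationError("reference contains unannotated cells")
    X = reference.X.tocsr() if sp.issparse(reference.X) else np.asarray(reference.X)

    cols = {}
    counts = {}
    for cell_type in pd.unique(ct):
        rows = np.flatnonzero(np.asarray(ct == cell_type))
        block = X[rows]
        block = np.asarray(block.todense()) if sp.issparse(block) else np.asarray(block, dtype=float)
        lib = block.sum(axis=1, keepdims=True)
        lib[lib == 0] = 1.0
        cols[str(cell_type)] = (block / lib * 1e6).mean(axis=0)
        counts[str(cell_type)] = len(rows)
    sig = pd.DataFrame(cols, index=reference.var_names.copy())
    sig = sig.loc[sig.sum(axis=1) > 0]
    return SignatureMatrix(values=sig, cell_counts=pd.Series(counts))


def nnls_solve(
    A: np.ndarray, b: np.ndarray, tol: float = 1e-10, max_iter: int | None = None
) -> np.ndarray:
    """Lawson-Hanson active-set solution of min ||Ax - b|| subject to x >= 0.

    Satisfies the KKT conditions to ``tol``: zero coordinates have gradient
    <= tol and positive coordinates have |gradient| <= tol. The outer loop is
    capped at 3x the number of columns (raise ``max_iter`` for pathological
    systems); exceeding the cap raises :class:`ConvergenceError`.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float).ravel()
    if A.ndim != 2 or A.shape[0] != b.shape[0]:
        raise ShapeError(f"incompatible shapes {A.shape} and {b.shape}")
    m, n = A.shape
    if max_iter is None:
        max_iter = 3 * n

    x = np.zeros(n)
    passive = np.zeros(n, dtype=bool)
    w = A.T @ b  # gradient of -0.5||Ax-b||^2 at x = 0

    outer = 0
    while True:
        free = ~passive
        if not free.any() or np.all(w[free] <= tol):
            break
        outer += 1
        if outer > max_iter:
            raise ConvergenceError(f"NNLS exceeded {max_iter} outer iterations")
        j = np.flatnonzero(free)[np.argmax(w[free])]
        passive[j] = True

        while True:
            idx = np.flatnonzero(passive)
            z = np.zeros(n)
            z[idx], *_ = np.linalg.lstsq(A[:, idx], b, rcond=None)
            if np.all(z[idx] > tol):
                x = z
                break
            # step toward z until the first passive coordinate hits zero
            neg = idx[z[idx] <= tol]
            denom = x[neg] - z[neg]
            ratios = np.where(denom > 0, x[neg] / np.where(denom > 0, denom, 1.0), 0.0)
            alpha = np.min(ratios)
            x = x + alpha * (z - x)
            passive[idx[x[idx] <= tol]] = False
            x[~passive] = 0.0
        w = A.T @ (b - A @ x)
    return x


class _Method:
    def __init__(self, name: str, solver: Callable, min_cells: int):
        self.name = name
        self.solver = solver
        self.min_cells = min_cells


_REGISTRY: dict[str, _Method] = {}


def register_method(name: str, solver: Callable, min_cells: int = 1) -> None:
    """Register a deconvolution backend.

    ``solver(signature_values: DataFrame, bulk_cpm: Series) -> Series`` maps
    a per-million-normalized bulk vector onto raw (possibly unnormalized)
    per-type coefficients; clamping and renormalization happen outside.
    ``min_cells`` is the backend's minimum reference cells per quantifiable
    type (e.g. 2 for MuSiC, 3 for CIBERSORTx).
    """
    _REGISTRY[name] = _Method(name, solver, min_cells)


def available_methods() -> list[str]:
    return sorted(_REGISTRY)


def _nnls_backend(sig: pd.DataFrame, bulk_cpm: pd.Series) -> pd.Series:
    coef = nnls_solve(sig.to_numpy(), bulk_cpm.to_numpy())
    return pd.Series(coef, index=sig.columns)


register_method("nnls", _nnls_backend, min_cells=1)


def deconvolve(
    signature: SignatureMatrix,
    bulk,
    method: str = "nnls",
    min_gene_overlap: int = 200,
    reference_tag: str | None = None,
) -> DeconvolutionResult:
    """Estimate a bulk sample's cell-type RNA fractions.

    ``bulk`` is a :class:`~deconvbench.simulate.BulkSample` or a
    gene-indexed count Series. Genes are intersected by exact id, both sides
    are per-million normalized, the method backend is dispatched, negatives
    are clamped and the result renormalized to sum to one. Cell types whose
    reference column was built from fewer cells than the backend's minimum
    are excluded and reported with a reason instead of silently set to zero.
    """
    if method not in _REGISTRY:
        raise RegistryError(
            f"unknown method {method!r}; registered: {available_methods()}"
        )
    backend = _REGISTRY[method]
    if isinstance(bulk, BulkSample):
        vec, sample_id, protocol = bulk.counts, bulk.sample_id, bulk.protocol
    else:
        vec = pd.Series(bulk)
        sample_id, protocol = str(vec.name or "bulk"), None

    shared = signature.genes.intersection(vec.index)
    if len(shared) < min_gene_overlap:
        raise GeneOverlapError(
            f"only {len(shared)} shared genes, need >= {min_gene_overlap}"
        )

    excluded = {
        t: f"built from {int(signature.cell_counts[t])} cells, "
           f"{method} requires >= {backend.min_cells}"
        for t in signature.cell_types
        if int(signature.cell_counts.get(t, 0)) < backend.min_cells
    }
    usable = [t for t in signature.cell_types if t not in excluded]
    if not usable:
        raise GeneOverlapError("no cell types satisfy the method's minimum-cell rule")

    sig = signature.values.loc[shared, usable]
    b = vec.loc[shared].astype(float)
    total = b.sum()
    if total <= 0:
        raise ShapeError("bulk vector has zero total counts on the shared genes")
    b = b / total * 1e6

    coef = backend.solver(sig, b).clip(lower=0.0)
    if coef.sum() <= 0:
        fractions = pd.Series(1.0 / len(usable), index=usable)
    else:
        fractions = coef / coef.sum()
    return DeconvolutionResult(
        method=method,
        sample_id=sample_id,
        protocol=protocol,
        reference_tag=reference_tag,
        fractions=fractions,
        excluded=excluded,
    )
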
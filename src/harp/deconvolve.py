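"""Deconvolution mode: estimate cell compositions of bulk samples.

The workhorse is per-sample non-negative least squares against a reference
matrix: ``c_m = argmin_{c >= 0} || W^(1/2) (y_m - X c) ||^2`` with an optional
diagonal gene weighting ``W``.  On top of that sits a minimal digital-tissue-
deconvolution (DTD) style weight learner: given training bulks with known
compositions, it adjusts the per-gene weights by projected gradient ascent so
that the weighted estimates correlate maximally (Pearson, per cell type,
across samples) with the known compositions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import scipy.optimize

from .matrixio import CompositionMatrix, ExpressionMatrix, align_features

if TYPE_CHECKING:  # pragma: no cover
    from .harmonize import HarmonizationResult

__all__ = [
    "GeneWeights",
    "DeconvolutionResult",
    "nnls_matrix",
    "estimate_composition_nnls",
    "learn_gene_weights_dtd",
    "deconvolve",
]


@dataclass
class GeneWeights:
    """Learned non-negative per-gene weights for weighted-NNLS deconvolution."""

    weights: np.ndarray
    gene_ids: list[str] | None = None
    trained_on: list[str] = field(default_factory=list)
    objective_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if np.any(self.weights < 0) or not np.all(np.isfinite(self.weights)):
            raise ValueError("gene weights must be finite and non-negative")
        if not np.any(self.weights > 0):
            raise ValueError("at least one gene weight must be positive")


@dataclass
class DeconvolutionResult:
    """Estimated compositions plus per-sample residual diagnostics."""

    c_hat: CompositionMatrix
    residual_norm: np.ndarray
    backend: str
    normalized: bool

    def identified_fractions(self) -> CompositionMatrix:
        """Fractions renormalized over identified cell types (UI dropped)."""
        sub = self.c_hat.drop_ui()
        sums = sub.values.sum(axis=0)
        vals = np.divide(sub.values, sums, out=np.zeros_like(sub.values),
                         where=sums > 0)
        return CompositionMatrix(vals, list(sub.celltype_ids),
                                 list(sub.sample_ids), False)


def nnls_matrix(y: np.ndarray, x: np.ndarray,
                weights: np.ndarray | None = None) -> np.ndarray:
    """Column-wise (weighted) NNLS: solve ``y[:, m] ~ x @ c_m`` with ``c_m >= 0``.

    Returns the (q x n) matrix of raw-scale solutions.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    if y.ndim == 1:
        y = y[:, None]
    if weights is not None:
        w = np.sqrt(np.asarray(weights, float).ravel())
        x = x * w[:, None]
        y = y * w[:, None]
    out = np.empty((x.shape[1], y.shape[1]))
    for m in range(y.shape[1]):
        out[:, m], _ = scipy.optimize.nnls(x, y[:, m])
    return out


def estimate_composition_nnls(
    y: ExpressionMatrix,
    x: ExpressionMatrix,
    gene_weights: GeneWeights | None = None,
    normalize: bool = False,
) -> DeconvolutionResult:
    """Per-sample (weighted) non-negative least squares deconvolution.

    Parameters
    ----------
    y, x
        Feature-aligned bulk and reference matrices (identical gene order).
    gene_weights
        Optional diagonal weighting of the residual per gene.
    normalize
        Rescale each estimated column to the simplex (columns of all zeros
        are left zero, with a warning).
    """
    if list(y.gene_ids) != list(x.gene_ids):
        raise ValueError("estimate_composition_nnls: matrices are not feature-aligned")
    w = None
    if gene_weights is not None:
        if gene_weights.weights.size != y.n_genes:
            raise ValueError("gene weights do not match the gene count")
        w = gene_weights.weights
    c = nnls_matrix(y.values, x.values, w)
    resid = y.values - x.values @ c
    if w is not None:
        resid = np.sqrt(w)[:, None] * resid
    residual_norm = np.linalg.norm(resid, axis=0)
    if normalize:
        sums = c.sum(axis=0)
        zero = np.nonzero(sums <= 0)[0]
        if zero.size:
            warnings.warn(
                f"all-zero composition estimate for sample(s) "
                f"{[y.column_ids[j] for j in zero]}", stacklevel=2)
        c = np.divide(c, sums, out=np.zeros_like(c), where=sums > 0)
    c_hat = CompositionMatrix(
        c, list(x.column_ids), list(y.column_ids),
        is_extended=bool(x.column_ids and x.column_ids[-1] == "UI"),
    )
    return DeconvolutionResult(c_hat=c_hat, residual_norm=residual_norm,
                               backend="nnls", normalized=normalize)


# ---------------------------------------------------------------------------
# DTD-style gene-weight learning
# ---------------------------------------------------------------------------

def _corr_objective_and_grad(
    w: np.ndarray, y: np.ndarray, x: np.ndarray, c_true: np.ndarray,
    skip_types: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Sum of per-cell-type Pearson correlations and its gradient in ``w``.

    The gradient flows through the weighted NNLS solutions via implicit
    differentiation on each sample's active set: with ``S`` the support of
    ``c_m`` and ``M = X_S' W X_S``, ``d c_S / d w_g = M^-1 x_{gS} r_g`` where
    ``r_g`` is the residual of gene ``g``.
    """
    q, n = c_true.shape
    c_hat = np.zeros((q, n))
    # jac[g, l, m] = d c_hat[l, m] / d w_g, assembled sample by sample
    jac = np.zeros((w.size, q, n))
    for m in range(n):
        sw = np.sqrt(w)
        cm, _ = scipy.optimize.nnls(sw[:, None] * x, sw * y[:, m])
        c_hat[:, m] = cm
        S = np.nonzero(cm > 1e-12)[0]
        if S.size == 0:
            continue
        xs = x[:, S]
        M = xs.T @ (w[:, None] * xs)
        r = y[:, m] - xs @ cm[S]
        try:
            dcS = np.linalg.solve(M, (xs * r[:, None]).T)  # (|S|, g)
        except np.linalg.LinAlgError:
            continue
        jac[:, S, m] = dcS.T
    obj = 0.0
    grad = np.zeros_like(w)
    for l in range(q):
        if skip_types[l]:
            continue
        u = c_hat[l, :] - c_hat[l, :].mean()
        v = c_true[l, :] - c_true[l, :].mean()
        su = np.sqrt((u * u).sum())
        sv = np.sqrt((v * v).sum())
        if su <= 1e-15 or sv <= 1e-15:
            continue
        r_l = float((u * v).sum() / (su * sv))
        obj += r_l
        # d r / d c_hat[l, m]
        dr_dc = v / (su * sv) - r_l * u / (su * su)
        grad += jac[:, l, :] @ dr_dc
    return obj, grad


def learn_gene_weights_dtd(
    y_train: ExpressionMatrix,
    c_train: CompositionMatrix,
    x: ExpressionMatrix,
    n_iter: int = 100,
    step: float = 1.0,
    seed: int = 0,
) -> GeneWeights:
    """Learn per-gene weights maximizing composition correlation on training data.

    Projected gradient ascent on ``sum_l cor(c_hat_l(w), c_train_l)`` over
    ``w >= 0`` with backtracking line search, starting from uniform weights;
    weights are renormalized to mean one after every step (the estimator is
    invariant to their overall scale).  Deterministic given its inputs; the
    ``seed`` argument is accepted for interface uniformity.
    """
    del seed  # the ascent is deterministic from uniform initialization
    if list(y_train.gene_ids) != list(x.gene_ids):
        raise ValueError("learn_gene_weights_dtd: matrices are not feature-aligned")
    yv, xv = y_train.values, x.values
    ct = c_train.values
    if ct.shape[0] != xv.shape[1]:
        raise ValueError("c_train rows must match reference columns")
    skip = ct.std(axis=1) <= 1e-15
    for l in np.nonzero(skip)[0]:
        warnings.warn(
            f"constant composition row {c_train.celltype_ids[l]!r}; "
            "its correlation term is skipped", stacklevel=2)
    w = np.ones(yv.shape[0])
    obj, grad = _corr_objective_and_grad(w, yv, xv, ct, skip)
    trace = [obj]
    cur_step = step
    for _ in range(n_iter):
        if np.linalg.norm(grad) <= 1e-12:
            trace.append(obj)
            continue
        improved = False
        for _ls in range(30):
            w_new = np.maximum(w + cur_step * grad, 0.0)
            if not np.any(w_new > 0):
                cur_step *= 0.5
                continue
            w_new = w_new / w_new.mean()
            obj_new, grad_new = _corr_objective_and_grad(w_new, yv, xv, ct, skip)
            if obj_new >= obj - 1e-12:
                improved = obj_new > obj + 1e-12
                w, obj, grad = w_new, obj_new, grad_new
                break
            cur_step *= 0.5
        trace.append(obj)
        if not improved:
            cur_step *= 2.0  # allow recovery after aggressive shrinking
    return GeneWeights(weights=w, gene_ids=list(y_train.gene_ids),
                       trained_on=list(y_train.column_ids),
                       objective_trace=trace)


# ---------------------------------------------------------------------------
# High-level Deconvolution mode
# ---------------------------------------------------------------------------

def deconvolve(
    y_new: ExpressionMatrix,
    result: "HarmonizationResult",
    backend: str = "nnls",
    weights: GeneWeights | None = None,
) -> DeconvolutionResult:
    """Deconvolve new bulks with a harmonized reference.

    Aligns ``y_new`` to the training gene space (fatal below 10 % overlap,
    warning below 50 %), runs the chosen backend and reports simplex-
    normalized compositions including the UI compartment when present.
    """
    if backend not in ("nnls", "dtd"):
        raise ValueError(f"unknown backend {backend!r}")
    x_prime = result.x_prime
    n_train_genes = x_prime.n_genes
    y_al, x_al, _ = align_features(y_new, x_prime)
    frac = y_al.n_genes / n_train_genes
    if frac < 0.10:
        raise ValueError(
            f"only {y_al.n_genes}/{n_train_genes} training genes present in the "
            "new bulks (<10%)")
    if frac < 0.50:
        warnings.warn(
            f"only {y_al.n_genes}/{n_train_genes} training genes present in the "
            "new bulks", stacklevel=2)
    if backend == "dtd":
        if weights is None:
            raise ValueError("dtd backend requires learned gene weights")
        lut = dict(zip(weights.gene_ids or x_prime.gene_ids, weights.weights))
        w = GeneWeights(np.array([lut[g] for g in y_al.gene_ids]),
                        gene_ids=list(y_al.gene_ids),
                        trained_on=weights.trained_on)
    else:
        w = None
    res = estimate_composition_nnls(y_al, x_al, gene_weights=w, normalize=True)
    res.backend = backend
    return res
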
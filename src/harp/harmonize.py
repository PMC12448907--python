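"""Training mode: harmonize a reference matrix against bulks and compositions.

Given bulk expression ``Y`` (genes x samples), an anchor reference ``X``
(genes x cell types) and experimentally measured compositions ``C`` (cell
types x samples) that need not be mutually consistent, this module learns

* a harmonized reference ``X'`` close to the anchor, and
* a non-negative per-cell-type scaling vector ``alpha`` correcting systematic
  bias in the measured compositions,

such that ``Y ~ X' diag(alpha) C*``.  ``C*`` is ``C`` extended by a residual
"UI" row for unidentified cell mass (skipped when the reference is declared
complete), and ``X*`` is the anchor extended by the mean profile of the
reference cell types absent from ``C``.

The loss is

    L(phi, alpha) = || Y - phi diag(alpha) C* ||_F^2 + lambda * R(X*, phi)

with the symmetric softplus anchor penalty

    R(X, phi) = sum_ij [ softplus(phi_ij - x_ij) + softplus(x_ij - phi_ij) ],

minimized by alternating a box-constrained quasi-Newton update of ``phi``
(gradient of the penalty is tanh((phi - x)/2)), column re-normalization of
``phi`` so each column sums to the gene count (identifiability), and a
closed-form update of ``alpha`` against compositions re-estimated from the
current reference by non-negative least squares.  The regularization
strength ``lambda`` is chosen by seeded k-fold cross-validation unless fixed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .deconvolve import nnls_matrix
from .matrixio import (
    UI_TOKEN,
    CompositionMatrix,
    ExpressionMatrix,
    ScalingVector,
)

__all__ = [
    "RegularizationConfig",
    "HarmonizationState",
    "HarmonizationResult",
    "extend_composition",
    "extend_reference",
    "regularizer",
    "regularizer_gradient",
    "training_loss",
    "update_reference",
    "normalize_columns",
    "update_alpha",
    "harmonize",
    "select_lambda",
    "default_lambda_grid",
]

logger = logging.getLogger(__name__)


def default_lambda_grid() -> np.ndarray:
    """``{0} U {2^0, 2^1, ..., 2^15}`` — the default search range for lambda."""
    return np.concatenate(([0.0], 2.0 ** np.arange(16)))


@dataclass
class RegularizationConfig:
    """How the anchor-penalty strength lambda is chosen.

    ``fixed_lambda`` bypasses cross-validation entirely; otherwise each value
    of ``lambda_grid`` is scored by ``cv_folds``-fold CV over training samples.
    """

    lambda_grid: np.ndarray = field(default_factory=default_lambda_grid)
    cv_folds: int = 5
    fixed_lambda: float | None = None

    def __post_init__(self) -> None:
        self.lambda_grid = np.sort(np.asarray(self.lambda_grid, dtype=float).ravel())
        if self.lambda_grid.size == 0:
            raise ValueError("lambda_grid must be nonempty")
        if np.any(self.lambda_grid < 0):
            raise ValueError("lambda values must be non-negative")
        if self.fixed_lambda is None and not np.any(self.lambda_grid > 0):
            raise ValueError("lambda_grid must contain at least one positive value")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class HarmonizationState:
    """Mutable state of the alternating optimization (mostly diagnostic)."""

    phi_star: np.ndarray
    alpha: np.ndarray
    iteration: int = 0
    loss_trace: list[float] = field(default_factory=list)


@dataclass
class HarmonizationResult:
    """Artifact of Training mode.

    Attributes
    ----------
    x_prime : ExpressionMatrix
        Harmonized reference; every column sums to the gene count.
    alpha : ScalingVector
        Composition correction factors, one per (extended) cell type.
    lambda_opt : float
        The anchor-penalty strength used for the final fit.
    c_prime : CompositionMatrix
        ``diag(alpha) C*`` on the training samples.
    x_star : ExpressionMatrix
        The (column-normalized, possibly extended) anchor the fit was
        regularized toward.
    cv_scores : dict or None
        Mean held-out score per lambda, if cross-validation ran.
    """

    x_prime: ExpressionMatrix
    alpha: ScalingVector
    lambda_opt: float
    c_prime: CompositionMatrix
    x_star: ExpressionMatrix
    cv_scores: dict[float, float] | None
    converged: bool
    n_iterations: int
    loss_trace: list[float]
    final_loss: float

    @property
    def celltype_ids(self) -> list[str]:
        return list(self.x_prime.column_ids)


# ---------------------------------------------------------------------------
# Extension of C and X by the unidentified compartment
# ---------------------------------------------------------------------------

def extend_composition(c: CompositionMatrix) -> CompositionMatrix:
    """Append the residual "UI" row ``max(0, 1 - column sum)`` to ``C``.

    Measured fractions are fractions of a whole; whatever mass they leave
    unexplained is attributed to unidentified cell types.  Columns whose
    measured fractions already exceed one get a zero residual and a warning.
    """
    if c.is_extended:
        raise ValueError("composition matrix is already extended")
    sums = c.values.sum(axis=0)
    ui = np.maximum(0.0, 1.0 - sums)
    over = np.nonzero(sums > 1.0 + 1e-9)[0]
    for j in over:
        warnings.warn(
            f"composition column {c.sample_ids[j]!r} sums to {sums[j]:.6g} > 1; "
            "UI residual clamped to 0",
            stacklevel=2,
        )
    values = np.vstack([c.values, ui])
    return CompositionMatrix(values, list(c.celltype_ids) + [UI_TOKEN],
                             list(c.sample_ids), is_extended=True)


def extend_reference(x_full: ExpressionMatrix, identified: list[str]) -> ExpressionMatrix:
    """Build ``X* = (X, X_UI)``.

    Keeps the ``identified`` columns in the given order and appends ``X_UI``,
    the gene-wise mean over all remaining reference columns — a generic
    profile for the compartment not covered by the composition measurement.
    Falls back to the mean of the identified columns (with a warning) when
    nothing is left over.
    """
    if not identified:
        raise ValueError("extend_reference: identified cell-type list is empty")
    missing = [t for t in identified if t not in set(x_full.column_ids)]
    if missing:
        raise ValueError(f"extend_reference: cell types not in reference: {missing}")
    leftover = [cid for cid in x_full.column_ids if cid not in set(identified)]
    x_id = x_full.subset_columns(identified)
    if leftover:
        ui_col = x_full.subset_columns(leftover).values.mean(axis=1)
    else:
        warnings.warn(
            "no leftover reference columns; UI profile set to mean of identified types",
            stacklevel=2,
        )
        ui_col = x_id.values.mean(axis=1)
    values = np.column_stack([x_id.values, ui_col])
    return ExpressionMatrix(values, list(x_full.gene_ids),
                            list(identified) + [UI_TOKEN])


# ---------------------------------------------------------------------------
# Loss pieces
# ---------------------------------------------------------------------------

def _pair_softplus(d: np.ndarray) -> np.ndarray:
    # softplus(d) + softplus(-d) = |d| + 2*log1p(exp(-|d|)); logaddexp is the
    # stable form of both halves.
    return np.logaddexp(0.0, d) + np.logaddexp(0.0, -d)


def regularizer(x_star: ExpressionMatrix | np.ndarray,
                phi_star: ExpressionMatrix | np.ndarray) -> float:
    """Symmetric softplus anchor penalty ``R(X*, phi*)`` (scalar).

    Per entry, ``softplus(phi - x) + softplus(x - phi)``: minimized (at
    ``2 ln 2``) when ``phi = x`` and asymptotically linear in ``|phi - x|``,
    so large corrections are penalized like an L1 distance from the anchor.
    """
    x = x_star.values if isinstance(x_star, ExpressionMatrix) else np.asarray(x_star, float)
    p = phi_star.values if isinstance(phi_star, ExpressionMatrix) else np.asarray(phi_star, float)
    if x.shape != p.shape:
        raise ValueError(f"regularizer: shape mismatch {x.shape} vs {p.shape}")
    return float(_pair_softplus(p - x).sum())


def regularizer_gradient(x_star: np.ndarray, phi_star: np.ndarray) -> np.ndarray:
    """Gradient of the anchor penalty w.r.t. ``phi``: ``tanh((phi - x)/2)``."""
    return np.tanh((np.asarray(phi_star, float) - np.asarray(x_star, float)) / 2.0)


def training_loss(y, phi_star, alpha, c_star, lam: float, x_star) -> float:
    """Full training loss: squared Frobenius residual plus ``lam * R``."""
    y = y.values if isinstance(y, ExpressionMatrix) else np.asarray(y, float)
    phi = phi_star.values if isinstance(phi_star, ExpressionMatrix) else np.asarray(phi_star, float)
    a = alpha.alpha if isinstance(alpha, ScalingVector) else np.asarray(alpha, float).ravel()
    c = c_star.values if isinstance(c_star, CompositionMatrix) else np.asarray(c_star, float)
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if phi.shape[1] != a.size or c.shape[0] != a.size or y.shape != (phi.shape[0], c.shape[1]):
        raise ValueError("training_loss: non-conformable shapes")
    resid = y - phi @ (a[:, None] * c)
    return float((resid * resid).sum()) + lam * regularizer(x_star, phi)


# ---------------------------------------------------------------------------
# Alternating updates
# ---------------------------------------------------------------------------

def update_reference(y, alpha, c_star, x_star, lam: float,
                     phi_init: np.ndarray | None = None) -> np.ndarray:
    """Minimize the training loss in ``phi`` for fixed ``alpha`` (``phi >= 0``).

    With ``A = diag(alpha) C*`` the objective separates across gene rows into
    convex problems ``|| y_g - phi_g A ||^2 + lam * sum_j pair_softplus(phi_gj
    - x_gj)``; all rows are solved in one vectorized box-constrained L-BFGS-B
    run with the analytic gradient.  Warm-startable via ``phi_init``
    (defaults to the anchor).
    """
    y = y.values if isinstance(y, ExpressionMatrix) else np.asarray(y, float)
    x = x_star.values if isinstance(x_star, ExpressionMatrix) else np.asarray(x_star, float)
    a = alpha.alpha if isinstance(alpha, ScalingVector) else np.asarray(alpha, float).ravel()
    c = c_star.values if isinstance(c_star, CompositionMatrix) else np.asarray(c_star, float)
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x)) and np.all(np.isfinite(c))):
        raise ValueError("update_reference: non-finite inputs")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    A = a[:, None] * c                      # (k, n)
    AAt = A @ A.T
    YAt = y @ A.T
    shape = x.shape
    phi0 = np.maximum(x if phi_init is None else np.asarray(phi_init, float), 0.0)

    def fun(v: np.ndarray) -> tuple[float, np.ndarray]:
        phi = v.reshape(shape)
        resid_term = float(np.einsum("ij,ij->", phi @ AAt, phi)) \
            - 2.0 * float(np.einsum("ij,ij->", phi, YAt)) + float((y * y).sum())
        grad = 2.0 * (phi @ AAt - YAt)
        if lam > 0:
            d = phi - x
            resid_term += lam * float(_pair_softplus(d).sum())
            grad = grad + lam * np.tanh(d / 2.0)
        return resid_term, grad.ravel()

    res = minimize(
        fun, phi0.ravel(), jac=True, method="L-BFGS-B",
        bounds=[(0.0, None)] * phi0.size,
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-8},
    )
    return res.x.reshape(shape)


def normalize_columns(x: ExpressionMatrix | np.ndarray):
    """Rescale each column to sum to the number of genes (identifiability).

    Harmonization can trade scale between a reference column and its alpha
    entry; pinning every column sum to ``g`` removes that degeneracy.
    """
    arr = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, float)
    g = arr.shape[0]
    sums = arr.sum(axis=0)
    zero = np.nonzero(sums <= 0)[0]
    if zero.size:
        if isinstance(x, ExpressionMatrix):
            bad = [x.column_ids[j] for j in zero]
        else:
            bad = zero.tolist()
        raise ValueError(f"normalize_columns: zero-sum column(s) {bad}")
    out = arr * (g / sums)
    if isinstance(x, ExpressionMatrix):
        return ExpressionMatrix(out, list(x.gene_ids), list(x.column_ids))
    return out


def update_alpha(c_star, c_hat) -> np.ndarray:
    """Closed-form row-wise minimizer of ``|| diag(alpha) C* - C_hat ||^2``.

    ``alpha_l = <C*_l, C_hat_l> / <C*_l, C*_l>`` clamped at zero; all-zero
    rows of ``C*`` are unidentifiable and get ``alpha_l = 1`` with a warning.
    """
    cs = c_star.values if isinstance(c_star, CompositionMatrix) else np.asarray(c_star, float)
    ch = c_hat.values if isinstance(c_hat, CompositionMatrix) else np.asarray(c_hat, float)
    if cs.shape != ch.shape:
        raise ValueError(f"update_alpha: shape mismatch {cs.shape} vs {ch.shape}")
    denom = (cs * cs).sum(axis=1)
    numer = (cs * ch).sum(axis=1)
    alpha = np.ones(cs.shape[0])
    ok = denom > 0
    alpha[ok] = np.maximum(0.0, numer[ok] / denom[ok])
    if np.any(~ok):
        warnings.warn("all-zero composition row(s); alpha set to 1 for them",
                      stacklevel=2)
    return alpha


# ---------------------------------------------------------------------------
# Full training loop
# ---------------------------------------------------------------------------

def _alternate(y: np.ndarray, x_star: np.ndarray, c_star: np.ndarray,
               lam: float, max_iter: int, tol: float,
               deconv_backend=None) -> HarmonizationState:
    """Run the alternating optimization on raw arrays for one lambda.

    ``deconv_backend(y, phi) -> c_hat`` re-estimates compositions each outer
    iteration; defaults to column-wise non-negative least squares.
    """
    backend = nnls_matrix if deconv_backend is None else deconv_backend
    g = x_star.shape[0]
    state = HarmonizationState(phi_star=x_star.copy(),
                               alpha=np.ones(x_star.shape[1]))
    prev = np.inf
    for it in range(1, max_iter + 1):
        state.phi_star = update_reference(y, state.alpha, c_star, x_star, lam,
                                          phi_init=state.phi_star)
        # normalize columns to sum g and move the scale into alpha: the
        # residual term is invariant under (phi_l * s, alpha_l / s)
        sums = state.phi_star.sum(axis=0)
        if np.any(sums <= 0):
            raise ValueError("reference column collapsed to zero during "
                             "optimization")
        state.phi_star = state.phi_star * (g / sums)
        state.alpha = state.alpha * (sums / g)
        c_hat = backend(y, state.phi_star)
        state.alpha = update_alpha(c_star, c_hat)
        loss = training_loss(y, state.phi_star, state.alpha, c_star, lam, x_star)
        state.loss_trace.append(loss)
        state.iteration = it
        logger.info("iteration %d: loss %.6g", it, loss)
        if np.isfinite(prev) and abs(prev - loss) <= tol * max(abs(prev), 1.0):
            break
        prev = loss
    # final polish: make the returned reference the exact phi-minimizer for
    # the returned alpha (it only ever lowers the loss), then re-normalize
    state.phi_star = update_reference(y, state.alpha, c_star, x_star, lam,
                                      phi_init=state.phi_star)
    sums = state.phi_star.sum(axis=0)
    state.phi_star = state.phi_star * (g / sums)
    state.alpha = state.alpha * (sums / g)
    state.loss_trace.append(
        training_loss(y, state.phi_star, state.alpha, c_star, lam, x_star))
    return state


def _loss_increases(trace: list[float], rel: float = 1e-6) -> int:
    ups = 0
    for a, b in zip(trace, trace[1:]):
        if b > a + rel * max(abs(a), 1.0):
            ups += 1
    return ups


def harmonize(
    y: ExpressionMatrix,
    x_full: ExpressionMatrix,
    c: CompositionMatrix,
    config: RegularizationConfig | None = None,
    max_iter: int = 50,
    tol: float = 1e-6,
    seed: int = 0,
    complete_reference: bool = False,
    rescale_bulk: str = "none",
    deconv_backend=None,
) -> HarmonizationResult:
    """Training mode: fit the harmonized reference and composition scalings.

    Parameters
    ----------
    y, x_full, c
        Feature-aligned bulk matrix, reference matrix and measured
        compositions (training samples only).  Cell types of ``c`` must be a
        subset of the reference columns.
    config
        Lambda selection settings; defaults to 5-fold CV over
        ``{0} U {2^0..2^15}``.
    complete_reference
        Declare that the reference covers all cell mass in the tissue: no UI
        row/column is appended and the reference is restricted to the measured
        cell types.
    rescale_bulk : {"none", "to_gene_count"}
        Optionally rescale each bulk column to sum to the gene count, putting
        ``Y`` on the same scale as the column-normalized reference so that
        ``alpha`` is interpretable as an absolute correction factor.

    Returns
    -------
    HarmonizationResult
    """
    if config is None:
        config = RegularizationConfig()
    if list(y.gene_ids) != list(x_full.gene_ids):
        raise ValueError("harmonize: bulk and reference must be feature-aligned "
                         "(run align_features first)")
    if list(c.sample_ids) != list(y.column_ids):
        y = y.subset_columns(c.sample_ids)

    if complete_reference:
        if c.is_extended:
            raise ValueError("complete_reference with an extended composition matrix")
        c_star = c.copy()
        x_star = x_full.subset_columns(list(c.celltype_ids))
    else:
        c_star = c if c.is_extended else extend_composition(c)
        identified = c_star.celltype_ids[:-1]
        x_star = extend_reference(x_full, list(identified))

    x_star = normalize_columns(x_star)
    y_arr = y.values
    if rescale_bulk == "to_gene_count":
        sums = y_arr.sum(axis=0)
        if np.any(sums <= 0):
            raise ValueError("rescale_bulk: bulk column with non-positive sum")
        y_arr = y_arr * (y.n_genes / sums)
    elif rescale_bulk != "none":
        raise ValueError(f"unknown rescale_bulk mode {rescale_bulk!r}")

    cv_scores: dict[float, float] | None = None
    if config.fixed_lambda is not None:
        lam = float(config.fixed_lambda)
    elif config.lambda_grid.size == 1:
        lam = float(config.lambda_grid[0])
    else:
        lam, cv_scores = select_lambda(
            y_arr, x_star, c_star, config, seed=seed,
            max_iter=max_iter, tol=tol, deconv_backend=deconv_backend,
        )

    state = _alternate(y_arr, x_star.values, c_star.values, lam, max_iter, tol,
                       deconv_backend=deconv_backend)
    # the last trace entry is the post-polish loss; the re-normalization after
    # the polish may raise it by O(eps) because the anchor penalty is not
    # scale-invariant, so convergence is judged on the loop iterations only
    ups = _loss_increases(state.loss_trace[:-1])
    converged = state.iteration < max_iter and ups == 0
    if ups:
        logger.warning("loss increased in %d outer iteration(s)", ups)

    x_prime = ExpressionMatrix(state.phi_star, list(x_star.gene_ids),
                               list(x_star.column_ids))
    c_prime = CompositionMatrix(state.alpha[:, None] * c_star.values,
                                list(c_star.celltype_ids), list(c_star.sample_ids),
                                c_star.is_extended)
    return HarmonizationResult(
        x_prime=x_prime,
        alpha=ScalingVector(state.alpha, list(c_star.celltype_ids)),
        lambda_opt=lam,
        c_prime=c_prime,
        x_star=x_star,
        cv_scores=cv_scores,
        converged=converged,
        n_iterations=state.iteration,
        loss_trace=state.loss_trace,
        final_loss=state.loss_trace[-1] if state.loss_trace else float("nan"),
    )


def select_lambda(
    y: np.ndarray,
    x_star: ExpressionMatrix,
    c_star: CompositionMatrix,
    config: RegularizationConfig,
    seed: int = 0,
    max_iter: int = 50,
    tol: float = 1e-6,
    deconv_backend=None,
) -> tuple[float, dict[float, float]]:
    """Choose lambda by seeded k-fold CV over training samples.

    Each held-out fold is scored by the predictive reconstruction R^2 of its
    bulks from the corrected measured compositions,
    ``1 - ||Y_ho - X' diag(alpha) C*_ho||^2 / ||Y_ho - mean||^2``
    (column-wise centering) — i.e. how well the harmonized model itself
    generalizes the relation ``Y ~ X' C'(alpha)`` to unseen samples.  An
    over-anchored reference underfits the held-out residual; an over-adjusted
    one overfits the training patients; both lose.  Scores built from
    re-estimated compositions are deliberately not used: any bias of ``X'``
    propagates identically into them and into ``diag(alpha) C*``, so they
    cannot detect over-anchoring.  Ties are broken toward the larger lambda
    (stronger anchoring).
    """
    grid = config.lambda_grid
    if grid.size == 1:
        return float(grid[0]), {float(grid[0]): float("nan")}
    n = y.shape[1]
    k = config.cv_folds
    if n < k:
        raise ValueError(f"select_lambda: {n} samples < {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = [perm[i::k] for i in range(k)]

    mean_scores: dict[float, float] = {}
    for lam in grid:
        fold_scores = []
        for ho in folds:
            tr = np.setdiff1d(perm, ho)
            state = _alternate(y[:, tr], x_star.values, c_star.values[:, tr],
                               float(lam), max_iter, tol,
                               deconv_backend=deconv_backend)
            recon = state.phi_star @ (state.alpha[:, None] * c_star.values[:, ho])
            ss_res = float(((y[:, ho] - recon) ** 2).sum())
            ss_tot = float(((y[:, ho] - y[:, ho].mean(axis=0)) ** 2).sum())
            fold_scores.append(1.0 - ss_res / ss_tot if ss_tot > 0 else -np.inf)
        mean_scores[float(lam)] = float(np.mean(fold_scores))
        logger.info("lambda %g: CV score %.6g", lam, mean_scores[float(lam)])

    best = max(mean_scores.values())
    # tie-break toward the larger lambda (favor anchoring)
    lam_opt = max(l for l, s in mean_scores.items() if s >= best - 1e-12)
    return lam_opt, mean_scores
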
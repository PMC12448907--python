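"""Model/Results interface for reference harmonization.

:class:`HarpModel` bundles the three training inputs — bulk expression ``Y``,
anchor reference ``X`` and measured compositions ``C`` — performs feature
alignment and validation up front, and :meth:`HarpModel.fit` runs Training
mode, returning a :class:`HarpResults` that carries the harmonized reference
``X'``, the composition correction factors ``alpha``, the selected
regularization strength and fit diagnostics.  Deconvolution of new bulks and
evaluation hang off the results object.
"""

from __future__ import annotations

import numpy as np

from . import metrics as _metrics
from .deconvolve import DeconvolutionResult, GeneWeights
from .deconvolve import deconvolve as _deconvolve
from .deconvolve import learn_gene_weights_dtd as _learn_weights
from .harmonize import (
    HarmonizationResult,
    RegularizationConfig,
    default_lambda_grid,
    harmonize as _harmonize,
)
from .matrixio import (
    CompositionMatrix,
    ExpressionMatrix,
    align_features,
    read_composition,
    read_matrix,
    validate_inputs,
)

__all__ = ["HarpModel", "HarpResults"]


class HarpModel:
    """Harmonization model for bulk deconvolution training data.

    Parameters
    ----------
    bulk : ExpressionMatrix
        Training bulk expression, genes x samples, linear scale.
    reference : ExpressionMatrix
        Anchor reference profiles, genes x cell types.
    composition : CompositionMatrix
        Experimentally measured cell fractions, cell types x samples.
    complete_reference : bool
        Declare that the measured cell types account for all cell mass, so no
        unidentified compartment is added.
    rescale_bulk : {"to_gene_count", "none"}
        Whether to rescale bulk columns onto the normalized-reference scale
        (recommended; makes ``alpha`` an absolute correction factor).

    Examples
    --------
    >>> model = HarpModel(y, x, c, complete_reference=True)
    >>> res = model.fit(seed=17)
    >>> print(res.summary())
    >>> fractions = res.deconvolve(y_new).c_hat
    """

    def __init__(
        self,
        bulk: ExpressionMatrix,
        reference: ExpressionMatrix,
        composition: CompositionMatrix,
        complete_reference: bool = False,
        rescale_bulk: str = "to_gene_count",
    ) -> None:
        y, x, self.alignment = align_features(bulk, reference)
        self.validation = validate_inputs(y, x, composition)
        if not self.validation.ok:
            raise ValueError(
                "invalid training inputs: " + "; ".join(self.validation.warnings))
        self.bulk = y
        self.reference = x
        self.composition = composition
        self.complete_reference = complete_reference
        self.rescale_bulk = rescale_bulk

    @classmethod
    def from_files(
        cls,
        bulk_path: str,
        reference_path: str,
        composition_path: str,
        expm1: bool = False,
        **kwargs,
    ) -> "HarpModel":
        """Build the model from delimited matrix files.

        ``expm1=True`` un-logs bulk and reference values (``exp(v) - 1``) for
        inputs stored on log1p scale; the model itself is linear-scale.
        """
        y = read_matrix(bulk_path)
        x = read_matrix(reference_path)
        c = read_composition(composition_path)
        if expm1:
            y = ExpressionMatrix(np.expm1(y.values), y.gene_ids, y.column_ids)
            x = ExpressionMatrix(np.expm1(x.values), x.gene_ids, x.column_ids)
        return cls(y, x, c, **kwargs)

    def fit(
        self,
        lambda_: float | None = None,
        lambda_grid: np.ndarray | None = None,
        cv_folds: int = 5,
        max_iter: int = 50,
        tol: float = 1e-6,
        seed: int = 0,
    ) -> "HarpResults":
        """Run Training mode (alternating optimization, lambda by CV).

        ``lambda_`` fixes the anchor-penalty strength; otherwise it is chosen
        by ``cv_folds``-fold cross-validation over ``lambda_grid`` (default
        ``{0} U {2^0..2^15}``).
        """
        config = RegularizationConfig(
            lambda_grid=(default_lambda_grid()
                         if lambda_grid is None else np.asarray(lambda_grid, float)),
            cv_folds=cv_folds,
            fixed_lambda=lambda_,
        )
        res = _harmonize(
            self.bulk, self.reference, self.composition,
            config=config, max_iter=max_iter, tol=tol, seed=seed,
            complete_reference=self.complete_reference,
            rescale_bulk=self.rescale_bulk,
        )
        return HarpResults(self, res)


class HarpResults:
    """Results of a harmonization fit.

    Attributes
    ----------
    x_prime : ExpressionMatrix
        Harmonized reference (columns sum to the gene count).
    alpha : ndarray
        Composition correction factors per (extended) cell type.
    lambda_opt : float
        Anchor-penalty strength used for the final fit.
    c_prime : CompositionMatrix
        Corrected training compositions ``diag(alpha) C*``.
    """

    def __init__(self, model: HarpModel, raw: HarmonizationResult) -> None:
        self.model = model
        self._raw = raw

    # -- estimates ---------------------------------------------------------
    @property
    def x_prime(self) -> ExpressionMatrix:
        return self._raw.x_prime

    @property
    def alpha(self) -> np.ndarray:
        return self._raw.alpha.alpha

    @property
    def celltype_ids(self) -> list[str]:
        return self._raw.celltype_ids

    @property
    def lambda_opt(self) -> float:
        return self._raw.lambda_opt

    @property
    def c_prime(self) -> CompositionMatrix:
        return self._raw.c_prime

    @property
    def x_star(self) -> ExpressionMatrix:
        return self._raw.x_star

    # -- diagnostics -------------------------------------------------------
    @property
    def converged(self) -> bool:
        return self._raw.converged

    @property
    def n_iterations(self) -> int:
        return self._raw.n_iterations

    @property
    def loss_trace(self) -> list[float]:
        return self._raw.loss_trace

    @property
    def cv_scores(self) -> dict[float, float] | None:
        return self._raw.cv_scores

    @property
    def anchor_shift(self) -> float:
        """Mean absolute per-entry shift of ``X'`` away from the anchor."""
        return float(np.abs(self.x_prime.values - self.x_star.values).mean())

    def summary(self) -> str:
        """Plain-text summary of the fit (estimates and diagnostics)."""
        r = self._raw
        lines = [
            "Harmonization Results",
            "=" * 54,
            f"genes:            {self.x_prime.n_genes}",
            f"cell types:       {len(self.celltype_ids)}"
            + ("  (incl. UI compartment)" if r.c_prime.is_extended else ""),
            f"training samples: {r.c_prime.n_samples}",
            f"lambda:           {self.lambda_opt:g}"
            + ("  (cross-validated)" if r.cv_scores is not None else "  (fixed)"),
            f"iterations:       {self.n_iterations}"
            + ("" if self.converged else "  [NOT converged]"),
            f"final loss:       {r.final_loss:.6g}",
            f"anchor shift:     {self.anchor_shift:.4g} (mean |X' - X*|)",
            "-" * 54,
            f"{'cell type':<20s} {'alpha':>10s}",
        ]
        for t, a in zip(self.celltype_ids, self.alpha):
            lines.append(f"{t:<20s} {a:>10.4f}")
        lines.append("=" * 54)
        return "\n".join(lines)

    # -- downstream --------------------------------------------------------
    def deconvolve(
        self,
        y_new: ExpressionMatrix,
        backend: str = "nnls",
        weights: GeneWeights | None = None,
    ) -> DeconvolutionResult:
        """Estimate compositions of new bulks with the harmonized reference."""
        if backend == "dtd" and weights is None:
            weights = self.learn_gene_weights()
        return _deconvolve(y_new, self._raw, backend=backend, weights=weights)

    def learn_gene_weights(self, n_iter: int = 100, seed: int = 0) -> GeneWeights:
        """Train DTD-style gene weights on the training bulks against C'."""
        return _learn_weights(
            self.model.bulk, self.c_prime, self.x_prime,
            n_iter=n_iter, seed=seed)

    def evaluate(
        self,
        c_est: CompositionMatrix,
        c_true: CompositionMatrix,
        y_obs: ExpressionMatrix | None = None,
    ) -> _metrics.MetricsReport:
        """Score an estimate against ground truth with the full metric suite."""
        return _metrics.evaluate(c_est, c_true, y_obs=y_obs, x=self.x_prime)
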
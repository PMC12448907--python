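"""Evaluation metrics for deconvolution results.

Compares estimated to ground-truth compositions — per cell type across
samples (Rc), per sample across cell types (Rs), and jointly over all entries
(combined R, RMSD, mAD) — and reconstructed to observed bulk expression
(per-sample rho).  A Fisher z-test compares correlation coefficients between
two methods or scenarios.

By convention, composition metrics are computed on identified cell types
only: when an estimate or truth carries the "UI" (unidentified) row it is
dropped and the remaining fractions are renormalized to the simplex, since
the unidentified compartment is not comparable across methods.  Undefined
correlations (zero-variance vectors) are reported as NaN, never as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .matrixio import CompositionMatrix, ExpressionMatrix

__all__ = [
    "MetricsReport",
    "CorrelationTest",
    "celltype_correlation",
    "sample_correlation",
    "combined_metrics",
    "bulk_reconstruction_rho",
    "compare_correlations_ztest",
    "evaluate",
]


@dataclass
class MetricsReport:
    """All composition / reconstruction metrics for one estimate."""

    r_c: dict[str, float]
    r_s: dict[str, float]
    r_combined: float
    rmsd: float
    mad: float
    rho: dict[str, float] | None
    n_samples: int
    n_celltypes: int

    def summary(self) -> dict:
        """Flat dict of summary means (NaNs ignored) for JSON reports."""
        def nanmean(vals):
            arr = np.array(list(vals), dtype=float)
            return float(np.nanmean(arr)) if arr.size else float("nan")

        out = {
            "mean_Rc": nanmean(self.r_c.values()),
            "mean_Rs": nanmean(self.r_s.values()),
            "R": self.r_combined,
            "RMSD": self.rmsd,
            "mAD": self.mad,
            "n_samples": self.n_samples,
            "n_celltypes": self.n_celltypes,
        }
        if self.rho is not None:
            out["mean_rho"] = nanmean(self.rho.values())
        return out


@dataclass
class CorrelationTest:
    """Fisher z-test comparing two correlation coefficients."""

    z: float
    p_value: float
    r1: float
    r2: float
    n1: int
    n2: int


def _as_pair(c_est: CompositionMatrix, c_true: CompositionMatrix
             ) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Drop UI rows, renormalize both matrices to the identified simplex."""
    est, tru = c_est.drop_ui(), c_true.drop_ui()
    if est.shape != tru.shape:
        raise ValueError(f"shape mismatch: estimate {est.shape} vs truth {tru.shape}")
    if list(est.celltype_ids) != list(tru.celltype_ids):
        tru = CompositionMatrix(
            tru.to_frame().loc[est.celltype_ids].to_numpy(),
            list(est.celltype_ids), list(tru.sample_ids), False)
    def norm(v: np.ndarray) -> np.ndarray:
        s = v.sum(axis=0)
        return np.divide(v, s, out=np.zeros_like(v), where=s > 0)
    return norm(est.values), norm(tru.values), list(est.celltype_ids), list(est.sample_ids)


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, float).ravel()
    v = np.asarray(v, float).ravel()
    if u.std() <= 1e-15 or v.std() <= 1e-15:
        return float("nan")
    return float(np.corrcoef(u, v)[0, 1])


def celltype_correlation(c_est: CompositionMatrix,
                         c_true: CompositionMatrix) -> dict[str, float]:
    """Rc(l): Pearson across samples between estimated and true fractions.

    Captures whether variation of a cell type's abundance across samples is
    tracked correctly.  Requires at least 3 samples; zero-variance rows give
    NaN with a warning.
    """
    est, tru, types, samples = _as_pair(c_est, c_true)
    if len(samples) < 3:
        raise ValueError("celltype_correlation requires >= 3 samples")
    out = {}
    for i, t in enumerate(types):
        r = _pearson(est[i], tru[i])
        if np.isnan(r):
            warnings.warn(f"undefined Rc for cell type {t!r} (zero variance)",
                          stacklevel=2)
        out[t] = r
    return out


def sample_correlation(c_est: CompositionMatrix,
                       c_true: CompositionMatrix) -> dict[str, float]:
    """Rs(m): Pearson across cell types within each sample."""
    est, tru, types, samples = _as_pair(c_est, c_true)
    if len(types) < 3:
        raise ValueError("sample_correlation requires >= 3 cell types")
    out = {}
    for j, s in enumerate(samples):
        r = _pearson(est[:, j], tru[:, j])
        if np.isnan(r):
            warnings.warn(f"undefined Rs for sample {s!r} (zero variance)",
                          stacklevel=2)
        out[s] = r
    return out


def combined_metrics(c_est: CompositionMatrix, c_true: CompositionMatrix
                     ) -> tuple[float, float, float]:
    """Overall (R, RMSD, mAD) over all flattened composition entries."""
    est, tru, _, _ = _as_pair(c_est, c_true)
    diff = est - tru
    rmsd = float(np.sqrt(np.mean(diff ** 2)))
    mad = float(np.mean(np.abs(diff)))
    return _pearson(est, tru), rmsd, mad


def bulk_reconstruction_rho(
    y_obs: ExpressionMatrix | np.ndarray,
    x: ExpressionMatrix | np.ndarray,
    c: CompositionMatrix | np.ndarray,
    scale: str = "log1p",
) -> np.ndarray:
    """rho(m): per-sample Pearson between reconstructed (Xc) and observed bulk.

    Computed across genes on the given scale; the default ``log1p`` keeps the
    correlation from being dominated by a handful of highly expressed genes.
    """
    yv = y_obs.values if isinstance(y_obs, ExpressionMatrix) else np.asarray(y_obs, float)
    xv = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, float)
    cv = c.values if isinstance(c, CompositionMatrix) else np.asarray(c, float)
    if cv.ndim == 1:
        cv = cv[:, None]
    recon = xv @ cv
    if scale == "log1p":
        yv, recon = np.log1p(np.maximum(yv, 0)), np.log1p(np.maximum(recon, 0))
    elif scale != "linear":
        raise ValueError(f"unknown rho scale {scale!r}")
    out = np.empty(yv.shape[1])
    for m in range(yv.shape[1]):
        out[m] = _pearson(yv[:, m], recon[:, m])
    if np.any(np.isnan(out)):
        warnings.warn("undefined rho for zero-variance sample(s)", stacklevel=2)
    return out


def compare_correlations_ztest(r1: float, n1: int, r2: float, n2: int) -> CorrelationTest:
    """Fisher z-test for the difference of two independent correlations.

    ``z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))`` with a
    two-sided normal p-value.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if n <= 3:
            raise ValueError("z-test requires n > 3 on both sides")
        if abs(r) >= 1:
            raise ValueError("z-test undefined for |r| = 1")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return CorrelationTest(z=float(z), p_value=float(p), r1=r1, r2=r2, n1=n1, n2=n2)


def evaluate(
    c_est: CompositionMatrix,
    c_true: CompositionMatrix,
    y_obs: ExpressionMatrix | None = None,
    x: ExpressionMatrix | None = None,
    rho_scale: str = "log1p",
) -> MetricsReport:
    """Full metric suite for one estimate; rho only when bulks are provided."""
    r_c = celltype_correlation(c_est, c_true)
    r_s = sample_correlation(c_est, c_true)
    r_combined, rmsd, mad = combined_metrics(c_est, c_true)
    rho = None
    if y_obs is not None and x is not None:
        xv = x.subset_columns([t for t in c_est.celltype_ids if t in set(x.column_ids)])
        ce = c_est.to_frame().loc[xv.column_ids]
        vals = bulk_reconstruction_rho(y_obs, xv, ce.to_numpy(), scale=rho_scale)
        rho = dict(zip(c_est.sample_ids, (float(v) for v in vals)))
    return MetricsReport(
        r_c=r_c, r_s=r_s, r_combined=r_combined, rmsd=rmsd, mad=mad, rho=rho,
        n_samples=c_est.n_samples,
        n_celltypes=len(c_est.drop_ui().celltype_ids),
    )
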
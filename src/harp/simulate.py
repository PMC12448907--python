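"""Synthetic data: single-cell-like profiles, pseudobulks, and distortions.

The generator emulates the structure that makes reference harmonization
necessary:

* labeled single-cell-like count profiles grouped by patient (negative
  binomial counts around cell-type mean profiles with marker genes, per-
  patient gene-wise log-normal heterogeneity, dropout);
* patient-wise pseudobulk mixtures — each artificial bulk sums cells drawn
  from a single patient, so the ground-truth composition is known by
  construction;
* gene-specific multiplicative batch noise on a fraction of genes, shared
  across all bulks (a platform/protocol effect);
* systematic (``delta``) and random composition distortions emulating
  cell-type-specific losses and measurement noise in experimental
  composition estimates.

All generators are pure functions of their seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .harmonize import normalize_columns
from .matrixio import CompositionMatrix, ExpressionMatrix

__all__ = [
    "CellTypeSpec",
    "SimulationSpec",
    "DistortionSpec",
    "PseudobulkSet",
    "BenchmarkScenario",
    "make_celltype_profiles",
    "simulate_single_cells",
    "build_pseudobulk",
    "perturb_genes",
    "distort_compositions",
    "make_benchmark_scenario",
    "normalize_cell_libraries",
    "celltype_mean_reference",
    "write_cells_mtx",
    "read_cells_mtx",
]


@dataclass
class CellTypeSpec:
    """Mean-profile settings for one simulated cell type."""

    name: str
    n_markers: int = 25
    marker_fold: float = 8.0
    mean_expression: tuple[float, float] = (5.0, 15.0)


def _default_celltypes() -> list[CellTypeSpec]:
    return [CellTypeSpec("B"), CellTypeSpec("T_CD8"), CellTypeSpec("T_reg")]


@dataclass
class SimulationSpec:
    """Parameters of the single-cell generator.

    ``patient_effect_sd`` is the log-scale standard deviation of gene-wise
    per-patient factors (patient heterogeneity); ``count_dispersion`` is the
    negative-binomial size parameter (smaller = more overdispersed);
    ``cells_per_patient_per_type`` bounds the uniform draw of how many cells
    each patient contributes per type.
    """

    n_genes: int = 500
    celltypes: list[CellTypeSpec] = field(default_factory=_default_celltypes)
    n_patients: int = 6
    cells_per_patient_per_type: tuple[int, int] = (30, 80)
    patient_effect_sd: float = 0.1
    dropout_rate: float = 0.1
    count_dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_patients <= 0:
            raise ValueError("counts must be positive")
        lo, hi = self.cells_per_patient_per_type
        if lo <= 0 or hi < lo:
            raise ValueError("invalid cells_per_patient_per_type range")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.patient_effect_sd < 0 or self.count_dispersion <= 0:
            raise ValueError("invalid noise parameters")


@dataclass
class DistortionSpec:
    """Systematic + random distortion of measured compositions.

    ``delta[l]`` multiplies cell type ``l``'s proportion in every sample
    (constant systematic bias, e.g. dissociation loss); ``noise_cv`` is the
    coefficient of variation of additional sample- and type-specific
    multiplicative noise.
    """

    delta: np.ndarray
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float).ravel()
        if np.any(self.delta <= 0):
            raise ValueError("delta factors must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass
class PseudobulkSet:
    """Artificial bulks with their designed ground-truth compositions."""

    y: ExpressionMatrix
    c_true: CompositionMatrix
    patient_of_sample: list[str]
    perturbed_genes: list[str] = field(default_factory=list)


@dataclass
class BenchmarkScenario:
    """A full train/test scenario with anchor reference and distorted C."""

    train: PseudobulkSet
    test: PseudobulkSet
    anchor: ExpressionMatrix
    c_train_measured: CompositionMatrix
    gene_factors: dict[str, float]
    params: dict
    cells: ExpressionMatrix | None = None
    cell_metadata: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Cell-type profiles and single cells
# ---------------------------------------------------------------------------

def make_celltype_profiles(spec: SimulationSpec,
                           rng: np.random.Generator) -> ExpressionMatrix:
    """Draw gene x cell-type mean expression profiles.

    A shared log-normal gene baseline is modulated per type by gene-wise
    log-normal factors plus an elevated block of disjoint marker genes, then
    each column is scaled to a mean expression drawn from the type's range.
    """
    g, q = spec.n_genes, len(spec.celltypes)
    total_markers = sum(ct.n_markers for ct in spec.celltypes)
    if total_markers > g:
        raise ValueError("more marker genes requested than genes available")
    base = rng.lognormal(mean=0.0, sigma=1.0, size=g)
    profiles = np.empty((g, q))
    marker_start = 0
    for j, ct in enumerate(spec.celltypes):
        factor = rng.lognormal(mean=0.0, sigma=0.4, size=g)
        col = base * factor
        col[marker_start:marker_start + ct.n_markers] *= ct.marker_fold
        marker_start += ct.n_markers
        target_mean = rng.uniform(*ct.mean_expression)
        profiles[:, j] = col * (target_mean / col.mean())
    gene_ids = [f"g{i:04d}" for i in range(g)]
    return ExpressionMatrix(profiles, gene_ids, [ct.name for ct in spec.celltypes])


def simulate_single_cells(
    spec: SimulationSpec,
    profiles: ExpressionMatrix | None = None,
    batch_factors: np.ndarray | None = None,
    patient_prefix: str = "P",
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate labeled single-cell count profiles grouped by patient.

    Per cell: negative-binomial counts around the cell type's mean profile,
    scaled by a gene-wise per-patient log-normal factor (mean one) and an
    optional gene-wise batch factor; entries are then zeroed with probability
    ``dropout_rate``.  Returns the cell matrix (genes x cells) and metadata
    with ``cell_type`` and ``patient`` per cell.
    """
    rng = np.random.default_rng(spec.seed)
    if profiles is None:
        profiles = make_celltype_profiles(spec, rng)
    means = profiles.values.copy()
    if batch_factors is not None:
        means = means * np.asarray(batch_factors, float).ravel()[:, None]
    g = means.shape[0]
    theta = spec.count_dispersion
    sd = spec.patient_effect_sd

    cols, types, patients = [], [], []
    for p in range(spec.n_patients):
        pid = f"{patient_prefix}{p + 1}"
        if sd > 0:
            pf = rng.lognormal(mean=-sd * sd / 2.0, sigma=sd, size=g)
        else:
            pf = np.ones(g)
        for j, ct in enumerate(spec.celltypes):
            n_cells = int(rng.integers(spec.cells_per_patient_per_type[0],
                                       spec.cells_per_patient_per_type[1] + 1))
            mu = np.maximum(means[:, j] * pf, 1e-12)
            pnb = theta / (theta + mu)
            counts = rng.negative_binomial(theta, pnb[:, None], size=(g, n_cells))
            counts = counts.astype(float)
            if spec.dropout_rate > 0:
                keep = rng.random(size=counts.shape) >= spec.dropout_rate
                counts *= keep
            cols.append(counts)
            types.extend([ct.name] * n_cells)
            patients.extend([pid] * n_cells)
    values = np.concatenate(cols, axis=1)
    cell_ids = [f"c{i:05d}" for i in range(values.shape[1])]
    meta = pd.DataFrame({"cell_id": cell_ids, "cell_type": types,
                         "patient": patients}).set_index("cell_id")
    return ExpressionMatrix(values, list(profiles.gene_ids), cell_ids), meta


def normalize_cell_libraries(cells: ExpressionMatrix,
                             target: float | None = None) -> ExpressionMatrix:
    """Scale each cell's profile to a common library size.

    Equalizes per-cell total counts (default target: the gene count), the
    standard single-cell normalization.  Without it, cell types with larger
    transcriptomes contribute more expression mass per cell, and pseudobulk
    deconvolution would recover mass fractions instead of the designed
    cell-count fractions.  All-zero cells are left untouched.
    """
    sums = cells.values.sum(axis=0)
    target = float(cells.n_genes) if target is None else float(target)
    factors = np.divide(target, sums, out=np.ones_like(sums), where=sums > 0)
    return ExpressionMatrix(cells.values * factors, list(cells.gene_ids),
                            list(cells.column_ids))


def celltype_mean_reference(cells: ExpressionMatrix, metadata: pd.DataFrame,
                            normalize: bool = True) -> ExpressionMatrix:
    """Per-type gene-wise mean profile over single cells (the anchor)."""
    types = list(pd.unique(metadata["cell_type"]))
    cols = []
    for t in types:
        ids = metadata.index[metadata["cell_type"] == t]
        sub = cells.subset_columns(list(ids))
        cols.append(sub.values.mean(axis=1))
    ref = ExpressionMatrix(np.column_stack(cols), list(cells.gene_ids), types)
    return normalize_columns(ref) if normalize else ref


# ---------------------------------------------------------------------------
# Pseudobulks
# ---------------------------------------------------------------------------

def build_pseudobulk(
    cells: ExpressionMatrix,
    metadata: pd.DataFrame,
    n_samples: int,
    perturb_sd: float = 0.3,
    seed: int = 0,
    sample_prefix: str = "s",
) -> PseudobulkSet:
    """Sum single-patient cell subsets into bulks with known compositions.

    Patients are visited round-robin in a seeded shuffled order.  For each
    sample and cell type, the patient's available cell count is perturbed by
    a normal factor (``max(0.05, N(1, perturb_sd))``) to set how many cells
    of that type are drawn without replacement; the bulk column is the sum of
    the selected cell profiles and the true composition is the selected-count
    fraction per type.
    """
    rng = np.random.default_rng(seed)
    patients = sorted(pd.unique(metadata["patient"]))
    order = list(rng.permutation(patients))
    celltypes = sorted(pd.unique(metadata["cell_type"]))
    col_of = {c: i for i, c in enumerate(cells.column_ids)}

    by_patient_type: dict[str, dict[str, np.ndarray]] = {}
    for pid in patients:
        sub = metadata[metadata["patient"] == pid]
        by_patient_type[pid] = {
            t: np.array([col_of[c] for c in sub.index[sub["cell_type"] == t]])
            for t in celltypes
        }
        if sum(len(v) > 0 for v in by_patient_type[pid].values()) < 2:
            warnings.warn(f"patient {pid!r} has cells of fewer than 2 types",
                          stacklevel=2)

    y = np.zeros((cells.n_genes, n_samples))
    c_true = np.zeros((len(celltypes), n_samples))
    patient_of_sample = []
    for m in range(n_samples):
        pid = order[m % len(order)]
        patient_of_sample.append(pid)
        chosen_counts = np.zeros(len(celltypes), dtype=int)
        chosen_cols: list[np.ndarray] = []
        for i, t in enumerate(celltypes):
            avail = by_patient_type[pid][t]
            if avail.size == 0:
                continue
            target = int(round(avail.size * max(0.05, rng.normal(1.0, perturb_sd))))
            target = min(max(target, 0), avail.size)
            if target == 0:
                continue
            sel = rng.choice(avail, size=target, replace=False)
            chosen_cols.append(sel)
            chosen_counts[i] = target
        total = chosen_counts.sum()
        if total == 0:  # degenerate draw: fall back to one cell of some type
            for i, t in enumerate(celltypes):
                avail = by_patient_type[pid][t]
                if avail.size:
                    chosen_cols.append(avail[:1])
                    chosen_counts[i] = 1
                    total = 1
                    break
        sel_all = np.concatenate(chosen_cols)
        y[:, m] = cells.values[:, sel_all].sum(axis=1)
        c_true[:, m] = chosen_counts / total
    sample_ids = [f"{sample_prefix}{m + 1}" for m in range(n_samples)]
    return PseudobulkSet(
        y=ExpressionMatrix(y, list(cells.gene_ids), sample_ids),
        c_true=CompositionMatrix(c_true, celltypes, sample_ids),
        patient_of_sample=patient_of_sample,
    )


# ---------------------------------------------------------------------------
# Distortions
# ---------------------------------------------------------------------------

def _truncated_normal_factors(rng: np.random.Generator, size, sd: float,
                              floor: float = 0.05) -> np.ndarray:
    return np.maximum(rng.normal(1.0, sd, size=size), floor)


def draw_gene_factors(gene_ids: list[str], fraction: float, factor_sd: float,
                      seed: int) -> dict[str, float]:
    """Pick ``floor(fraction * g)`` genes and one multiplicative factor each."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    g = len(gene_ids)
    n_sel = int(np.floor(fraction * g))
    sel = rng.choice(g, size=n_sel, replace=False)
    factors = _truncated_normal_factors(rng, n_sel, factor_sd)
    return {gene_ids[i]: float(f) for i, f in zip(sel, factors)}


def apply_gene_factors(y: ExpressionMatrix,
                       factors: dict[str, float]) -> ExpressionMatrix:
    """Multiply each listed gene's row by its factor, across all samples."""
    out = y.values.copy()
    idx = {g: i for i, g in enumerate(y.gene_ids)}
    for gene, f in factors.items():
        if gene in idx:
            out[idx[gene], :] *= f
    return ExpressionMatrix(out, list(y.gene_ids), list(y.column_ids))


def perturb_genes(y: ExpressionMatrix, fraction: float = 0.4,
                  factor_sd: float = 0.3, seed: int = 0
                  ) -> tuple[ExpressionMatrix, list[str]]:
    """Gene-specific multiplicative batch noise on a random gene subset.

    Each selected gene gets one factor drawn from ``N(1, factor_sd)``
    (truncated at 0.05) applied to its whole row — i.e. the same distortion
    in every bulk sample, mimicking a platform effect.  Unselected rows are
    bit-identical to the input.
    """
    factors = draw_gene_factors(list(y.gene_ids), fraction, factor_sd, seed)
    return apply_gene_factors(y, factors), sorted(factors)


def distort_compositions(c_true: CompositionMatrix,
                         spec: DistortionSpec) -> CompositionMatrix:
    """Multiply true proportions by ``delta[l]`` and per-entry random noise.

    Columns are deliberately NOT renormalized: the distorted matrix emulates
    raw experimental composition measurements whose systematic scale errors
    the harmonization's alpha mechanism is meant to absorb.
    """
    if spec.delta.size != c_true.shape[0]:
        raise ValueError("delta length must equal the number of cell types")
    rng = np.random.default_rng(spec.seed)
    vals = c_true.values * spec.delta[:, None]
    if spec.noise_cv > 0:
        vals = vals * _truncated_normal_factors(rng, c_true.shape, spec.noise_cv)
    return CompositionMatrix(vals, list(c_true.celltype_ids),
                             list(c_true.sample_ids), c_true.is_extended)


# ---------------------------------------------------------------------------
# Full benchmark scenario
# ---------------------------------------------------------------------------

def write_cells_mtx(cells: ExpressionMatrix, metadata: pd.DataFrame,
                    out_dir) -> None:
    """Write single cells as MatrixMarket + id files + metadata TSV."""
    from pathlib import Path

    import scipy.io
    import scipy.sparse

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "cells.mtx"),
                     scipy.sparse.csc_matrix(cells.values))
    (out / "genes.txt").write_text("\n".join(cells.gene_ids) + "\n")
    (out / "barcodes.txt").write_text("\n".join(cells.column_ids) + "\n")
    metadata.to_csv(out / "cell_metadata.tsv", sep="\t")


def read_cells_mtx(in_dir) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Read single cells written by :func:`write_cells_mtx`."""
    from pathlib import Path

    import scipy.io

    src = Path(in_dir)
    values = np.asarray(scipy.io.mmread(str(src / "cells.mtx")).todense())
    genes = (src / "genes.txt").read_text().splitlines()
    barcodes = (src / "barcodes.txt").read_text().splitlines()
    meta = pd.read_csv(src / "cell_metadata.tsv", sep="\t", index_col=0)
    return ExpressionMatrix(values, genes, barcodes), meta


def make_benchmark_scenario(
    spec: SimulationSpec | None = None,
    distortion: DistortionSpec | None = None,
    n_train: int = 20,
    n_test: int = 40,
    seed: int = 0,
    batch_lognorm_sd: float = 0.3,
    gene_perturb_fraction: float = 0.4,
    gene_perturb_sd: float = 0.3,
    perturb_sd: float = 0.3,
    keep_cells: bool = False,
) -> BenchmarkScenario:
    """Simulate a complete inconsistent train/test deconvolution scenario.

    Two cell populations share the same underlying cell-type profiles but
    differ by gene-wise log-normal batch factors and disjoint patient sets:
    one provides the anchor reference (per-type mean profile, column
    normalized), the other provides training and test pseudobulks from
    disjoint patient halves.  A shared gene-perturbation map (``fraction`` of
    genes, factors ``N(1, sd)``) is applied to all bulks, and the measured
    training compositions are optionally distorted.
    """
    if spec is None:
        spec = SimulationSpec()
    ss = np.random.SeedSequence(seed)
    s_anchor, s_bulk, s_batch, s_tr, s_te, s_genes, s_dist = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(7))

    rng_profiles = np.random.default_rng(int(ss.generate_state(1)[0] % (2**31)))
    profiles = make_celltype_profiles(spec, rng_profiles)

    # anchor population: its own patients, no batch offset
    anchor_spec = SimulationSpec(**{**spec.__dict__, "seed": s_anchor})
    cells_a, meta_a = simulate_single_cells(anchor_spec, profiles=profiles,
                                            patient_prefix="A")
    cells_a = normalize_cell_libraries(cells_a)
    anchor = celltype_mean_reference(cells_a, meta_a, normalize=True)

    # bulk population: disjoint patients, gene-wise batch offset
    batch = np.random.default_rng(s_batch).lognormal(
        mean=-batch_lognorm_sd**2 / 2.0, sigma=batch_lognorm_sd,
        size=spec.n_genes) if batch_lognorm_sd > 0 else None
    bulk_spec = SimulationSpec(**{**spec.__dict__, "seed": s_bulk,
                                  "n_patients": 2 * spec.n_patients})
    cells_b, meta_b = simulate_single_cells(bulk_spec, profiles=profiles,
                                            batch_factors=batch,
                                            patient_prefix="B")
    cells_b = normalize_cell_libraries(cells_b)
    patients = sorted(pd.unique(meta_b["patient"]))
    train_pat = set(patients[: spec.n_patients])
    meta_tr = meta_b[meta_b["patient"].isin(train_pat)]
    meta_te = meta_b[~meta_b["patient"].isin(train_pat)]
    train = build_pseudobulk(cells_b.subset_columns(list(meta_tr.index)), meta_tr,
                             n_train, perturb_sd=perturb_sd, seed=s_tr,
                             sample_prefix="tr")
    test = build_pseudobulk(cells_b.subset_columns(list(meta_te.index)), meta_te,
                            n_test, perturb_sd=perturb_sd, seed=s_te,
                            sample_prefix="te")

    gene_factors = draw_gene_factors(list(train.y.gene_ids),
                                     gene_perturb_fraction, gene_perturb_sd,
                                     s_genes)
    train.y = apply_gene_factors(train.y, gene_factors)
    test.y = apply_gene_factors(test.y, gene_factors)
    train.perturbed_genes = sorted(gene_factors)
    test.perturbed_genes = sorted(gene_factors)

    if distortion is not None:
        dist = DistortionSpec(delta=distortion.delta,
                              noise_cv=distortion.noise_cv, seed=s_dist)
        c_measured = distort_compositions(train.c_true, dist)
    else:
        c_measured = train.c_true.copy()

    params = {
        "seed": seed, "n_train": n_train, "n_test": n_test,
        "n_genes": spec.n_genes,
        "celltypes": [ct.name for ct in spec.celltypes],
        "n_patients_per_half": spec.n_patients,
        "batch_lognorm_sd": batch_lognorm_sd,
        "gene_perturb_fraction": gene_perturb_fraction,
        "gene_perturb_sd": gene_perturb_sd,
        "perturb_sd": perturb_sd,
        "delta": None if distortion is None else distortion.delta.tolist(),
        "noise_cv": 0.0 if distortion is None else distortion.noise_cv,
    }
    return BenchmarkScenario(train=train, test=test, anchor=anchor,
                             c_train_measured=c_measured,
                             gene_factors=gene_factors, params=params,
                             cells=cells_b if keep_cells else None,
                             cell_metadata=meta_b if keep_cells else None)
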
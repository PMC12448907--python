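# harp — reference harmonization for bulk tissue deconvolution

Bulk tissue deconvolution estimates the cell-type composition of a bulk
expression profile from per-cell-type reference profiles via the mixing
model `Y ≈ X C`.  When the bulks, the reference and experimentally measured
compositions come from different platforms or cohorts, they are mutually
inconsistent — reference profiles carry batch effects relative to the
bulks, and measured compositions (flow cytometry, scRNA-seq) carry
systematic cell-type-specific losses — and plain reference-based
deconvolution degrades badly.

This package harmonizes the three data sources.  Given a training set with
bulk expression `Y` (genes × samples), an anchor reference `X*`
(genes × cell types) and measured compositions `C` (cell types × samples),
Training mode minimizes by alternation

    L(φ, α) = ‖Y − φ diag(α) C*‖²_F + λ Σ_ij [softplus(φ − x*)_ij + softplus(x* − φ)_ij]

over a non-negative adjusted reference `φ` (columns normalized to sum to
the gene count) and a non-negative per-cell-type scaling vector `α` that
corrects systematic bias in the measured compositions.  `C*` optionally
extends `C` by a residual "UI" row for unidentified cell mass, and the
anchor penalty — a smooth, symmetric L1-like distance — keeps the
harmonized reference `X'` biologically close to the measured one.  The
regularization strength `λ` is chosen by seeded cross-validation on
held-out reconstruction R².  Deconvolution mode then applies `X'` to new
bulks by per-sample non-negative least squares, optionally with learned
per-gene weights (a minimal digital-tissue-deconvolution-style backend).

The package is aimed at computational biologists who have paired bulk +
composition training data from one cohort and want to deconvolve further
bulks from comparable tissue, as well as at method developers who need a
controlled simulation test-bed: the built-in generator produces labeled
single-cell-like profiles with patient structure, patient-wise pseudobulks
with known ground truth, gene-level batch noise and composition
distortions.

## Worked example

```python
import numpy as np
from harp import HarpModel, DistortionSpec, SimulationSpec, make_benchmark_scenario

# synthetic study: anchor from one population, bulks from another (batch
# offset + 40% of genes perturbed), measured compositions distorted by
# delta = (0.5, 1, 2) per cell type
scen = make_benchmark_scenario(
    SimulationSpec(seed=0),
    distortion=DistortionSpec(delta=np.array([0.5, 1.0, 2.0])),
    seed=1)

model = HarpModel(scen.train.y, scen.anchor, scen.c_train_measured,
                  complete_reference=True)
res = model.fit(seed=1)          # lambda by 5-fold CV over {0} U {2^0..2^15}
print(res.summary())
```

```
Harmonization Results
======================================================
genes:            500
cell types:       3
training samples: 20
lambda:           1  (cross-validated)
iterations:       11
final loss:       2668.12
anchor shift:     0.3221 (mean |X' - X*|)
------------------------------------------------------
cell type                 alpha
B                        2.0579
T_CD8                    0.9910
T_reg                    0.4969
======================================================
```

The fitted `α ≈ (2.06, 0.99, 0.50)` inverts the simulated measurement distortion
`δ = (0.5, 1, 2)` — the method has recovered that B cells were
under-counted two-fold and regulatory T cells over-counted two-fold — and
`anchor shift` summarizes how far the harmonized reference moved to absorb
the batch offset.  Deconvolving the 40 held-out test bulks:

```python
from harp.metrics import combined_metrics
dec = res.deconvolve(scen.test.y)
R, rmsd, mad = combined_metrics(dec.c_hat, scen.test.c_true)
print(f"R = {R:.3f}, RMSD = {rmsd:.3f}, mAD = {mad:.3f}")
```

```
R = 0.917, RMSD = 0.034, mAD = 0.028
```

`R` is the overall Pearson correlation between estimated and true fractions
over all test entries; RMSD/mAD are absolute errors on the fraction scale.

The same pipeline is available from the shell:

```bash
harp simulate --out sim/ --seed 17 --delta 0.5,1,2
harp train --bulk sim/Y_train.tsv --reference sim/X_anchor.tsv \
           --composition sim/C_measured_train.tsv --complete-reference \
           --seed 17 --out fit/
harp deconvolve --bulk sim/Y_test.tsv --model fit/ --out chat.tsv
harp evaluate --estimated chat.tsv --truth sim/C_true_test.tsv --out report.json
```

See `docs/methods.md` for the model, the cross-validation score, the
generator's assumptions and known limitations.

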
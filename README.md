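# plscore

Physics-based protein–ligand interaction descriptors, empirical scoring
models and virtual-screening evaluation metrics.

The package computes six intermolecular terms on a parameterized
receptor–ligand complex — buffered Coulomb electrostatics with sigmoidal
distance-dependent dielectrics (Hingerty or Ramstein–Lavery), buffered 14-7
van der Waals, piecewise-linear lipophilic contacts, a buried-charge polar
solvation count, a surface-area-based nonpolar solvation energy, and a
frozen-rotatable-bond torsional entropy count — and combines them through
published multiple-linear-regression coefficient sets or retrainable
SVR/random-forest models. Screening runs are evaluated with Pearson R,
RMSE, ROC AUC, enrichment factors and BEDROC.

## Layout

| module | contents |
|---|---|
| `plscore.structure` | molecular data model, PDB/SDF/MOL2 I/O (RDKit-backed), MMFF94S or builtin parameterization, rotatable-bond detection, affinity→energy conversion |
| `plscore.surface` | deterministic Shrake–Rupley solvent-accessible surface areas and ΔSAS |
| `plscore.descriptors` | the six interaction terms, the merged `oneSolv` variant and the descriptor vector |
| `plscore.models` | shipped coefficient sets (`general-random`, `general-all`, `protease`, `ippi`, `ippi-onesolv`), MLR/SVR/RF training, ten-fold CV, one-term-at-a-time ablation |
| `plscore.metrics` | Pearson R, RMSE, ROC AUC, (fractional) enrichment factor + its theoretical maximum, BEDROC |
| `plscore.fixtures` | synthetic toy complexes with analytic ground truth, feature tables, screening score sets |

Notes on deliberate substitutions: SAS uses a fixed golden-spiral
Shrake–Rupley lattice (960 points/atom, 1.4 Å probe) rather than a
molecular-surface program; cross-pair vdW well parameters are combined from
homonuclear values (arithmetic R*, geometric ε). Downstream terms consume
SAS only through a linear map and thresholded ratios, so both substitutions
are benign but documented here. The "buried" criterion of the polar term
(bound SAS ≤ 10 % of free) and the Bondi radii feeding `d_vdW` are
configurable via `TermConfig`.

## CLI

All commands live under a single `plscore` entry point:

```sh
# descriptor vector for one complex (CSV columns E_coul, E_vdW, E_lipo,
# E_entropy, E_polar_solv, E_np_solv — or oneSolv)
plscore descriptors --receptor rec.pdb --ligand lig.sdf --out desc.csv

# score with a shipped linear model
plscore score --receptor rec.pdb --ligand lig.sdf --model general-random --out pred.csv

# train on a feature table (columns: complex_id, term columns, dG_exp)
plscore train --features table.csv --algo rf --cv 10 --seed 17 --out model/

# screening metrics from a score table (columns: id, score, label)
plscore screen-eval --scores scores.csv --ef 0.01 --bedroc 20,100 --out metrics.json

# synthetic data
plscore fixtures make-complex --seed 7 --out dir/
plscore fixtures make-table --model protease --n 500 --out table.csv
plscore fixtures make-screening --n-active 100 --n-inactive 5000 --out scores.csv
```

Scores follow the lower-is-better convention (predicted binding free
energies); pass `--higher-is-better` to `screen-eval` to invert.

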
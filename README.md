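# cytotraject

Trajectory inference for **longitudinal mass cytometry** (CyTOF) of immune
reconstitution after allogeneic stem-cell transplantation.

After a transplant, an entire immune system regenerates from donor stem
cells over months. Blood samples drawn at a handful of visits (here 1, 2,
3, 6 and 12 months) are discrete snapshots of a continuous differentiation
process. `cytotraject` reconstructs that continuum from ~40-marker
single-cell data: it classifies the principal immune populations from all
markers jointly, converts their frequencies into absolute blood
concentrations using clinical labs, builds a diffusion map per patient and
population with all time-points merged, identifies the diffusion
components that correlate with time as **pseudo-time axes**, and extracts
continuous marker-expression profiles along them.

The package is aimed at computational immunologists who have per-sample
cell event tables (FCS or CSV) plus clinical white-cell counts, and at
method developers who need a fully synthetic longitudinal cohort with
known ground truth.

## The method

For one patient and one population, cells from all time-points are merged
into a single matrix of arcsinh-transformed intensities
(`asinh(x / c)`, cofactor `c = 5`). A diffusion map is built from first
principles:

1. **kNN Gaussian kernel** — `K_ij = exp(-d_ij² / 2σ²)` on a
   union-symmetrized k-nearest-neighbour graph (default `k = 100`), with a
   global bandwidth `σ` set to the median distance to the 15th neighbour.
2. **Anisotropic normalization** — `W_ij = K_ij / (q_i q_j)` with
   `q_i = Σ_j K_ij` (the `α = 1` construction), which removes sampling-
   density effects so unequal cell numbers per time-point cannot distort
   the geometry.
3. **Markov operator and spectrum** — `P = D⁻¹W` is diagonalized through
   its symmetric conjugate `S = D^{1/2} P D^{-1/2}`; eigenvectors map back
   as `ψ = D^{-1/2} v`. The trivial constant eigenvector (eigenvalue 1) is
   verified and excluded; the remaining **diffusion components**
   DC1…DCm are the candidate axes.
4. **Pseudo-time selection** — each DC is Spearman-correlated with months
   post-transplant (rank correlation is robust to the uneven 1/2/3/6/12
   spacing); the top |ρ| components are oriented so pseudo-time increases
   with months, and sliding-window medians of every marker are computed
   along them. Branching is reported descriptively via a bimodality
   coefficient of DC coordinates among late-pseudo-time cells.

Classification mirrors the ACCENSE-style workflow: a 2-D embedding (tSNE,
or deterministic 2-component PCA), kernel density estimation on a grid,
strict 8-neighbour density peaks, steepest-ascent basin assignment, and
cluster→population mapping by marker-median rules (T = CD3⁺CD19⁻,
B = CD19⁺CD3⁻, NK = CD56⁺CD3⁻, monocytes = CD14⁺CD3⁻,
basophils = CD123⁺CCR3⁺CD3⁻). Absolute counts use the clinical
mononuclear pool: `count(P) = frequency(P) × (WBC − neutrophils)`, in
10⁷ cells/L.

The `synthetic_data` module generates full cohorts with known latent
maturation `s ∈ [0,1]` per cell (Beta-distributed per time-point, mean
advancing with months), logistic marker responses, a branched B-cell
configuration, NK phenotypic convergence, and realistic clinical count
kinetics — giving every other module a ground-truth test surface.

## Worked example

```python
from cytotraject import (default_sim_config, simulate_cohort,
                         run_patient_trajectory, DiffusionParams)

cfg = default_sim_config(n_patients=1, cells_per_sample=1000, seed=0)
tables, metas, truth = simulate_cohort(cfg)           # 5 samples, months 1..12
patient_tables = [tables[k] for k in sorted(tables)]

run = run_patient_trajectory(patient_tables, "NK",
                             params=DiffusionParams(seed=0))
print(run.report["n_cells_merged"])     # 936
print(run.report["top_dcs"])            # [1, 6, 4]
print(run.report["pseudotime_dc"])      # 1
```

Here the NK cells of one synthetic patient (936 cells across the five
visits) yield DC1 as the dominant time-correlated axis (Spearman ρ = 0.73
with months; the runner-up DCs are near 0.06, i.e. noise). Marker trends
along the oriented DC1 (`cytotraject.marker_trend`, disjoint-window bin
medians vs. bin index) recover the generator's biology:

```
CD57  +0.984     CD16  +0.981      # rising with maturation
CD56  -0.926     CD27  -0.978      # falling
2B4   -0.210                       # flat (null trend)
```

i.e. the classic maturation signature of NK cells — CD57/CD16 up,
CD56/CD27 down, 2B4 stable — read out as a continuum from five discrete
snapshots. The same machinery is available from the shell:

```bash
cytotraject simulate --config sim.yaml --out cohort/
cytotraject classify --in cohort/P01_t1.csv --out labeled/P01_t1.csv --seed 7
cytotraject counts --events 'labeled/P01_t*.csv' --meta cohort/clinical.csv --out counts.csv
cytotraject trajectory --patient P01 --population NK --events labeled/ --out traj/
cytotraject run-all --out results/        # simulate -> classify -> counts -> trajectories
```

## Layout

```
src/cytotraject/
  io_cytometry.py    event tables, FCS/CSV I/O, arcsinh transform, merging
  classify.py        embedding, KDE density peaks, population rules, gating
  counts.py          frequencies and absolute counts
  diffusion.py       kNN kernel, anisotropic Markov operator, spectrum
  trajectory.py      DC/time ranking, pseudo-time, marker profiles, plots
  synthetic_data.py  ground-truth cohort generator
  pipeline.py, cli.py  orchestration and the `cytotraject` command
docs/methods.md      modelling assumptions, parameter choices, limitations
```
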
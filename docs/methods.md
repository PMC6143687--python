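# Methods

This note documents the models, parameter choices and limitations behind
`cytotraject`. It covers (1) the diffusion-map pseudo-time machinery,
(2) the population-classification procedure, (3) absolute-count
arithmetic, (4) the synthetic cohort generator and what it does and does
not emulate, and (5) numerical conventions and known limitations.

## 1. Diffusion maps and pseudo-time

**Model.** Cells of one population from one patient, pooled over all
visits, are treated as samples from a low-dimensional differentiation
manifold embedded in marker space (arcsinh scale). The random-walk
(diffusion-map) construction recovers the manifold's intrinsic
coordinates as eigenvectors of a Markov transition operator; components
whose coordinate correlates with calendar time are interpreted as
pseudo-time axes of the underlying maturation process.

**Construction.** Euclidean distances over all analysis markers feed a
k-nearest-neighbour graph symmetrized by union (if *i* lists *j*, *j*
lists *i*). The Gaussian kernel `K_ij = exp(-d_ij²/2σ²)` is truncated
outside the graph, which keeps the eigenproblem sparse and scalable to
~10⁵ cells. Density normalization uses the anisotropic exponent `α = 1`:
`W_ij = K_ij/(q_i q_j)` with `q_i = Σ_j K_ij`. This choice matters here
because cell numbers differ strongly between time-points — with `α = 1`
the operator estimates manifold geometry rather than sampling density, so
an over-represented visit cannot masquerade as dense structure. The
transition matrix `P = D⁻¹W` is diagonalized via the symmetric conjugate
`S = D^{1/2} P D^{-1/2}` (same spectrum; stable symmetric solvers apply),
and eigenvectors are mapped back as `ψ = D^{-1/2} v`.

**Parameters.**

| parameter | default | rationale |
|---|---|---|
| `k_neighbors` | min(n−1, 100) | dense enough for connectivity at n ~ 10³–10⁴, sparse enough for ARPACK |
| `sigma` | median distance to the 15th neighbour | a single global bandwidth, deterministic and scale-equivariant; a local per-cell bandwidth is a known refinement left as an extension hook |
| `alpha` | 1.0 | density-free geometry (see above); 0 recovers the classical graph walk |
| `zero_diagonal` | true | no self-transitions, the convention of destiny-style implementations |
| `n_components` | 20 | enough to let time-correlated structure appear beyond DC1 |

**Conventions.** The leading eigenvalue must equal 1 within 1e-10 and its
eigenvector must be constant (coefficient of variation < 1e-6); it is
verified and excluded, so DC1 is the first *non-trivial* component
(1-based). If the unit eigenvalue is numerically degenerate (a
disconnected graph), the eigenspace basis is rotated so the constant
vector can be identified before the check. Components are returned with
unit Euclidean norm; eigenvalue scaling of coordinates is intentionally
off by default since rank-based statistics downstream are scale-free.
Eigenvector sign is mathematically arbitrary: a fixed convention (largest
|entry| positive) makes runs reproducible, and all cross-run comparisons
align signs by correlation first.

**Pseudo-time selection and orientation.** Every DC is Spearman-correlated
with months post-transplant; rank correlation is used because the visit
schedule (1, 2, 3, 6, 12 months) is uneven and the drift need not be
linear in time. The full ranking is reported so a user can still choose
axes by eye; the top three are profiled by default. The chosen axis is
flipped, if necessary, so pseudo-time increases with months. Cells of all
visits are pooled before the map is computed, with an equal per-time-point
subsample cap (default 2000, fixed seed) so abundance kinetics cannot
dominate the kernel density structure.

**Marker profiles.** Cells are sorted by the oriented coordinate and a
sliding window (10% of cells, advanced by 1%) yields per-window medians of
every marker — smooth curves suitable for plots. For *trend statistics*
the package uses `marker_trend`, which bins into 100 **disjoint** windows
instead: overlapping windows share ~90% of their cells, so their medians
are strongly autocorrelated and the rank correlation of a truly flat
marker against bin index has a null standard deviation of ~1/3 —
unusable as a flatness test. With 100 independent medians the null SD is
~0.1, so |ρ| ≤ 0.3 is a meaningful flatness bound while monotone markers
still reach ρ ≈ 1.

**Branching.** No formal branch assignment is attempted. Branching is
reported descriptively: for each profiled DC, the sample-size-corrected
bimodality coefficient `(g₁² + 1)/(g₂ + 3(n−1)²/((n−2)(n−3)))` of the DC
coordinate among the latest 25% of pseudo-time cells; values above 0.555
(the uniform-distribution reference) suggest two late modes, i.e. a fork.

## 2. Classification

The classifier formalizes an interactive embedding-plus-density-clusters
workflow as a deterministic algorithm: 2-D embedding (tSNE via
scikit-learn with fixed seed and PCA initialization, or an in-repo
2-component PCA for an exactly deterministic test path), Gaussian KDE on a
128×128 grid with per-axis Silverman bandwidth `h = σ̂ n^{-1/6}` (grid
extended 3h beyond the data, renormalized to integrate to 1), strict
8-neighbour local maxima at ≥ 5% of the global density maximum as peaks,
and steepest-ascent hill-climbing from each cell's bin to a peak. Bins
whose ascent terminates at a sub-prominence maximum join the nearest peak
(ties to the denser one); zero-density bins are unassigned (−1).

Clusters map to populations by marker-median rules: a cluster is
population P when each required-high marker median exceeds the cohort-wide
60th percentile of that marker and each required-low median falls below
the 40th; unmatched or multiply-matched clusters become "other". The
percentiles are computed over whatever event table is passed in, and the
pipeline deliberately pools a patient's samples before labeling: a
percentile cutoff is only meaningful when the positive population is a
substantial fraction of the reference. Concretely, if a marker is
expressed on a fraction p of cells, the 40th percentile sits at quantile
0.4/(1−p) of the negative distribution — for p < 0.2 that is *below* the
negative median, and no negative cluster could ever pass a required-low
test on a sample where the positive population is rare. Pooling across
visits stabilizes p; the 60/40 defaults are configurable.

The threshold gate is the deterministic fallback: per-cell, first rule
(in rule order) whose high/low cutpoints are all satisfied. It needs
explicit per-marker cutpoints and is exact when populations are separable
marker-by-marker, whereas the density-peak path uses all markers jointly
and needs no cutpoints.

## 3. Absolute counts

Frequencies are computed over labeled cells only ("unassigned" cells are
analysis failures, not a biological compartment, and are excluded from
numerator and denominator). Absolute concentration is
`frequency × (WBC − neutrophils)` in 10⁷ cells/L. WBC minus neutrophils
approximates the mononuclear pool; eosinophils and other granulocytes are
not subtracted because only total WBC and neutrophil counts are assumed
available from the clinical laboratory — the approximation is declared
rather than hidden. Conservation (population counts summing to the pool)
holds by construction and is asserted in tests to 1e-9.

## 4. The synthetic cohort generator

**What it emulates.** A transplantation-recovery cohort: configurable
number of patients (default 3 for test economy; the design scales to a
26-patient cohort unchanged), five visits at 1/2/3/6/12 months, five
populations on a 37-marker surface panel. Each population carries a latent
maturation coordinate `s ∈ [0,1]`; at visit *t* cells draw
`s ~ Beta(a_t, b_t)` with means (0.15, 0.30, 0.45, 0.65, 0.85) at
concentration 8, so consecutive visits overlap and the pooled cells cover
the continuum — snapshots are cross-sectional, cells are not aged
individually, matching how a real cohort samples a process. Marker means
are logistic in `s` (steepness 10): increasing, decreasing (mirrored) or
constant; Gaussian noise (SD 0.25 by default) is added on the arcsinh
scale and values are clipped at 0. A raw-emission mode back-transforms
through `sinh` to exercise the transform path.

**Wired-in biology.** NK cells: CD57/CD16 increasing, CD56/CD27
decreasing, 2B4/CD45 constant, with noise SD shrinking linearly in `s`
(factor 1 + (1−s)) to model a heterogeneous early pool converging to a
focused late phenotype. B cells: a trunk (CD38/CD44/CD22 up, CD24 down)
that bifurcates at `s* = 0.5` with weight 0.5; branch-B cells diverge
strongly (CD27 up by 2.5, IgD down) while branch A continues the trunk —
the asymmetry keeps the branch-separating diffusion component weakly
time-correlated so it surfaces among the top-ranked DCs. Basophils:
CCR3/CD123/CD38/CD44 increasing. Monocytes: phenotypically stable
(Beta(2,2) at every visit, constant markers).

**Composition and counts.** Per-visit population fractions follow
abundance kinetics (slow-rise for T and B: weights 0.2→1.0; early-plateau
for NK and monocytes: 0.8 then 1.0; stable for basophils) applied to base
proportions (T 0.56, B 0.53, NK 0.177, monocytes 0.135, basophils 0.08,
normalized per visit). The adaptive populations are deliberately large in
the pooled cohort (~31% T, ~29% B): percentile-based labeling rules are
only well-posed when their reference markers are expressed on >~25% of
cells (see §2), and a marked late B-cell expansion is a documented feature
of post-transplant reconstitution. Clinical labs per patient: neutrophils
recover early (350·(1 − 0.6·e^{−t/1.5})), the mononuclear pool slowly
(80 + 220·(1 − e^{−t/4})), both in 10⁷ cells/L with patient-level (10%)
and visit-level (5%) lognormal factors; WBC = pool + neutrophils, so
WBC ≥ neutrophils structurally. Cell counts per population are
deterministic (largest-remainder rounding of fractions), so composition
kinetics are exactly reproducible.

**What it does not emulate.** Instrument artifacts (doublets, bead
events, acquisition drift, spillover), batch effects, inter-patient
biological random effects beyond seed variation, rare subsets, and any
deviation from logistic/constant marker responses. Passing tests on this
generator therefore demonstrate that the algorithms recover known
continuum structure under realistic noise and composition — not that they
are robust to every artifact of real acquisitions.

**Reproducibility.** The entire cohort is a pure function of the
configuration, seed included; per-patient/population/visit generator
streams are derived from fixed key tuples so outputs are independent of
iteration order.

## 5. Numerical choices, degenerate inputs, limitations

* kNN self-matches are located explicitly per row (with duplicate points
  the self entry need not sort first); duplicate cells yield legitimate
  zero-distance edges with kernel weight 1.
* `σ = 0` (all points coincident), zero-variance embeddings, isolated
  cells (all-zero kernel rows), constant DCs (Spearman undefined → ρ = 0,
  ranked last) and sub-minimum cell counts all raise typed errors rather
  than propagating NaNs.
* Transition row sums are 1 within 1e-12; the sparse pipeline matches a
  dense reference implementation to 1e-8 on full graphs (kept in the test
  suite as an independent oracle).
* Bit-level determinism: fixed ARPACK start vector, fixed sign
  convention, seeded subsampling and tSNE, and JSON/CSV writers with
  stable ordering — two identical runs produce identical artifact
  checksums.
* Problem sizes in the test and acceptance suites (2000 cells per
  time-point per population for pseudo-time recovery; 1000 cells/sample
  for classification; n ≤ 300 for oracle comparisons) were chosen as the
  smallest sizes at which the statistical properties under test are
  stable; the algorithms themselves scale well beyond.
* Known limitations: no diffusion-pseudotime (DPT) distances or root-cell
  selection; no out-of-sample extension; no formal branch assignment; no
  cross-patient trajectory alignment or statistical comparison between
  patients — the per-patient ranking and profiles are descriptive.
  The DC *indices* reported for real cohorts elsewhere depend on
  implementation details (bandwidths, normalization, eigenvector
  ordering); this package claims recovery of the underlying continuum
  structure, not reproduction of any specific historical index numbering.
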
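"""Synthetic longitudinal cytometry cohorts with known ground truth.

Emulates a transplantation-recovery study: a handful of patients sampled at
1, 2, 3, 6 and 12 months, each sample a mixture of the five principal PBMC
populations (T, B, NK, monocyte, basophil) measured on a 37-marker panel.

Each population carries a latent maturation coordinate ``s in [0, 1]``.
Samples are cross-sectional snapshots: at time-point ``t`` cells draw
``s ~ Beta(a_t, b_t)`` with the Beta mean advancing over time for maturing
populations (cells are not aged individually). Marker means follow
logistic responses in ``s`` (increasing, decreasing or constant) and cells
add Gaussian noise on the arcsinh scale. The defaults wire in the
qualitative biology the package is meant to recover:

* NK cells: CD57 and CD16 rise, CD56 and CD27 fall, 2B4 and CD45 stay
  flat; early cells are noisier than late ones (phenotypic convergence).
* B cells: branched maturation — beyond ``s* = 0.5`` half the cells
  diverge (CD27 up, IgD down) from the trunk.
* Basophils: CCR3, CD123, CD38 and CD44 increase continuously.
* Abundance kinetics: innate populations (NK, monocytes) near-plateau
  early, adaptive ones (T, B) rise slowly; basophils stay stable.
* Clinical labs: neutrophils recover before the mononuclear pool; WBC >=
  neutrophils always.

Every cohort is a pure function of its :class:`SimConfig` (seed included),
and the emitted tables are valid inputs to every other module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_cytometry import (
    DEFAULT_COFACTOR,
    EventTable,
    MarkerPanel,
    SampleMeta,
    make_annotations,
)

DEFAULT_TIMEPOINTS = (1.0, 2.0, 3.0, 6.0, 12.0)

#: the 37-antibody surface panel the generator emulates
DEFAULT_MARKERS = (
    "CD3", "CD4", "CD8", "CD19", "CD20", "CD22", "CD24", "CD27", "CD28",
    "CD33", "CD38", "CD44", "CD45", "CD45RA", "CD56", "CD57", "CD16",
    "CD14", "CD123", "CCR3", "CCR7", "CD127", "CD25", "CD161", "CD7",
    "CD11b", "CD11c", "HLA-DR", "IgD", "CD85j", "2B4", "NKG2D", "CD34",
    "PD-1", "CD95", "Ki-67", "TCRgd",
)

BASELINE_LEVEL = 0.3
BASELINE_NOISE_SD = 0.25
LOGISTIC_STEEPNESS = 10.0


@dataclass(frozen=True)
class MarkerSpec:
    """Mean response of one marker to latent maturation ``s``.

    ``increasing``: base -> base + amplitude (logistic in s);
    ``decreasing``: base + amplitude -> base (mirrored logistic);
    ``constant``: base everywhere.
    """

    shape: str = "constant"
    base: float = BASELINE_LEVEL
    amplitude: float = 0.0
    noise_sd: float = BASELINE_NOISE_SD

    def __post_init__(self):
        if self.shape not in ("increasing", "decreasing", "constant"):
            raise ValueError(f"unknown response shape {self.shape!r}")
        if not self.noise_sd > 0:
            raise ValueError("noise SD must be positive")


@dataclass(frozen=True)
class BranchSpec:
    """Optional bifurcation beyond ``branch_point``.

    Cells with ``s > branch_point`` join branch B with probability
    ``weight`` (else branch A, which keeps the trunk responses); branch-B
    ``markers`` override the trunk spec, evaluated on the rescaled
    coordinate ``u = (s - s*) / (1 - s*)`` so responses are continuous at
    the branch point.
    """

    branch_point: float = 0.5
    weight: float = 0.5
    markers: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 < self.branch_point < 1.0:
            raise ValueError("branch_point must lie in (0, 1)")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("branch weight must lie in [0, 1]")


@dataclass(frozen=True)
class PopulationSpec:
    """One population: abundance kinetics, maturation drift, responses."""

    name: str
    kinetics: str                       # early-plateau | slow-rise | stable
    base_proportion: float
    beta_params: tuple                  # per-time-point (a_t, b_t)
    markers: dict = field(default_factory=dict)   # marker -> MarkerSpec
    branch: BranchSpec | None = None
    noise_convergence: float = 0.0      # noise SD factor 1 + c*(1-s)

    def __post_init__(self):
        if self.kinetics not in ("early-plateau", "slow-rise", "stable"):
            raise ValueError(f"unknown kinetics {self.kinetics!r}")
        for a, b in self.beta_params:
            if not (a > 0 and b > 0):
                raise ValueError("Beta parameters must be positive")


_KINETICS_WEIGHTS = {
    "early-plateau": (0.8, 1.0, 1.0, 1.0, 1.0),
    "slow-rise": (0.2, 0.35, 0.5, 0.8, 1.0),
    "stable": (1.0, 1.0, 1.0, 1.0, 1.0),
}


@dataclass(frozen=True)
class SimConfig:
    """Complete description of one synthetic cohort."""

    n_patients: int = 3
    timepoints_months: tuple = DEFAULT_TIMEPOINTS
    populations: tuple = ()             # PopulationSpec, ...
    markers: tuple = DEFAULT_MARKERS
    cells_per_sample: int = 1000
    cofactor: float = DEFAULT_COFACTOR
    emit_raw: bool = False              # emit sinh-backtransformed raw counts
    seed: int = 0

    def __post_init__(self):
        n_tp = len(self.timepoints_months)
        for pop in self.populations:
            if len(pop.beta_params) != n_tp:
                raise ValueError(
                    f"population {pop.name!r}: beta_params length != "
                    f"number of time-points")
            for m in pop.markers:
                if m not in self.markers:
                    raise ValueError(
                        f"population {pop.name!r} references unknown "
                        f"marker {m!r}")
            if pop.branch:
                for m in pop.branch.markers:
                    if m not in self.markers:
                        raise ValueError(
                            f"branch of {pop.name!r} references unknown "
                            f"marker {m!r}")

    @property
    def panel(self) -> MarkerPanel:
        return MarkerPanel.from_markers(self.markers)


def _drift_beta(means=(0.15, 0.30, 0.45, 0.65, 0.85), kappa=8.0):
    return tuple((kappa * m, kappa * (1.0 - m)) for m in means)


def default_sim_config(n_patients: int = 3, cells_per_sample: int = 1000,
                       seed: int = 0, timepoints=DEFAULT_TIMEPOINTS,
                       emit_raw: bool = False) -> SimConfig:
    """The default five-population cohort with the built-in biology."""
    drift = _drift_beta()
    stable = tuple((2.0, 2.0) for _ in timepoints)
    lineage_low = {"CD3": MarkerSpec("constant", 0.05, noise_sd=0.25)}
    cd45 = {"CD45": MarkerSpec("constant", 3.0)}

    pops = (
        PopulationSpec(
            "T", "slow-rise", 0.56, drift,
            markers={
                "CD3": MarkerSpec("constant", 4.0),
                "CD4": MarkerSpec("constant", 2.5),
                "CD8": MarkerSpec("constant", 2.0),
                "CD7": MarkerSpec("constant", 2.5),
                "CD27": MarkerSpec("constant", 2.0),
                "CD28": MarkerSpec("constant", 2.5),
                "CCR7": MarkerSpec("decreasing", 1.0, 1.5),
                "CD45RA": MarkerSpec("decreasing", 1.8, 1.2),
                "CD95": MarkerSpec("increasing", 1.0, 1.5),
                **cd45,
            }),
        PopulationSpec(
            "B", "slow-rise", 0.53, drift,
            markers={
                "CD19": MarkerSpec("constant", 3.4),
                "CD20": MarkerSpec("constant", 3.2),
                "HLA-DR": MarkerSpec("constant", 2.5),
                "IgD": MarkerSpec("constant", 2.5),
                "CD24": MarkerSpec("decreasing", 1.3, 1.5),
                "CD38": MarkerSpec("increasing", 1.0, 1.5),
                "CD44": MarkerSpec("increasing", 1.5, 1.2),
                "CD22": MarkerSpec("increasing", 1.0, 1.0),
                **lineage_low, **cd45,
            },
            branch=BranchSpec(0.5, 0.5, markers={
                "CD27": MarkerSpec("increasing", 0.3, 2.5),
                "IgD": MarkerSpec("decreasing", 0.3, 2.2),
            })),
        PopulationSpec(
            "NK", "early-plateau", 0.177, drift,
            markers={
                "CD56": MarkerSpec("decreasing", 2.1, 1.3),
                "CD16": MarkerSpec("increasing", 1.0, 2.0),
                "CD57": MarkerSpec("increasing", 0.4, 2.2),
                "CD27": MarkerSpec("decreasing", 0.5, 1.5),
                "NKG2D": MarkerSpec("constant", 2.5),
                "CD7": MarkerSpec("constant", 2.5),
                "2B4": MarkerSpec("constant", 2.0),
                **lineage_low, **cd45,
            },
            noise_convergence=1.0),
        PopulationSpec(
            "monocyte", "early-plateau", 0.135, stable,
            markers={
                "CD14": MarkerSpec("constant", 3.6),
                "CD33": MarkerSpec("constant", 2.8),
                "CD11b": MarkerSpec("constant", 2.5),
                "CD11c": MarkerSpec("constant", 2.8),
                "HLA-DR": MarkerSpec("constant", 2.8),
                "CD4": MarkerSpec("constant", 1.0),
                **lineage_low, **cd45,
            }),
        PopulationSpec(
            "basophil", "stable", 0.08, drift,
            markers={
                "CD123": MarkerSpec("increasing", 2.8, 1.0),
                "CCR3": MarkerSpec("increasing", 2.6, 1.0),
                "CD38": MarkerSpec("increasing", 1.2, 1.5),
                "CD44": MarkerSpec("increasing", 1.0, 1.2),
                **lineage_low, **cd45,
            }),
    )
    return SimConfig(n_patients=n_patients, timepoints_months=tuple(timepoints),
                     populations=pops, cells_per_sample=cells_per_sample,
                     seed=seed, emit_raw=emit_raw)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def marker_response(s, shape: str, base: float, amplitude: float):
    """Mean expression (arcsinh scale) at latent maturation ``s``."""
    s = np.asarray(s, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("latent s must lie in [0, 1]")
    if shape == "constant":
        return np.broadcast_to(np.float64(base), s.shape).copy()
    z = LOGISTIC_STEEPNESS * (s - 0.5)
    if shape == "increasing":
        return base + amplitude / (1.0 + np.exp(-z))
    if shape == "decreasing":
        return base + amplitude / (1.0 + np.exp(z))
    raise ValueError(f"unknown response shape {shape!r}")


def population_fractions(config: SimConfig) -> pd.DataFrame:
    """Deterministic per-time-point population composition of a sample."""
    weights = {
        pop.name: np.array(_KINETICS_WEIGHTS[pop.kinetics][:len(config.timepoints_months)])
        * pop.base_proportion
        for pop in config.populations
    }
    W = pd.DataFrame(weights, index=list(config.timepoints_months))
    return W.div(W.sum(axis=1), axis=0)


def _cells_per_population(config: SimConfig, timepoint: float) -> dict:
    fr = population_fractions(config).loc[timepoint]
    target = fr * config.cells_per_sample
    counts = np.floor(target).astype(int)
    short = config.cells_per_sample - counts.sum()
    # largest-remainder rounding keeps the sample size exact
    order = np.argsort(-(target - counts).to_numpy(), kind="stable")
    for i in order[:short]:
        counts.iloc[i] += 1
    return counts.to_dict()


def simulate_population_timecourse(config: SimConfig, patient: str,
                                   population: str, rng=None):
    """All time-points of one patient x population.

    Returns ``(tables, truth)``: per-time-point :class:`EventTable` dict and
    a row-aligned truth DataFrame (concatenated in time order) with the
    latent ``s`` and branch identity of every cell.
    """
    pop = next((p for p in config.populations if p.name == population), None)
    if pop is None:
        raise ValueError(f"population {population!r} not in config")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    tables, truth_rows = {}, []
    for ti, tp in enumerate(config.timepoints_months):
        n = _cells_per_population(config, tp)[population]
        a, b = pop.beta_params[ti]
        s = rng.beta(a, b, size=n)
        branch = np.array(["none"] * n, dtype=object)
        if pop.branch is not None:
            past = s > pop.branch.branch_point
            take_b = past & (rng.random(n) < pop.branch.weight)
            branch[past] = "A"
            branch[take_b] = "B"

        means = np.empty((n, len(config.markers)))
        sds = np.empty_like(means)
        for j, m in enumerate(config.markers):
            spec = pop.markers.get(m, MarkerSpec())
            mean = marker_response(s, spec.shape, spec.base, spec.amplitude)
            sd = np.full(n, spec.noise_sd)
            if pop.branch is not None and m in pop.branch.markers:
                bspec = pop.branch.markers[m]
                on_b = branch == "B"
                if on_b.any():
                    u = (s[on_b] - pop.branch.branch_point) \
                        / (1.0 - pop.branch.branch_point)
                    mean[on_b] = marker_response(
                        u, bspec.shape, bspec.base, bspec.amplitude)
                    sd[on_b] = bspec.noise_sd
            means[:, j] = mean
            sds[:, j] = sd
        if pop.noise_convergence:
            sds = sds * (1.0 + pop.noise_convergence * (1.0 - s))[:, None]
        X = np.clip(means + rng.normal(size=means.shape) * sds, 0.0, None)

        state = f"arcsinh({config.cofactor:g})"
        if config.emit_raw:
            X = np.clip(np.sinh(X) * config.cofactor, 0.0, None)
            state = "raw"
        ann = make_annotations(n, patient, tp, population)
        tables[tp] = EventTable(X, config.panel, ann, transform_state=state)
        truth_rows.append(pd.DataFrame({
            "patient_id": patient, "timepoint_months": tp,
            "population": population, "latent_s": s, "branch_id": branch,
        }))
    return tables, pd.concat(truth_rows, ignore_index=True)


def simulate_clinical_counts(config: SimConfig, patient: str,
                             rng=None) -> list[SampleMeta]:
    """WBC / neutrophil trajectories (10^7 cells/L) for one patient.

    Neutrophils recover early; the mononuclear pool (WBC - neutrophils)
    rises more slowly. Patient- and visit-level lognormal factors add
    realistic spread while keeping WBC >= neutrophils structurally.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    patient_factor = float(np.exp(rng.normal(0.0, 0.10)))
    metas = []
    for tp in config.timepoints_months:
        visit = float(np.exp(rng.normal(0.0, 0.05)))
        pool = (80.0 + 220.0 * (1.0 - np.exp(-tp / 4.0))) * patient_factor * visit
        neut = 350.0 * (1.0 - 0.6 * np.exp(-tp / 1.5)) * patient_factor \
            * float(np.exp(rng.normal(0.0, 0.05)))
        metas.append(SampleMeta(patient, tp, wbc_count=pool + neut,
                                neutrophil_count=neut))
    return metas


def simulate_cohort(config: SimConfig):
    """Full cohort: per-sample event tables, clinical metadata, truth table.

    Returns ``(tables, metas, truth)`` where ``tables`` maps
    ``(patient_id, timepoint)`` to a mixed, shuffled :class:`EventTable`
    and ``truth`` is row-aligned with the tables iterated in (patient,
    time-point) order.
    """
    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    tables: dict = {}
    truth_parts = []
    metas: list[SampleMeta] = []
    for pi, patient in enumerate(patients):
        per_pop = {}
        for qi, pop in enumerate(config.populations):
            rng = np.random.default_rng([config.seed, 7919, pi, qi])
            per_pop[pop.name] = simulate_population_timecourse(
                config, patient, pop.name, rng)
        for tp in config.timepoints_months:
            parts = [per_pop[p.name][0][tp] for p in config.populations]
            truths = []
            for p in config.populations:
                tdf = per_pop[p.name][1]
                truths.append(tdf[tdf["timepoint_months"] == tp])
            X = np.vstack([t.intensities for t in parts])
            ann = pd.concat([t.annotations for t in parts], ignore_index=True)
            tru = pd.concat(truths, ignore_index=True)
            rng = np.random.default_rng([config.seed, 104729, pi,
                                         int(round(tp * 12))])
            perm = rng.permutation(len(ann))
            tables[(patient, tp)] = EventTable(
                X[perm], config.panel, ann.iloc[perm].reset_index(drop=True),
                transform_state=parts[0].transform_state)
            truth_parts.append(tru.iloc[perm].reset_index(drop=True))
        metas.extend(simulate_clinical_counts(
            config, patient, np.random.default_rng([config.seed, 15485863, pi])))
    return tables, metas, pd.concat(truth_parts, ignore_index=True)


def gating_cutpoints(config: SimConfig, rules) -> dict[str, float]:
    """Midpoint cutpoints implied by the generator's own response levels.

    For each marker referenced by the rules: halfway between the lowest
    mean the rule-positive populations ever reach and the highest mean any
    other population reaches (over a grid of ``s``).
    """
    grid = np.linspace(0.0, 1.0, 101)
    cut: dict[str, float] = {}
    needed = set()
    for rule in rules:
        needed |= set(rule.required_high) | set(rule.required_low)
    for m in needed:
        highs = {r.population for r in rules if m in r.required_high}
        pos, neg = [], []
        for pop in config.populations:
            spec = pop.markers.get(m, MarkerSpec())
            levels = marker_response(grid, spec.shape, spec.base,
                                     spec.amplitude)
            (pos if pop.name in highs else neg).append(
                levels.min() if pop.name in highs else levels.max())
        if not pos or not neg:
            raise ValueError(f"marker {m!r} has no high/low contrast in config")
        cut[m] = float((min(pos) + max(neg)) / 2.0)
    return cut
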
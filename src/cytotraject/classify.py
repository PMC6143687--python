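"""Population classification from all markers jointly.

Mirrors the ACCENSE-style workflow: embed cells in 2-D (tSNE, or an
in-repo 2-component PCA for a fully deterministic path), estimate a kernel
density on the embedding, find density peaks, assign every cell to a peak
by steepest-ascent hill-climbing, and map clusters to named immune
populations via marker-median rules (e.g. T = CD3-high, CD19-low). A
deterministic per-cell threshold gate is provided as a fallback that skips
the embedding entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import (
    ConfigError,
    DegenerateInputError,
    InsufficientDataError,
    SchemaError,
)
from .io_cytometry import EventTable

DEFAULT_N_BINS = 128
DEFAULT_MIN_PROMINENCE = 0.05
DEFAULT_HIGH_PERCENTILE = 60.0
DEFAULT_LOW_PERCENTILE = 40.0
OTHER = "other"


@dataclass(frozen=True)
class Embedding2D:
    coords: np.ndarray   # (n_cells, 2)
    method: str
    seed: int

    def __post_init__(self):
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("embedding coords must be (n_cells, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding contains non-finite values")


@dataclass(frozen=True)
class DensityGrid:
    """KDE evaluated on a regular grid over the embedding bounding box."""

    density: np.ndarray     # (n_bins, n_bins), density[ix, iy]
    x_centers: np.ndarray
    y_centers: np.ndarray
    bandwidth: tuple[float, float]

    @property
    def cell_area(self) -> float:
        return float((self.x_centers[1] - self.x_centers[0])
                     * (self.y_centers[1] - self.y_centers[0]))

    def bin_of(self, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest grid bin of each 2-D point."""
        dx = self.x_centers[1] - self.x_centers[0]
        dy = self.y_centers[1] - self.y_centers[0]
        ix = np.clip(np.round((coords[:, 0] - self.x_centers[0]) / dx),
                     0, len(self.x_centers) - 1).astype(int)
        iy = np.clip(np.round((coords[:, 1] - self.y_centers[0]) / dy),
                     0, len(self.y_centers) - 1).astype(int)
        return ix, iy


@dataclass(frozen=True)
class Peak:
    x: float
    y: float
    density: float
    ix: int
    iy: int


@dataclass
class ClusterResult:
    cluster_id: np.ndarray        # per-cell int, -1 = unassigned
    peaks: list[Peak]
    grid_spec: tuple[int, tuple[float, float]]   # (n_bins, bandwidth)


@dataclass(frozen=True)
class PopulationRule:
    """A population is defined by markers that must be high and/or low."""

    population: str
    required_high: tuple[str, ...] = ()
    required_low: tuple[str, ...] = ()

    def __post_init__(self):
        both = set(self.required_high) & set(self.required_low)
        if both:
            raise ConfigError(
                f"rule {self.population!r}: markers cannot be both high and "
                f"low: {sorted(both)}")

    def check_markers(self, panel_markers) -> None:
        missing = (set(self.required_high) | set(self.required_low)) \
            - set(panel_markers)
        if missing:
            raise SchemaError(
                f"rule {self.population!r} references unknown markers: "
                f"{sorted(missing)}")


def default_population_rules() -> list[PopulationRule]:
    """Canonical definitions of the five principal PBMC populations."""
    return [
        PopulationRule("T", ("CD3",), ("CD19",)),
        PopulationRule("B", ("CD19",), ("CD3",)),
        PopulationRule("NK", ("CD56",), ("CD3",)),
        PopulationRule("monocyte", ("CD14",), ("CD3",)),
        PopulationRule("basophil", ("CD123", "CCR3"), ("CD3",)),
    ]


def rules_from_dict(populations: dict) -> list[PopulationRule]:
    """Build rules from a config mapping ``{name: {high: [...], low: [...]}}``."""
    return [PopulationRule(name,
                           tuple(spec.get("high", ())),
                           tuple(spec.get("low", ())))
            for name, spec in populations.items()]


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

def _pca2(X: np.ndarray) -> np.ndarray:
    """First two principal axes via SVD, deterministic sign convention."""
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    coords = U[:, :2] * s[:2]
    for j in range(2):
        load = Vt[j]
        i = int(np.argmax(np.abs(load)))
        if load[i] < 0:
            coords[:, j] = -coords[:, j]
    return coords


def embed_2d(events: EventTable, method: str = "tsne",
             seed: int = 0) -> Embedding2D:
    """2-D embedding of the cells over all analysis markers.

    ``pca2`` is computed in-repo and is exactly deterministic; ``tsne``
    delegates to scikit-learn with a fixed seed and PCA initialization.
    """
    if events.n_cells < 10:
        raise InsufficientDataError(
            f"need >= 10 cells to embed, got {events.n_cells}")
    X = events.intensities
    if method == "pca2":
        coords = _pca2(X)
    elif method == "tsne":
        from sklearn.manifold import TSNE
        tsne = TSNE(n_components=2, random_state=seed, init="pca",
                    perplexity=min(30.0, (events.n_cells - 1) / 3.0))
        coords = np.asarray(tsne.fit_transform(X), dtype=np.float64)
    else:
        raise ConfigError(f"unknown embedding method {method!r}")
    return Embedding2D(coords, method, seed)


# ---------------------------------------------------------------------------
# density-peak clustering
# ---------------------------------------------------------------------------

def kde_grid(embedding: Embedding2D, n_bins: int = DEFAULT_N_BINS,
             bandwidth="silverman") -> DensityGrid:
    """Gaussian KDE on a regular grid over the embedding.

    Per-axis Silverman bandwidth for 2-D data: ``h = sigma_hat * n^(-1/6)``.
    The grid extends 3 bandwidths beyond the data and is renormalized so
    that ``sum(density) * cell_area == 1`` exactly.
    """
    if n_bins < 16:
        raise ValueError(f"n_bins must be >= 16, got {n_bins}")
    pts = embedding.coords
    n = pts.shape[0]
    sx, sy = pts[:, 0].std(), pts[:, 1].std()
    if sx == 0 or sy == 0:
        raise DegenerateInputError("zero-variance embedding axis")
    if bandwidth == "silverman":
        hx, hy = sx * n ** (-1 / 6), sy * n ** (-1 / 6)
    else:
        hx = hy = float(bandwidth)
        if hx <= 0:
            raise ValueError("bandwidth must be positive")

    x_lo, x_hi = pts[:, 0].min() - 3 * hx, pts[:, 0].max() + 3 * hx
    y_lo, y_hi = pts[:, 1].min() - 3 * hy, pts[:, 1].max() + 3 * hy
    xc = np.linspace(x_lo, x_hi, n_bins)
    yc = np.linspace(y_lo, y_hi, n_bins)
    # separable Gaussian: density = Gx^T Gy accumulated over points
    Gx = np.exp(-0.5 * ((xc[None, :] - pts[:, 0][:, None]) / hx) ** 2)
    Gy = np.exp(-0.5 * ((yc[None, :] - pts[:, 1][:, None]) / hy) ** 2)
    dens = Gx.T @ Gy / (n * 2 * np.pi * hx * hy)
    area = (xc[1] - xc[0]) * (yc[1] - yc[0])
    dens = dens / (dens.sum() * area)
    return DensityGrid(dens, xc, yc, (hx, hy))


def find_density_peaks(grid: DensityGrid,
                       min_prominence_frac: float = DEFAULT_MIN_PROMINENCE
                       ) -> list[Peak]:
    """Strict 8-neighbourhood local maxima above a fraction of the global max."""
    d = grid.density
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    neigh_max = ndimage.maximum_filter(d, footprint=footprint,
                                       mode="constant", cval=-np.inf)
    is_peak = (d > neigh_max) & (d >= min_prominence_frac * d.max())
    ixs, iys = np.nonzero(is_peak)
    peaks = [Peak(float(grid.x_centers[ix]), float(grid.y_centers[iy]),
                  float(d[ix, iy]), int(ix), int(iy))
             for ix, iy in zip(ixs, iys)]
    peaks.sort(key=lambda p: (-p.density, p.ix, p.iy))
    return peaks


def assign_clusters(embedding: Embedding2D, grid: DensityGrid,
                    peaks: list[Peak]) -> ClusterResult:
    """Assign cells to density peaks by steepest ascent on the grid.

    Every grid bin follows its steepest strictly-ascending 8-neighbour until
    a local maximum; bins terminating at a listed peak take that peak's
    index; bins terminating at a sub-prominence maximum take the nearest
    listed peak (ties to the denser peak). Cells in zero-density bins get -1.
    """
    if not peaks:
        raise ValueError("need at least one peak")
    d = grid.density
    nb, _ = d.shape
    # steepest-ascent pointer per bin
    padded = np.full((nb + 2, nb + 2), -np.inf)
    padded[1:-1, 1:-1] = d
    shifts = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1)]
    stacked = np.stack([padded[1 + dx:nb + 1 + dx, 1 + dy:nb + 1 + dy]
                        for dx, dy in shifts])
    best = np.argmax(stacked, axis=0)
    center = shifts.index((0, 0))
    improves = stacked.max(axis=0) > d
    best = np.where(improves, best, center)

    ix_grid, iy_grid = np.meshgrid(np.arange(nb), np.arange(nb), indexing="ij")
    dxs = np.array([s[0] for s in shifts])
    dys = np.array([s[1] for s in shifts])
    nxt = (np.clip(ix_grid + dxs[best], 0, nb - 1) * nb
           + np.clip(iy_grid + dys[best], 0, nb - 1))
    # pointer jumping to the fixed point
    flat = nxt.ravel()
    for _ in range(int(np.ceil(np.log2(nb * nb))) + 1):
        new = flat[flat]
        if np.array_equal(new, flat):
            break
        flat = new

    peak_bins = {p.ix * nb + p.iy: i for i, p in enumerate(peaks)}
    term_ids = np.full(nb * nb, -1, dtype=int)
    terminals = np.unique(flat)
    pk_ix = np.array([p.ix for p in peaks])
    pk_iy = np.array([p.iy for p in peaks])
    for t in terminals:
        if t in peak_bins:
            term_ids[t] = peak_bins[t]
        else:
            tx, ty = divmod(t, nb)
            dist2 = (pk_ix - tx) ** 2 + (pk_iy - ty) ** 2
            term_ids[t] = int(np.argmin(dist2))  # ties -> denser peak (listed first)
    bin_cluster = term_ids[flat]

    cix, ciy = grid.bin_of(embedding.coords)
    cell_bin = cix * nb + ciy
    cluster_id = bin_cluster[cell_bin]
    zero = d.ravel()[cell_bin] <= 0.0
    cluster_id = np.where(zero, -1, cluster_id)
    return ClusterResult(cluster_id.astype(int), peaks,
                         (nb, grid.bandwidth))


# ---------------------------------------------------------------------------
# cluster -> population mapping
# ---------------------------------------------------------------------------

def label_populations(events: EventTable, clusters: ClusterResult,
                      rules: list[PopulationRule],
                      high_percentile: float = DEFAULT_HIGH_PERCENTILE,
                      low_percentile: float = DEFAULT_LOW_PERCENTILE
                      ) -> EventTable:
    """Label each cluster by its marker medians against cohort percentiles.

    A cluster gets population P when every required-high marker median lies
    above that marker's cohort-wide ``high_percentile`` and every
    required-low median below the ``low_percentile``; clusters matching no
    rule or several rules become ``"other"``, unassigned cells (cluster -1)
    stay ``"unassigned"``. Percentiles are computed over the events passed
    in, so callers should pass a cohort-representative table.
    """
    markers = events.markers
    for rule in rules:
        rule.check_markers(markers)
    if len(clusters.cluster_id) != events.n_cells:
        raise SchemaError("cluster result not aligned with events")

    hi_cut = {m: np.percentile(events.marker_column(m), high_percentile)
              for m in markers}
    lo_cut = {m: np.percentile(events.marker_column(m), low_percentile)
              for m in markers}

    labels = np.array([OTHER] * events.n_cells, dtype=object)
    labels[clusters.cluster_id < 0] = "unassigned"
    for cid in np.unique(clusters.cluster_id):
        if cid < 0:
            continue
        mask = clusters.cluster_id == cid
        medians = np.median(events.intensities[mask], axis=0)
        med = dict(zip(markers, medians))
        matches = [r.population for r in rules
                   if all(med[m] > hi_cut[m] for m in r.required_high)
                   and all(med[m] < lo_cut[m] for m in r.required_low)]
        if len(matches) == 1:
            labels[mask] = matches[0]
    return events.with_populations(labels)


def threshold_gate(events: EventTable, rules: list[PopulationRule],
                   cutpoints: dict[str, float]) -> EventTable:
    """Deterministic per-cell gate: first rule fully satisfied wins.

    ``cutpoints`` maps each marker referenced by any rule to its high/low
    boundary; a cell satisfies a rule when all required-high markers exceed
    their cutpoint and all required-low markers fall below it.
    """
    markers = events.markers
    needed = set()
    for rule in rules:
        rule.check_markers(markers)
        needed |= set(rule.required_high) | set(rule.required_low)
    missing = needed - set(cutpoints)
    if missing:
        raise ConfigError(f"missing cutpoints for markers: {sorted(missing)}")

    labels = np.array([OTHER] * events.n_cells, dtype=object)
    undecided = np.ones(events.n_cells, dtype=bool)
    for rule in rules:
        ok = np.ones(events.n_cells, dtype=bool)
        for m in rule.required_high:
            ok &= events.marker_column(m) > cutpoints[m]
        for m in rule.required_low:
            ok &= events.marker_column(m) < cutpoints[m]
        take = ok & undecided
        labels[take] = rule.population
        undecided &= ~take
    return events.with_populations(labels)


def classify_events(events: EventTable, rules: list[PopulationRule],
                    method: str = "tsne", seed: int = 0,
                    n_bins: int = DEFAULT_N_BINS,
                    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE,
                    high_percentile: float = DEFAULT_HIGH_PERCENTILE,
                    low_percentile: float = DEFAULT_LOW_PERCENTILE
                    ) -> EventTable:
    """Convenience composition: embed -> KDE -> peaks -> basins -> labels."""
    emb = embed_2d(events, method=method, seed=seed)
    grid = kde_grid(emb, n_bins=n_bins)
    peaks = find_density_peaks(grid, min_prominence_frac)
    clusters = assign_clusters(emb, grid, peaks)
    return label_populations(events, clusters, rules,
                             high_percentile, low_percentile)
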
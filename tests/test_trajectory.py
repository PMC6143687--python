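import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy.stats import spearmanr

from cytotraject.diffusion import DiffusionMap, DiffusionParams
from cytotraject.exceptions import InsufficientDataError
from cytotraject.synthetic_data import default_sim_config, \
    simulate_population_timecourse
from cytotraject.trajectory import (
    OrientedCoordinate,
    bimodality_coefficient,
    marker_profile,
    marker_trend,
    orient_pseudotime,
    plot_dc_scatter,
    plot_marker_profiles,
    rank_dcs_by_time,
    run_patient_trajectory,
    subsample_per_timepoint,
)

from conftest import make_table


def fake_dmap(components):
    components = np.asarray(components, dtype=float)
    n, m = components.shape
    return DiffusionMap(np.linspace(0.9, 0.5, m), components, {},
                        pd.DataFrame(index=range(n)))


class TestRanking:
    def test_time_identical_dc_ranks_first(self):
        t = np.repeat([1.0, 2.0, 3.0], 10)
        rng = np.random.default_rng(0)
        dmap = fake_dmap(np.column_stack([rng.normal(size=30), t]))
        ranking = rank_dcs_by_time(dmap, t)
        assert ranking.top == 2
        assert ranking.rho(2) == pytest.approx(1.0)

    def test_constant_dc_ranks_last(self):
        t = np.repeat([1.0, 2.0], 10)
        rng = np.random.default_rng(1)
        dmap = fake_dmap(np.column_stack([np.zeros(20),
                                          rng.normal(size=20) + t]))
        ranking = rank_dcs_by_time(dmap, t)
        assert list(ranking.table["dc_index"])[-1] == 1
        assert ranking.rho(1) == 0.0

    def test_single_timepoint_rejected(self):
        dmap = fake_dmap(np.random.default_rng(2).normal(size=(10, 2)))
        with pytest.raises(ValueError):
            rank_dcs_by_time(dmap, np.ones(10))


class TestOrientation:
    def test_negative_rho_flipped(self):
        t = np.repeat([1.0, 2.0, 3.0], 5)
        dmap = fake_dmap((-t + 0.01 * np.arange(15))[:, None])
        coord = orient_pseudotime(dmap, 1, t)
        assert coord.flipped
        assert spearmanr(coord.values, t).statistic > 0

    def test_positive_rho_unchanged(self):
        t = np.repeat([1.0, 2.0, 3.0], 5)
        dmap = fake_dmap(t[:, None])
        coord = orient_pseudotime(dmap, 1, t)
        assert not coord.flipped
        np.testing.assert_array_equal(coord.values, t)

    def test_idempotent_on_oriented(self):
        t = np.repeat([1.0, 2.0, 3.0], 5)
        dmap = fake_dmap((-t)[:, None])
        once = orient_pseudotime(dmap, 1, t)
        again = orient_pseudotime(fake_dmap(once.values[:, None]), 1, t)
        np.testing.assert_array_equal(once.values, again.values)
        assert not again.flipped


class TestMarkerProfile:
    def _events_and_coord(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        coord = rng.uniform(size=n)
        X = np.column_stack([np.full(n, 2.5), coord])
        events = make_table(X, markers=["const", "tracker"])
        return events, OrientedCoordinate(coord, 1, False)

    def test_constant_marker_constant_bins(self):
        events, coord = self._events_and_coord()
        prof = marker_profile(events, coord)
        np.testing.assert_allclose(prof.marker_medians("const"), 2.5)

    def test_coordinate_marker_increasing(self):
        events, coord = self._events_and_coord()
        prof = marker_profile(events, coord)
        meds = prof.marker_medians("tracker")
        assert np.all(np.diff(meds) > 0)

    def test_every_cell_covered(self):
        events, coord = self._events_and_coord(n=97)
        prof = marker_profile(events, coord, window_frac=0.2, step_frac=0.1)
        w = prof.bins["n_cells"].iloc[0]
        last_start = prof.bins["rank_center"].iloc[-1] - (w - 1) / 2.0
        assert last_start + w == 97

    def test_order_invariance(self):
        events, coord = self._events_and_coord()
        perm = np.random.default_rng(1).permutation(events.n_cells)
        prof_a = marker_profile(events, coord)
        prof_b = marker_profile(
            events.select(perm),
            OrientedCoordinate(coord.values[perm], 1, False))
        pd.testing.assert_frame_equal(prof_a.bins, prof_b.bins)

    def test_bad_fractions(self):
        events, coord = self._events_and_coord()
        with pytest.raises(ValueError):
            marker_profile(events, coord, window_frac=0.1, step_frac=0.2)

    def test_too_few_cells(self):
        events, coord = self._events_and_coord(n=10)
        with pytest.raises(InsufficientDataError):
            marker_profile(events, coord)


class TestMarkerTrend:
    def test_monotone_marker_near_one(self):
        rng = np.random.default_rng(11)
        coord = rng.uniform(size=500)
        X = np.column_stack([coord + rng.normal(0, 0.05, 500),
                             np.full(500, 1.0)])
        events = make_table(X, markers=["up", "flat"])
        oc = OrientedCoordinate(coord, 1, False)
        assert marker_trend(events, oc, "up") > 0.95
        assert marker_trend(events, oc, "flat") == 0.0

    def test_null_marker_small_trend(self):
        rng = np.random.default_rng(12)
        coord = rng.uniform(size=2000)
        X = rng.normal(2.0, 0.3, size=(2000, 1))
        events = make_table(X, markers=["noise"])
        oc = OrientedCoordinate(coord, 1, False)
        assert abs(marker_trend(events, oc, "noise")) < 0.3


class TestBimodality:
    def test_separated_modes_above_threshold(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(-3, 0.5, 500),
                            rng.normal(3, 0.5, 500)])
        assert bimodality_coefficient(x) > 0.555

    def test_gaussian_below_threshold(self):
        rng = np.random.default_rng(4)
        assert bimodality_coefficient(rng.normal(size=2000)) < 0.555

    def test_degenerate_input(self):
        assert bimodality_coefficient(np.ones(10)) == 0.0


class TestSubsample:
    def test_caps_each_timepoint(self, small_cohort):
        _, tables, _, _ = small_cohort
        from conftest import pool_tables
        pooled = pool_tables(tables)
        capped = subsample_per_timepoint(pooled, cap=50, seed=0)
        per_tp = capped.annotations.groupby("timepoint_months").size()
        assert (per_tp <= 50).all()

    def test_deterministic(self, small_cohort):
        _, tables, _, _ = small_cohort
        from conftest import pool_tables
        pooled = pool_tables(tables)
        a = subsample_per_timepoint(pooled, cap=50, seed=5)
        b = subsample_per_timepoint(pooled, cap=50, seed=5)
        np.testing.assert_array_equal(a.intensities, b.intensities)


@pytest.fixture(scope="module")
def nk_run():
    base = default_sim_config()
    nk = next(p for p in base.populations if p.name == "NK")
    cfg = replace(base, populations=(nk,), cells_per_sample=700,
                  n_patients=1, seed=21)
    rng = np.random.default_rng(21)
    tabs, truth = simulate_population_timecourse(cfg, "P01", "NK", rng)
    run = run_patient_trajectory(list(tabs.values()), "NK",
                                 params=DiffusionParams(seed=0))
    return tabs, truth, run


class TestRunPatientTrajectory:

    def test_pseudotime_tracks_latent_maturation(self, nk_run):
        _, truth, run = nk_run
        rho = spearmanr(run.pseudotime.values, truth["latent_s"]).statistic
        assert rho >= 0.8

    def test_convergence_variance_decreases(self, nk_run):
        """NK heterogeneity shrinks along pseudo-time: mean per-marker cell
        variance in the first bin exceeds that in the last bin."""
        tabs, _, run = nk_run
        from cytotraject.io_cytometry import merge_timepoints
        merged = merge_timepoints(list(tabs.values()), "NK")
        order = np.argsort(run.pseudotime.values, kind="stable")
        w = int(np.ceil(0.1 * merged.n_cells))
        first = merged.intensities[order[:w]]
        last = merged.intensities[order[-w:]]
        assert first.var(axis=0).mean() > last.var(axis=0).mean()

    def test_report_is_complete(self, nk_run):
        _, _, run = nk_run
        for key in ("diffusion_params", "top_dcs", "pseudotime_dc",
                    "dc_time_rho", "late_bimodality", "n_cells_merged"):
            assert key in run.report
        assert len(run.profiles) == len(run.report["top_dcs"])

    def test_identical_runs_identical_outputs(self, nk_run):
        tabs, _, run = nk_run
        again = run_patient_trajectory(list(tabs.values()), "NK",
                                       params=DiffusionParams(seed=0))
        np.testing.assert_array_equal(run.pseudotime.values,
                                      again.pseudotime.values)
        for a, b in zip(run.profiles, again.profiles):
            pd.testing.assert_frame_equal(a.bins, b.bins)


class TestPlotting:
    def test_plot_helpers_smoke(self, nk_run, tmp_path):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        _, _, run = nk_run
        tps = run.dmap.cell_index["timepoint_months"]
        ax = plot_dc_scatter(run.dmap, 1, 2, tps)
        ax.figure.savefig(tmp_path / "scatter.png")
        ax2 = plot_marker_profiles(run.profiles[0], ["CD57", "CD56", "2B4"])
        ax2.figure.savefig(tmp_path / "profiles.png")
        plt.close("all")
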
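"""PMF post-processing: combination, error maps, states, paths, occupancy."""
import numpy as np
import pytest

from permeon import (
    AnalysisGrid,
    BiasSpec,
    DoubleWell,
    PermeationMap,
    PMFGrid,
    RCTrajectory,
    bin_samples,
    boltzmann_pmf,
    classify_occupancy,
    combine_runs,
    find_states,
    interval_error,
    minimax_path,
    wham_solve,
)
from permeon.analysis import interval_offset

from .oracles import enumerate_minimax

T = 323.25


class TestCombineRuns:
    def test_needs_two_sets(self, harmonic_windows, harmonic_1d):
        _, grid = harmonic_1d
        with pytest.raises(ValueError, match="two window sets"):
            combine_runs([harmonic_windows], grid, T)

    def test_same_run_twice_reproduces_single_run(self, harmonic_windows,
                                                  harmonic_1d):
        _, grid = harmonic_1d
        single = wham_solve(harmonic_windows, grid, T)
        comb = combine_runs([harmonic_windows, harmonic_windows], grid, T)
        m = single.pmf.mask
        # agreement at the solver's offset tolerance
        assert np.allclose(comb.pmf.free_energy[m], single.pmf.free_energy[m],
                           atol=1e-5)

    def test_split_halves_identity_bit_for_bit(self, harmonic_windows,
                                               harmonic_1d):
        _, grid = harmonic_1d
        unsplit = wham_solve(harmonic_windows, grid, T)
        comb = combine_runs([harmonic_windows[:4], harmonic_windows[4:]],
                            grid, T)
        assert np.array_equal(comb.pmf.free_energy, unsplit.pmf.free_energy,
                              equal_nan=True)
        assert np.array_equal(comb.solution.offsets, unsplit.offsets)

    def test_provenance_records_window_counts(self, harmonic_windows,
                                              harmonic_1d):
        _, grid = harmonic_1d
        comb = combine_runs([harmonic_windows[:4], harmonic_windows[4:]],
                            grid, T, run_ids=["fwd", "bwd"])
        assert comb.provenance == [("fwd", 4), ("bwd", 5)]
        assert comb.pmf.mask.sum() >= max(
            w.counts.astype(bool).sum() for w in harmonic_windows
        )


def periodic_window(grid, block, n_blocks, interval=1.0, k=0.0, center=0.0):
    """Window whose sampling repeats the same block every slice."""
    coords = np.tile(np.asarray(block, dtype=float), n_blocks).reshape(-1, 1)
    times = interval * np.arange(len(coords))
    traj = RCTrajectory(times=times, coords=coords,
                        bias=BiasSpec((center,), (k,)))
    return bin_samples(traj, grid, discard=100.0)


class TestIntervalError:
    def test_identical_intervals_give_zero_error(self):
        grid = AnalysisGrid((-1.0,), (1.0,), 0.1)
        rng = np.random.default_rng(2)
        block = rng.uniform(-0.9, 0.9, size=100)
        w = periodic_window(grid, block, 6)  # 600 ps, identical 100 ps slices
        final = wham_solve([w], grid, T).pmf
        err = interval_error([w], final, slice_length=100.0, n_last=5,
                             temperature=T)
        assert err.n_intervals == 5
        assert np.nanmax(err.sd) == pytest.approx(0.0, abs=1e-12)

    def test_offset_closed_form_matches_grid_scan(self):
        rng = np.random.default_rng(3)
        f_final = rng.normal(2.0, 1.5, size=50)
        f_int = f_final + rng.normal(0.0, 0.3, size=50) + 4.2
        mask = f_final < 3.0
        c_star = interval_offset(f_int, f_final, mask)
        cs = np.linspace(-10, 10, 200001)
        sse = ((f_int[mask][None, :] + cs[:, None] - f_final[mask][None, :]) ** 2
               ).sum(axis=1)
        assert c_star == pytest.approx(cs[np.argmin(sse)], abs=1e-4)

    def test_600ps_windows_give_exactly_five_intervals(self, harmonic_windows,
                                                       harmonic_1d):
        _, grid = harmonic_1d
        final = wham_solve(harmonic_windows, grid, T).pmf
        # mask restricted to the window-covered region: the far F < 6
        # tail bins of the full-sampling PMF are not revisited by every
        # 100 ps slice
        err = interval_error(harmonic_windows, final, slice_length=100.0,
                             n_last=5, mask_level=2.0, temperature=T)
        assert err.n_intervals == 5
        assert np.nanmax(err.sd) > 0
        with pytest.raises(ValueError, match="need 6"):
            interval_error(harmonic_windows, final, slice_length=100.0,
                           n_last=6, mask_level=2.0, temperature=T)

    def test_final_reference_shift_leaves_error_unchanged(
        self, harmonic_windows, harmonic_1d
    ):
        _, grid = harmonic_1d
        final = wham_solve(harmonic_windows, grid, T).pmf
        shifted = PMFGrid(grid=final.grid,
                          free_energy=final.free_energy + 3.7,
                          mask=final.mask, temperature=T)
        a = interval_error(harmonic_windows, final, mask_level=2.0,
                           temperature=T)
        b = interval_error(harmonic_windows, shifted, mask_level=2.0 + 3.7,
                           temperature=T)
        assert np.allclose(a.sd, b.sd, atol=1e-10, equal_nan=True)

    def test_interval_missing_mask_bins_is_reported(self):
        grid = AnalysisGrid((-1.0,), (1.0,), 0.1)
        # bin near 0.55 is sampled only in the first retained slice
        coords = np.concatenate([
            np.full(150, 0.05), np.full(50, 0.55), np.full(400, 0.05)
        ])
        traj = RCTrajectory(times=np.arange(600.0),
                            coords=coords.reshape(-1, 1),
                            bias=BiasSpec((0.0,), (0.0,)))
        w = bin_samples(traj, grid, discard=100.0)
        final = wham_solve([w], grid, T).pmf
        with pytest.raises(ValueError, match="interval"):
            interval_error([w], final, slice_length=100.0, n_last=5,
                           temperature=T)


class TestFindStates:
    def test_single_well_single_state(self):
        grid = AnalysisGrid((-1.0,), (1.0,), 0.1)
        f = (grid.centers(0) ** 2).reshape(grid.shape)
        pmf = PMFGrid.from_energies(grid, f, T)
        states = find_states(pmf, max_f=6.0)
        assert len(states) == 1
        assert states[0].free_energy == 0.0
        assert abs(states[0].coords[0]) < 0.1

    def test_three_well_map_recovers_configured_wells(self):
        L = PermeationMap(
            bounds=((-3.0, 3.0), (-2.0, 2.0)),
            anchor=(0.0, 0.0), direction=(1.0, 0.0),
            well_s=(-1.5, 0.0, 1.5), barriers=(2.5, 2.5), k_perp=10.0,
            k_wall=5.0,  # walls beyond the end wells keep them strict minima
        )
        # grid centers aligned with the wells so the minima are strict
        # (a symmetric grid straddling a well creates ties by construction)
        grid = AnalysisGrid((-3.05, -2.05), (2.95, 1.95), 0.1)
        pmf = boltzmann_pmf(L, grid, T)
        states = find_states(pmf, max_f=6.0, merge_radius=0.3)
        assert len(states) == 3
        found = sorted(s.coords[0] for s in states)
        assert np.allclose(found, [-1.5, 0.0, 1.5], atol=0.1)
        assert all(abs(s.coords[1]) <= 0.05 for s in states)

    def test_max_f_filters_shallow_minima(self):
        L = DoubleWell(bounds=((-3.0, 3.0),), barrier=6.0, half_separation=1.5)
        grid = AnalysisGrid((-3.0,), (3.0,), 0.1)
        f = boltzmann_pmf(L, grid, T).free_energy + np.where(
            grid.centers(0) > 0, 1.0, 0.0
        )  # push the right well to F = 1
        pmf = PMFGrid.from_energies(grid, f, T)
        assert len(find_states(pmf, max_f=6.0)) == 2
        assert len(find_states(pmf, max_f=0.5)) == 1

    def test_merge_radius_collapses_nearby_minima(self):
        grid = AnalysisGrid((0.0,), (1.0,), 0.1)
        f = np.array([0.5, 0.1, 0.4, 0.0, 0.6, 0.2, 0.9, 0.3, 0.8, 0.4])
        pmf = PMFGrid.from_energies(grid, f, T)
        loose = find_states(pmf, max_f=2.0, merge_radius=0.0)
        merged = find_states(pmf, max_f=2.0, merge_radius=0.45)
        assert len(merged) < len(loose)
        assert merged[0].free_energy == 0.0


class TestMinimaxPath:
    def test_identical_states_give_empty_path(self):
        grid = AnalysisGrid((-1.0,), (1.0,), 0.1)
        pmf = PMFGrid.from_energies(grid, grid.centers(0) ** 2, T)
        res = minimax_path(pmf, (0.0,), (0.0,))
        assert res.bins == []
        assert res.barrier == 0.0

    def test_double_well_designed_barrier(self, double_well_1d):
        landscape, grid = double_well_1d
        pmf = boltzmann_pmf(landscape, grid, T)
        res = minimax_path(pmf, (-1.5,), (1.5,))
        assert res.barrier == pytest.approx(6.0, abs=0.05)
        assert abs(res.saddle[0]) <= 0.05

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_enumeration_on_5x5(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.uniform(0.0, 10.0, size=(5, 5))
        f[rng.uniform(size=(5, 5)) < 0.15] = np.nan
        grid = AnalysisGrid((0.0, 0.0), (0.5, 0.5), 0.1)
        a, b = (0, 0), (4, 4)
        f[a] = 0.3
        f[b] = 0.7
        pmf = PMFGrid.from_energies(grid, f, T)
        fr = pmf.free_energy  # referenced copy
        expected = enumerate_minimax(fr, a, b) - fr[a]
        res = minimax_path(pmf, (0.05, 0.05), (0.45, 0.45))
        assert res.barrier == pytest.approx(expected, abs=1e-12)

    def test_barrier_invariant_under_constant_shift(self):
        rng = np.random.default_rng(9)
        f = rng.uniform(0.0, 5.0, size=(6, 6))
        grid = AnalysisGrid((0.0, 0.0), (0.6, 0.6), 0.1)
        base = minimax_path(PMFGrid(grid, f, temperature=T),
                            (0.05, 0.05), (0.55, 0.55)).barrier
        shifted = minimax_path(PMFGrid(grid, f + 11.0, temperature=T),
                               (0.05, 0.05), (0.55, 0.55)).barrier
        assert shifted == pytest.approx(base, abs=1e-12)

    def test_barrier_monotone_when_bins_increase(self):
        rng = np.random.default_rng(10)
        f = rng.uniform(0.0, 5.0, size=(6, 6))
        grid = AnalysisGrid((0.0, 0.0), (0.6, 0.6), 0.1)
        args = ((0.05, 0.05), (0.55, 0.55))
        base = minimax_path(PMFGrid(grid, f.copy(), temperature=T), *args).barrier
        for _ in range(10):
            g = f.copy()
            i, j = rng.integers(0, 6, size=2)
            g[i, j] += rng.uniform(0.0, 4.0)
            higher = minimax_path(PMFGrid(grid, g, temperature=T), *args).barrier
            assert higher >= base - 1e-12

    def test_disconnected_states_raise(self):
        grid = AnalysisGrid((0.0, 0.0), (0.5, 0.5), 0.1)
        f = np.zeros((5, 5))
        f[:, 2] = np.nan  # NaN wall splits the map
        pmf = PMFGrid(grid, f, temperature=T)
        with pytest.raises(ValueError, match="not connected"):
            minimax_path(pmf, (0.05, 0.05), (0.45, 0.45))


BOUNDARIES = [14.0, 11.0, 8.0, 5.0, 2.0, -1.0, -13.0]
STATIONS = [-16.0, -7.0, 0.5, 3.5, 6.5, 9.5, 12.5, 16.0]


def conveyor_series(n_ions=3, stagger=2, n_cycles=1):
    """Ions marching one site per frame from intracellular to extracellular."""
    frames = []
    total = len(STATIONS) + stagger * (n_ions - 1)
    for cycle in range(n_cycles):
        for t in range(total):
            row = []
            for i in range(n_ions):
                k = np.clip(t - stagger * i, 0, len(STATIONS) - 1)
                row.append(STATIONS[k])
            frames.append(row)
        # return everyone to the intracellular side between cycles
        frames.append([STATIONS[0]] * n_ions)
    return np.asarray(frames)


class TestOccupancy:
    def test_boundaries_must_decrease(self):
        with pytest.raises(ValueError, match="decreasing"):
            classify_occupancy(np.zeros((3, 1)), [1.0, 2.0, 0.0])

    def test_monotone_ramp_is_one_event(self):
        z = np.linspace(-16, 16, 40).reshape(-1, 1)
        s = classify_occupancy(z, BOUNDARIES)
        assert s.n_events == 1
        assert np.all(np.diff(s.events_cumulative) >= 0)

    def test_oscillation_across_internal_boundary_counts_nothing(self):
        z = np.array([4.0, 6.0] * 20).reshape(-1, 1)  # across the S2|S3 cutoff
        s = classify_occupancy(z, BOUNDARIES)
        assert s.n_events == 0

    def test_incomplete_crossing_counts_nothing(self):
        # rises from the cavity (never below the intracellular cutoff) to
        # extracellular: lower threshold was never crossed
        z = np.linspace(-7, 16, 30).reshape(-1, 1)
        assert classify_occupancy(z, BOUNDARIES).n_events == 0

    def test_site_labels_default(self):
        s = classify_occupancy(np.array([[16.0, 9.0, -20.0]]), BOUNDARIES)
        assert s.labels[0] == "extracellular"
        named = [s.labels[i] for i in s.sites[0]]
        assert named == ["extracellular", "S1", "intracellular"]

    @pytest.mark.parametrize("n_cycles", [1, 2, 4])
    def test_conveyor_cycles_count_exactly(self, n_cycles):
        z = conveyor_series(n_ions=3, stagger=2, n_cycles=n_cycles)
        s = classify_occupancy(z, BOUNDARIES)
        assert s.n_events == 3 * n_cycles
        assert s.bound_count.max() == 3
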
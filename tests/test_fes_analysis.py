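"""FES post-processing: minima, minimax MFEP, barriers, tube averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from puckerpath.errors import PuckerPathError
from puckerpath.fes import (
    FESGrid,
    barrier_and_dg,
    find_mfep,
    find_minima,
    minimax_path,
    project_1d,
    tube_average,
)
from puckerpath.synthetic import reaction_distance_series


def grid_from(values, lo=0.0, hi=1.0):
    values = np.asarray(values, dtype=float)
    axes = [np.linspace(lo, hi, n) for n in values.shape]
    return FESGrid(axes=tuple(axes), values=values)


def enumerate_minimax(values, a, b):
    """Exhaustive simple-path enumeration oracle (small grids only)."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    best = [np.inf]

    def neighbors(ij):
        i, j = ij
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                if 0 <= i + di < n and 0 <= j + dj < m:
                    yield (i + di, j + dj)

    def dfs(node, seen, bottleneck):
        if bottleneck >= best[0]:
            return
        if node == b:
            best[0] = min(best[0], bottleneck)
            return
        for nb in neighbors(node):
            if nb not in seen:
                dfs(nb, seen | {nb}, max(bottleneck, values[nb]))

    dfs(a, {a}, values[a])
    return best[0]


def threshold_minimax(values, a, b):
    """Exhaustive check over all level thresholds via connectivity."""
    from scipy.ndimage import label

    values = np.asarray(values, dtype=float)
    for t in sorted(values.ravel()):
        mask = values <= t
        lab, _ = label(mask, structure=np.ones((3, 3)))
        if lab[a] and lab[a] == lab[b]:
            return t
    raise AssertionError("unreachable")


class TestFindMinima:
    def test_single_bowl_has_one_minimum(self):
        x = np.linspace(-1, 1, 41)
        vals = np.add.outer(x**2, x**2)
        mins = find_minima(grid_from(vals), depth_floor=0.1)
        assert len(mins) == 1
        assert mins[0].idx == (20, 20)

    def test_flat_grid_has_no_deep_minima(self):
        mins = find_minima(grid_from(np.zeros((15, 15))), depth_floor=0.1)
        assert mins == [] or all(np.isinf(m.prominence) for m in mins)
        # only the (arbitrary) global cell can survive, never a deep basin
        assert len(mins) <= 1

    def test_surrogate_reaction_minima_land_on_reported_coordinates(self, reaction_landscape):
        fes = reaction_landscape.fes_grid(101)
        mins = find_minima(fes, depth_floor=2.0)
        coords = np.array([m.coords for m in mins])
        cell = np.array([ax[1] - ax[0] for ax in fes.axes])
        for target in ([-1.0, 1.1], [1.8, 1.7], [1.8, 3.4]):
            d = np.abs(coords - np.array(target)).min(axis=0)
            assert np.all(d <= cell + 1e-9)

    def test_depth_floor_filters_shallow_dimples(self):
        x = np.linspace(0, 1, 61)
        vals = np.add.outer(0 * x, 4 * (x - 0.5) ** 2)
        vals[30, 10] -= 0.2  # shallow dimple
        deep = find_minima(grid_from(vals), depth_floor=0.5)
        shallow = find_minima(grid_from(vals), depth_floor=0.05)
        assert len(deep) == 1 and len(shallow) == 2


class TestMinimaxPath:
    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_exhaustive_enumeration_on_3x4_grids(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 10, size=(3, 4))
        g = grid_from(vals)
        a, b = (0, 0), (2, 3)
        path = minimax_path(g, a, b)
        got = max(vals[p] for p in path)
        assert got == pytest.approx(enumerate_minimax(vals, a, b))

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_threshold_connectivity_on_5x5_grids(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 10, size=(5, 5))
        g = grid_from(vals)
        a, b = (0, 0), (4, 4)
        path = minimax_path(g, a, b)
        got = max(vals[p] for p in path)
        assert got == pytest.approx(threshold_minimax(vals, a, b))

    @settings(max_examples=15, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_bottleneck_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 5, size=(6, 6))
        a, b = (0, 0), (5, 5)
        p1 = minimax_path(grid_from(vals), a, b)
        p2 = minimax_path(grid_from(np.exp(vals)), a, b)
        assert np.exp(max(vals[p] for p in p1)) == pytest.approx(
            max(np.exp(vals)[p] for p in p2)
        )

    def test_path_is_8_connected(self):
        rng = np.random.default_rng(0)
        g = grid_from(rng.uniform(0, 1, (10, 10)))
        path = minimax_path(g, (0, 0), (9, 9))
        for p, q in zip(path, path[1:]):
            assert max(abs(p[0] - q[0]), abs(p[1] - q[1])) == 1


class TestFindMfep:
    def two_bowls(self):
        x = np.linspace(-2, 2, 81)
        y = np.linspace(-1, 1, 41)
        X, Y = np.meshgrid(x, y, indexing="ij")
        # two bowls separated by a parabolic ridge along x = 0, lowest at y = 0
        vals = 3 * (1 - np.exp(-((X - 1) ** 2 + Y**2)) - np.exp(-((X + 1) ** 2 + Y**2))) + 2 * Y**2
        return FESGrid(axes=(x, y), values=vals)

    def test_symmetric_ridge_crossed_at_its_lowest_point(self):
        fes = self.two_bowls()
        mins = find_minima(fes, depth_floor=0.2)
        assert len(mins) == 2
        path = find_mfep(fes, mins[0], mins[1])
        ts = path.station_coords("TS")
        assert abs(ts[0]) < 0.08 and abs(ts[1]) < 0.08

    def test_forward_and_reverse_share_saddle_energy(self, reaction_landscape):
        fes = reaction_landscape.fes_grid(81)
        mins = find_minima(fes, depth_floor=2.0)
        mc = min(mins, key=lambda m: np.linalg.norm(m.coords - [-1, 1.1]))
        pc = min(mins, key=lambda m: np.linalg.norm(m.coords - [1.8, 3.4]))
        fwd = find_mfep(fes, mc, pc)
        rev = find_mfep(fes, pc, mc)
        assert fwd.station_F("TS") == pytest.approx(rev.station_F("TS"), abs=1e-9)

    def test_surrogate_saddle_matches_reported_location(self, reaction_landscape):
        fes = reaction_landscape.fes_grid(101)
        mins = find_minima(fes, depth_floor=2.0)
        mc = min(mins, key=lambda m: np.linalg.norm(m.coords - [-1, 1.1]))
        pc = min(mins, key=lambda m: np.linalg.norm(m.coords - [1.8, 3.4]))
        path = find_mfep(fes, mc, pc)
        cell = np.array([ax[1] - ax[0] for ax in fes.axes])
        assert np.all(np.abs(path.station_coords("TS") - [0.7, 0.3]) <= cell + 1e-9)

    def test_identical_endpoints_rejected(self):
        fes = self.two_bowls()
        with pytest.raises(PuckerPathError):
            find_mfep(fes, (0, 0), (0, 0))

    def test_path_connectivity_invariant(self, reaction_landscape):
        fes = reaction_landscape.fes_grid(81)
        mins = find_minima(fes, depth_floor=2.0)
        path = find_mfep(fes, mins[-1], mins[0])
        for p, q in zip(path.path, path.path[1:]):
            assert max(abs(p[0] - q[0]), abs(p[1] - q[1])) == 1


class TestBarriers:
    def test_surrogate_energetics(self, reaction_landscape):
        fes = reaction_landscape.fes_grid(101)
        mins = find_minima(fes, depth_floor=2.0)
        mc = min(mins, key=lambda m: np.linalg.norm(m.coords - [-1, 1.1]))
        pc = min(mins, key=lambda m: np.linalg.norm(m.coords - [1.8, 3.4]))
        path = find_mfep(fes, mc, pc)
        dga, dg0, ics = barrier_and_dg(path)
        assert dga == pytest.approx(19.0, abs=0.25)
        assert dg0 == pytest.approx(-5.0, abs=0.25)
        assert "IC" in ics and ics["IC"] == pytest.approx(-1.0, abs=0.25)

    def test_monotone_descent_has_zero_barrier(self):
        vals = np.linspace(5, 0, 50)[:, None] * np.ones((1, 3))
        path = find_mfep(grid_from(vals), (0, 1), (49, 1))
        dga, dg0, _ = barrier_and_dg(path)
        assert dga == pytest.approx(0.0, abs=1e-12)
        assert dg0 == pytest.approx(-5.0, abs=1e-9)

    def test_reverse_path_swaps_dg0_sign(self, reaction_landscape):
        fes = reaction_landscape.fes_grid(81)
        mins = find_minima(fes, depth_floor=2.0)
        mc = min(mins, key=lambda m: np.linalg.norm(m.coords - [-1, 1.1]))
        pc = min(mins, key=lambda m: np.linalg.norm(m.coords - [1.8, 3.4]))
        fwd = find_mfep(fes, mc, pc)
        dga_f, dg0_f, _ = barrier_and_dg(fwd)
        dga_r, dg0_r, _ = barrier_and_dg(fwd.reversed())
        assert dg0_r == pytest.approx(-dg0_f)
        assert dga_r == pytest.approx(dga_f - dg0_f)  # re-referenced to the new start

    def test_symmetric_double_well_by_construction(self):
        x = np.linspace(-1.5, 1.5, 201)
        b = 6.0
        vals = b * (x**2 - 1) ** 2  # 1D profile embedded in 2D
        fes = FESGrid(axes=(x, np.linspace(0, 1, 3)), values=np.repeat(vals[:, None], 3, axis=1))
        mins = find_minima(fes, depth_floor=1.0)
        path = find_mfep(fes, mins[0], mins[1])
        dga, dg0, _ = barrier_and_dg(path)
        # minima fall between grid points, so the anchor is off by O(dx^2)
        assert dga == pytest.approx(b, abs=1e-2)
        assert dg0 == pytest.approx(0.0, abs=1e-9)

    def test_grid_refinement_stability(self, reaction_landscape):
        out = []
        for n in (101, 201):
            fes = reaction_landscape.fes_grid(n)
            mins = find_minima(fes, depth_floor=2.0)
            mc = min(mins, key=lambda m: np.linalg.norm(m.coords - [-1, 1.1]))
            pc = min(mins, key=lambda m: np.linalg.norm(m.coords - [1.8, 3.4]))
            dga, _, _ = barrier_and_dg(find_mfep(fes, mc, pc))
            out.append(dga)
        assert abs(out[0] - out[1]) < 0.2


class TestProjection:
    def test_projection_preserves_extrema(self, reaction_landscape):
        fes = reaction_landscape.fes_grid(81)
        mins = find_minima(fes, depth_floor=2.0)
        mc = min(mins, key=lambda m: np.linalg.norm(m.coords - [-1, 1.1]))
        pc = min(mins, key=lambda m: np.linalg.norm(m.coords - [1.8, 3.4]))
        path = find_mfep(fes, mc, pc)
        s, f = project_1d(path)
        assert s[0] == 0.0 and s[-1] == pytest.approx(1.0)
        assert f.max() == path.F.max() and f[0] == path.F[0] and f[-1] == path.F[-1]
        dga, _, _ = barrier_and_dg(path)
        assert f.max() == pytest.approx(dga + path.F[0])

    def test_straight_line_on_a_plane_is_linear(self):
        from puckerpath.fes import MFEPResult

        coords = np.column_stack([np.linspace(0, 1, 21), np.zeros(21)])
        path = MFEPResult(
            path=[(i, 0) for i in range(21)],
            coords=coords,
            F=3.0 * coords[:, 0],
            arclength=coords[:, 0],
            stations={"MC": 0, "TS": 20, "PC": 20},
        )
        s, f = project_1d(path)
        assert np.allclose(np.diff(f, 2), 0.0, atol=1e-9)
        assert np.allclose(s, coords[:, 0])

    def test_stage_ordering_on_surrogate(self, reaction_landscape):
        fes = reaction_landscape.fes_grid(101)
        mins = find_minima(fes, depth_floor=2.0)
        mc = min(mins, key=lambda m: np.linalg.norm(m.coords - [-1, 1.1]))
        pc = min(mins, key=lambda m: np.linalg.norm(m.coords - [1.8, 3.4]))
        path = find_mfep(fes, mc, pc)
        st_ = path.stations
        assert st_["MC"] < st_["TS"] < st_["IC"] < st_["PC"]


class TestTubeAverage:
    def path_stub(self):
        coords = np.array([[-1.0, 1.1], [0.7, 0.3], [1.8, 3.4]])
        from puckerpath.fes import MFEPResult

        return MFEPResult(
            path=[(0, 0), (1, 1), (2, 2)],
            coords=coords,
            F=np.array([0.0, 19.0, -5.0]),
            arclength=np.array([0.0, 1.0, 2.0]),
            stations={"MC": 0, "TS": 1, "PC": 2},
        )

    def test_constant_observable_gives_constant_profile(self):
        path = self.path_stub()
        frames = pd.DataFrame({
            "cv1": np.repeat(path.coords[:, 0], 30) ,
            "cv2": np.repeat(path.coords[:, 1], 30),
            "obs": np.ones(90) * 2.5,
        })
        out = tube_average(frames, path, tol=(0.1, 0.1), observables=["obs"])
        assert np.allclose(out["obs"], 2.5)

    def test_observable_equal_to_cv1_tracks_path(self, rng):
        path = self.path_stub()
        cv1 = np.concatenate([c + rng.uniform(-0.08, 0.08, 40) for c in path.coords[:, 0]])
        cv2 = np.concatenate([c + rng.uniform(-0.08, 0.08, 40) for c in path.coords[:, 1]])
        frames = pd.DataFrame({"cv1": cv1, "cv2": cv2, "obs": cv1})
        out = tube_average(frames, path, tol=(0.1, 0.1), observables=["obs"])
        assert np.all(np.abs(out["obs"].to_numpy() - path.coords[:, 0]) <= 0.1)

    def test_bond_distance_means_at_stages(self):
        # fixture interpolates d(C5-C6) from 1.54 at MC to 1.45 at TS
        df = reaction_distance_series(n_frames=301, seed=5, noise=0.01)
        path = self.path_stub()
        out = tube_average(df, path, tol=(0.1, 0.1),
                           cv_cols=["cv1", "cv2"], observables=["dC5C6", "dC4C5"])
        assert out.loc[0, "dC5C6"] == pytest.approx(1.54, abs=0.02)
        assert out.loc[1, "dC5C6"] == pytest.approx(1.45, abs=0.02)
        assert out.loc[0, "dC4C5"] == pytest.approx(1.50, abs=0.02)

    def test_empty_boxes_are_nan_never_interpolated(self):
        path = self.path_stub()
        frames = pd.DataFrame({"cv1": [-1.0], "cv2": [1.1], "obs": [1.0]})
        out = tube_average(frames, path, tol=(0.05, 0.05), observables=["obs"])
        assert np.isnan(out.loc[1, "obs"]) and out.loc[1, "n_frames"] == 0

    def test_all_empty_raises(self):
        path = self.path_stub()
        frames = pd.DataFrame({"cv1": [10.0], "cv2": [10.0], "obs": [1.0]})
        with pytest.raises(PuckerPathError):
            tube_average(frames, path, tol=(0.1, 0.1), observables=["obs"])

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(PuckerPathError):
            tube_average(pd.DataFrame({"cv1": [0], "cv2": [0]}), self.path_stub(), tol=(0.0, 0.1))
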
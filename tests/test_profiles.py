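"""Axis profiles, kymographs, demographs, profile matrices and clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cellaxis import profiles, synthetic
from cellaxis.core import ImageStack, Mesh, MeshFrame
from cellaxis.errors import ClusterError, DissimilarityError, EmptyCell, MissingFrame
from cellaxis.profiles import (
    axis_profile,
    bin_profiles_by_percent,
    cluster_profiles,
    demograph,
    dissimilarity_matrix,
    kymograph,
    profile_matrix,
)


def pixel_frame(l, intensity):
    return pd.DataFrame({"l": np.asarray(l, float), "intensity": np.asarray(intensity, float)})


class TestAxisProfile:
    def test_uniform_intensity_gives_flat_profile(self):
        l = np.linspace(-4.9, 4.9, 200)
        prof = axis_profile(pixel_frame(l, np.full(200, 3.0)), length=10.0, n_bins=25)
        assert prof.values == pytest.approx(np.full(25, 3.0))
        assert not prof.interpolated.any()

    def test_linear_gradient_matches_per_bin_mean_oracle(self, rng):
        l = rng.uniform(-5, 5, 500)
        prof = axis_profile(pixel_frame(l, l), length=10.0, n_bins=20)
        edges = np.linspace(-0.5, 0.5, 21)
        rel = l / 10.0
        for b in range(20):
            sel = (rel >= edges[b]) & (rel < edges[b + 1]) if b < 19 else (rel >= edges[b])
            if sel.any():
                assert prof.values[b] == pytest.approx(l[sel].mean(), abs=1e-9)

    def test_single_pixel_cell_interpolates_rest(self):
        prof = axis_profile(pixel_frame([0.0], [9.0]), length=10.0, n_bins=11)
        assert prof.interpolated.sum() == 10
        assert prof.values == pytest.approx(np.full(11, 9.0))  # edge extension

    def test_no_pixels_raises(self):
        with pytest.raises(EmptyCell):
            axis_profile(pixel_frame([], []), length=10.0)


class TestKymograph:
    def test_uniform_movie_gives_constant_matrix(self):
        mesh = Mesh("c0", 0, synthetic.make_mesh("rod", 20, 8, (16, 16), 0.0, 40))
        records = [
            MeshFrame.from_meshes([Mesh("c0", f, mesh.vertices)]).records[0] for f in range(5)
        ]
        stack = ImageStack(frames=[np.full((32, 32), 4.0)] * 5)
        k = kymograph(records, stack, n_bins=15)
        assert k.matrix.shape == (5, 15)
        assert k.matrix == pytest.approx(np.full((5, 15), 4.0))

    def test_planted_band_sweep_tracked_within_one_bin(self):
        mf, stack, centers = synthetic.sweeping_band_movie(n_frames=20)
        k = kymograph(list(mf), stack, n_bins=25, track_id="band")
        argmax = k.matrix.argmax(axis=1)
        true_bins = np.clip(((centers + 0.5) * 25).astype(int), 0, 24)
        assert np.abs(argmax - true_bins).max() <= 1

    def test_missing_frame_raises(self):
        mesh = Mesh("c0", 3, synthetic.make_mesh("rod", 20, 8, (16, 16), 0.0, 40))
        records = MeshFrame.from_meshes([mesh]).records
        stack = ImageStack(frames=[np.zeros((32, 32))])
        with pytest.raises(MissingFrame):
            kymograph(records, stack)


class TestDemograph:
    def profiles_df(self, rows):
        return pd.DataFrame(rows).T if isinstance(rows, dict) else rows

    def test_rows_ordered_by_length(self):
        prof = pd.DataFrame(
            {0: [1.0, 2.0], 1: [3.0, 4.0]}, index=["long", "short"]
        )
        lengths = pd.DataFrame({"cell_id": ["long", "short"], "length": [4.0, 2.0]})
        d = demograph(prof, lengths)
        assert d.cell_ids == ["short", "long"]
        assert d.matrix[0].tolist() == [2.0, 4.0]

    def test_normalization_scales_rows_to_unit_peak(self):
        prof = pd.DataFrame({0: [2.0], 1: [4.0]}, index=["c"])
        lengths = pd.DataFrame({"cell_id": ["c"], "length": [3.0]})
        d = demograph(prof, lengths, normalize=True)
        assert d.matrix.max() == 1.0

    def test_invariant_to_input_order(self, rng):
        ids = [f"c{i}" for i in range(30)]
        prof = pd.DataFrame(rng.uniform(0, 1, (30, 10)), index=ids)
        lengths = pd.DataFrame({"cell_id": ids, "length": rng.uniform(2, 6, 30)})
        a = demograph(prof, lengths)
        perm = rng.permutation(30)
        b = demograph(prof.iloc[perm], lengths.iloc[rng.permutation(30)])
        assert a.cell_ids == b.cell_ids
        assert a.matrix == pytest.approx(b.matrix)


class TestProfileMatrix:
    def annotated(self, tid, p, f):
        return pd.DataFrame(
            {"track_id": tid, "percentage": p, "fluor": f, "cycle": 0, "complete": True}
        )

    def test_constant_fluorescence_gives_constant_row(self):
        pm = profile_matrix(self.annotated("t0", [0.0, 50.0, 100.0], [5.0, 5.0, 5.0]))
        assert pm.values.loc["t0"].to_numpy() == pytest.approx(np.full(101, 5.0))

    def test_linear_fluorescence_interpolates_linearly(self):
        pm = profile_matrix(self.annotated("t0", [0.0, 100.0], [0.0, 10.0]))
        assert pm.values.loc["t0"].to_numpy() == pytest.approx(pm.grid / 10.0)

    def test_matches_piecewise_linear_oracle(self, rng):
        p = np.sort(rng.uniform(0, 100, 12))
        p[0], p[-1] = 0.0, 100.0
        f = rng.normal(size=12)
        pm = profile_matrix(self.annotated("t0", p, f))
        for g in [0.0, 17.3, 50.0, 99.9]:
            i = np.searchsorted(p, g, side="right") - 1
            i = min(i, len(p) - 2)
            w = (g - p[i]) / (p[i + 1] - p[i])
            expect = f[i] * (1 - w) + f[i + 1] * w
            assert np.interp(g, pm.grid, pm.values.loc["t0"]) == pytest.approx(expect, abs=1e-9)

    def test_short_tracks_excluded(self):
        ann = pd.concat(
            [
                self.annotated("ok", [0.0, 100.0], [1.0, 2.0]),
                self.annotated("short", [50.0], [1.0]),
            ]
        )
        pm = profile_matrix(ann)
        assert pm.excluded == ["short"]
        assert list(pm.values.index) == ["ok"]

    def test_extrapolation_flagged(self):
        pm = profile_matrix(self.annotated("t0", [20.0, 80.0], [1.0, 2.0]))
        assert pm.extrapolated.loc["t0", 0.0]
        assert not pm.extrapolated.loc["t0", 50.0]


class TestDissimilarity:
    def test_identical_rows_distance_zero(self):
        v = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]], index=["a", "b"])
        D = dissimilarity_matrix(v)
        assert D == pytest.approx(np.zeros((2, 2)))

    def test_symmetric_zero_diagonal(self, rng):
        v = rng.uniform(0, 1, (10, 6))
        D = dissimilarity_matrix(v)
        assert D == pytest.approx(D.T)
        assert np.diag(D) == pytest.approx(np.zeros(10))

    def test_anticorrelated_rows_have_dissimilarity_two(self):
        v = pd.DataFrame([[0.0, 1.0, 2.0], [2.0, 1.0, 0.0]], index=["a", "b"])
        D = dissimilarity_matrix(v, method="correlation")
        assert D[0, 1] == pytest.approx(2.0)

    def test_zero_variance_row_named_in_error(self):
        v = pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]], index=["flatcell", "ok"])
        with pytest.raises(DissimilarityError, match="flatcell"):
            dissimilarity_matrix(v, method="correlation")


class TestClustering:
    def test_k1_puts_everyone_in_one_cluster(self, rng):
        v = pd.DataFrame(rng.uniform(0, 1, (8, 5)))
        r = cluster_profiles(dissimilarity_matrix(v), 1, profiles=v)
        assert (r.labels == 1).all()
        assert r.summary["fraction"].tolist() == [1.0]

    def test_k_larger_than_n_rejected(self, rng):
        v = rng.uniform(0, 1, (4, 5))
        with pytest.raises(ClusterError):
            cluster_profiles(dissimilarity_matrix(v), 5)

    def test_two_planted_archetypes_recovered(self, rng):
        # step-down vs flat, noise at 10% of separation
        grid = np.linspace(0, 100, 21)
        step = np.where(grid < 50, 1.0, 0.2)
        flat = np.full_like(grid, 0.6)
        sep = np.linalg.norm(step - flat) / np.sqrt(len(grid))
        rows, truth = [], []
        for i in range(100):
            base = step if i % 2 == 0 else flat
            rows.append(base + rng.normal(0, 0.1 * sep, len(grid)))
            truth.append(i % 2)
        v = pd.DataFrame(rows)
        r = cluster_profiles(dissimilarity_matrix(v), 2, profiles=v)
        assert adjusted_rand_score(truth, r.labels) >= 0.9

    def test_three_archetype_cohort_recovered_with_mean_profiles(self):
        cohort, truth = synthetic.simulate_profile_cohort(n_cells=90, seed=5)
        pm = profile_matrix(cohort)
        D = dissimilarity_matrix(pm.znormalized())
        r = cluster_profiles(D, 3, profiles=pm.values)
        assert adjusted_rand_score(truth.labels.loc[r.labels.index], r.labels) >= 0.9
        # each recovered cluster mean tracks its archetype within the noise band
        noise = truth.params["noise_sd"]
        for c in r.summary["cluster"]:
            members = r.labels[r.labels == c].index
            arch = truth.labels.loc[members].mode()[0]
            curve = synthetic.ARCHETYPES[arch](pm.grid)
            mean = r.mean_profiles[r.mean_profiles["cluster"] == c]["mean"].to_numpy()
            assert np.abs(mean - curve).max() <= 4 * noise

    def test_labels_ordered_by_cluster_size(self, rng):
        v = np.vstack([np.zeros((6, 4)), np.ones((3, 4)) * 5])
        v = pd.DataFrame(v + rng.normal(0, 0.01, v.shape))
        r = cluster_profiles(dissimilarity_matrix(v), 2, profiles=v)
        assert (r.labels.iloc[:6] == 1).all()
        assert (r.labels.iloc[6:] == 2).all()


class TestBinProfilesByPercent:
    def test_means_match_group_by(self, rng):
        prof = rng.uniform(0, 1, (40, 8))
        pct = rng.uniform(0, 100, 40)
        out = bin_profiles_by_percent(prof, pct)
        edges = np.linspace(0, 100, 11)
        idx = np.minimum(np.digitize(pct, edges) - 1, 9)
        for b in range(10):
            if (idx == b).any():
                assert out[b] == pytest.approx(prof[idx == b].mean(axis=0))
            else:
                assert np.isnan(out[b]).all()
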
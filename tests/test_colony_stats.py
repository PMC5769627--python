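"""Colony identification, radial trends, smoothing, hex overlays, gating."""

import numpy as np
import pandas as pd
import pytest

from rdpi.colony_stats import (
    hex_bin_index,
    hex_center,
    hex_overlay,
    identify_colonies,
    percent_positive,
    radial_trend,
    smooth_profile,
)
from rdpi.rd import RadialProfile
from rdpi.synthetic import ColonySpec, GradientSpec, apply_gradient, generate_colony_layout


def grid_cells(shape=(3, 3), pitch=1500.0, diameter=1000.0, n_cells=250, seed=0):
    return generate_colony_layout(
        ColonySpec(diameter=diameter, n_cells=n_cells, layout="grid",
                   grid_shape=shape, grid_pitch=pitch, seed=seed)
    )


class TestIdentifyColonies:
    def test_two_distant_disks_two_colonies(self):
        cells = grid_cells(shape=(1, 2), pitch=3000.0, n_cells=300)
        out = identify_colonies(cells, eps_um=100.0, min_samples=5)
        assert out[out.colony_id >= 0].colony_id.nunique() == 2

    def test_chain_within_eps_single_colony(self):
        xy = np.arange(0, 500, 10.0)
        cells = pd.DataFrame({"well": "A1", "field": 1, "cell_id": range(len(xy)),
                              "x_um": xy, "y_um": 0.0})
        out = identify_colonies(cells, eps_um=50.0, min_samples=3)
        assert out.colony_id.nunique() == 1
        assert (out.colony_id == 0).all()

    def test_grid_layout_recovers_nine_colonies_and_centroids(self):
        cells = grid_cells()
        out = identify_colonies(cells, eps_um=150.0, min_samples=5)
        good = out[out.colony_id >= 0]
        assert good.colony_id.nunique() == 9
        # centroid accuracy: within 2x mean nearest-neighbor spacing
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=2).fit(cells[["x_um", "y_um"]])
        d, _ = nn.kneighbors()
        tol = 2 * d[:, -1].mean()
        for (cx, cy), grp in good.groupby(["true_cx_um", "true_cy_um"]):
            assert abs(grp.cx_um.iloc[0] - cx) < tol
            assert abs(grp.cy_um.iloc[0] - cy) < tol

    def test_matches_eps_graph_connected_components_oracle(self):
        from scipy.sparse.csgraph import connected_components
        from sklearn.neighbors import radius_neighbors_graph

        cells = grid_cells(shape=(2, 2), pitch=2000.0, n_cells=250, seed=3)
        eps = 120.0
        out = identify_colonies(cells, eps_um=eps, min_samples=3)
        # with dense colonies every point is core, so DBSCAN partition equals
        # the connected components of the eps-neighborhood graph
        g = radius_neighbors_graph(cells[["x_um", "y_um"]].to_numpy(), eps)
        _, comp = connected_components(g, directed=False)
        pairs = set(zip(out.colony_id, comp))
        assert len(pairs) == out.colony_id.nunique() == len(set(comp))

    def test_row_order_permutation_gives_same_partition(self):
        cells = grid_cells(shape=(1, 3), pitch=2000.0, seed=4)
        out1 = identify_colonies(cells, eps_um=120.0, min_samples=5)
        shuffled = cells.sample(frac=1.0, random_state=9).reset_index(drop=True)
        out2 = identify_colonies(shuffled, eps_um=120.0, min_samples=5)
        merged = out2.set_index("cell_id").loc[out1.cell_id]
        # same partition up to label renaming: label pairs form a bijection
        mapping = set(zip(out1.colony_id, merged.colony_id))
        assert len(mapping) == out1.colony_id.nunique()

    def test_nonpositive_eps_rejected(self):
        cells = grid_cells(shape=(1, 1))
        with pytest.raises(ValueError, match="eps"):
            identify_colonies(cells, eps_um=0.0)


def labeled_gradient_cells(n_cells=4000, noise=0.05, seed=5):
    cells = generate_colony_layout(
        ColonySpec(diameter=1000.0, n_cells=n_cells, layout="grid",
                   grid_shape=(1, 4), grid_pitch=2000.0, seed=seed)
    )
    cells = apply_gradient(cells, GradientSpec(profile=lambda r: r, noise_sd=noise),
                           seed=seed)
    return identify_colonies(cells, eps_um=150.0, min_samples=5)


class TestRadialTrend:
    def test_constant_channel_flat_profile(self):
        cells = labeled_gradient_cells(noise=0.0)
        cells["flat"] = 2.0
        prof = radial_trend(cells, "flat", n_bins=10)
        assert np.allclose(prof.mean, 2.0)
        assert np.allclose(prof.sd, 0.0)

    def test_identity_gradient_recovered_within_3_se(self):
        cells = labeled_gradient_cells()
        prof = radial_trend(cells, "ch1", n_bins=10)
        se = prof.sd / np.sqrt(prof.n) + 1e-9
        # bin means lie on the identity line (r_frac normalized per colony)
        assert np.all(np.abs(prof.mean - prof.r_frac) < 4 * se + 0.02)

    def test_ci_matches_t_interval_closed_form(self):
        # two colonies with constant intensities c and c+d
        cells = grid_cells(shape=(1, 2), pitch=3000.0, n_cells=200, seed=6)
        out = identify_colonies(cells, eps_um=150.0, min_samples=5)
        c, d = 1.0, 0.4
        out["ch"] = np.where(out.true_colony_id == 0, c, c + d)
        prof = radial_trend(out, "ch", n_bins=3)
        from scipy.stats import t

        sd = np.std([c, c + d], ddof=1)  # = d / sqrt(2)
        expected_ci = t.ppf(0.975, 1) * sd / np.sqrt(2)
        assert np.allclose(prof.ci95, expected_ci, rtol=1e-10)
        assert np.allclose(prof.mean, c + d / 2)

    def test_translation_invariance(self):
        cells = labeled_gradient_cells(n_cells=500)
        moved = cells.copy()
        moved["x_um"] += 1e4
        moved["y_um"] -= 3e3
        relabeled = identify_colonies(
            moved[["well", "field", "cell_id", "x_um", "y_um", "ch1"]],
            eps_um=150.0, min_samples=5)
        p1 = radial_trend(cells, "ch1", n_bins=8)
        p2 = radial_trend(relabeled, "ch1", n_bins=8)
        assert np.allclose(p1.mean, p2.mean)

    def test_missing_channel_rejected(self):
        cells = labeled_gradient_cells(n_cells=200)
        with pytest.raises(ValueError, match="channel"):
            radial_trend(cells, "nope")


class TestSmoothProfile:
    @staticmethod
    def profile_from(y):
        x = np.arange(len(y), dtype=float)
        return RadialProfile(r_um=x, r_frac=x / len(y), mean=np.asarray(y, float))

    def test_low_degree_polynomial_unchanged(self):
        x = np.arange(20.0)
        y = 0.5 + 0.3 * x - 0.02 * x**2 + 0.001 * x**3
        sm = smooth_profile(self.profile_from(y), window=7, polyorder=3)
        assert np.allclose(sm.mean, y, atol=1e-9)

    def test_constant_series_unchanged(self):
        sm = smooth_profile(self.profile_from(np.full(15, 4.2)), window=5, polyorder=2)
        assert np.allclose(sm.mean, 4.2)

    def test_impulse_response_matches_least_squares_oracle(self):
        # central SG coefficient set = first row of (X^T X)^-1 X^T for the
        # local polynomial design matrix, computed here independently
        window, polyorder = 7, 3
        half = window // 2
        X = np.vander(np.arange(-half, half + 1), polyorder + 1, increasing=True)
        coeffs = np.linalg.lstsq(X, np.eye(window), rcond=None)[0][0]
        y = np.zeros(31)
        y[15] = 1.0
        sm = smooth_profile(self.profile_from(y), window=window, polyorder=polyorder)
        assert np.allclose(sm.mean[15 - half:15 + half + 1], coeffs[::-1], atol=1e-12)

    def test_window_larger_than_series_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile(self.profile_from(np.ones(5)), window=7, polyorder=2)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile(self.profile_from(np.ones(15)), window=6, polyorder=2)


class TestHexOverlay:
    def test_single_cell_single_bin(self):
        cells = labeled_gradient_cells(n_cells=500).iloc[:1].copy()
        ov = hex_overlay(cells, "ch1", hex_size_um=50.0)
        assert len(ov.mean) == 1
        assert ov.bounds == (ov.mean[0], ov.mean[0])

    def test_bin_assignment_matches_brute_force_nearest_center(self):
        rng = np.random.default_rng(7)
        xy = rng.uniform(-300, 300, size=(400, 2))
        size = 40.0
        qr = hex_bin_index(xy, size)
        # enumerate candidate centers over a generous axial range
        q0, r0 = np.meshgrid(np.arange(-15, 16), np.arange(-15, 16))
        cand = np.stack([q0.ravel(), r0.ravel()], axis=1)
        centers = hex_center(cand, size)
        nearest = cand[np.argmin(
            ((xy[:, None, :] - centers[None, :, :]) ** 2).sum(-1), axis=1)]
        assert np.array_equal(qr, nearest)

    def test_radially_symmetric_gradient_depends_only_on_radius(self):
        cells = labeled_gradient_cells(n_cells=30000, noise=0.0, seed=8)
        ov = hex_overlay(cells, "ch1", hex_size_um=60.0)
        r = np.hypot(ov.centers[:, 0], ov.centers[:, 1]) / 500.0
        # azimuthal symmetry: bins at the same center radius agree with each
        # other regardless of angle (well-populated interior bins)
        df = pd.DataFrame({"r": np.round(r, 3), "mean": ov.mean, "n": ov.n})
        df = df[(df.n > 20) & (df.r < 0.9)]
        spread = df.groupby("r")["mean"].agg(lambda v: v.max() - v.min())
        groups = df.groupby("r").size()
        assert np.max(spread[groups >= 3]) < 0.03

    def test_pooling_identical_colonies_equals_single_colony(self):
        single = labeled_gradient_cells(n_cells=2000, noise=0.0, seed=9)
        one = single[single.colony_id == 0]
        ov_one = hex_overlay(one, "ch1", hex_size_um=50.0)
        ov_all = hex_overlay(single, "ch1", hex_size_um=50.0)
        # same gradient in every colony: pooled means equal per-bin means
        d_one = {tuple(c): m for c, m in zip(np.round(ov_one.centers, 6), ov_one.mean)}
        d_all = {tuple(c): m for c, m in zip(np.round(ov_all.centers, 6), ov_all.mean)}
        common = set(d_one) & set(d_all)
        assert common
        # noise-free radial gradient: identical up to which cells landed in bin
        for k in common:
            assert abs(d_one[k] - d_all[k]) < 0.05

    def test_empty_input_rejected(self):
        cells = labeled_gradient_cells(n_cells=200).iloc[:0]
        with pytest.raises(ValueError):
            hex_overlay(cells, "ch1")


class TestPercentPositive:
    def test_gate_zero_everything_positive(self):
        cells = labeled_gradient_cells(n_cells=400)
        pp = percent_positive(cells, "ch1", gate=0.0)
        assert (pp.fraction == 1.0).all()

    def test_gate_above_max_nothing_positive(self):
        cells = labeled_gradient_cells(n_cells=400)
        pp = percent_positive(cells, "ch1", gate=cells.ch1.max() + 1)
        assert (pp.fraction == 0.0).all()

    def test_monotone_nonincreasing_in_gate(self):
        cells = labeled_gradient_cells(n_cells=800)
        fracs = [percent_positive(cells, "ch1", gate=g).fraction.mean()
                 for g in [0.1, 0.3, 0.5, 0.7]]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_otsu_gate_recovers_mixture_fraction(self):
        rng = np.random.default_rng(10)
        n, frac_pos = 4000, 0.3
        pos = rng.random(n) < frac_pos
        intensity = np.where(pos, rng.lognormal(2.0, 0.25, n), rng.lognormal(0.0, 0.25, n))
        cells = generate_colony_layout(ColonySpec(diameter=1000.0, n_cells=n, seed=11))
        cells["mix"] = intensity
        out = identify_colonies(cells, eps_um=150.0, min_samples=5)
        pp = percent_positive(out, "mix")  # default Otsu gate
        se = np.sqrt(frac_pos * (1 - frac_pos) / n)
        assert abs(pp.fraction.iloc[0] - frac_pos) < 3 * se + 0.02
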
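import numpy as np
import pandas as pd
import pytest

import betascale as bs
from betascale.grains import topo_metrics, upscale_environment
from betascale.io import SOIL_VARS, ValidationError


@pytest.mark.parametrize(
    "g,n,area",
    [(20, 130, 5.2), (30, 48, 4.32), (40, 30, 4.8), (50, 20, 5.0)],
)
def test_grain_designs_on_standard_plot(g, n, area):
    d = bs.make_grain_design((260.0, 200.0), g)
    assert d.n_grains == n
    assert d.covered_area_ha == pytest.approx(area, abs=1e-12)
    assert d.n_x == int(260 // g) and d.n_y == int(200 // g)


def test_identity_tiling_and_errors():
    d = bs.make_grain_design((100.0, 100.0), 100.0)
    assert d.n_grains == 1 and d.covered_area_ha == pytest.approx(1.0)
    with pytest.raises(ValueError):
        bs.make_grain_design((100.0, 100.0), 120.0)
    with pytest.raises(ValueError):
        bs.make_grain_design((100.0, 100.0), 0.0)


def test_footprints_disjoint_and_inside():
    d = bs.make_grain_design((260.0, 200.0), 30.0)
    org = d.origins
    assert len(np.unique(org, axis=0)) == d.n_grains
    assert (org >= 0).all()
    assert (org[:, 0] + d.grain_size <= 260.0 + 1e-9).all()
    assert (org[:, 1] + d.grain_size <= 200.0 + 1e-9).all()


class TestAggregation:
    def test_single_stem_lands_in_origin_grain(self):
        sm = bs.StemMap(
            260.0, 200.0,
            pd.DataFrame({"x": [0.0], "y": [0.0], "species": ["A"], "dbh": [5.0]}),
        )
        cm = bs.aggregate_community(sm, bs.make_grain_design((260.0, 200.0), 20.0))
        assert cm.counts.to_numpy().sum() == 1
        assert cm.counts.loc[0, "A"] == 1

    def test_remainder_strip_excluded(self):
        sm = bs.StemMap(
            260.0, 200.0,
            pd.DataFrame({"x": [259.5], "y": [199.5], "species": ["A"], "dbh": [5.0]}),
        )
        cm = bs.aggregate_community(sm, bs.make_grain_design((260.0, 200.0), 30.0))
        assert cm.counts.to_numpy().sum() == 0
        assert cm.counts.shape[1] == 0  # zero-total species dropped

    def test_full_coverage_column_sums_match_species_counts(self, rng):
        n = 500
        stems = pd.DataFrame(
            {
                "x": rng.uniform(0, 260, n),
                "y": rng.uniform(0, 200, n),
                "species": rng.choice(["A", "B", "C"], n),
                "dbh": 1.0 + rng.exponential(7, n),
            }
        )
        sm = bs.StemMap(260.0, 200.0, stems)
        cm = bs.aggregate_community(sm, bs.make_grain_design((260.0, 200.0), 20.0))
        expect = stems["species"].value_counts()
        for sp in expect.index:
            assert cm.counts[sp].sum() == expect[sp]

    def test_row_order_invariance(self, rng, tiny_stem_map):
        d = bs.make_grain_design((260.0, 200.0), 20.0)
        a = bs.aggregate_community(tiny_stem_map, d).counts
        shuffled = bs.StemMap(
            260.0, 200.0, tiny_stem_map.stems.sample(frac=1, random_state=1).reset_index(drop=True)
        )
        b = bs.aggregate_community(shuffled, d).counts
        pd.testing.assert_frame_equal(a, b)

    def test_dimension_mismatch(self, tiny_stem_map):
        with pytest.raises(ValidationError, match="dimensions"):
            bs.aggregate_community(tiny_stem_map, bs.make_grain_design((100.0, 100.0), 20.0))


def _sample_table(field, base=20.0):
    return field.sample_table(base_grain=base)


class TestUpscaling:
    @pytest.mark.parametrize("method", ["block_mean", "kriging"])
    def test_identity_at_native_scale(self, method, mixed_scenario):
        _, _, table = mixed_scenario
        d = bs.make_grain_design((260.0, 200.0), 20.0)
        out = upscale_environment(table, d, method=method)
        want = table.samples.sort_values(["cy", "cx"]).reset_index(drop=True)
        for v in SOIL_VARS:
            np.testing.assert_allclose(out[v].to_numpy(), want[v].to_numpy(), atol=1e-9)

    @pytest.mark.parametrize("method", ["block_mean", "kriging"])
    def test_constant_field_constant_predictions(self, method):
        d20 = bs.make_grain_design((260.0, 200.0), 20.0)
        c = d20.centroids
        df = pd.DataFrame({"cx": c[:, 0], "cy": c[:, 1]})
        for v in SOIL_VARS:
            df[v] = 5.0
        table = bs.EnvSampleTable(df)
        d40 = bs.make_grain_design((260.0, 200.0), 40.0)
        out = upscale_environment(table, d40, method=method)
        np.testing.assert_allclose(out.to_numpy(), 5.0, atol=1e-6)

    def test_block_mean_conserves_mean_on_nested_design(self, rng):
        # 160 x 160 plot: the 40 m design nests the 20 m base design exactly
        d20 = bs.make_grain_design((160.0, 160.0), 20.0)
        c = d20.centroids
        df = pd.DataFrame({"cx": c[:, 0], "cy": c[:, 1]})
        for v in SOIL_VARS:
            df[v] = rng.uniform(1, 10, len(c))
        table = bs.EnvSampleTable(df)
        out = upscale_environment(table, bs.make_grain_design((160.0, 160.0), 40.0))
        for v in SOIL_VARS:
            assert out[v].mean() == pytest.approx(df[v].mean(), abs=1e-12)

    def test_unknown_method_and_too_few_samples(self, mixed_scenario):
        _, _, table = mixed_scenario
        d = bs.make_grain_design((260.0, 200.0), 40.0)
        with pytest.raises(ValueError, match="method"):
            upscale_environment(table, d, method="idw")
        small = bs.EnvSampleTable(table.samples.iloc[:5])
        with pytest.raises(ValidationError, match="10 samples"):
            upscale_environment(small, d, method="kriging")

    def test_kriging_beats_block_mean_on_smooth_field(self):
        """Monte Carlo over 50 replicate exponential random fields (simulated
        exactly at the sample and target points): mean kriging RMSE at the
        40 m grain centers does not exceed the block-mean RMSE."""
        from scipy.spatial.distance import cdist

        d20 = bs.make_grain_design((260.0, 200.0), 20.0)
        d40 = bs.make_grain_design((260.0, 200.0), 40.0)
        pts, targets = d20.centroids, d40.centroids
        allp = np.vstack([pts, targets])
        C = 25.0 * np.exp(-cdist(allp, allp) / 60.0)
        L = np.linalg.cholesky(C + 1e-8 * np.eye(len(allp)))
        rmse_k, rmse_b = [], []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            z = 100.0 + L @ rng.standard_normal(len(allp))
            df = pd.DataFrame({"cx": pts[:, 0], "cy": pts[:, 1]})
            for v in SOIL_VARS:
                df[v] = z[: len(pts)]
            table = bs.EnvSampleTable(df)
            truth = z[len(pts):]
            k = upscale_environment(table, d40, method="kriging")["om"].to_numpy()
            b = upscale_environment(table, d40, method="block_mean")["om"].to_numpy()
            rmse_k.append(np.sqrt(np.mean((k - truth) ** 2)))
            rmse_b.append(np.sqrt(np.mean((b - truth) ** 2)))
        assert np.mean(rmse_k) <= np.mean(rmse_b)


class TestTopography:
    def _vertex_frame(self, fn, g=20.0, plot=(260.0, 200.0)):
        d = bs.make_grain_design(plot, g)
        v = d.vertices()
        return pd.DataFrame({"vx": v[:, 0], "vy": v[:, 1], "elev": fn(v[:, 0], v[:, 1])})

    def test_flat_field(self):
        vt = self._vertex_frame(lambda x, y: np.full_like(x, 100.0))
        d = bs.make_grain_design((260.0, 200.0), 20.0)
        out = topo_metrics(vt, d)
        np.testing.assert_allclose(out["slope"], 0.0, atol=1e-9)
        np.testing.assert_allclose(out["convexity"], 0.0, atol=1e-9)
        np.testing.assert_allclose(out["aspect"], 0.0, atol=1e-9)
        assert out["flat"].all()

    def test_inclined_plane_closed_form(self):
        vt = self._vertex_frame(lambda x, y: 0.1 * x)
        d = bs.make_grain_design((260.0, 200.0), 20.0)
        out = topo_metrics(vt, d)
        np.testing.assert_allclose(out["slope"], np.degrees(np.arctan(0.1)), atol=1e-9)
        np.testing.assert_allclose(out["aspect"], 270.0, atol=1e-9)
        assert not out["flat"].any()
        # interior grains of a plane have symmetric neighborhoods
        interior = [
            iy * d.n_x + ix for ix in range(1, d.n_x - 1) for iy in range(1, d.n_y - 1)
        ]
        np.testing.assert_allclose(out.loc[interior, "convexity"], 0.0, atol=1e-9)
        # edge grains see a one-sided neighborhood, so convexity is nonzero there
        assert out.loc[0, "convexity"] != 0.0

    def test_interior_bump_positive_convexity(self):
        d = bs.make_grain_design((100.0, 100.0), 20.0)

        def fn(x, y):
            # raise only the vertices of the central grain (40..60, 40..60)
            z = np.zeros_like(x)
            inside = (x >= 40) & (x <= 60) & (y >= 40) & (y <= 60)
            return z + 5.0 * inside

        out = topo_metrics(self._vertex_frame(fn, plot=(100.0, 100.0)), d)
        center = 2 * d.n_x + 2  # grain (ix=2, iy=2)
        assert out.loc[center, "convexity"] > 0
        assert out.loc[center, "convexity"] == out["convexity"].max()

    def test_vertex_interpolation_for_30m_design(self, mixed_scenario):
        env, _, table = mixed_scenario
        d30 = bs.make_grain_design((260.0, 200.0), 30.0)
        out = topo_metrics(table.vertex_elevations, d30)
        assert len(out) == d30.n_grains
        assert out["mean_elev"].notna().all()
        # mean elevation should track the underlying surface (bilinear
        # interpolation from the 20 m lattice loses some fine structure)
        truth = env.values("elev", d30.centroids)
        assert np.corrcoef(out["mean_elev"], truth)[0, 1] > 0.9
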
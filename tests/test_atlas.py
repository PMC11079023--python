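"""Multi-SAM alignment, polar-grid averaging and the statistics toolbox.

Every statistic is checked against an independent brute-force oracle on
small inputs (exhaustive rank / ECDF computation), never against itself.
"""
import numpy as np
import pandas as pd
import pytest

from gasig._geometry import PolarGrid
from gasig.atlas import (
    SAMSample,
    align_sams,
    average_map,
    atlas_to_dataframe,
    ks_two_sample,
    kruskal_wallis,
    pca_cells,
    region_intensity_ratio,
    spearman,
    welch_ttest,
)
from gasig.regions import PrimordiumDisc, RegionGeometry


# ----------------------------------------------------------------- oracles
def brute_spearman(x, y):
    """Pearson correlation of average ranks, computed from first principles."""

    def ranks(v):
        v = np.asarray(v, dtype=float)
        r = np.empty(len(v))
        for i, vi in enumerate(v):
            less = np.sum(v < vi)
            equal = np.sum(v == vi)
            r[i] = less + (equal + 1) / 2.0
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def brute_ks(a, b):
    """Sup distance between the two ECDFs, swept over every sample point."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    grid = np.concatenate([a, b])
    d = 0.0
    for t in grid:
        d = max(d, abs(np.mean(a <= t) - np.mean(b <= t)))
    return d


class TestSpearman:
    def test_perfectly_monotone(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman(x, x)[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_ties_match_brute_force(self):
        x = [1.0, 2.0, 2.0, 3.0]
        y = [1.0, 3.0, 2.0, 4.0]
        assert spearman(x, y)[0] == pytest.approx(brute_spearman(x, y), abs=1e-12)

    def test_random_small_inputs_match_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.integers(0, 5, size=8).astype(float)
            y = rng.integers(0, 5, size=8).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert spearman(x, y)[0] == pytest.approx(brute_spearman(x, y), abs=1e-12)

    def test_constant_input_flagged(self):
        with pytest.warns(UserWarning):
            rho, p = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rho)


class TestKolmogorovSmirnov:
    def test_identical_samples(self):
        assert ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])[0] == 0.0

    def test_disjoint_singletons(self):
        assert ks_two_sample([0.0], [1.0])[0] == 1.0

    def test_shifted_triples_match_ecdf_sweep(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        assert ks_two_sample(a, b)[0] == pytest.approx(brute_ks(a, b), abs=1e-12)

    def test_random_small_inputs_match_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 9))
            b = rng.normal(size=rng.integers(2, 9))
            assert ks_two_sample(a, b)[0] == pytest.approx(brute_ks(a, b), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestOtherTests:
    def test_welch_symmetric_under_swap(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0]
        t1, p1 = welch_ttest(a, b)
        t2, p2 = welch_ttest(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_kruskal_detects_separation(self):
        _, p = kruskal_wallis([1, 2, 3, 4], [10, 11, 12, 13], [20, 21, 22, 23])
        assert p < 0.05


class TestPCA:
    def test_perfectly_correlated_pair(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        res = pca_cells(df, ["a", "b"])
        assert res.explained_variance_pct[0] == pytest.approx(100.0, abs=1e-9)

    def test_independent_variables_share_variance(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(100_000, 4)), columns=list("abcd"))
        res = pca_cells(df, list("abcd"))
        np.testing.assert_allclose(res.explained_variance_pct, 25.0, atol=2.0)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(500, 3)), columns=list("abc"))
        r1 = pca_cells(df, list("abc"))
        r2 = pca_cells(df, list("abc"))
        np.testing.assert_array_equal(r1.loadings, r2.loadings)
        for k in range(r1.loadings.shape[1]):
            j = np.argmax(np.abs(r1.loadings[:, k]))
            assert r1.loadings[j, k] > 0

    def test_zero_variance_variable_dropped(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50), "c": 1.0})
        with pytest.warns(UserWarning):
            res = pca_cells(df, ["a", "b", "c"])
        assert res.variables == ["a", "b"]


class TestAlignment:
    @staticmethod
    def _sample(sam_id, rotation_deg=0.0, offset=(0.0, 0.0), n=40, seed=0):
        rng = np.random.default_rng(seed)
        r = 25.0 * np.sqrt(rng.uniform(size=n))
        th = rng.uniform(0, 2 * np.pi, size=n)
        x = r * np.cos(th)
        y = r * np.sin(th)
        sig = 1.5 + r / 25.0  # radial signaling pattern
        a = np.deg2rad(rotation_deg)
        xr = x * np.cos(a) - y * np.sin(a) + offset[0]
        yr = x * np.sin(a) + y * np.cos(a) + offset[1]
        obs = pd.DataFrame(
            {"cell_id": np.arange(n), "x_um": xr, "y_um": yr, "signaling": sig}
        )
        return SAMSample(
            sam_id=sam_id,
            observations=obs,
            clv3_centroid_xy_um=offset,
            ref_primordium_azimuth_deg=rotation_deg,
        )

    def test_single_sample_centred_at_clv3(self):
        s = self._sample("a", offset=(12.0, -5.0))
        _, pooled = align_sams([s])
        r_direct = np.hypot(
            s.observations.x_um - 12.0, s.observations.y_um + 5.0
        )
        np.testing.assert_allclose(np.sort(pooled.r_um), np.sort(r_direct), atol=1e-9)

    def test_rotated_copy_recovers_rotation(self):
        a = self._sample("a", seed=7)
        b = self._sample("b", rotation_deg=40.0, offset=(6.0, 3.0), seed=7)
        _, pooled = align_sams([a, b])
        pa = pooled[pooled.sam == "a"].sort_values("cell_id")
        pb = pooled[pooled.sam == "b"].sort_values("cell_id")
        np.testing.assert_allclose(
            pa[["x_um", "y_um"]].to_numpy(), pb[["x_um", "y_um"]].to_numpy(), atol=1e-6
        )

    def test_sample_without_reference_skipped(self):
        a = self._sample("a")
        b = SAMSample("b", a.observations.copy(), clv3_centroid_xy_um=None)
        transforms, pooled = align_sams([a, b])
        assert len(transforms) == 1
        assert set(pooled.sam) == {"a"}
        with pytest.raises(ValueError):
            align_sams([b])


class TestAverageMap:
    grid = PolarGrid(r_max_um=30.0, dr_um=5.0, dtheta_deg=90.0)

    def test_single_observation_single_bin(self):
        obs = pd.DataFrame(
            {"sam": ["a"], "r_um": [7.0], "azimuth_deg": [45.0], "signaling": [2.2]}
        )
        atlas = average_map(obs, self.grid)
        assert atlas.n.sum() == 1
        assert atlas.mean["signaling"][1, 0] == pytest.approx(2.2)
        assert atlas.mean["signaling"].mask.sum() == atlas.mean["signaling"].size - 1

    def test_two_constant_sams_average(self):
        rng = np.random.default_rng(0)
        rows = []
        for sam, value in (("a", 2.0), ("b", 2.4)):
            for _ in range(200):
                rows.append(
                    dict(sam=sam, r_um=rng.uniform(0, 29), azimuth_deg=rng.uniform(0, 360),
                         signaling=value)
                )
        atlas = average_map(pd.DataFrame(rows), self.grid)
        both = atlas.mean["signaling"][~atlas.mean["signaling"].mask]
        assert np.all((both >= 2.0) & (both <= 2.4))
        pooled = pd.DataFrame(rows)
        assert atlas.mean["signaling"].mean() == pytest.approx(2.2, abs=0.1)

    def test_atlas_of_identical_copies_matches_single(self):
        rng = np.random.default_rng(1)
        obs = pd.DataFrame(
            {"sam": "a", "r_um": rng.uniform(0, 29, 100),
             "azimuth_deg": rng.uniform(0, 360, 100),
             "signaling": rng.uniform(0, 3, 100)}
        )
        single = average_map(obs, self.grid)
        tripled = average_map(
            pd.concat([obs.assign(sam=s) for s in "abc"], ignore_index=True), self.grid
        )
        np.testing.assert_allclose(
            single.mean["signaling"].filled(np.nan),
            tripled.mean["signaling"].filled(np.nan),
            atol=1e-12, equal_nan=True,
        )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        obs = pd.DataFrame(
            {"sam": rng.choice(list("ab"), 100), "r_um": rng.uniform(0, 29, 100),
             "azimuth_deg": rng.uniform(0, 360, 100), "signaling": rng.uniform(0, 3, 100)}
        )
        a = average_map(obs, self.grid)
        b = average_map(obs.iloc[::-1].reset_index(drop=True), self.grid)
        np.testing.assert_allclose(
            a.mean["signaling"].filled(np.nan), b.mean["signaling"].filled(np.nan),
            atol=1e-12, equal_nan=True,
        )

    def test_empty_rejected_and_dataframe_roundtrip(self):
        with pytest.raises(ValueError):
            average_map(pd.DataFrame(), self.grid)
        obs = pd.DataFrame(
            {"sam": ["a"], "r_um": [7.0], "azimuth_deg": [45.0], "signaling": [2.2]}
        )
        df = atlas_to_dataframe(average_map(obs, self.grid))
        assert len(df) == 1
        assert df.iloc[0].signaling == pytest.approx(2.2)


class TestRegionIntensityRatio:
    geometry = RegionGeometry(
        sam_center_xy_um=(30.0, 30.0),
        cz_radius_um=10.0,
        primordia=[PrimordiumDisc((50.0, 30.0), 6.0, 2)],
        outer_radius_um=28.0,
    )

    def _image(self, ipr_level, other_level, noise=0.0, seed=0):
        from gasig.regions import region_masks

        rng = np.random.default_rng(seed)
        masks = region_masks(self.geometry, (60, 60), (1.0, 1.0))
        img = np.zeros((60, 60))
        img[masks["CZ"]] = other_level
        img[masks["P"]] = other_level
        img[masks["IPR"]] = ipr_level
        return img + rng.normal(0.0, noise, img.shape)

    def test_uniform_image_ratio_one(self):
        assert region_intensity_ratio(self._image(10.0, 10.0), self.geometry) == pytest.approx(1.0)

    def test_twofold_enrichment(self):
        assert region_intensity_ratio(self._image(20.0, 10.0), self.geometry) == pytest.approx(2.0)

    def test_enrichment_recovered_under_noise(self):
        img = self._image(18.0, 10.0, noise=1.0, seed=3)
        assert region_intensity_ratio(img, self.geometry) == pytest.approx(1.8, abs=0.05)

    def test_empty_region_rejected(self):
        geom = RegionGeometry(
            sam_center_xy_um=(500.0, 500.0), cz_radius_um=10.0, outer_radius_um=20.0
        )
        with pytest.raises(ValueError):
            region_intensity_ratio(np.ones((60, 60)), geom)
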
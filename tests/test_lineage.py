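"""Temporal registration, lineage assignment and growth measurement."""
import numpy as np
import pandas as pd
import pytest

from gasig._geometry import RigidTransform
from gasig.cellseg import CellLabelMap, extract_L1
from gasig.lineage import (
    LineageMap,
    RegistrationError,
    build_lineage,
    compute_growth,
    growth_to_dataframe,
    register_timepoints,
)
from gasig.stack import ImageStack


def _gt_map(gt, stack):
    return extract_L1(CellLabelMap.from_volume(gt.cell_label_volume, stack.voxel_spacing_um))


class TestRegistration:
    def test_identity_for_identical_stacks(self, dome50_noisy):
        _, stack, _ = dome50_noisy
        tr = register_timepoints(stack, stack)
        assert abs(tr.rotation_deg) <= 0.2
        assert np.all(np.abs(tr.translation_um) < 0.5)

    def test_recovers_generator_drift(self, drift_series):
        spec, frames = drift_series
        (s0, _), (s1, g1) = frames
        tr = register_timepoints(s0, s1)
        true = g1.transform
        assert tr.rotation_deg == pytest.approx(true.rotation_deg, abs=1.0)
        err = np.abs(np.array(tr.translation_um) - np.array(true.translation_um))
        assert np.all(err <= np.array(spec.voxel_spacing_um))  # within one voxel

    def test_recovers_pure_z_shift(self, dome50_noisy):
        _, stack, _ = dome50_noisy
        shifted = ImageStack(
            channels={k: np.roll(v, 2, axis=0) for k, v in stack.channels.items()},
            voxel_spacing_um=stack.voxel_spacing_um,
        )
        tr = register_timepoints(stack, shifted)
        assert tr.translation_um[0] == pytest.approx(2.0 * stack.voxel_spacing_um[0], abs=0.5)

    def test_uncorrelated_stacks_rejected(self, dome50_noisy):
        _, stack, _ = dome50_noisy
        rng = np.random.default_rng(0)
        junk = ImageStack(
            channels={"wall": rng.normal(100.0, 5.0, size=stack.shape)},
            voxel_spacing_um=stack.voxel_spacing_um,
        )
        with pytest.raises(RegistrationError):
            register_timepoints(stack, junk, min_correlation=0.5)

    def test_transform_composition_consistency(self):
        """Chaining the two interval registrations of a 3-frame series agrees
        with the composed ground-truth drift."""
        from gasig.synthgen import SyntheticSAMSpec, generate_timelapse

        spec = SyntheticSAMSpec(
            n_cells_l1=80, seed=13,
            growth_field={"CZ": 0.0, "IPR": 0.0, "P": 0.0}, division_fraction=0.0,
        )
        frames = generate_timelapse(spec, n_frames=3)
        t01 = register_timepoints(frames[0][0], frames[1][0])
        t12 = register_timepoints(frames[1][0], frames[2][0])
        chained = t12.compose(t01)
        true02 = frames[2][1].transform.compose(frames[1][1].transform)
        assert chained.rotation_deg == pytest.approx(true02.rotation_deg, abs=1.5)
        err = np.abs(np.array(chained.translation_um) - np.array(true02.translation_um))
        assert np.all(err < 1.5)


class TestLineage:
    def test_identity_without_division_or_drift(self):
        vol = np.zeros((4, 20, 20), dtype=np.int32)
        vol[1:3, :10] = 1
        vol[1:3, 10:] = 2
        m = CellLabelMap.from_volume(vol, (1.0, 1.0, 1.0))
        lin = build_lineage(m, m, RigidTransform(), 10.0)
        assert lin.pairs == {1: [1], 2: [2]}
        assert lin.orphans == []

    def test_division_maps_parent_to_two_children(self):
        """Under drift without growth, overlap tracking recovers every
        division as exactly two children of the true parent. (Strong radial
        growth displaces rim cells by about a cell diameter per interval, so
        curated lineages are used for growth maps — see the growth tests.)"""
        from gasig.synthgen import SyntheticSAMSpec, generate_timelapse

        spec = SyntheticSAMSpec(
            n_cells_l1=100, seed=17, division_fraction=0.2,
            growth_field={"CZ": 0.0, "IPR": 0.0, "P": 0.0},
        )
        (s0, g0), (s1, g1) = generate_timelapse(spec, n_frames=2)
        m0 = _gt_map(g0, s0)
        m1 = _gt_map(g1, s1)
        lin = build_lineage(m0, m1, g1.transform, spec.interval_h)
        true_div = {p: c for p, c in g1.lineage.items() if len(c) == 2}
        assert len(true_div) > 5
        for p, c in true_div.items():
            assert sorted(lin.pairs.get(p, [])) == c

    def test_corrections_override_verbatim(self):
        vol = np.zeros((4, 20, 20), dtype=np.int32)
        vol[1:3, :10] = 1
        vol[1:3, 10:] = 2
        m = CellLabelMap.from_volume(vol, (1.0, 1.0, 1.0))
        corrections = pd.DataFrame([{"parent_label": 1, "child_label": 2}])
        lin = build_lineage(m, m, RigidTransform(), 10.0, corrections=corrections)
        assert lin.pairs == {1: [1, 2]}

    def test_child_cannot_have_two_parents(self):
        with pytest.raises(ValueError):
            LineageMap(transform=RigidTransform(), pairs={1: [3], 2: [3]}, interval_h=10.0)


def _column_map(footprint: np.ndarray, label: int, spacing=(1.0, 1.0, 1.0)) -> CellLabelMap:
    vol = np.zeros((3,) + footprint.shape, dtype=np.int32)
    vol[1][footprint] = label
    return CellLabelMap.from_volume(vol, spacing)


def _disc(shape, center, radii):
    yy, xx = np.mgrid[: shape[0], : shape[1]].astype(float)
    return ((xx - center[0]) / radii[0]) ** 2 + ((yy - center[1]) / radii[1]) ** 2 <= 1.0


class TestGrowth:
    def test_zero_growth(self):
        fp = _disc((60, 60), (30, 30), (10, 10))
        m = _column_map(fp, 1)
        lin = LineageMap(transform=RigidTransform(), pairs={1: [1]}, interval_h=10.0)
        (rec,) = compute_growth(m, m, lin, l1_only=False)
        assert rec.growth_intensity_per_h == pytest.approx(0.0)
        assert rec.anisotropy == pytest.approx(0.0, abs=1e-6)

    def test_area_doubling_rate(self):
        fp1 = _disc((80, 80), (40, 40), (10, 10))
        fp2 = _disc((80, 80), (40, 40), (10 * np.sqrt(2), 10 * np.sqrt(2)))
        m1, m2 = _column_map(fp1, 1), _column_map(fp2, 1)
        lin = LineageMap(transform=RigidTransform(), pairs={1: [1]}, interval_h=10.0)
        (rec,) = compute_growth(m1, m2, lin, l1_only=False)
        assert rec.growth_intensity_per_h == pytest.approx(0.1, rel=0.05)
        assert rec.anisotropy == pytest.approx(0.0, abs=0.01)

    def test_uniaxial_stretch_anisotropy_one_third(self):
        fp1 = _disc((100, 100), (50, 50), (12, 12))
        fp2 = _disc((100, 100), (50, 50), (24, 12))  # x2 along x
        m1, m2 = _column_map(fp1, 1), _column_map(fp2, 1)
        lin = LineageMap(transform=RigidTransform(), pairs={1: [1]}, interval_h=10.0)
        (rec,) = compute_growth(m1, m2, lin, l1_only=False)
        assert rec.anisotropy == pytest.approx(1.0 / 3.0, abs=0.01)
        assert abs(rec.principal_direction[0]) == pytest.approx(1.0, abs=0.01)

    def test_pure_rotation_gives_zero_anisotropy(self):
        fp1 = _disc((100, 100), (50, 50), (20, 8))
        fp2 = _disc((100, 100), (50, 50), (8, 20))  # same ellipse rotated 90 deg
        m1, m2 = _column_map(fp1, 1), _column_map(fp2, 1)
        lin = LineageMap(transform=RigidTransform(), pairs={1: [1]}, interval_h=10.0)
        (rec,) = compute_growth(m1, m2, lin, l1_only=False)
        assert rec.anisotropy == pytest.approx(0.0, abs=0.01)

    def test_log_growth_option(self):
        fp1 = _disc((80, 80), (40, 40), (10, 10))
        fp2 = _disc((80, 80), (40, 40), (10 * np.sqrt(2), 10 * np.sqrt(2)))
        m1, m2 = _column_map(fp1, 1), _column_map(fp2, 1)
        lin = LineageMap(transform=RigidTransform(), pairs={1: [1]}, interval_h=10.0)
        (rec,) = compute_growth(m1, m2, lin, l1_only=False, log_growth=True)
        assert rec.growth_intensity_per_h == pytest.approx(np.log(2.0) / 10.0, rel=0.05)

    def test_imposed_field_recovered_per_region(self, growth_series):
        """Per-region mean growth within 10% and anisotropy within 0.05 of the
        generator-imposed values, with >= 30 cells per region (expert
        lineages, as in a curated analysis)."""
        spec, frames = growth_series
        (s0, g0), (s1, g1) = frames
        m0, m1 = _gt_map(g0, s0), _gt_map(g1, s1)
        lin = LineageMap(transform=g1.transform, pairs=g1.lineage, interval_h=spec.interval_h)
        df = (
            growth_to_dataframe(compute_growth(m0, m1, lin))
            .drop(columns=["region"])
            .merge(g1.growth_truth, on="parent")
        )
        stats = df.groupby("region").agg(
            n=("parent", "size"),
            gi=("growth_intensity_per_h", "mean"),
            gi_true=("growth_intensity_true", "mean"),
            an=("anisotropy", "mean"),
            an_true=("anisotropy_true", "mean"),
        )
        assert (stats.n >= 30).all(), stats.n.to_dict()
        for region, row in stats.iterrows():
            assert row.gi == pytest.approx(row.gi_true, rel=0.10), region
            assert abs(row.an - row.an_true) < 0.05, region

    def test_anisotropy_scale_invariant(self):
        fp1 = _disc((100, 100), (50, 50), (12, 12))
        fp2 = _disc((100, 100), (50, 50), (24, 12))
        m1 = _column_map(fp1, 1)
        m2 = _column_map(fp2, 1)
        m1h = _column_map(fp1, 1, spacing=(1.0, 0.5, 0.5))
        m2h = _column_map(fp2, 1, spacing=(1.0, 0.5, 0.5))
        lin = LineageMap(transform=RigidTransform(), pairs={1: [1]}, interval_h=10.0)
        a = compute_growth(m1, m2, lin, l1_only=False)[0].anisotropy
        b = compute_growth(m1h, m2h, lin, l1_only=False)[0].anisotropy
        assert a == pytest.approx(b, abs=1e-6)
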
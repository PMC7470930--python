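"""The generator: distribution helpers, geometry realization, slicing."""

import math

import numpy as np
import pytest

from spinemorph.geometry import measure_series, object_volume
from spinemorph.synthetic import (
    SynthGroupConfig,
    build_geometry,
    generate_dataset,
    lognormal_params_from_mean_median,
    sample_spine_population,
    slice_to_series,
)


def _config(**overrides):
    base = dict(
        genotype="WT", age_months=1, n_dendrites=2,
        dendrite_length_mean=6.0, dendrite_length_sd=0.5,
        spine_density=2.0, head_volume_mean=0.050, head_volume_median=0.027,
        neck_length_mean=1.0, neck_length_sd=0.5, perforation_prob=0.05,
    )
    base.update(overrides)
    return SynthGroupConfig(**base)


class TestLognormalParams:
    def test_degenerate_zero_variance(self):
        mu, sigma = lognormal_params_from_mean_median(0.04, 0.04)
        assert sigma == 0.0
        assert math.exp(mu) == pytest.approx(0.04)

    def test_mean_below_median_rejected(self):
        with pytest.raises(ValueError):
            lognormal_params_from_mean_median(0.02, 0.03)

    @pytest.mark.parametrize(
        "mean,median", [(0.050, 0.027), (0.089, 0.030), (0.143, 0.047)]
    )
    def test_monte_carlo_recovers_moments(self, mean, median):
        mu, sigma = lognormal_params_from_mean_median(mean, median)
        assert mu == pytest.approx(math.log(median))
        assert sigma == pytest.approx(math.sqrt(2 * math.log(mean / median)))
        draws = np.random.default_rng(0).lognormal(mu, sigma, 10**6)
        assert draws.mean() == pytest.approx(mean, rel=0.01)
        assert np.median(draws) == pytest.approx(median, rel=0.02)


class TestSamplePopulation:
    def test_poisson_spine_counts(self):
        cfg = _config(n_dendrites=7, dendrite_length_mean=9.2,
                      dendrite_length_sd=1.6, spine_density=2.0)
        truth = sample_spine_population(cfg, np.random.default_rng(1))
        total = sum(d.n_spines for d in truth.dendrites)
        expected = 2.0 * sum(d.arc_length for d in truth.dendrites)
        assert abs(total - expected) <= 3 * math.sqrt(expected)

    def test_noise_free_psd_coupling_is_exact_ratio(self):
        cfg = _config(psd_noise_sd=1e-12, psd_coupling_slope=0.8)
        truth = sample_spine_population(cfg, np.random.default_rng(2))
        small = [s for s in truth.spines if s.psd_cos_outer > -0.59]  # unclamped
        ratios = [s.psd_area / s.head_volume for s in small]
        assert np.ptp(ratios) < 1e-6
        assert ratios[0] == pytest.approx(0.8, rel=1e-6)

    def test_zero_slope_marginal_rate(self):
        cfg = _config(perforation_prob=0.2, perforation_volume_odds_slope=1e-9,
                      n_dendrites=40, spine_density=3.0,
                      dendrite_length_mean=10.0)
        truth = sample_spine_population(cfg, np.random.default_rng(3))
        rate = np.mean([s.perforated for s in truth.spines])
        n = len(truth.spines)
        assert abs(rate - 0.2) <= 3 * math.sqrt(0.2 * 0.8 / n)

    def test_calibrated_slope_preserves_marginal_rate(self):
        cfg = _config(perforation_prob=0.2, perforation_volume_odds_slope=1.5,
                      n_dendrites=40, spine_density=3.0,
                      dendrite_length_mean=10.0)
        truth = sample_spine_population(cfg, np.random.default_rng(4))
        rate = np.mean([s.perforated for s in truth.spines])
        n = len(truth.spines)
        assert abs(rate - 0.2) <= 3 * math.sqrt(0.2 * 0.8 / n)
        # and perforated spines skew large
        perf = [s.head_volume for s in truth.spines if s.perforated]
        rest = [s.head_volume for s in truth.spines if not s.perforated]
        assert np.median(perf) > np.median(rest)

    def test_neck_lengths_respect_floor(self):
        truth = sample_spine_population(_config(), np.random.default_rng(5))
        assert all(s.neck_length >= 0.05 for s in truth.spines)


class TestBuildGeometry:
    def test_head_radius_from_volume(self):
        truth = sample_spine_population(_config(), np.random.default_rng(6))
        for s in truth.spines:
            assert s.head_radius == pytest.approx(
                (3 * s.head_volume / (4 * math.pi)) ** (1 / 3)
            )

    def test_neck_gap_equals_truth(self):
        cfg = _config()
        rng = np.random.default_rng(7)
        truth = sample_spine_population(cfg, rng)
        scenes = build_geometry(truth, cfg, rng)
        by_id = {s.spine_id: s for s in truth.spines}
        for scene in scenes:
            axis = scene.axis
            for sp in scene.spines:
                t = by_id[sp.spine_id]
                # head centre sits exactly shaft_radius + neck + head_radius
                # from its anchor on the axis
                d = np.min(np.linalg.norm(axis - sp.head_center, axis=1))
                gap = d - scene.shaft_radius - t.head_radius
                assert gap == pytest.approx(t.neck_length, abs=0.02)

    def test_realized_arc_length_recorded(self):
        cfg = _config()
        rng = np.random.default_rng(8)
        truth = sample_spine_population(cfg, rng)
        scenes = build_geometry(truth, cfg, rng)
        for d, scene in zip(truth.dendrites, scenes):
            seg = np.diff(scene.axis, axis=0)
            assert d.arc_length == pytest.approx(
                float(np.sum(np.linalg.norm(seg, axis=1))), rel=1e-9
            )


class TestSliceToSeries:
    def test_sphere_section_count(self):
        """A 0.2 µm sphere at 50 nm sections spans 8 or 9 nonempty sections."""
        cfg = _config(spine_density=1.0, dendrite_length_mean=5.0,
                      head_volume_mean=0.0335, head_volume_median=0.0335)
        # fixed-volume heads: V = 4/3 pi 0.2^3
        rng = np.random.default_rng(9)
        truth = sample_spine_population(cfg, rng)
        scenes = build_geometry(truth, cfg, rng)
        found = 0
        for scene in scenes:
            md, contours, hier = slice_to_series(scene, 50.0, 4.5)
            for sp in scene.spines:
                n_sec = len({c.section for c in contours if c.object_id == sp.spine_id})
                assert n_sec in (8, 9)
                found += 1
        assert found >= 1

    def test_end_to_end_sphere_volume_within_5pct(self):
        cfg = _config(spine_density=1.0, dendrite_length_mean=5.0,
                      head_volume_mean=0.0335, head_volume_median=0.0335)
        rng = np.random.default_rng(10)
        truth = sample_spine_population(cfg, rng)
        scenes = build_geometry(truth, cfg, rng)
        expected = 4 / 3 * math.pi * 0.2**3
        checked = 0
        for scene in scenes:
            md, contours, hier = slice_to_series(scene, 50.0, 4.5)
            for sp in scene.spines:
                head = [c for c in contours if c.object_id == sp.spine_id]
                v = object_volume(head, md.section_thickness_um)
                assert v == pytest.approx(expected, rel=0.05)
                checked += 1
        assert checked >= 1

    def test_annular_psd_yields_disjoint_traces(self, tiny_group):
        """Every perforated spine's PSD shows two traces in some section."""
        _, truth, series, _ = tiny_group
        perforated = {s.spine_id for s in truth.spines if s.perforated}
        if not perforated:
            pytest.skip("no perforated spines drawn in fixture group")
        for md, contours, hier in series:
            for sid in perforated:
                psd = [c for c in contours if c.object_id == f"{sid}_psd"]
                if not psd:
                    continue
                per_section = {}
                for c in psd:
                    per_section[c.section] = per_section.get(c.section, 0) + 1
                assert max(per_section.values()) >= 2

    def test_series_passes_validation_and_measures(self, tiny_group):
        _, truth, series, _ = tiny_group
        for md, contours, hier in series:
            hier.validate()
            m = measure_series(md, contours, hier)
            assert all(s.head_volume > 0 for s in m.spines)


class TestGenerateDataset:
    def test_determinism_same_seed(self, tmp_path):
        cfgs = [_config()]
        d1, d2 = tmp_path / "a", tmp_path / "b"
        m1 = generate_dataset(cfgs, master_seed=42, out_dir=d1)
        m2 = generate_dataset(cfgs, master_seed=42, out_dir=d2)
        assert m1.equals(m2)
        for f in sorted(p.name for p in d1.glob("*")):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        cfgs = [_config()]
        m1 = generate_dataset(cfgs, master_seed=1, out_dir=tmp_path / "a")
        m2 = generate_dataset(cfgs, master_seed=2, out_dir=tmp_path / "b")
        assert not m1["n_contours"].equals(m2["n_contours"])

    def test_duplicate_labels_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="duplicate"):
            generate_dataset([_config(), _config()], 1, tmp_path)

    def test_paper_scale_preset_counts(self):
        from spinemorph.presets import paper_scale

        cfgs = paper_scale()
        assert len(cfgs) == 8
        assert sum(c.n_dendrites for c in cfgs) == 65
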
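"""Process density, turnover rings, protrusions and contact sites."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mitomorph import morphology, simulate, spatial
from mitomorph.spatial import (build_process_map, classify_protrusion,
                               contact_site_density, number_density,
                               radial_rings, soma_distance_um,
                               turnover_ratio)


def _toy_object(center_um=(2.0, 2.0), angle_deg=0.0, length_um=2.0,
                width_nm=150.0, shape_px=(160, 160), pixel_size_nm=25.0):
    spec = simulate.ObjectSpec(center_um, angle_deg, length_um, width_nm)
    foot = simulate.capsule_footprint(spec, shape_px, pixel_size_nm)
    objs, _ = morphology.label_objects(foot, pixel_size_nm=pixel_size_nm)
    assert len(objs) == 1
    return objs[0], foot


class TestProcessMap:
    def test_blank_image_zero_length(self):
        pm = build_process_map(np.zeros((64, 64)), pixel_size_nm=25.0)
        assert pm.total_length_um == 0.0

    def test_isolated_19px_speck_removed(self):
        img = np.zeros((128, 128))
        img[60:70, 30:110] = 30.0          # a real process band
        img[10:14, 10:15] = 50.0
        img[10, 14] = 0.0                  # 19-px speck
        pm = build_process_map(img, pixel_size_nm=25.0)
        assert not pm.mask[:20, :20].any()

    def test_straight_neurite_length_recovered(self):
        """A 120-um straight neurite with mitochondria on it is recovered
        within 10% of its planted length."""
        from scipy import ndimage
        rng = np.random.default_rng(13)
        h, w = 200, 4800                  # 5 x 120 um at 25 nm/px
        img = np.full((h, w), 5.0)
        ribbon = np.zeros((h, w), dtype=bool)
        ribbon[80:120, :] = True          # 1-um-wide straight process
        img += 6.0 * ndimage.gaussian_filter(ribbon.astype(float), 2.0)
        cfg = simulate.SimConfig(image_size_px=(h, w), poisson_noise=False,
                                 gaussian_read_sigma=0.0)
        for k in range(12):
            spec = simulate.ObjectSpec((5.0 + k * 9.5, 2.5),
                                       float(rng.uniform(-15, 15)), 2.0,
                                       180.0)
            patch = simulate.render_membrane_object(spec, cfg)
            ph, pw = patch.shape
            r0, c0 = 100 - ph // 2, int(spec.center_um[0] / 0.025) - pw // 2
            img[r0:r0 + ph, c0:c0 + pw] += 150.0 * patch
        img = rng.poisson(img).astype(float)
        pm = build_process_map(img, pixel_size_nm=25.0)
        assert pm.total_length_um == pytest.approx(120.0, rel=0.10)

    def test_length_invariant_to_scaling_above_cap(self):
        rng = np.random.default_rng(4)
        img = rng.poisson(5.0, (256, 256)).astype(float)
        img[100:110, 20:240] += 25.0
        pm1 = build_process_map(img, pixel_size_nm=25.0)
        img2 = img.copy()
        img2[img2 > 20] *= 10.0            # brighten far above the cap
        pm2 = build_process_map(img2, pixel_size_nm=25.0)
        assert pm2.total_length_um == pytest.approx(pm1.total_length_um,
                                                    rel=0.10)


class TestNumberDensity:
    def test_density_arithmetic(self):
        pm = spatial.ProcessMap(np.zeros((4, 4), bool),
                                np.zeros((4, 4), bool), 60.0, 25.0)
        assert number_density(12, pm) == pytest.approx(0.2)

    def test_zero_objects_zero_density(self):
        pm = spatial.ProcessMap(np.zeros((4, 4), bool),
                                np.zeros((4, 4), bool), 60.0, 25.0)
        assert number_density(0, pm) == 0.0

    def test_zero_length_withheld(self):
        pm = spatial.ProcessMap(np.zeros((4, 4), bool),
                                np.zeros((4, 4), bool), 0.0, 25.0)
        with pytest.raises(ValueError):
            number_density(5, pm)

    def test_equal_planted_densities_indistinguishable(self):
        """Two compartments planted at the same density give counts whose
        two-sided Poisson comparison accepts equality in >= 90% of seeds."""
        rng = np.random.default_rng(0)
        passes = 0
        n_seeds = 20
        for _ in range(n_seeds):
            length_a = length_b = 100.0
            counts_a = rng.poisson(0.25 * length_a)
            counts_b = rng.poisson(0.25 * length_b)
            # exact binomial split test of two Poisson rates
            p = stats.binomtest(counts_a, counts_a + counts_b, 0.5).pvalue
            passes += p > 0.05
        assert passes >= 0.9 * n_seeds


class TestTurnover:
    def test_pure_old_signal_gives_zero(self):
        obj, foot = _toy_object()
        old = np.where(foot, 10.0, 0.0)
        assert turnover_ratio(obj, old, np.zeros_like(old)) == 0.0

    def test_pure_new_signal_gives_one(self):
        obj, foot = _toy_object()
        new = np.where(foot, 10.0, 0.0)
        assert turnover_ratio(obj, np.zeros_like(new), new) == 1.0

    def test_zero_over_zero_undefined(self):
        obj, _ = _toy_object()
        z = np.zeros((160, 160))
        assert np.isnan(turnover_ratio(obj, z, z))

    def test_planted_gradient_recovered_per_ring(self):
        """Ring means track the planted soma-to-distal refreshment line
        within 0.05 despite shot noise."""
        cfg = simulate.SimConfig(image_size_px=(1024, 1024), seed=31,
                                 n_mitochondria=25, n_mds=15,
                                 turnover_ratio_at_soma=0.8,
                                 turnover_slope_per_um=0.02)
        field = simulate.generate_field(cfg)
        from mitomorph.segment import (apply_region_exclusion,
                                       binarize_global, refine_mask)
        mask = binarize_global(field.structural, "auto")
        mask = refine_mask(mask, [("fill_holes", None), ("erode", None),
                                  ("erode", None), ("remove_small", 8)])
        mask = apply_region_exclusion(mask, field.soma_mask)
        objects, _ = morphology.label_objects(mask, field.structural)
        ratios = [turnover_ratio(o, field.channels["old"],
                                 field.channels["new"]) for o in objects]
        rings = radial_rings(objects, field.soma_mask, ratios,
                             pixel_size_nm=cfg.pixel_size_nm,
                             ring_width_um=4.0)
        for _, row in rings.iterrows():
            d_mid = (row.inner_um + row.outer_um) / 2
            planted = np.clip(0.8 - 0.02 * d_mid, 0.02, 0.98)
            assert row["mean"] == pytest.approx(planted, abs=0.05)

    def test_ring_means_follow_planted_monotone_trend(self, clean_field,
                                                      clean_objects):
        """With a decreasing planted gradient, ring means never correlate
        positively with distance (Spearman <= 0)."""
        objects, _, _ = clean_objects
        ratios = [turnover_ratio(o, clean_field.channels["old"],
                                 clean_field.channels["new"])
                  for o in objects]
        rings = radial_rings(objects, clean_field.soma_mask, ratios,
                             pixel_size_nm=clean_field.cfg.pixel_size_nm,
                             ring_width_um=3.0)
        sub = rings[rings["object_class"] == "all"]
        if len(sub) >= 3:
            rho = stats.spearmanr(sub["ring"], sub["mean"]).statistic
            assert rho <= 0


class TestRadialRings:
    def _soma(self, shape=(400, 400), radius_px=40):
        yy, xx = np.mgrid[:shape[0], :shape[1]]
        return (yy - shape[0] // 2) ** 2 + (xx - shape[1] // 2) ** 2 \
            <= radius_px ** 2

    def _objects_at(self, cols, shape=(400, 400)):
        mask = np.zeros(shape, dtype=bool)
        for c in cols:
            mask[198:202, c:c + 4] = True
        objs, _ = morphology.label_objects(mask, pixel_size_nm=25.0)
        return objs

    def test_ring_assignment_half_open(self):
        """Distance 45 um lands in ring 1; exactly 30 um also in ring 1."""
        # pixels: soma edge at col 240 (radius 40 px = 1 um at 25 nm/px)
        soma = self._soma()
        # place objects at controlled distances using a large ring width
        objs = self._objects_at([300, 360])
        d = soma_distance_um(objs, soma, 25.0)
        rings = np.floor(d / 1.0)
        assert rings[1] > rings[0]
        out = radial_rings(objs, soma, [0.5, 0.5], pixel_size_nm=25.0,
                           ring_width_um=1.0)
        assert set(out["ring"]) == set(int(r) for r in rings)

    def test_centroid_inside_soma_excluded(self):
        soma = self._soma()
        objs = self._objects_at([198, 300])   # first sits inside the soma
        out = radial_rings(objs, soma, [0.4, 0.6], pixel_size_nm=25.0,
                           ring_width_um=1.0)
        assert out["n"].sum() == 1

    def test_identical_values_have_zero_sd(self):
        soma = self._soma()
        objs = self._objects_at([300, 320])
        out = radial_rings(objs, soma, [0.7, 0.7], pixel_size_nm=25.0,
                           ring_width_um=50.0)
        assert (out["sd"] == 0).all()

    def test_every_object_in_exactly_one_ring(self, clean_field,
                                              clean_objects):
        objects, _, _ = clean_objects
        values = np.ones(len(objects))
        out = radial_rings(objects, clean_field.soma_mask, values,
                           pixel_size_nm=clean_field.cfg.pixel_size_nm,
                           ring_width_um=2.0)
        d = soma_distance_um(objects, clean_field.soma_mask,
                             clean_field.cfg.pixel_size_nm)
        assert out["n"].sum() == int((d >= 0).sum())

    def test_ring0_normalization(self):
        soma = self._soma()
        objs = self._objects_at([260, 300, 360])
        out = radial_rings(objs, soma, [10.0, 5.0, 2.0],
                           pixel_size_nm=25.0, ring_width_um=0.5,
                           normalize_to_ring0=True)
        first = out.sort_values("ring").iloc[0]
        assert first["mean"] == pytest.approx(1.0)


class TestProtrusions:
    @pytest.mark.parametrize("frac,expected", [
        (0.10, "tip"), (0.40, "side"), (0.25, "tip"), (0.75, "tip"),
        (0.60, "side"), (0.90, "tip"),
    ])
    def test_quarters_rule(self, frac, expected):
        obj, _ = _toy_object(center_um=(2.0, 2.0), angle_deg=0.0,
                             length_um=2.0)
        anchor = (2.0 + (frac - 0.5) * 2.0, 2.0 - 0.095)
        rec = classify_protrusion(obj, anchor, parent_length_um=2.0)
        assert rec.position_class == expected
        assert rec.axial_fraction == pytest.approx(frac, abs=0.02)

    def test_marker_call_against_background(self):
        obj, _ = _toy_object()
        ch = np.full((160, 160), 10.0)
        ch[75:85, 110:120] = 100.0
        anchor_hot = (115 * 0.025, 80 * 0.025)
        anchor_cold = (20 * 0.025, 20 * 0.025)
        rec_hot = classify_protrusion(obj, anchor_hot,
                                      parent_length_um=2.0,
                                      marker_channels={"px": ch},
                                      background=(10.0, 2.0))
        rec_cold = classify_protrusion(obj, anchor_cold,
                                       parent_length_um=2.0,
                                       marker_channels={"px": ch},
                                       background=(10.0, 2.0))
        assert rec_hot.marker_calls["px"] == "+"
        assert rec_cold.marker_calls["px"] == "-"

    def test_planted_tip_fraction_recovered(self):
        """Classifying planted protrusions by their ground-truth anchors
        recovers the planted tip fraction within binomial bounds."""
        cfg = simulate.SimConfig(image_size_px=(1024, 1024), seed=41,
                                 n_mitochondria=25, n_mds=0,
                                 n_protrusions=40,
                                 protrusion_tip_fraction=0.5,
                                 poisson_noise=False,
                                 gaussian_read_sigma=0.0)
        field = simulate.generate_field(cfg)
        hits = 0
        n = len(field.truth_protrusions)
        for _, row in field.truth_protrusions.iterrows():
            parent = field.truth.iloc[int(row.parent_id)]
            spec = simulate.ObjectSpec(
                (parent.center_x_um, parent.center_y_um), parent.angle_deg,
                parent.true_length_um, parent.true_width_nm)
            foot = simulate.capsule_footprint(spec, cfg.image_size_px,
                                              cfg.pixel_size_nm)
            objs, _ = morphology.label_objects(
                foot, pixel_size_nm=cfg.pixel_size_nm)
            rec = classify_protrusion(
                objs[0], (row.anchor_x_um, row.anchor_y_um),
                parent_length_um=parent.true_length_um)
            hits += rec.position_class == row.placement
        assert hits / n >= 0.9
        tips = sum(field.truth_protrusions["placement"] == "tip")
        lo, hi = stats.binom.interval(0.99, n, 0.5)
        assert lo <= tips <= hi


class TestContactSites:
    def test_density_arithmetic(self):
        mito = np.zeros((100, 100), dtype=bool)
        mito[40:44, 10:90] = True
        puncta = np.zeros((100, 100), dtype=bool)
        for c in (15, 30, 45, 60, 75):
            puncta[44:47, c:c + 3] = True     # touching below the tubule
        density, n = contact_site_density(25.0, mito, puncta, 25.0)
        assert n == 5
        assert density == pytest.approx(0.2)

    def test_empty_puncta_mask_zero(self):
        mito = np.zeros((50, 50), dtype=bool)
        mito[20:24, 10:40] = True
        density, n = contact_site_density(
            10.0, mito, np.zeros((50, 50), bool), 25.0)
        assert density == 0.0 and n == 0

    def test_zero_length_withheld(self):
        with pytest.raises(ValueError):
            contact_site_density(0.0, np.zeros((10, 10), bool),
                                 np.zeros((10, 10), bool), 25.0)

    def test_planted_contact_count_exact_on_clean_masks(self):
        """With geometrically planted puncta (50% touching), the contact
        count matches the plant exactly on noise-free masks."""
        cfg = simulate.SimConfig(image_size_px=(768, 768), seed=51,
                                 n_mitochondria=12, n_mds=6,
                                 poisson_noise=False,
                                 gaussian_read_sigma=0.0)
        field = simulate.generate_field(cfg)
        puncta_mask, table = simulate.generate_puncta(
            field, n_puncta=20, fraction_contacting=0.5, seed=52)
        mito_mask = np.zeros(cfg.image_size_px, dtype=bool)
        for _, row in field.truth.iterrows():
            spec = simulate.ObjectSpec(
                (row.center_x_um, row.center_y_um), row.angle_deg,
                row.true_length_um, row.true_width_nm)
            mito_mask |= simulate.capsule_footprint(
                spec, cfg.image_size_px, cfg.pixel_size_nm)
        total_len = field.truth["true_length_um"].sum()
        density, n = contact_site_density(total_len, mito_mask,
                                          puncta_mask, cfg.pixel_size_nm)
        assert n == int(table["contacting"].sum())
        assert density == pytest.approx(n / total_len)
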
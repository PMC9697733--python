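import numpy as np
import pytest
from skimage.feature import peak_local_max

from hrdot import phantom
from hrdot.detection import (
    DotDetection,
    assign_location,
    detect_dots,
    filter_onl,
    measure_axial_diameter,
    suppress_background,
)
from hrdot.io_core import BScanStack, ClassificationParams, LayerModel, ScanProtocol
from hrdot.phantom import (
    GroundTruthObject,
    PhantomConfig,
    make_layer_geometry,
    render_structural,
)


def make_detection(**kw):
    base = dict(scan_index=0, lateral=1000.0, scanaxis=0.0, depth=215.0,
                axial_diameter=15.0, peak_contrast=2.0, layer="INL",
                location="inside_INL", distance_to_nearest_boundary=20.0)
    base.update(kw)
    return DotDetection(**base)


def flat_layers(inl_top=200.0, inl_bot=240.0):
    ys = np.array([-300.0, 300.0])
    xs = np.array([-400.0, 2000.0])
    depths = {"ipl_inner": inl_top - 30, "ipl_inl": inl_top, "inl_opl": inl_bot,
              "opl_onl": inl_bot + 25, "onl_outer": inl_bot + 100}
    return LayerModel(
        scanaxis_um=ys, lateral_um=xs,
        boundaries={n: np.full((2, 2), d) for n, d in depths.items()},
    )


def single_granule_scene(lateral, diameter=18.0, seed=9, noiseless=True):
    cfg = PhantomConfig(seed=seed, n_capillaries=0, n_inl_granules=0,
                        n_onl_granules=0, n_superficial_vessels=0)
    if noiseless:
        cfg = phantom.noiseless(cfg)
    layers = make_layer_geometry(cfg)
    top, bot = layers.band("INL", 0.0, lateral)
    obj = GroundTruthObject(
        id=0, kind="granule", center=(lateral, 0.0, float(top + bot) / 2.0),
        axial_diameter=diameter, length=diameter, orientation=(0.0, 1.0, 0.0),
        layer_attachment="inside_INL",
    )
    return cfg, layers, obj, render_structural(layers, [obj], cfg)


class TestSuppressBackground:
    def test_noiseless_peak_ratio_preserved_within_ten_percent(self):
        cfg, layers, obj, stack = single_granule_scene(1000.0)
        sup = suppress_background(stack)
        i = stack.scan_to_index(0.0)
        xi = int(stack.lateral_to_index(obj.center[0]))
        zi = int(stack.depth_to_index(obj.center[2]))
        raw = stack.reflectivity[i]
        band_bg = np.median(raw[zi - 1:zi + 2, xi - 30:xi - 20])  # same band, off-dot
        raw_ratio = raw[zi - 1:zi + 2, xi - 1:xi + 2].max() / band_bg
        sup_ratio = sup.reflectivity[i, zi - 1:zi + 2, xi - 1:xi + 2].max()
        assert sup_ratio == pytest.approx(raw_ratio, rel=0.10)

    def test_noise_maxima_reduced(self):
        rng = np.random.default_rng(3)
        proto = ScanProtocol(n_scans=3, scan_spacing=11.0, lateral_pitch=5.7,
                             axial_pitch=3.9, field_width=570.0)
        noise = rng.gamma(20.0, 1.0 / 20.0, size=(3, 80, proto.n_lateral)).astype(np.float32)
        stack = BScanStack(reflectivity=noise, protocol=proto)
        sup = suppress_background(stack)
        n_raw = sum(
            len(peak_local_max(noise[i] / np.median(noise[i]), threshold_abs=1.2))
            for i in range(3)
        )
        n_sup = sum(
            len(peak_local_max(sup.reflectivity[i], threshold_abs=1.2)) for i in range(3)
        )
        assert n_sup < n_raw

    def test_idempotent_within_tolerance_inside_band(self):
        cfg, layers, obj, stack = single_granule_scene(1000.0, noiseless=False)
        once = suppress_background(stack)
        twice = suppress_background(once)
        z = stack.depth_coords()
        lat = stack.lateral_coords()
        top, bot = layers.band("INL", 0.0, lat)
        mask = (z[:, None] >= np.asarray(top) + 4) & (z[:, None] <= np.asarray(bot) - 4)
        diff = np.abs(twice.reflectivity - once.reflectivity)[:, mask]
        assert np.quantile(diff, 0.95) < 0.15


class TestDetectDots:
    def test_noiseless_completeness_and_no_false_positives(self, noiseless0):
        """On a noiseless phantom every planted INL cross-section in the ROI is
        detected and nothing else is."""
        sup = suppress_background(noiseless0.structural)
        dets = detect_dots(sup, noiseless0.layers, roi="INL")
        truth = [o for o in noiseless0.objects
                 if o.layer_attachment in phantom.INL_ATTACHMENTS]
        orphans = 0
        hits = {o.id: 0 for o in truth}
        for d in dets:
            matched = False
            for o in truth:
                t = (d.scanaxis - o.center[1]) / o.orientation[1] if o.orientation[1] else 0.0
                x_exp = o.center[0] + t * o.orientation[0]
                if (abs(t) <= o.length / 2 + o.radius
                        and abs(d.lateral - x_exp) < 20 and abs(d.depth - o.center[2]) < 20):
                    hits[o.id] += 1
                    matched = True
                    break
            orphans += not matched
        assert orphans == 0
        for o in truth:
            assert hits[o.id] >= (4 if o.kind == "capillary" else 1)

    def test_parafoveal_roi_excludes_object_at_400um(self):
        """A dot 400 µm temporal of the fovea lies inside the foveal avascular
        zone exclusion and must not be counted in INL mode."""
        cfg, layers, obj, stack = single_granule_scene(400.0)
        dets = detect_dots(suppress_background(stack), layers, roi="INL")
        assert dets == []
        cfg, layers, obj, stack = single_granule_scene(1000.0)
        dets = detect_dots(suppress_background(stack), layers, roi="INL")
        assert len(dets) >= 1

    def test_empty_onl_yields_no_detections(self):
        cfg, layers, obj, stack = single_granule_scene(1000.0)  # INL object only
        dets = detect_dots(suppress_background(stack), layers, roi="ONL")
        assert filter_onl(dets) == []

    def test_missing_layer_model_rejected(self, suppressed0):
        with pytest.raises(ValueError):
            detect_dots(suppressed0, None, roi="INL")

    def test_count_monotone_in_contrast_threshold(self, suppressed0, pair0):
        low = detect_dots(suppressed0, pair0.layers,
                          ClassificationParams(contrast_threshold=1.5))
        high = detect_dots(suppressed0, pair0.layers,
                           ClassificationParams(contrast_threshold=2.0))
        assert len(high) <= len(low)


class TestDiameterMeasurement:
    def test_sphere_with_negligible_blur_measures_its_diameter(self):
        from dataclasses import replace

        cfg = phantom.noiseless(PhantomConfig(
            seed=1, n_capillaries=0, n_inl_granules=0, n_onl_granules=0,
            n_superficial_vessels=0,
        ))
        cfg = replace(cfg, structural_protocol=replace(
            cfg.structural_protocol, axial_resolution=0.5, lateral_resolution=0.5))
        layers = make_layer_geometry(cfg)
        top, bot = layers.band("INL", 0.0, 1000.0)
        obj = GroundTruthObject(
            id=0, kind="granule", center=(1000.0, 0.0, float(top + bot) / 2.0),
            axial_diameter=20.0, length=20.0, orientation=(0.0, 1.0, 0.0),
            layer_attachment="inside_INL",
        )
        stack = render_structural(layers, [obj], cfg)
        sup = suppress_background(stack)
        dets = detect_dots(sup, layers, roi="INL")
        center = [d for d in dets if abs(d.scanaxis) < 6.0]
        assert center
        d = max(center, key=lambda d: d.peak_contrast)
        assert d.axial_diameter == pytest.approx(20.0, abs=stack.protocol.axial_pitch)
        assert measure_axial_diameter(sup, d, layers) == pytest.approx(
            d.axial_diameter, abs=1e-6)

    def test_symmetric_profile_reports_center_depth(self):
        cfg, layers, obj, stack = single_granule_scene(1000.0)
        dets = detect_dots(suppress_background(stack), layers, roi="INL")
        center = [d for d in dets if abs(d.scanaxis) < 6.0]
        assert center
        assert center[0].depth == pytest.approx(obj.center[2],
                                                abs=stack.protocol.axial_pitch)

    def test_planted_range_recovered_with_blur_broadening(self, noiseless0):
        """Equator cross-sections of planted objects (drawn from 10–25 µm)
        measure inside the planted range plus blur broadening."""
        sup = suppress_background(noiseless0.structural)
        dets = detect_dots(sup, noiseless0.layers, roi="INL")
        for o in noiseless0.objects:
            if o.kind != "granule" or o.layer_attachment not in phantom.INL_ATTACHMENTS:
                continue
            near = [d for d in dets
                    if abs(d.lateral - o.center[0]) < 15
                    and abs(d.scanaxis - o.center[1]) <= 0.35 * o.axial_diameter + 1]
            assert near
            best = max(near, key=lambda d: d.peak_contrast)
            assert best.axial_diameter == pytest.approx(o.axial_diameter, abs=8.0)


class TestAssignLocation:
    def test_mid_band_dot_is_inside(self):
        det = make_detection(depth=220.0, axial_diameter=15.0)
        assert assign_location(det, flat_layers()) == "inside_INL"

    def test_edge_contact_is_near_opl(self):
        det = make_detection(depth=232.0, axial_diameter=16.0)  # lower edge at 240
        assert assign_location(det, flat_layers()) == "near_OPL"

    def test_double_contact_resolves_to_nearer_boundary(self):
        det = make_detection(depth=224.0, axial_diameter=44.0)  # spans whole band
        assert assign_location(det, flat_layers()) == "near_OPL"
        det = make_detection(depth=216.0, axial_diameter=44.0)
        assert assign_location(det, flat_layers()) == "near_IPL"


class TestFilterOnl:
    def onl_det(self, diameter, distance):
        return make_detection(layer="ONL", location="not_applicable",
                              axial_diameter=diameter,
                              distance_to_nearest_boundary=distance)

    @pytest.mark.parametrize("diameter,distance,kept", [
        (14.0, 40.0, False),   # below the 15 µm size threshold
        (18.0, 15.0, False),   # boundary distance not greater than the width
        (18.0, 25.0, True),
        (15.0, 40.0, False),   # threshold is strict
    ])
    def test_grading_rules(self, diameter, distance, kept):
        out = filter_onl([self.onl_det(diameter, distance)])
        assert bool(out) is kept

    def test_subset_order_preserved_and_idempotent(self):
        rng = np.random.default_rng(0)
        dets = [self.onl_det(rng.uniform(10, 30), rng.uniform(5, 50)) for _ in range(40)]
        once = filter_onl(dets)
        assert all(d in dets for d in once)
        assert [dets.index(d) for d in once] == sorted(dets.index(d) for d in once)
        assert filter_onl(once) == once
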
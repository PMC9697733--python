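import numpy as np
import pytest

from hrdot import phantom
from hrdot.io_core import BOUNDARY_NAMES
from hrdot.phantom import (
    GroundTruthObject,
    PhantomConfig,
    PlacementError,
    export_truth,
    generate_pair,
    load_truth,
    make_layer_geometry,
    plant_objects,
    render_angiographic,
    render_structural,
)


class TestLayerGeometry:
    def test_boundaries_strictly_ordered_everywhere(self):
        model = make_layer_geometry(PhantomConfig(seed=1))
        stacked = np.stack([model.boundaries[n] for n in BOUNDARY_NAMES])
        assert np.all(np.diff(stacked, axis=0) > 0)

    def test_deterministic_for_fixed_seed(self):
        a = make_layer_geometry(PhantomConfig(seed=3))
        b = make_layer_geometry(PhantomConfig(seed=3))
        for name in BOUNDARY_NAMES:
            np.testing.assert_array_equal(a.boundaries[name], b.boundaries[name])

    def test_inl_tapers_toward_fovea(self):
        model = make_layer_geometry(PhantomConfig(seed=0))
        def thickness(x):
            top, bot = model.band("INL", 0.0, x)
            return float(bot) - float(top)
        assert thickness(0.0) < thickness(1000.0)


class TestPlanting:
    def test_healthy_config_all_capillaries_perfused(self):
        cfg = PhantomConfig(seed=2, fraction_nonperfused=0.0)
        layers = make_layer_geometry(cfg)
        objs = plant_objects(layers, cfg)
        caps = [o for o in objs if o.kind == "capillary"]
        assert caps and all(o.perfused for o in caps)

    def test_default_nonperfused_count(self, pair0):
        caps = [o for o in pair0.objects if o.kind == "capillary"]
        assert len(caps) == 12
        assert sum(not o.perfused for o in caps) == 2

    def test_capillary_lengths_within_configured_range(self, pair0):
        lo, hi = pair0.config.capillary_length_range
        for o in pair0.objects:
            if o.kind == "capillary":
                assert lo <= o.length <= hi

    def test_onl_capillaries_rejected(self):
        with pytest.raises(ValueError, match="no vessels"):
            GroundTruthObject(
                id=0, kind="capillary", center=(0, 0, 300), axial_diameter=15,
                length=80, orientation=(0, 1, 0), layer_attachment="ONL", perfused=True,
            )

    def test_kind_recoverable_from_geometry(self, pair0):
        """Class separability by construction: planted granules intersect at
        most three structural scan planes, capillary barrels at least four."""
        proto = pair0.config.structural_protocol
        origin = pair0.config.structural_origin()[1]
        for o in pair0.objects:
            if o.kind == "granule":
                assert len(phantom.scan_planes_hit(o, proto, origin)) <= 3
            elif o.kind == "capillary":
                assert len(phantom.scan_planes_hit(o, proto, origin)) >= 4

    def test_infeasible_counts_raise_placement_error(self):
        cfg = PhantomConfig(seed=0, superficial_zone=(0.0, 10.0))
        layers = make_layer_geometry(cfg)
        with pytest.raises(PlacementError):
            plant_objects(layers, cfg)


class TestRendering:
    def test_pair_generation_is_bit_deterministic(self, pair0):
        again = generate_pair(PhantomConfig(seed=0))
        np.testing.assert_array_equal(again.structural.reflectivity,
                                      pair0.structural.reflectivity)
        np.testing.assert_array_equal(again.angiographic.motion_contrast,
                                      pair0.angiographic.motion_contrast)

    def test_speckle_variance_scales_inversely_with_frame_count(self):
        """7-frame averaging leaves ~100/7 times the speckle variance of
        100-frame averaging (multiplicative gamma noise model)."""
        cfg = PhantomConfig(seed=4, n_capillaries=0, n_inl_granules=0,
                            n_onl_granules=0, n_superficial_vessels=0)
        layers = make_layer_geometry(cfg)
        clean = render_structural(layers, [], phantom.noiseless(cfg)).reflectivity
        noisy100 = render_structural(layers, [], cfg,
                                     rng=np.random.default_rng(11)).reflectivity
        proto7 = phantom._default_structural_protocol()
        from dataclasses import replace
        cfg7 = replace(cfg, structural_protocol=replace(proto7, n_averaged_frames=7))
        noisy7 = render_structural(layers, [], cfg7,
                                   rng=np.random.default_rng(12)).reflectivity
        sel = clean > 0.1
        assert sel.sum() > 10_000
        v100 = np.var(noisy100[sel] / clean[sel])
        v7 = np.var(noisy7[sel] / clean[sel])
        assert v7 / v100 == pytest.approx(100.0 / 7.0, rel=0.2)

    def test_empty_scene_has_no_detectable_maxima(self):
        """An object-free scene yields no detections in the noiseless limit
        and at most isolated speckle blobs at full noise."""
        from hrdot import detection
        from hrdot.io_core import ClassificationParams

        cfg = PhantomConfig(seed=5, n_capillaries=0, n_inl_granules=0,
                            n_onl_granules=0, n_superficial_vessels=0)
        pair_layers = make_layer_geometry(cfg)
        clean = render_structural(pair_layers, [], phantom.noiseless(cfg))
        sup = detection.suppress_background(clean)
        assert detection.detect_dots(sup, pair_layers, ClassificationParams(),
                                     roi="INL") == []
        noisy = render_structural(pair_layers, [], cfg)
        sup_n = detection.suppress_background(noisy)
        dets = detection.detect_dots(sup_n, pair_layers, ClassificationParams(),
                                     roi="INL")
        assert len(dets) <= 2

    def test_capillary_spans_expected_consecutive_scans(self):
        """An 88 µm capillary along the scan axis crosses >= 8 scan-to-scan
        intervals at 11 µm spacing."""
        cfg = phantom.noiseless(PhantomConfig(seed=0))
        layers = make_layer_geometry(cfg)
        obj = GroundTruthObject(
            id=0, kind="capillary", center=(1000.0, 0.0, 0.0), axial_diameter=16.0,
            length=88.0, orientation=(0.0, 1.0, 0.0), layer_attachment="near_OPL",
            perfused=True,
        )
        stack = render_structural(layers, [obj], cfg)
        xi = int(round((1000.0 - stack.origin_offset[0]) / 5.7))
        bright = []
        for i in range(stack.shape[0]):
            window = stack.reflectivity[i, :, xi - 2:xi + 3]
            bright.append(window.max() > 1.5 * 0.25)
        runs = np.flatnonzero(bright)
        assert runs.size >= 9  # 9 scans = 8 adjacent-scan intervals
        assert np.all(np.diff(runs) == 1)

    def test_motion_covers_perfused_and_spares_nonperfused(self, noiseless0):
        """Motion contrast overlaps every perfused capillary footprint, is zero
        inside non-perfused capillaries, and never covers a granule."""
        angio = noiseless0.angiographic
        cfg = noiseless0.config
        dx, dy, rot = cfg.misregistration
        th = np.radians(rot)
        for o in noiseless0.objects:
            if o.layer_attachment not in phantom.INL_ATTACHMENTS:
                continue
            xa = np.cos(th) * o.center[0] - np.sin(th) * o.center[1] + dx
            ya = np.sin(th) * o.center[0] + np.cos(th) * o.center[1] + dy
            j = int(round((ya - angio.origin_offset[1]) / angio.protocol.scan_spacing))
            xi = int(round((xa - angio.origin_offset[0]) / angio.protocol.lateral_pitch))
            zi = int(round(o.center[2] / angio.protocol.axial_pitch))
            window = angio.motion_contrast[j, zi - 3:zi + 4, xi - 3:xi + 4]
            if o.kind == "capillary" and o.perfused:
                assert window.max() > 0.5
            else:
                assert window.max() == 0.0

    def test_projection_artifact_without_structural_object(self):
        """A superficial vessel casts motion signal into the INL band at its
        lateral position although no structural object sits there."""
        cfg = phantom.noiseless(PhantomConfig(
            seed=6, n_capillaries=0, n_inl_granules=0, n_onl_granules=0,
            n_superficial_vessels=1, projection_artifact_density=0.5,
        ))
        layers = make_layer_geometry(cfg)
        objs = plant_objects(layers, cfg)
        angio = render_angiographic(layers, objs, cfg,
                                    misregistration=(0.0, 0.0, 0.0),
                                    rng_motion=np.random.default_rng(7))
        vessel = objs[0]
        x, y = vessel.center[0], vessel.center[1]
        j = int(round((y - angio.origin_offset[1]) / angio.protocol.scan_spacing))
        xi = int(round((x - angio.origin_offset[0]) / angio.protocol.lateral_pitch))
        top, bot = layers.band("INL", y, x)
        rows = slice(int(float(top) / 3.9) + 1, int(float(bot) / 3.9))
        assert angio.motion_contrast[j, rows, xi - 2:xi + 3].max() > 0.5
        interior = slice(int((float(top) + 8) / 3.9) + 1, int((float(bot) - 8) / 3.9))
        band = angio.reflectivity[j, interior, xi - 2:xi + 3]
        assert band.max() < 1.5 * cfg.background["INL"]  # no structural dot there

    def test_structural_speckle_independent_of_motion_geometry(self):
        cfg = PhantomConfig(seed=8, n_capillaries=2, n_inl_granules=1,
                            n_onl_granules=0, n_superficial_vessels=1)
        layers = make_layer_geometry(cfg)
        objs = plant_objects(layers, cfg)
        kwargs = dict(misregistration=cfg.misregistration)
        a = render_angiographic(layers, objs, cfg, rng_speckle=np.random.default_rng(1),
                                rng_motion=np.random.default_rng(42), **kwargs)
        b = render_angiographic(layers, objs, cfg, rng_speckle=np.random.default_rng(2),
                                rng_motion=np.random.default_rng(42), **kwargs)
        assert not np.array_equal(a.reflectivity, b.reflectivity)
        np.testing.assert_array_equal(a.motion_contrast, b.motion_contrast)


class TestTruthPersistence:
    def test_round_trip(self, tmp_path, pair0):
        path = tmp_path / "truth.csv"
        export_truth(pair0.objects, path)
        back = load_truth(path)
        assert len(back) == len(pair0.objects)
        for a, b in zip(back, pair0.objects):
            assert a.id == b.id and a.kind == b.kind
            assert a.center == pytest.approx(b.center)
            assert a.perfused == b.perfused and a.branch_of == b.branch_of

    def test_empty_list_yields_header_only(self, tmp_path):
        path = tmp_path / "truth.csv"
        export_truth([], path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("id,")

    def test_duplicate_ids_rejected(self, tmp_path):
        obj = GroundTruthObject(
            id=1, kind="granule", center=(0, 0, 0), axial_diameter=12, length=12,
            orientation=(0, 1, 0), layer_attachment="inside_INL",
        )
        with pytest.raises(ValueError, match="unique"):
            export_truth([obj, obj], tmp_path / "t.csv")
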
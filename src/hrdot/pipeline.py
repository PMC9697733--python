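"""End-to-end drivers: phantom pair in, classified elements and recovery out."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import detection, perfusion, phantom, tracing
from .io_core import ClassificationParams

__all__ = ["run_inl_pipeline", "run_onl_pipeline", "evaluate_recovery"]


def run_inl_pipeline(pair: phantom.PhantomPair,
                     params: ClassificationParams = ClassificationParams()):
    """Detect, trace, align and classify the parafoveal INL of a phantom pair.

    Returns (classified top-level elements, alignment transform).
    """
    suppressed = detection.suppress_background(pair.structural)
    dets = detection.detect_dots(suppressed, pair.layers, params, roi="INL")
    elements = tracing.link_detections(
        dets, pair.structural.protocol,
        gating=(params.link_gate_lateral, params.link_gate_depth),
    )
    for el in elements:
        tracing.classify_shape(el, params)
    transform = perfusion.align_stacks(pair.structural, pair.angiographic)
    classified = []
    for el in tracing.merge_branches(elements):
        assessment = perfusion.assess_perfusion(el, pair.angiographic, transform, params)
        classified.append(perfusion.classify_element(el, assessment, params))
    return classified, transform


def run_onl_pipeline(pair: phantom.PhantomPair,
                     params: ClassificationParams = ClassificationParams()):
    """Detect, size-filter and trace outer-nuclear-layer dots (full field)."""
    suppressed = detection.suppress_background(pair.structural)
    dets = detection.detect_dots(suppressed, pair.layers, params, roi="ONL")
    dets = detection.filter_onl(dets, params)
    elements = tracing.link_detections(
        dets, pair.structural.protocol,
        gating=(params.link_gate_lateral, params.link_gate_depth),
    )
    for el in elements:
        tracing.classify_shape(el, params)
    return tracing.merge_branches(elements)


def _expected_class(obj: phantom.GroundTruthObject) -> str:
    if obj.kind == "granule":
        return "granule"
    return "perfused_filiform" if obj.perfused else "nonperfused_filiform"


def evaluate_recovery(pair: phantom.PhantomPair, classified,
                      lateral_tol: float = 15.0, depth_tol: float = 15.0) -> pd.DataFrame:
    """Match planted parafoveal INL objects against classified elements.

    A planted object is recovered when exactly one top-level element tracks
    its footprint (per-scan lateral/depth correspondence on the scans both
    occupy) and that element reproduces the planted shape class, perfusion
    class and location label.  Branch children count as part of their
    parents on both sides.
    """
    proto = pair.structural.protocol
    origin_scan = pair.config.structural_origin()[1]
    truth = [
        o for o in pair.objects
        if o.kind in ("granule", "capillary")
        and o.layer_attachment in phantom.INL_ATTACHMENTS
        and o.branch_of is None
    ]
    rows = []
    for obj in truth:
        hit_scans = set(phantom.scan_planes_hit(obj, proto, origin_scan))
        ux, uy = obj.orientation[0], obj.orientation[1]
        matches = []
        for c in classified:
            el = c.element
            common = [d for d in el.detections if d.scan_index in hit_scans]
            if not common:
                continue
            dlat, ddep = [], []
            for det in common:
                # expected en-face position of the centerline on this scan
                t = (det.scanaxis - obj.center[1]) / uy if uy else 0.0
                dlat.append(abs(det.lateral - (obj.center[0] + t * ux)))
                ddep.append(abs(det.depth - obj.center[2]))
            if np.median(dlat) > lateral_tol or np.median(ddep) > depth_tol:
                continue
            matches.append(c)
        row = {
            "object_id": obj.id,
            "kind": obj.kind,
            "perfused": obj.perfused,
            "layer_attachment": obj.layer_attachment,
            "n_matches": len(matches),
        }
        if len(matches) == 1:
            c = matches[0]
            expected_shape = "granule" if obj.kind == "granule" else "elongated"
            row.update({
                "shape_ok": c.element.shape_class == expected_shape,
                "class_ok": c.final_class == _expected_class(obj),
                "location_ok": c.element.location == obj.layer_attachment,
            })
        else:
            row.update({"shape_ok": False, "class_ok": False, "location_ok": False})
        row["recovered"] = bool(
            row["n_matches"] == 1 and row["shape_ok"] and row["class_ok"] and row["location_ok"]
        )
        rows.append(row)
    return pd.DataFrame(rows)
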
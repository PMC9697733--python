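"""Synthetic OCT phantom: paired structural/angiographic B-scan stacks with truth.

The phantom emulates the statistical structure the grading procedure relies
on, not the wave optics of the instrument:

* layered retinal reflectivity with a foveal pit (thin INL centrally);
* hyperreflective granules (quasi-spherical, 10–25 µm) in the INL and ONL;
* filiform capillary segments in the INL (diameter 10–25 µm, length
  51–183 µm) running predominantly perpendicular to the B-scan plane,
  each carrying a perfusion flag; the avascular ONL receives no vessels;
* superficial vessels anterior to the IPL that act as alignment landmarks
  and cast projection artifacts into the motion-contrast channel;
* multiplicative gamma speckle whose variance scales as 1/n_averaged_frames
  (100 frames for the structural stack, 7 for the angiographic one);
* a small rigid en-face misregistration between the two stacks.

Stacks are rendered over a parafoveal sub-field that covers everything the
grading touches (the 500–1500 µm temporal region of interest plus margins)
at the acquisition pitches of the reference protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io_core import BOUNDARY_NAMES, BScanStack, LayerModel, ScanProtocol

__all__ = [
    "GroundTruthObject",
    "PhantomConfig",
    "PhantomPair",
    "PlacementError",
    "make_layer_geometry",
    "plant_objects",
    "render_structural",
    "render_angiographic",
    "generate_pair",
    "export_truth",
    "load_truth",
    "noiseless",
    "scan_planes_hit",
]

INL_ATTACHMENTS = ("near_IPL", "inside_INL", "near_OPL")
# attached objects sit tangent to their boundary (center one radius away),
# the natural geometry for a capillary lying against a plexiform layer
_ATTACH_OVERLAP = 1.0
_INSIDE_CLEARANCE = 8.0   # µm free space demanded around an unattached object
_SUPERFICIAL_ELEVATION = 15.0  # µm anterior to the inner IPL edge


class PlacementError(RuntimeError):
    """Requested object counts do not fit the available layer volume."""


@dataclass
class GroundTruthObject:
    """One planted scene object, in scene (structural-frame) coordinates."""

    id: int
    kind: str                               # granule | capillary | superficial_vessel
    center: tuple[float, float, float]      # (lateral, scan-axis, depth) µm
    axial_diameter: float                   # µm
    length: float                           # µm along the centerline
    orientation: tuple[float, float, float]  # unit en-face direction (lat, scan, depth)
    layer_attachment: str                   # near_IPL | inside_INL | near_OPL | ONL | superficial
    perfused: bool | None = None
    branch_of: int | None = None

    def __post_init__(self) -> None:
        if self.kind == "granule":
            if self.length >= 44:
                raise ValueError("granule length must stay below 44 µm")
            if self.perfused is not None:
                raise ValueError("perfused is defined only for vessels")
        elif self.kind in ("capillary", "superficial_vessel"):
            if self.kind == "capillary" and self.length < 33:
                raise ValueError("capillary length must be >= 33 µm")
            if self.perfused is None:
                raise ValueError(f"{self.kind} requires a perfusion flag")
            if self.layer_attachment == "ONL":
                raise ValueError("the outer nuclear layer contains no vessels")
        else:
            raise ValueError(f"unknown object kind {self.kind!r}")

    @property
    def radius(self) -> float:
        return self.axial_diameter / 2.0

    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """En-face (lateral, scan-axis) endpoints of the centerline."""
        c = np.array(self.center[:2])
        u = np.array(self.orientation[:2])
        half = self.length / 2.0 if self.kind != "granule" else 0.0
        return c - half * u, c + half * u


def _default_structural_protocol() -> ScanProtocol:
    return ScanProtocol(
        n_scans=43, scan_spacing=11.0, lateral_pitch=5.7, axial_pitch=3.9,
        field_width=2100.0, n_averaged_frames=100,
    )


def _default_angiographic_protocol() -> ScanProtocol:
    return ScanProtocol(
        n_scans=89, scan_spacing=5.9, lateral_pitch=5.7, axial_pitch=3.9,
        field_width=2100.0, n_averaged_frames=7,
    )


@dataclass
class PhantomConfig:
    """Scene composition and imaging parameters.

    Defaults plant 12 INL capillaries of which a sixth (i.e. two) are
    non-perfused, 4 INL granules, 2 ONL granules and 3 perfused superficial
    vessels; sizes follow the observed ranges (capillary diameter 10–25 µm,
    length 51–183 µm; granules 10–25 µm).  ``fraction_nonperfused = 0``
    yields a healthy phantom.
    """

    n_capillaries: int = 12
    n_inl_granules: int = 4
    n_onl_granules: int = 2
    n_superficial_vessels: int = 3
    capillary_diameter_range: tuple[float, float] = (10.0, 22.0)
    capillary_length_range: tuple[float, float] = (51.0, 183.0)
    granule_diameter_range: tuple[float, float] = (10.0, 25.0)
    onl_granule_diameter_range: tuple[float, float] = (18.0, 28.0)
    fraction_nonperfused: float = 1.0 / 6.0
    attachment_probs: dict = field(
        default_factory=lambda: {"near_OPL": 0.5, "near_IPL": 0.3, "inside_INL": 0.2}
    )
    orientation_cone_deg: float = 20.0
    branch_probability: float = 0.0
    misregistration: tuple[float, float, float] = (15.0, 8.0, 0.5)  # (µm, µm, deg)
    speckle_shape_per_frame: float | None = 1.0   # None disables speckle
    motion_noise_density: float = 2e-4
    projection_artifact_density: float = 0.15
    dot_contrast: float = 3.0        # object reflectivity over layer background
    vessel_reflectivity: float = 0.7
    background: dict = field(
        default_factory=lambda: {
            "vitreous": 0.03, "IPL": 0.55, "INL": 0.25,
            "OPL": 0.55, "ONL": 0.18, "posterior": 0.75,
        }
    )
    superficial_zone: tuple[float, float] = (-280.0, 460.0)   # lateral µm
    superficial_diameter: float = 25.0
    superficial_length: float = 250.0
    lateral_origin: float = -300.0
    depth_px: int = 100
    structural_protocol: ScanProtocol = field(default_factory=_default_structural_protocol)
    angiographic_protocol: ScanProtocol = field(default_factory=_default_angiographic_protocol)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_nonperfused <= 1.0:
            raise ValueError("fraction_nonperfused must lie in [0, 1]")

    def structural_origin(self) -> tuple[float, float]:
        return (self.lateral_origin, -self.structural_protocol.field_depth_scans / 2.0)

    def angiographic_origin(self) -> tuple[float, float]:
        return (self.lateral_origin, -self.angiographic_protocol.field_depth_scans / 2.0)


def noiseless(config: PhantomConfig) -> PhantomConfig:
    """A copy of *config* with speckle and motion-channel noise disabled."""
    return replace(config, speckle_shape_per_frame=None, motion_noise_density=0.0)


def _seeds(config: PhantomConfig) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(config.seed)
    names = ("layers", "objects", "speckle_structural", "speckle_angiographic", "motion_noise")
    return dict(zip(names, (np.random.default_rng(c) for c in ss.spawn(len(names)))))


# ---------------------------------------------------------------------------
# layer geometry

def make_layer_geometry(config: PhantomConfig, rng: np.random.Generator | None = None) -> LayerModel:
    """Smooth layer surfaces with a central foveal pit.

    The INL and IPL taper toward the fovea (the pit) while the ONL thickens;
    each surface carries a small smooth seeded perturbation (clipped to
    ±2.5 µm) that keeps the strict depth ordering and gives the en-face
    projection some registration texture.
    """
    if rng is None:
        rng = _seeds(config)["layers"]
    ys = np.arange(-320.0, 321.0, 20.0)
    xs = np.arange(-360.0, 1861.0, 20.0)
    X, Y = np.meshgrid(xs, ys)
    r2 = X**2 + Y**2

    def perturb() -> np.ndarray:
        raw = rng.normal(size=X.shape)
        sm = gaussian_filter(raw, sigma=3.0, mode="nearest")
        sm = sm / max(sm.std(), 1e-9) * 1.4
        return np.clip(sm, -2.5, 2.5)

    pit = np.exp(-r2 / (2 * 300.0**2))
    fovea_bump = np.exp(-r2 / (2 * 250.0**2))
    onl_outer = 330.0 + 8.0 * ((X - 750.0) / 1050.0) ** 2 + perturb()
    t_onl = 70.0 + 25.0 * fovea_bump + perturb()
    t_opl = 25.0 + perturb()
    t_inl = 40.0 * (1.0 - 0.8 * pit) + perturb()
    t_ipl = 35.0 * (1.0 - 0.8 * pit) + perturb()

    opl_onl = onl_outer - t_onl
    inl_opl = opl_onl - t_opl
    ipl_inl = inl_opl - t_inl
    ipl_inner = ipl_inl - t_ipl
    return LayerModel(
        scanaxis_um=ys,
        lateral_um=xs,
        boundaries={
            "ipl_inner": ipl_inner, "ipl_inl": ipl_inl, "inl_opl": inl_opl,
            "opl_onl": opl_onl, "onl_outer": onl_outer,
        },
        fovea_center=(0.0, 0.0),
    )


# ---------------------------------------------------------------------------
# object planting

def _segment_distance(p0, p1, q0, q1) -> float:
    """Minimum distance between two 2D segments."""
    p0, p1, q0, q1 = (np.asarray(a, dtype=float) for a in (p0, p1, q0, q1))

    def point_seg(pt, a, b):
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom == 0 else float(np.clip((pt - a) @ ab / denom, 0.0, 1.0))
        return float(np.linalg.norm(pt - (a + t * ab)))

    d = min(
        point_seg(p0, q0, q1), point_seg(p1, q0, q1),
        point_seg(q0, p0, p1), point_seg(q1, p0, p1),
    )
    # segment interiors can only be closer than endpoint distances if they cross
    def ccw(a, b, c):
        return (c[1] - a[1]) * (b[0] - a[0]) - (b[1] - a[1]) * (c[0] - a[0])

    if (ccw(p0, p1, q0) * ccw(p0, p1, q1) < 0) and (ccw(q0, q1, p0) * ccw(q0, q1, p1) < 0):
        return 0.0
    return d


def scan_planes_hit(obj: GroundTruthObject, protocol: ScanProtocol, origin_scan: float) -> list[int]:
    """Structural scan indices whose plane intersects the object footprint."""
    ys = origin_scan + np.arange(protocol.n_scans) * protocol.scan_spacing
    yc = obj.center[1]
    if obj.kind == "granule":
        half = obj.radius
    else:
        half = obj.length / 2.0 * abs(obj.orientation[1]) + obj.radius
    return list(np.nonzero(np.abs(ys - yc) <= half)[0])


def _barrel_plane_count(obj, protocol, origin_scan) -> int:
    ys = origin_scan + np.arange(protocol.n_scans) * protocol.scan_spacing
    half = obj.length / 2.0 * abs(obj.orientation[1])
    return int(np.count_nonzero(np.abs(ys - obj.center[1]) <= half))


def plant_objects(
    layers: LayerModel, config: PhantomConfig, rng: np.random.Generator | None = None
) -> list[GroundTruthObject]:
    """Place capillaries, granules and superficial vessels in the scene.

    Capillaries live in the INL with their attachment category sampled from
    ``attachment_probs``; granules go to the INL and ONL (the ONL receives
    no vessels); a deterministic ``round(fraction_nonperfused × n)`` of the
    capillaries are flagged non-perfused.  Placement enforces pairwise
    separation and pre-checks that every object's planted kind is
    recoverable from its own geometry under the class boundary (granules
    intersect at most three structural scan planes, capillary barrels at
    least four).
    """
    if rng is None:
        rng = _seeds(config)["objects"]
    proto = config.structural_protocol
    origin_lat, origin_scan = config.structural_origin()
    y_half = proto.field_depth_scans / 2.0
    accepted: list[GroundTruthObject] = []
    next_id = 0

    def collides(cand: GroundTruthObject) -> bool:
        c0, c1 = cand.endpoints()
        for other in accepted:
            if other.id == cand.branch_of:
                continue
            if abs(other.center[2] - cand.center[2]) >= 25.0 and other.kind != "superficial_vessel":
                continue
            o0, o1 = other.endpoints()
            clearance = cand.radius + other.radius + 12.0
            if _segment_distance(c0, c1, o0, o1) < clearance:
                return True
        return False

    def sample_direction() -> tuple[float, float, float]:
        tilt = math.radians(config.orientation_cone_deg) * math.sqrt(rng.uniform())
        sign = rng.choice([-1.0, 1.0])
        return (sign * math.sin(tilt), math.cos(tilt), 0.0)

    def attachment_depth(att: str, x: float, y: float, radius: float) -> float | None:
        top, bot = layers.band("INL", y, x)
        if att == "near_OPL":
            return float(bot) - _ATTACH_OVERLAP * radius
        if att == "near_IPL":
            return float(top) + _ATTACH_OVERLAP * radius
        lo = float(top) + radius + _INSIDE_CLEARANCE
        hi = float(bot) - radius - _INSIDE_CLEARANCE
        if hi <= lo:
            return None
        return float(rng.uniform(lo, hi))

    att_names = list(config.attachment_probs)
    att_p = np.array([config.attachment_probs[k] for k in att_names], dtype=float)
    att_p /= att_p.sum()

    def place(kind: str, n: int, maker) -> None:
        nonlocal next_id
        for _ in range(n):
            for _try in range(600):
                cand = maker(next_id)
                if cand is None or collides(cand):
                    continue
                accepted.append(cand)
                next_id += 1
                break
            else:
                raise PlacementError(f"could not place requested {kind} objects")

    # superficial vessels: oblique landmarks confined to the nasal margin so
    # their projection artifacts never overlie the parafoveal INL objects
    def make_vessel(oid: int) -> GroundTruthObject | None:
        alpha = math.radians(rng.uniform(30.0, 50.0))
        u = (math.sin(alpha) * rng.choice([-1.0, 1.0]), math.cos(alpha), 0.0)
        L = config.superficial_length
        lat_half = abs(u[0]) * L / 2.0
        lo, hi = config.superficial_zone
        r = config.superficial_diameter / 2.0
        if hi - lo < 2 * (lat_half + r):
            return None
        x = rng.uniform(lo + lat_half + r, hi - lat_half - r)
        ymax = y_half - L / 2.0 * abs(u[1]) - r
        y = rng.uniform(-min(110.0, ymax), min(110.0, ymax))
        z = float(layers.boundary_depth("ipl_inner", y, x)) - _SUPERFICIAL_ELEVATION
        return GroundTruthObject(
            id=oid, kind="superficial_vessel", center=(x, y, z),
            axial_diameter=config.superficial_diameter, length=L,
            orientation=u, layer_attachment="superficial", perfused=True,
        )

    place("superficial_vessel", config.n_superficial_vessels, make_vessel)

    # INL capillaries
    def make_capillary(oid: int) -> GroundTruthObject | None:
        d = rng.uniform(*config.capillary_diameter_range)
        L = rng.uniform(*config.capillary_length_range)
        u = sample_direction()
        att = att_names[rng.choice(len(att_names), p=att_p)]
        if att == "inside_INL" and d > 20.0:
            d = rng.uniform(config.capillary_diameter_range[0], 20.0)
        drift = abs(u[0]) * L / 2.0
        x = rng.uniform(600.0 + drift, 1400.0 - drift)
        span = abs(u[1]) * L / 2.0 + d / 2.0
        if span + 15.0 >= y_half:
            return None
        y = rng.uniform(-(y_half - span - 15.0), y_half - span - 15.0)
        z = attachment_depth(att, x, y, d / 2.0)
        if z is None:
            return None
        obj = GroundTruthObject(
            id=oid, kind="capillary", center=(x, y, z), axial_diameter=d,
            length=L, orientation=u, layer_attachment=att, perfused=True,
        )
        if _barrel_plane_count(obj, proto, origin_scan) < 4:
            return None
        return obj

    place("capillary", config.n_capillaries, make_capillary)
    capillaries = [o for o in accepted if o.kind == "capillary"]
    n_occluded = int(round(config.fraction_nonperfused * len(capillaries)))
    for idx in rng.choice(len(capillaries), size=n_occluded, replace=False) if n_occluded else []:
        capillaries[int(idx)].perfused = False

    # optional branch children sharing a parent endpoint
    if config.branch_probability > 0:
        children = []
        for parent in capillaries:
            if rng.uniform() >= config.branch_probability:
                continue
            _, tip = parent.endpoints()
            dtheta = math.radians(rng.uniform(20.0, 40.0)) * rng.choice([-1.0, 1.0])
            ca, sa = math.cos(dtheta), math.sin(dtheta)
            pu = parent.orientation
            u = (pu[0] * ca - pu[1] * sa, pu[0] * sa + pu[1] * ca, 0.0)
            L = rng.uniform(40.0, 80.0)
            cx, cy = tip + np.array(u[:2]) * L / 2.0
            z = attachment_depth(parent.layer_attachment, float(cx), float(cy), parent.radius)
            if z is None:
                continue
            children.append(GroundTruthObject(
                id=len(accepted) + len(children), kind="capillary",
                center=(float(cx), float(cy), z), axial_diameter=parent.axial_diameter,
                length=L, orientation=u, layer_attachment=parent.layer_attachment,
                perfused=parent.perfused, branch_of=parent.id,
            ))
        accepted.extend(children)

    # INL granules
    def make_inl_granule(oid: int) -> GroundTruthObject | None:
        d = rng.uniform(*config.granule_diameter_range)
        att = att_names[rng.choice(len(att_names), p=att_p)]
        x = rng.uniform(600.0, 1400.0)
        y = rng.uniform(-(y_half - d), y_half - d)
        # keep one scan plane close to the sphere equator so the planted
        # granule presents a measurable cross-section
        nearest = (y - origin_scan) / proto.scan_spacing
        frac = abs(nearest - round(nearest)) * proto.scan_spacing
        if frac > 0.35 * d:
            return None
        z = attachment_depth(att, x, y, d / 2.0)
        if z is None:
            return None
        obj = GroundTruthObject(
            id=oid, kind="granule", center=(x, y, z), axial_diameter=d,
            length=d, orientation=(0.0, 1.0, 0.0), layer_attachment=att,
        )
        if len(scan_planes_hit(obj, proto, origin_scan)) > 3:
            return None
        return obj

    place("inl_granule", config.n_inl_granules, make_inl_granule)

    # ONL granules (no vessels ever go here)
    def make_onl_granule(oid: int) -> GroundTruthObject | None:
        d = rng.uniform(*config.onl_granule_diameter_range)
        x = rng.uniform(-150.0, 1650.0)
        y = rng.uniform(-(y_half - d), y_half - d)
        nearest = (y - origin_scan) / proto.scan_spacing
        frac = abs(nearest - round(nearest)) * proto.scan_spacing
        if frac > 0.2 * d:
            return None
        top, bot = layers.band("ONL", y, x)
        lo, hi = float(top) + d + _INSIDE_CLEARANCE, float(bot) - d - _INSIDE_CLEARANCE
        if hi <= lo:
            return None
        obj = GroundTruthObject(
            id=oid, kind="granule", center=(x, y, float(rng.uniform(lo, hi))),
            axial_diameter=d, length=d, orientation=(0.0, 1.0, 0.0),
            layer_attachment="ONL",
        )
        if len(scan_planes_hit(obj, proto, origin_scan)) > 3:
            return None
        return obj

    place("onl_granule", config.n_onl_granules, make_onl_granule)
    return accepted


# ---------------------------------------------------------------------------
# rendering

def _rotation(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s], [s, c]])


def _object_depth_profile(obj, layers, xs, ys, config):
    """Centerline depth of *obj* at scene positions (xs, ys), following its
    attachment surface so attached tubes stay in contact with a curved boundary."""
    att = obj.layer_attachment
    r = obj.radius
    if att == "near_OPL":
        return np.asarray(layers.boundary_depth("inl_opl", ys, xs)) - _ATTACH_OVERLAP * r
    if att == "near_IPL":
        return np.asarray(layers.boundary_depth("ipl_inl", ys, xs)) + _ATTACH_OVERLAP * r
    if att == "superficial":
        return np.asarray(layers.boundary_depth("ipl_inner", ys, xs)) - _SUPERFICIAL_ELEVATION
    if att == "inside_INL":
        top = np.asarray(layers.boundary_depth("ipl_inl", obj.center[1], obj.center[0]))
        bot = np.asarray(layers.boundary_depth("inl_opl", obj.center[1], obj.center[0]))
        delta = obj.center[2] - (float(top) + float(bot)) / 2.0
        top_l = np.asarray(layers.boundary_depth("ipl_inl", ys, xs))
        bot_l = np.asarray(layers.boundary_depth("inl_opl", ys, xs))
        return (top_l + bot_l) / 2.0 + delta
    # ONL granules: fixed depth (spheres do not extend along the scan axis far)
    return np.full(np.shape(xs), obj.center[2])


def _render_scene_scan(
    layers, objects, config, x_scene, y_scene, depth_px, axial_pitch,
    channel, rng_motion=None,
):
    """Render one slice through the scene at scene coordinates (x_scene[i], y_scene[i]).

    channel 'structural': layered background plus hyperreflective solids.
    channel 'motion': flow signal inside perfused vessels, projection
    artifacts under superficial vessels, optional sparse noise.
    """
    n_lat = x_scene.size
    z = np.arange(depth_px) * axial_pitch
    bounds = np.stack([
        np.asarray(layers.boundary_depth(n, y_scene, x_scene)) for n in BOUNDARY_NAMES
    ])  # (5, n_lat)
    if channel == "structural":
        bg = config.background
        values = np.array([
            bg["vitreous"], bg["IPL"], bg["INL"], bg["OPL"], bg["ONL"], bg["posterior"],
        ])
        idx = (z[:, None] >= bounds[:, None, :]).sum(axis=0)  # (depth, n_lat)
        img = values[idx]
    else:
        img = np.zeros((depth_px, n_lat))

    for obj in objects:
        if channel == "motion" and (obj.kind == "granule" or not obj.perfused):
            continue
        p0, p1 = obj.endpoints()
        seg = p1 - p0
        seg2 = float(seg @ seg)
        pts = np.stack([x_scene, y_scene], axis=-1)
        if seg2 == 0.0:
            t = np.zeros(n_lat)
        else:
            t = np.clip((pts - p0) @ seg / seg2, 0.0, 1.0)
        closest = p0[None, :] + t[:, None] * seg[None, :]
        dist = np.linalg.norm(pts - closest, axis=1)
        r = obj.radius
        lat_pitch = abs(x_scene[1] - x_scene[0]) if n_lat > 1 else 5.7
        cols = np.nonzero(dist < r + 0.5 * lat_pitch)[0]
        if cols.size == 0:
            continue
        zc = _object_depth_profile(obj, layers, x_scene[cols], y_scene[cols], config)
        if channel == "structural":
            if obj.kind == "superficial_vessel":
                amp = config.vessel_reflectivity
            else:
                layer_bg = config.background["ONL" if obj.layer_attachment == "ONL" else "INL"]
                amp = (config.dot_contrast - 1.0) * layer_bg
        else:
            amp = 1.0
        z_edges = np.arange(depth_px + 1) * axial_pitch - 0.5 * axial_pitch
        dist_cols = dist[cols]
        for j, col in enumerate(cols):
            # partial-volume fill: lateral pixel coverage of the disc edge and
            # per-row overlap with the chord keep sub-pixel objects faithful
            d_eff = min(dist_cols[j], r)
            h = math.sqrt(max(r**2 - d_eff**2, 0.0))
            w_lat = float(np.clip((r + 0.5 * lat_pitch - dist_cols[j]) / lat_pitch, 0.0, 1.0))
            z0, z1 = zc[j] - h, zc[j] + h
            lo = max(int(math.floor(z0 / axial_pitch + 0.5)), 0)
            hi = min(int(math.ceil(z1 / axial_pitch - 0.5)), depth_px - 1)
            if hi < lo - 1:
                continue
            rows = np.arange(max(lo - 1, 0), min(hi + 2, depth_px))
            cover = (
                np.minimum(z_edges[rows + 1], z1) - np.maximum(z_edges[rows], z0)
            ) / axial_pitch
            cover = np.clip(cover, 0.0, 1.0)
            if channel == "structural":
                img[rows, col] += amp * w_lat * cover
            else:
                sel = rows[w_lat * cover >= 0.25]
                img[sel, col] = 1.0
        if channel == "motion" and obj.kind == "superficial_vessel":
            # projection artifact: speckly flow signal cast posterior to the vessel
            art_cols = cols[dist[cols] < 0.7 * r]
            for j, col in zip(np.nonzero(dist[cols] < 0.7 * r)[0], art_cols):
                lo = int(math.ceil((zc[j] + r) / axial_pitch)) + 1
                hi = min(int(bounds[4, col] / axial_pitch), depth_px - 1)
                if hi > lo and rng_motion is not None and config.projection_artifact_density > 0:
                    hits = rng_motion.uniform(size=hi - lo) < config.projection_artifact_density
                    img[lo:hi, col][hits] = 1.0

    if channel == "motion" and rng_motion is not None and config.motion_noise_density > 0:
        band = (z[:, None] >= bounds[0, None, :]) & (z[:, None] <= bounds[4, None, :])
        noise = rng_motion.uniform(size=img.shape) < config.motion_noise_density
        img[band & noise] = 1.0
    return img


def _apply_speckle(volume, protocol, config, rng) -> np.ndarray:
    if config.speckle_shape_per_frame is None:
        return volume
    k = config.speckle_shape_per_frame * protocol.n_averaged_frames
    return volume * rng.gamma(k, 1.0 / k, size=volume.shape)


def _psf_sigmas(protocol) -> tuple[float, float]:
    to_sigma = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return (
        protocol.axial_resolution * to_sigma / protocol.axial_pitch,
        protocol.lateral_resolution * to_sigma / protocol.lateral_pitch,
    )


def render_structural(
    layers: LayerModel,
    objects: list[GroundTruthObject],
    config: PhantomConfig,
    protocol: ScanProtocol | None = None,
    rng: np.random.Generator | None = None,
) -> BScanStack:
    """Render the structural stack: per-layer background, objects blurred by
    the instrument PSF (in-plane), multiplicative speckle with variance
    ∝ 1/n_averaged_frames.  Dots cast no back-shadow."""
    protocol = protocol or config.structural_protocol
    if rng is None:
        rng = _seeds(config)["speckle_structural"]
    origin_lat, origin_scan = config.structural_origin()
    xs = origin_lat + np.arange(protocol.n_lateral) * protocol.lateral_pitch
    sig_ax, sig_lat = _psf_sigmas(protocol)
    vol = np.empty((protocol.n_scans, config.depth_px, protocol.n_lateral), dtype=np.float32)
    for i in range(protocol.n_scans):
        y = origin_scan + i * protocol.scan_spacing
        img = _render_scene_scan(
            layers, objects, config, xs, np.full(xs.shape, y),
            config.depth_px, protocol.axial_pitch, "structural",
        )
        vol[i] = gaussian_filter(img, sigma=(sig_ax, sig_lat), mode="nearest")
    vol = _apply_speckle(vol, protocol, config, rng)
    return BScanStack(
        reflectivity=np.clip(vol, 0.0, None),
        protocol=protocol,
        origin_offset=(origin_lat, origin_scan),
    )


def render_angiographic(
    layers: LayerModel,
    objects: list[GroundTruthObject],
    config: PhantomConfig,
    protocol: ScanProtocol | None = None,
    misregistration: tuple[float, float, float] | None = None,
    rng_speckle: np.random.Generator | None = None,
    rng_motion: np.random.Generator | None = None,
) -> BScanStack:
    """Render the angiographic stack in its own (misregistered) frame.

    The structural channel is rendered like :func:`render_structural` at
    7-frame noise; the motion-contrast channel is positive inside perfused
    vessels only, plus projection artifacts posterior to superficial
    vessels and sparse noise speckles.  The whole stack is displaced from
    the structural frame by the configured rigid en-face misregistration
    ``p_angio = R(rot) · p_scene + t`` (rotation about the fovea center).
    """
    protocol = protocol or config.angiographic_protocol
    if misregistration is None:
        misregistration = config.misregistration
    seeds = None
    if rng_speckle is None or rng_motion is None:
        seeds = _seeds(config)
    rng_speckle = rng_speckle or seeds["speckle_angiographic"]
    rng_motion = rng_motion or seeds["motion_noise"]
    dx, dy, rot = misregistration
    Rinv = _rotation(-rot)
    t = np.array([dx, dy])
    origin_lat, origin_scan = config.angiographic_origin()
    xa = origin_lat + np.arange(protocol.n_lateral) * protocol.lateral_pitch
    sig_ax, sig_lat = _psf_sigmas(protocol)
    shape = (protocol.n_scans, config.depth_px, protocol.n_lateral)
    refl = np.empty(shape, dtype=np.float32)
    motion = np.empty(shape, dtype=np.float32)
    for i in range(protocol.n_scans):
        ya = origin_scan + i * protocol.scan_spacing
        pts_a = np.stack([xa, np.full(xa.shape, ya)], axis=-1)
        pts_s = (pts_a - t) @ Rinv.T
        x_scene, y_scene = pts_s[:, 0], pts_s[:, 1]
        img = _render_scene_scan(
            layers, objects, config, x_scene, y_scene,
            config.depth_px, protocol.axial_pitch, "structural",
        )
        refl[i] = gaussian_filter(img, sigma=(sig_ax, sig_lat), mode="nearest")
        motion[i] = _render_scene_scan(
            layers, objects, config, x_scene, y_scene,
            config.depth_px, protocol.axial_pitch, "motion", rng_motion=rng_motion,
        )
    refl = _apply_speckle(refl, protocol, config, rng_speckle)
    return BScanStack(
        reflectivity=np.clip(refl, 0.0, None),
        protocol=protocol,
        origin_offset=(origin_lat, origin_scan),
        motion_contrast=motion,
    )


@dataclass
class PhantomPair:
    structural: BScanStack
    angiographic: BScanStack
    layers: LayerModel
    objects: list[GroundTruthObject]
    config: PhantomConfig
    true_transform: tuple[float, float, float]   # (lateral µm, scan-axis µm, deg)


def generate_pair(config: PhantomConfig) -> PhantomPair:
    """Generate the full phantom: layers, objects, both stacks, ground truth.

    Deterministic for a fixed config (bit-identical volumes); the
    structural speckle stream is independent of the motion-contrast
    geometry and noise streams.
    """
    rngs = _seeds(config)
    layers = make_layer_geometry(config, rngs["layers"])
    objects = plant_objects(layers, config, rngs["objects"])
    structural = render_structural(layers, objects, config, rng=rngs["speckle_structural"])
    angiographic = render_angiographic(
        layers, objects, config,
        rng_speckle=rngs["speckle_angiographic"], rng_motion=rngs["motion_noise"],
    )
    return PhantomPair(structural, angiographic, layers, objects, config, config.misregistration)


# ---------------------------------------------------------------------------
# ground-truth persistence

_TRUTH_COLUMNS = [
    "id", "kind", "lateral_um", "scanaxis_um", "depth_um", "axial_diameter_um",
    "length_um", "orient_lat", "orient_scan", "orient_depth",
    "layer_attachment", "perfused", "branch_of",
]


def export_truth(objects: list[GroundTruthObject], path) -> None:
    """Write ground truth as CSV, one row per object; lossless reload."""
    rows = [
        {
            "id": o.id, "kind": o.kind,
            "lateral_um": o.center[0], "scanaxis_um": o.center[1], "depth_um": o.center[2],
            "axial_diameter_um": o.axial_diameter, "length_um": o.length,
            "orient_lat": o.orientation[0], "orient_scan": o.orientation[1],
            "orient_depth": o.orientation[2],
            "layer_attachment": o.layer_attachment,
            "perfused": "" if o.perfused is None else str(o.perfused),
            "branch_of": "" if o.branch_of is None else o.branch_of,
        }
        for o in objects
    ]
    ids = [o.id for o in objects]
    if len(set(ids)) != len(ids):
        raise ValueError("object ids must be unique")
    pd.DataFrame(rows, columns=_TRUTH_COLUMNS).to_csv(path, index=False)


def load_truth(path) -> list[GroundTruthObject]:
    df = pd.read_csv(Path(path), keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        out.append(GroundTruthObject(
            id=int(r["id"]), kind=r["kind"],
            center=(float(r["lateral_um"]), float(r["scanaxis_um"]), float(r["depth_um"])),
            axial_diameter=float(r["axial_diameter_um"]), length=float(r["length_um"]),
            orientation=(float(r["orient_lat"]), float(r["orient_scan"]), float(r["orient_depth"])),
            layer_attachment=r["layer_attachment"],
            perfused=None if r["perfused"] == "" else r["perfused"] == "True",
            branch_of=None if r["branch_of"] == "" else int(r["branch_of"]),
        ))
    return out
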
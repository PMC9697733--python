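"""Structural↔angiographic alignment and perfusion-based classification.

The two stacks are acquired separately and differ by a small rigid en-face
displacement.  Alignment maximizes the normalized cross-correlation of the
depth-projected structural channels over a rotation/shift search, then each
element's footprint is mapped into the angiographic frame (checking the
mapped B-scan and its ±1 neighbours, the tolerance the manual grading
allowed) and tested for motion-contrast signal inside it.  The final
classes are: granule, perfused filiform, non-perfused filiform, or
unclassifiable (no correlate of the dot on the angiographic scans).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter, median_filter, shift as nd_shift
from skimage.registration import phase_cross_correlation

from .io_core import BScanStack, ClassificationParams
from .tracing import Element

__all__ = [
    "AlignmentError",
    "AlignmentTransform",
    "PerfusionAssessment",
    "ClassifiedElement",
    "align_stacks",
    "assess_perfusion",
    "classify_element",
]


class AlignmentError(RuntimeError):
    """The correlation peak is too weak to trust the alignment."""


@dataclass(frozen=True)
class AlignmentTransform:
    """Rigid en-face mapping ``p_angio = R(rotation) · p_structural + t``,
    rotation about the fovea center, translation in µm."""

    lateral_shift: float
    scanaxis_shift: float
    rotation: float          # degrees
    residual: float          # RMS intensity residual of the registered overlap

    def map_points(self, lateral_um, scanaxis_um) -> tuple[np.ndarray, np.ndarray]:
        th = math.radians(self.rotation)
        c, s = math.cos(th), math.sin(th)
        x = np.asarray(lateral_um, dtype=float)
        y = np.asarray(scanaxis_um, dtype=float)
        return c * x - s * y + self.lateral_shift, s * x + c * y + self.scanaxis_shift

    def matched_scan_index(
        self, structural: BScanStack, angiographic: BScanStack, lateral_ref: float = 1000.0
    ) -> np.ndarray:
        """Angiographic scan index nearest to each structural scan at the
        reference lateral position; monotone in the structural index."""
        ys = structural.scanaxis_coords()
        _, ya = self.map_points(np.full(ys.shape, lateral_ref), ys)
        idx = np.round(
            (ya - angiographic.origin_offset[1]) / angiographic.protocol.scan_spacing
        ).astype(int)
        return np.clip(idx, 0, angiographic.protocol.n_scans - 1)


def _enface(stack: BScanStack) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Depth-mean projection of the structural channel, high-pass filtered so
    vessels and dots (not the nearly uniform layered background) drive the
    registration; physical axes returned alongside."""
    img = stack.reflectivity.mean(axis=1)
    sigma = (60.0 / stack.protocol.scan_spacing, 60.0 / stack.protocol.lateral_pitch)
    img = img - gaussian_filter(img, sigma=sigma, mode="nearest")
    return img, stack.scanaxis_coords(), stack.lateral_coords()


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = a.std() * b.std()
    return float((a * b).mean() / denom) if denom > 0 else 0.0


def align_stacks(
    structural: BScanStack,
    angiographic: BScanStack,
    grid_um: float = 5.0,
    ncc_floor: float = 0.2,
    split_um: float | None = None,
) -> AlignmentTransform:
    """Estimate the rigid en-face transform between the two stacks.

    Both depth projections are resampled onto a common µm grid.  The field
    is split into two lateral halves that are registered independently by
    subpixel phase correlation; the scan-axis shift difference between the
    halves over their lateral lever arm measures the rotation, the mean
    shifts the translation (iterated to convergence).  Raises
    :class:`AlignmentError` when the registered normalized
    cross-correlation stays below ``ncc_floor``.
    """
    s_img, s_y, s_x = _enface(structural)
    a_img, a_y, a_x = _enface(angiographic)
    gy = np.arange(s_y[0], s_y[-1] + 1e-6, grid_um)
    gx = np.arange(s_x[0], s_x[-1] + 1e-6, grid_um)
    s_interp = RegularGridInterpolator((s_y, s_x), s_img, bounds_error=False, fill_value=None)
    a_interp = RegularGridInterpolator((a_y, a_x), a_img, bounds_error=False, fill_value=None)
    GY, GX = np.meshgrid(gy, gx, indexing="ij")
    S = s_interp(np.stack([GY.ravel(), GX.ravel()], axis=-1)).reshape(GY.shape)
    S = (S - S.mean()) / max(S.std(), 1e-9)
    if split_um is None:
        split_um = float(gx[0] + (gx[-1] - gx[0]) / 2.5)
    halves = [gx < split_um, gx >= split_um]

    def warp(theta_deg: float) -> np.ndarray:
        th = math.radians(theta_deg)
        c, s = math.cos(th), math.sin(th)
        qx = c * GX - s * GY
        qy = s * GX + c * GY
        W = a_interp(np.stack([qy.ravel(), qx.ravel()], axis=-1)).reshape(GY.shape)
        return (W - W.mean()) / max(W.std(), 1e-9)

    theta = 0.0
    delta = np.zeros(2)   # residual displacement (scan-axis, lateral) on the warped frame
    for _ in range(6):
        W = warp(theta)
        # S(p) = W(p + d(p)) with d(p) ~ const + residual rotation about the fovea
        levers, dys, dxs = [], [], []
        for cols in halves:
            Sp, Wp = S[:, cols], W[:, cols]
            if Sp.std() < 1e-6:
                continue
            shift_px, _, _ = phase_cross_correlation(
                Sp, Wp, upsample_factor=50, normalization=None
            )
            d = -shift_px * grid_um
            weights = (Sp**2).sum(axis=0)
            levers.append(float(np.average(gx[cols], weights=weights)))
            dys.append(float(d[0]))
            dxs.append(float(d[1]))
        if not levers:
            raise AlignmentError("no usable structure in the en-face projections")
        if len(levers) == 2 and abs(levers[1] - levers[0]) > 100.0:
            d_theta = math.degrees(
                math.asin(np.clip((dys[1] - dys[0]) / (levers[1] - levers[0]), -0.2, 0.2))
            )
        else:
            d_theta = 0.0
        dy0 = dys[0] - math.sin(math.radians(d_theta)) * levers[0]
        delta = np.array([dy0, float(np.mean(dxs))])
        theta += d_theta
        if abs(d_theta) < 0.005:
            break
    # residual displacement on the theta-warped frame is R(theta)^-1 t
    th = math.radians(theta)
    c, s = math.cos(th), math.sin(th)
    dx = c * delta[1] - s * delta[0]
    dy = s * delta[1] + c * delta[0]
    W = warp(theta)
    aligned = nd_shift(W, -delta / grid_um, order=1, mode="nearest")
    best_ncc = _ncc(S, aligned)
    if best_ncc < ncc_floor:
        raise AlignmentError(f"correlation peak {best_ncc:.3f} below floor {ncc_floor}")
    residual = float(np.sqrt(np.mean((S - aligned) ** 2)))
    return AlignmentTransform(
        lateral_shift=float(dx), scanaxis_shift=float(dy),
        rotation=float(theta), residual=residual,
    )


@dataclass(frozen=True)
class PerfusionAssessment:
    overlap_fraction: float      # element scans with interior motion signal / n_scans
    adjacent_signal: bool        # signal consistently beside, not inside, the dot
    projection_risk: bool        # superficial flow signal directly anterior
    retrievable: bool            # dot has a correlate on the angiographic scans
    correlate_fraction: float = 0.0


def _window(center_idx: int, half: int, size: int) -> slice:
    return slice(max(center_idx - half, 0), min(center_idx + half + 1, size))


def assess_perfusion(
    element: Element,
    angio: BScanStack,
    transform: AlignmentTransform,
    params: ClassificationParams = ClassificationParams(),
) -> PerfusionAssessment:
    """Map each of the element's detections into the angiographic frame and
    test the motion-contrast channel inside (and beside) its footprint.

    For every scan the element occupies, the mapped angiographic scan and
    its ±``alignment_tolerance_scans`` neighbours are checked.  A detection
    outside the angiographic field, or one whose footprint shows no
    structural correlate in at least half of the scans, makes the element
    non-retrievable.
    """
    if angio.motion_contrast is None:
        raise ValueError("angiographic stack carries no motion-contrast channel")
    proto = angio.protocol
    z = angio.depth_coords()
    n_lat, n_dep = angio.shape[2], angio.shape[1]
    interior_hits = adjacent_hits = projection_hits = correlate_hits = 0
    in_field = True
    for det in element.detections:
        xa, ya = transform.map_points(det.lateral, det.scanaxis)
        xa, ya = float(xa), float(ya)
        j0 = int(round((ya - angio.origin_offset[1]) / proto.scan_spacing))
        xi = int(round((xa - angio.origin_offset[0]) / proto.lateral_pitch))
        zi = int(round(det.depth / proto.axial_pitch))
        tol = params.alignment_tolerance_scans
        if not (0 <= j0 < proto.n_scans and 0 <= xi < n_lat and 0 <= zi < n_dep):
            in_field = False
            continue
        r = det.axial_diameter / 2.0
        lat_half = int(round((r + proto.lateral_pitch + 6.0) / proto.lateral_pitch))
        dep_half = int(round((r + 4.0) / proto.axial_pitch))
        adj_lat = int(round(params.adjacency_window / proto.lateral_pitch))
        adj_dep = int(round(params.adjacency_window / proto.axial_pitch))
        sl_lat = _window(xi, lat_half, n_lat)
        sl_dep = _window(zi, dep_half, n_dep)
        sl_lat_w = _window(xi, lat_half + adj_lat, n_lat)
        sl_dep_w = _window(zi, dep_half + adj_dep, n_dep)
        interior = adjacent = projection = correlate = False
        for j in range(max(j0 - tol, 0), min(j0 + tol, proto.n_scans - 1) + 1):
            motion = angio.motion_contrast[j]
            inner = motion[sl_dep, sl_lat]
            # a real flow signal fills the lumen; demand two voxels so an
            # isolated noise speckle cannot fake perfusion
            if np.count_nonzero(inner > 0.5) >= 2:
                interior = True
            ring = motion[sl_dep_w, sl_lat_w].copy()
            r0 = sl_dep.start - sl_dep_w.start
            c0 = sl_lat.start - sl_lat_w.start
            ring[r0:r0 + (sl_dep.stop - sl_dep.start),
                 c0:c0 + (sl_lat.stop - sl_lat.start)] = 0.0
            if np.any(ring > 0.5):
                adjacent = True
            z_above = max(int((det.depth - r - params.adjacency_window) / proto.axial_pitch), 0)
            if z_above > 0 and np.any(motion[:z_above, sl_lat] > 0.5):
                projection = True
            refl = median_filter(angio.reflectivity[j][sl_dep, sl_lat], size=(3, 3))
            strip = angio.reflectivity[j][sl_dep, _window(xi, lat_half + 16, n_lat)]
            bg = float(np.median(strip))
            if bg > 0 and float(np.quantile(refl, 0.9)) / bg >= 1.3:
                correlate = True
        interior_hits += interior
        adjacent_hits += adjacent and not interior
        projection_hits += projection
        correlate_hits += correlate
    n = element.n_scans
    overlap = interior_hits / n
    retrievable = in_field and (correlate_hits / n) >= 0.5
    return PerfusionAssessment(
        overlap_fraction=overlap,
        adjacent_signal=(adjacent_hits / n) >= params.perfusion_overlap_fraction,
        projection_risk=projection_hits > 0,
        retrievable=retrievable,
        correlate_fraction=correlate_hits / n,
    )


@dataclass(frozen=True)
class ClassifiedElement:
    element: Element
    final_class: str             # granule | perfused_filiform | nonperfused_filiform | unclassifiable
    motion_overlap_fraction: float
    adjacent_signal: bool
    projection_risk: bool
    retrievable: bool


def classify_element(
    element: Element,
    assessment: PerfusionAssessment,
    params: ClassificationParams = ClassificationParams(),
) -> ClassifiedElement:
    """Final class from shape and motion-contrast overlap.

    Non-retrievable elements are unclassifiable.  Granule-shaped elements
    without interior flow are granules (a granule-shaped element *with*
    flow contradicts both definitions and is unclassifiable).  Elongated
    elements are perfused filiform when flow overlaps at least
    ``perfusion_overlap_fraction`` of their scans, non-perfused filiform
    otherwise (including the flow-consistently-beside-the-dot reading).
    Projection risk is carried as a flag, never a class.
    """
    if element.shape_class is None:
        raise ValueError("classify_shape must run before classify_element")
    thr = params.perfusion_overlap_fraction
    if not assessment.retrievable:
        final = "unclassifiable"
    elif element.shape_class == "granule":
        final = "granule" if assessment.overlap_fraction < thr else "unclassifiable"
    else:
        final = "perfused_filiform" if assessment.overlap_fraction >= thr else "nonperfused_filiform"
    return ClassifiedElement(
        element=element,
        final_class=final,
        motion_overlap_fraction=assessment.overlap_fraction,
        adjacent_signal=assessment.adjacent_signal,
        projection_risk=assessment.projection_risk,
        retrievable=assessment.retrievable,
    )
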
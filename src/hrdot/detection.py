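"""Per-B-scan detection of hyperreflective dots inside layer-defined bands.

Detection works on a background-suppressed copy of the structural stack in
which every voxel holds its contrast over the local median background
(background ≈ 1).  Candidates are local maxima above a contrast threshold
inside the nuclear-layer band; each detection carries an axial
full-width-at-half-maximum diameter, its distance to the nearest band
boundary and — for INL detections — a location category (attached to the
IPL, attached to the OPL, or free inside the INL).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter, percentile_filter
from skimage.feature import peak_local_max
from skimage.transform import resize

from .io_core import BScanStack, ClassificationParams, LayerModel

__all__ = [
    "DotDetection",
    "suppress_background",
    "detect_dots",
    "measure_axial_diameter",
    "assign_location",
    "filter_onl",
]

# band-interior margins (µm) excluding the blurred boundary transition itself
_BAND_MARGIN = {"INL": 4.0, "ONL": 8.0}
# sub-resolution floor: a measured FWHM below this is a speckle/boundary blob,
# not a dot (the graded dots measure >= 10 µm axially)
_MIN_DIAMETER = 6.0


@dataclass(frozen=True)
class DotDetection:
    """One hyperreflective dot on one B-scan; positions in physical µm."""

    scan_index: int
    lateral: float                   # µm temporal of the fovea
    scanaxis: float                  # µm along the slow axis
    depth: float                     # µm
    axial_diameter: float            # µm, FWHM
    peak_contrast: float             # peak over local median background
    layer: str                       # 'INL' | 'ONL'
    location: str                    # near_IPL | near_OPL | inside_INL | not_applicable
    distance_to_nearest_boundary: float  # µm, from the dot center
    diameter_capped: bool = False    # FWHM not bounded inside the band

    def __post_init__(self) -> None:
        if self.axial_diameter <= 0:
            raise ValueError("axial_diameter must be > 0")
        if (self.layer == "ONL") != (self.location == "not_applicable"):
            raise ValueError("location is defined exactly for INL detections")


def suppress_background(stack: BScanStack) -> BScanStack:
    """Median-filter each B-scan and normalize by the local median background.

    The returned stack holds contrast ratios (background ≈ 1).  The median
    footprint is 3 px axially (the axial profile of a >=10 µm dot has a
    flat core at the acquisition pitch, so object peaks survive within 10%
    of their peak-to-background ratio); the background window is short
    axially and long laterally so it tracks a layer band rather than
    averaging across bands.
    """
    vol = stack.reflectivity
    out = np.empty_like(vol)
    for i in range(vol.shape[0]):
        med = median_filter(vol[i], size=(3, 1), mode="nearest")
        # local background from a coarse grid (cheap large window); a low
        # quantile keeps the estimate anchored to the hyporeflective band
        # even when the window reaches into a bright plexiform layer
        small = resize(med, (max(vol.shape[1] // 2, 8), max(vol.shape[2] // 4, 8)),
                       anti_aliasing=False, preserve_range=True)
        bg_small = percentile_filter(small, 25, size=(5, 5), mode="nearest")
        bg = resize(bg_small, med.shape, preserve_range=True)
        out[i] = med / np.maximum(bg, 1e-6)
    return BScanStack(
        reflectivity=out,
        protocol=stack.protocol,
        origin_offset=stack.origin_offset,
        motion_contrast=None,
    )


def _band_rows(stack, layers, layer, scanaxis, lateral):
    top, bot = layers.band(layer, scanaxis, lateral)
    return np.asarray(top), np.asarray(bot)


def detect_dots(
    suppressed: BScanStack,
    layers: LayerModel,
    params: ClassificationParams = ClassificationParams(),
    roi: str = "INL",
) -> list[DotDetection]:
    """Detect dots on every scan of a background-suppressed stack.

    ``roi='INL'`` restricts candidates to the band between the IPL/INL and
    INL/OPL interfaces and to the parafoveal region of interest
    (``roi_inner``–``roi_outer`` µm temporal of the fovea); ``roi='ONL'``
    scans the full lateral field between the OPL/ONL interface and the
    outer limit of the ONL.
    """
    if layers is None:
        raise ValueError("a layer model is required for detection")
    layer = "INL" if roi.upper().startswith("INL") else "ONL"
    vol = suppressed.reflectivity
    lat = suppressed.lateral_coords()
    z = suppressed.depth_coords()
    scan_pos = suppressed.scanaxis_coords()
    margin = _BAND_MARGIN[layer]
    min_dist_px = max(
        int(round(12.0 / suppressed.protocol.lateral_pitch)),
        int(round(12.0 / suppressed.protocol.axial_pitch)),
        2,
    )
    detections: list[DotDetection] = []
    pitch = suppressed.protocol.axial_pitch
    for i in range(vol.shape[0]):
        top, bot = _band_rows(suppressed, layers, layer, scan_pos[i], lat)
        # hysteresis: candidates come from the eroded band interior at a lower
        # floor (a dot attached to a boundary may have its apparent peak inside
        # the blurred boundary transition), then each candidate is promoted to
        # the full-band column maximum, which must clear the real threshold
        mask = (z[:, None] >= top[None, :] + margin) & (z[:, None] <= bot[None, :] - margin)
        if layer == "INL":
            mask &= (lat >= params.roi_inner)[None, :] & (lat <= params.roi_outer)[None, :]
        img = np.where(mask, vol[i], 0.0)
        peaks = peak_local_max(
            img, min_distance=min_dist_px,
            threshold_abs=0.92 * params.contrast_threshold, exclude_border=False,
        )
        seen: set[tuple[int, int]] = set()
        scan_dets: list[DotDetection] = []
        for zi, xi in peaks:
            zbest, xbest, vbest = int(zi), int(xi), float(vol[i, zi, xi])
            for xc in range(max(xi - 1, 0), min(xi + 2, vol.shape[2])):
                lo = max(int(np.ceil(top[xc] / pitch)), int(zi) - 2, 0)
                hi = min(int(np.floor(bot[xc] / pitch)), int(zi) + 2, vol.shape[1] - 1)
                if hi < lo:
                    continue
                zc = lo + int(np.argmax(vol[i, lo:hi + 1, xc]))
                if vol[i, zc, xc] > vbest:
                    zbest, xbest, vbest = zc, int(xc), float(vol[i, zc, xc])
            if vbest < params.contrast_threshold or (zbest, xbest) in seen:
                continue
            seen.add((zbest, xbest))
            det = _measure_at_peak(
                suppressed, layers, layer, params,
                scan_index=i, z_index=zbest, x_index=xbest,
                top=float(top[xbest]), bot=float(bot[xbest]),
            )
            if det is not None and det.axial_diameter >= _MIN_DIAMETER:
                scan_dets.append(det)
        # one detection per dot: candidate plateaus can promote to adjacent
        # pixels, so merge detections closer than a dot radius
        scan_dets.sort(key=lambda d: (-d.peak_contrast, -d.axial_diameter, d.lateral))
        kept: list[DotDetection] = []
        for det in scan_dets:
            if all(abs(det.lateral - k.lateral) > 12.0 or abs(det.depth - k.depth) > 12.0
                   for k in kept):
                kept.append(det)
        detections.extend(kept)
    detections.sort(key=lambda d: (d.scan_index, d.lateral, d.depth))
    return detections


def _axial_fwhm(profile, z, peak_idx, top, bot, axial_pitch):
    """FWHM of a contrast profile (background ≈ 1) about ``peak_idx``,
    searched inside the band [top, bot] widened by one pixel; returns
    (diameter µm, center depth µm, capped flag)."""
    peak = profile[peak_idx]
    half = (peak + 1.0) / 2.0
    lo_lim = max(int(np.floor((top - axial_pitch) / axial_pitch)), 0)
    hi_lim = min(int(np.ceil((bot + axial_pitch) / axial_pitch)), profile.size - 1)
    capped = False

    def cross(direction):
        nonlocal capped
        j = peak_idx
        while True:
            nxt = j + direction
            if nxt < lo_lim or nxt > hi_lim:
                # profile not bounded inside the band: cap at the boundary
                capped = True
                return bot if direction > 0 else top
            if profile[nxt] < half:
                frac = (profile[j] - half) / max(profile[j] - profile[nxt], 1e-9)
                return z[j] + direction * frac * axial_pitch
            j = nxt

    z_lo, z_hi = cross(-1), cross(+1)
    return float(z_hi - z_lo), float((z_hi + z_lo) / 2.0), capped


def _measure_at_peak(suppressed, layers, layer, params, scan_index, z_index, x_index, top, bot):
    vol = suppressed.reflectivity
    z = suppressed.depth_coords()
    # the peak pixel can sit laterally off the dot center (pixel quantization),
    # where a single column samples a chord of the dot; the per-row maximum
    # over the pixel and its lateral neighbours approximates the profile
    # through the center, while a boundary ramp's envelope stays a ramp
    lo_c = max(x_index - 1, 0)
    hi_c = min(x_index + 2, vol.shape[2])
    profile = vol[scan_index, :, lo_c:hi_c].max(axis=1)
    diameter, center, capped = _axial_fwhm(
        profile, z, z_index, top, bot, suppressed.protocol.axial_pitch
    )
    if diameter <= 0:
        return None
    lateral = float(suppressed.lateral_coords()[x_index])
    scanaxis = float(suppressed.scanaxis_coords()[scan_index])
    dist = float(min(center - top, bot - center))
    location = "not_applicable"
    if layer == "INL":
        location = _location_from_extent(center, diameter, top, bot)
    return DotDetection(
        scan_index=scan_index,
        lateral=lateral,
        scanaxis=scanaxis,
        depth=center,
        axial_diameter=diameter,
        peak_contrast=float(profile[z_index]),
        layer=layer,
        location=location,
        distance_to_nearest_boundary=dist,
        diameter_capped=capped,
    )


def measure_axial_diameter(suppressed: BScanStack, detection: DotDetection,
                           layers: LayerModel) -> float:
    """Axial FWHM (µm) of the intensity profile through a detection's peak.

    The profile is evaluated on the background-suppressed stack and the
    half-maximum is taken over the local background level; the search is
    bounded by the detection's layer band (capped and flagged when the
    profile does not come down inside it).
    """
    vol = suppressed.reflectivity
    x_index = int(suppressed.lateral_to_index(detection.lateral))
    z_index = int(suppressed.depth_to_index(detection.depth))
    top, bot = layers.band(detection.layer, detection.scanaxis, detection.lateral)
    lo_c = max(x_index - 1, 0)
    profile = vol[detection.scan_index, :, lo_c:min(x_index + 2, vol.shape[2])].max(axis=1)
    z = suppressed.depth_coords()
    z_index = max(z_index - 2, 0) + int(np.argmax(profile[max(z_index - 2, 0):z_index + 3]))
    diameter, _, _ = _axial_fwhm(
        profile, z, z_index, float(top), float(bot), suppressed.protocol.axial_pitch
    )
    return diameter


def _location_from_extent(depth: float, diameter: float, top: float, bot: float,
                          tol: float = 4.0) -> str:
    r = diameter / 2.0
    touch_top = (depth - r) <= top + tol
    touch_bot = (depth + r) >= bot - tol
    if touch_top and touch_bot:
        return "near_IPL" if (depth - top) <= (bot - depth) else "near_OPL"
    if touch_top:
        return "near_IPL"
    if touch_bot:
        return "near_OPL"
    return "inside_INL"


def assign_location(detection: DotDetection, layers: LayerModel) -> str:
    """Location of an INL dot: attached to the IPL, attached to the OPL, or
    free inside the INL (contact = the dot's axial extent reaches within
    one axial pixel of the boundary; touching both sides resolves to the
    nearer boundary)."""
    top, bot = layers.band("INL", detection.scanaxis, detection.lateral)
    return _location_from_extent(
        detection.depth, detection.axial_diameter, float(top), float(bot)
    )


def filter_onl(detections: list[DotDetection],
               params: ClassificationParams = ClassificationParams()) -> list[DotDetection]:
    """Keep ONL detections with diameter above the grading threshold and a
    boundary distance greater than the dot's own width; order preserved."""
    return [
        d for d in detections
        if d.axial_diameter > params.onl_min_diameter
        and d.distance_to_nearest_boundary > d.axial_diameter
    ]
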
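"""Data model, coordinate conventions and volume/table I/O.

Coordinate contract
-------------------
Volumes are indexed ``[scan, depth, lateral]`` with 0-based indices and
half-open pixel boxes.  The scan axis (first, slow axis) is the direction
perpendicular to the B-scan plane.  Physical positions are expressed in
micrometres (µm):

* lateral: ``index * lateral_pitch + origin_offset[0]``, measured temporal
  from the fovea center (positive temporal);
* scan axis: ``index * scan_spacing + origin_offset[1]``;
* depth: ``index * axial_pitch``, increasing posteriorly from the top of
  the frame.

Every operation in the other modules consumes physical µm at its
interface, never raw indices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "FormatError",
    "ScanProtocol",
    "BScanStack",
    "LayerModel",
    "ClassificationParams",
    "BOUNDARY_NAMES",
    "read_stack",
    "write_stack",
    "load_subject_table",
    "PATIENT_IDS",
    "CONTROL_IDS",
]


class FormatError(ValueError):
    """A persisted volume or sidecar violates the storage contract."""


@dataclass(frozen=True)
class ScanProtocol:
    """Acquisition geometry of one B-scan stack.

    The reference acquisitions are a structural stack of 131 horizontal
    B-scans spaced 11 µm apart (100-frame averaging) and an angiographic
    stack of B-scans spaced 5.9 µm apart (7-frame averaging), both on an
    instrument with a nominal axial resolution of 7 µm and lateral
    resolution of 14 µm.
    """

    n_scans: int
    scan_spacing: float        # µm between adjacent B-scans
    lateral_pitch: float       # µm per pixel within a B-scan
    axial_pitch: float         # µm per pixel in depth
    field_width: float         # µm lateral extent of a B-scan
    n_averaged_frames: int = 1
    axial_resolution: float = 7.0    # µm FWHM of the instrument PSF
    lateral_resolution: float = 14.0  # µm FWHM

    def __post_init__(self) -> None:
        if self.n_scans < 1:
            raise ValueError("n_scans must be >= 1")
        for name in ("scan_spacing", "lateral_pitch", "axial_pitch", "field_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_averaged_frames < 1:
            raise ValueError("n_averaged_frames must be >= 1")

    @property
    def field_depth_scans(self) -> float:
        """Extent of the stack along the scan axis, µm: spacing × (n_scans − 1)."""
        return self.scan_spacing * (self.n_scans - 1)

    @property
    def n_lateral(self) -> int:
        return int(round(self.field_width / self.lateral_pitch))

    def to_dict(self) -> dict:
        return {
            "n_scans": self.n_scans,
            "scan_spacing_um": self.scan_spacing,
            "lateral_pitch_um": self.lateral_pitch,
            "axial_pitch_um": self.axial_pitch,
            "field_width_um": self.field_width,
            "n_averaged_frames": self.n_averaged_frames,
            "axial_resolution_um": self.axial_resolution,
            "lateral_resolution_um": self.lateral_resolution,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScanProtocol":
        try:
            return cls(
                n_scans=int(d["n_scans"]),
                scan_spacing=float(d["scan_spacing_um"]),
                lateral_pitch=float(d["lateral_pitch_um"]),
                axial_pitch=float(d["axial_pitch_um"]),
                field_width=float(d["field_width_um"]),
                n_averaged_frames=int(d.get("n_averaged_frames", 1)),
                axial_resolution=float(d.get("axial_resolution_um", 7.0)),
                lateral_resolution=float(d.get("lateral_resolution_um", 14.0)),
            )
        except KeyError as exc:  # pragma: no cover - message detail
            raise FormatError(f"sidecar missing protocol field {exc}") from exc


@dataclass
class BScanStack:
    """A reflectivity volume with an optional motion-contrast channel.

    ``origin_offset`` is the (lateral µm, scan-axis µm) position of the
    [*, *, 0] / [0, *, *] corner relative to the fovea center.
    """

    reflectivity: np.ndarray          # [scan, depth, lateral], non-negative
    protocol: ScanProtocol
    origin_offset: tuple[float, float] = (0.0, 0.0)
    motion_contrast: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.reflectivity = np.asarray(self.reflectivity, dtype=np.float32)
        if self.reflectivity.ndim != 3:
            raise FormatError("reflectivity must be a 3D [scan, depth, lateral] array")
        if self.reflectivity.shape[0] != self.protocol.n_scans:
            raise FormatError(
                f"n_scans mismatch: protocol says {self.protocol.n_scans}, "
                f"volume has {self.reflectivity.shape[0]} scans"
            )
        if np.any(self.reflectivity < 0):
            raise FormatError("reflectivity must be non-negative")
        expected_w = self.protocol.n_lateral
        if abs(self.reflectivity.shape[2] - expected_w) > 1:
            raise FormatError(
                f"field_width mismatch: protocol implies {expected_w} lateral "
                f"pixels, volume has {self.reflectivity.shape[2]}"
            )
        if self.motion_contrast is not None:
            self.motion_contrast = np.asarray(self.motion_contrast, dtype=np.float32)
            if self.motion_contrast.shape != self.reflectivity.shape:
                raise FormatError("motion_contrast shape differs from reflectivity")
            if np.any(self.motion_contrast < 0):
                raise FormatError("motion_contrast must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.reflectivity.shape

    # physical coordinate axes, µm
    def lateral_coords(self) -> np.ndarray:
        p = self.protocol
        return self.origin_offset[0] + np.arange(self.shape[2]) * p.lateral_pitch

    def depth_coords(self) -> np.ndarray:
        return np.arange(self.shape[1]) * self.protocol.axial_pitch

    def scanaxis_coords(self) -> np.ndarray:
        p = self.protocol
        return self.origin_offset[1] + np.arange(self.shape[0]) * p.scan_spacing

    def lateral_to_index(self, lateral_um) -> np.ndarray:
        return np.round(
            (np.asarray(lateral_um) - self.origin_offset[0]) / self.protocol.lateral_pitch
        ).astype(int)

    def depth_to_index(self, depth_um) -> np.ndarray:
        return np.round(np.asarray(depth_um) / self.protocol.axial_pitch).astype(int)

    def scan_to_index(self, scanaxis_um) -> np.ndarray:
        return np.round(
            (np.asarray(scanaxis_um) - self.origin_offset[1]) / self.protocol.scan_spacing
        ).astype(int)


BOUNDARY_NAMES = ("ipl_inner", "ipl_inl", "inl_opl", "opl_onl", "onl_outer")


@dataclass
class LayerModel:
    """Smooth retinal layer interfaces sampled on a physical (scan-axis, lateral) grid.

    Five surfaces are carried, ordered anterior to posterior: the inner
    edge of the IPL, the IPL/INL interface, the INL/OPL interface, the
    OPL/ONL interface and the outer limit of the ONL.  Depths are µm and
    strictly increase through the ordering at every grid node.  Sampling
    on a physical grid (rather than per scan of one protocol) lets the
    same model serve stacks with different scan spacings.
    """

    scanaxis_um: np.ndarray                 # 1D, strictly increasing
    lateral_um: np.ndarray                  # 1D, strictly increasing
    boundaries: dict[str, np.ndarray]       # name -> [n_scanaxis, n_lateral] depth µm
    fovea_center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.scanaxis_um = np.asarray(self.scanaxis_um, dtype=float)
        self.lateral_um = np.asarray(self.lateral_um, dtype=float)
        missing = [n for n in BOUNDARY_NAMES if n not in self.boundaries]
        if missing:
            raise ValueError(f"missing boundary surfaces: {missing}")
        shape = (self.scanaxis_um.size, self.lateral_um.size)
        for name in BOUNDARY_NAMES:
            arr = np.asarray(self.boundaries[name], dtype=float)
            if arr.shape != shape:
                raise ValueError(f"boundary {name!r} has shape {arr.shape}, expected {shape}")
            self.boundaries[name] = arr
        stackd = np.stack([self.boundaries[n] for n in BOUNDARY_NAMES])
        if not np.all(np.diff(stackd, axis=0) > 0):
            raise ValueError("boundaries must be strictly ordered in depth everywhere")
        self._interp = {
            name: RegularGridInterpolator(
                (self.scanaxis_um, self.lateral_um),
                self.boundaries[name],
                bounds_error=False,
                fill_value=None,  # linear extrapolation at the field margin
            )
            for name in BOUNDARY_NAMES
        }

    def boundary_depth(self, name: str, scanaxis_um, lateral_um) -> np.ndarray:
        """Depth (µm) of the named surface at physical position(s)."""
        y = np.asarray(scanaxis_um, dtype=float)
        x = np.asarray(lateral_um, dtype=float)
        y, x = np.broadcast_arrays(y, x)
        pts = np.stack([y.ravel(), x.ravel()], axis=-1)
        out = self._interp[name](pts).reshape(y.shape)
        return out if out.shape else float(out)

    def band(self, layer: str, scanaxis_um, lateral_um) -> tuple[np.ndarray, np.ndarray]:
        """(top, bottom) depth µm of a nuclear layer band, 'INL' or 'ONL'."""
        if layer == "INL":
            top, bot = "ipl_inl", "inl_opl"
        elif layer == "ONL":
            top, bot = "opl_onl", "onl_outer"
        else:
            raise ValueError("layer must be 'INL' or 'ONL'")
        return (
            self.boundary_depth(top, scanaxis_um, lateral_um),
            self.boundary_depth(bot, scanaxis_um, lateral_um),
        )

    def to_json(self, path) -> None:
        payload = {
            "scanaxis_um": self.scanaxis_um.tolist(),
            "lateral_um": self.lateral_um.tolist(),
            "fovea_center_um": list(self.fovea_center),
            "boundaries": {n: self.boundaries[n].tolist() for n in BOUNDARY_NAMES},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "LayerModel":
        d = json.loads(Path(path).read_text())
        return cls(
            scanaxis_um=np.asarray(d["scanaxis_um"]),
            lateral_um=np.asarray(d["lateral_um"]),
            boundaries={n: np.asarray(v) for n, v in d["boundaries"].items()},
            fovea_center=tuple(d["fovea_center_um"]),
        )


@dataclass(frozen=True)
class ClassificationParams:
    """Grading thresholds.

    Defaults encode the manual grading protocol: elements on no more than
    three adjacent B-scans are granules; outer-nuclear-layer dots count
    only above 15 µm diameter; the parafoveal region of interest runs
    500–1500 µm temporal of the fovea center; structural/angiographic
    correspondence is trusted to ±1 angiographic B-scan.
    """

    granule_max_scans: int = 3
    onl_min_diameter: float = 15.0      # µm, strict ">"
    roi_inner: float = 500.0            # µm temporal of the fovea
    roi_outer: float = 1500.0
    alignment_tolerance_scans: int = 1
    perfusion_overlap_fraction: float = 0.5
    adjacency_window: float = 15.0      # µm, "signal beside the dot"
    contrast_threshold: float = 1.5     # peak over local median background
    link_gate_lateral: float = 20.0     # µm, detection linking gate
    link_gate_depth: float = 15.0       # µm

    def __post_init__(self) -> None:
        if self.roi_inner >= self.roi_outer:
            raise ValueError("roi_inner must be < roi_outer")
        if self.granule_max_scans < 1:
            raise ValueError("granule_max_scans must be >= 1")
        if not 0.0 <= self.perfusion_overlap_fraction <= 1.0:
            raise ValueError("perfusion_overlap_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# volume persistence: multi-page TIFF + JSON sidecar

def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_stack(stack: BScanStack, path) -> None:
    """Persist a stack as a multi-page TIFF plus a JSON metadata sidecar.

    One TIFF page per B-scan; with a motion-contrast channel the page axis
    interleaves as [scan, channel].  Bytes are deterministic for identical
    input (no timestamps are written).
    """
    path = Path(path)
    if stack.motion_contrast is not None:
        data = np.stack([stack.reflectivity, stack.motion_contrast], axis=1)
        channels = ["structural", "motion"]
    else:
        data = stack.reflectivity
        channels = ["structural"]
    tifffile.imwrite(path, data, photometric="minisblack")
    sidecar = dict(stack.protocol.to_dict())
    sidecar["origin_um"] = [stack.origin_offset[0], stack.origin_offset[1]]
    sidecar["channels"] = channels
    _sidecar_path(path).write_text(json.dumps(sidecar, sort_keys=True))


def read_stack(path) -> BScanStack:
    """Load a stack written by :func:`write_stack`; exact round trip at float32."""
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FormatError(f"missing metadata sidecar {sidecar_file.name}")
    meta = json.loads(sidecar_file.read_text())
    protocol = ScanProtocol.from_dict(meta)
    data = tifffile.imread(path)
    channels = meta.get("channels", ["structural"])
    if "motion" in channels:
        if data.ndim != 4 or data.shape[1] != 2:
            raise FormatError("channels lists motion but volume is not 2-channel")
        reflectivity, motion = data[:, 0], data[:, 1]
    else:
        if data.ndim != 3:
            raise FormatError("expected a single-channel 3D volume")
        reflectivity, motion = data, None
    if reflectivity.shape[0] != protocol.n_scans:
        raise FormatError(
            f"n_scans mismatch: sidecar says {protocol.n_scans}, "
            f"volume holds {reflectivity.shape[0]} pages"
        )
    origin = tuple(meta.get("origin_um", (0.0, 0.0)))
    return BScanStack(
        reflectivity=reflectivity,
        protocol=protocol,
        origin_offset=origin,
        motion_contrast=motion,
    )


# ---------------------------------------------------------------------------
# packaged per-subject grading table

PATIENT_IDS = tuple(range(1, 9))
CONTROL_IDS = tuple(range(9, 17))


def load_subject_table() -> pd.DataFrame:
    """Per-subject grading results of the reference study (8 patients with
    diabetic retinopathy, 8 healthy controls), indexed by subject_id.

    Columns carry inner-nuclear-layer dot counts, granule/elongated tallies,
    mean transverse extents (µm), location tallies with printed integer
    percentages, and outer-nuclear-layer counts and extents.  A subject with
    no ONL dots has NaN in ``mean_onl_extent_um`` — the explicit "absent"
    marker (printed as a dash in the source table).
    """
    with resources.files("hrdot.data").joinpath("study_subjects.csv").open("r") as fh:
        df = pd.read_csv(fh)
    return df.set_index("subject_id")
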
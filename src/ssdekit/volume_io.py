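"""CT volume and dose-record I/O.

Reads an axial CT DICOM series into a geometry-validated stack of
Hounsfield-unit slices, writes single-frame CT images (used to export the
slice-averaged image and by the phantom simulator), and loads scan-level
dose metadata from a JSON sidecar that stands in for the Radiation Dose
Structured Report.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _dicom

__all__ = [
    "CTVolume",
    "ScanDoseRecord",
    "GeometryError",
    "read_series",
    "write_slice",
    "write_series",
    "load_dose_record",
]

#: Rescale used when storing HU as signed 16-bit integers.
RESCALE_SLOPE = 1.0
RESCALE_INTERCEPT = -1024.0

_AXIAL_ORIENTATION = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)


class GeometryError(ValueError):
    """Inconsistent slice geometry within one series."""


@dataclass
class CTVolume:
    """Ordered axial HU slices with geometry and per-slice tube loading.

    Parameters
    ----------
    slices : list of 2D float arrays
        CT numbers in HU, one array per axial position, all the same shape.
    z_positions : array-like
        Axial position of each slice in mm, strictly increasing.
    pixel_spacing : (float, float)
        Row and column spacing in mm/pixel.
    slice_thickness : float
        Nominal reconstructed thickness in mm.
    exposures : array-like or None
        Per-slice tube loading mAs(z); ``None`` when unavailable.
    series_id : str
        Opaque series identifier.
    """

    slices: list[np.ndarray]
    z_positions: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_thickness: float = 5.0
    exposures: np.ndarray | None = None
    series_id: str = ""

    def __post_init__(self) -> None:
        if len(self.slices) < 1:
            raise ValueError("CTVolume requires at least one slice")
        self.slices = [np.asarray(s, dtype=float) for s in self.slices]
        shape = self.slices[0].shape
        if any(s.shape != shape or s.ndim != 2 for s in self.slices):
            raise GeometryError("all slices must share one matrix shape")
        self.z_positions = np.asarray(self.z_positions, dtype=float)
        if self.z_positions.shape != (len(self.slices),):
            raise GeometryError("z_positions length must equal slice count")
        dz = np.diff(self.z_positions)
        if len(dz) and not np.all(dz > 0):
            raise GeometryError("z_positions must be strictly increasing")
        self.pixel_spacing = (float(self.pixel_spacing[0]),
                              float(self.pixel_spacing[1]))
        if min(self.pixel_spacing) <= 0:
            raise GeometryError("pixel_spacing components must be positive")
        if self.exposures is not None:
            self.exposures = np.asarray(self.exposures, dtype=float)
            if self.exposures.shape != (len(self.slices),):
                raise ValueError("exposures length must equal slice count")
            if not np.all(self.exposures > 0):
                raise ValueError("exposures must be positive")
        if len(dz) > 1:
            mean_dz = float(np.mean(dz))
            if mean_dz > 0 and np.max(np.abs(dz - mean_dz)) > 0.01 * mean_dz:
                warnings.warn(
                    "slice spacing varies by more than 1%; the unweighted "
                    "slice average changes meaning on nonuniform grids",
                    stacklevel=2)

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices[0].shape

    def pixel_area_cm2(self) -> float:
        """Area of one pixel in cm^2 (spacing is stored in mm)."""
        return self.pixel_spacing[0] * self.pixel_spacing[1] / 100.0


@dataclass
class ScanDoseRecord:
    """Scan-level dose metadata (sidecar stand-in for the RDSR)."""

    mean_ctdi_vol: float
    mean_mas: float
    reference_phantom_diameter: int = 32
    tube_voltage: float | None = None

    def __post_init__(self) -> None:
        if not self.mean_ctdi_vol > 0:
            raise ValueError("mean_ctdi_vol must be positive")
        if not self.mean_mas > 0:
            raise ValueError("mean_mas must be positive")
        if self.reference_phantom_diameter not in (16, 32):
            raise ValueError("reference_phantom_diameter must be 16 or 32")
        if self.reference_phantom_diameter == 16:
            warnings.warn(
                "16 cm reference phantom: the built-in size-conversion "
                "constants target 32 cm trunk protocols and do not apply",
                stacklevel=2)


def load_dose_record(path: str | os.PathLike) -> ScanDoseRecord:
    """Load and validate the JSON dose sidecar."""
    with open(path) as fh:
        data = json.load(fh)
    for key in ("mean_ctdi_vol", "mean_mas", "reference_phantom_diameter"):
        if key not in data:
            raise ValueError(f"dose record is missing required key {key!r}")
    return ScanDoseRecord(
        mean_ctdi_vol=float(data["mean_ctdi_vol"]),
        mean_mas=float(data["mean_mas"]),
        reference_phantom_diameter=int(data["reference_phantom_diameter"]),
        tube_voltage=(float(data["tube_voltage"])
                      if data.get("tube_voltage") is not None else None),
    )


def _check_axial(elements: dict, path: str) -> None:
    orient = elements.get("ImageOrientationPatient")
    if orient is None:
        return
    if any(abs(a - b) > 1e-4 for a, b in zip(orient, _AXIAL_ORIENTATION)):
        raise GeometryError(
            f"{path}: non-axial orientation (tilt unsupported)")


def read_series(directory_path: str | os.PathLike) -> CTVolume:
    """Read an axial CT DICOM series from a directory.

    Files are sorted by the axial (z) component of the slice position, so
    the on-disk file order is irrelevant. Stored values are converted to HU
    via the rescale slope/intercept. Per-slice exposure is taken from
    ExposureInmAs when present (exact) and from the integer Exposure
    attribute otherwise; if any slice lacks both, exposures are dropped
    with a warning.
    """
    paths = sorted(
        os.path.join(directory_path, name)
        for name in os.listdir(directory_path)
        if not name.startswith(".") and not name.endswith(".json")
    )
    if not paths:
        raise ValueError(f"no DICOM files found in {directory_path}")

    records = []
    for path in paths:
        el = _dicom.read_file(path)
        _check_axial(el, path)
        rows, cols = int(el["Rows"]), int(el["Columns"])
        raw = np.frombuffer(el["PixelData"], dtype="<i2").reshape(rows, cols)
        slope = float(el.get("RescaleSlope", 1.0))
        intercept = float(el.get("RescaleIntercept", 0.0))
        hu = raw.astype(float) * slope + intercept
        pos = el.get("ImagePositionPatient", [0.0, 0.0, 0.0])
        z = float(pos[2]) if isinstance(pos, (list, tuple)) else float(pos)
        spacing = el["PixelSpacing"]
        exposure = el.get("ExposureInmAs", el.get("Exposure"))
        records.append({
            "z": z,
            "hu": hu,
            "spacing": (float(spacing[0]), float(spacing[1])),
            "thickness": float(el.get("SliceThickness", 5.0)),
            "exposure": None if exposure is None else float(exposure),
            "series": el.get("SeriesInstanceUID", ""),
            "path": path,
        })

    shapes = {r["hu"].shape for r in records}
    if len(shapes) > 1:
        raise GeometryError(f"mixed matrix sizes in series: {sorted(shapes)}")
    spacings = {r["spacing"] for r in records}
    if len(spacings) > 1:
        raise GeometryError(f"mixed pixel spacings in series: {sorted(spacings)}")

    records.sort(key=lambda r: r["z"])
    zs = [r["z"] for r in records]
    if len(set(zs)) != len(zs):
        raise GeometryError("duplicate slice z positions in series")

    exposures: list[float] | None = [r["exposure"] for r in records]
    if any(e is None for e in exposures):
        warnings.warn("exposure attribute missing on one or more slices; "
                      "per-slice mAs unavailable", stacklevel=2)
        exposures = None

    return CTVolume(
        slices=[r["hu"] for r in records],
        z_positions=np.array(zs),
        pixel_spacing=records[0]["spacing"],
        slice_thickness=records[0]["thickness"],
        exposures=None if exposures is None else np.array(exposures),
        series_id=records[0]["series"],
    )


def write_slice(
    image: np.ndarray,
    pixel_spacing: tuple[float, float],
    z_position: float,
    out_path: str | os.PathLike,
    *,
    slice_thickness: float = 5.0,
    exposure_mas: float | None = None,
    series_id: str | None = None,
    instance_number: int = 1,
) -> None:
    """Write one axial HU image as a single-frame CT DICOM file.

    HU values are stored as signed 16-bit integers with rescale slope 1 and
    intercept -1024, so the round trip is exact to +/-0.5 HU.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    stored = np.round((image - RESCALE_INTERCEPT) / RESCALE_SLOPE)
    stored = np.clip(stored, -32768, 32767).astype("<i2")

    elements = {
        "Modality": "CT",
        "SeriesInstanceUID": series_id or _dicom.generate_uid(),
        "InstanceNumber": int(instance_number),
        "ImagePositionPatient": [0.0, 0.0, float(z_position)],
        "ImageOrientationPatient": list(_AXIAL_ORIENTATION),
        "SliceThickness": float(slice_thickness),
        "SamplesPerPixel": 1,
        "PhotometricInterpretation": "MONOCHROME2",
        "Rows": image.shape[0],
        "Columns": image.shape[1],
        "PixelSpacing": [float(pixel_spacing[0]), float(pixel_spacing[1])],
        "BitsAllocated": 16,
        "BitsStored": 16,
        "HighBit": 15,
        "PixelRepresentation": 1,
        "RescaleIntercept": RESCALE_INTERCEPT,
        "RescaleSlope": RESCALE_SLOPE,
    }
    if exposure_mas is not None:
        elements["Exposure"] = int(round(exposure_mas))
        elements["ExposureInmAs"] = float(exposure_mas)
    _dicom.write_file(os.fspath(out_path), elements, stored.tobytes())


def write_series(volume: CTVolume, out_dir: str | os.PathLike) -> list[str]:
    """Write a CTVolume as one DICOM file per slice; returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    series_id = volume.series_id or _dicom.generate_uid()
    width = max(4, int(math.log10(volume.n_slices)) + 1)
    paths = []
    for i in range(volume.n_slices):
        path = os.path.join(out_dir, f"slice_{i + 1:0{width}d}.dcm")
        write_slice(
            volume.slices[i],
            volume.pixel_spacing,
            float(volume.z_positions[i]),
            path,
            slice_thickness=volume.slice_thickness,
            exposure_mas=(None if volume.exposures is None
                          else float(volume.exposures[i])),
            series_id=series_id,
            instance_number=i + 1,
        )
        paths.append(path)
    return paths
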
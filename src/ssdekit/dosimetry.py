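"""Size-specific dose estimates from CT volumes.

Implements the full per-slice chain — water-equivalent diameter D_w, the
per-slice dose index CTDI_vol,z obtained by scaling the scan-mean CTDI_vol
with the slice's relative tube loading, the exponential size-conversion
factor f(D_w), and SSDE_z = CTDI_vol,z * f(D_w,z) — together with the three
scan-level dose indices built on top of it:

* ``mean_ssde``      — unweighted slice average of SSDE_z (reference standard);
* ``ssde_center``    — mean CTDI_vol * f(D_w of the central slice);
* ``ssde_sai``       — mean CTDI_vol * f(D_w of the slice-averaged image),
  where the slice-averaged image (SAI) is the per-pixel mean of all slices.

A subsampled ``dw_nslice`` baseline (mean D_w from n evenly spaced slices)
is provided for comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .segmentation import ROIStats, SegConfig, segment_body, roi_stats
from .volume_io import CTVolume, ScanDoseRecord

__all__ = [
    "ConversionModel",
    "SliceDoseProfile",
    "ScanDoseSummary",
    "water_equivalent_diameter",
    "conversion_factor",
    "normalized_ctdi",
    "ctdi_vol_z",
    "per_slice_profiles",
    "mean_ssde",
    "center_slice_index",
    "ssde_center",
    "generate_sai",
    "ssde_sai",
    "ssde_sai_slicewise",
    "dw_nslice",
    "summarize_scan",
]


@dataclass(frozen=True)
class ConversionModel:
    """Exponential size-conversion factor f(D_w) = a * exp(-b * D_w).

    Default constants are the published fit for a 32 cm reference phantom
    (D_w in cm); f is dimensionless, strictly decreasing and positive.
    """

    coefficient_a: float = 4.378094
    decay_b: float = 0.04331124  # 1/cm
    valid_dw_range: tuple[float, float] = (6.0, 55.0)

    def __post_init__(self) -> None:
        if not (self.coefficient_a > 0 and self.decay_b > 0):
            raise ValueError("conversion model constants must be positive")


@dataclass
class SliceDoseProfile:
    """Per-slice dose quantities; ``slice_index`` is 1-based, z-ordered."""

    slice_index: int
    z_mm: float
    dw_z: float       # cm
    mas_z: float      # mAs
    ctdi_vol_z: float  # mGy
    f_z: float
    ssde_z: float     # mGy


@dataclass
class ScanDoseSummary:
    """All scan-level dose indices and diameters for one CT scan."""

    normalized_ctdi: float  # mGy/mAs
    mean_dw: float          # cm
    dw_center: float        # cm
    dw_sai: float           # cm
    dw_nslice: float        # cm
    nslice_n: int
    mean_ssde: float        # mGy
    ssde_center: float      # mGy
    ssde_sai: float         # mGy
    n_slices: int

    def __post_init__(self) -> None:
        for name in ("mean_dw", "dw_center", "dw_sai", "dw_nslice"):
            v = getattr(self, name)
            if not 0.0 < v < 100.0:
                raise ValueError(f"{name} = {v:.3f} cm outside (0, 100)")
        for name in ("mean_ssde", "ssde_center", "ssde_sai"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def as_dict(self) -> dict:
        return {
            "normalized_ctdi_mgy_per_mas": self.normalized_ctdi,
            "mean_dw_cm": self.mean_dw,
            "dw_center_cm": self.dw_center,
            "dw_sai_cm": self.dw_sai,
            "dw_nslice_cm": self.dw_nslice,
            "nslice_n": self.nslice_n,
            "mean_ssde_mgy": self.mean_ssde,
            "ssde_center_mgy": self.ssde_center,
            "ssde_sai_mgy": self.ssde_sai,
            "n_slices": self.n_slices,
        }


# ---------------------------------------------------------------------------
# elementary quantities


def water_equivalent_diameter(stats: ROIStats) -> float:
    """Water-equivalent diameter in cm from ROI area and mean CT number.

    D_w = 2 * sqrt((mean_HU/1000 + 1) * A_ROI / pi), with A_ROI in cm^2.
    For pure water (0 HU) this reduces to the effective diameter
    2*sqrt(A/pi); at -1000 HU (air) it is 0.
    """
    if not stats.area_cm2 > 0:
        raise ValueError("ROI area must be positive")
    radicand = (stats.mean_hu / 1000.0 + 1.0) * stats.area_cm2 / math.pi
    if radicand < 0:
        raise ValueError(
            f"mean HU {stats.mean_hu:.1f} below -1000: negative radicand")
    return 2.0 * math.sqrt(radicand)


def conversion_factor(dw: float, model: ConversionModel | None = None) -> float:
    """Size-conversion factor f(D_w) = a * exp(-b * D_w), D_w in cm."""
    model = model or ConversionModel()
    dw = float(dw)
    if dw < 0:
        raise ValueError("D_w must be non-negative")
    lo, hi = model.valid_dw_range
    if not lo <= dw <= hi:
        warnings.warn(
            f"D_w = {dw:.1f} cm outside the fit domain [{lo}, {hi}] cm; "
            "the conversion factor is extrapolated", stacklevel=2)
    return model.coefficient_a * math.exp(-model.decay_b * dw)


def normalized_ctdi(record: ScanDoseRecord) -> float:
    """CTDI_vol per unit mAs for the whole scan (mGy/mAs)."""
    return record.mean_ctdi_vol / record.mean_mas


def ctdi_vol_z(norm_ctdi: float, mas_z: float) -> float:
    """Per-slice CTDI_vol,z = normalized CTDI_vol * mAs(z), in mGy."""
    if norm_ctdi < 0 or mas_z < 0:
        raise ValueError("normalized CTDI and mAs(z) must be non-negative")
    return norm_ctdi * mas_z


# ---------------------------------------------------------------------------
# per-slice chain


def _slice_dw(image: np.ndarray, volume: CTVolume, config: SegConfig) -> float:
    body = segment_body(image, volume.pixel_spacing, config.threshold_hu,
                        fill_holes=config.fill_holes)
    return water_equivalent_diameter(roi_stats(image, body))


def per_slice_profiles(
    volume: CTVolume,
    record: ScanDoseRecord,
    config: SegConfig | None = None,
    model: ConversionModel | None = None,
) -> list[SliceDoseProfile]:
    """Segment every slice and compute D_w,z, CTDI_vol,z, f and SSDE_z.

    Raises a per-slice error summary unless ``config.skip_bad_slices`` is
    set, in which case failing slices are dropped with a warning.
    """
    config = config or SegConfig()
    model = model or ConversionModel()
    if volume.exposures is None:
        raise ValueError("volume has no per-slice exposures; "
                         "per-slice dose profiles need mAs(z)")
    norm = normalized_ctdi(record)
    profiles: list[SliceDoseProfile] = []
    failures: list[str] = []
    for i in range(volume.n_slices):
        try:
            dw = _slice_dw(volume.slices[i], volume, config)
        except ValueError as exc:
            failures.append(f"slice {i + 1}: {exc}")
            continue
        mas = float(volume.exposures[i])
        cz = ctdi_vol_z(norm, mas)
        fz = conversion_factor(dw, model)
        profiles.append(SliceDoseProfile(
            slice_index=i + 1,
            z_mm=float(volume.z_positions[i]),
            dw_z=dw,
            mas_z=mas,
            ctdi_vol_z=cz,
            f_z=fz,
            ssde_z=cz * fz,
        ))
    if failures:
        if not config.skip_bad_slices:
            raise ValueError("per-slice dose failed on "
                             f"{len(failures)} slice(s): " + "; ".join(failures))
        warnings.warn(f"skipped {len(failures)} bad slice(s)", stacklevel=2)
    if not profiles:
        raise ValueError("no usable slices in volume")
    return profiles


def mean_ssde(profiles: list[SliceDoseProfile]) -> float:
    """Unweighted mean of SSDE_z over the scan range (mGy)."""
    if not profiles:
        raise ValueError("empty profile list")
    return float(np.mean([p.ssde_z for p in profiles]))


def center_slice_index(n_slices: int) -> int:
    """1-based central slice index; lower-middle (ceil(n/2)) for even n."""
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    return (n_slices + 1) // 2


def ssde_center(
    volume: CTVolume,
    record: ScanDoseRecord,
    config: SegConfig | None = None,
    model: ConversionModel | None = None,
) -> tuple[float, float]:
    """(D_w of the central slice, SSDE_center).

    SSDE_center = mean CTDI_vol * f(D_w,center) — the scan-mean CTDI_vol,
    not the central slice's CTDI_vol,z.
    """
    config = config or SegConfig()
    idx = center_slice_index(volume.n_slices) - 1
    dw = _slice_dw(volume.slices[idx], volume, config)
    return dw, record.mean_ctdi_vol * conversion_factor(dw, model)


def generate_sai(volume: CTVolume) -> np.ndarray:
    """Slice-averaged image: per-pixel arithmetic mean over all slices.

    Returned in floating point; no integer re-quantization is applied
    before analysis.
    """
    return np.mean(np.stack(volume.slices, axis=0), axis=0)


def ssde_sai(
    volume: CTVolume,
    record: ScanDoseRecord,
    config: SegConfig | None = None,
    model: ConversionModel | None = None,
) -> tuple[float, float]:
    """(D_w of the slice-averaged image, SSDE_SAI).

    The SAI is segmented with the same table-removal pipeline as any single
    slice; SSDE_SAI = mean CTDI_vol * f(D_w,SAI).
    """
    config = config or SegConfig()
    sai = generate_sai(volume)
    dw = _slice_dw(sai, volume, config)
    return dw, record.mean_ctdi_vol * conversion_factor(dw, model)


def ssde_sai_slicewise(
    profiles: list[SliceDoseProfile],
    model: ConversionModel | None = None,
) -> float:
    """Diagnostic variant: f(mean per-slice D_w) * mean CTDI_vol,z.

    Algebraically distinct from both ``mean_ssde`` and the image-domain
    ``ssde_sai``; exposed for analysis only.
    """
    if not profiles:
        raise ValueError("empty profile list")
    mean_dw = float(np.mean([p.dw_z for p in profiles]))
    mean_cz = float(np.mean([p.ctdi_vol_z for p in profiles]))
    return conversion_factor(mean_dw, model) * mean_cz


def nslice_indices(n_slices: int, n: int) -> list[int]:
    """1-based indices of n slices evenly spaced over [1, n_slices].

    Endpoints are included for n >= 2; positions are rounded to the nearest
    index and duplicates collapsed (with a warning). n = 1 selects the
    central slice.
    """
    if not 1 <= n <= n_slices:
        raise ValueError(f"n must lie in [1, {n_slices}]")
    if n == 1:
        return [center_slice_index(n_slices)]
    positions = [1 + (n_slices - 1) * k / (n - 1) for k in range(n)]
    indices = sorted({int(round(p)) for p in positions})
    if len(indices) < n:
        warnings.warn(
            f"{n}-slice sampling collapsed to {len(indices)} distinct "
            "slices", stacklevel=2)
    return indices


def dw_nslice(
    volume: CTVolume,
    n: int,
    config: SegConfig | None = None,
) -> float:
    """Mean D_w over n evenly spaced slices (cm)."""
    config = config or SegConfig()
    idx = nslice_indices(volume.n_slices, n)
    dws = [_slice_dw(volume.slices[i - 1], volume, config) for i in idx]
    return float(np.mean(dws))


# ---------------------------------------------------------------------------
# scan-level summary


def summarize_scan(
    volume: CTVolume,
    record: ScanDoseRecord,
    config: SegConfig | None = None,
    model: ConversionModel | None = None,
    nslice_n: int = 9,
) -> tuple[ScanDoseSummary, list[SliceDoseProfile]]:
    """Compute every dose index for one scan.

    Returns the summary plus the per-slice profiles it was built from.
    """
    config = config or SegConfig()
    model = model or ConversionModel()
    profiles = per_slice_profiles(volume, record, config, model)
    dw_c, ssde_c = ssde_center(volume, record, config, model)
    dw_s, ssde_s = ssde_sai(volume, record, config, model)
    nslice_n = min(nslice_n, volume.n_slices)
    summary = ScanDoseSummary(
        normalized_ctdi=normalized_ctdi(record),
        mean_dw=float(np.mean([p.dw_z for p in profiles])),
        dw_center=dw_c,
        dw_sai=dw_s,
        dw_nslice=dw_nslice(volume, nslice_n, config),
        nslice_n=nslice_n,
        mean_ssde=mean_ssde(profiles),
        ssde_center=ssde_c,
        ssde_sai=ssde_s,
        n_slices=volume.n_slices,
    )
    return summary, profiles
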
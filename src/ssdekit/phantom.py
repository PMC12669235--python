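"""Synthetic trunk phantoms with analytic ground truth.

Generates seeded axial CT volumes — elliptical water-density body, optional
lung inserts, a CT table slab, Gaussian HU noise — together with the exact
per-slice water-equivalent diameter implied by the continuous geometry, and
a generic exponential tube-current-modulation model so that the per-slice
dose chain is exercised end to end without patient data.

Templates encode plausible axial size profiles (the chest tapers cranially,
the chest-abdomen-pelvis profile has shoulder/diaphragm/pelvis waypoints)
as piecewise-linear semi-axis curves. They are test geometry, not
anatomical claims.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .volume_io import CTVolume, ScanDoseRecord

__all__ = [
    "PhantomSpec",
    "ATCMModel",
    "GroundTruth",
    "template_semi_axes",
    "generate_phantom",
    "simulate_atcm",
    "make_cohort",
]

TEMPLATES = ("constant", "chest", "abdomen_pelvis", "cap")

_BACKGROUND_HU = -1000.0
_TABLE_HU = -500.0
_MARGIN_PX = 5


@dataclass
class ATCMModel:
    """Generic exponential tube-current modulation.

    mAs(z) = clamp(reference_mas * exp(strength_gamma * (D_w,z - reference_dw))).
    """

    reference_mas: float = 100.0
    reference_dw: float = 28.0       # cm
    strength_gamma: float = 0.05     # 1/cm
    clamp: tuple[float, float] = (20.0, 400.0)

    def __post_init__(self) -> None:
        if not self.reference_mas > 0:
            raise ValueError("reference_mas must be positive")
        if self.clamp[0] > self.clamp[1]:
            raise ValueError("clamp min must not exceed clamp max")


@dataclass
class LungInsert:
    """Elliptical low-density insert, fully inside the body ellipse."""

    center_offset_cm: tuple[float, float]  # (row, col) offset from body center
    semi_axes_cm: tuple[float, float]      # (row, col)
    hu: float = -800.0


@dataclass
class PhantomSpec:
    """Full parameterization of one synthetic trunk phantom."""

    region_template: str = "constant"
    n_slices: int = 20
    matrix: int = 256
    pixel_spacing_mm: float = 2.0
    body_semi_axes_cm: list[tuple[float, float]] | None = None
    body_hu: float = 0.0
    lung_inserts: list[list[LungInsert]] | None = None  # per slice
    table: bool = True
    table_hu: float = _TABLE_HU
    noise_sigma: float = 0.0
    slice_thickness_mm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_template not in TEMPLATES:
            raise ValueError(f"unknown template {self.region_template!r}")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.body_semi_axes_cm is None:
            self.body_semi_axes_cm = template_semi_axes(
                self.region_template, self.n_slices)
        if len(self.body_semi_axes_cm) != self.n_slices:
            raise ValueError("semi-axes profile length must equal n_slices")
        fov_cm = self.matrix * self.pixel_spacing_mm / 10.0
        for a, b in self.body_semi_axes_cm:
            if a <= 0 or b <= 0:
                raise ValueError("semi-axes must be positive")
            margin_cm = _MARGIN_PX * self.pixel_spacing_mm / 10.0
            # body is vertically offset upward to leave room for the table
            if 2 * a + margin_cm + 3.0 > fov_cm or 2 * b + 2 * margin_cm > fov_cm:
                raise ValueError(
                    f"body ({a} x {b} cm) does not fit a {fov_cm:.0f} cm FOV "
                    "with the required margin")
        if self.lung_inserts is not None and len(self.lung_inserts) != self.n_slices:
            raise ValueError("lung_inserts must have one entry per slice")


@dataclass
class GroundTruth:
    """Analytic (noise-free, continuous-geometry) per-slice quantities."""

    dw_cm: np.ndarray
    area_cm2: np.ndarray
    mean_hu: np.ndarray
    mas: np.ndarray | None = None
    mean_mas: float | None = None
    mean_ctdi_vol: float | None = None
    normalized_ctdi: float | None = None

    def as_dict(self) -> dict:
        out = {
            "dw_cm": self.dw_cm.tolist(),
            "area_cm2": self.area_cm2.tolist(),
            "mean_hu": self.mean_hu.tolist(),
        }
        if self.mas is not None:
            out.update(
                mas=self.mas.tolist(),
                mean_mas=self.mean_mas,
                mean_ctdi_vol=self.mean_ctdi_vol,
                normalized_ctdi=self.normalized_ctdi,
            )
        return out


def analytic_dw(area_cm2: float, mean_hu: float) -> float:
    """Closed-form water-equivalent diameter of a region (cm)."""
    return 2.0 * math.sqrt((mean_hu / 1000.0 + 1.0) * area_cm2 / math.pi)


def template_semi_axes(template: str, n_slices: int,
                       base_a: float = 10.0, base_b: float = 15.0
                       ) -> list[tuple[float, float]]:
    """Piecewise-linear per-slice (a, b) semi-axes in cm.

    ``a`` is the anteroposterior (row) semi-axis and ``b`` the lateral
    (column) semi-axis. Waypoints are expressed as scale factors applied to
    the base semi-axes at fractional z positions.
    """
    if template == "constant":
        waypoints = [(0.0, 1.0), (1.0, 1.0)]
    elif template == "chest":
        # tapers toward the lung apex, widens toward the diaphragm
        waypoints = [(0.0, 0.70), (0.3, 0.88), (1.0, 1.05)]
    elif template == "abdomen_pelvis":
        waypoints = [(0.0, 1.00), (0.5, 0.94), (1.0, 1.02)]
    elif template == "cap":
        # wide shoulder girdle, diaphragm waist, pelvic flare
        waypoints = [(0.0, 0.93), (0.15, 1.00), (0.45, 0.88),
                     (0.75, 0.94), (1.0, 1.00)]
    else:
        raise ValueError(f"unknown template {template!r}")
    xs = np.array([w[0] for w in waypoints])
    ys = np.array([w[1] for w in waypoints])
    if n_slices == 1:
        fracs = np.array([0.5])
    else:
        fracs = np.linspace(0.0, 1.0, n_slices)
    scale = np.interp(fracs, xs, ys)
    return [(base_a * s, base_b * s) for s in scale]


def default_lungs(spec: PhantomSpec) -> list[list[LungInsert]] | None:
    """Two lateral lung ellipses on the chest portion of a template."""
    if spec.region_template == "constant":
        return None
    if spec.region_template == "abdomen_pelvis":
        return None
    inserts: list[list[LungInsert]] = []
    chest_end = 1.0 if spec.region_template == "chest" else 0.45
    for i, (a, b) in enumerate(spec.body_semi_axes_cm):
        frac = i / max(spec.n_slices - 1, 1)
        if frac <= chest_end and a > 4.0:
            la, lb = 0.45 * a, 0.30 * b
            off = 0.42 * b
            inserts.append([
                LungInsert((0.0, -off), (la, lb)),
                LungInsert((0.0, +off), (la, lb)),
            ])
        else:
            inserts.append([])
    return inserts


def _ellipse_mask(shape: tuple[int, int], center_px: tuple[float, float],
                  semi_axes_px: tuple[float, float]) -> np.ndarray:
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    return (((rows - center_px[0]) / semi_axes_px[0]) ** 2
            + ((cols - center_px[1]) / semi_axes_px[1]) ** 2) <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, GroundTruth]:
    """Rasterize a phantom and return it with its analytic ground truth.

    The ground truth uses the continuous geometry (exact ellipse areas,
    area-weighted mean HU) and ignores pixelization and noise. Lungs count
    toward the body cross-section (they are enclosed air); the table is
    geometrically disjoint from the body and excluded from the truth.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.matrix
    px_cm = spec.pixel_spacing_mm / 10.0
    lungs = (spec.lung_inserts if spec.lung_inserts is not None
             else default_lungs(spec))

    max_a = max(a for a, _ in spec.body_semi_axes_cm)
    # body center: horizontally centered, shifted up so the table fits below
    center_col = (n - 1) / 2.0
    center_row = (n - 1) / 2.0 - 1.0 / px_cm  # 1 cm above geometric center

    slices: list[np.ndarray] = []
    dw = np.empty(spec.n_slices)
    area = np.empty(spec.n_slices)
    mean_hu = np.empty(spec.n_slices)

    table_top_row = int(center_row + max_a / px_cm + _MARGIN_PX)
    table_rows = slice(table_top_row, table_top_row + max(int(1.5 / px_cm), 2))
    table_cols = slice(int(n * 0.2), int(n * 0.8))
    if spec.table and table_rows.stop >= n:
        raise ValueError("table does not fit below the body; enlarge matrix")

    for i, (a_cm, b_cm) in enumerate(spec.body_semi_axes_cm):
        img = np.full((n, n), _BACKGROUND_HU)
        body = _ellipse_mask((n, n), (center_row, center_col),
                             (a_cm / px_cm, b_cm / px_cm))
        img[body] = spec.body_hu

        a_body = math.pi * a_cm * b_cm
        lung_term = 0.0
        for lung in (lungs[i] if lungs else []):
            lr = center_row + lung.center_offset_cm[0] / px_cm
            lc = center_col + lung.center_offset_cm[1] / px_cm
            lmask = _ellipse_mask((n, n), (lr, lc),
                                  (lung.semi_axes_cm[0] / px_cm,
                                   lung.semi_axes_cm[1] / px_cm))
            if not (lmask <= body).all():
                raise ValueError("lung insert extends outside the body")
            img[lmask] = lung.hu
            a_lung = math.pi * lung.semi_axes_cm[0] * lung.semi_axes_cm[1]
            lung_term += a_lung * (lung.hu - spec.body_hu)

        if spec.table:
            img[table_rows, table_cols] = spec.table_hu

        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)

        slices.append(img)
        area[i] = a_body
        mean_hu[i] = spec.body_hu + lung_term / a_body
        dw[i] = analytic_dw(a_body, mean_hu[i])

    volume = CTVolume(
        slices=slices,
        z_positions=np.arange(spec.n_slices) * spec.slice_thickness_mm,
        pixel_spacing=(spec.pixel_spacing_mm, spec.pixel_spacing_mm),
        slice_thickness=spec.slice_thickness_mm,
        series_id=f"phantom-{spec.region_template}-{spec.seed}",
    )
    return volume, GroundTruth(dw_cm=dw, area_cm2=area, mean_hu=mean_hu)


def simulate_atcm(dw_profile: np.ndarray, model: ATCMModel | None = None
                  ) -> np.ndarray:
    """Per-slice mAs from a D_w profile under exponential modulation."""
    model = model or ATCMModel()
    dw_profile = np.asarray(dw_profile, dtype=float)
    if not np.all(dw_profile > 0):
        raise ValueError("D_w profile must be positive")
    mas = model.reference_mas * np.exp(
        model.strength_gamma * (dw_profile - model.reference_dw))
    return np.clip(mas, model.clamp[0], model.clamp[1])


def make_cohort(
    n_cases: int,
    region_template: str = "cap",
    *,
    n_slices: int = 40,
    matrix: int = 256,
    pixel_spacing_mm: float = 2.0,
    mean_radius_range_cm: tuple[float, float] = (11.0, 17.0),
    shape_jitter: float = 0.06,
    noise_sigma: float = 5.0,
    normalized_ctdi_mgy_per_mas: float = 0.09,
    atcm: ATCMModel | None = None,
    seed: int = 0,
) -> list[tuple[CTVolume, ScanDoseRecord, GroundTruth]]:
    """Seeded cohort of phantoms with self-consistent dose records.

    Per-case body size is drawn uniformly from ``mean_radius_range_cm``
    (the lateral semi-axis; the anteroposterior semi-axis is 2/3 of it),
    and the template z-profile is perturbed per case by a smooth
    piecewise-linear factor within ``1 +/- shape_jitter`` so cases differ
    in shape, not just scale. Each case's mean CTDI_vol is derived from
    the fixed normalized CTDI and the simulated mAs profile, so scan-mean
    quantities are consistent by construction.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    lo, hi = mean_radius_range_cm
    if not 0 < lo <= hi:
        raise ValueError("invalid mean_radius_range_cm")
    if not 0 <= shape_jitter < 0.5:
        raise ValueError("shape_jitter must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    atcm = atcm or ATCMModel()
    cases = []
    for k in range(n_cases):
        base_b = rng.uniform(lo, hi)
        base_a = base_b * 2.0 / 3.0
        profile = template_semi_axes(
            region_template, n_slices, base_a=base_a, base_b=base_b)
        if shape_jitter > 0 and n_slices > 1:
            knots = np.linspace(0.0, 1.0, 5)
            factors = rng.uniform(1 - shape_jitter, 1 + shape_jitter, 5)
            smooth = np.interp(np.linspace(0, 1, n_slices), knots, factors)
            profile = [(a * s, b * s) for (a, b), s in zip(profile, smooth)]
        spec = PhantomSpec(
            region_template=region_template,
            n_slices=n_slices,
            matrix=matrix,
            pixel_spacing_mm=pixel_spacing_mm,
            body_semi_axes_cm=profile,
            noise_sigma=noise_sigma,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        volume, truth = generate_phantom(spec)
        mas = simulate_atcm(truth.dw_cm, atcm)
        volume.exposures = mas
        mean_mas = float(np.mean(mas))
        record = ScanDoseRecord(
            mean_ctdi_vol=normalized_ctdi_mgy_per_mas * mean_mas,
            mean_mas=mean_mas,
            reference_phantom_diameter=32,
        )
        truth.mas = mas
        truth.mean_mas = mean_mas
        truth.mean_ctdi_vol = record.mean_ctdi_vol
        truth.normalized_ctdi = normalized_ctdi_mgy_per_mas
        cases.append((volume, record, truth))
    return cases
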
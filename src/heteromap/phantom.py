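"""Synthetic pelvic-MRI phantoms with known cellularity ground truth.

Patient data for this kind of pipeline is rarely shareable, so the package
ships a generator of ground-truth-known study cases that reproduce the
statistical structure the pipeline relies on:

* a tumor (ellipsoid) embedded in a body ellipsoid, split into spatially
  structured subregions of distinct ADC — a low-ADC (highly cellular) part
  and a high-ADC (less cellular) part;
* DWI subseries following the monoexponential diffusion decay
  ``S(b) = S0 · exp(-b · ADC(x))`` plus additive Gaussian noise;
* a T2-weighted volume whose regional mean intensity and local texture
  (amplitude and spatial autocorrelation) differ between the subregions, so
  that T2 radiomics carry information about the ADC class without being a
  copy of the ADC map;
* a known rigid/affine + smooth elastic misalignment between the T2 frame
  and the DWI/ADC frame, creating the registration problem the pipeline
  solves.

Everything is deterministic under the spec's seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import GeometryError, StudyCase, Volume

__all__ = [
    "SubregionSpec",
    "PhantomSpec",
    "generate_phantom",
    "apply_misalignment",
    "generate_cohort",
]


@dataclass(frozen=True)
class SubregionSpec:
    """One intratumoral compartment.

    ``adc`` in mm²/s; ``fraction`` of tumor volume; T2 appearance given by a
    mean intensity, a texture amplitude (intensity units) and a texture
    correlation length (mm).
    """

    name: str
    adc: float
    fraction: float
    t2_mean: float
    t2_texture_amp: float
    t2_texture_corr_mm: float

    def __post_init__(self) -> None:
        if self.adc <= 0:
            raise ValueError(f"subregion {self.name!r}: ADC must be > 0")
        if not 0 < self.fraction <= 1:
            raise ValueError(f"subregion {self.name!r}: fraction must be in (0,1]")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic study.

    Defaults emulate a pelvic study at 3 T: 1 mm in-plane resolution, 3 mm
    slices, a tumor a few cm across with a highly cellular core
    (ADC 0.6e-3 mm²/s, well below the 0.85e-3 mm²/s cut-off) and a less
    cellular remainder (1.3e-3), surrounded by body tissue of higher
    diffusivity.  b-values {0, 600, 1200} s/mm².
    """

    shape: tuple[int, int, int] = (14, 56, 56)
    spacing: tuple[float, float, float] = (2.6, 1.0, 1.0)
    tumor_center_mm: tuple[float, float, float] | None = None  # None -> grid centre
    tumor_radii_mm: tuple[float, float, float] = (9.0, 8.5, 6.5)
    subregions: tuple[SubregionSpec, ...] = (
        SubregionSpec("high_cellularity", 0.70e-3, 0.40, 175.0, 26.0, 0.9),
        SubregionSpec("low_cellularity", 1.10e-3, 0.60, 140.0, 12.0, 2.5),
    )
    background_adc: float = 2.2e-3
    air_adc: float = 2.5e-3
    body_radii_frac: tuple[float, float, float] = (0.98, 0.95, 0.78)
    # fixed anatomical anchors (bone-like, dark on every sequence): give the
    # body interior structure so rotation is well determined by registration
    anchor_centers_frac: tuple = ((0.5, 0.28, 0.30), (0.5, 0.30, 0.72))
    anchor_radii_mm: tuple[float, float, float] = (14.0, 5.0, 4.0)
    anchor_s0: float = 40.0
    anchor_t2: float = 45.0
    anchor_adc: float = 0.4e-3
    b_values: tuple[float, ...] = (0.0, 600.0, 1200.0)
    s0: float = 150.0
    tumor_s0: float = 260.0
    air_s0: float = 5.0
    t2_body: float = 120.0
    t2_air: float = 10.0
    t2_body_texture_amp: float = 8.0
    t2_body_texture_corr_mm: float = 3.0
    adc_edge_smooth_mm: float = 0.0
    noise_sigma: float = 3.0
    # misalignment of the DWI/ADC frame relative to T2
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    warp_amplitude_mm: float = 0.0
    warp_smoothness_mm: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.tumor_radii_mm):
            raise ValueError("tumor radii must be > 0")
        if self.background_adc <= 0 or self.air_adc <= 0:
            raise ValueError("ADC values must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        bvals = tuple(float(b) for b in self.b_values)
        if any(b < 0 for b in bvals):
            raise ValueError("b-values must be non-negative")
        if len(set(bvals)) != len(bvals):
            raise ValueError("b-values must be distinct")
        fr = sum(s.fraction for s in self.subregions)
        if not self.subregions or abs(fr - 1.0) > 1e-9:
            raise ValueError("subregion fractions must sum to 1")

    def replace(self, **kw) -> "PhantomSpec":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# geometry helpers

def _grid_world(shape, spacing):
    """World (mm) coordinate arrays for each axis of a grid at origin 0."""
    return np.meshgrid(
        *(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij"
    )


def _ellipsoid(shape, spacing, center_mm, radii_mm) -> np.ndarray:
    zz, yy, xx = _grid_world(shape, spacing)
    d2 = (
        ((zz - center_mm[0]) / radii_mm[0]) ** 2
        + ((yy - center_mm[1]) / radii_mm[1]) ** 2
        + ((xx - center_mm[2]) / radii_mm[2]) ** 2
    )
    return d2 <= 1.0


def _smooth_field(shape, spacing, corr_mm, rng) -> np.ndarray:
    """Unit-variance Gaussian random field with correlation length corr_mm."""
    white = rng.standard_normal(shape)
    sig = [max(corr_mm / s, 1e-6) for s in spacing]
    f = ndimage.gaussian_filter(white, sigma=sig, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> StudyCase:
    """Render one aligned study case from ``spec``.

    The returned case carries the ground-truth tumor mask, the noiseless ADC
    field (which is also the stored ADC map) and is flagged ``aligned``; use
    :func:`apply_misalignment` to create the registration problem.
    """
    shape, spacing = spec.shape, spec.spacing
    extent = np.array([(n - 1) * s for n, s in zip(shape, spacing)])
    center = (
        np.asarray(spec.tumor_center_mm, dtype=float)
        if spec.tumor_center_mm is not None
        else extent / 2.0
    )
    radii = np.asarray(spec.tumor_radii_mm, dtype=float)
    if np.any(center - radii < 0) or np.any(center + radii > extent):
        raise GeometryError(
            f"tumor (center {center} mm, radii {radii} mm) does not fit the "
            f"grid extent {extent} mm"
        )

    rng = np.random.default_rng(spec.seed)

    body = _ellipsoid(
        shape,
        spacing,
        extent / 2.0,
        extent / 2.0 * np.asarray(spec.body_radii_frac) + 1e-9,
    )
    tumor = _ellipsoid(shape, spacing, center, radii)
    if not tumor.any():
        raise GeometryError("tumor mask is empty")
    anchors = np.zeros(shape, dtype=bool)
    for cf in spec.anchor_centers_frac:
        anchors |= _ellipsoid(
            shape, spacing, np.asarray(cf) * extent, spec.anchor_radii_mm
        )
    anchors &= body & ~tumor

    # spatially structured subregion layout: threshold a smooth random field
    # inside the tumor at the quantiles matching the requested fractions
    layout_field = _smooth_field(shape, spacing, 4.0, rng)
    vals = layout_field[tumor]
    cum = np.cumsum([s.fraction for s in spec.subregions])
    # quantile edges; last edge = +inf
    edges = [np.quantile(vals, c) for c in cum[:-1]] + [np.inf]
    region_idx = np.zeros(shape, dtype=int)  # 0 = not tumor
    assigned = np.full(shape, False)
    for i, edge in enumerate(edges):
        sel = tumor & ~assigned & (layout_field <= edge)
        region_idx[sel] = i + 1
        assigned |= sel

    # ADC field (mm²/s): air / body / anchors / per-subregion
    adc = np.where(body, spec.background_adc, spec.air_adc)
    adc = np.where(anchors, spec.anchor_adc, adc)
    for i, sub in enumerate(spec.subregions):
        adc = np.where(region_idx == i + 1, sub.adc, adc)
    if spec.adc_edge_smooth_mm > 0:
        adc = ndimage.gaussian_filter(
            adc, sigma=[spec.adc_edge_smooth_mm / s for s in spacing]
        )

    # T2-weighted volume: regional means + per-region texture + noise
    t2 = np.where(body, spec.t2_body, spec.t2_air).astype(float)
    t2 = t2 + np.where(
        body & ~tumor,
        spec.t2_body_texture_amp
        * _smooth_field(shape, spacing, spec.t2_body_texture_corr_mm, rng),
        0.0,
    )
    t2 = np.where(anchors, spec.anchor_t2, t2)
    for i, sub in enumerate(spec.subregions):
        tex = _smooth_field(shape, spacing, sub.t2_texture_corr_mm, rng)
        in_sub = region_idx == i + 1
        t2 = np.where(in_sub, sub.t2_mean + sub.t2_texture_amp * tex, t2)
    if spec.noise_sigma > 0:
        t2 = t2 + rng.normal(0.0, spec.noise_sigma, shape)

    # DWI subseries: monoexponential decay of the noiseless ADC field
    s0_field = np.where(body, spec.s0, spec.air_s0)
    s0_field = np.where(anchors, spec.anchor_s0, s0_field)
    s0_field = np.where(tumor, spec.tumor_s0, s0_field)
    dwi: dict[float, Volume] = {}
    for b in spec.b_values:
        signal = s0_field * np.exp(-float(b) * adc)
        if spec.noise_sigma > 0:
            signal = signal + rng.normal(0.0, spec.noise_sigma, shape)
        dwi[float(b)] = Volume(signal, spacing)

    adc_vol = Volume(adc, spacing)
    case = StudyCase(
        case_id=f"phantom-{spec.seed}",
        t2=Volume(t2, spacing),
        dwi=dwi,
        adc=adc_vol,
        alignment="aligned",
        truth_tumor_mask=tumor,
        truth_adc=adc_vol,
        meta={"spec_seed": spec.seed, "subregions": [s.name for s in spec.subregions]},
    )
    case.validate_geometry()
    return case


# ---------------------------------------------------------------------------
# misalignment

def _rotation_matrix(rotation_deg) -> np.ndarray:
    """Rotation about the grid axes (axis0, axis1, axis2), in that order."""
    a0, a1, a2 = (np.deg2rad(float(r)) for r in rotation_deg)
    c, s = np.cos(a0), np.sin(a0)
    r0 = np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    c, s = np.cos(a1), np.sin(a1)
    r1 = np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
    c, s = np.cos(a2), np.sin(a2)
    r2 = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)
    return r2 @ r1 @ r0


def _elastic_field(shape, spacing, amplitude_mm, smoothness_mm, rng) -> np.ndarray:
    """(3, *shape) smooth random displacement, RMS magnitude = amplitude."""
    u = np.stack(
        [_smooth_field(shape, spacing, smoothness_mm, rng) for _ in range(3)]
    )
    rms = np.sqrt(np.mean(np.sum(u**2, axis=0)))
    return u * (amplitude_mm / rms) if rms > 0 else u


def apply_misalignment(case: StudyCase, spec: PhantomSpec) -> StudyCase:
    """Displace the DWI/ADC frame relative to T2 by a known transform.

    Every DWI subseries and the ADC map are resampled through the same
    rigid/affine + smooth elastic pullback (the subseries share one frame);
    T2 stays put.  The output voxel at world position ``x`` takes the value
    of the input at ``R⁻¹(x − c − t) + c + u(x)``, so a pure translation
    ``t`` moves image content by ``+t``.  The true transform is recorded in
    ``truth_transform`` for registration tests.
    """
    if case.alignment != "aligned":
        raise ValueError("apply_misalignment expects an aligned case")
    ref = case.t2
    shape, spacing = ref.shape, ref.spacing
    rng = np.random.default_rng(spec.seed + 0x5EED)

    rot = _rotation_matrix(spec.rotation_deg)
    rot_inv = rot.T
    t = np.asarray(spec.translation_mm, dtype=float)
    c = ref.center_world()

    if spec.warp_amplitude_mm > 0:
        warp = _elastic_field(
            shape, spacing, spec.warp_amplitude_mm, spec.warp_smoothness_mm, rng
        )
    else:
        warp = np.zeros((3,) + shape)

    grids = _grid_world(shape, spacing)
    x = np.stack(grids)  # (3, *shape) world mm
    src = (
        np.einsum("ij,j...->i...", rot_inv, x - c.reshape(3, 1, 1, 1) - t.reshape(3, 1, 1, 1))
        + c.reshape(3, 1, 1, 1)
        + warp
    )
    src_idx = src / np.asarray(spacing).reshape(3, 1, 1, 1)

    def _pull(data: np.ndarray, order: int = 1) -> np.ndarray:
        return ndimage.map_coordinates(data, src_idx, order=order, mode="nearest")

    dwi = {b: v.with_data(_pull(v.data)) for b, v in case.dwi.items()}
    adc = case.adc.with_data(_pull(case.adc.data)) if case.adc is not None else None

    if case.truth_tumor_mask is not None:
        # forward-map tumor voxels (affine part) and require them in-FOV
        pts = np.argwhere(case.truth_tumor_mask) * np.asarray(spacing)
        fwd = (rot @ (pts - c).T).T + c + t
        extent = np.array([(n - 1) * s for n, s in zip(shape, spacing)])
        margin = spec.warp_amplitude_mm
        if np.any(fwd < -margin) or np.any(fwd > extent + margin):
            raise GeometryError("misalignment pushes the tumor outside the grid")

    out = StudyCase(
        case_id=case.case_id,
        t2=case.t2,
        dwi=dwi,
        adc=adc,
        alignment="raw",
        truth_tumor_mask=case.truth_tumor_mask,
        truth_adc=case.truth_adc,
        truth_transform={
            "rotation_deg": tuple(float(r) for r in spec.rotation_deg),
            "translation_mm": tuple(float(v) for v in t),
            "center_mm": tuple(float(v) for v in c),
            "matrix": rot,
            "warp_mm": warp,
        },
        meta=dict(case.meta),
    )
    return out


# ---------------------------------------------------------------------------
# cohorts

def generate_cohort(
    n_cases: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    misaligned: bool = True,
) -> list[StudyCase]:
    """Deterministically jittered cohort of phantoms.

    Per-case geometry, ADC layout, T2 appearance and (if ``misaligned``)
    the DWI/ADC frame offset are sampled from ``seed``.  Needs ``n_cases >=
    2`` so that leave-one-patient-out evaluation is possible.
    """
    if n_cases < 2:
        raise ValueError("a cohort needs at least 2 cases (LOPO requires >= 2)")
    base = base_spec if base_spec is not None else PhantomSpec()
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        case_seed = int(rng.integers(0, 2**31 - 1))
        jitter = np.random.default_rng(case_seed)
        radii = np.asarray(base.tumor_radii_mm) * jitter.uniform(0.88, 1.12, 3)
        extent = np.array([(n - 1) * s for n, s in zip(base.shape, base.spacing)])
        center = extent / 2.0 + np.array(
            [jitter.uniform(-1.5, 1.5), jitter.uniform(-4, 4), jitter.uniform(-4, 4)]
        )
        subs = []
        frac0 = float(np.clip(
            base.subregions[0].fraction + jitter.uniform(-0.08, 0.08), 0.2, 0.7
        ))
        rest = 1.0 - frac0
        others = base.subregions[1:]
        for j, sub in enumerate(base.subregions):
            frac = frac0 if j == 0 else rest * sub.fraction / sum(
                s.fraction for s in others
            )
            subs.append(
                dataclasses.replace(
                    sub,
                    adc=sub.adc * jitter.uniform(0.9, 1.1),
                    fraction=frac,
                    t2_mean=sub.t2_mean + jitter.uniform(-8, 8),
                )
            )
        spec_i = base.replace(
            tumor_center_mm=tuple(center),
            tumor_radii_mm=tuple(radii),
            subregions=tuple(subs),
            translation_mm=(
                float(jitter.uniform(-2, 2)),
                float(jitter.uniform(-5, 5)),
                float(jitter.uniform(-5, 5)),
            ),
            rotation_deg=(
                float(jitter.uniform(-6, 6)),
                float(jitter.uniform(-2, 2)),
                float(jitter.uniform(-2, 2)),
            ),
            warp_amplitude_mm=float(jitter.uniform(0.6, 1.4)),
            seed=case_seed,
        )
        case = generate_phantom(spec_i)
        case.case_id = f"case-{i + 1:02d}"
        if misaligned:
            case = apply_misalignment(case, spec_i)
        case.meta["phantom_spec_seed"] = case_seed
        cases.append(case)
    return cases
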
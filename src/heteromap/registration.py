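"""Two-stage alignment of the DWI/ADC frame to the T2 reference.

Stage one is an affine registration driven by Mattes-style mutual
information (joint-histogram estimate over a seeded voxel sample) and the
downhill-simplex (Nelder–Mead) optimizer; stage two is the classic Demons
algorithm, run on histogram-matched intensities because T2 and DWI are
different modalities and Demons assumes comparable gray scales.  Alignment
quality is tracked with the root-mean-square intensity difference: the
smaller it is, the better the volumes match.

Transforms map reference (fixed, T2) world coordinates to moving-volume
world coordinates; the moving volume is resampled onto the fixed grid with
linear interpolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage.exposure import match_histograms

from .volume import StudyCase, Volume

__all__ = [
    "AffineTransform",
    "DeformationField",
    "RegistrationConfig",
    "MetricError",
    "mattes_mutual_information",
    "register_affine",
    "register_demons",
    "resample_affine",
    "apply_deformation",
    "rms_difference",
    "align_study",
]

_EPS = np.finfo(float).eps


class MetricError(RuntimeError):
    """Raised when a similarity metric cannot be evaluated."""


@dataclass(frozen=True)
class AffineTransform:
    """x_moving = matrix @ (x_fixed - center) + center + translation (mm)."""

    matrix: np.ndarray
    translation: np.ndarray
    center: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("affine matrix must be invertible")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "translation", np.asarray(self.translation, float).reshape(3))
        object.__setattr__(self, "center", np.asarray(self.center, float).reshape(3))

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3), np.asarray(center, float))

    @classmethod
    def from_params(
        cls,
        rotation_deg=(0, 0, 0),
        translation=(0, 0, 0),
        scale=(1, 1, 1),
        shear=(0, 0, 0),
        center=(0, 0, 0),
    ) -> "AffineTransform":
        a0, a1, a2 = (np.deg2rad(float(r)) for r in rotation_deg)
        c, s = np.cos(a0), np.sin(a0)
        r0 = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
        c, s = np.cos(a1), np.sin(a1)
        r1 = np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
        c, s = np.cos(a2), np.sin(a2)
        r2 = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        sh = np.array(
            [[1, shear[0], shear[1]], [0, 1, shear[2]], [0, 0, 1]], dtype=float
        )
        mat = (r2 @ r1 @ r0) @ sh @ np.diag(np.asarray(scale, float))
        return cls(mat, np.asarray(translation, float), np.asarray(center, float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map world points of shape (3, ...) fixed -> moving."""
        pts = np.asarray(points, float)
        c = self.center.reshape(3, *([1] * (pts.ndim - 1)))
        t = self.translation.reshape(3, *([1] * (pts.ndim - 1)))
        return np.einsum("ij,j...->i...", self.matrix, pts - c) + c + t


@dataclass(frozen=True)
class DeformationField:
    """Per-voxel displacement (mm) on the reference grid: x -> x + u(x)."""

    displacement: np.ndarray  # (3, n0, n1, n2)
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        u = np.asarray(self.displacement, float)
        if u.ndim != 4 or u.shape[0] != 3:
            raise ValueError(f"displacement must have shape (3, n0, n1, n2), got {u.shape}")
        if not np.all(np.isfinite(u)):
            raise ValueError("displacement field contains non-finite values")
        object.__setattr__(self, "displacement", u)

    @property
    def magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.displacement**2, axis=0))


@dataclass
class RegistrationConfig:
    """Tunables for both stages; defaults are the package's choices."""

    mi_bins: int = 32
    mi_sample_fraction: float = 0.20
    metric_seed: int = 12345
    stages: tuple[str, ...] = ("translation", "rigid", "affine")
    simplex_max_iter: int = 500
    simplex_xatol: float = 0.01
    simplex_fatol: float = 1e-5
    init_translation_step_mm: float = 3.0
    init_rotation_step_deg: float = 3.0
    init_scale_step: float = 0.02
    init_shear_step: float = 0.02
    demons_iterations: int = 50
    # field smoothing: matched to the smoothness of inter-sequence warps
    # (centimetre scale); narrower deformations warrant a smaller sigma
    demons_sigma_mm: float = 2.0
    demons_tolerance: float = 1e-4
    # interpolation order for the final resampling of the aligned volumes
    # (cubic keeps edges crisper than linear; the metric stays linear)
    resample_order: int = 3
    demons_histogram_match: bool = True
    # subseries used to estimate the transform; b=0 carries the most
    # anatomical signal and the subseries share one frame
    register_b: float = 0.0


# ---------------------------------------------------------------------------
# resampling and metrics

def _world_grid(vol: Volume) -> np.ndarray:
    grids = np.meshgrid(
        *(np.arange(n) * s + o for n, s, o in zip(vol.shape, vol.spacing, vol.origin)),
        indexing="ij",
    )
    return np.stack(grids)


def resample_affine(
    moving: Volume, fixed: Volume, transform: AffineTransform, order: int = 1
) -> Volume:
    """Resample ``moving`` onto the grid of ``fixed`` through ``transform``."""
    x = _world_grid(fixed)
    y = transform.apply(x)
    idx = (y - np.asarray(moving.origin).reshape(3, 1, 1, 1)) / np.asarray(
        moving.spacing
    ).reshape(3, 1, 1, 1)
    data = ndimage.map_coordinates(moving.data, idx, order=order, mode="nearest")
    return Volume(data, fixed.spacing, fixed.origin)


def apply_deformation(
    moving: Volume,
    fixed: Volume,
    transform: AffineTransform,
    dfield: DeformationField | None,
    order: int = 1,
) -> Volume:
    """Single-interpolation composite resampling: moving(A(x + u(x)))."""
    x = _world_grid(fixed)
    if dfield is not None:
        x = x + dfield.displacement
    y = transform.apply(x)
    idx = (y - np.asarray(moving.origin).reshape(3, 1, 1, 1)) / np.asarray(
        moving.spacing
    ).reshape(3, 1, 1, 1)
    data = ndimage.map_coordinates(moving.data, idx, order=order, mode="nearest")
    return Volume(data, fixed.spacing, fixed.origin)


def _sample_positions(fixed: Volume, fraction: float, seed: int) -> np.ndarray:
    n = int(np.prod(fixed.shape))
    k = max(int(round(n * fraction)), 2)
    rng = np.random.default_rng(seed)
    flat = rng.choice(n, size=min(k, n), replace=False)
    return np.stack(np.unravel_index(flat, fixed.shape)).astype(float)


def _mi_from_samples(fv: np.ndarray, mv: np.ndarray, n_bins: int) -> float:
    joint, _, _ = np.histogram2d(fv, mv, bins=n_bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def mattes_mutual_information(
    fixed: Volume,
    moving: Volume,
    n_bins: int = 32,
    n_samples: int | None = None,
    seed: int = 12345,
    transform: AffineTransform | None = None,
) -> float:
    """Mutual information (nats) of a seeded voxel sample of the overlap.

    Fixed-image voxels are sampled once from ``seed``; the moving image is
    linearly interpolated at the (optionally transformed) sample positions.
    Higher values mean a better match.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    fraction = 0.10 if n_samples is None else n_samples / np.prod(fixed.shape)
    pos = _sample_positions(fixed, fraction, seed)
    return _mi_at(fixed, moving, pos, n_bins, transform)


def _mi_at(fixed, moving, pos_idx, n_bins, transform):
    fv = fixed.data[tuple(pos_idx.astype(int))]
    world = pos_idx * np.asarray(fixed.spacing).reshape(3, 1) + np.asarray(
        fixed.origin
    ).reshape(3, 1)
    y = transform.apply(world) if transform is not None else world
    idx = (y - np.asarray(moving.origin).reshape(3, 1)) / np.asarray(
        moving.spacing
    ).reshape(3, 1)
    inside = np.all((idx >= 0) & (idx <= np.asarray(moving.shape).reshape(3, 1) - 1), axis=0)
    if not inside.any():
        raise MetricError("no sample points fall inside the moving volume")
    mv = ndimage.map_coordinates(moving.data, idx[:, inside], order=1)
    return _mi_from_samples(fv[inside], mv, n_bins)


def rms_difference(a: Volume, b: Volume, mask: np.ndarray | None = None) -> float:
    """Root-mean-square intensity difference over (masked) voxels."""
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    d = a.data - b.data
    if mask is not None:
        mask = np.asarray(mask, bool)
        if not mask.any():
            raise ValueError("empty mask")
        d = d[mask]
    return float(np.sqrt(np.mean(d**2)))


# ---------------------------------------------------------------------------
# affine stage

_STAGE_PARAMS = {"translation": 3, "rigid": 6, "affine": 12}


def _params_to_transform(p: np.ndarray, center: np.ndarray) -> AffineTransform:
    """12-vector (t0 t1 t2 | r0 r1 r2 deg | 50*(s-1) ×3 | 50*shear ×3)."""
    full = np.zeros(12)
    full[: p.size] = p
    return AffineTransform.from_params(
        rotation_deg=full[3:6],
        translation=full[0:3],
        scale=1.0 + full[6:9] / 50.0,
        shear=full[9:12] / 50.0,
        center=center,
    )


@dataclass
class AffineResult:
    transform: AffineTransform
    metric: float
    trace: list = field(default_factory=list)
    warning: str | None = None


def _center_of_mass_offset(fixed: Volume, moving: Volume) -> np.ndarray:
    def com(v: Volume) -> np.ndarray:
        w = v.data - v.data.min()
        tot = w.sum()
        if tot <= 0:
            return v.center_world()
        idx = np.array(ndimage.center_of_mass(w))
        return v.voxel_to_world(idx)

    return com(moving) - com(fixed)


def register_affine(
    fixed: Volume, moving: Volume, config: RegistrationConfig | None = None
) -> AffineResult:
    """Maximize mutual information over affine parameters by downhill simplex.

    Runs coarse-to-fine stages (translation → rigid → full affine by
    default), each a Nelder–Mead search started from the previous stage's
    optimum; the translation stage is initialized from the intensity
    centre-of-mass offset.  The optimizer trace (parameters, metric) is kept
    for logging; a flat metric or hitting the iteration cap sets ``warning``.
    """
    cfg = config or RegistrationConfig()
    center = fixed.center_world()
    pos = _sample_positions(fixed, cfg.mi_sample_fraction, cfg.metric_seed)

    if np.ptp(moving.data) == 0 or np.ptp(fixed.data) == 0:
        return AffineResult(
            AffineTransform.identity(center),
            0.0,
            warning="constant image: metric is flat, returning identity",
        )

    trace: list[tuple[np.ndarray, float]] = []

    def neg_mi(p: np.ndarray) -> float:
        t = _params_to_transform(p, center)
        try:
            mi = _mi_at(fixed, moving, pos, cfg.mi_bins, t)
        except MetricError:
            mi = 0.0
        trace.append((p.copy(), mi))
        return -mi

    steps = np.array(
        [cfg.init_translation_step_mm] * 3
        + [cfg.init_rotation_step_deg] * 3
        + [cfg.init_scale_step * 50.0] * 3
        + [cfg.init_shear_step * 50.0] * 3
    )
    x = np.zeros(12)
    x[0:3] = _center_of_mass_offset(fixed, moving)
    warning = None
    for stage in cfg.stages:
        ndim = _STAGE_PARAMS[stage]
        x0 = x[:ndim].copy()
        simplex = np.vstack([x0] + [x0 + steps[i] * np.eye(ndim)[i] for i in range(ndim)])
        res = optimize.minimize(
            neg_mi,
            x0,
            method="Nelder-Mead",
            options={
                "maxiter": cfg.simplex_max_iter,
                "xatol": cfg.simplex_xatol,
                "fatol": cfg.simplex_fatol,
                "initial_simplex": simplex,
                "adaptive": True,
            },
        )
        x[:ndim] = res.x
        if not res.success and "maximum" in (res.message or "").lower():
            warning = f"stage {stage!r}: {res.message}"

    final = _params_to_transform(x, center)
    mi = _mi_at(fixed, moving, pos, cfg.mi_bins, final)
    if len(trace) > 1 and np.ptp([m for _, m in trace]) < 1e-12:
        warning = "metric is flat over the search"
    return AffineResult(final, mi, trace, warning)


# ---------------------------------------------------------------------------
# Demons stage

@dataclass
class DemonsResult:
    field: DeformationField
    rms_trace: list[float]
    warning: str | None = None


def register_demons(
    fixed: Volume, moving: Volume, config: RegistrationConfig | None = None
) -> DemonsResult:
    """Classic Demons: intensity-difference driven elastic refinement.

    ``moving`` must already be resampled onto the fixed grid (affine
    pre-alignment) and, being a different modality, is histogram-matched to
    the fixed image first.  Each iteration adds the Thirion update
    ``(m−f)·∇f / (|∇f|² + (m−f)²)`` to the displacement field, Gaussian-
    smooths the field, and is accepted only if the RMS intensity difference
    does not increase, so the RMS trace is non-increasing by construction.
    """
    cfg = config or RegistrationConfig()
    if fixed.shape != moving.shape:
        raise ValueError("register_demons expects moving resampled onto the fixed grid")
    f = fixed.data.astype(float)
    m = moving.data.astype(float)
    if cfg.demons_histogram_match and np.ptp(m) > 0 and np.ptp(f) > 0:
        m = match_histograms(m, f)

    spacing = np.asarray(fixed.spacing)
    grad = np.stack(np.gradient(f, *spacing))
    grad_sq = np.sum(grad**2, axis=0)
    if not np.any(grad_sq > 0):
        return _zero_field_result(fixed)

    base_idx = np.stack(
        np.meshgrid(*(np.arange(n, dtype=float) for n in fixed.shape), indexing="ij")
    )
    sigma_vox = [cfg.demons_sigma_mm / s for s in spacing]

    u = np.zeros((3,) + fixed.shape)

    def warp(field: np.ndarray) -> np.ndarray:
        idx = base_idx + field / spacing.reshape(3, 1, 1, 1)
        return ndimage.map_coordinates(m, idx, order=1, mode="nearest")

    mw = warp(u)
    rms_trace = [float(np.sqrt(np.mean((mw - f) ** 2)))]
    warning = None
    for _ in range(cfg.demons_iterations):
        # warped moving is sampled at x + u(x), so the first-order step that
        # pulls m toward f is (f − m)·∇f / (|∇f|² + (f − m)²)
        diff = f - mw
        denom = grad_sq + diff**2
        with np.errstate(invalid="ignore", divide="ignore"):
            step = np.where(denom > 0, diff / denom, 0.0)
        cand = u + step * grad
        for ax in range(3):
            cand[ax] = ndimage.gaussian_filter(cand[ax], sigma=sigma_vox)
        mw_cand = warp(cand)
        rms = float(np.sqrt(np.mean((mw_cand - f) ** 2)))
        if rms > rms_trace[-1]:
            break
        u, mw = cand, mw_cand
        improved = (rms_trace[-1] - rms) / max(rms_trace[-1], _EPS)
        rms_trace.append(rms)
        if improved < cfg.demons_tolerance:
            break
    return DemonsResult(DeformationField(u, fixed.spacing), rms_trace, warning)


def _zero_field_result(fixed: Volume) -> DemonsResult:
    u = np.zeros((3,) + fixed.shape)
    return DemonsResult(
        DeformationField(u, fixed.spacing),
        [0.0],
        warning="fixed image has zero gradient everywhere; returning zero field",
    )


# ---------------------------------------------------------------------------
# whole-study alignment

def align_study(case: StudyCase, config: RegistrationConfig | None = None) -> StudyCase:
    """Align every DWI subseries and the ADC map to the T2 frame.

    The transform (affine, then Demons) is estimated once between T2 and the
    chosen DWI subseries (b=1200 by default — the subseries share a frame)
    and applied identically to all b-values and the ADC map.  RMS intensity
    differences (after histogram matching, since the modalities differ) are
    recorded before and after per volume in ``meta['registration']``.
    """
    cfg = config or RegistrationConfig()
    if case.alignment != "raw":
        raise ValueError("align_study expects a raw (unaligned) case")
    fixed = case.t2
    b_reg = cfg.register_b if float(cfg.register_b) in case.dwi else min(case.dwi)
    moving = case.dwi[b_reg]

    aff = register_affine(fixed, moving, cfg)
    pre_aligned = resample_affine(moving, fixed, aff.transform)
    dem = register_demons(fixed, pre_aligned, cfg)

    def _xmatch(v: np.ndarray) -> np.ndarray:
        if np.ptp(v) == 0 or np.ptp(fixed.data) == 0:
            return v
        return match_histograms(v, fixed.data)

    report: dict[str, dict[str, float]] = {}

    def _apply(vol: Volume, name: str) -> Volume:
        out = apply_deformation(vol, fixed, aff.transform, dem.field, order=cfg.resample_order)
        report[name] = {
            "rms_before": rms_difference(fixed, Volume(_xmatch(vol.data), fixed.spacing, fixed.origin)),
            "rms_after": rms_difference(fixed, Volume(_xmatch(out.data), fixed.spacing, fixed.origin)),
        }
        return out

    dwi = {b: _apply(v, f"dwi_b{b:g}") for b, v in case.dwi.items()}
    adc = None
    if case.adc is not None:
        adc = _apply(case.adc, "adc")
        adc = adc.with_data(np.clip(adc.data, 0.0, None))

    out = StudyCase(
        case_id=case.case_id,
        t2=case.t2,
        dwi=dwi,
        adc=adc,
        alignment="aligned",
        truth_tumor_mask=case.truth_tumor_mask,
        truth_adc=case.truth_adc,
        truth_transform=case.truth_transform,
        meta=dict(case.meta),
    )
    out.meta["registration"] = {
        "rms": report,
        "affine_metric": aff.metric,
        "affine_warning": aff.warning,
        "demons_rms_trace": dem.rms_trace,
        "demons_warning": dem.warning,
    }
    out.meta["transform"] = {"affine": aff.transform, "demons": dem.field}
    return out
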
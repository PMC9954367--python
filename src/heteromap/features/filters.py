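"""Filter bank of derived 2D images for radiomic feature extraction.

Each filter maps a slice to a same-shape derived image: a single-level
stationary wavelet decomposition (LL/LH/HL/HH), Laplacian-of-Gaussian at a
set of scales, pointwise intensity remappings (square, square root,
logarithm, exponential — each linearly rescaled back to the original
intensity range), gradient magnitude, and local binary patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage
from skimage.feature import local_binary_pattern

__all__ = ["FilterBankConfig", "apply_filter_bank"]


@dataclass(frozen=True)
class FilterBankConfig:
    log_sigmas_mm: tuple[float, ...] = (1.0, 2.0, 3.0)
    wavelet: str = "coif1"
    lbp_points: int = 8
    lbp_radius: float = 1.0
    spacing_mm: tuple[float, float] = (1.0, 1.0)


def _rescale(derived: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Linearly map ``derived`` onto the intensity range of ``reference``."""
    lo, hi = float(reference.min()), float(reference.max())
    dlo, dhi = float(derived.min()), float(derived.max())
    if dhi == dlo:
        return np.full_like(derived, lo)
    return lo + (derived - dlo) * (hi - lo) / (dhi - dlo)


def _swt_level1(image: np.ndarray, wavelet: str) -> dict[str, np.ndarray]:
    # swt needs even dims; pad with edge values, crop back
    pad = [(0, s % 2) for s in image.shape]
    padded = np.pad(image, pad, mode="edge")
    (ca, (ch, cv, cd)), = pywt.swt2(padded, wavelet, level=1, norm=True)
    h, w = image.shape
    return {
        "wavelet-LL": ca[:h, :w],
        "wavelet-LH": ch[:h, :w],
        "wavelet-HL": cv[:h, :w],
        "wavelet-HH": cd[:h, :w],
    }


def apply_filter_bank(
    slice_image: np.ndarray,
    mask: np.ndarray | None = None,
    config: FilterBankConfig | None = None,
) -> dict[str, np.ndarray]:
    """All derived images for one 2D slice, keyed by filter name."""
    cfg = config or FilterBankConfig()
    img = np.asarray(slice_image, float)
    if img.ndim != 2:
        raise ValueError("apply_filter_bank expects a 2D slice")
    if mask is not None and not np.asarray(mask, bool).any():
        raise ValueError("empty mask")

    out: dict[str, np.ndarray] = {"original": img}
    out.update(_swt_level1(img, cfg.wavelet))

    for sig in cfg.log_sigmas_mm:
        sig_vox = [sig / s for s in cfg.spacing_mm]
        out[f"log-sigma-{sig:g}mm"] = ndimage.gaussian_laplace(img, sigma=sig_vox)

    absx = np.abs(img)
    amax = absx.max()
    out["square"] = _rescale(img**2, img)
    out["squareroot"] = _rescale(np.sqrt(absx), img)
    out["logarithm"] = _rescale(np.log1p(absx), img)
    out["exponential"] = _rescale(
        np.exp(absx / amax) if amax > 0 else np.ones_like(img), img
    )

    g = np.gradient(img, *cfg.spacing_mm)
    out["gradient"] = np.sqrt(g[0] ** 2 + g[1] ** 2)

    # LBP codes are comparison-based; quantize to integer intensities to
    # avoid spurious codes from float noise ties
    out["lbp"] = local_binary_pattern(
        np.round(img).astype(np.int64), P=cfg.lbp_points, R=cfg.lbp_radius,
        method="uniform",
    ).astype(float)
    return out
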
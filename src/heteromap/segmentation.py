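"""Tumor detection on high-b DWI and ADC-threshold cellularity labeling.

The tumor is hyperintense on the b=1200 s/mm² DWI volume, so K-means
clustering of the voxel intensities separates it from the body; the cluster
with the highest mean intensity, reduced to its largest 3D connected
component, is the tumor mask.  Within the mask, the ADC map provides the
reference ("golden standard") cellularity labels: voxels with
ADC < 0.85e-3 mm²/s are the highly cellular class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .volume import StudyCase, Volume

__all__ = [
    "DEFAULT_ADC_CUTOFF",
    "DEFAULT_UNCERTAIN_BAND",
    "LABEL_BACKGROUND",
    "LABEL_HIGH",
    "LABEL_LOW",
    "LABEL_UNCERTAIN",
    "TumorMask",
    "CellularityLabelMap",
    "RoiExtraction",
    "segment_tumor_kmeans",
    "label_cellularity",
    "extract_roi",
    "compute_adc",
]

#: ADC threshold (mm²/s) below which tumor tissue counts as highly cellular.
DEFAULT_ADC_CUTOFF = 0.85e-3
#: ADC interval (mm²/s) rendered as "uncertain" in overlays; binary labels
#: collapse it into the low-cellularity class.
DEFAULT_UNCERTAIN_BAND = (0.85e-3, 1.0e-3)

LABEL_BACKGROUND, LABEL_HIGH, LABEL_LOW, LABEL_UNCERTAIN = 0, 1, 2, 3


@dataclass(frozen=True)
class TumorMask:
    """Binary tumor mask on the reference (T2) grid."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, bool))

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def __bool__(self) -> bool:
        return bool(self.mask.any())


@dataclass(frozen=True)
class CellularityLabelMap:
    """Per-voxel label in {background, high, low, uncertain}.

    ``labels`` uses the integer codes 0/1/2/3 (background / high / low /
    uncertain).  ``binary_within`` collapses uncertain into low for the
    two-class problem the classifier is trained on.
    """

    labels: np.ndarray
    cutoff: float
    uncertain_band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels, np.int8))

    def binary_within(self, mask: np.ndarray) -> np.ndarray:
        """1 = high cellularity, 0 = low (incl. uncertain), within ``mask``."""
        return (self.labels == LABEL_HIGH)[np.asarray(mask, bool)].astype(int)

    def counts(self) -> dict[str, int]:
        lab = self.labels
        return {
            "background": int((lab == LABEL_BACKGROUND).sum()),
            "high": int((lab == LABEL_HIGH).sum()),
            "low": int((lab == LABEL_LOW).sum()),
            "uncertain": int((lab == LABEL_UNCERTAIN).sum()),
        }


def segment_tumor_kmeans(dwi_b1200: Volume, k: int = 2, seed: int = 0) -> TumorMask:
    """K-means tumor segmentation of the b=1200 DWI volume.

    Lloyd's algorithm with k-means++ initialization on the voxel
    intensities; the tumor is the cluster with the highest mean intensity,
    cleaned up to its largest 3D connected component (6-connectivity).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    data = dwi_b1200.data
    if np.ptp(data) == 0:
        raise ValueError("cannot cluster a constant image")
    x = data.reshape(-1, 1)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
    tumor_cluster = int(np.argmax(km.cluster_centers_.ravel()))
    mask = (km.labels_ == tumor_cluster).reshape(data.shape)
    comp, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("k-means produced an empty tumor cluster")
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
    mask = comp == (1 + int(np.argmax(sizes)))
    return TumorMask(mask)


def label_cellularity(
    adc: Volume,
    mask: TumorMask,
    cutoff: float = DEFAULT_ADC_CUTOFF,
    uncertain_band: tuple[float, float] | None = DEFAULT_UNCERTAIN_BAND,
) -> CellularityLabelMap:
    """ADC-threshold labels within the tumor mask.

    ADC < cutoff → high; ADC within the (optional) uncertain band →
    uncertain; otherwise low; everything outside the mask is background.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    m = mask.mask
    if adc.data.shape != m.shape:
        raise ValueError(f"grid mismatch: ADC {adc.data.shape} vs mask {m.shape}")
    if np.any(adc.data[m] < 0):
        raise ValueError("negative ADC values inside the tumor mask")
    lab = np.full(m.shape, LABEL_BACKGROUND, dtype=np.int8)
    vals = adc.data
    lab[m] = LABEL_LOW
    if uncertain_band is not None:
        lo, hi = uncertain_band
        lab[m & (vals >= lo) & (vals <= hi)] = LABEL_UNCERTAIN
    lab[m & (vals < cutoff)] = LABEL_HIGH
    return CellularityLabelMap(lab, float(cutoff), uncertain_band)


@dataclass(frozen=True)
class RoiExtraction:
    """Tight crop of the tumor region, with the bookkeeping to map back.

    ``offset`` is the 0-based voxel index of the crop's corner in the
    original grid; bounding boxes are half-open.
    """

    t2: Volume
    mask: TumorMask
    offset: tuple[int, int, int]
    original_shape: tuple[int, int, int]

    def to_original(self, idx: np.ndarray) -> np.ndarray:
        """Map crop voxel indices (n, 3) back to original-grid indices."""
        return np.asarray(idx, int) + np.asarray(self.offset, int)


def extract_roi(t2: Volume, mask: TumorMask) -> RoiExtraction:
    """Crop T2 and mask to the tumor bounding box, zeroing the background."""
    m = mask.mask
    if not m.any():
        raise ValueError("empty tumor mask")
    if t2.data.shape != m.shape:
        raise ValueError(f"grid mismatch: T2 {t2.data.shape} vs mask {m.shape}")
    nz = np.nonzero(m)
    lo = [int(a.min()) for a in nz]
    hi = [int(a.max()) + 1 for a in nz]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    crop_mask = m[sl]
    crop_t2 = np.where(crop_mask, t2.data[sl], 0.0)
    origin = tuple(
        o + a * s for o, a, s in zip(t2.origin, lo, t2.spacing)
    )
    return RoiExtraction(
        t2=Volume(crop_t2, t2.spacing, origin),
        mask=TumorMask(crop_mask),
        offset=tuple(lo),
        original_shape=t2.data.shape,
    )


def compute_adc(dwi: dict[float, Volume]) -> Volume:
    """Monoexponential ADC fit from the DWI subseries (fallback map).

    Ordinary least-squares slope of ``ln S(b)`` against ``b`` per voxel;
    ADC is the negated slope, clipped at zero.  Voxels with non-positive
    signal at any b are set to 0 (they will be background anyway).
    """
    bvals = sorted(float(b) for b in dwi)
    if len(bvals) < 2 or 0.0 not in bvals:
        raise ValueError("compute_adc needs >= 2 b-values including b=0")
    ref = dwi[bvals[0]]
    stack = np.stack([dwi[b].data for b in bvals])
    valid = np.all(stack > 0, axis=0)
    logs = np.where(stack > 0, np.log(np.where(stack > 0, stack, 1.0)), 0.0)
    b = np.asarray(bvals).reshape(-1, 1, 1, 1)
    bbar = b.mean()
    denom = float(np.sum((np.asarray(bvals) - bbar) ** 2))
    slope = np.sum((b - bbar) * (logs - logs.mean(axis=0)), axis=0) / denom
    adc = np.clip(-slope, 0.0, None)
    adc[~valid] = 0.0
    return Volume(adc, ref.spacing, ref.origin)
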
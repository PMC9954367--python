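"""Assembly of the per-pixel feature matrix for classification.

Feature extraction runs slice by slice over the tumor ROI.  For every tumor
pixel the row holds: the value of each filter-bank image at that pixel,
first-order and texture-matrix statistics of the W×W window centred on it
(intersected with the tumor mask), and the 2D shape descriptors of the
tumor outline in that slice (identical for all pixels of the slice).  Rows
are ordered deterministically (slice, then row-major) and chunked into
blocks of 400 pixels — the unit the classifier consumes at prediction time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from ..segmentation import CellularityLabelMap, LABEL_BACKGROUND, LABEL_HIGH, TumorMask
from ..volume import Volume
from .filters import FilterBankConfig, apply_filter_bank
from .firstorder import compute_first_order
from .texture import (
    compute_gldm_features,
    compute_glcm_features,
    compute_glrlm_features,
    compute_glszm_features,
    compute_ngtdm_features,
    discretize,
    gldm_matrix,
    glcm_matrix,
    glrlm_matrix,
    glszm_matrix,
    ngtdm_matrix,
)

logger = logging.getLogger(__name__)

__all__ = ["FeatureConfig", "FeatureMatrix", "pixel_feature_matrix", "remove_constant_features"]

INDEX_COLUMNS = ["case_id", "slice", "y", "x", "block"]
LABEL_COLUMN = "label"

#: Pixels per prediction block.
BLOCK_SIZE = 400


@dataclass(frozen=True)
class FeatureConfig:
    window: int = 9
    n_bins: int = 32
    block_size: int = BLOCK_SIZE
    min_window_pixels: int = 2
    filters: FilterBankConfig = field(default_factory=FilterBankConfig)


@dataclass
class FeatureMatrix:
    """Tidy per-pixel table: index columns, feature columns, binary label."""

    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def feature_columns(self) -> list[str]:
        return [
            c for c in self.frame.columns if c not in INDEX_COLUMNS + [LABEL_COLUMN]
        ]

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def features(self) -> np.ndarray:
        return self.frame[self.feature_columns].to_numpy(float)

    def labels(self) -> np.ndarray:
        return self.frame[LABEL_COLUMN].to_numpy(int)

    def groups(self) -> np.ndarray:
        return self.frame["case_id"].to_numpy()

    def blocks(self):
        """Yield (block_id, row_positions) in deterministic order."""
        keys = list(zip(self.frame["case_id"], self.frame["block"]))
        seen: dict = {}
        for pos, k in enumerate(keys):
            seen.setdefault(k, []).append(pos)
        for k in seen:
            yield k, np.asarray(seen[k], int)

    def concat(self, other: "FeatureMatrix") -> "FeatureMatrix":
        return FeatureMatrix(
            pd.concat([self.frame, other.frame], ignore_index=True),
            {**self.meta, **other.meta},
        )


def _shape2d(mask_slice: np.ndarray, pixel_area: float) -> dict[str, float]:
    props = regionprops(mask_slice.astype(np.uint8))[0]
    area = float(props.area) * pixel_area
    perim = float(props.perimeter)
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    return {
        "shape_PixelSurface": area,
        "shape_Perimeter": perim,
        "shape_PerimeterSurfaceRatio": perim / area if area > 0 else 0.0,
        "shape_Sphericity": (
            2.0 * np.sqrt(np.pi * area) / perim if perim > 0 else 1.0
        ),
        "shape_MajorAxisLength": major,
        "shape_MinorAxisLength": minor,
        "shape_Elongation": minor / major if major > 0 else 1.0,
        "shape_Eccentricity": float(props.eccentricity),
        "shape_MaximumDiameter": float(props.feret_diameter_max),
    }


def _window_features(img, lev, mask, y, x, cfg: FeatureConfig, pixel_area: float):
    half = cfg.window // 2
    ys = slice(max(y - half, 0), y + half + 1)
    xs = slice(max(x - half, 0), x + half + 1)
    wm = mask[ys, xs]
    npix = int(wm.sum())
    if npix < cfg.min_window_pixels:
        return None
    wl = lev[ys, xs]
    wi = img[ys, xs]
    ng = cfg.n_bins
    feats = compute_first_order(wi[wm], n_bins=cfg.n_bins, pixel_volume=pixel_area)
    glcm = glcm_matrix(wl, wm, ng)
    if not np.any(glcm.sum(axis=(1, 2)) > 0):
        return None
    feats.update(compute_glcm_features(glcm))
    feats.update(compute_glrlm_features(glrlm_matrix(wl, wm, ng), npix))
    feats.update(compute_glszm_features(glszm_matrix(wl, wm, ng), npix))
    feats.update(compute_gldm_features(gldm_matrix(wl, wm, ng)))
    p, s, nv = ngtdm_matrix(wl, wm, ng)
    if nv == 0:
        return None
    feats.update(compute_ngtdm_features(p, s, nv))
    return feats


def pixel_feature_matrix(
    roi_t2: Volume,
    mask: TumorMask,
    labels: CellularityLabelMap,
    config: FeatureConfig | None = None,
    case_id: str = "case",
) -> FeatureMatrix:
    """Build the per-pixel feature matrix of one case's tumor ROI.

    ``roi_t2``, ``mask`` and ``labels`` must share the (cropped) ROI grid.
    The binary label is 1 for the highly cellular class and 0 otherwise
    (the uncertain band collapses into 0).  Pixels whose window carries too
    few masked neighbours for the texture matrices are dropped; the count
    is logged and recorded in ``meta``.
    """
    cfg = config or FeatureConfig()
    m3 = mask.mask
    if roi_t2.data.shape != m3.shape or labels.labels.shape != m3.shape:
        raise ValueError("ROI, mask and label map must share one grid")
    if not m3.any():
        raise ValueError("empty ROI")
    pixel_area = float(roi_t2.spacing[1] * roi_t2.spacing[2])
    fcfg = FilterBankConfig(
        **{
            **cfg.filters.__dict__,
            "spacing_mm": (roi_t2.spacing[1], roi_t2.spacing[2]),
        }
    )

    rows: list[dict] = []
    dropped = 0
    for z in range(m3.shape[0]):
        ms = m3[z]
        if not ms.any():
            continue
        img = roi_t2.data[z]
        bank = apply_filter_bank(img, ms, fcfg)
        lev = discretize(img, ms, cfg.n_bins)
        shape_feats = _shape2d(ms, pixel_area)
        for y, x in np.argwhere(ms):
            lab = labels.labels[z, y, x]
            if lab == LABEL_BACKGROUND:
                continue
            wf = _window_features(img, lev, ms, y, x, cfg, pixel_area)
            if wf is None:
                dropped += 1
                continue
            row = {
                "case_id": case_id,
                "slice": int(z),
                "y": int(y),
                "x": int(x),
            }
            row.update({f"filt_{k}": float(v[y, x]) for k, v in bank.items()})
            row.update(wf)
            row.update(shape_feats)
            row[LABEL_COLUMN] = int(lab == LABEL_HIGH)
            rows.append(row)
    if not rows:
        raise ValueError("no usable tumor pixels")
    if dropped:
        logger.info("%s: dropped %d pixels with insufficient window support", case_id, dropped)
    frame = pd.DataFrame(rows)
    frame.insert(4, "block", np.arange(len(frame)) // cfg.block_size)
    # fixed column order: index, features sorted, label
    feat_cols = sorted(c for c in frame.columns if c not in INDEX_COLUMNS + [LABEL_COLUMN])
    frame = frame[INDEX_COLUMNS + feat_cols + [LABEL_COLUMN]]
    fm = FeatureMatrix(frame, {"dropped_pixels": {case_id: dropped}, "config": cfg})
    arr = fm.features()
    if not np.all(np.isfinite(arr)):
        bad = [fm.feature_columns[i] for i in np.unique(np.argwhere(~np.isfinite(arr))[:, 1])]
        raise FloatingPointError(f"non-finite feature values in columns {bad}")
    return fm


def remove_constant_features(fm: FeatureMatrix) -> FeatureMatrix:
    """Drop zero-variance feature columns (idempotent); names are recorded."""
    if fm.n_rows < 1:
        raise ValueError("empty feature matrix")
    arr = fm.features()
    var = arr.var(axis=0)
    cols = fm.feature_columns
    dropped = [c for c, v in zip(cols, var) if v == 0]
    if len(dropped) == len(cols):
        raise ValueError("all feature columns are constant")
    if dropped:
        logger.info("removing %d constant features: %s", len(dropped), dropped)
    keep = [c for c in fm.frame.columns if c not in dropped]
    meta = dict(fm.meta)
    meta["dropped_constant"] = sorted(set(meta.get("dropped_constant", [])) | set(dropped))
    return FeatureMatrix(fm.frame[keep].copy(), meta)
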
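"""Study I/O (NIfTI + JSON sidecar) and 2D overlay export.

A study directory holds one NIfTI file per volume (``t2.nii``,
``dwi_b{b}.nii``, ``adc.nii``) plus ``study.json`` with case id, b-values,
alignment state and — for phantoms — pointers to the ground-truth volumes.
Label maps and masks are written as integer-coded NIfTI
(0 background, 1 high, 2 low, 3 uncertain).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .segmentation import (
    CellularityLabelMap,
    LABEL_HIGH,
    LABEL_LOW,
    LABEL_UNCERTAIN,
    compute_adc,
)
from .volume import GeometryError, StudyCase, Volume

logger = logging.getLogger(__name__)

__all__ = ["write_volume", "read_volume", "write_study", "read_study", "export_overlay"]

OVERLAY_COLORS = {
    "high": (220, 50, 50),
    "low": (60, 90, 220),
    "uncertain": (235, 200, 50),
}


def _affine(vol: Volume) -> np.ndarray:
    aff = np.diag(list(vol.spacing) + [1.0])
    aff[:3, 3] = vol.origin
    return aff


def write_volume(vol: Volume, path: Path, dtype=np.float64) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=dtype), _affine(vol))
    nib.save(img, str(path))


def read_volume(path: Path) -> Volume:
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(aff[i, i]) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return Volume(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


def write_study(case: StudyCase, out_dir: str | Path) -> Path:
    """Write all volumes plus the JSON sidecar; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(case.t2, out / "t2.nii")
    for b, v in case.dwi.items():
        write_volume(v, out / f"dwi_b{b:g}.nii")
    if case.adc is not None:
        write_volume(case.adc, out / "adc.nii")
    sidecar: dict = {
        "case_id": case.case_id,
        "alignment": case.alignment,
        "b_values": case.b_values,
        "meta": {k: v for k, v in case.meta.items() if _jsonable(v)},
    }
    if case.truth_tumor_mask is not None:
        write_volume(
            Volume(case.truth_tumor_mask.astype(np.uint8), case.t2.spacing, case.t2.origin),
            out / "truth_mask.nii",
            dtype=np.uint8,
        )
        sidecar["truth_mask"] = "truth_mask.nii"
    if case.truth_adc is not None:
        write_volume(case.truth_adc, out / "truth_adc.nii")
        sidecar["truth_adc"] = "truth_adc.nii"
    if case.truth_transform is not None:
        tt = case.truth_transform
        sidecar["truth_transform"] = {
            "rotation_deg": list(tt["rotation_deg"]),
            "translation_mm": list(tt["translation_mm"]),
            "center_mm": list(tt["center_mm"]),
        }
        warp = np.moveaxis(np.asarray(tt["warp_mm"]), 0, -1)
        nib.save(
            nib.Nifti1Image(warp, _affine(case.t2)), str(out / "truth_warp.nii")
        )
    (out / "study.json").write_text(json.dumps(sidecar, indent=2))
    return out


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def read_study(path: str | Path) -> StudyCase:
    """Load a study directory; geometry is validated on load.

    A missing ADC map is tolerated: it is refitted from the DWI series with
    a logged notice.  A missing b=1200 s/mm² subseries is an error.
    """
    p = Path(path)
    sidecar = json.loads((p / "study.json").read_text())
    t2 = read_volume(p / "t2.nii")
    dwi = {float(b): read_volume(p / f"dwi_b{b:g}.nii") for b in sidecar["b_values"]}
    if 1200.0 not in dwi:
        raise ValueError(
            f"study {sidecar['case_id']!r} lacks the required b=1200 s/mm² "
            f"subseries (has {sorted(dwi)})"
        )
    adc_path = p / "adc.nii"
    if adc_path.exists():
        adc = read_volume(adc_path)
    else:
        logger.info("study %s: no scanner ADC map; fitting from DWI", sidecar["case_id"])
        adc = compute_adc(dwi)
    truth_mask = None
    if "truth_mask" in sidecar:
        truth_mask = read_volume(p / sidecar["truth_mask"]).data > 0.5
    truth_adc = (
        read_volume(p / sidecar["truth_adc"]) if "truth_adc" in sidecar else None
    )
    truth_transform = None
    if "truth_transform" in sidecar:
        tt = dict(sidecar["truth_transform"])
        warp_path = p / "truth_warp.nii"
        if warp_path.exists():
            tt["warp_mm"] = np.moveaxis(
                np.asarray(nib.load(str(warp_path)).dataobj, float), -1, 0
            )
        from .phantom import _rotation_matrix

        tt["matrix"] = _rotation_matrix(tt["rotation_deg"])
        truth_transform = tt
    case = StudyCase(
        case_id=sidecar["case_id"],
        t2=t2,
        dwi=dwi,
        adc=adc,
        alignment=sidecar.get("alignment", "raw"),
        truth_tumor_mask=truth_mask,
        truth_adc=truth_adc,
        truth_transform=truth_transform,
        meta=sidecar.get("meta", {}),
    )
    shapes = {n: v.shape for n, v in [("t2", t2), *[(f"dwi_b{b:g}", v) for b, v in dwi.items()]]}
    if len(set(shapes.values())) != 1:
        raise GeometryError(f"grid shape mismatch across volumes: {shapes}")
    return case


def _to_rgb(slice2d: np.ndarray) -> np.ndarray:
    lo, hi = slice2d.min(), slice2d.max()
    g = np.zeros_like(slice2d) if hi == lo else (slice2d - lo) / (hi - lo)
    return np.repeat((g[..., None] * 255).astype(np.uint8), 3, axis=-1)


def _blend(rgb: np.ndarray, labels2d: np.ndarray, alpha: float = 0.55) -> np.ndarray:
    out = rgb.astype(float)
    for code, color in (
        (LABEL_HIGH, OVERLAY_COLORS["high"]),
        (LABEL_LOW, OVERLAY_COLORS["low"]),
        (LABEL_UNCERTAIN, OVERLAY_COLORS["uncertain"]),
    ):
        sel = labels2d == code
        out[sel] = (1 - alpha) * out[sel] + alpha * np.asarray(color, float)
    return out.astype(np.uint8)


def export_overlay(
    t2: Volume,
    labels: CellularityLabelMap,
    pred: CellularityLabelMap | None = None,
    out_dir: str | Path = "overlays",
) -> list[Path]:
    """Per-slice PNGs: T2 with the reference labels (red = highly cellular,
    blue = low, yellow = uncertain) and, if given, a side-by-side panel
    with the predicted labels.  Writes ``colors.json`` alongside."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lab = labels.labels
    if lab.shape != t2.data.shape:
        raise ValueError("label map and T2 must share a grid")
    if not np.any(lab > 0):
        logger.warning("label map is background-only; exporting plain T2 slices")
    paths = []
    for z in range(t2.data.shape[0]):
        rgb = _to_rgb(t2.data[z])
        panel = _blend(rgb, lab[z])
        if pred is not None:
            panel = np.concatenate([panel, _blend(rgb, pred.labels[z])], axis=1)
        path = out / f"slice_{z:03d}.png"
        iio.imwrite(path, panel)
        paths.append(path)
    (out / "colors.json").write_text(
        json.dumps({"colors": OVERLAY_COLORS, "panels": ["reference"] + (["prediction"] if pred is not None else [])}, indent=2)
    )
    return paths
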
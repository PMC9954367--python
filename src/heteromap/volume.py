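"""3D scalar volumes with physical geometry, and per-patient study bundles.

A :class:`Volume` is a plain ``(n0, n1, n2)`` float array plus voxel spacing
(mm) and a world origin (mm); axis 0 is the slice (through-plane) axis.  A
:class:`StudyCase` bundles the volumes of one MRI study: the T2-weighted
reference, the DWI subseries keyed by b-value (s/mm²), and the ADC map
(mm²/s), together with its alignment state and — for synthetic phantoms —
the ground truth the pipeline is evaluated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = ["Volume", "StudyCase", "REQUIRED_B", "GeometryError"]

#: b-value (s/mm²) the tumor-segmentation stage requires.
REQUIRED_B = 1200.0


class GeometryError(ValueError):
    """Raised when volume geometries are inconsistent or out of bounds."""


@dataclass(frozen=True)
class Volume:
    """A 3D scalar image with voxel spacing and origin in millimetres."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        object.__setattr__(self, "data", arr)
        if arr.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {arr.shape}")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise GeometryError(f"invalid spacing {self.spacing}")
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "Volume":
        """Same geometry, new voxel data (shape must match)."""
        data = np.asarray(data, dtype=np.float64)
        if data.shape != self.data.shape:
            raise GeometryError(
                f"data shape {data.shape} != volume shape {self.data.shape}"
            )
        return replace(self, data=data)

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to world mm coordinates."""
        idx = np.asarray(idx, dtype=np.float64)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=np.float64)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)

    def center_world(self) -> np.ndarray:
        """World coordinates of the grid centre."""
        half = (np.asarray(self.shape, dtype=np.float64) - 1.0) / 2.0
        return self.voxel_to_world(half)


@dataclass
class StudyCase:
    """One patient's (or phantom's) MRI study.

    ``alignment`` is ``"raw"`` until the DWI/ADC frame has been registered to
    the T2 frame, then ``"aligned"``.  Phantoms additionally carry the ground
    truth used by the test-bed: the true tumor mask, the true per-voxel ADC
    field and the misalignment transform that was applied.
    """

    case_id: str
    t2: Volume
    dwi: dict[float, Volume]
    adc: Volume | None = None
    alignment: str = "aligned"
    truth_tumor_mask: np.ndarray | None = None
    truth_adc: Volume | None = None
    truth_transform: dict | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dwi = {float(b): v for b, v in self.dwi.items()}
        if self.alignment not in ("raw", "aligned"):
            raise ValueError(f"alignment must be raw|aligned, got {self.alignment!r}")

    @property
    def b_values(self) -> list[float]:
        return sorted(self.dwi)

    def require_b(self, b: float = REQUIRED_B) -> Volume:
        if float(b) not in self.dwi:
            raise ValueError(
                f"case {self.case_id!r} lacks the b={b:g} s/mm² DWI subseries "
                f"(has {self.b_values})"
            )
        return self.dwi[float(b)]

    def validate_geometry(self) -> None:
        """All volumes must live on a common grid once aligned."""
        vols: Mapping[str, Volume] = {"t2": self.t2}
        vols = dict(vols, **{f"dwi_b{b:g}": v for b, v in self.dwi.items()})
        if self.adc is not None:
            vols["adc"] = self.adc
        ref_name, ref = next(iter(vols.items()))
        for name, v in vols.items():
            if v.shape != ref.shape:
                raise GeometryError(
                    f"grid shape mismatch: {ref_name} has {ref.shape}, "
                    f"{name} has {v.shape}"
                )
            if self.alignment == "aligned" and not v.same_grid(ref):
                raise GeometryError(
                    f"geometry mismatch between {ref_name} and {name}"
                )
        if self.adc is not None and np.any(self.adc.data < 0):
            raise ValueError("ADC map contains negative values")
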
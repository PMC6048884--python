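"""CT series loading and square patch extraction around lesion marks.

Slices are stacked in ascending z and converted to Hounsfield units with
each slice's rescale slope/intercept.  Patches of 16, 32 or 64 pixels are
cropped centred on each micro-nodule or non-nodule mark using the
half-open convention [c - s/2, c + s/2); positions falling outside the
image are padded with -1000 HU (air) so the lesion stays centred.
Intensities are then windowed to the standard lung range [-1000, 400] HU
and mapped affinely onto [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom

from .annotations import ScanAnnotation, SliceRef, center_of_mass

__all__ = [
    "CTVolume",
    "Patch",
    "SliceResolutionError",
    "load_ct_series",
    "map_mark_to_voxel",
    "extract_patch",
    "normalize_patch",
    "build_patch_dataset",
    "PATCH_SIZES",
    "HU_WINDOW",
    "AIR_HU",
]

PATCH_SIZES = (16, 32, 64)
HU_WINDOW = (-1000.0, 400.0)  # standard lung window
AIR_HU = -1000.0

_REQUIRED_TAGS = ("ImagePositionPatient", "PixelSpacing",
                  "RescaleSlope", "RescaleIntercept")


class SliceResolutionError(ValueError):
    """A mark's slice reference cannot be matched to the loaded volume."""


@dataclass
class CTVolume:
    """An axial CT stack in Hounsfield units with its geometry."""

    voxels: np.ndarray                 # (H, W, S)
    pixel_spacing: tuple[float, float]  # (row mm, col mm)
    slice_z: np.ndarray                # (S,) strictly ascending, mm
    slice_uids: list[str]

    def __post_init__(self) -> None:
        self.slice_z = np.asarray(self.slice_z, dtype=float)
        s = self.voxels.shape[2]
        if len(self.slice_z) != s or len(self.slice_uids) != s:
            raise ValueError("slice metadata length must match slice count")
        if s > 1 and not np.all(np.diff(self.slice_z) > 0):
            raise ValueError("slice_z must be strictly ascending")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[2]

    @property
    def slice_spacing(self) -> float:
        """Median inter-slice gap in mm (1.0 for single-slice volumes)."""
        if self.n_slices < 2:
            return 1.0
        return float(np.median(np.diff(self.slice_z)))


def load_ct_series(slice_files) -> CTVolume:
    """Read a set of DICOM slice files into a z-sorted HU volume.

    All files must belong to one series; stored values are converted to HU
    via each slice's RescaleSlope and RescaleIntercept.  Missing geometry
    tags raise a ValueError naming the tag.
    """
    files = sorted(Path(f) for f in slice_files)
    if not files:
        raise ValueError("no slice files given")
    slices = []
    series_uids = set()
    for path in files:
        ds = pydicom.dcmread(str(path))
        series_uids.add(str(getattr(ds, "SeriesInstanceUID", "")))
        for tag in _REQUIRED_TAGS:
            if getattr(ds, tag, None) is None:
                raise ValueError(f"slice {path.name} is missing tag {tag}")
        slices.append(ds)
    if len(series_uids) > 1:
        raise ValueError(f"mixed series in input: {sorted(series_uids)}")

    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    z = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    uids = [str(ds.SOPInstanceUID) for ds in slices]
    hu = np.stack(
        [ds.pixel_array.astype(np.float64) * float(ds.RescaleSlope)
         + float(ds.RescaleIntercept) for ds in slices],
        axis=2,
    )
    spacing = tuple(float(v) for v in slices[0].PixelSpacing)
    return CTVolume(voxels=hu, pixel_spacing=spacing, slice_z=z, slice_uids=uids)


def map_mark_to_voxel(mark_point: tuple[float, float, SliceRef],
                      volume: CTVolume) -> tuple[int, int, int]:
    """Map an annotation point (x, y, slice ref) to (row, col, slice index).

    XML x is the column axis and y the row axis, both taken as 0-based
    pixel indices.  The slice resolves by exact SOP-UID match first, then
    by nearest z within half the median slice spacing.
    """
    x, y, ref = mark_point
    if ref.sop_uid and ref.sop_uid in volume.slice_uids:
        k = volume.slice_uids.index(ref.sop_uid)
    elif ref.z_mm is not None:
        diffs = np.abs(volume.slice_z - ref.z_mm)
        k = int(np.argmin(diffs))
        tol = 0.5 * volume.slice_spacing
        if diffs[k] > tol:
            raise SliceResolutionError(
                f"z = {ref.z_mm} mm is {diffs[k]:.2f} mm from the nearest "
                f"slice (tolerance {tol:.2f} mm); volume spans "
                f"[{volume.slice_z[0]}, {volume.slice_z[-1]}] mm"
            )
    else:
        raise SliceResolutionError(
            f"SOP UID {ref.sop_uid!r} not in volume and no z given; "
            f"volume spans [{volume.slice_z[0]}, {volume.slice_z[-1]}] mm"
        )
    return int(round(y)), int(round(x)), k


def extract_patch(volume: CTVolume, center: tuple[int, int, int],
                  size: int) -> np.ndarray:
    """Crop a size x size HU window centred on a voxel.

    The window covers rows [row - size/2, row + size/2) and the analogous
    columns (half-open, even-size convention); out-of-image positions are
    filled with -1000 HU.
    """
    row, col, k = center
    if not 0 <= k < volume.n_slices:
        raise IndexError(f"slice index {k} out of range")
    img = volume.voxels[:, :, k]
    h, w = img.shape
    half = size // 2
    out = np.full((size, size), AIR_HU, dtype=np.float64)
    r0, c0 = row - half, col - half
    rs, re = max(r0, 0), min(r0 + size, h)
    cs, ce = max(c0, 0), min(c0 + size, w)
    if rs < re and cs < ce:
        out[rs - r0:re - r0, cs - c0:ce - c0] = img[rs:re, cs:ce]
    return out


def normalize_patch(raw: np.ndarray) -> np.ndarray:
    """Clip HU to the lung window [-1000, 400] and map affinely to [0, 1]."""
    raw = np.asarray(raw, dtype=np.float64)
    if not np.isfinite(raw).all():
        raise ValueError("patch contains non-finite HU values")
    lo, hi = HU_WINDOW
    return (np.clip(raw, lo, hi) - lo) / (hi - lo)


@dataclass(frozen=True)
class Patch:
    """A normalised intensity window around one mark."""

    pixels: np.ndarray
    size: int
    label: int  # 1 = micro-nodule, 0 = non-nodule
    patient_id: str
    reader_index: int
    mark_id: str

    def __post_init__(self) -> None:
        if self.size not in PATCH_SIZES:
            raise ValueError(f"size must be one of {PATCH_SIZES}")
        if self.pixels.shape != (self.size, self.size):
            raise ValueError("pixel array does not match declared size")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if not (np.isfinite(self.pixels).all()
                and self.pixels.min() >= 0.0 and self.pixels.max() <= 1.0):
            raise ValueError("pixels must be finite and within [0, 1]")


_LABEL_OF = {"micro_nodule": 1, "non_nodule": 0}

MANIFEST_COLUMNS = [
    "patient_id", "reader_index", "mark_id", "label", "size",
    "row", "col", "slice_index",
]


def build_patch_dataset(
    scans: list[ScanAnnotation],
    volumes: dict[str, CTVolume],
    sizes=PATCH_SIZES,
) -> tuple[dict[int, list[Patch]], pd.DataFrame, list[str]]:
    """Extract one patch per micro-nodule/non-nodule mark per size.

    ``volumes`` maps patient_id to the loaded CT volume.  Contoured
    (>= 3 mm) nodule marks produce nothing.  Marks whose slice cannot be
    resolved are skipped, each with a logged reason.  Returns the per-size
    patch store, the manifest (one row per patch), and the skip log.
    """
    store: dict[int, list[Patch]] = {int(s): [] for s in sizes}
    rows = []
    skipped: list[str] = []
    for scan in scans:
        volume = volumes.get(scan.patient_id)
        if volume is None:
            skipped.append(f"{scan.patient_id}: no CT volume loaded")
            continue
        for mark in scan.iter_marks():
            label = _LABEL_OF.get(mark.category)
            if label is None:
                continue  # contoured nodules yield no patches
            try:
                center = map_mark_to_voxel(center_of_mass(mark), volume)
            except SliceResolutionError as exc:
                skipped.append(
                    f"{scan.patient_id}/{mark.mark_id} "
                    f"(reader {mark.reader_index}): {exc}"
                )
                continue
            for size in sizes:
                size = int(size)
                pixels = normalize_patch(extract_patch(volume, center, size))
                store[size].append(Patch(
                    pixels=pixels, size=size, label=label,
                    patient_id=scan.patient_id,
                    reader_index=mark.reader_index,
                    mark_id=mark.mark_id,
                ))
                rows.append({
                    "patient_id": scan.patient_id,
                    "reader_index": mark.reader_index,
                    "mark_id": mark.mark_id,
                    "label": label,
                    "size": size,
                    "row": center[0],
                    "col": center[1],
                    "slice_index": center[2],
                })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return store, manifest, skipped


def patches_to_arrays(patches: list[Patch]) -> tuple[np.ndarray, np.ndarray]:
    """Stack a patch list into (X, y) arrays for training."""
    if not patches:
        raise ValueError("empty patch list")
    x = np.stack([p.pixels for p in patches])
    y = np.array([p.label for p in patches], dtype=int)
    return x, y
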
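"""Synthetic fixtures: miniature CT scans with planted marks, and labeled
patch datasets with controllable class separability.

Two generators are provided.  :func:`generate_scan_fixture` writes a small
DICOM slice series plus a matching LIDC-dialect annotation XML from a
:class:`FixturePlan`, so the parsing/extraction pipeline can be exercised
end-to-end against planted ground truth with no external archive.
:func:`generate_patch_dataset` emits labeled intensity patches directly:
micro-nodule patches carry a centred Gaussian bright blob whose diameter
is drawn below the 3 mm micro-nodule bound (at the nominal pixel
spacing), non-nodule patches carry an off-centre elongated vessel-like
ridge or plain texture.  The background is correlated (smoothed) noise in
a lung-parenchyma HU range — seeded and reproducible, but not a model of
real CT texture.

The ``separation`` parameter scales lesion/ridge contrast in units of the
background noise standard deviation; at separation 0 both classes are
drawn from the identical pure-texture distribution by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian
from scipy import ndimage

__all__ = [
    "FixturePlan",
    "PlantedMark",
    "SyntheticPatchParams",
    "generate_scan_fixture",
    "generate_patch_dataset",
]

_UID_ROOT = "1.2.826.0.1.3680043.10.1234"  # synthetic fixtures only

_BACKGROUND_HU = -850.0   # aerated lung parenchyma
_CONTRAST_REF_HU = 60.0   # 1 unit of separation in HU per noise-sd unit


@dataclass(frozen=True)
class PlantedMark:
    """Ground truth for one planted lesion mark."""

    category: str            # nodule / micro_nodule / non_nodule
    row: int
    col: int
    slice_index: int
    reader_index: int = 0


@dataclass
class FixturePlan:
    """Layout of a miniature scan fixture."""

    shape: tuple[int, int, int] = (64, 64, 3)   # (H, W, S)
    marks: list[PlantedMark] = field(default_factory=list)
    patient_id: str = "SYN-0001"
    pixel_spacing_mm: tuple[float, float] = (0.7, 0.7)
    slice_spacing_mm: float = 2.5
    noise_sd_hu: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w, s = self.shape
        for m in self.marks:
            if not (0 <= m.row < h and 0 <= m.col < w
                    and 0 <= m.slice_index < s):
                raise ValueError(f"planted mark {m} outside volume {self.shape}")
            if not 0 <= m.reader_index <= 3:
                raise ValueError("reader_index must be in 0..3")


def _uid(plan_seed: int, kind: int, index: int) -> str:
    return f"{_UID_ROOT}.{plan_seed % 100000}.{kind}.{index}"


def _background(rng: np.random.Generator, shape, noise_sd: float) -> np.ndarray:
    """Correlated texture: smoothed white noise, variance renormalised."""
    white = rng.normal(0.0, 1.0, size=shape)
    smooth = ndimage.gaussian_filter(white, sigma=1.5)
    smooth /= smooth.std() or 1.0
    return _BACKGROUND_HU + noise_sd * smooth


def _add_blob(img: np.ndarray, row: int, col: int, amplitude: float,
              sigma_px: float) -> None:
    h, w = img.shape
    rr, cc = np.ogrid[:h, :w]
    img += amplitude * np.exp(-((rr - row) ** 2 + (cc - col) ** 2)
                              / (2.0 * sigma_px ** 2))


def _add_ridge(img: np.ndarray, row: int, col: int, amplitude: float,
               angle: float, width_px: float) -> None:
    h, w = img.shape
    rr, cc = np.ogrid[:h, :w]
    # distance from the line through (row, col) at the given angle
    d = (cc - col) * np.sin(angle) - (rr - row) * np.cos(angle)
    img += amplitude * np.exp(-d ** 2 / (2.0 * width_px ** 2))


def generate_scan_fixture(plan: FixturePlan, out_dir) -> pd.DataFrame:
    """Write a DICOM slice series and LIDC-dialect XML for a plan.

    Micro-nodule marks become nodule elements with a single edge point,
    non-nodule marks become ``nonNodule`` elements with a ``locus``, and
    contoured nodules become multi-point edge maps.  Bright blobs are
    painted into the volume at every planted mark so extraction can be
    checked against image content.  Returns the planted-mark manifest.
    """
    out_dir = Path(out_dir)
    (out_dir / "dicom").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(plan.seed)
    h, w, s = plan.shape
    volume = np.stack(
        [_background(rng, (h, w), plan.noise_sd_hu) for _ in range(s)], axis=2
    )
    sigma_px = 1.5 / (2.355 * plan.pixel_spacing_mm[0])  # ~1.5 mm FWHM lesion
    for m in plan.marks:
        _add_blob(volume[:, :, m.slice_index], m.row, m.col,
                  amplitude=400.0, sigma_px=max(sigma_px, 0.8))

    series_uid = _uid(plan.seed, 1, 0)
    sop_uids = [_uid(plan.seed, 2, k) for k in range(s)]
    slice_z = [k * plan.slice_spacing_mm for k in range(s)]
    intercept, slope = -1024.0, 1.0
    for k in range(s):
        stored = np.clip(np.round(volume[:, :, k] - intercept), 0, 65535)
        ds = Dataset()
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = sop_uids[k]
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = _uid(plan.seed, 0, 0)
        ds.PatientID = plan.patient_id
        ds.Modality = "CT"
        ds.ImagePositionPatient = [0.0, 0.0, slice_z[k]]
        ds.PixelSpacing = [plan.pixel_spacing_mm[0], plan.pixel_spacing_mm[1]]
        ds.SliceThickness = plan.slice_spacing_mm
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        ds.Rows, ds.Columns = h, w
        ds.BitsAllocated, ds.BitsStored, ds.HighBit = 16, 16, 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = stored.astype(np.uint16).tobytes()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = sop_uids[k]
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        pydicom.dcmwrite(str(out_dir / "dicom" / f"slice_{k:03d}.dcm"), ds,
                         enforce_file_format=True)

    (out_dir / "xml").mkdir(exist_ok=True)
    xml = _fixture_xml(plan, sop_uids, slice_z, series_uid)
    (out_dir / "xml" / f"{plan.patient_id}.xml").write_text(xml)

    return pd.DataFrame(
        [{"patient_id": plan.patient_id, "category": m.category,
          "row": m.row, "col": m.col, "slice_index": m.slice_index,
          "reader_index": m.reader_index} for m in plan.marks]
    )


def _fixture_xml(plan: FixturePlan, sop_uids, slice_z, series_uid) -> str:
    n_sessions = max((m.reader_index for m in plan.marks), default=0) + 1
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<LidcReadMessage xmlns="http://www.nih.gov">',
        "  <ResponseHeader>",
        f"    <SeriesInstanceUid>{series_uid}</SeriesInstanceUid>",
        f"    <PatientID>{plan.patient_id}</PatientID>",
        "  </ResponseHeader>",
    ]
    counter = 0
    for session in range(n_sessions):
        lines.append("  <readingSession>")
        for m in plan.marks:
            if m.reader_index != session:
                continue
            counter += 1
            sop = sop_uids[m.slice_index]
            z = slice_z[m.slice_index]
            if m.category == "non_nodule":
                lines += [
                    "    <nonNodule>",
                    f"      <nonNoduleID>NN{counter:03d}</nonNoduleID>",
                    f"      <imageZposition>{z}</imageZposition>",
                    f"      <imageSOP_UID>{sop}</imageSOP_UID>",
                    "      <locus>",
                    f"        <xCoord>{m.col}</xCoord>",
                    f"        <yCoord>{m.row}</yCoord>",
                    "      </locus>",
                    "    </nonNodule>",
                ]
            elif m.category == "micro_nodule":
                lines += [
                    "    <unblindedReadNodule>",
                    f"      <noduleID>MN{counter:03d}</noduleID>",
                    "      <roi>",
                    f"        <imageZposition>{z}</imageZposition>",
                    f"        <imageSOP_UID>{sop}</imageSOP_UID>",
                    "        <inclusion>TRUE</inclusion>",
                    "        <edgeMap>",
                    f"          <xCoord>{m.col}</xCoord>",
                    f"          <yCoord>{m.row}</yCoord>",
                    "        </edgeMap>",
                    "      </roi>",
                    "    </unblindedReadNodule>",
                ]
            else:  # contoured >= 3 mm nodule: a small square outline
                pts = [(m.col - 2, m.row - 2), (m.col + 2, m.row - 2),
                       (m.col + 2, m.row + 2), (m.col - 2, m.row + 2)]
                edge = []
                for x, y in pts:
                    edge += [
                        "        <edgeMap>",
                        f"          <xCoord>{x}</xCoord>",
                        f"          <yCoord>{y}</yCoord>",
                        "        </edgeMap>",
                    ]
                lines += [
                    "    <unblindedReadNodule>",
                    f"      <noduleID>N{counter:03d}</noduleID>",
                    "      <roi>",
                    f"        <imageZposition>{z}</imageZposition>",
                    f"        <imageSOP_UID>{sop}</imageSOP_UID>",
                    "        <inclusion>TRUE</inclusion>",
                    *edge,
                    "      </roi>",
                    "    </unblindedReadNodule>",
                ]
        lines.append("  </readingSession>")
    lines.append("</LidcReadMessage>")
    return "\n".join(lines) + "\n"


@dataclass
class SyntheticPatchParams:
    """Conditions for a labeled synthetic patch dataset."""

    n_pos: int = 1000
    n_neg: int = 1000
    size: int = 32
    separation: float = 5.0     # lesion contrast in noise-sd units
    noise_sd: float = 60.0      # background texture sd, HU
    diameter_mm: tuple[float, float] = (1.0, 2.9)  # micro-nodule bound
    pixel_spacing_mm: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size not in (16, 32, 64):
            raise ValueError("size must be one of 16, 32, 64")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        if not (0 < self.diameter_mm[0] <= self.diameter_mm[1] < 3.0):
            raise ValueError("diameter range must lie within (0, 3) mm")


def generate_patch_dataset(
    params: SyntheticPatchParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled patches (X in [0,1], y in {0,1}), reproducible from seed.

    Label-1 patches: centred Gaussian blob, diameter drawn uniformly in
    ``diameter_mm`` (converted to pixels at ``pixel_spacing_mm``),
    amplitude ``separation * noise_sd`` HU.  Label-0 patches: with equal
    probability plain texture, or a vessel-like ridge of the same
    amplitude whose axis is offset from the patch centre.  Patches are
    normalised with the extraction module's lung window so they match
    pipeline output.
    """
    from .extraction import normalize_patch

    rng = np.random.default_rng(params.seed)
    n = params.n_pos + params.n_neg
    size = params.size
    amplitude = params.separation * params.noise_sd
    x = np.empty((n, size, size), dtype=np.float64)
    y = np.r_[np.ones(params.n_pos, dtype=int), np.zeros(params.n_neg, dtype=int)]
    # the extraction convention [c - s/2, c + s/2) places the mark at
    # index s//2, so plant the blob there
    center = float(size // 2)
    for i in range(n):
        img = _background(rng, (size, size), params.noise_sd)
        if y[i] == 1:
            d_mm = rng.uniform(*params.diameter_mm)
            sigma_px = (d_mm / params.pixel_spacing_mm) / 4.0  # d ~ 2 FWHM-ish
            _add_blob(img, center, center, amplitude, max(sigma_px, 0.5))
        elif rng.random() < 0.5:
            offset = rng.uniform(4.0, max(size / 2.0 - 2.0, 5.0))
            angle = rng.uniform(0.0, np.pi)
            prow = center + offset * np.cos(angle + np.pi / 2)
            pcol = center + offset * np.sin(angle + np.pi / 2)
            _add_ridge(img, prow, pcol, amplitude, angle,
                       width_px=rng.uniform(0.8, 1.5))
        x[i] = normalize_patch(img)
    perm = rng.permutation(n)
    return x[perm], y[perm]
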
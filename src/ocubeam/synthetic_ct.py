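"""Synthetic DICOM CT head series and its conversion to density/WER grids.

Generates a small head-like CT study — soft-tissue head ellipse, bony orbit
ring, a right-eye globe with lens, Gaussian HU noise — with the exact slice
geometry of the clinical series the pipeline emulates (10 slices, 512x512
pixels of 0.97x0.97 mm^2, 2 mm slice thickness), plus the 86x86-pixel
eye crop and a documented piecewise-linear HU-to-density calibration.  The
HU values and the calibration ramp are synthetic stand-ins for a real
patient scan; they exercise the identical code path at desk scale.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .eye import LabeledGrid

CT_ROOT_UID = "1.2.826.0.1.3680043.8.498."  # pydicom's example root


@dataclass(frozen=True)
class SyntheticHeadSpec:
    n_slices: int = 10
    matrix: int = 512
    pixel_spacing: float = 0.97  # mm
    slice_thickness: float = 2.0  # mm
    eye_center: tuple[int, int] = (200, 160)  # (row, col) of the right eye
    eye_radius_mm: float = 12.25
    seed: int = 0
    noise_sigma: float = 8.0  # HU
    hu_air: float = -1000.0
    hu_tissue: float = 40.0
    hu_bone: float = 700.0
    hu_globe: float = 15.0
    hu_lens: float = 80.0

    def __post_init__(self):
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("spacing and thickness must be positive")


def _head_slice(spec: SyntheticHeadSpec, k: int, rng) -> np.ndarray:
    n = spec.matrix
    r = np.arange(n)[:, None] - n / 2
    c = np.arange(n)[None, :] - n / 2
    img = np.full((n, n), spec.hu_air)
    # head ellipse (in pixels); the column half-axis is chosen so the face
    # surface sits just anterior of the globe (the eye is superficial)
    head = (r / 180.0) ** 2 + (c / 118.0) ** 2 <= 1.0
    img[head] = spec.hu_tissue
    # bony orbit: ring around the eye in the central slices
    er, ec = spec.eye_center
    rr = np.sqrt((np.arange(n)[:, None] - er) ** 2 + (np.arange(n)[None, :] - ec) ** 2)
    z_off = (k - (spec.n_slices - 1) / 2) * spec.slice_thickness
    eye_r_pix = spec.eye_radius_mm / spec.pixel_spacing
    if abs(z_off) < spec.eye_radius_mm:
        sl_r = eye_r_pix * np.sqrt(
            max(1.0 - (z_off / spec.eye_radius_mm) ** 2, 0.0)
        )
        orbit = (rr >= sl_r + 2) & (rr <= sl_r + 6) & head
        img[orbit] = spec.hu_bone
        globe = rr <= sl_r
        img[globe] = spec.hu_globe
        lens_r = 4.5 / spec.pixel_spacing
        if abs(z_off) < 4.5:
            lr = np.sqrt(
                (np.arange(n)[:, None] - er) ** 2
                + (np.arange(n)[None, :] - (ec - sl_r * 0.65)) ** 2
            )
            img[(lr <= lens_r) & globe] = spec.hu_lens
    img += rng.normal(0.0, spec.noise_sigma, img.shape)
    return np.clip(np.round(img), -1024, 3000).astype(np.int16)


def generate_head_ct(spec: SyntheticHeadSpec, out_dir) -> list[Path]:
    """Write the synthetic CT series; returns the slice file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    study_uid = generate_uid(CT_ROOT_UID, entropy_srcs=[f"study{spec.seed}"])
    series_uid = generate_uid(CT_ROOT_UID, entropy_srcs=[f"series{spec.seed}"])
    paths = []
    for k in range(spec.n_slices):
        arr = _head_slice(spec, k, rng)
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid(
            CT_ROOT_UID, entropy_srcs=[f"slice{spec.seed}_{k}"]
        )
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.PatientName = "Synthetic^Head"
        ds.PatientID = "SYN001"
        ds.ContentDate = datetime.date(2015, 1, 1).strftime("%Y%m%d")
        ds.Rows = ds.Columns = spec.matrix
        ds.PixelSpacing = [spec.pixel_spacing, spec.pixel_spacing]
        ds.SliceThickness = spec.slice_thickness
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [0.0, 0.0, k * spec.slice_thickness]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.RescaleIntercept = 0.0
        ds.RescaleSlope = 1.0
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = arr.tobytes()
        p = out / f"ct_{k:03d}.dcm"
        ds.save_as(p, enforce_file_format=True)
        paths.append(p)
    return paths


def read_series(directory) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a CT series back as (HU volume [row, col, slice], spacings)."""
    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no DICOM slices in {directory}")
    slices = [pydicom.dcmread(f) for f in files]
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    vol = np.stack(
        [
            s.pixel_array * float(s.RescaleSlope) + float(s.RescaleIntercept)
            for s in slices
        ],
        axis=-1,
    )
    s0 = slices[0]
    return vol, (
        float(s0.PixelSpacing[0]),
        float(s0.PixelSpacing[1]),
        float(s0.SliceThickness),
    )


@dataclass(frozen=True)
class CropWindow:
    size: int = 86
    offset: tuple[int, int] = (157, 117)  # (row, col) of the crop corner

    def __post_init__(self):
        if self.size <= 0:
            raise ValueError("crop size must be positive")


def default_crop(spec: SyntheticHeadSpec) -> CropWindow:
    """Crop window centered on the synthetic eye.

    The documented central index (43 of 0..85) maps to the eye center, i.e.
    the isocenter of the irradiation.
    """
    er, ec = spec.eye_center
    return CropWindow(86, (er - 43, ec - 43))


def crop_roi(volume: np.ndarray, window: CropWindow):
    """Crop the eye region of interest from the full-matrix volume."""
    r0, c0 = window.offset
    n = window.size
    if r0 < 0 or c0 < 0 or r0 + n > volume.shape[0] or c0 + n > volume.shape[1]:
        raise ValueError("crop window out of slice bounds")
    return volume[r0 : r0 + n, c0 : c0 + n, :]


# --- HU calibration ---------------------------------------------------------

#: Piecewise-linear HU->density ramp anchors (HU, g/cm^3): air and water are
#: universal calibration points; the bone segment has the standard reduced
#: slope.
HU_DENSITY_ANCHORS = ((-1000.0, 0.001), (0.0, 1.000), (100.0, 1.090), (3000.0, 2.64))


def hu_to_density_wer(hu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Convert an HU grid to density and WER grids.

    Monotone piecewise-linear ramp through the air and water anchors; WER is
    approximated by the density ratio for soft tissue and reduced for bone
    (WER/density ~ 0.95 above the soft-tissue segment).
    """
    hu = np.asarray(hu, float)
    if hu.min() < -1024 or hu.max() > 3000:
        import warnings

        warnings.warn("HU outside [-1024, 3000]; clamping", stacklevel=2)
        hu = np.clip(hu, -1024, 3000)
    xs = np.array([a[0] for a in HU_DENSITY_ANCHORS])
    ys = np.array([a[1] for a in HU_DENSITY_ANCHORS])
    density = np.interp(hu, xs, ys)
    wer = np.where(hu <= 100.0, density, density * 0.95)
    return density, wer


def ct_to_grid(
    hu_roi: np.ndarray,
    spacing: tuple[float, float, float],
    beam_axis: str = "col",
) -> LabeledGrid:
    """Build a LabeledGrid from a cropped HU volume.

    The beam travels along the chosen image axis ('col' by default: the
    anterior-posterior direction of the synthetic head); the grid's first
    index is depth along the beam.  The documented central crop index maps
    to x = 0 (the isocenter).
    """
    density, wer = hu_to_density_wer(hu_roi)
    if beam_axis == "col":
        density = np.transpose(density, (1, 0, 2))
        wer = np.transpose(wer, (1, 0, 2))
        vs = np.array([spacing[1], spacing[0], spacing[2]])
    else:
        vs = np.array(spacing, float)
    from .eye import LABELS

    labels = np.where(density > 0.3, LABELS["brain"], LABELS["air"]).astype(np.uint8)
    shape = np.array(density.shape)
    origin = -vs * 43.0 * np.array([1.0, 1.0, 0.0]) - np.array(
        [0.0, 0.0, vs[2] * (shape[2] - 1) / 2.0]
    )
    return LabeledGrid(vs, origin, labels, density, wer)
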
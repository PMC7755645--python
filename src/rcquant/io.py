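"""Reading, writing and resampling of CT sections and masks.

Supported formats: single-frame CT DICOM, NIfTI-1, and 16-bit PNG with a
JSON calibration sidecar ``{"slope", "intercept", "pixel_size_mm"}``.
Masks travel as NIfTI-1 (uint8) or 8-bit PNG.  Pixel spacing is mandatory
everywhere — quantification is area-based, so a file without spacing is a
hard error, not a warning.

Resampling conventions: HU images are interpolated linearly (no
anti-aliasing filter, which could push values across tissue thresholds);
masks use nearest-neighbor and stay strictly binary.  Physical extent is
preserved by rescaling ``pixel_size_mm`` with the inverse zoom.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from PIL import Image
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid
from skimage.transform import resize

from .types import HU_MIN, CTSection, PremorbidMask

# ---------------------------------------------------------------------------
# sections


def write_section_nifti(section: CTSection, path: str | Path) -> None:
    affine = np.diag([section.pixel_size_mm[1], section.pixel_size_mm[0], 1.0, 1.0])
    img = nib.Nifti1Image(
        np.round(section.pixels).astype(np.int16).T, affine
    )
    img.header.set_zooms((section.pixel_size_mm[1], section.pixel_size_mm[0]))
    nib.save(img, str(path))


def _read_section_nifti(path: Path) -> CTSection:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:2]
    if not all(z > 0 for z in zooms):
        raise ValueError(f"{path}: missing or invalid pixel spacing in NIfTI header")
    data = np.asanyarray(img.dataobj)
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a 2D section, got shape {data.shape}")
    return CTSection(
        data.T.astype(np.float64),
        (float(zooms[1]), float(zooms[0])),
        origin_id=str(path),
    )


def write_section_dicom(section: CTSection, path: str | Path) -> None:
    """Write a minimal single-frame CT DICOM with HU calibration."""
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.Rows, ds.Columns = section.shape
    ds.PixelSpacing = [str(section.pixel_size_mm[0]), str(section.pixel_size_mm[1])]
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0  # unsigned, shifted by the rescale intercept
    ds.RescaleSlope = "1"
    ds.RescaleIntercept = str(HU_MIN)
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    stored = np.round(section.pixels).astype(np.int32) - HU_MIN
    ds.PixelData = stored.astype(np.uint16).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def _read_section_dicom(path: Path) -> CTSection:
    ds = pydicom.dcmread(str(path))
    if "PixelSpacing" not in ds:
        raise ValueError(f"{path}: DICOM lacks PixelSpacing; quantification is area-based")
    if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
        raise ValueError(f"{path}: DICOM lacks rescale calibration to HU")
    hu = ds.pixel_array.astype(np.float64) * float(ds.RescaleSlope) + float(
        ds.RescaleIntercept
    )
    spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    return CTSection(hu, spacing, origin_id=str(path))


def write_section_png16(section: CTSection, path: str | Path) -> None:
    """16-bit grayscale PNG + JSON sidecar with HU calibration."""
    path = Path(path)
    stored = np.round(section.pixels).astype(np.int32) - HU_MIN
    Image.fromarray(stored.astype(np.uint16)).save(path)
    sidecar = {
        "slope": 1.0,
        "intercept": float(HU_MIN),
        "pixel_size_mm": list(section.pixel_size_mm),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def _read_section_png16(path: Path) -> CTSection:
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise ValueError(f"{path}: missing calibration sidecar {sidecar_path.name}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("slope", "intercept", "pixel_size_mm"):
        if key not in sidecar:
            raise ValueError(f"{sidecar_path}: sidecar lacks {key!r}")
    stored = np.asarray(Image.open(path), dtype=np.float64)
    hu = stored * sidecar["slope"] + sidecar["intercept"]
    return CTSection(hu, tuple(sidecar["pixel_size_mm"]), origin_id=str(path))


_READERS = {
    "nifti": _read_section_nifti,
    "dicom": _read_section_dicom,
    "png16": _read_section_png16,
}
_SUFFIX_FORMAT = {".nii": "nifti", ".gz": "nifti", ".dcm": "dicom", ".png": "png16"}


def read_section(path: str | Path, format: str | None = None) -> CTSection:
    """Read a CT section, calibrated to HU, with mandatory pixel spacing."""
    path = Path(path)
    if format is None:
        format = _SUFFIX_FORMAT.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")
    if format not in _READERS:
        raise ValueError(f"unknown format {format!r}; choose from {sorted(_READERS)}")
    return _READERS[format](path)


# ---------------------------------------------------------------------------
# masks


def write_mask(mask: PremorbidMask, path: str | Path,
               pixel_size_mm: tuple[float, float] = (1.0, 1.0)) -> None:
    path = Path(path)
    if path.suffix.lower() == ".png":
        Image.fromarray((mask.pixels * 255).astype(np.uint8)).save(path)
    else:
        affine = np.diag([pixel_size_mm[1], pixel_size_mm[0], 1.0, 1.0])
        nib.save(nib.Nifti1Image(mask.pixels.T, affine), str(path))


def read_mask(path: str | Path, muscle_label: str = "SS") -> PremorbidMask:
    path = Path(path)
    if path.suffix.lower() == ".png":
        arr = np.asarray(Image.open(path))
        return PremorbidMask((arr > 0).astype(np.uint8), muscle_label)
    data = np.asanyarray(nib.load(str(path)).dataobj)
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    return PremorbidMask((data.T > 0).astype(np.uint8), muscle_label)


# ---------------------------------------------------------------------------
# resampling


def resample_to_network(obj: CTSection | PremorbidMask, target_size: int,
                        pixel_size_mm: tuple[float, float] | None = None):
    """Resample a section (linear) or mask (nearest) to a square grid.

    ``pixel_size_mm`` only matters for masks written back to disk; a
    section carries and rescales its own spacing.
    """
    if target_size < 32:
        raise ValueError("target_size must be ≥ 32")
    if isinstance(obj, CTSection):
        h, w = obj.shape
        out = resize(obj.pixels, (target_size, target_size), order=1,
                     anti_aliasing=False, preserve_range=True)
        new_spacing = (
            obj.pixel_size_mm[0] * h / target_size,
            obj.pixel_size_mm[1] * w / target_size,
        )
        return CTSection(out, new_spacing, origin_id=obj.origin_id)
    if isinstance(obj, PremorbidMask):
        out = resize(obj.pixels.astype(bool), (target_size, target_size),
                     order=0, anti_aliasing=False, preserve_range=True)
        return PremorbidMask(out.astype(np.uint8), obj.muscle_label)
    raise TypeError(f"cannot resample {type(obj).__name__}")


def upscale_mask(mask: PremorbidMask, original_size: int) -> PremorbidMask:
    """Nearest-neighbor upscale of a network-resolution mask.

    Refuses to downscale (use :func:`resample_to_network` for that); the
    mask stays binary and its area scales with the square of the zoom.
    """
    h, w = mask.shape
    if original_size < max(h, w):
        raise ValueError(
            f"upscale_mask target {original_size} smaller than mask {mask.shape}; "
            "use resample_to_network to downscale"
        )
    if original_size == h == w:
        return PremorbidMask(mask.pixels.copy(), mask.muscle_label)
    out = resize(mask.pixels.astype(bool), (original_size, original_size),
                 order=0, anti_aliasing=False, preserve_range=True)
    return PremorbidMask(out.astype(np.uint8), mask.muscle_label)


# ---------------------------------------------------------------------------
# phantom case export


def write_phantom_case(case, out_dir: str | Path) -> None:
    """Write a phantom case: NIfTI image + per-muscle/rater masks + JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cid = case.case_id
    write_section_nifti(case.section, out_dir / f"{cid}_image.nii.gz")
    spacing = case.section.pixel_size_mm
    for mask in case.premorbid_masks:
        write_mask(mask, out_dir / f"{cid}_{mask.muscle_label}_truth.nii.gz", spacing)
    for r, masks in enumerate(case.rater_masks):
        for mask in masks:
            write_mask(
                mask, out_dir / f"{cid}_{mask.muscle_label}_rater{r}.nii.gz", spacing
            )
    manifest = {
        "case_id": cid,
        "spec": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(case.spec).items()
        },
        "n_raters": case.n_raters,
        "true_measures": [m.as_dict() for m in case.true_measures],
    }
    (out_dir / f"{cid}_manifest.json").write_text(json.dumps(manifest, indent=2))
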
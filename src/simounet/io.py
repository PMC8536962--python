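"""Volume I/O: NIfTI (canonical) and per-slice PNG + JSON sidecars.

Conventions: in-memory stacks are (slice, row, column); NIfTI files
store (row, column, slice) with a diagonal affine encoding (dx, dy, dz)
in mm.  Masks live in a sibling ``*_mask`` file as unsigned 8-bit
{0, 1}; images are 32-bit float in NIfTI and scaled 16-bit in PNG (the
sidecar records the scaling, so PNG round-trips are exact to the
16-bit quantisation step).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .phantom import VolumeStack

__all__ = ["read_volume", "write_volume", "write_overlay_png"]


def _nifti_paths(path: Path):
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            stem = name[: -len(suffix)]
            return path, path.with_name(f"{stem}_mask{suffix}")
    raise ValueError(f"not a NIfTI path: {path}")


def write_volume(stack: VolumeStack, path) -> Path:
    """Write a VolumeStack to ``path``.

    A ``.nii``/``.nii.gz`` path produces one volume file plus a
    ``*_mask`` file when a mask is present; any other path is treated
    as a directory of per-slice 16-bit PNGs with JSON sidecars.
    """
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        return _write_nifti(stack, path)
    return _write_png_dir(stack, path)


def read_volume(path, subject_id=None) -> VolumeStack:
    """Read a volume (and mask, if present) written by write_volume."""
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        return _read_nifti(path, subject_id)
    if path.is_dir():
        return _read_png_dir(path, subject_id)
    raise FileNotFoundError(f"no volume at {path}")


# -- NIfTI ---------------------------------------------------------------


def _write_nifti(stack: VolumeStack, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    vol_path, mask_path = _nifti_paths(path)
    dx, dy = stack.pixel_spacing_mm
    affine = np.diag([dx, dy, stack.slice_thickness_mm, 1.0])
    data = stack.slices.transpose(1, 2, 0).astype(np.float32)
    nib.save(nib.Nifti1Image(data, affine), str(vol_path))
    if stack.mask is not None:
        mdata = stack.mask.transpose(1, 2, 0).astype(np.uint8)
        nib.save(nib.Nifti1Image(mdata, affine), str(mask_path))
    return vol_path


def _read_nifti(path: Path, subject_id=None) -> VolumeStack:
    vol_path, mask_path = _nifti_paths(path)
    img = nib.load(str(vol_path))
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(
            f"{vol_path}: non-positive voxel spacing in header; "
            "provide explicit spacing via a rewritten affine"
        )
    data = np.asarray(img.dataobj, dtype=np.float32).transpose(2, 0, 1)
    mask = None
    if mask_path.exists():
        mask = np.asarray(nib.load(str(mask_path)).dataobj).transpose(2, 0, 1)
        mask = np.rint(mask).astype(np.uint8)
    if subject_id is None:
        subject_id = vol_path.name.split(".")[0]
    return VolumeStack(
        slices=data,
        mask=mask,
        pixel_spacing_mm=(float(zooms[0]), float(zooms[1])),
        slice_thickness_mm=float(zooms[2]),
        subject_id=subject_id,
    )


# -- PNG + JSON sidecar --------------------------------------------------


def _write_png_dir(stack: VolumeStack, out_dir: Path) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    vmin = float(stack.slices.min())
    vmax = float(stack.slices.max())
    span = (vmax - vmin) or 1.0
    dx, dy = stack.pixel_spacing_mm
    for s in range(stack.n_slices):
        stem = f"{stack.subject_id}_{s:04d}"
        q = np.round((stack.slices[s] - vmin) / span * 65535.0).astype(np.uint16)
        iio.imwrite(out_dir / f"{stem}.png", q)
        sidecar = {
            "subject_id": stack.subject_id,
            "slice_index": s,
            "dx": dx,
            "dy": dy,
            "dz": stack.slice_thickness_mm,
            "vmin": vmin,
            "vmax": vmax,
        }
        (out_dir / f"{stem}.json").write_text(json.dumps(sidecar))
        if stack.mask is not None:
            iio.imwrite(out_dir / f"{stem}_mask.png", stack.mask[s].astype(np.uint8))
    return out_dir


def _read_png_dir(in_dir: Path, subject_id=None) -> VolumeStack:
    sidecars = sorted(in_dir.glob("*.json"))
    if not sidecars:
        raise ValueError(
            f"{in_dir}: no JSON sidecars found; geometry (dx, dy, dz) must be "
            "recorded per slice"
        )
    records = []
    for sc_path in sidecars:
        sc = json.loads(sc_path.read_text())
        if subject_id is not None and sc["subject_id"] != subject_id:
            continue
        records.append((sc["slice_index"], sc_path, sc))
    records.sort(key=lambda r: r[0])
    slices, masks = [], []
    sc0 = records[0][2]
    for _, sc_path, sc in records:
        stem = sc_path.with_suffix("")
        q = iio.imread(stem.with_suffix(".png")).astype(np.float32)
        span = (sc["vmax"] - sc["vmin"]) or 1.0
        slices.append(q / 65535.0 * span + sc["vmin"])
        mask_path = stem.parent / (stem.name + "_mask.png")
        if mask_path.exists():
            masks.append(np.rint(iio.imread(mask_path)).astype(np.uint8))
    return VolumeStack(
        slices=np.stack(slices),
        mask=np.stack(masks) if masks else None,
        pixel_spacing_mm=(sc0["dx"], sc0["dy"]),
        slice_thickness_mm=sc0["dz"],
        subject_id=sc0["subject_id"],
    )


# -- diagnostic overlays -------------------------------------------------


def write_overlay_png(image, pred_mask, truth_mask, path):
    """Static RGB overlay of a segmentation result on one slice:
    TP cyan, FP red, FN yellow, TN left as the grayscale image."""
    image = np.asarray(image, dtype=np.float32)
    lo, hi = float(image.min()), float(image.max())
    gray = np.round((image - lo) / ((hi - lo) or 1.0) * 255.0).astype(np.uint8)
    rgb = np.stack([gray, gray, gray], axis=-1)
    pred = np.asarray(pred_mask).astype(bool)
    truth = np.asarray(truth_mask).astype(bool)
    rgb[pred & truth] = (0, 255, 255)     # TP
    rgb[pred & ~truth] = (255, 0, 0)      # FP
    rgb[~pred & truth] = (255, 255, 0)    # FN
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, rgb)
    return path
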
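"""Dataset readers and writers.

Two on-disk layouts are supported, matching common dementia-MRI releases:

* 2D: one folder per class of PNG/JPEG images.  Images are decoded to a
  single channel (RGB via luminance), resampled bilinearly to the target
  size, and rescaled linearly from [0, 255] to [-1, 1].  Class indices
  follow the lexicographic order of the folder names.
* 3D: a CSV manifest with columns ``path,label`` pointing at NIfTI volumes.
  Volumes are resampled trilinearly to the target size and robustly rescaled
  (1st-99th intensity percentile) to [-1, 1], then clamped; volumes with a
  degenerate intensity range map to all zeros, and volumes already lying in
  [-1, 1] are taken as pre-normalized and left untouched (which makes the
  write/read round trip exact).  Orientation is taken as stored.

Item order is deterministic (sorted paths / manifest order) so repeated
loads are identical.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .trainer import LabeledDataset

__all__ = [
    "load_image_folder",
    "load_nifti_dataset",
    "write_image_folder",
    "write_nifti_dataset",
]

_IMAGE_EXTS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


def load_image_folder(
    root, target_size: tuple[int, int] = (128, 128), skip_bad: bool = False
) -> LabeledDataset:
    """Read a one-folder-per-class 2D image dataset."""
    root = Path(root)
    if not root.is_dir():
        raise ValueError(f"not a directory: {root}")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subfolders under {root}")
    class_names = [d.name for d in class_dirs]
    images, labels = [], []
    for ci, d in enumerate(class_dirs):
        files = sorted(p for p in d.iterdir() if p.suffix.lower() in _IMAGE_EXTS)
        for p in files:
            try:
                with Image.open(p) as im:
                    im = im.convert("L")
                    im = im.resize(target_size[::-1], Image.BILINEAR)
                arr = np.asarray(im, dtype=float) / 127.5 - 1.0
            except Exception as exc:
                if skip_bad:
                    continue
                raise ValueError(f"cannot decode image {p}: {exc}") from exc
            images.append(arr)
            labels.append(ci)
    if not images:
        raise ValueError(f"no decodable images under {root}")
    return LabeledDataset(np.stack(images), np.asarray(labels), class_names)


def load_nifti_dataset(
    manifest_path, target_size: tuple[int, int, int] = (32, 32, 32)
) -> LabeledDataset:
    """Read a CSV-manifest 3D NIfTI dataset (columns: path, label)."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    for col in ("path", "label"):
        if col not in df.columns:
            raise ValueError(f"manifest {manifest_path} lacks required column {col!r}")
    if df.empty:
        raise ValueError(f"empty manifest {manifest_path}")
    class_names = sorted(df["label"].astype(str).unique())
    label_index = {name: i for i, name in enumerate(class_names)}
    images, labels = [], []
    for row_i, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = manifest_path.parent / p
        try:
            vol = np.asarray(nib.load(str(p)).get_fdata(), dtype=float)
        except Exception as exc:
            raise ValueError(f"manifest row {row_i}: cannot read {p}: {exc}") from exc
        vol = np.squeeze(vol)
        if vol.ndim != 3:
            raise ValueError(f"manifest row {row_i}: {p} is not a 3D volume (shape {vol.shape})")
        factors = [t / s for t, s in zip(target_size, vol.shape)]
        if any(f != 1 for f in factors):
            vol = ndimage.zoom(vol, factors, order=1)
        if vol.min() >= -1.0 - 1e-6 and vol.max() <= 1.0 + 1e-6:
            pass  # already in the network's input range: taken as pre-normalized
        else:
            lo, hi = np.percentile(vol, [1.0, 99.0])
            if hi - lo < 1e-12:
                vol = np.zeros_like(vol)
            else:
                vol = np.clip(2.0 * (vol - lo) / (hi - lo) - 1.0, -1.0, 1.0)
        images.append(vol)
        labels.append(label_index[str(row["label"])])
    return LabeledDataset(np.stack(images), np.asarray(labels), class_names)


def write_image_folder(ds: LabeledDataset, out_dir) -> Path:
    """Write a 2D dataset as 8-bit PNGs in one folder per class."""
    out_dir = Path(out_dir)
    if ds.images.ndim != 3:
        raise ValueError("write_image_folder requires 2D images")
    for name in ds.class_names:
        (out_dir / name).mkdir(parents=True, exist_ok=True)
    counters = {name: 0 for name in ds.class_names}
    for img, label in zip(ds.images, ds.labels):
        name = ds.class_names[label]
        arr = np.clip(np.round((img + 1.0) * 127.5), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(
            out_dir / name / f"{name}_{counters[name]:05d}.png"
        )
        counters[name] += 1
    return out_dir


def write_nifti_dataset(ds: LabeledDataset, out_dir) -> Path:
    """Write a 3D dataset as float32 NIfTI volumes plus a CSV manifest."""
    out_dir = Path(out_dir)
    if ds.images.ndim != 4:
        raise ValueError("write_nifti_dataset requires 3D volumes")
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (vol, label) in enumerate(zip(ds.images, ds.labels)):
        name = ds.class_names[label]
        fname = f"vol_{i:05d}.nii"
        nib.save(
            nib.Nifti1Image(vol.astype(np.float32), affine=np.eye(4)),
            str(out_dir / fname),
        )
        rows.append({"path": fname, "label": name})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
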
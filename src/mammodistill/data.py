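"""Dataset records, manifest I/O, preprocessing and the train/val/test split.

A dataset is a flat directory of single-channel PNG tiles plus a
``manifest.csv`` with columns ``id, image_path, mask_path, label, split``.
Weakly-annotated records carry a pathology label but no mask (empty
``mask_path``); fully-annotated records carry both.  Images are stored as
8-bit grayscale and mapped to [0, 1] on load; masks are thresholded at 127
to exact {0, 1}.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from PIL import Image

MANIFEST_COLUMNS = ["id", "image_path", "mask_path", "label", "split"]
LABELS = ("benign", "malignant")


class ManifestError(ValueError):
    """Raised for malformed manifests or inconsistent records."""


@dataclass
class SampleRecord:
    """One tile: image, optional binary mask, optional pathology label."""

    id: str
    image: np.ndarray | None = None
    mask: np.ndarray | None = None
    label: str | None = None
    split: str | None = None
    image_path: str | None = None
    mask_path: str | None = None

    def __post_init__(self):
        if self.label is not None and self.label not in LABELS:
            raise ManifestError(f"record {self.id}: unknown label {self.label!r}")
        if self.image is not None and self.mask is not None \
                and self.image.shape != self.mask.shape:
            raise ManifestError(
                f"record {self.id}: image {self.image.shape} and mask "
                f"{self.mask.shape} differ in size")

    @property
    def label_index(self) -> int:
        """0 = benign, 1 = malignant (the positive class)."""
        if self.label is None:
            raise ValueError(f"record {self.id} has no label")
        return LABELS.index(self.label)

    def materialize(self) -> "SampleRecord":
        """Load pixel data from disk if this record is path-backed."""
        image, mask = self.image, self.mask
        if image is None and self.image_path:
            image = load_png(self.image_path)
        if mask is None and self.mask_path:
            mask = load_png(self.mask_path, as_mask=True)
        rec = replace(self, image=image, mask=mask)
        return rec


@dataclass
class DatasetManifest:
    """All records of a dataset plus the split policy."""

    records: list[SampleRecord]
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ManifestError(
                f"split fractions must sum to 1, got {self.split_fractions}")

    def subset(self, split: str) -> list[SampleRecord]:
        return [r for r in self.records if r.split == split]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"id": r.id,
              "image_path": r.image_path or "",
              "mask_path": r.mask_path or "",
              "label": r.label or "",
              "split": r.split or ""} for r in self.records],
            columns=MANIFEST_COLUMNS)


def load_png(path: str, as_mask: bool = False) -> np.ndarray:
    """Read a single-channel PNG into [0,1] floats, or a {0,1} mask."""
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:
        arr = arr[..., 0]
    if as_mask:
        return (arr > 127).astype(np.uint8)
    scale = 65535.0 if arr.dtype == np.uint16 else 255.0
    return (arr.astype(np.float32) / scale).clip(0.0, 1.0)


def save_png(path: str, arr: np.ndarray, is_mask: bool = False) -> None:
    if is_mask:
        data = (np.asarray(arr) > 0).astype(np.uint8) * 255
    else:
        data = np.round(np.clip(arr, 0.0, 1.0) * 255.0).astype(np.uint8)
    Image.fromarray(data, mode="L").save(path)


def write_dataset(records: list[SampleRecord], out_dir: str,
                  split_fractions=(0.8, 0.1, 0.1), seed: int = 0) -> str:
    """Write image/mask PNGs plus manifest.csv; returns the manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for rec in records:
        image_path = os.path.join(out_dir, f"{rec.id}_img.png")
        save_png(image_path, rec.image)
        mask_path = ""
        if rec.mask is not None:
            mask_path = os.path.join(out_dir, f"{rec.id}_mask.png")
            save_png(mask_path, rec.mask, is_mask=True)
        rows.append({"id": rec.id, "image_path": image_path,
                     "mask_path": mask_path, "label": rec.label or "",
                     "split": rec.split or ""})
    path = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)
    return path


def load_manifest(path: str, split_fractions=(0.8, 0.1, 0.1),
                  seed: int = 0) -> DatasetManifest:
    """Parse a manifest CSV into path-backed (lazy) records.

    Image/mask dimensions are cross-checked from the PNG headers; labels
    parse case-insensitively.  Errors cite the offending row or record id.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ManifestError(f"manifest missing columns: {sorted(missing)}")
    base = os.path.dirname(os.path.abspath(path))

    def _resolve(p: str) -> str:
        return p if os.path.isabs(p) else os.path.join(base, p)

    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            label = row.label.strip().lower() or None
            rec = SampleRecord(
                id=row.id,
                label=label,
                split=row.split.strip() or None,
                image_path=_resolve(row.image_path),
                mask_path=_resolve(row.mask_path) if row.mask_path else None,
            )
        except ManifestError as exc:
            raise ManifestError(f"manifest row {i + 2}: {exc}") from exc
        if not os.path.exists(rec.image_path):
            raise ManifestError(f"manifest row {i + 2}: missing image {rec.image_path}")
        if rec.mask_path:
            with Image.open(rec.image_path) as im:
                img_size = im.size
            with Image.open(rec.mask_path) as im:
                mask_size = im.size
            if img_size != mask_size:
                raise ManifestError(
                    f"record {rec.id}: image size {img_size} does not match "
                    f"mask size {mask_size}")
        records.append(rec)
    return DatasetManifest(records=records, split_fractions=tuple(split_fractions),
                           seed=seed)


# ---------------------------------------------------------------------------
# Preprocessing


def preprocess(image: np.ndarray, target_size: int) -> np.ndarray:
    """Crop to the tissue region, pad if needed, and min-max normalize.

    The crop window is centered on the centroid of the largest
    above-Otsu-threshold connected component (the breast region in a
    mammographic tile), clipped so the window stays inside the image.
    Degenerate tiles (constant intensity) come back as zeros with a
    warning.  Flip augmentation is *not* applied here; it is a
    training-time option only (see :func:`random_flip`).
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label as cc_label, regionprops

    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("preprocess expects a single-channel 2-D tile")
    if np.any(img < 0):
        raise ValueError("preprocess expects nonnegative intensities")

    h, w = img.shape
    if h < target_size or w < target_size:
        padded = np.zeros((max(h, target_size), max(w, target_size)))
        padded[:h, :w] = img
        img = padded
        h, w = img.shape

    if img.max() == img.min():
        warnings.warn("degenerate intensity range; returning zero tile")
        return np.zeros((target_size, target_size), dtype=np.float32)

    thr = threshold_otsu(img)
    fg = img > thr
    if fg.any():
        lbl = cc_label(fg)
        largest = max(regionprops(lbl), key=lambda r: r.area)
        cy, cx = largest.centroid
    else:
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0

    half = target_size // 2
    top = int(round(cy)) - half
    left = int(round(cx)) - half
    top = min(max(top, 0), h - target_size)
    left = min(max(left, 0), w - target_size)
    crop = img[top:top + target_size, left:left + target_size]

    lo, hi = crop.min(), crop.max()
    if hi == lo:
        warnings.warn("degenerate intensity range in crop; returning zero tile")
        return np.zeros((target_size, target_size), dtype=np.float32)
    return ((crop - lo) / (hi - lo)).astype(np.float32)


def random_flip(image: np.ndarray, mask: np.ndarray | None,
                rng: np.random.Generator, p: float = 0.5):
    """Training-time horizontal flip applied identically to image and mask."""
    if rng.random() < p:
        image = image[:, ::-1].copy()
        mask = mask[:, ::-1].copy() if mask is not None else None
    return image, mask


# ---------------------------------------------------------------------------
# Splitting


def split(manifest: DatasetManifest) -> DatasetManifest:
    """Assign every record to train/val/test by seeded uniform permutation.

    Counts are floor-allocated for val and test with the remainder going
    to train.
    """
    n = len(manifest.records)
    if n < 3:
        raise ManifestError(f"need at least 3 records to populate all splits, got {n}")
    f_train, f_val, f_test = manifest.split_fractions
    n_val = int(np.floor(f_val * n))
    n_test = int(np.floor(f_test * n))
    n_train = n - n_val - n_test
    rng = np.random.default_rng(manifest.seed)
    order = rng.permutation(n)
    tags = np.empty(n, dtype=object)
    tags[order[:n_train]] = "train"
    tags[order[n_train:n_train + n_val]] = "val"
    tags[order[n_train + n_val:]] = "test"
    records = [replace(r, split=t) for r, t in zip(manifest.records, tags)]
    return DatasetManifest(records=records,
                           split_fractions=manifest.split_fractions,
                           seed=manifest.seed)


def dicom_to_png(dicom_path: str, png_path: str) -> None:
    """Convert one DICOM tile's pixel array to an 8-bit grayscale PNG.

    Thin utility for users holding the original mammography DICOMs; only
    pixel data is used, no metadata parsing.
    """
    import pydicom

    ds = pydicom.dcmread(dicom_path)
    arr = ds.pixel_array.astype(np.float64)
    lo, hi = arr.min(), arr.max()
    norm = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    save_png(png_path, norm)
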
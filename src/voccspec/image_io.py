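"""ROI extraction, z-score normalization, and 3-slice stack assembly.

A subject contributes three consecutive tumor slices per MRI contrast, each
paired with a binary tumor mask.  The tumor is cut out at the mask's tight
bounding box, background is zeroed, foreground intensities are z-scored over
the mask, and the three crops are zero-padded (centered) to a common shape so
that downstream lag analysis sees compatible dimensions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GliomaStack",
    "apply_mask_and_crop",
    "zscore_normalize",
    "assemble_stack",
    "read_slice_image",
    "read_mask_image",
    "load_nifti_stack",
    "read_manifest",
    "load_subject",
    "load_cohort",
    "save_stack",
    "load_stack",
]

LABELS = ("co-deleted", "non-deleted")
CONTRASTS = ("T1C", "T2W")
GRADES = ("G-II", "G-III")


@dataclass
class GliomaStack:
    """One subject's 3 masked, cropped, z-scored ROI slices for one contrast.

    ``slices`` has shape (3, M, N); ``masks`` is the matching padded boolean
    foreground (background pixels of ``slices`` are exactly 0).
    """

    slices: np.ndarray
    masks: np.ndarray
    label: str
    contrast: str
    subject_id: str
    grade: str = "G-II"

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=float)
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.slices.ndim != 3 or self.slices.shape[0] != 3:
            raise ValueError("a stack holds exactly 3 slices of one common shape")
        if self.masks.shape != self.slices.shape:
            raise ValueError("mask stack shape must match slice stack shape")
        if not np.all(np.isfinite(self.slices)):
            raise ValueError("slice intensities must be finite")
        if np.any(self.slices[~self.masks] != 0):
            raise ValueError("background pixels must be exactly 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices.shape[1:]


def _as_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] < 1 or image.shape[1] < 1:
        raise ValueError("image must be a non-empty 2D array")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    return image


def _as_mask(mask: np.ndarray, image: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.shape != image.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {image.shape}"
        )
    return mask != 0  # non-strict: any nonzero pixel is foreground


def apply_mask_and_crop(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Restrict ``image`` to the mask's tight bounding box, zeroing background.

    Foreground pixels are preserved; everything outside the mask is 0 in the
    returned crop.  Raises ``ValueError`` on an empty mask ("empty ROI") or a
    shape mismatch.
    """
    image = _as_image(image)
    mask = _as_mask(mask, image)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("empty ROI: mask has no foreground pixels")
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    return np.where(mask[r0:r1, c0:c1], image[r0:r1, c0:c1], 0.0)


def zscore_normalize(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    population: bool = True,
) -> np.ndarray:
    """Z-score the foreground: (X - mu) / sigma over mask pixels only.

    mu and sigma are computed over foreground pixels, not the full rectangle
    (background zeros would otherwise dominate the statistics).  ``sigma`` is
    the population standard deviation by default (``population=False`` gives
    the n-1 sample version).  Background pixels remain exactly 0.
    """
    image = _as_image(image)
    if mask is None:
        fg = image != 0
    else:
        fg = _as_mask(mask, image)
    vals = image[fg]
    if vals.size < 2:
        raise ValueError("need at least 2 foreground pixels to normalize")
    mu = vals.mean()
    sigma = vals.std(ddof=0 if population else 1)
    if sigma == 0:
        raise ValueError("degenerate intensity: constant ROI has zero spread")
    out = np.zeros_like(image)
    out[fg] = (vals - mu) / sigma
    return out


def _pad_centered(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Zero-pad ``image`` to ``shape``, centering the original content."""
    m, n = image.shape
    pm, pn = shape[0] - m, shape[1] - n
    return np.pad(image, ((pm // 2, pm - pm // 2), (pn // 2, pn - pn // 2)))


def assemble_stack(
    slices: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    label: str,
    contrast: str,
    subject_id: str,
    grade: str = "G-II",
    population: bool = True,
) -> GliomaStack:
    """Mask, crop, and z-score 3 slices, then pad to a common M x N.

    Each slice is processed independently; the three crops are zero-padded
    (centered) to the maximum bounding-box height and width across the stack.
    Per-slice errors are re-raised with the offending slice index.
    """
    if len(slices) != 3 or len(masks) != 3:
        raise ValueError(f"expected exactly 3 slice/mask pairs, got {len(slices)}")
    crops, mask_crops = [], []
    for idx, (img, msk) in enumerate(zip(slices, masks)):
        try:
            img = _as_image(img)
            fg = _as_mask(msk, img)
            crops.append(zscore_normalize(apply_mask_and_crop(img, fg),
                                          apply_mask_and_crop(fg.astype(float), fg),
                                          population=population))
            mask_crops.append(apply_mask_and_crop(fg.astype(float), fg) != 0)
        except ValueError as err:
            raise ValueError(f"slice {idx}: {err}") from err
    target = (max(c.shape[0] for c in crops), max(c.shape[1] for c in crops))
    padded = np.stack([_pad_centered(c, target) for c in crops])
    padded_masks = np.stack([_pad_centered(m.astype(float), target) != 0 for m in mask_crops])
    return GliomaStack(padded, padded_masks, label, contrast, subject_id, grade)


# ---------------------------------------------------------------------------
# Readers / writers


def read_slice_image(path: str | os.PathLike) -> np.ndarray:
    """Read a grayscale slice raster (PNG, 16-bit recommended) as float."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse accidental RGB
        arr = arr[..., 0]
    return arr.astype(float)


def read_mask_image(path: str | os.PathLike) -> np.ndarray:
    """Read a binary mask raster; any nonzero pixel counts as foreground."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr != 0).astype(np.uint8)


def load_nifti_stack(
    volume_path: str | os.PathLike,
    mask_path: str | os.PathLike,
    slice_indices: Sequence[int],
    axis: int = 2,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Pull 3 slices + masks out of a NIfTI volume/mask pair along ``axis``."""
    import nibabel as nib

    if len(slice_indices) != 3:
        raise ValueError("exactly 3 slice indices are required")
    vol = np.asanyarray(nib.load(os.fspath(volume_path)).dataobj).astype(float)
    msk = np.asanyarray(nib.load(os.fspath(mask_path)).dataobj)
    slices = [np.take(vol, i, axis=axis) for i in slice_indices]
    masks = [(np.take(msk, i, axis=axis) != 0).astype(np.uint8) for i in slice_indices]
    return slices, masks


MANIFEST_COLUMNS = [
    "subject_id", "grade", "contrast", "label",
    "slice1", "slice2", "slice3", "mask1", "mask2", "mask3",
]


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read a cohort manifest CSV (one row per subject per contrast)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    return df


def load_subject(row: pd.Series, root: str | os.PathLike = ".") -> GliomaStack:
    """Assemble one subject-contrast stack from a manifest row."""
    slices = [read_slice_image(os.path.join(root, row[f"slice{i}"])) for i in (1, 2, 3)]
    masks = [read_mask_image(os.path.join(root, row[f"mask{i}"])) for i in (1, 2, 3)]
    return assemble_stack(
        slices, masks,
        label=row["label"], contrast=row["contrast"],
        subject_id=str(row["subject_id"]), grade=row["grade"],
    )


def load_cohort(
    manifest_path: str | os.PathLike,
    contrast: str | None = None,
) -> list[GliomaStack]:
    """Load every subject stack listed in a manifest, optionally one contrast."""
    df = read_manifest(manifest_path)
    if contrast is not None:
        df = df[df["contrast"] == contrast]
    root = os.path.dirname(os.fspath(manifest_path))
    return [load_subject(row, root) for _, row in df.iterrows()]


def save_stack(stack: GliomaStack, path: str | os.PathLike) -> None:
    """Serialize a normalized stack to a compressed .npz archive."""
    np.savez_compressed(
        path,
        slices=stack.slices,
        masks=stack.masks.astype(np.uint8),
        label=stack.label,
        contrast=stack.contrast,
        subject_id=stack.subject_id,
        grade=stack.grade,
    )


def load_stack(path: str | os.PathLike) -> GliomaStack:
    with np.load(path, allow_pickle=False) as z:
        return GliomaStack(
            z["slices"], z["masks"] != 0,
            label=str(z["label"]), contrast=str(z["contrast"]),
            subject_id=str(z["subject_id"]), grade=str(z["grade"]),
        )
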
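"""Manifest/image loading and ROI normalization.

The matcher operates on a fixed analysis grid: every Region of Interest
is cropped from its source image, converted to grayscale, resampled to a
common size (64x64 by default) and photometrically normalized to zero
mean and unit variance.  The normalization makes the downstream
sign-binarized code invariant to the brightness/contrast drift the
capture model deliberately injects.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize

from .errors import DegenerateInputError, ManifestError, ValidationError
from .synthetic import MANIFEST_COLUMNS

DEFAULT_GRID = (64, 64)


@dataclass(frozen=True)
class CaptureImage:
    """One acquired (or synthesized) nose image with its ROI geometry.

    ``roi_rect`` is (x, y, w, h) in pixels, 0-based, origin top-left,
    half-open: the crop is columns [x, x+w) and rows [y, y+h).
    """

    subject_id: str
    capture_index: int
    pixels: np.ndarray  # 2-D float in [0, 1]
    roi_rect: tuple[int, int, int, int]


@dataclass(frozen=True)
class ROIImage:
    """A normalized ROI on the analysis grid (zero mean, unit variance).

    ``norm_mean``/``norm_std`` record the affine map removed at
    normalization time, so the original intensities remain recoverable.
    """

    subject_id: str
    capture_index: int
    pixels: np.ndarray
    norm_mean: float
    norm_std: float


def _to_gray_unit(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3:  # unweighted channel mean; the method is grayscale-agnostic
        arr = arr.mean(axis=2)
    return np.clip(arr, 0.0, 1.0)


def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG/TIFF as a 2-D float array in [0, 1]."""
    with Image.open(path) as im:
        return _to_gray_unit(np.asarray(im))


def load_manifest(path: str | Path) -> list[CaptureImage]:
    """Read a dataset manifest CSV and load every referenced image.

    Row order is preserved; group by subject with :func:`group_by_subject`.
    Raises :class:`ManifestError` for a missing file (naming the row) and
    :class:`ValidationError` for an ROI outside the image bounds.
    """
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ManifestError(f"manifest {path} lacks columns: {sorted(missing)}")
    base = path.parent
    entries: list[CaptureImage] = []
    for i, row in enumerate(df.itertuples(index=False)):
        img_path = base / str(row.path)
        if not img_path.exists():
            raise ManifestError(f"row {i} ({row.subject_id}): image file missing: {img_path}")
        pixels = load_image(img_path)
        rect = (int(row.roi_x), int(row.roi_y), int(row.roi_w), int(row.roi_h))
        x, y, w, h = rect
        ih, iw = pixels.shape
        if w <= 0 or h <= 0 or x < 0 or y < 0 or x + w > iw or y + h > ih:
            raise ValidationError(
                f"row {i} ({row.subject_id}): ROI {rect} outside image bounds {iw}x{ih}"
            )
        entries.append(
            CaptureImage(
                subject_id=str(row.subject_id),
                capture_index=int(row.capture_index),
                pixels=pixels,
                roi_rect=rect,
            )
        )
    return entries


def group_by_subject(entries: list[CaptureImage]) -> dict[str, list[CaptureImage]]:
    groups: dict[str, list[CaptureImage]] = {}
    for e in entries:
        groups.setdefault(e.subject_id, []).append(e)
    return groups


def extract_roi(
    img: CaptureImage, target_size: tuple[int, int] = DEFAULT_GRID
) -> ROIImage:
    """Crop, resample and normalize one capture to the analysis grid.

    Crops ``roi_rect``, resamples bilinearly to ``target_size`` and maps
    to zero mean / unit variance; the removed (mean, std) are kept as
    metadata.  A constant crop carries no pattern and raises
    :class:`DegenerateInputError`.  Idempotent (to ~1e-6) on inputs that
    are already normalized and already on the grid.
    """
    x, y, w, h = img.roi_rect
    crop = np.asarray(img.pixels, dtype=np.float64)[y : y + h, x : x + w]
    if crop.shape != tuple(target_size):
        crop = resize(crop, target_size, order=1, mode="edge", preserve_range=True)
    mean = float(crop.mean())
    std = float(crop.std())
    if std < 1e-9:
        raise DegenerateInputError(
            f"{img.subject_id}/{img.capture_index}: constant-intensity ROI (std={std:g})"
        )
    return ROIImage(
        subject_id=img.subject_id,
        capture_index=img.capture_index,
        pixels=(crop - mean) / std,
        norm_mean=mean,
        norm_std=std,
    )
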
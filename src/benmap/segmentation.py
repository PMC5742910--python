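"""Color segmentation of activation overlay images.

Pipeline stage: classify every pixel of an RGB component image into one of
the five color classes (nearest reference color, Euclidean distance in RGB),
keep the white/grey/blue pixels, drop the background, and remove red
artifact signal.  The surviving pixels are reduced to 8-bit grayscale
luminance, which is what the entropy stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .colors import CLASS_ORDER, DEFAULT_PALETTE, EXCLUDED_CLASSES, ColorPalette

#: ITU-R BT.601 luminance weights for 8-bit RGB -> grayscale.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class ComponentImage:
    """One RGB activation-overlay raster attributed to a subject.

    Attributes
    ----------
    pixels
        ``(H, W, 3)`` uint8 array.
    subject_id, component_index, source_path
        Provenance metadata; free-form.
    true_labels
        Optional ``(H, W)`` integer ground-truth class grid (indices into
        :data:`benmap.colors.CLASS_ORDER`).  Populated by the synthetic
        generator; ``None`` for real images.
    """

    pixels: np.ndarray
    subject_id: str = ""
    component_index: int = 0
    source_path: str = ""
    true_labels: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[-1] != 3:
            raise ValueError(f"pixels must be (H, W, 3), got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have H, W >= 1")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @classmethod
    def from_file(
        cls, path: str | Path, subject_id: str = "", component_index: int = 0
    ) -> "ComponentImage":
        """Read an 8-bit RGB raster (PNG/JPEG); other modes are converted."""
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
        return cls(arr, subject_id=subject_id, component_index=component_index,
                   source_path=str(path))

    def save(self, path: str | Path) -> None:
        Image.fromarray(self.pixels, mode="RGB").save(path)


@dataclass
class SegmentationResult:
    """Per-pixel classification plus the retained grayscale image.

    ``labels`` is a total, exclusive classification: every pixel carries
    exactly one class index.  ``retained_mask`` is true only for
    white/grey/blue pixels; ``retained_gray`` holds BT.601 luminance and is
    meaningful only where the mask is true.
    """

    labels: np.ndarray            # (H, W) int8 indices into CLASS_ORDER
    retained_mask: np.ndarray     # (H, W) bool
    retained_gray: np.ndarray     # (H, W) uint8, defined where retained
    class_counts: dict[str, int]
    palette: ColorPalette = field(default=DEFAULT_PALETTE, repr=False)

    @property
    def n_retained(self) -> int:
        return int(self.retained_mask.sum())

    def retained_intensities(self) -> np.ndarray:
        """1-D uint8 array of grayscale values of the retained pixels."""
        return self.retained_gray[self.retained_mask]

    def label_names(self) -> np.ndarray:
        return np.asarray(CLASS_ORDER, dtype=object)[self.labels]

    def save_label_map(self, path: str | Path) -> None:
        """Write the label grid as an indexed PNG (palette = class colors)."""
        im = Image.fromarray(self.labels.astype(np.uint8), mode="P")
        flat = [v for c in self.palette for v in c.reference_color]
        im.putpalette(flat + [0] * (768 - len(flat)))
        im.save(path)


def segment_colors(
    image: ComponentImage, palette: ColorPalette = DEFAULT_PALETTE
) -> SegmentationResult:
    """Classify each pixel to its nearest reference color.

    Distance is Euclidean in RGB; ties are broken by the fixed class order
    background < white < grey < blue < red (``np.argmin`` keeps the first
    minimum, and the reference array is stored in that order).
    """
    px = image.pixels.astype(np.float64)
    ref = palette.reference_array  # (5, 3)
    # squared distances suffice for argmin and avoid the sqrt
    d2 = ((px[..., None, :] - ref[None, None, :, :]) ** 2).sum(axis=-1)
    labels = d2.argmin(axis=-1).astype(np.int8)

    retained = np.isin(labels, palette.retained_indices)
    gray = to_grayscale(image, retained)
    counts = np.bincount(labels.ravel(), minlength=len(CLASS_ORDER))
    class_counts = {name: int(counts[i]) for i, name in enumerate(CLASS_ORDER)}
    return SegmentationResult(
        labels=labels,
        retained_mask=retained,
        retained_gray=gray,
        class_counts=class_counts,
        palette=palette,
    )


def remove_red_artifacts(result: SegmentationResult) -> SegmentationResult:
    """Exclude red-labelled pixels from the retained set.

    Red signal outside the activation region is treated as artifact and must
    not contribute to the intensity histogram.  ``segment_colors`` already
    leaves red out of the retained mask, so this is a guard stage: it is
    idempotent, leaves ``labels`` and ``class_counts`` untouched (the audit
    record of what was seen), and zeroes the grayscale of anything excluded.
    """
    red = result.labels == result.palette.index("red")
    excluded = np.isin(result.labels, [result.palette.index(n) for n in EXCLUDED_CLASSES])
    mask = result.retained_mask & ~red & ~excluded
    gray = np.where(mask, result.retained_gray, 0).astype(np.uint8)
    return replace(result, retained_mask=mask, retained_gray=gray)


def to_grayscale(image: ComponentImage, mask: np.ndarray) -> np.ndarray:
    """BT.601 luminance of the retained pixels.

    Each retained pixel maps to ``round(0.299 R + 0.587 G + 0.114 B)``
    (half-up), clamped to [0, 255]; non-retained pixels are set to 0 but
    carry no meaning outside the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {image.shape}"
        )
    luma = image.pixels.astype(np.float64) @ LUMA_WEIGHTS
    gray = np.clip(np.floor(luma + 0.5), 0, 255).astype(np.uint8)
    return np.where(mask, gray, 0).astype(np.uint8)


def segment_and_clean(
    image: ComponentImage, palette: ColorPalette = DEFAULT_PALETTE
) -> SegmentationResult:
    """Convenience: :func:`segment_colors` then :func:`remove_red_artifacts`."""
    return remove_red_artifacts(segment_colors(image, palette))
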
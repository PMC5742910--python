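"""Shannon brain entropy (BEN) of segmented component images.

The brain-entropy statistic used here is the Shannon entropy of the 256-bin
pixel-intensity distribution of an activation image after color segmentation
has restricted it to meaningful (white/grey/blue) pixels:

    H = - sum_i p_i log2 p_i ,   p_i = count_i / n_retained ,

with the convention 0 * log2(0) = 0.  H lies in [0, 8] bits for 8-bit
intensities; the normalized BEN is H / log2(256) = H / 8, dimensionless in
[0, 1].  A subject's BEN is the arithmetic mean over their (by default two)
component images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colors import DEFAULT_PALETTE, ColorPalette
from .segmentation import ComponentImage, segment_and_clean

#: Number of intensity levels / histogram bins.
N_LEVELS = 256
#: Maximum attainable entropy in bits: log2(256).
MAX_ENTROPY_BITS = 8.0


class NoRetainedPixelsError(ValueError):
    """Raised when segmentation leaves no pixels to build a histogram from.

    Signals an empty or failed segmentation — the analogue of a subject with
    no meaningful visual activation in their component image.
    """


@dataclass
class IntensityHistogram:
    """256-bin count histogram over 8-bit intensities with probabilities."""

    counts: np.ndarray  # (256,) int64

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (N_LEVELS,):
            raise ValueError(f"counts must have shape ({N_LEVELS},), got {c.shape}")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if c.sum() < 1:
            raise NoRetainedPixelsError("histogram has zero total count")
        self.counts = c

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.counts.sum()


@dataclass(frozen=True)
class BENResult:
    """Entropy of one image: raw bits, normalized BEN, and pixel count."""

    entropy_bits: float
    ben: float
    n_pixels: int


@dataclass(frozen=True)
class SubjectBEN:
    """Subject-level aggregate over the subject's component images.

    ``ben`` is the arithmetic mean of the per-image normalized entropies.
    ``excluded`` marks subjects for whom any image produced an empty
    segmentation; their ``ben`` is NaN and they drop out of group statistics.
    """

    subject_id: str
    image_bens: tuple[float, ...]
    image_bits: tuple[float, ...]
    ben: float
    entropy_bits: float
    excluded: bool = False
    reason: str = ""


def intensity_histogram(values: np.ndarray) -> IntensityHistogram:
    """Tally 8-bit intensities into 256 bins.

    Parameters
    ----------
    values
        Integer intensities in [0, 255]; any shape (flattened).  Must be
        non-empty, otherwise :class:`NoRetainedPixelsError` is raised.
    """
    v = np.asarray(values).ravel()
    if v.size == 0:
        raise NoRetainedPixelsError("no retained pixels to histogram")
    v = v.astype(np.int64)
    if v.min() < 0 or v.max() >= N_LEVELS:
        raise ValueError("intensities must lie in [0, 255]")
    return IntensityHistogram(np.bincount(v, minlength=N_LEVELS))


def shannon_entropy(hist: IntensityHistogram) -> float:
    """Shannon entropy in bits of the histogram's probability distribution.

    Empty bins contribute zero (0 log 0 = 0).  The result is clipped at
    zero to absorb floating-point round-off on near-degenerate histograms.
    """
    p = hist.probabilities
    p = p[p > 0]
    h = float(-(p * np.log2(p)).sum())
    return h if h > 0.0 else 0.0


def normalize_ben(entropy_bits: float) -> float:
    """Normalize raw entropy to [0, 1] by the 8-bit maximum log2(256) = 8."""
    if not 0.0 <= entropy_bits <= MAX_ENTROPY_BITS:
        raise ValueError(
            f"entropy must lie in [0, {MAX_ENTROPY_BITS}] bits, got {entropy_bits}"
        )
    return entropy_bits / MAX_ENTROPY_BITS


def image_ben(
    image: ComponentImage, palette: ColorPalette = DEFAULT_PALETTE
) -> BENResult:
    """Full per-image pipeline: segment, drop artifacts, histogram, entropy."""
    seg = segment_and_clean(image, palette)
    hist = intensity_histogram(seg.retained_intensities())
    bits = shannon_entropy(hist)
    return BENResult(entropy_bits=bits, ben=normalize_ben(bits), n_pixels=hist.total)


def subject_ben(
    subject_id: str,
    images: list[ComponentImage] | tuple[ComponentImage, ...],
    palette: ColorPalette = DEFAULT_PALETTE,
    images_per_subject: int = 2,
) -> SubjectBEN:
    """Aggregate a subject's component images into one BEN value.

    Exactly ``images_per_subject`` images are required (the two sequential,
    best-matched component renderings per subject).  If any image yields an
    empty segmentation the subject is flagged ``excluded`` rather than
    raising, mirroring the exclusion of participants without meaningful
    visual activation.
    """
    if len(images) != images_per_subject:
        raise ValueError(
            f"subject {subject_id!r}: expected {images_per_subject} images, "
            f"got {len(images)}"
        )
    bens: list[float] = []
    bits: list[float] = []
    for k, img in enumerate(images):
        try:
            res = image_ben(img, palette)
        except NoRetainedPixelsError:
            return SubjectBEN(
                subject_id=subject_id,
                image_bens=(),
                image_bits=(),
                ben=float("nan"),
                entropy_bits=float("nan"),
                excluded=True,
                reason=f"image {k + 1}: no retained pixels after segmentation",
            )
        bens.append(res.ben)
        bits.append(res.entropy_bits)
    return SubjectBEN(
        subject_id=subject_id,
        image_bens=tuple(bens),
        image_bits=tuple(bits),
        ben=float(np.mean(bens)),
        entropy_bits=float(np.mean(bits)),
    )
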
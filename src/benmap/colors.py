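"""Five-class color profiles used to segment activation overlay images.

An ICA component overlay rendered on an anatomical slice is, for this
analysis, a composition of five semantic color classes: the ``background``
outside the head, ``white`` and ``grey`` brain tissue, ``blue`` occipital
activation, and ``red`` artifact signal.  Each class is represented by a
single reference RGB value; pixels are classified by nearest reference
color (see :mod:`benmap.segmentation`).

The class *order* is part of the contract: nearest-color ties are broken in
favour of the earlier class in :data:`CLASS_ORDER`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: Fixed class order; also the tie-break order for nearest-color ties.
CLASS_ORDER: tuple[str, ...] = ("background", "white", "grey", "blue", "red")

#: Classes whose pixels enter the entropy histogram.
RETAINED_CLASSES: tuple[str, ...] = ("white", "grey", "blue")

#: Classes excluded from the histogram (non-brain background; artifact).
EXCLUDED_CLASSES: tuple[str, ...] = ("background", "red")


@dataclass(frozen=True)
class ColorClass:
    """One named color profile.

    Parameters
    ----------
    name
        One of :data:`CLASS_ORDER`.
    reference_color
        8-bit RGB triple representing the class.
    """

    name: str
    reference_color: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.name not in CLASS_ORDER:
            raise ValueError(
                f"unknown color class {self.name!r}; expected one of {CLASS_ORDER}"
            )
        rc = tuple(int(v) for v in self.reference_color)
        if len(rc) != 3 or any(not (0 <= v <= 255) for v in rc):
            raise ValueError(f"reference color must be an 8-bit RGB triple, got {rc}")
        object.__setattr__(self, "reference_color", rc)


class ColorPalette:
    """An ordered set of exactly five :class:`ColorClass` profiles.

    The palette validates that all five class names are present and that the
    reference colors are pairwise distinct.  Iteration order follows
    :data:`CLASS_ORDER` regardless of input order.
    """

    def __init__(self, classes: list[ColorClass] | tuple[ColorClass, ...]):
        by_name = {c.name: c for c in classes}
        if len(classes) != len(by_name):
            raise ValueError("duplicate class names in palette")
        missing = set(CLASS_ORDER) - set(by_name)
        if missing:
            raise ValueError(f"palette is missing classes: {sorted(missing)}")
        ordered = tuple(by_name[name] for name in CLASS_ORDER)
        colors = {c.reference_color for c in ordered}
        if len(colors) != len(ordered):
            raise ValueError("duplicate reference colors in palette")
        self.classes: tuple[ColorClass, ...] = ordered

    # -- lookups ---------------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return CLASS_ORDER

    def index(self, name: str) -> int:
        return CLASS_ORDER.index(name)

    @property
    def reference_array(self) -> np.ndarray:
        """(5, 3) float array of reference colors in class order."""
        return np.asarray([c.reference_color for c in self.classes], dtype=float)

    @property
    def retained_indices(self) -> np.ndarray:
        return np.asarray([self.index(n) for n in RETAINED_CLASSES])

    def min_pairwise_distance(self) -> float:
        """Smallest Euclidean RGB distance between any two reference colors.

        Additive pixel noise with norm strictly below half this value can
        never flip a pixel's nearest reference color.
        """
        ref = self.reference_array
        d = np.linalg.norm(ref[:, None, :] - ref[None, :, :], axis=-1)
        d[np.diag_indices_from(d)] = np.inf
        return float(d.min())

    def __iter__(self):
        return iter(self.classes)

    def __eq__(self, other) -> bool:
        return isinstance(other, ColorPalette) and self.classes == other.classes

    def __hash__(self) -> int:
        return hash(self.classes)

    def __repr__(self) -> str:
        body = ", ".join(f"{c.name}={c.reference_color}" for c in self.classes)
        return f"ColorPalette({body})"

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path) -> "ColorPalette":
        """Load a palette from a ``name,R,G,B`` CSV (header optional)."""
        classes = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].strip().lower() in ("name", ""):
                    continue
                name, r, g, b = row[:4]
                classes.append(ColorClass(name.strip(), (int(r), int(g), int(b))))
        return cls(classes)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["name", "R", "G", "B"])
            for c in self.classes:
                writer.writerow([c.name, *c.reference_color])


#: Default profiles: maximally separated 8-bit values for the five classes.
DEFAULT_PALETTE = ColorPalette(
    [
        ColorClass("background", (0, 0, 0)),
        ColorClass("white", (255, 255, 255)),
        ColorClass("grey", (128, 128, 128)),
        ColorClass("blue", (0, 0, 255)),
        ColorClass("red", (255, 0, 0)),
    ]
)
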
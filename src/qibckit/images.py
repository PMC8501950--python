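"""Core image containers: single-channel images, multi-channel fields, label masks.

All pixel grids are 2-D numpy arrays indexed ``(row, col)``, 0-based.
Intensities are non-negative and bounded by the declared bit depth; float
arrays are allowed (e.g. noiseless synthetic renders) as long as values stay
inside the dynamic range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ValidationError

DAPI = "DAPI"


@dataclass
class ChannelImage:
    """One 2-D intensity grid for a named channel.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities.
    channel_name
        Name of the stain/marker (e.g. ``"DAPI"``, ``"EdU"``).
    bit_depth
        8 or 16; bounds the admissible intensity range.
    """

    pixels: np.ndarray
    channel_name: str
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError(
                f"channel {self.channel_name!r}: expected a 2-D grid, "
                f"got ndim={self.pixels.ndim}"
            )
        if self.bit_depth not in (8, 16):
            raise ValidationError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixels.size:
            lo = float(self.pixels.min())
            hi = float(self.pixels.max())
            if lo < 0 or hi > self.max_value:
                raise ValidationError(
                    f"channel {self.channel_name!r}: intensities [{lo}, {hi}] "
                    f"outside [0, {self.max_value}]"
                )

    @property
    def max_value(self) -> float:
        return float(2**self.bit_depth - 1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class FieldOfView:
    """A set of named channel images sharing one coordinate grid.

    The unit of acquisition; must contain a DAPI channel.
    """

    channels: Mapping[str, ChannelImage]
    field_id: str = "field"

    def __post_init__(self) -> None:
        if DAPI not in self.channels:
            raise ValidationError("FieldOfView must contain a 'DAPI' channel")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValidationError(f"channels disagree on shape: {sorted(shapes)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[DAPI].shape

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    @property
    def dapi(self) -> ChannelImage:
        return self.channels[DAPI]


@dataclass
class LabelMask:
    """Integer-labelled object mask: background 0, objects 1..n_objects, no gaps."""

    labels: np.ndarray
    n_objects: int = field(default=-1)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValidationError("labels must be a 2-D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("labels must be an integer grid")
        present = np.unique(self.labels)
        present = present[present > 0]
        n = int(present[-1]) if present.size else 0
        if present.size != n:
            raise ValidationError("labels are not a gap-free 1..n numbering")
        if self.labels.size and self.labels.min() < 0:
            raise ValidationError("labels must be non-negative")
        if self.n_objects == -1:
            self.n_objects = n
        elif self.n_objects != n:
            raise ValidationError(
                f"n_objects={self.n_objects} does not match labels (n={n})"
            )

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "LabelMask":
        """Build a mask from an arbitrary non-negative labelling, renumbering
        the positive labels to a gap-free 1..n in ascending original order."""
        labels = np.asarray(labels)
        present = np.unique(labels)
        present = present[present > 0]
        lut = np.zeros(int(labels.max()) + 1 if labels.size else 1, dtype=np.int32)
        lut[present] = np.arange(1, present.size + 1, dtype=np.int32)
        return cls(lut[labels])

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def areas(self) -> np.ndarray:
        """Pixel count per label, index 1..n_objects (index 0 = background)."""
        return np.bincount(self.labels.ravel(), minlength=self.n_objects + 1)
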
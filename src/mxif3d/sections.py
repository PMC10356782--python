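"""Core container for one serial section."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Section"]


@dataclass
class Section:
    """One 2D multichannel serial section.

    ``channels`` maps channel name (e.g. ``"DAPI"``, ``"AF"``, ``"CD31"``)
    to a row-major 2D raster. ``retained_index`` counts the sections kept
    for analysis (0-based, contiguous); ``physical_index`` is the position
    in the original cutting order, so skipped physical sections show up as
    gaps: ``physical_index >= retained_index`` always holds.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    retained_index: int
    physical_index: int
    af_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("section has no channels")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.retained_index < 0 or self.physical_index < 0:
            raise ValueError("section indices must be non-negative")
        if self.physical_index < self.retained_index:
            raise ValueError("physical_index must be >= retained_index")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def z_um(self, thickness_um: float) -> float:
        """Physical z of the slab's lower face."""
        return self.physical_index * thickness_um
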
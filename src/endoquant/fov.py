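"""Two-channel field-of-view container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FieldOfView:
    """One imaging field: receptor channel + QD-ligand channel + metadata.

    Both grids are finite, non-negative, same-shape 2-D intensity arrays in
    arbitrary units.  ``metadata`` carries at least ``ligand``, ``time_min``
    and ``field_id`` when the field belongs to a time-course experiment.
    """

    receptor: np.ndarray
    qd: np.ndarray
    metadata: dict = field(default_factory=dict)
    pixel_size_um: float | None = None

    def __post_init__(self):
        self.receptor = np.asarray(self.receptor, dtype=float)
        self.qd = np.asarray(self.qd, dtype=float)
        if self.receptor.shape != self.qd.shape:
            raise ValueError("receptor and qd grids must share a shape")
        if not (np.all(np.isfinite(self.receptor)) and np.all(np.isfinite(self.qd))):
            raise ValueError("intensity grids must be finite")

    @property
    def shape(self):
        return self.receptor.shape
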
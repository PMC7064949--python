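"""4D signal series container shared across fitting, registration and I/O."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SignalSeries"]


@dataclass
class SignalSeries:
    """A 4D image: three spatial axes plus the protocol index.

    data : float array of shape (nx, ny, nz, n_volumes).
    spacing : voxel size in mm per spatial axis.
    affine : voxel-to-world transform (4x4); defaults to a diagonal affine
        built from the spacing.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive numbers")
        if self.affine is None:
            aff = np.diag((*self.spacing, 1.0))
            self.affine = aff
        else:
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (4, 4):
                raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]  # type: ignore[return-value]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def volume(self, i: int) -> np.ndarray:
        return self.data[..., i]

    def with_data(self, data: np.ndarray) -> "SignalSeries":
        return SignalSeries(data, spacing=self.spacing, affine=self.affine.copy())
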
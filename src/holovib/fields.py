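"""Raster displacement fields on a circular aperture, plus TIFF/JSON sidecar I/O.

The package-wide raster convention is a square row-major grid centred on the
plate axis: x increases with column index, y increases with decreasing row
index (image convention), and only pixels with ``r <= radius`` are valid.
Invalid pixels carry NaN, never zero, so that masking survives arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["DisplacementField", "raster_coords", "make_field"]


def raster_coords(radius_m: float, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Return ``(x, y, mask, pixel_size)`` for an ``n x n`` raster spanning the disc.

    The grid spans ``[-radius, radius]`` in both axes so the circle inscribes
    the raster exactly; ``mask`` is True where ``r <= radius``.
    """
    if n < 3:
        raise ValueError("raster must be at least 3x3")
    if radius_m <= 0:
        raise ValueError("radius must be positive")
    c = np.linspace(-radius_m, radius_m, n)
    x, y = np.meshgrid(c, -c)  # row 0 is the top of the image
    mask = x * x + y * y <= radius_m * radius_m * (1 + 1e-12)
    pixel = c[1] - c[0]
    return x, y, mask, pixel


@dataclass
class DisplacementField:
    """Transverse amplitude sampled on the standard raster.

    ``values`` is in the unit given by ``unit`` (metres for physical fields,
    dimensionless for normalized mode shapes); pixels outside ``mask`` are NaN.
    """

    values: np.ndarray
    mask: np.ndarray
    pixel_size_m: float
    radius_m: float
    unit: str = "m"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape or self.values.ndim != 2:
            raise ValueError("values and mask must be matching 2D arrays")
        # enforce the invalid-pixel convention
        self.values = np.where(self.mask, self.values, np.nan)

    # -- geometry helpers -------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        x, y, _, _ = raster_coords(self.radius_m, self.n)
        return x, y

    @property
    def center_index(self) -> tuple[int, int]:
        return (self.n - 1) // 2, (self.n - 1) // 2

    def max_abs(self) -> float:
        return float(np.nanmax(np.abs(self.values)))

    def normalized(self) -> "DisplacementField":
        """Scale to max |value| = 1 (the convention for plotted mode shapes)."""
        m = self.max_abs()
        if m == 0 or not np.isfinite(m):
            raise ValueError("cannot normalize an all-zero or invalid field")
        return DisplacementField(self.values / m, self.mask, self.pixel_size_m,
                                 self.radius_m, unit="1")

    def scaled(self, factor: float, unit: str = "m") -> "DisplacementField":
        return DisplacementField(self.values * factor, self.mask, self.pixel_size_m,
                                 self.radius_m, unit=unit)

    def sample(self, xq: np.ndarray, yq: np.ndarray) -> np.ndarray:
        """Bilinear sample at physical coordinates; NaN outside the mask."""
        n = self.n
        half = self.radius_m
        col = (np.asarray(xq) + half) / (2 * half) * (n - 1)
        row = (half - np.asarray(yq)) / (2 * half) * (n - 1)
        from scipy.ndimage import distance_transform_edt, map_coordinates

        # extend by nearest valid value so rim samples do not blend with the
        # invalid exterior; the circular mask is reapplied below
        idx = distance_transform_edt(~self.mask, return_distances=False,
                                     return_indices=True)
        filled = self.values[tuple(idx)]
        out = map_coordinates(filled, [row, col], order=1, mode="nearest")
        inside = np.asarray(xq) ** 2 + np.asarray(yq) ** 2 <= self.radius_m ** 2
        return np.where(inside, out, np.nan)

    # -- I/O ---------------------------------------------------------------
    def to_tiff(self, path: str | Path) -> None:
        """Write a 32-bit float TIFF plus a JSON sidecar with the physical scale."""
        path = Path(path)
        tifffile.imwrite(path, self.values.astype(np.float32))
        sidecar = {
            "pixel_size_m": self.pixel_size_m,
            "amplitude_unit": self.unit,
            "mask_radius_px": self.radius_m / self.pixel_size_m,
            "radius_m": self.radius_m,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_tiff(cls, path: str | Path) -> "DisplacementField":
        path = Path(path)
        values = np.asarray(tifffile.imread(path), dtype=float)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        radius = meta.get("radius_m", meta["pixel_size_m"] * meta["mask_radius_px"])
        _, _, mask, _ = raster_coords(radius, values.shape[0])
        return cls(values, mask, meta["pixel_size_m"], radius, unit=meta["amplitude_unit"])


def make_field(values: np.ndarray, radius_m: float, unit: str = "m") -> DisplacementField:
    """Wrap an ``n x n`` array as a DisplacementField on the standard raster."""
    n = np.asarray(values).shape[0]
    _, _, mask, pixel = raster_coords(radius_m, n)
    return DisplacementField(values, mask, pixel, radius_m, unit=unit)
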
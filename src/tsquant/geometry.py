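"""Cell geometry and image-stack containers.

All stacks are indexed ``(z, y, x)`` with 0-based voxel indices; continuous
positions (spot centers, ground-truth emitter positions) are expressed in
voxel units with integer coordinates at voxel centers.  Physical voxel
dimensions default to the confocal sampling used throughout: 107.5 nm in
x-y and a 300 nm z-step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: default x-y pixel size, nm
DEFAULT_DXY_NM = 107.5
#: default z-step, nm
DEFAULT_DZ_NM = 300.0


@dataclass
class ImageStack:
    """A single-channel 3D voxel grid with physical voxel dimensions.

    Parameters
    ----------
    data : ndarray, shape (n_z, n_y, n_x)
        Voxel values in camera counts.
    dx_nm, dy_nm, dz_nm : float
        Physical voxel dimensions.
    """

    data: np.ndarray
    dx_nm: float = DEFAULT_DXY_NM
    dy_nm: float = DEFAULT_DXY_NM
    dz_nm: float = DEFAULT_DZ_NM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack must be 3D (z, y, x); got ndim={self.data.ndim}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_z(self) -> int:
        return self.data.shape[0]


@dataclass
class CellGeometry:
    """Voxel grid plus cytoplasm/nucleus masks for one cell.

    The masks are 2D boolean arrays over (y, x), extruded along z: an
    emitter at continuous position (z, y, x) is cytoplasmic iff the mask is
    True at its nearest x-y pixel.  Cytoplasm and nucleus are disjoint.
    """

    shape: tuple[int, int, int]
    cyto_mask: np.ndarray
    nucleus_mask: np.ndarray
    dx_nm: float = DEFAULT_DXY_NM
    dy_nm: float = DEFAULT_DXY_NM
    dz_nm: float = DEFAULT_DZ_NM

    def __post_init__(self) -> None:
        self.cyto_mask = np.asarray(self.cyto_mask, dtype=bool)
        self.nucleus_mask = np.asarray(self.nucleus_mask, dtype=bool)
        n_z, n_y, n_x = self.shape
        if self.cyto_mask.shape != (n_y, n_x):
            raise ValueError("cyto_mask shape must match (n_y, n_x)")
        if self.nucleus_mask.shape != (n_y, n_x):
            raise ValueError("nucleus_mask shape must match (n_y, n_x)")
        if self.dx_nm != self.dy_nm:
            raise ValueError("x and y pixel sizes must be equal")
        if np.any(self.cyto_mask & self.nucleus_mask):
            raise ValueError("cytoplasm and nucleus masks must be disjoint")

    @property
    def n_cyto_pixels(self) -> int:
        return int(self.cyto_mask.sum())


def _ellipse_mask(n_y: int, n_x: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:n_y, 0:n_x]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def default_geometry(
    shape: tuple[int, int, int] = (11, 256, 256),
    cell_radius_frac: tuple[float, float] = (0.44, 0.47),
    nucleus_radius_frac: tuple[float, float] = (0.17, 0.19),
    dx_nm: float = DEFAULT_DXY_NM,
    dz_nm: float = DEFAULT_DZ_NM,
) -> CellGeometry:
    """An elliptical cell with a central elliptical nucleus.

    Radii are fractions of the field size, leaving a border so diffraction-
    limited spots render without edge truncation.
    """
    n_z, n_y, n_x = shape
    cy, cx = (n_y - 1) / 2.0, (n_x - 1) / 2.0
    cell = _ellipse_mask(n_y, n_x, cy, cx, cell_radius_frac[0] * n_y, cell_radius_frac[1] * n_x)
    nuc = _ellipse_mask(n_y, n_x, cy, cx, nucleus_radius_frac[0] * n_y, nucleus_radius_frac[1] * n_x)
    return CellGeometry(
        shape=shape,
        cyto_mask=cell & ~nuc,
        nucleus_mask=nuc,
        dx_nm=dx_nm,
        dy_nm=dx_nm,
        dz_nm=dz_nm,
    )
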
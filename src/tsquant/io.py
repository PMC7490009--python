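"""Stack and table I/O.

Stacks are multi-page TIFF, one page per z-plane, 16-bit unsigned with
saturation clipping; voxel sizes travel in the ImageDescription tag as JSON
so a written stack reads back with its physical calibration intact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .geometry import DEFAULT_DXY_NM, DEFAULT_DZ_NM, ImageStack


class StackFormatError(RuntimeError):
    """Raised when a TIFF stack cannot be read or parsed."""


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as multi-page uint16 TIFF with voxel-size metadata."""
    data = np.clip(np.round(np.asarray(stack.data, dtype=float)), 0, 65535).astype(np.uint16)
    meta = {"dx_nm": stack.dx_nm, "dy_nm": stack.dy_nm, "dz_nm": stack.dz_nm}
    tifffile.imwrite(
        str(path), data, photometric="minisblack", description=json.dumps(meta)
    )


def read_stack(path: str | Path) -> ImageStack:
    """Read a multi-page TIFF stack; raises StackFormatError naming the file."""
    path = Path(path)
    try:
        with tifffile.TiffFile(str(path)) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description
    except Exception as exc:
        raise StackFormatError(f"cannot read TIFF stack {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise StackFormatError(f"{path}: expected a 2D/3D stack, got ndim={data.ndim}")
    dx, dy, dz = DEFAULT_DXY_NM, DEFAULT_DXY_NM, DEFAULT_DZ_NM
    if desc:
        try:
            meta = json.loads(desc)
            dx = float(meta.get("dx_nm", dx))
            dy = float(meta.get("dy_nm", dy))
            dz = float(meta.get("dz_nm", dz))
        except (ValueError, AttributeError):
            pass  # foreign description; keep defaults
    return ImageStack(data, dx_nm=dx, dy_nm=dy, dz_nm=dz)
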
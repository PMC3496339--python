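"""Raster-image interchange: TIFF (canonical, n-D via pages) and PNG (2-D).

Axis convention: image dimension 0 is x (file columns), dimension 1 is y
(file rows), dimension 2 is the page index of a multi-page TIFF.  Write
followed by read preserves dimensions, value type (within the format's
capability) and every sample exactly.
"""

from __future__ import annotations

import os

import numpy as np
import imageio.v3 as iio
import tifffile

from .storage import ArrayImg
from .types import argb_pack, argb_unpack

__all__ = ["read_image", "write_image", "FormatError"]


class FormatError(ValueError):
    """Unsupported file format, bit depth or layout."""


_DTYPE_TO_TAG = {
    "uint8": "u8",
    "uint16": "u16",
    "int16": "i16",
    "int32": "i32",
    "float32": "f32",
    "float64": "f64",
}
_TAG_TO_DTYPE = {v: np.dtype(k) for k, v in _DTYPE_TO_TAG.items()}


def _rgba_to_argb(data: np.ndarray) -> np.ndarray:
    if data.shape[-1] == 3:
        data = np.concatenate(
            [data, np.full(data.shape[:-1] + (1,), 255, dtype=data.dtype)], axis=-1
        )
    r, g, b, a = (data[..., i].astype(np.uint32) for i in range(4))
    return (a << 24) | (r << 16) | (g << 8) | b


def _argb_to_rgba(packed: np.ndarray) -> np.ndarray:
    p = packed.astype(np.uint32)
    out = np.empty(p.shape + (4,), dtype=np.uint8)
    out[..., 0] = (p >> 16) & 0xFF
    out[..., 1] = (p >> 8) & 0xFF
    out[..., 2] = p & 0xFF
    out[..., 3] = (p >> 24) & 0xFF
    return out


def read_image(path) -> ArrayImg:
    """Read a TIFF or PNG into an array-backed image.

    2-D files become (w, h) images; multi-page TIFFs become (w, h, pages);
    RGB(A) channel data becomes a packed ``argb`` image.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        data = tifffile.imread(path)
    elif ext == ".png":
        data = iio.imread(path)
    else:
        raise FormatError(f"{path}: unsupported format {ext!r} (TIFF/PNG only)")

    if data.ndim >= 2 and data.shape[-1] in (3, 4) and data.dtype == np.uint8 and ext == ".png":
        packed = _rgba_to_argb(data)
        return ArrayImg.from_numpy(packed.T, "argb")
    tag = _DTYPE_TO_TAG.get(data.dtype.name)
    if tag is None:
        raise FormatError(
            f"{path}: unsupported sample dtype {data.dtype.name!r}; "
            f"expected one of {sorted(_DTYPE_TO_TAG)}"
        )
    if data.ndim == 2:  # (y, x) -> (x, y)
        arr = data.T
    elif data.ndim == 3:  # (page, y, x) -> (x, y, page)
        arr = np.transpose(data, (2, 1, 0))
    else:
        raise FormatError(f"{path}: {data.ndim}-D data not supported (2-D/3-D only)")
    return ArrayImg.from_numpy(arr, tag)


def write_image(img, path) -> None:
    """Write an image to TIFF (any supported type, 2-D or 3-D) or PNG
    (2-D u8 / argb)."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if not isinstance(img, ArrayImg):
        dense = ArrayImg.from_numpy(
            np.array(
                [img.get(p) for p in img.interval.positions()]
            ).reshape(img.interval.dims, order="F").astype(
                img.type.dtype, copy=False
            ),
            img.type.tag,
        )
        img = dense
    arr = img.to_numpy()
    tag = img.type.tag
    if ext == ".png":
        if arr.ndim != 2:
            raise FormatError(f"{path}: PNG supports 2-D images only")
        if tag == "argb":
            iio.imwrite(path, _argb_to_rgba(arr.T))
        elif tag == "u8":
            iio.imwrite(path, arr.T.astype(np.uint8))
        else:
            raise FormatError(f"{path}: PNG supports u8/argb, image is {tag!r}")
        return
    if ext not in (".tif", ".tiff"):
        raise FormatError(f"{path}: unsupported format {ext!r} (TIFF/PNG only)")
    if tag == "argb":
        if arr.ndim != 2:
            raise FormatError(f"{path}: argb TIFF export supports 2-D only")
        tifffile.imwrite(path, _argb_to_rgba(arr.T), photometric="rgb")
        return
    dtype = _TAG_TO_DTYPE.get(tag, np.dtype(np.float64) if tag == "f64" else None)
    if tag == "bit":
        dtype = np.dtype(np.uint8)
    if dtype is None:
        raise FormatError(f"{path}: cannot export value type {tag!r} to TIFF")
    if arr.ndim == 2:
        data = arr.T.astype(dtype)
    elif arr.ndim == 3:
        data = np.transpose(arr, (2, 1, 0)).astype(dtype)
    else:
        raise FormatError(f"{path}: TIFF export supports 2-D/3-D only")
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        metadata={"axes": "QYX"[3 - data.ndim:]},
    )
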
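"""Read open microscopy formats into the domain model.

Dispatch is by file content, never by extension: MRC is recognized by its
MAP stamp, TIFF by its magic, multichannel stacks by their OME metadata,
pyramids by reduced-resolution levels.  A tiled RGB TIFF whose reduced
levels are absent (or that carries no OME description) takes the
``unrecognized_pyramid`` branch and is first rebuilt as a pyramidal
OME-TIFF by :func:`pyramidalize`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import mrcfile
import numpy as np
import tifffile

from . import _omexml
from ._resample import downsample2x
from .model import ChannelInfo, ImageVolume, ModelError, PyramidImage, PyramidLevel

__all__ = [
    "FormatError",
    "SourceDescriptor",
    "sniff",
    "read_volume",
    "read_pyramid",
    "pyramidalize",
    "recorded_jpeg_quality",
    "DEFAULT_TILE_SIZE",
]

DEFAULT_TILE_SIZE = 512

Kind = Literal["volume", "em_stack", "pyramid", "unrecognized_pyramid"]


class FormatError(ValueError):
    """The file content does not match any supported structure."""


@dataclass(frozen=True)
class SourceDescriptor:
    path: Path
    detected_kind: Kind
    format_name: str


_TIFF_MAGICS = (b"II*\x00", b"MM\x00*", b"II+\x00", b"MM\x00+")


def _is_mrc(header: bytes) -> bool:
    return len(header) >= 212 and header[208:212] == b"MAP "


def sniff(path: str | os.PathLike) -> SourceDescriptor:
    """Classify *path* by inspecting file magic and structure."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file: {p}")
    if p.is_dir():
        if sorted(p.glob("*.png")):
            return SourceDescriptor(p, "volume", "png_stack")
        raise FormatError(f"directory contains no supported slice images: {p}")
    if p.stat().st_size == 0:
        raise FormatError(f"zero-byte file: {p}")
    with open(p, "rb") as fh:
        header = fh.read(1024)
    if _is_mrc(header):
        return SourceDescriptor(p, "em_stack", "mrc")
    if header[:4] in _TIFF_MAGICS:
        return _sniff_tiff(p)
    raise FormatError(f"unrecognized file format: {p}")


def _sniff_tiff(p: Path) -> SourceDescriptor:
    with tifffile.TiffFile(p) as tif:
        fmt = "ome-tiff" if tif.is_ome else "tiff"
        page0 = tif.pages[0]
        if page0.samplesperpixel < 3:
            return SourceDescriptor(p, "volume", fmt)
        # RGB: pyramid when reduced-resolution levels are present and readable
        series = tif.series
        if len(series[0].levels) > 1:
            return SourceDescriptor(p, "pyramid", fmt)
        widths = [s.shape[-2] for s in series if s.shape[-1] == 3]
        if len(widths) > 1 and all(b < a for a, b in zip(widths, widths[1:])):
            return SourceDescriptor(p, "pyramid", fmt)
        if tif.is_ome:
            # a recognized single-level image is a trivial one-level pyramid
            return SourceDescriptor(p, "pyramid", fmt)
        return SourceDescriptor(p, "unrecognized_pyramid", fmt)


# ---------------------------------------------------------------------------
# volumes


def read_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a multichannel z-stack or EM section series as an XYCZT volume.

    EM stacks come back with C = T = 1 and Z equal to the section count.
    Channel metadata is taken from OME-XML where present, else defaulted.
    """
    desc = sniff(path)
    if desc.detected_kind == "em_stack":
        return _read_mrc(desc.path)
    if desc.detected_kind != "volume":
        raise FormatError(f"not a volume input: {desc.path} ({desc.detected_kind})")
    if desc.format_name == "png_stack":
        return _read_png_stack(desc.path)
    return _read_tiff_volume(desc.path)


_MRC_BIT_DEPTH = {0: 8, 1: 16, 2: 16, 6: 16}  # mode 2 is float, rescaled to 16-bit


def _read_mrc(path: Path) -> ImageVolume:
    with mrcfile.open(path, permissive=True) as mrc:
        mode = int(mrc.header.mode)
        nx, ny, nz = int(mrc.header.nx), int(mrc.header.ny), int(mrc.header.nz)
        data = mrc.data
        if data is None:
            expected = nx * ny * nz * np.dtype(_mrc_dtype(mode)).itemsize + 1024
            actual = path.stat().st_size
            raise FormatError(
                f"truncated MRC pixel data in {path}: expected {expected} bytes, "
                f"file has {actual}"
            )
        data = np.asarray(data)
        if data.ndim == 2:
            data = data[None]
        if data.size < nx * ny * nz:
            raise FormatError(
                f"truncated MRC pixel data in {path}: header promises "
                f"{nx * ny * nz} voxels, file provides {data.size}"
            )
    if mode not in _MRC_BIT_DEPTH:
        raise FormatError(f"unsupported MRC mode {mode} in {path}")
    if mode == 0:  # int8 per MRC2014; shift only when really signed
        data = (
            (data.astype(np.int16) + 128).astype(np.uint8)
            if data.min() < 0
            else data.astype(np.uint8)
        )
    elif mode == 1:
        data = (
            (data.astype(np.int32) - int(data.min())).astype(np.uint16)
            if data.min() < 0
            else data.astype(np.uint16)
        )
    elif mode == 2:  # float: min-max rescale into the 16-bit range
        lo, hi = float(data.min()), float(data.max())
        scale = 65535.0 / (hi - lo) if hi > lo else 0.0
        data = np.round((data.astype(np.float64) - lo) * scale).astype(np.uint16)
    else:  # mode 6: uint16
        data = data.astype(np.uint16)
    pixels = np.ascontiguousarray(data.transpose(2, 1, 0))[:, :, None, :, None]
    return ImageVolume(
        pixels=pixels,
        bit_depth=_MRC_BIT_DEPTH[mode],
        channels=[ChannelInfo(channel_id="0", channel_name="EM", illumination_type="Electron")],
        source_name=path.name,
    )


def _mrc_dtype(mode: int) -> str:
    return {0: "i1", 1: "i2", 2: "f4", 6: "u2"}.get(mode, "u1")


def _read_png_stack(path: Path) -> ImageVolume:
    from PIL import Image

    slices = []
    for p in sorted(path.glob("*.png")):  # lexicographic slice order
        with Image.open(p) as im:
            slices.append(np.asarray(im.convert("L") if im.mode not in ("L", "I;16") else im))
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise FormatError(f"slice images in {path} disagree in shape: {sorted(shapes)}")
    stack = np.stack(slices)  # (Z, Y, X)
    bit_depth = 16 if stack.dtype.itemsize == 2 else 8
    pixels = np.ascontiguousarray(stack.transpose(2, 1, 0))[:, :, None, :, None]
    return ImageVolume(
        pixels=pixels,
        bit_depth=bit_depth,
        channels=[ChannelInfo(channel_id="0")],
        source_name=path.name,
    )


def _read_pages(tif: tifffile.TiffFile, path: Path) -> list[np.ndarray]:
    arrays = []
    for i, page in enumerate(tif.pages):
        try:
            arrays.append(page.asarray())
        except Exception as exc:
            expected = int(np.prod(page.shape)) * page.dtype.itemsize
            actual = max(path.stat().st_size - int(page.dataoffsets[0]), 0) if page.dataoffsets else 0
            raise FormatError(
                f"truncated pixel data in {path} (page {i}): expected {expected} bytes, "
                f"found {actual} ({exc})"
            ) from exc
    return arrays


def _read_tiff_volume(path: Path) -> ImageVolume:
    with tifffile.TiffFile(path) as tif:
        ome = None
        if tif.is_ome and tif.ome_metadata:
            try:
                ome = _omexml.parse(tif.ome_metadata)
            except Exception:
                ome = None
        pages = _read_pages(tif, path)
    if ome is not None:
        c, z, t = ome.size_c, ome.size_z, ome.size_t
        order = ome.dimension_order
    else:
        c, z, t = 1, len(pages), 1
        order = "XYCZT"
    if len(pages) != c * z * t:
        raise FormatError(
            f"{path}: {len(pages)} pages but metadata promises C*Z*T = {c * z * t}"
        )
    ny, nx = pages[0].shape[:2]
    dtype = pages[0].dtype
    pixels = np.empty((nx, ny, c, z, t), dtype=dtype)
    # page index nesting follows DimensionOrder: axis 3 of "XY???" varies fastest
    sizes = {"C": c, "Z": z, "T": t}
    fast, mid, slow = order[2], order[3], order[4]
    for p, page in enumerate(pages):
        idx = {
            fast: p % sizes[fast],
            mid: (p // sizes[fast]) % sizes[mid],
            slow: p // (sizes[fast] * sizes[mid]),
        }
        pixels[:, :, idx["C"], idx["Z"], idx["T"]] = page.T

    if ome is not None and ome.significant_bits in (8, 12, 16):
        bit_depth = ome.significant_bits
    else:
        bit_depth = 16 if dtype.itemsize == 2 else 8
    channels = list(ome.channels) if ome is not None else []
    while len(channels) < c:
        channels.append(ChannelInfo(channel_id=str(len(channels))))
    pixel_size = None
    if ome is not None and ome.physical_size_xy_um:
        pixel_size = (
            ome.physical_size_xy_um,
            ome.physical_size_xy_um,
            ome.physical_size_z_um or ome.physical_size_xy_um,
        )
    return ImageVolume(
        pixels=pixels,
        bit_depth=bit_depth,
        channels=channels[:c],
        pixel_size=pixel_size,
        source_name=path.name,
    )


# ---------------------------------------------------------------------------
# pyramids


def read_pyramid(path: str | os.PathLike) -> PyramidImage:
    """Read a multi-resolution RGB image (SubIFD or multi-series layout)."""
    p = Path(path)
    with tifffile.TiffFile(p) as tif:
        s0 = tif.series[0]
        if len(s0.levels) > 1:
            arrays = [lvl.asarray() for lvl in s0.levels]
        elif len(tif.series) > 1:
            arrays = [s.asarray() for s in tif.series]
        else:
            arrays = [s0.asarray()]
    norm = []
    for arr in arrays:
        if arr.ndim == 3:
            arr = arr[None]
        if arr.ndim != 4 or arr.shape[-1] != 3:
            raise FormatError(f"{p}: level shape {arr.shape} is not RGB")
        norm.append(arr)
    z_counts = {a.shape[0] for a in norm}
    if len(z_counts) != 1:
        raise FormatError(f"{p}: levels disagree in z-plane count: {sorted(z_counts)}")
    norm.sort(key=lambda a: a.shape[2], reverse=True)
    base_w = norm[0].shape[2]
    levels = [PyramidLevel(a, downsample_vs_base=base_w / a.shape[2]) for a in norm]
    try:
        return PyramidImage(levels=levels, z_planes=norm[0].shape[0], source_name=p.name)
    except ModelError as exc:
        raise FormatError(f"{p}: {exc}") from exc


def pyramidalize(
    path: str | os.PathLike,
    jpeg_quality: int = 90,
    out_path: str | os.PathLike | None = None,
    overwrite: bool = False,
    force: bool = False,
    tile_size: int = DEFAULT_TILE_SIZE,
) -> Path:
    """Rebuild an unrecognized single-level RGB TIFF as a pyramidal OME-TIFF.

    Reduced levels are generated by successive 2× area averaging until the
    smaller dimension is ≤ *tile_size*; tiles are JPEG-compressed at
    *jpeg_quality*.  The output is accepted by :func:`read_pyramid`.
    """
    p = Path(path)
    desc = sniff(p)
    if desc.detected_kind != "unrecognized_pyramid" and not force:
        raise FormatError(
            f"{p} is recognized as {desc.detected_kind}; pass force=True to pyramidalize anyway"
        )
    try:
        with tifffile.TiffFile(p) as tif:
            base = tif.series[0].levels[0].asarray()
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"base level of {p} is unreadable: {exc}") from exc
    if base.ndim != 3 or base.shape[-1] != 3:
        raise FormatError(f"{p}: base level shape {base.shape} is not a single RGB plane")

    levels = [base]
    while min(levels[-1].shape[0], levels[-1].shape[1]) > tile_size:
        levels.append(downsample2x(levels[-1]))

    out = Path(out_path) if out_path is not None else p.with_name(p.stem + ".pyramid.ome.tiff")
    if out.exists() and not overwrite:
        raise FileExistsError(f"output exists: {out} (pass overwrite=True to replace)")

    meta = _omexml.OmeImageMeta(
        size_x=base.shape[1], size_y=base.shape[0], size_c=3, size_z=1,
        pixel_type="uint8", interleaved=True, name=p.stem,
    )
    with tifffile.TiffWriter(out) as tw:
        tw.write(
            levels[0],
            subifds=len(levels) - 1,
            tile=(tile_size, tile_size),
            compression="jpeg",
            compressionargs={"level": jpeg_quality},
            photometric="rgb",
            description=_omexml.pyramid_xml(meta),
            software=f"dicomizer pyramidalize jpeg_quality={jpeg_quality}",
            metadata=None,
        )
        for lvl in levels[1:]:
            tw.write(
                lvl,
                tile=(tile_size, tile_size),
                compression="jpeg",
                compressionargs={"level": jpeg_quality},
                photometric="rgb",
                metadata=None,
            )
    return out


def recorded_jpeg_quality(path: str | os.PathLike) -> str:
    """The JPEG quality recorded in a pyramidalized file's metadata."""
    with tifffile.TiffFile(path) as tif:
        tag = tif.pages[0].tags.get("Software")
        text = tag.value if tag is not None else ""
    for token in str(text).split():
        if token.startswith("jpeg_quality="):
            return token.split("=", 1)[1]
    raise FormatError(f"{path}: no recorded JPEG quality")
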
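"""Deterministic synthetic inputs for every pathway the converters accept.

Three generators emulate the structure (not the vendor metadata or file
sizes) of the instrument outputs the pipelines target:

* :func:`make_clsm_volume` — a multichannel confocal z-stack as OME-TIFF,
  Gaussian-blob textures per channel, channel names and illumination in the
  OME-XML;
* :func:`make_em_stack` — a serial-section 8-bit electron-microscopy stack
  as multi-page TIFF or MRC2014;
* :func:`make_wsi_pyramid` — a tiled multi-resolution RGB slide image with
  an H&E-like blob texture on a white background, optional focal planes,
  and configurable inter-level spacing (2× or 4×).

Equal arguments produce byte-identical files, so tests and the acceptance
surface need no stored binary data.
"""

from __future__ import annotations

import os
from pathlib import Path

import mrcfile
import numpy as np
import tifffile

from . import _omexml
from .model import ChannelInfo

__all__ = ["make_clsm_volume", "make_em_stack", "make_wsi_pyramid", "make_unrecognized_wsi"]

_CHANNEL_NAMES = ["DAPI", "FITC", "TRITC", "Cy5", "Cy7", "SHG"]
_EXCITATION_NM = [405.0, 488.0, 555.0, 640.0, 750.0, 880.0]
_EMISSION_NM = [461.0, 520.0, 580.0, 670.0, 780.0, 440.0]


def _blob_field(rng: np.random.Generator, ny: int, nx: int, n_blobs: int) -> np.ndarray:
    """Sum of random 2D Gaussians in [0, 1]."""
    yy, xx = np.mgrid[0:ny, 0:nx].astype(np.float64)
    field = np.zeros((ny, nx))
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, ny), rng.uniform(0, nx)
        sy = rng.uniform(ny / 12, ny / 4)
        sx = rng.uniform(nx / 12, nx / 4)
        amp = rng.uniform(0.4, 1.0)
        field += amp * np.exp(-(((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2))
    peak = field.max()
    return field / peak if peak > 0 else field


def make_clsm_volume(
    path: str | os.PathLike,
    channels: int = 3,
    z_planes: int = 46,
    xy: int = 64,
    bit_depth: int = 16,
    seed: int = 0,
) -> Path:
    """Write a confocal-like multichannel z-stack as OME-TIFF."""
    if channels < 1 or z_planes < 1:
        raise ValueError(f"channels and z_planes must be >= 1, got {channels}, {z_planes}")
    if xy < 16:
        raise ValueError(f"xy must be >= 16, got {xy}")
    if bit_depth not in (8, 12, 16):
        raise ValueError(f"bit_depth must be 8, 12 or 16, got {bit_depth}")
    path = Path(path)
    rng = np.random.default_rng(seed)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    peak = 2**bit_depth - 1

    infos = []
    planes = np.empty((z_planes, channels, xy, xy), dtype=dtype)
    for c in range(channels):
        base = _blob_field(rng, xy, xy, n_blobs=4)
        focus = rng.uniform(0, max(z_planes - 1, 1))
        depth = max(z_planes / 3.0, 1.0)
        for z in range(z_planes):
            atten = np.exp(-(((z - focus) / depth) ** 2))  # optical sectioning falloff
            img = base * atten + rng.normal(0, 0.02, (xy, xy))
            planes[z, c] = np.clip(np.round(img * peak * 0.9), 0, peak).astype(dtype)
        i = c % len(_CHANNEL_NAMES)
        infos.append(
            ChannelInfo(
                channel_id=f"Channel:0:{c}",
                channel_name=_CHANNEL_NAMES[i],
                illumination_type="Epifluorescence",
                magnification="40",
                excitation_nm=_EXCITATION_NM[i],
                emission_nm=_EMISSION_NM[i],
            )
        )

    meta = _omexml.OmeImageMeta(
        size_x=xy, size_y=xy, size_c=channels, size_z=z_planes, size_t=1,
        pixel_type="uint8" if bit_depth == 8 else "uint16",
        significant_bits=bit_depth,
        physical_size_xy_um=0.25, physical_size_z_um=0.5,
        name=path.stem, magnification="40", channels=infos,
    )
    # page order: C fastest, then Z (DimensionOrder XYCZT)
    pages = planes.reshape(z_planes * channels, xy, xy)
    with tifffile.TiffWriter(path) as tw:
        tw.write(
            pages,
            photometric="minisblack",
            compression="zlib",
            description=_omexml.volume_xml(meta),
            metadata=None,
            contiguous=False,
        )
    return path


def make_em_stack(
    path: str | os.PathLike,
    n_slices: int = 361,
    xy: int = 32,
    container: str = "mrc",
    seed: int = 0,
) -> Path:
    """Write a serial-section EM-like 8-bit stack as multi-page TIFF or MRC."""
    if n_slices < 1:
        raise ValueError(f"n_slices must be >= 1, got {n_slices}")
    if container not in ("tiff", "mrc"):
        raise ValueError(f"container must be 'tiff' or 'mrc', got {container!r}")
    path = Path(path)
    rng = np.random.default_rng(seed)
    # speckle: correlated membrane-like texture plus shot noise, drifting with depth
    base = _blob_field(rng, xy, xy, n_blobs=6)
    stack = np.empty((n_slices, xy, xy), dtype=np.uint8)
    for z in range(n_slices):
        drift = np.roll(base, z % max(xy // 4, 1), axis=0)
        img = 0.6 * drift + 0.4 * rng.random((xy, xy))
        stack[z] = np.clip(np.round(img * 127), 0, 127).astype(np.uint8)

    if container == "mrc":
        with mrcfile.new(path, overwrite=True) as mrc:
            mrc.set_data(stack.astype(np.int8))  # mode 0; values kept non-negative
    else:
        with tifffile.TiffWriter(path) as tw:
            tw.write(stack, photometric="minisblack", compression="zlib",
                     metadata=None, contiguous=False)
    return path


def _he_planes(rng: np.random.Generator, bw: int, bh: int, z_planes: int) -> np.ndarray:
    """H&E-like texture: white background, hematoxylin/eosin coloured blobs.

    All focal planes share the blob layout but shift phase; mild noise keeps
    JPEG round-trip assertions meaningful without approaching the codec's
    pure-noise worst case.
    """
    palette = np.array([[120, 60, 140], [200, 110, 160], [150, 80, 170]], dtype=np.float64)
    n_blobs = 40
    cx = rng.uniform(0, bw, n_blobs)
    cy = rng.uniform(0, bh, n_blobs)
    radius = rng.uniform(bw / 60, bw / 12, n_blobs)
    colors = palette[rng.integers(0, len(palette), n_blobs)]
    phase = rng.uniform(0, bw / 20, z_planes)  # per-plane texture shift

    planes = np.empty((z_planes, bh, bw, 3), dtype=np.uint8)
    yy, xx = np.mgrid[0:bh, 0:bw].astype(np.float64)
    for z in range(z_planes):
        img = np.full((bh, bw, 3), 255.0)
        for b in range(n_blobs):
            d2 = ((xx - cx[b] - phase[z]) ** 2 + (yy - cy[b]) ** 2) / radius[b] ** 2
            w = np.exp(-d2 * 2.0)
            img += (colors[b] - 255.0)[None, None, :] * w[:, :, None]
        noise = rng.normal(0, 3, (bh, bw, 1))
        planes[z] = np.clip(np.round(img + noise), 0, 255).astype(np.uint8)
    return planes


def make_unrecognized_wsi(
    path: str | os.PathLike,
    base_wh: tuple[int, int] = (1800, 1400),
    seed: int = 0,
    tile_size: int = 512,
) -> Path:
    """Write a single-level tiled RGB TIFF without OME metadata or reduced
    pages — the input class that takes the pyramidalization fallback."""
    bw, bh = base_wh
    path = Path(path)
    rng = np.random.default_rng(seed)
    img = _he_planes(rng, bw, bh, 1)[0]
    tifffile.imwrite(
        path, img, tile=(tile_size, tile_size), compression="zlib",
        photometric="rgb", metadata=None,
    )
    return path


def make_wsi_pyramid(
    path: str | os.PathLike,
    n_levels: int = 5,
    level_ratio: int = 4,
    base_wh: tuple[int, int] = (2048, 1024),
    z_planes: int = 1,
    seed: int = 0,
    tile_size: int = 512,
) -> Path:
    """Write a whole-slide-like RGB pyramid as tiled OME-TIFF.

    Level *k* has dimensions ``floor(base / level_ratio**k)``; all focal
    planes share geometry but differ in texture phase.
    """
    if n_levels < 1:
        raise ValueError(f"n_levels must be >= 1, got {n_levels}")
    if level_ratio not in (2, 4):
        raise ValueError(f"level_ratio must be 2 or 4, got {level_ratio}")
    if z_planes < 1:
        raise ValueError(f"z_planes must be >= 1, got {z_planes}")
    bw, bh = base_wh
    ratio_last = level_ratio ** (n_levels - 1)
    if bw // ratio_last < 1 or bh // ratio_last < 1:
        raise ValueError(
            f"base {base_wh} too small for {n_levels} levels at ratio {level_ratio}"
        )
    path = Path(path)
    rng = np.random.default_rng(seed)
    base_planes = _he_planes(rng, bw, bh, z_planes)

    levels = []
    for k in range(n_levels):
        r = level_ratio**k
        h_k, w_k = bh // r, bw // r
        cropped = base_planes[:, : h_k * r, : w_k * r, :]
        blocks = cropped.reshape(z_planes, h_k, r, w_k, r, 3)
        lvl = np.round(blocks.astype(np.float64).mean(axis=(2, 4))).astype(np.uint8)
        levels.append(lvl)

    meta = _omexml.OmeImageMeta(
        size_x=bw, size_y=bh, size_c=3, size_z=z_planes,
        pixel_type="uint8", interleaved=True, name=path.stem,
    )
    with tifffile.TiffWriter(path, bigtiff=False) as tw:
        tw.write(
            levels[0],
            subifds=n_levels - 1,
            tile=(tile_size, tile_size),
            compression="zlib",
            photometric="rgb",
            description=_omexml.pyramid_xml(meta),
            metadata=None,
        )
        for lvl in levels[1:]:
            tw.write(lvl, tile=(tile_size, tile_size), compression="zlib",
                     photometric="rgb", metadata=None)
    return path
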
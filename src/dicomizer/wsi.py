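"""Convert pyramid images into tiled multi-frame DICOM WSI series.

Every source resolution level yields two planned output levels: the level
itself (function-1: crop into 512×512 tiles) and its 2× reduction
(function-2: crop 1024×1024 source regions, area-average down to 512×512).
A synthesized candidate is dropped when an existing native level already
has those dimensions (±1 px), which closes 4×-per-axis zoom gaps while
leaving dense 2×-spaced pyramids almost unchanged.  Tiles become the
frames of one encapsulated JPEG-baseline multi-frame instance per level;
one series (folder) is emitted per focal plane.
"""

from __future__ import annotations

import io
import json
import math
import os
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from PIL import Image
from pydicom.dataset import Dataset
from pydicom.encaps import encapsulate
from pydicom.uid import UID

from . import ingest
from ._resample import downsample2x
from .model import (
    DicomInstanceSpec,
    LevelPlan,
    LevelPlanEntry,
    PyramidImage,
    UIDSet,
)
from .uid import derive_patient_id, derive_uids
from .volume import PRIVATE_GROUP, PRIVATE_CREATOR, write_instance

__all__ = [
    "VL_WSI_SOP_CLASS",
    "JPEG_BASELINE",
    "TileGrid",
    "plan_levels",
    "tile_level",
    "encode_frames",
    "decode_frame",
    "build_wsi_instance",
    "convert_wsi",
]

VL_WSI_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.77.1.6"
JPEG_BASELINE = "1.2.840.10008.1.2.4.50"

DEFAULT_TILE_SIZE = 512
DEFAULT_JPEG_QUALITY = 90


@dataclass(frozen=True)
class TileGrid:
    """Row-major full tiling of one output level."""

    tile_size: int
    cols: int
    rows: int

    @classmethod
    def for_level(cls, width: int, height: int, tile_size: int = DEFAULT_TILE_SIZE) -> "TileGrid":
        return cls(
            tile_size=tile_size,
            cols=math.ceil(width / tile_size),
            rows=math.ceil(height / tile_size),
        )

    @property
    def frame_count(self) -> int:
        return self.cols * self.rows


def plan_levels(pyramid: PyramidImage, tile_size: int = DEFAULT_TILE_SIZE) -> LevelPlan:
    """Plan the output levels: every native level plus gap-filling halves.

    A synthesized floor(source/2) candidate is dropped iff a native level
    matches its dimensions within ±1 px on both axes (floor-division
    off-by-one); duplicates among synthesized candidates collapse too.
    """
    entries: list[LevelPlanEntry] = []
    native_dims: list[tuple[int, int]] = []
    for i, lvl in enumerate(pyramid.levels):
        entries.append(
            LevelPlanEntry(
                source_level_index=i, mode="native",
                out_width=lvl.width, out_height=lvl.height,
                source_width=lvl.width, source_height=lvl.height,
            )
        )
        native_dims.append((lvl.width, lvl.height))
    for i, lvl in enumerate(pyramid.levels):
        sw, sh = lvl.width // 2, lvl.height // 2
        if sw < 1 or sh < 1:
            continue
        if any(abs(w - sw) <= 1 and abs(h - sh) <= 1 for w, h in native_dims):
            continue
        if any((e.out_width, e.out_height) == (sw, sh) for e in entries):
            continue
        entries.append(
            LevelPlanEntry(
                source_level_index=i, mode="synthesized",
                out_width=sw, out_height=sh,
                source_width=lvl.width, source_height=lvl.height,
            )
        )
    entries.sort(key=lambda e: (e.out_width, e.out_height), reverse=True)
    return LevelPlan(entries=entries)


RegionAccessor = Callable[[int, int, int, int], np.ndarray]
"""(x, y, w, h) -> clipped RGB region of the SOURCE level."""


def _pad_into(
    canvas_h: int, canvas_w: int, region: np.ndarray, background: tuple[int, int, int]
) -> np.ndarray:
    out = np.empty((canvas_h, canvas_w, 3), dtype=np.uint8)
    out[:, :] = background
    if region.size:
        out[: region.shape[0], : region.shape[1]] = region
    return out


def tile_level(
    accessor: RegionAccessor,
    out_width: int,
    out_height: int,
    mode: str,
    tile_size: int = DEFAULT_TILE_SIZE,
    background: tuple[int, int, int] = (255, 255, 255),
) -> list[np.ndarray]:
    """Cut one output level into row-major tiles of exactly tile_size².

    ``native``: each tile is read 1:1 from the source level.
    ``synthesized``: each tile reads the corresponding 2× larger source
    region and area-downsamples it by 2.  Edge tiles are padded with the
    pyramid background value.
    """
    if mode not in ("native", "synthesized"):
        raise ValueError(f"mode must be native|synthesized, got {mode!r}")
    grid = TileGrid.for_level(out_width, out_height, tile_size)
    tiles: list[np.ndarray] = []
    for row in range(grid.rows):
        for col in range(grid.cols):
            x, y = col * tile_size, row * tile_size
            valid_w = min(tile_size, out_width - x)
            valid_h = min(tile_size, out_height - y)
            try:
                if mode == "native":
                    region = accessor(x, y, tile_size, tile_size)
                    tile = _pad_into(tile_size, tile_size, region, background)
                else:
                    src = accessor(2 * x, 2 * y, 2 * tile_size, 2 * tile_size)
                    canvas = _pad_into(2 * tile_size, 2 * tile_size, src, background)
                    tile = downsample2x(canvas)
            except Exception as exc:
                raise RuntimeError(
                    f"tile read failed at grid (row={row}, col={col}), "
                    f"origin ({x}, {y}): {exc}"
                ) from exc
            # everything beyond the level extent is exact background
            tile[valid_h:, :] = background
            tile[:, valid_w:] = background
            tiles.append(tile)
    return tiles


def encode_frames(tiles: Sequence[np.ndarray], jpeg_quality: int = DEFAULT_JPEG_QUALITY) -> list[bytes]:
    """Encode tiles as independent baseline JPEG byte streams (YCbCr 4:2:2)."""
    frames = []
    for i, tile in enumerate(tiles):
        try:
            buf = io.BytesIO()
            Image.fromarray(tile).save(buf, "jpeg", quality=jpeg_quality, subsampling="4:2:2")
            frames.append(buf.getvalue())
        except Exception as exc:
            raise RuntimeError(f"JPEG encoding failed for tile {i}: {exc}") from exc
    return frames


def decode_frame(frame: bytes) -> np.ndarray:
    """Decode one baseline JPEG frame back to RGB pixels."""
    with Image.open(io.BytesIO(frame)) as im:
        return np.asarray(im.convert("RGB"))


def build_wsi_instance(
    plan_entry: LevelPlanEntry,
    frames: list[bytes],
    uids: UIDSet,
    pyramid_meta: dict | None = None,
    tile_size: int = DEFAULT_TILE_SIZE,
    source_name: str = "",
) -> DicomInstanceSpec:
    """One encapsulated multi-frame VL WSI dataset for one planned level."""
    grid = TileGrid.for_level(plan_entry.out_width, plan_entry.out_height, tile_size)
    if len(frames) != grid.frame_count:
        raise ValueError(
            f"frame count {len(frames)} inconsistent with tile grid "
            f"{grid.cols}x{grid.rows} = {grid.frame_count} for level "
            f"{plan_entry.out_width}x{plan_entry.out_height}"
        )
    ds = Dataset()
    ds.SOPClassUID = UID(VL_WSI_SOP_CLASS)
    ds.SOPInstanceUID = UID(uids.sop_uid)
    ds.StudyInstanceUID = UID(uids.study_uid)
    ds.SeriesInstanceUID = UID(uids.series_uid)
    ds.PatientID = uids.patient_id[:64]
    ds.PatientName = Path(source_name).stem or "UNKNOWN"
    ds.Modality = "SM"
    ds.ImageType = ["DERIVED", "PRIMARY", "VOLUME", "NONE"]
    ds.SamplesPerPixel = 3
    ds.PhotometricInterpretation = "YBR_FULL_422"
    ds.PlanarConfiguration = 0
    ds.Rows = tile_size
    ds.Columns = tile_size
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.NumberOfFrames = len(frames)
    ds.TotalPixelMatrixColumns = plan_entry.out_width
    ds.TotalPixelMatrixRows = plan_entry.out_height
    ds.DimensionOrganizationType = "TILED_FULL"  # row-major full tiling
    ds.LossyImageCompression = "01"
    ds.LossyImageCompressionMethod = "ISO_10918_1"

    meta = pyramid_meta or {}
    block = ds.private_block(PRIVATE_GROUP, PRIVATE_CREATOR, create=True)
    block.add_new(0x11, "LO", meta.get("device_maker", ""))
    block.add_new(0x12, "LO", meta.get("capture_mode", ""))
    block.add_new(0x13, "LO", meta.get("device_model", ""))
    block.add_new(0x14, "LO", plan_entry.mode)

    ds.PixelData = encapsulate(list(frames))
    ds["PixelData"].VR = "OB"
    return DicomInstanceSpec(
        attributes=ds,
        sop_class_uid=VL_WSI_SOP_CLASS,
        transfer_syntax_uid=JPEG_BASELINE,
        pixel_payload=list(frames),
        frame_count=len(frames),
    )


def convert_wsi(
    path: str | os.PathLike,
    out_dir: str | os.PathLike,
    tile_size: int = DEFAULT_TILE_SIZE,
    jpeg_quality: int = DEFAULT_JPEG_QUALITY,
    pyramid_meta: dict | None = None,
) -> dict:
    """DICOMize a pyramid: one folder per focal plane, one file per level.

    The series index equals the z-plane index; instance indices count the
    emitted files within each series, widest level first.
    """
    src = Path(path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pyramid = ingest.read_pyramid(src)
    patient_id = derive_patient_id(src)
    plan = plan_levels(pyramid, tile_size)

    folders = []
    written_dirs: list[Path] = []
    try:
        for z in range(pyramid.z_planes):
            folder = out_dir / f"stack_{z:02d}"
            folder.mkdir(exist_ok=True)
            written_dirs.append(folder)
            files = []
            for instance_index, entry in enumerate(plan):
                lvl = pyramid.levels[entry.source_level_index]
                accessor: RegionAccessor = (
                    lambda x, y, w, h, _lvl=lvl, _z=z: _lvl.read_region(x, y, w, h, _z)
                )
                tiles = tile_level(
                    accessor, entry.out_width, entry.out_height, entry.mode,
                    tile_size, pyramid.background_value,
                )
                frames = encode_frames(tiles, jpeg_quality)
                uids = derive_uids(patient_id, series_index=z, instance_index=instance_index)
                spec = build_wsi_instance(
                    entry, frames, uids, pyramid_meta, tile_size, pyramid.source_name
                )
                spec.attributes.InstanceNumber = instance_index + 1
                spec.attributes.SeriesNumber = z + 1
                fname = folder / f"level_{instance_index:02d}.dcm"
                write_instance(spec, fname)
                files.append(
                    {
                        "file": fname.name,
                        "mode": entry.mode,
                        "level_width": entry.out_width,
                        "level_height": entry.out_height,
                        "frame_count": len(frames),
                        "sop_instance_uid": uids.sop_uid,
                    }
                )
            folders.append({"folder": folder.name, "series_uid": f"1.{patient_id}.{z}", "files": files})
    except Exception:
        for d in written_dirs:
            shutil.rmtree(d, ignore_errors=True)
        raise

    manifest = {
        "kind": "wsi",
        "source": src.name,
        "patient_id": patient_id,
        "study_uid": f"1.{patient_id}",
        "z_planes": pyramid.z_planes,
        "tile_size": tile_size,
        "jpeg_quality": jpeg_quality,
        "n_levels": len(plan),
        "planned_levels": [
            {"mode": e.mode, "width": e.out_width, "height": e.out_height,
             "source_level": e.source_level_index}
            for e in plan
        ],
        "folders": folders,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
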
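"""In-memory domain model shared by the conversion pipelines.

The converters never touch files directly through these types: ingestion
builds them, the DICOMizers consume them.  The pixel model is a 5-axis
``X, Y, C, Z, T`` volume for microscope stacks (width, height, channel,
focal plane, time point) and an ordered list of resolution levels for
whole-slide pyramids.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ModelError",
    "ChannelInfo",
    "ImageVolume",
    "PyramidLevel",
    "PyramidImage",
    "LevelPlanEntry",
    "LevelPlan",
    "DicomInstanceSpec",
    "UIDSet",
    "is_valid_uid",
]

#: dotted-decimal UID grammar: digit components, no leading zeros (lone "0" ok)
_UID_RE = re.compile(r"^(0|[1-9][0-9]*)(\.(0|[1-9][0-9]*))*$")
UID_MAX_LENGTH = 64

VALID_BIT_DEPTHS = (8, 12, 16)


class ModelError(ValueError):
    """A domain type was constructed with a violated invariant."""


def is_valid_uid(uid: str) -> bool:
    """True when *uid* is dotted-decimal, ≤ 64 chars, with no leading zeros."""
    return bool(uid) and len(uid) <= UID_MAX_LENGTH and _UID_RE.match(uid) is not None


@dataclass
class ChannelInfo:
    """Acquisition metadata for one fluorescence (or EM) channel."""

    channel_id: str
    channel_name: str = ""
    illumination_type: str = ""
    magnification: str = ""
    excitation_nm: float | None = None
    emission_nm: float | None = None

    def __post_init__(self) -> None:
        if not self.channel_id:
            raise ModelError("ChannelInfo.channel_id must be non-empty")


@dataclass
class ImageVolume:
    """A 5-axis grayscale pixel volume ordered X, Y, C, Z, T.

    ``pixels[x, y, c, z, t]`` is the intensity of column *x*, row *y* of
    channel *c* at focal plane *z* and time point *t*.  12-bit data is
    carried in a 16-bit container with ``bit_depth == 12``.
    """

    pixels: np.ndarray
    bit_depth: int
    channels: list[ChannelInfo]
    pixel_size: tuple[float, float, float] | None = None  # µm per voxel (x, y, z)
    source_name: str = ""

    def __post_init__(self) -> None:
        if self.pixels.ndim != 5:
            raise ModelError(
                f"ImageVolume.pixels must have 5 axes (X,Y,C,Z,T), got {self.pixels.ndim}"
            )
        if self.bit_depth not in VALID_BIT_DEPTHS:
            raise ModelError(
                f"ImageVolume.bit_depth must be one of {VALID_BIT_DEPTHS}, got {self.bit_depth}"
            )
        nx, ny, nc, nz, nt = self.pixels.shape
        if min(nc, nz, nt) < 1 or min(nx, ny) < 1:
            raise ModelError(f"ImageVolume.pixels has an empty axis: shape {self.pixels.shape}")
        if self.pixels.size and int(self.pixels.max()) >= 2**self.bit_depth:
            raise ModelError(
                f"ImageVolume.pixels max {int(self.pixels.max())} exceeds "
                f"bit_depth {self.bit_depth} range"
            )
        if len(self.channels) != nc:
            raise ModelError(
                f"ImageVolume.channels length {len(self.channels)} != C axis {nc}"
            )

    @property
    def shape_xyczt(self) -> tuple[int, int, int, int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def slice2d(self, c: int, z: int, t: int) -> np.ndarray:
        """The (rows, columns) = (Y, X) image of one channel/plane/time point."""
        return np.ascontiguousarray(self.pixels[:, :, c, z, t].T)


class PyramidLevel:
    """One resolution level of a whole-slide pyramid.

    Pixel access goes through :meth:`read_region`, which returns the
    requested rectangle clipped at the level edges.  Access is pure:
    repeated reads of the same region return identical pixels.
    """

    def __init__(self, data: np.ndarray, downsample_vs_base: float) -> None:
        # data: (Z, H, W, 3) uint8
        if data.ndim != 4 or data.shape[-1] != 3:
            raise ModelError(f"PyramidLevel.data must be (Z, H, W, 3), got {data.shape}")
        if data.shape[1] < 1 or data.shape[2] < 1:
            raise ModelError(f"PyramidLevel.width/height must be >= 1, got {data.shape}")
        if downsample_vs_base < 1:
            raise ModelError(
                f"PyramidLevel.downsample_vs_base must be >= 1, got {downsample_vs_base}"
            )
        self._data = data
        self.downsample_vs_base = float(downsample_vs_base)

    @property
    def width(self) -> int:
        return self._data.shape[2]

    @property
    def height(self) -> int:
        return self._data.shape[1]

    @property
    def z_planes(self) -> int:
        return self._data.shape[0]

    def read_region(self, x: int, y: int, w: int, h: int, z: int = 0) -> np.ndarray:
        """RGB pixels of the rectangle (x, y, w, h), clipped at the edges.

        The result may be smaller than (h, w, 3) near the borders and empty
        when the rectangle lies entirely outside the level.
        """
        if w < 0 or h < 0:
            raise ModelError(f"read_region: negative extent ({w}, {h})")
        x0, y0 = max(x, 0), max(y, 0)
        x1 = min(x + w, self.width)
        y1 = min(y + h, self.height)
        if x1 <= x0 or y1 <= y0:
            return np.empty((0, 0, 3), dtype=self._data.dtype)
        return self._data[z, y0:y1, x0:x1, :].copy()


@dataclass
class PyramidImage:
    """An ordered multi-resolution RGB image with optional focal planes."""

    levels: list[PyramidLevel]
    z_planes: int = 1
    background_value: tuple[int, int, int] = (255, 255, 255)
    source_name: str = ""

    def __post_init__(self) -> None:
        if not self.levels:
            raise ModelError("PyramidImage.levels must be non-empty")
        widths = [lvl.width for lvl in self.levels]
        if any(b >= a for a, b in zip(widths, widths[1:])):
            raise ModelError(f"PyramidImage.levels widths must strictly decrease, got {widths}")
        if self.z_planes < 1:
            raise ModelError(f"PyramidImage.z_planes must be >= 1, got {self.z_planes}")
        for i, lvl in enumerate(self.levels):
            if lvl.z_planes != self.z_planes:
                raise ModelError(
                    f"PyramidImage.levels[{i}] has {lvl.z_planes} z-planes, "
                    f"expected z_planes == {self.z_planes}"
                )

    @property
    def base(self) -> PyramidLevel:
        return self.levels[0]


Mode = Literal["native", "synthesized"]


@dataclass(frozen=True)
class LevelPlanEntry:
    """One output resolution level: a source level kept as-is (``native``)
    or its 2× area-averaged reduction (``synthesized``)."""

    source_level_index: int
    mode: Mode
    out_width: int
    out_height: int
    source_width: int
    source_height: int

    def __post_init__(self) -> None:
        if self.mode not in ("native", "synthesized"):
            raise ModelError(f"LevelPlanEntry.mode must be native|synthesized, got {self.mode!r}")
        if self.mode == "native":
            if (self.out_width, self.out_height) != (self.source_width, self.source_height):
                raise ModelError(
                    "LevelPlanEntry.out_width/out_height must preserve source dimensions "
                    f"for native entries, got {(self.out_width, self.out_height)} vs "
                    f"{(self.source_width, self.source_height)}"
                )
        else:
            expect = (self.source_width // 2, self.source_height // 2)
            if (self.out_width, self.out_height) != expect:
                raise ModelError(
                    "LevelPlanEntry.out_width/out_height must be floor(source/2) for "
                    f"synthesized entries, got {(self.out_width, self.out_height)} vs {expect}"
                )


@dataclass
class LevelPlan:
    """The post-synthesis list of output resolution levels, widest first."""

    entries: list[LevelPlanEntry]

    def __post_init__(self) -> None:
        dims = [(e.out_width, e.out_height) for e in self.entries]
        if len(set(dims)) != len(dims):
            raise ModelError(f"LevelPlan.entries contains duplicate dimensions: {dims}")
        widths = [e.out_width for e in self.entries]
        if widths != sorted(widths, reverse=True):
            raise ModelError(f"LevelPlan.entries must be sorted by out_width descending: {widths}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


@dataclass
class DicomInstanceSpec:
    """Everything needed to serialize one output DICOM file.

    ``attributes`` is a pydicom dataset (tag → VR/value); the pixel payload
    is either raw frame bytes (uncompressed single-frame path) or a list of
    independently encoded compressed frames (encapsulated multi-frame path).
    """

    attributes: "object"  # pydicom.Dataset; kept untyped to keep this module I/O-free
    sop_class_uid: str
    transfer_syntax_uid: str
    pixel_payload: bytes | list[bytes]
    frame_count: int

    def __post_init__(self) -> None:
        for name in ("sop_class_uid", "transfer_syntax_uid"):
            value = getattr(self, name)
            if not is_valid_uid(value):
                raise ModelError(f"DicomInstanceSpec.{name} is not a valid UID: {value!r}")
        if isinstance(self.pixel_payload, bytes):
            if self.frame_count != 1:
                raise ModelError(
                    f"DicomInstanceSpec.frame_count must be 1 for the raw single-frame "
                    f"path, got {self.frame_count}"
                )
        else:
            if self.frame_count != len(self.pixel_payload):
                raise ModelError(
                    f"DicomInstanceSpec.frame_count {self.frame_count} != number of "
                    f"encapsulated frames {len(self.pixel_payload)}"
                )


@dataclass(frozen=True)
class UIDSet:
    """Patient/study/series/SOP identifiers derived from a content hash.

    The hierarchy nests by construction: ``study = "1." + patient_id``,
    ``series = study + "." + i``, ``sop = series + "." + j``.
    """

    patient_id: str
    study_uid: str
    series_uid: str
    sop_uid: str

    def __post_init__(self) -> None:
        if not re.match(r"^(0|[1-9][0-9]*)$", self.patient_id):
            raise ModelError(f"UIDSet.patient_id must be plain decimal, got {self.patient_id!r}")
        if self.study_uid != "1." + self.patient_id:
            raise ModelError(
                f"UIDSet.study_uid must equal '1.' + patient_id, got {self.study_uid!r}"
            )
        if not self.series_uid.startswith(self.study_uid + "."):
            raise ModelError(
                f"UIDSet.series_uid must extend study_uid, got {self.series_uid!r}"
            )
        if not self.sop_uid.startswith(self.series_uid + "."):
            raise ModelError(f"UIDSet.sop_uid must extend series_uid, got {self.sop_uid!r}")
        for name in ("study_uid", "series_uid", "sop_uid"):
            value = getattr(self, name)
            if not is_valid_uid(value):
                raise ModelError(f"UIDSet.{name} is not a valid UID: {value!r}")
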
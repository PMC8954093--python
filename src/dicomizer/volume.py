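"""Convert XYCZT volumes into single-frame DICOM instances.

Each (channel, z, t) optical section becomes one VL Microscopic Image
Storage file, uncompressed, explicit VR little-endian.  Per-channel
acquisition metadata (channel name, dimension order, illumination, pixel
size, channel ID, magnification) is carried in a private tag block because
the standard microscopy IOD has no public slots for it.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import UID, PYDICOM_IMPLEMENTATION_UID

from . import ingest
from .model import ChannelInfo, DicomInstanceSpec, ImageVolume, UIDSet
from .uid import derive_patient_id, derive_patient_id_from_paths, derive_uids

__all__ = [
    "VL_MICROSCOPIC_SOP_CLASS",
    "EXPLICIT_VR_LE",
    "PRIVATE_GROUP",
    "PRIVATE_CREATOR",
    "plan_instances",
    "build_instance",
    "embed_private_tags",
    "write_instance",
    "convert_volume",
]

VL_MICROSCOPIC_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.77.1.2"
EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"

PRIVATE_GROUP = 0x0099
PRIVATE_CREATOR = "DICOMIZER MICROSCOPY 1.0"

#: (Bits Allocated, Bits Stored, High Bit) per source bit depth;
#: High Bit = Bits Stored - 1, 12-bit rides in a 16-bit container
_BIT_LAYOUT = {8: (8, 8, 7), 12: (16, 12, 11), 16: (16, 16, 15)}


def plan_instances(volume: ImageVolume) -> list[tuple[int, int, int]]:
    """Channel-major ordering of all (c, z, t) slices; one instance each."""
    _, _, nc, nz, nt = volume.shape_xyczt
    return [(c, z, t) for c in range(nc) for z in range(nz) for t in range(nt)]


def build_instance(
    volume: ImageVolume, channel_idx: int, z_idx: int, t_idx: int, uids: UIDSet
) -> DicomInstanceSpec:
    """One uncompressed single-frame dataset for one optical section."""
    if volume.bit_depth not in _BIT_LAYOUT:
        raise ValueError(f"unsupported bit depth {volume.bit_depth} (expected 8, 12 or 16)")
    allocated, stored, high = _BIT_LAYOUT[volume.bit_depth]
    sl = volume.slice2d(channel_idx, z_idx, t_idx)  # (rows, cols)
    if allocated == 16:
        payload = sl.astype("<u2").tobytes()
    else:
        payload = sl.astype(np.uint8).tobytes()

    ds = Dataset()
    ds.SOPClassUID = UID(VL_MICROSCOPIC_SOP_CLASS)
    ds.SOPInstanceUID = UID(uids.sop_uid)
    ds.StudyInstanceUID = UID(uids.study_uid)
    ds.SeriesInstanceUID = UID(uids.series_uid)
    ds.PatientID = uids.patient_id[:64]
    ds.PatientName = Path(volume.source_name).stem or "UNKNOWN"
    ds.Modality = "GM"
    ds.SeriesNumber = 1
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = sl.shape
    ds.BitsAllocated = allocated
    ds.BitsStored = stored
    ds.HighBit = high
    ds.PixelRepresentation = 0
    if volume.pixel_size is not None:
        ds.PixelSpacing = [f"{volume.pixel_size[1] / 1000:.6f}", f"{volume.pixel_size[0] / 1000:.6f}"]
    ds.PixelData = payload
    return DicomInstanceSpec(
        attributes=ds,
        sop_class_uid=VL_MICROSCOPIC_SOP_CLASS,
        transfer_syntax_uid=EXPLICIT_VR_LE,
        pixel_payload=payload,
        frame_count=1,
    )


def embed_private_tags(
    spec: DicomInstanceSpec,
    channel_info: ChannelInfo,
    volume_meta: ImageVolume | None = None,
    private_creator: str = PRIVATE_CREATOR,
) -> DicomInstanceSpec:
    """Record microscope acquisition metadata in one reserved private block.

    Elements (offset within the block): 0x01 channel name, 0x02 dimension
    order, 0x03 illumination type, 0x04 physical pixel size with units,
    0x05 channel ID, 0x06 magnification.  Absent fields are written empty.
    """
    ds: Dataset = spec.attributes
    block = ds.private_block(PRIVATE_GROUP, private_creator, create=True)
    if volume_meta is not None and volume_meta.pixel_size is not None:
        px = volume_meta.pixel_size
        pixel_size_text = f"{px[0]:g} um x {px[1]:g} um x {px[2]:g} um"
    else:
        pixel_size_text = ""
    block.add_new(0x01, "LO", channel_info.channel_name or "")
    block.add_new(0x02, "LO", "XYCZT")
    block.add_new(0x03, "LO", channel_info.illumination_type or "")
    block.add_new(0x04, "LO", pixel_size_text)
    block.add_new(0x05, "LO", channel_info.channel_id or "")
    block.add_new(0x06, "LO", channel_info.magnification or "")
    return spec


def read_private_tags(ds: Dataset, private_creator: str = PRIVATE_CREATOR) -> dict[str, str]:
    """Parse the private block back into its six text fields."""
    block = ds.private_block(PRIVATE_GROUP, private_creator)
    names = ["channel_name", "dimension_order", "illumination_type",
             "pixel_size", "channel_id", "magnification"]
    return {name: str(block[0x01 + i].value) for i, name in enumerate(names)}


def write_instance(spec: DicomInstanceSpec, path: str | os.PathLike) -> Path:
    """Serialize a spec as a DICOM Part 10 file (preamble + DICM magic)."""
    ds: Dataset = spec.attributes
    fm = FileMetaDataset()
    fm.MediaStorageSOPClassUID = UID(spec.sop_class_uid)
    fm.MediaStorageSOPInstanceUID = UID(ds.SOPInstanceUID)
    fm.TransferSyntaxUID = UID(spec.transfer_syntax_uid)
    fm.ImplementationClassUID = UID(PYDICOM_IMPLEMENTATION_UID)
    ds.file_meta = fm
    path = Path(path)
    ds.save_as(path, enforce_file_format=True)
    return path


def convert_volume(
    path: str | os.PathLike,
    out_dir: str | os.PathLike,
    private_creator: str = PRIVATE_CREATOR,
) -> dict:
    """DICOMize a volume file: one Part 10 file per (channel, z, t) slice.

    All instances share one study and one series; SOP instance UIDs are
    sequential.  Returns (and writes) a manifest describing every file.
    Partially written outputs are removed when the conversion fails.
    """
    src = Path(path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    volume = ingest.read_volume(src)
    if src.is_dir():
        patient_id = derive_patient_id_from_paths(sorted(src.glob("*.png")))
    else:
        patient_id = derive_patient_id(src)

    written: list[Path] = []
    entries = []
    try:
        for instance_index, (c, z, t) in enumerate(plan_instances(volume)):
            uids = derive_uids(patient_id, series_index=0, instance_index=instance_index)
            spec = build_instance(volume, c, z, t, uids)
            spec.attributes.InstanceNumber = instance_index + 1
            embed_private_tags(spec, volume.channels[c], volume, private_creator)
            fname = out_dir / f"instance_{instance_index:05d}.dcm"
            write_instance(spec, fname)
            written.append(fname)
            entries.append(
                {"file": fname.name, "channel": c, "z": z, "t": t,
                 "sop_instance_uid": uids.sop_uid}
            )
    except Exception:
        for f in written:
            f.unlink(missing_ok=True)
        raise

    manifest = {
        "kind": "volume",
        "source": src.name,
        "patient_id": patient_id,
        "study_uid": f"1.{patient_id}",
        "series_uid": f"1.{patient_id}.0",
        "shape_xyczt": list(volume.shape_xyczt),
        "bit_depth": volume.bit_depth,
        "n_instances": len(entries),
        "instances": entries,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
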
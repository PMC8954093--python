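"""Content-hash identifier hierarchy.

Every converted sample gets a patient ID derived from the SHA-1 digest of
its source bytes, rendered in decimal.  Study, series and SOP instance UIDs
nest under it::

    patient  186355…481          (SHA-1 of the file, base 10)
    study    1.186355…481
    series   1.186355…481.0      (series index: z-plane for WSI, 0 for volumes)
    sop      1.186355…481.0.23   (instance index within the series)

The leading "1." is reproduced from the scheme this package implements; it
is not a registered UID root.
"""

from __future__ import annotations

import hashlib
import os
from pathlib import Path
from typing import BinaryIO, Iterable

from .model import ModelError, UIDSet, UID_MAX_LENGTH

__all__ = ["derive_patient_id", "derive_patient_id_from_paths", "derive_uids"]

_CHUNK = 1 << 20


def derive_patient_id(source: bytes | BinaryIO | str | os.PathLike) -> str:
    """SHA-1 of the complete source byte stream as unsigned decimal text.

    The 160-bit digest is interpreted as a big-endian unsigned integer and
    rendered in base 10 (at most 49 digits, no leading zeros).  Accepts raw
    bytes, a readable binary stream, or a filesystem path (hashed
    incrementally).
    """
    sha = hashlib.sha1()
    n = 0
    if isinstance(source, bytes):
        sha.update(source)
        n = len(source)
    elif isinstance(source, (str, os.PathLike)):
        with open(source, "rb") as fh:
            while chunk := fh.read(_CHUNK):
                sha.update(chunk)
                n += len(chunk)
    else:
        while chunk := source.read(_CHUNK):
            sha.update(chunk)
            n += len(chunk)
    if n == 0:
        raise ValueError("derive_patient_id: empty byte stream (pass the real file bytes)")
    return str(int.from_bytes(sha.digest(), "big"))


def derive_patient_id_from_paths(paths: Iterable[str | os.PathLike]) -> str:
    """One digest over several files, hashed in lexicographic name order.

    Used for multi-file inputs such as per-slice image directories.
    """
    ordered = sorted(Path(p) for p in paths)
    if not ordered:
        raise ValueError("derive_patient_id_from_paths: no files given")
    sha = hashlib.sha1()
    n = 0
    for p in ordered:
        with open(p, "rb") as fh:
            while chunk := fh.read(_CHUNK):
                sha.update(chunk)
                n += len(chunk)
    if n == 0:
        raise ValueError("derive_patient_id_from_paths: all files empty")
    return str(int.from_bytes(sha.digest(), "big"))


def derive_uids(patient_id: str, series_index: int, instance_index: int) -> UIDSet:
    """Build the nested study/series/SOP identifier set for one instance.

    Raises when any resulting UID would exceed the 64-character DICOM limit;
    identifiers are never silently truncated.
    """
    if series_index < 0 or instance_index < 0:
        raise ValueError(
            f"derive_uids: indices must be non-negative, got "
            f"series={series_index}, instance={instance_index}"
        )
    study = f"1.{patient_id}"
    series = f"{study}.{series_index}"
    sop = f"{series}.{instance_index}"
    for name, value in (("study_uid", study), ("series_uid", series), ("sop_uid", sop)):
        if len(value) > UID_MAX_LENGTH:
            raise ModelError(
                f"derive_uids: {name} exceeds {UID_MAX_LENGTH} characters "
                f"({len(value)}): {value}"
            )
    return UIDSet(patient_id=patient_id, study_uid=study, series_uid=series, sop_uid=sop)
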
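"""Read-back validation of converted output trees.

Replays every emitted Part 10 file through pydicom and checks, per file:
parseability, UID grammar, tile-grid/frame-count arithmetic, and pixel
decodability; and per conversion: a single study UID, one series per
folder, and pairwise-distinct SOP instance UIDs.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import pydicom

from .model import is_valid_uid

__all__ = ["ValidationReport", "validate"]


@dataclass
class ValidationReport:
    n_files: int = 0
    failures: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures

    def fail(self, path: str | Path, message: str) -> None:
        self.failures.append((str(path), message))

    def summary(self) -> str:
        lines = [f"checked {self.n_files} files, {len(self.failures)} failure(s)"]
        lines += [f"  {p}: {m}" for p, m in self.failures]
        return "\n".join(lines)


def validate(dicom_dir: str | os.PathLike) -> ValidationReport:
    """Validate one conversion output directory (recursively)."""
    root = Path(dicom_dir)
    if not root.is_dir():
        raise IOError(f"not a readable directory: {root}")
    report = ValidationReport()
    study_uids: set[str] = set()
    sop_uids: dict[str, str] = {}
    series_by_folder: dict[Path, set[str]] = {}

    files = sorted(root.rglob("*.dcm"))
    report.n_files = len(files)
    if not files:
        report.fail(root, "no DICOM files found")
        return report

    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception as exc:
            report.fail(f, f"unparseable: {exc}")
            continue
        for kw in ("SOPClassUID", "SOPInstanceUID", "StudyInstanceUID", "SeriesInstanceUID"):
            value = str(getattr(ds, kw, ""))
            if not is_valid_uid(value):
                report.fail(f, f"invalid {kw}: {value!r}")
        study_uids.add(str(getattr(ds, "StudyInstanceUID", "")))
        sop = str(getattr(ds, "SOPInstanceUID", ""))
        if sop in sop_uids:
            report.fail(f, f"duplicate SOPInstanceUID {sop} (also in {sop_uids[sop]})")
        else:
            sop_uids[sop] = str(f)
        series_by_folder.setdefault(f.parent, set()).add(str(getattr(ds, "SeriesInstanceUID", "")))

        n_frames = int(getattr(ds, "NumberOfFrames", 1))
        if "TotalPixelMatrixColumns" in ds:
            cols = math.ceil(ds.TotalPixelMatrixColumns / ds.Columns)
            rows = math.ceil(ds.TotalPixelMatrixRows / ds.Rows)
            if n_frames != cols * rows:
                report.fail(
                    f,
                    f"frame count {n_frames} != grid {cols}x{rows} = {cols * rows}",
                )
        try:
            arr = ds.pixel_array
            expect_frames = (n_frames,) if n_frames > 1 else ()
            if arr.shape[: len(expect_frames)] != expect_frames:
                report.fail(f, f"decoded frame count {arr.shape} != {n_frames}")
        except Exception as exc:
            report.fail(f, f"pixel data not decodable: {exc}")

    if len(study_uids) != 1:
        report.fail(root, f"expected a single study UID, found {len(study_uids)}")
    for folder, series in series_by_folder.items():
        if len(series) != 1:
            report.fail(folder, f"expected one series per folder, found {len(series)}")
    return report
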
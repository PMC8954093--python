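# dicomizer

Microscopy labs and pathology archives accumulate images in dozens of
container formats — confocal z-stacks, serial electron-microscopy section
series, gigapixel whole-slide pyramids — which keeps them outside the
standard medical-imaging infrastructure (PACS archives, DICOM viewers,
vendor-neutral exchange). `dicomizer` converts these three image classes
from open containers (OME-TIFF, plain TIFF, MRC2014, PNG slice
directories) into standard DICOM, preserving the acquisition metadata.

## What it does

**Volumes (CLSM / FIB-SEM).** A multichannel stack is modelled as a 5-axis
`X, Y, C, Z, T` volume. Every (channel, focal plane, time point) slice
becomes one single-frame *VL Microscopic Image Storage* instance
(SOP class `1.2.840.10008.5.1.4.1.1.77.1.2`), uncompressed, explicit VR
little-endian (`1.2.840.10008.1.2.1`), `MONOCHROME2`, with
`(Bits Allocated, Bits Stored, High Bit)` = (8,8,7), (16,12,11) or
(16,16,15) for 8/12/16-bit data. A conversion of a C-channel, Z-plane,
T-point volume therefore emits exactly C·Z·T files sharing one study and
one series. Channel name, dimension order, illumination type, pixel size,
channel ID and magnification travel in a reserved private tag block.

**Whole-slide pyramids.** Each resolution level is cut into 512×512 tiles
(row-major), each tile JPEG-baseline encoded (quality 90, 4:2:2) as one
frame of a multi-frame *VL Whole Slide Microscopy Image Storage* instance
(SOP class `…77.1.6`, transfer syntax `1.2.840.10008.1.2.4.50`,
`YBR_FULL_422`, 3 samples per pixel). Sparse pyramids — adjacent levels 4×
apart per axis, a common scanner layout — force viewers to fetch huge tile
counts between magnifications. To close these *zoom gaps* the planner
emits, for every source level, both the level itself and a synthesized
half-resolution rendition (2×2 area averaging, output dimensions
⌊source/2⌋); a synthesized candidate is dropped when a native level
already has those dimensions (±1 px). A 5-level 4×-spaced pyramid thus
emits 10 levels, while a dense 9-level 2×-spaced pyramid emits 10 (only
the deepest level's half is new). One output folder (= one series) is
written per focal plane.

**Identifiers.** Every sample gets a patient ID equal to the SHA-1 digest
of its source bytes rendered in decimal (≤ 49 digits); study, series and
SOP instance UIDs nest under it as `1.<id>`, `1.<id>.<series>`,
`1.<id>.<series>.<instance>`, with the series index equal to the focal
plane for slides and 0 for volumes.

**Fallback.** A tiled RGB TIFF whose reduced-resolution levels are absent
(and that carries no OME metadata) is first rebuilt as a tiled pyramidal
OME-TIFF — levels halved by area averaging until the smaller dimension is
≤ 512, tiles JPEG-compressed at quality 90 — and then converted like any
other pyramid.

## Worked example

```
$ dicomizer generate clsm /tmp/demo.ome.tif --channels 3 --z-planes 46 --xy 64
/tmp/demo.ome.tif
$ dicomizer convert /tmp/demo.ome.tif --out /tmp/demo_dcm
{"manifest": "/tmp/demo_dcm/manifest.json", "n_instances": 138}
$ dicomizer validate /tmp/demo_dcm
checked 138 files, 0 failure(s)
```

The generated stack has 3 channels × 46 focal planes, so the conversion
emits 138 DICOM files (instances `1.<sha1-decimal>.0.0` …
`….0.137`), and the validator re-reads every file, checks UID grammar,
frame arithmetic and pixel decodability, and confirms they form a single
study with one series.

The same flow for a slide pyramid:

```
$ dicomizer generate wsi /tmp/slide.ome.tif --n-levels 5 --level-ratio 4 \
    --base-width 2048 --base-height 1024 --z-planes 11
$ dicomizer convert /tmp/slide.ome.tif --out /tmp/slide_dcm
{"manifest": "/tmp/slide_dcm/manifest.json", "n_instances": 10}
```

This writes 11 folders `stack_00 … stack_10` (one per focal plane), each
holding 10 files `level_00 … level_09` — the 5 native levels plus 5
synthesized gap-filling levels.

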
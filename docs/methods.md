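# Methods

## Data model

All converters work on two in-memory types. A **volume** is a 5-axis array
ordered `X, Y, C, Z, T` (width, height, channel, focal plane, time point)
with a recorded bit depth in {8, 12, 16}; 12-bit data rides in a 16-bit
container, and the bit depth — not the container — drives the DICOM
`Bits Stored` / `High Bit` attributes. A **pyramid** is an ordered list of
RGB resolution levels, strictly decreasing in width, all sharing one focal
plane count; pixel access is by arbitrary rectangle, clipped at the level
edges. Ingestion reorders whatever layout the source file uses into these
shapes, so the DICOMizers never see file-format details.

## Ingestion and dispatch

Inputs are classified by content, never by extension: the MRC `MAP ` stamp
at byte 208, the TIFF magic, OME-XML in the first ImageDescription,
reduced-resolution SubIFDs or decreasing multi-page series. Four kinds
result: `volume` (grayscale stack), `em_stack` (MRC), `pyramid`
(multi-resolution RGB, including an OME-TIFF that declares a single
level), and `unrecognized_pyramid` (a single-level RGB TIFF without OME
metadata whose reduced levels are missing). The last kind is first rebuilt
as a tiled pyramidal OME-TIFF and re-enters the pipeline as a recognized
pyramid.

MRC modes map to bit depths as {0: 8, 1: 16, 2: float → min–max rescaled
to 16-bit, 6: 16}. Mode 0 is signed int8 in MRC2014 but serial-section EM
data is conventionally unsigned; values are reinterpreted as uint8 when
non-negative and shifted by +128 otherwise. Multi-file PNG stacks are read
in lexicographic filename order.

## Volume DICOMization

Instances are planned channel-major (`c` outer, then `z`, then `t`), one
single-frame file per slice, so a conversion emits exactly C·Z·T files —
the invariant the instance-count checks rest on. The transfer syntax is
explicit VR little-endian and the pixel payload is the raw slice
(little-endian for 16-bit containers), making the path bit-exact
reversible; tests assert the round trip at all three depths. Six
acquisition fields (channel name, dimension order `XYCZT`, illumination
type, pixel size with units, channel ID, magnification) are stored as text
in one reserved private block (group 0x0099, creator
`DICOMIZER MICROSCOPY 1.0`), because the microscopy IODs have no public
attributes for them; absent fields are written empty rather than omitted
so the read-back contract is uniform.

## Level planning and gap synthesis

For each source level the planner emits a native entry and a synthesized
candidate of ⌊source/2⌋ per axis, produced by 2×2 area averaging
(deterministic, alias-free; averages round half up so constant regions are
preserved exactly). A candidate is dropped when some native level matches
it within ±1 px on both axes — the tolerance absorbs floor-division
off-by-ones between ⌊⌊w/2ᵏ⌋/2⌋ and ⌊w/2ᵏ⁺¹⌋. Consequences: a 5-level
4×-spaced pyramid plans 10 levels and a 6-level one 12 (no candidate
collides), while a 9-level 2×-spaced pyramid plans 10 (every candidate but
the deepest collides). Synthesized levels smaller than one tile are kept;
only a candidate that would reach zero pixels on an axis is impossible and
skipped. Planning the plan's own native entries reproduces the plan — the
planner is a fixed point over its native set — and adding input levels
never shrinks the plan.

## Tiling and encoding

Output levels are cut into 512×512 tiles, row-major. Native tiles read the
source 1:1; synthesized tiles read the corresponding 1024×1024 source
rectangle and downsample by 2. Edge tiles are padded with the pyramid
background value — white (255,255,255), the brightfield slide background;
padding is applied after downsampling so the pad region is exact
background, not an averaged fringe. Each tile is an independently
decodable baseline JPEG (Pillow, quality 90 by default, explicit 4:2:2
chroma subsampling to match the declared `YBR_FULL_422` photometric
interpretation); frames are encapsulated with a basic offset table, and
`Number of Frames` always equals ⌈W/512⌉·⌈H/512⌉. Frame organization is
declared `TILED_FULL`, so frame index alone determines tile position.

## Identifier scheme

The patient ID is the SHA-1 digest of the complete source byte stream,
interpreted as a big-endian unsigned integer and rendered in decimal — at
most 49 digits, within the 64-character limit of the DICOM value
representations used. Study/series/SOP UIDs nest by string concatenation
(`1.<id>`, `.<series>`, `.<instance>`); worst case 49 digits + series +
instance stays under 64 characters for any realistic series/instance
count, and the derivation raises rather than truncates beyond it. The
series index is the focal-plane index for slides and 0 for volumes;
instance indices count emitted files within a series. The `1.` prefix is
part of the reproduced scheme, not a registered UID root. Multi-file
sources are hashed in lexicographic name order into a single digest.

## Synthetic data

The generators produce structure-faithful, content-synthetic inputs:
Gaussian-blob fluorescence channels with an axial intensity falloff
(confocal), correlated speckle with per-section drift (EM), and
hematoxylin/eosin-coloured blobs on a white background with per-plane
phase shifts (slides). Equal arguments give byte-identical files — the
OME-XML is emitted from a fixed template (constant UUID field) to keep the
writer deterministic. Textures exist so that JPEG round-trip assertions
are meaningful on non-constant images while staying far from the codec's
pure-noise worst case; they do not mimic vendor metadata blocks, optics,
stitching artifacts, or the file-size characteristics of real scanner
output. Passing tests therefore demonstrate structural and numerical
correctness of the conversion (counts, layouts, attributes, fidelity
bounds), not robustness to vendor-specific container quirks.

Default test-scale geometries (64×64 or smaller slices, slide bases
around 2048×1024) keep the full suite at roughly two minutes and the
acceptance run near one minute on one CPU; every reproduced count is
invariant to these scales because instance counts depend only on axis
lengths and level counts only on the level-dimension lattice.

## Numerical choices and degenerate inputs

JPEG fidelity checks use mean absolute error < 10 for one quality-90
round trip and a max deviation ≤ 2 for constant tiles. The validator
re-parses every written file and enforces UID grammar (dotted decimal, no
leading zeros, ≤ 64 chars), grid arithmetic, pixel decodability, single
study per conversion, one series per folder, and pairwise-distinct SOP
UIDs. Zero-byte files, truncated pixel data (reported with expected vs
actual byte counts), inconsistent z-plane counts, and output-path
collisions are all rejected with diagnostics rather than repaired.
Pyramidalization stops once the smaller dimension is ≤ 512 — levels below
one tile add no navigation value — and is structurally idempotent.

## Known limitations

* No native decoders for proprietary vendor containers; inputs must be in
  the supported open formats (or be converted upstream).
* No ICC profiles, label/macro images, sparse tiling, or DICOM network
  services; outputs are files on disk plus a JSON manifest.
* Time-series volumes (T > 1) are supported by extension of the axis
  model but exercised only synthetically.
* The OME-XML emitted is a minimal subset — sufficient for the readers
  here and for tifffile's OME series detection, not a full schema
  implementation.
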
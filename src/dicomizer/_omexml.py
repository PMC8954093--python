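"""Minimal deterministic OME-XML emission and parsing.

The writer emits just the subset of the OME 2016-06 schema the readers in
this package (and tifffile's OME series detection) need: Pixels geometry,
dimension order, per-channel acquisition metadata, and an objective
magnification.  The UUID attribute is a fixed placeholder so that equal
inputs produce byte-identical files.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from .model import ChannelInfo

_OME_NS = "http://www.openmicroscopy.org/Schemas/OME/2016-06"
_FIXED_UUID = "urn:uuid:00000000-0000-0000-0000-000000000000"

_HEADER = (
    '<?xml version="1.0" encoding="UTF-8"?>'
    f'<OME xmlns="{_OME_NS}" UUID="{_FIXED_UUID}" Creator="dicomizer">'
)


def _esc(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;").replace('"', "&quot;")
    )


@dataclass
class OmeImageMeta:
    """Geometry and acquisition metadata recovered from (or written to) OME-XML."""

    size_x: int
    size_y: int
    size_c: int = 1
    size_z: int = 1
    size_t: int = 1
    dimension_order: str = "XYCZT"
    pixel_type: str = "uint8"
    significant_bits: int | None = None
    physical_size_xy_um: float | None = None
    physical_size_z_um: float | None = None
    interleaved: bool = False
    name: str = "image"
    magnification: str = ""
    channels: list[ChannelInfo] = field(default_factory=list)


def volume_xml(meta: OmeImageMeta) -> str:
    """OME-XML for a grayscale multichannel z-stack (one plane per page)."""
    parts = [_HEADER]
    if meta.magnification:
        parts.append(
            '<Instrument ID="Instrument:0">'
            f'<Objective ID="Objective:0" NominalMagnification="{_esc(meta.magnification)}"/>'
            "</Instrument>"
        )
    parts.append(f'<Image ID="Image:0" Name="{_esc(meta.name)}">')
    if meta.magnification:
        parts.append('<ObjectiveSettings ID="Objective:0"/>')
    attrs = (
        f'ID="Pixels:0" DimensionOrder="{meta.dimension_order}" Type="{meta.pixel_type}" '
        f'SizeX="{meta.size_x}" SizeY="{meta.size_y}" SizeC="{meta.size_c}" '
        f'SizeZ="{meta.size_z}" SizeT="{meta.size_t}" Interleaved="false"'
    )
    if meta.significant_bits:
        attrs += f' SignificantBits="{meta.significant_bits}"'
    if meta.physical_size_xy_um:
        attrs += (
            f' PhysicalSizeX="{meta.physical_size_xy_um}" PhysicalSizeXUnit="&#181;m"'
            f' PhysicalSizeY="{meta.physical_size_xy_um}" PhysicalSizeYUnit="&#181;m"'
        )
    if meta.physical_size_z_um:
        attrs += f' PhysicalSizeZ="{meta.physical_size_z_um}" PhysicalSizeZUnit="&#181;m"'
    parts.append(f"<Pixels {attrs}>")
    for i, ch in enumerate(meta.channels):
        ch_attrs = f'ID="Channel:0:{i}" SamplesPerPixel="1"'
        if ch.channel_name:
            ch_attrs += f' Name="{_esc(ch.channel_name)}"'
        if ch.illumination_type:
            ch_attrs += f' IlluminationType="{_esc(ch.illumination_type)}"'
        if ch.excitation_nm is not None:
            ch_attrs += f' ExcitationWavelength="{ch.excitation_nm:g}" ExcitationWavelengthUnit="nm"'
        if ch.emission_nm is not None:
            ch_attrs += f' EmissionWavelength="{ch.emission_nm:g}" EmissionWavelengthUnit="nm"'
        parts.append(f"<Channel {ch_attrs}/>")
    n_planes = meta.size_c * meta.size_z * meta.size_t
    parts.append(f'<TiffData IFD="0" PlaneCount="{n_planes}"/></Pixels></Image></OME>')
    return "".join(parts)


def pyramid_xml(meta: OmeImageMeta) -> str:
    """OME-XML for an interleaved RGB image with optional focal planes."""
    parts = [
        _HEADER,
        f'<Image ID="Image:0" Name="{_esc(meta.name)}">',
        f'<Pixels ID="Pixels:0" DimensionOrder="{meta.dimension_order}" '
        f'Type="{meta.pixel_type}" SizeX="{meta.size_x}" SizeY="{meta.size_y}" '
        f'SizeC="3" SizeZ="{meta.size_z}" SizeT="1" Interleaved="true">',
        '<Channel ID="Channel:0:0" SamplesPerPixel="3"/>',
        f'<TiffData IFD="0" PlaneCount="{meta.size_z}"/></Pixels></Image></OME>',
    ]
    return "".join(parts)


def parse(xml_text: str) -> OmeImageMeta:
    """Recover geometry and channel metadata from OME-XML text."""
    root = ET.fromstring(xml_text)

    def findall(elem, tag):
        return elem.findall(f"{{{_OME_NS}}}{tag}") + elem.findall(tag)

    images = findall(root, "Image")
    if not images:
        raise ValueError("OME-XML has no Image element")
    image = images[0]
    pixels = findall(image, "Pixels")[0]
    a = pixels.attrib
    meta = OmeImageMeta(
        size_x=int(a["SizeX"]),
        size_y=int(a["SizeY"]),
        size_c=int(a.get("SizeC", 1)),
        size_z=int(a.get("SizeZ", 1)),
        size_t=int(a.get("SizeT", 1)),
        dimension_order=a.get("DimensionOrder", "XYCZT"),
        pixel_type=a.get("Type", "uint8"),
        significant_bits=int(a["SignificantBits"]) if "SignificantBits" in a else None,
        physical_size_xy_um=float(a["PhysicalSizeX"]) if "PhysicalSizeX" in a else None,
        physical_size_z_um=float(a["PhysicalSizeZ"]) if "PhysicalSizeZ" in a else None,
        interleaved=a.get("Interleaved", "false").lower() == "true",
        name=image.attrib.get("Name", "image"),
    )
    for inst in findall(root, "Instrument"):
        for obj in findall(inst, "Objective"):
            if "NominalMagnification" in obj.attrib:
                meta.magnification = obj.attrib["NominalMagnification"]
    for i, ch in enumerate(findall(pixels, "Channel")):
        ca = ch.attrib
        meta.channels.append(
            ChannelInfo(
                channel_id=ca.get("ID", f"Channel:0:{i}"),
                channel_name=ca.get("Name", ""),
                illumination_type=ca.get("IlluminationType", ""),
                magnification=meta.magnification,
                excitation_nm=float(ca["ExcitationWavelength"])
                if "ExcitationWavelength" in ca
                else None,
                emission_nm=float(ca["EmissionWavelength"])
                if "EmissionWavelength" in ca
                else None,
            )
        )
    return meta
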
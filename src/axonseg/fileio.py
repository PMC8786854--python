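"""Raster, manifest and contour I/O.

Images are 8-bit single-channel PNG or TIFF; instance maps are 16-bit
single-channel PNG or TIFF.  Physical resolution survives a round-trip:
TIFF files carry it in the standard resolution tags (centimetre unit),
any other format gets a JSON sidecar next to the file.

Contours use a small package-defined XML dialect (schema in
``axonseg/data/contours.xsd``): one ``<contour>`` element per instance,
holding the outer boundary polygon in 0-based, y-down pixel coordinates
aligned with pixel corners.  This supports the expert-in-the-loop
workflow where automated detections are exported for human refinement
and read back after editing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
import tifffile
from PIL import Image as PILImage

from .core import GrayImage, InstanceMap

_NM_PER_CM = 1e7


# ---------------------------------------------------------------------------
# raster I/O


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(path, image: GrayImage) -> None:
    """Write an 8-bit grayscale image, preserving nm/px resolution."""
    path = Path(path)
    arr = image.pixels
    if arr.dtype != np.uint8:
        raise ValueError("write_image requires 8-bit data")
    if path.suffix.lower() in (".tif", ".tiff"):
        px_per_cm = _NM_PER_CM / image.resolution_nm_per_px
        tifffile.imwrite(
            path, arr, resolution=(px_per_cm, px_per_cm), resolutionunit="CENTIMETER"
        )
    else:
        PILImage.fromarray(arr, mode="L").save(path)
        _sidecar(path).write_text(
            json.dumps({"resolution_nm_per_px": image.resolution_nm_per_px})
        )


def read_image(path) -> GrayImage:
    """Read an 8-bit grayscale image written by :func:`write_image`."""
    path = Path(path)
    res = None
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            arr = page.asarray()
            tags = page.tags
            if "XResolution" in tags:
                num, den = tags["XResolution"].value
                unit = tags.get("ResolutionUnit")
                px_per_unit = num / den
                if px_per_unit > 0:
                    unit_nm = {2: 2.54e7, 3: 1e7}.get(
                        getattr(unit, "value", 3) if unit else 3, 1e7
                    )
                    res = unit_nm / px_per_unit
    else:
        arr = np.asarray(PILImage.open(path))
        sc = _sidecar(path)
        if sc.exists():
            res = json.loads(sc.read_text()).get("resolution_nm_per_px")
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit data, got {arr.dtype}")
    return GrayImage(arr, res if res else 11.9)


def write_instance_map(path, mask: InstanceMap) -> None:
    """Write an instance map as 16-bit single-channel PNG/TIFF."""
    path = Path(path)
    labels = mask.labels
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError(
            f"instance map holds label {labels.max()} > 65535; "
            "the 16-bit writer cannot represent it"
        )
    arr = labels.astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        PILImage.fromarray(arr).save(path)  # uint16 -> 16-bit grayscale PNG


def read_instance_map(path) -> InstanceMap:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(PILImage.open(path))
    return InstanceMap(np.asarray(arr, dtype=np.int32))


def write_classmap(path, classmap) -> None:
    """8-bit PNG/TIFF with the documented palette {0: bg, 1: fiber, 2: border}."""
    path = Path(path)
    arr = np.asarray(classmap.classes, dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        PILImage.fromarray(arr, mode="L").save(path)


def read_classmap(path):
    from .core import ClassMap

    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(PILImage.open(path))
    return ClassMap(arr)


# ---------------------------------------------------------------------------
# contours


@dataclass
class Contour:
    """Outer boundary of one instance: closed polygon in pixel-corner coords."""

    instance_id: int
    vertices: np.ndarray  # (N, 2) array of (row, col) corner coordinates
    area: float

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Contour)
            and self.instance_id == other.instance_id
            and np.allclose(self.vertices, other.vertices)
            and np.isclose(self.area, other.area)
        )


def mask_to_contours(mask: InstanceMap) -> list[Contour]:
    """Trace each instance's outer boundary at pixel-edge precision.

    The polygon of an instance is the exterior ring of the union of its
    pixels' unit squares, so for hole-free instances the shoelace area
    equals the pixel count exactly.
    """
    from shapely import box
    from shapely.ops import unary_union

    contours = []
    labels = mask.labels
    objects = _find_objects(labels)
    for lab, sl in objects:
        rows, cols = np.nonzero(labels[sl] == lab)
        rows = rows + sl[0].start
        cols = cols + sl[1].start
        squares = [box(c, r, c + 1, r + 1) for r, c in zip(rows, cols)]
        poly = unary_union(squares)
        if poly.geom_type == "MultiPolygon":  # 8-connected but 4-disconnected
            poly = max(poly.geoms, key=lambda g: g.area)
        xy = np.asarray(poly.exterior.coords)
        verts = np.column_stack([xy[:, 1], xy[:, 0]])  # back to (row, col)
        contours.append(Contour(int(lab), verts, float(poly.area)))
    return contours


def _find_objects(labels):
    from scipy import ndimage

    out = []
    slices = ndimage.find_objects(labels)
    for i, sl in enumerate(slices, start=1):
        if sl is not None:
            out.append((i, sl))
    return out


def write_contours_xml(contours: list[Contour], path, image_ref: str = "") -> None:
    """Write contours to the package XML dialect (units: pixels, y-down)."""
    root = ET.Element("contours", attrib={"units": "pixels", "image": image_ref})
    for c in contours:
        el = ET.SubElement(
            root,
            "contour",
            attrib={"id": str(c.instance_id), "area": repr(c.area)},
        )
        pts = " ".join(f"{r:g},{col:g}" for r, col in c.vertices)
        ET.SubElement(el, "points").text = pts
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


def read_contours_xml(path) -> list[Contour]:
    root = ET.parse(path).getroot()
    out = []
    for el in root.findall("contour"):
        pts = el.findtext("points") or ""
        plist = [[float(v) for v in p.split(",")] for p in pts.split()]
        verts = np.asarray(plist, dtype=float).reshape(-1, 2)
        out.append(Contour(int(el.get("id")), verts, float(el.get("area"))))
    return out


def contours_to_mask(contours: list[Contour], shape) -> InstanceMap:
    """Rasterize contours back to an instance map (plumbing for edited files)."""
    from skimage.draw import polygon

    labels = np.zeros(shape, dtype=np.int32)
    for c in contours:
        # vertices are pixel-corner coords; pixel centers are corners + 0.5
        rr, cc = polygon(c.vertices[:, 0] - 0.5, c.vertices[:, 1] - 0.5, shape)
        labels[rr, cc] = c.instance_id
    return InstanceMap(labels)
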